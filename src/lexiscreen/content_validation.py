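"""Expert content validation: CVR, retention decisions, rescue rule, CVI.

Each keyword is rated by a complete panel of experts as *essential*, *useful
but not essential* or *not necessary*.  The content validity ratio (CVR) per
keyword is, in this toolkit's default reading, the plain proportion of
panelists rating it essential; the classic Lawshe form
``(n_e - N/2) / (N/2)`` is available as an alternative.  Keywords at or
above the CVR threshold (default 0.75) are retained.  A keyword below the
threshold can still be rescued: with judgment points awarded per rating
(default essential=2, useful=1, not necessary=0), a keyword whose CVR lies
in [0, 0.5] and whose mean judgment points exceed 1.5 is accepted.

Whether the rescue rule can fire at all depends on the CVR formula and the
points map; :func:`rescue_trigger_compositions` enumerates every panel
composition (n_e, n_u, n_n) up to a panel size that triggers it, and
:func:`validate_lexicon` warns when the configured rule is vacuous (e.g. any
essential-only points scheme, where mean points > 1.5 already implies a CVR
above threshold).

The content validity index (CVI) is the mean CVR over retained keywords.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .lexicon_model import CATEGORY_IDS, Lexicon, LexiconFormatError

__all__ = [
    "Rating",
    "RatingTable",
    "ValidationConfig",
    "EntryResult",
    "ValidationResult",
    "RescueVacuousWarning",
    "cvr",
    "mean_judgment_points",
    "decide",
    "validate_lexicon",
    "rescue_trigger_compositions",
    "load_ratings",
    "save_ratings",
]


class Rating(str, Enum):
    """Three-level expert relevance judgment."""

    ESSENTIAL = "essential"
    USEFUL_NOT_ESSENTIAL = "useful_not_essential"
    NOT_NECESSARY = "not_necessary"


_RATING_TOKENS = {
    "e": Rating.ESSENTIAL,
    "essential": Rating.ESSENTIAL,
    "u": Rating.USEFUL_NOT_ESSENTIAL,
    "useful_not_essential": Rating.USEFUL_NOT_ESSENTIAL,
    "n": Rating.NOT_NECESSARY,
    "not_necessary": Rating.NOT_NECESSARY,
}


class RescueVacuousWarning(UserWarning):
    """The configured rescue rule can never fire for any panel composition."""


@dataclass
class RatingTable:
    """Complete panel of ratings: every entry rated once by every rater."""

    ratings: dict[tuple[str, str], Rating]
    panel: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.panel:
            raise ValueError("empty rater panel")
        self.panel = tuple(self.panel)
        entry_ids = {eid for eid, _ in self.ratings}
        for eid in entry_ids:
            raters = {r for e, r in self.ratings if e == eid}
            if raters != set(self.panel):
                missing = sorted(set(self.panel) - raters)
                extra = sorted(raters - set(self.panel))
                raise ValueError(
                    f"incomplete panel for entry {eid!r}: missing raters {missing}, unknown raters {extra}"
                )

    @property
    def entry_ids(self) -> frozenset[str]:
        return frozenset(eid for eid, _ in self.ratings)

    def for_entry(self, entry_id: str) -> list[Rating]:
        return [self.ratings[(entry_id, r)] for r in self.panel]


@dataclass
class ValidationConfig:
    """Validation behaviour.

    ``cvr_formula`` — "proportion" (n_e / N) or "lawshe_classic"
    ((n_e − N/2)/(N/2)).  ``cvr_threshold`` — retention cut-off (≥).
    ``points`` — judgment points per rating level.  Rescue accepts a keyword
    with CVR in [``rescue_cvr_low``, ``rescue_cvr_high``] whose mean points
    strictly exceed ``rescue_mean_points``.
    """

    cvr_formula: str = "proportion"
    cvr_threshold: float = 0.75
    rescue_enabled: bool = True
    points: dict[Rating, float] = field(
        default_factory=lambda: {
            Rating.ESSENTIAL: 2.0,
            Rating.USEFUL_NOT_ESSENTIAL: 1.0,
            Rating.NOT_NECESSARY: 0.0,
        }
    )
    rescue_cvr_low: float = 0.0
    rescue_cvr_high: float = 0.5
    rescue_mean_points: float = 1.5
    category_mean_over: str = "retained"  # or "all"

    def __post_init__(self) -> None:
        if self.cvr_formula not in ("proportion", "lawshe_classic"):
            raise ValueError(f"unknown cvr_formula {self.cvr_formula!r}")
        if not 0.0 <= self.cvr_threshold <= 1.0:
            raise ValueError("cvr_threshold must be in [0, 1]")
        if self.rescue_cvr_low > self.rescue_cvr_high:
            raise ValueError("rescue_cvr_low must be <= rescue_cvr_high")
        if any(v < 0 for v in self.points.values()):
            raise ValueError("judgment points must be nonnegative")
        if self.category_mean_over not in ("retained", "all"):
            raise ValueError("category_mean_over must be 'retained' or 'all'")


def cvr(ratings: Iterable[Rating], formula: str = "proportion") -> float:
    """Content validity ratio of one keyword's complete panel of ratings."""
    ratings = list(ratings)
    n = len(ratings)
    if n == 0:
        raise ValueError("empty panel")
    n_e = sum(r is Rating.ESSENTIAL for r in ratings)
    if formula == "proportion":
        return n_e / n
    if formula == "lawshe_classic":
        return (n_e - n / 2) / (n / 2)
    raise ValueError(f"unknown cvr formula {formula!r}")


def mean_judgment_points(ratings: Iterable[Rating], points: Mapping[Rating, float]) -> float:
    """Mean of per-rating judgment points over the panel."""
    ratings = list(ratings)
    if not ratings:
        raise ValueError("empty panel")
    return sum(points[r] for r in ratings) / len(ratings)


def decide(cvr_value: float, mean_points: float, cfg: ValidationConfig) -> str:
    """Retention decision for one keyword.

    ``retained_threshold`` when CVR ≥ threshold; otherwise
    ``retained_rescue`` when rescue is enabled, CVR lies in the closed rescue
    interval and mean points strictly exceed the rescue cut-off; otherwise
    ``dropped``.
    """
    if cvr_value >= cfg.cvr_threshold:
        return "retained_threshold"
    if (
        cfg.rescue_enabled
        and cfg.rescue_cvr_low <= cvr_value <= cfg.rescue_cvr_high
        and mean_points > cfg.rescue_mean_points
    ):
        return "retained_rescue"
    return "dropped"


def rescue_trigger_compositions(
    cfg: ValidationConfig, max_panel: int = 12
) -> list[tuple[int, int, int]]:
    """All panel compositions (n_essential, n_useful, n_not_necessary) with
    panel size ≤ ``max_panel`` for which the rescue rule fires.

    Exhaustive enumeration; an empty result proves the configured rescue
    rule vacuous for every panel up to that size.
    """
    hits: list[tuple[int, int, int]] = []
    for n in range(1, max_panel + 1):
        for n_e in range(n + 1):
            for n_u in range(n - n_e + 1):
                n_n = n - n_e - n_u
                ratings = (
                    [Rating.ESSENTIAL] * n_e
                    + [Rating.USEFUL_NOT_ESSENTIAL] * n_u
                    + [Rating.NOT_NECESSARY] * n_n
                )
                c = cvr(ratings, cfg.cvr_formula)
                m = mean_judgment_points(ratings, cfg.points)
                if decide(c, m, cfg) == "retained_rescue":
                    hits.append((n_e, n_u, n_n))
    return hits


@dataclass
class EntryResult:
    entry_id: str
    category: str
    cvr: float
    mean_points: float
    decision: str


@dataclass
class ValidationResult:
    """Per-entry decisions plus category-level and overall summaries."""

    entries: list[EntryResult]
    category_cvr: dict[str, float]
    cvi: float
    config: ValidationConfig

    @property
    def retained_ids(self) -> frozenset[str]:
        return frozenset(e.entry_id for e in self.entries if e.decision != "dropped")

    @property
    def dropped_ids(self) -> frozenset[str]:
        return frozenset(e.entry_id for e in self.entries if e.decision == "dropped")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "entry_id": e.entry_id,
                    "category": e.category,
                    "cvr": e.cvr,
                    "mean_points": e.mean_points,
                    "decision": e.decision,
                }
                for e in self.entries
            ]
        ).set_index("entry_id")

    def category_cvr_frame(self, ndigits: int = 2) -> pd.DataFrame:
        """Category-CVR report with a final CVI row, rounded for display."""
        rows = {cid: round(v, ndigits) for cid, v in self.category_cvr.items()}
        df = pd.DataFrame.from_dict(rows, orient="index", columns=["cvr"])
        df.loc["cvi"] = round(self.cvi, ndigits)
        df.index.name = "category"
        return df


def validate_lexicon(
    lex: Lexicon, table: RatingTable, cfg: ValidationConfig | None = None
) -> tuple[ValidationResult, Lexicon]:
    """Apply the retention procedure to a whole lexicon.

    Every entry must be rated; dropped entries are removed together with
    their derivatives and variations (those inherit the main keyword's
    decision).  Per-category CVR averages over retained entries by default,
    and CVI is the grand mean over retained entries.  Emits
    :class:`RescueVacuousWarning` when rescue is enabled but unreachable.
    """
    cfg = cfg or ValidationConfig()
    unrated = sorted({e.entry_id for e in lex.entries} - table.entry_ids)
    if unrated:
        raise LexiconFormatError(f"unrated entries: {unrated}")
    if cfg.rescue_enabled and not rescue_trigger_compositions(cfg):
        warnings.warn(
            "rescue rule is vacuous: no panel composition of size <= 12 has CVR in "
            f"[{cfg.rescue_cvr_low}, {cfg.rescue_cvr_high}] with mean judgment points "
            f"> {cfg.rescue_mean_points} under formula {cfg.cvr_formula!r} and the "
            "configured points map; only the CVR threshold can retain keywords",
            RescueVacuousWarning,
            stacklevel=2,
        )
    results: list[EntryResult] = []
    for e in lex.entries:
        ratings = table.for_entry(e.entry_id)
        c = cvr(ratings, cfg.cvr_formula)
        m = mean_judgment_points(ratings, cfg.points)
        results.append(EntryResult(e.entry_id, e.category, c, m, decide(c, m, cfg)))

    pool = results if cfg.category_mean_over == "all" else [r for r in results if r.decision != "dropped"]
    category_cvr: dict[str, float] = {}
    for cid in CATEGORY_IDS:
        vals = [r.cvr for r in pool if r.category == cid]
        if vals:
            category_cvr[cid] = sum(vals) / len(vals)
    retained = [r for r in results if r.decision != "dropped"]
    cvi = sum(r.cvr for r in retained) / len(retained) if retained else float("nan")

    keep = {r.entry_id for r in retained}
    filtered = Lexicon(
        entries=[e for e in lex.entries if e.entry_id in keep],
        metadata={**lex.metadata, "validated": "true"},
    )
    return ValidationResult(results, category_cvr, cvi, cfg), filtered


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def load_ratings(path: str | Path) -> RatingTable:
    """Read a tab-separated rating file: entry_id, rater_id, rating.

    Ratings accept the single-letter tokens E/U/N or the full level names,
    case-insensitively.
    """
    ratings: dict[tuple[str, str], Rating] = {}
    raters: list[str] = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("entry_id\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise LexiconFormatError(
                f"{path}: line {lineno}: expected 'entry_id<TAB>rater_id<TAB>rating'"
            )
        eid, rid, tok = (p.strip() for p in parts)
        rating = _RATING_TOKENS.get(tok.lower())
        if rating is None:
            raise LexiconFormatError(
                f"{path}: line {lineno}: unknown rating {tok!r} (use E/U/N)"
            )
        if (eid, rid) in ratings:
            raise LexiconFormatError(f"{path}: line {lineno}: duplicate rating for ({eid}, {rid})")
        ratings[(eid, rid)] = rating
        if rid not in raters:
            raters.append(rid)
    return RatingTable(ratings=ratings, panel=tuple(raters))


def save_ratings(table: RatingTable, path: str | Path) -> None:
    lines = ["entry_id\trater_id\trating"]
    for eid in sorted(table.entry_ids):
        for rid in table.panel:
            lines.append(f"{eid}\t{rid}\t{table.ratings[(eid, rid)].value[0].upper()}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
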