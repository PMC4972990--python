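"""Symptom taxonomy and lexicon data structures.

A depression lexicon is organised into 13 symptom categories anchored in the
DSM-5 depressive-episode criteria and the ICD-10 clinical descriptions
(including the associated features anxiety, alcohol/substance use and
histrionic behaviour).  Each lexicon entry is a *main keyword* (a word or
phrase such as "i feel worthless"), its enumerated *derivatives*
(tense/word-order variants) and its *spelling variations* (textspeak
abbreviations), all bound to exactly one category so that per-category counts
add up to the lexicon totals.
"""

from __future__ import annotations

import difflib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("lexiscreen")

__all__ = [
    "SymptomCategory",
    "CATEGORIES",
    "CATEGORY_IDS",
    "KeywordEntry",
    "Lexicon",
    "VALID_SOURCES",
    "normalize_text",
    "map_category",
    "count_summary",
    "frequency_summary",
    "load_lexicon",
    "save_lexicon",
    "make_stub_lexicon",
    "LexiconFormatError",
]


class LexiconFormatError(ValueError):
    """A lexicon / rating / message file violates its schema."""


# ---------------------------------------------------------------------------
# Categories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SymptomCategory:
    """One of the 13 depressive-symptom classes.

    ``id`` is the stable machine token; ``dsm5_label`` and ``icd10_label``
    carry the wording of the respective diagnostic system.
    """

    id: str
    dsm5_label: str
    icd10_label: str


CATEGORIES: tuple[SymptomCategory, ...] = (
    SymptomCategory("mood", "Depressed mood", "Clearly abnormal depressive mood"),
    SymptomCategory(
        "interest",
        "Markedly diminished interest or pleasure in all or almost all activities",
        "Marked loss of interest or ability to enjoy activities that were previously pleasurable",
    ),
    SymptomCategory(
        "appetite_weight",
        "Significant weight loss or gain, or increase or decrease in appetite",
        "Changes of appetite (decrease or increase), with the corresponding weight change",
    ),
    SymptomCategory("sleep", "Sleep problems", "Sleep alterations of any kind"),
    SymptomCategory(
        "psychomotor_agitation",
        "Psychomotor agitation or retardation",
        "Changes of psychomotor activity, with agitation or inhibition",
    ),
    SymptomCategory(
        "psychomotor_retardation",
        "Psychomotor agitation or retardation",
        "Changes of psychomotor activity, with agitation or inhibition",
    ),
    SymptomCategory("fatigue", "Fatigue or loss of energy", "Lack of vitality or increase of fatigability"),
    SymptomCategory(
        "guilt_self_esteem",
        "Feelings of guilt, worthlessness, negative self-appraisal",
        "Disproportionate self-reproaches and feelings of excessive guilt or inadequacy; "
        "loss of confidence and self-esteem and feelings of inferiority",
    ),
    SymptomCategory(
        "concentration",
        "Diminished concentration or indecisiveness",
        "Complaints about or decrease of the ability to concentrate and think, "
        "accompanied by a lack of decision and vacillation",
    ),
    SymptomCategory(
        "suicide",
        "Recurrent thoughts of death or suicidal ideation",
        "Recurrent thoughts of death or suicide or any suicidal behavior",
    ),
    SymptomCategory("anxiety", "Anxiety", "Anxiety"),
    SymptomCategory("alcohol_substance", "Substance abuse", "Excessive consumption of alcohol"),
    SymptomCategory("histrionic", "Histrionic behavior", "Histrionic behavior"),
)

CATEGORY_IDS: tuple[str, ...] = tuple(c.id for c in CATEGORIES)
_CATEGORY_BY_ID: dict[str, SymptomCategory] = {c.id: c for c in CATEGORIES}

# The two psychomotor categories share one symptom line in both systems, so a
# label lookup on that wording is ambiguous without an explicit qualifier.
_PSYCHOMOTOR_IDS = ("psychomotor_agitation", "psychomotor_retardation")

VALID_SOURCES: frozenset[str] = frozenset(
    {"focus_group", "expert_interview", "scale_review", "researcher_extension"}
)


# ---------------------------------------------------------------------------
# Text normalization
# ---------------------------------------------------------------------------

_APOSTROPHES = str.maketrans({"’": "'", "‘": "'"})


def normalize_text(raw: str) -> str:
    """Canonical form used for all storage and matching.

    Lower-cases, strips, collapses whitespace runs to single spaces, and maps
    curly apostrophes to ``'``.  Punctuation — including emoticon glyphs such
    as ``:-(`` — is preserved verbatim.  Idempotent.
    """
    return " ".join(raw.translate(_APOSTROPHES).lower().split())


# ---------------------------------------------------------------------------
# Entries and lexicon
# ---------------------------------------------------------------------------

@dataclass
class KeywordEntry:
    """A main keyword with its derivatives and spelling variations.

    All texts are normalized on construction; derivatives and variations are
    stored as sets and never contain the surface itself.
    """

    entry_id: str
    category: str
    surface: str
    derivatives: frozenset[str] = frozenset()
    variations: frozenset[str] = frozenset()
    sources: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.category not in _CATEGORY_BY_ID:
            raise LexiconFormatError(
                f"unknown category {self.category!r}; valid ids: {', '.join(CATEGORY_IDS)}"
            )
        self.surface = normalize_text(self.surface)
        if not self.surface:
            raise LexiconFormatError(f"entry {self.entry_id!r}: surface is empty after normalization")
        self.derivatives = frozenset(normalize_text(d) for d in self.derivatives) - {self.surface, ""}
        self.variations = frozenset(normalize_text(v) for v in self.variations) - {self.surface, ""}
        self.sources = frozenset(self.sources)
        bad = self.sources - VALID_SOURCES
        if bad:
            raise LexiconFormatError(
                f"entry {self.entry_id!r}: unknown sources {sorted(bad)}; valid: {sorted(VALID_SOURCES)}"
            )

    @property
    def all_phrases(self) -> frozenset[str]:
        """Surface, derivatives and variations together (all matchable forms)."""
        return frozenset({self.surface}) | self.derivatives | self.variations


@dataclass
class Lexicon:
    """A keyword collection plus free-form metadata (name, language, version)."""

    entries: list[KeywordEntry] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.entry_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LexiconFormatError(f"duplicate entry_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_id(self, entry_id: str) -> KeywordEntry:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e
        raise KeyError(entry_id)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def map_category(label: str, system: str, qualifier: str | None = None) -> str:
    """Map a DSM-5 or ICD-10 symptom wording to its category id.

    The lookup is case-insensitive on the full label.  The psychomotor
    symptom line is shared between agitation and retardation in both systems,
    so it resolves only with ``qualifier="agitation"`` or ``"retardation"``.
    """
    if system not in ("dsm5", "icd10"):
        raise ValueError(f"system must be 'dsm5' or 'icd10', got {system!r}")
    key = normalize_text(label)
    if not key:
        raise LexiconFormatError("empty label")
    attr = "dsm5_label" if system == "dsm5" else "icd10_label"
    hits = [c.id for c in CATEGORIES if normalize_text(getattr(c, attr)) == key]
    if not hits:
        pool = {normalize_text(getattr(c, attr)): c.id for c in CATEGORIES}
        near = difflib.get_close_matches(key, pool, n=1, cutoff=0.4)
        hint = f"; did you mean {near[0]!r} ({pool[near[0]]})?" if near else ""
        raise LexiconFormatError(f"no {system} label matches {label!r}{hint}")
    if set(hits) == set(_PSYCHOMOTOR_IDS):
        if qualifier not in ("agitation", "retardation"):
            raise LexiconFormatError(
                "psychomotor wording is shared by agitation and retardation; "
                "pass qualifier='agitation' or qualifier='retardation'"
            )
        return f"psychomotor_{qualifier}"
    return hits[0]


def count_summary(lex: Lexicon) -> pd.DataFrame:
    """Per-category counts of main keywords, derivatives and variations.

    Returns a DataFrame indexed by the 13 category ids (in taxonomy order)
    plus a final ``total`` row; columns ``main``, ``derivatives``,
    ``variations``, ``total``.  Row totals are plain sums, so the grand-total
    row equals the column sums — each entry is counted exactly once.
    """
    rows = {cid: [0, 0, 0] for cid in CATEGORY_IDS}
    for e in lex.entries:
        r = rows[e.category]
        r[0] += 1
        r[1] += len(e.derivatives)
        r[2] += len(e.variations)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["main", "derivatives", "variations"])
    df["total"] = df.sum(axis=1)
    df.loc["total"] = df.sum(axis=0)
    df.index.name = "category"
    return df.astype(int)


def frequency_summary(counts: Mapping[str, int], mode: str = "decimal") -> pd.DataFrame:
    """Frequency table with percent and cumulative-percent columns.

    Rows are sorted by descending count (stable for ties).  ``mode="decimal"``
    rounds percent to 1 decimal and cumulative to 2 decimals; ``"integer"``
    rounds both to whole percent.  Cumulative percentages are accumulated on
    the unrounded values, so the last row is exactly 100.
    """
    if mode not in ("decimal", "integer"):
        raise ValueError(f"mode must be 'decimal' or 'integer', got {mode!r}")
    items = list(counts.items())
    if any(c < 0 for _, c in items):
        raise ValueError("counts must be nonnegative")
    total = sum(c for _, c in items)
    if total == 0:
        raise ValueError("all counts are zero; nothing to summarize")
    items.sort(key=lambda kv: -kv[1])
    labels = [k for k, _ in items]
    vals = [c for _, c in items]
    pct = [100.0 * c / total for c in vals]
    cum: list[float] = []
    run = 0.0
    for c in vals:
        run += 100.0 * c / total
        cum.append(run)
    if mode == "decimal":
        pct_r = [_round_half_up(p, 1) for p in pct]
        cum_r = [_round_half_up(c, 2) for c in cum]
    else:
        pct_r = [int(_round_half_up(p, 0)) for p in pct]
        cum_r = [int(_round_half_up(c, 0)) for c in cum]
    df = pd.DataFrame(
        {"count": vals, "percent": pct_r, "cumulative_percent": cum_r}, index=pd.Index(labels, name="label")
    )
    return df


def _round_half_up(x: float, nd: int) -> float:
    """Round half away from zero, as printed tables conventionally do."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-nd)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_COLUMNS = ("entry_id", "category", "surface", "derivatives", "variations", "sources")


def _split_multi(cell: str) -> list[str]:
    return [p for p in (s.strip() for s in cell.split("|")) if p] if cell else []


def load_lexicon(path: str | Path, format: str = "delimited") -> Lexicon:
    """Read a lexicon file.

    ``delimited`` is tab-separated UTF-8 with a header row and |-joined
    multi-valued cells; ``structured`` is a JSON document with the same
    schema.  Duplicate derivatives/variations within an entry are merged
    silently with a logged count.  Malformed rows raise
    :class:`LexiconFormatError` naming the line number.
    """
    path = Path(path)
    if format == "structured":
        doc = json.loads(path.read_text(encoding="utf-8"))
        raw_entries = [
            (i, r.get("entry_id", ""), r.get("category", ""), r.get("surface", ""),
             list(r.get("derivatives", [])), list(r.get("variations", [])), list(r.get("sources", [])))
            for i, r in enumerate(doc.get("entries", []), start=1)
        ]
        metadata = dict(doc.get("metadata", {}))
    elif format == "delimited":
        lines = path.read_text(encoding="utf-8").splitlines()
        if not lines or [h.strip() for h in lines[0].split("\t")] != list(_COLUMNS):
            header = "\t".join(_COLUMNS)
            raise LexiconFormatError(f"{path}: line 1: expected header {header!r}")
        raw_entries = []
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != len(_COLUMNS):
                raise LexiconFormatError(
                    f"{path}: line {lineno}: expected {len(_COLUMNS)} tab-separated fields, got {len(parts)}"
                )
            eid, cat, surf, deriv, var, src = parts
            raw_entries.append(
                (lineno, eid, cat, surf, _split_multi(deriv), _split_multi(var), _split_multi(src))
            )
        metadata = {}
    else:
        raise ValueError(f"format must be 'delimited' or 'structured', got {format!r}")

    entries = []
    merged = 0
    for lineno, eid, cat, surf, deriv, var, src in raw_entries:
        norm_d = [normalize_text(d) for d in deriv]
        norm_v = [normalize_text(v) for v in var]
        try:
            entry = KeywordEntry(
                entry_id=eid.strip(), category=cat.strip(), surface=surf,
                derivatives=frozenset(norm_d), variations=frozenset(norm_v),
                sources=frozenset(s.strip() for s in src),
            )
        except LexiconFormatError as err:
            raise LexiconFormatError(f"{path}: line {lineno}: {err}") from None
        merged += len(norm_d) + len(norm_v) - len(set(norm_d)) - len(set(norm_v))
        entries.append(entry)
    if merged:
        logger.info("load_lexicon(%s): merged %d duplicate derivative/variation cells", path, merged)
    return Lexicon(entries=entries, metadata=metadata)


def save_lexicon(lex: Lexicon, path: str | Path, format: str = "delimited") -> None:
    """Write a lexicon in the schema :func:`load_lexicon` reads."""
    path = Path(path)
    if format == "structured":
        doc = {
            "metadata": lex.metadata,
            "entries": [
                {
                    "entry_id": e.entry_id, "category": e.category, "surface": e.surface,
                    "derivatives": sorted(e.derivatives), "variations": sorted(e.variations),
                    "sources": sorted(e.sources),
                }
                for e in lex.entries
            ],
        }
        path.write_text(json.dumps(doc, indent=1, ensure_ascii=False), encoding="utf-8")
        return
    if format != "delimited":
        raise ValueError(f"format must be 'delimited' or 'structured', got {format!r}")
    lines = ["\t".join(_COLUMNS)]
    for e in lex.entries:
        lines.append(
            "\t".join(
                (e.entry_id, e.category, e.surface,
                 "|".join(sorted(e.derivatives)), "|".join(sorted(e.variations)),
                 "|".join(sorted(e.sources)))
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def make_stub_lexicon(per_category: Mapping[str, tuple[int, int, int]]) -> Lexicon:
    """Rebuild a lexicon skeleton from per-category (main, derivative,
    variation) counts, as printed in a categorization table.

    The actual keyword texts are synthetic placeholders; only the counting
    structure is reproduced, so :func:`count_summary` on the result recovers
    the printed totals.  Derivatives and variations are attached to the first
    entry of each category.
    """
    entries: list[KeywordEntry] = []
    for cid, (n_main, n_deriv, n_var) in per_category.items():
        if cid not in _CATEGORY_BY_ID:
            raise LexiconFormatError(
                f"unknown category {cid!r}; valid ids: {', '.join(CATEGORY_IDS)}"
            )
        for i in range(n_main):
            deriv = frozenset(f"{cid} deriv {j}" for j in range(n_deriv)) if i == 0 else frozenset()
            var = frozenset(f"{cid} var {j}" for j in range(n_var)) if i == 0 else frozenset()
            entries.append(
                KeywordEntry(
                    entry_id=f"{cid}-{i:06d}", category=cid, surface=f"{cid} keyword {i}",
                    derivatives=deriv, variations=var, sources=frozenset({"scale_review"}),
                )
            )
    return Lexicon(entries=entries, metadata={"name": "stub"})
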