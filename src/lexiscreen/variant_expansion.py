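"""Combinatorial spelling-variant expansion of multi-word keywords.

Textspeak variation of a phrase is generated by giving each word a small set
of spelling options and taking all combinations of per-word choices — the
rule used to extend a hand-collected variant list to full coverage.  A
variant map may also carry multi-word keys (e.g. ``"can not" -> "cant"``)
whose options replace the whole span; those are matched greedily
left-to-right before per-word expansion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .lexicon_model import normalize_text

__all__ = [
    "VariantMap",
    "ExpansionConfig",
    "ExpansionOverflowError",
    "expand_keyword",
    "expansion_count",
    "apply_textspeak_rules",
    "load_variant_map",
    "save_variant_map",
]


class ExpansionOverflowError(ValueError):
    """The combination count exceeds the configured cap."""


@dataclass
class VariantMap:
    """Mapping from a word (or multi-word span) to its spelling variants.

    Variants are single tokens, normalized, duplicate-free and never equal to
    the source key.
    """

    options: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for key, variants in self.options.items():
            k = normalize_text(key)
            if not k:
                raise ValueError("empty variant-map key")
            seen: list[str] = []
            for v in variants:
                nv = normalize_text(v)
                if not nv or nv == k:
                    continue
                if " " in nv:
                    raise ValueError(f"variant {v!r} of {key!r} is not a single token")
                if nv not in seen:
                    seen.append(nv)
            clean[k] = tuple(seen)
        self.options = clean

    @property
    def max_key_words(self) -> int:
        return max((k.count(" ") + 1 for k in self.options), default=1)

    def __contains__(self, key: str) -> bool:
        return key in self.options

    def get(self, key: str) -> tuple[str, ...]:
        return self.options.get(key, ())


@dataclass
class ExpansionConfig:
    """Expansion behaviour: whether the unmodified phrase is kept in the
    output, and the per-keyword combination cap (exceeding it is an error)."""

    include_original: bool = False
    max_output: int = 1_000_000

    def __post_init__(self) -> None:
        if self.max_output < 1:
            raise ValueError("max_output must be >= 1")


def _segment(phrase: str, vmap: VariantMap) -> list[tuple[str, tuple[str, ...]]]:
    """Split a normalized phrase into (span, variants) units.

    Greedy left-to-right: at each position the longest variant-map key wins,
    so multi-word keys consume their whole span before per-word options
    apply.  Words absent from the map become units with no variants.
    """
    words = phrase.split()
    units: list[tuple[str, tuple[str, ...]]] = []
    i = 0
    limit = vmap.max_key_words
    while i < len(words):
        for k in range(min(limit, len(words) - i), 0, -1):
            span = " ".join(words[i : i + k])
            if k > 1 and span not in vmap:
                continue
            units.append((span, vmap.get(span)))
            i += k
            break
    return units


def expand_keyword(phrase: str, vmap: VariantMap, cfg: ExpansionConfig | None = None) -> set[str]:
    """All spelling variations of ``phrase`` under the variant map.

    The output is the Cartesian product over units of {original span} ∪
    variants, minus the unmodified phrase unless ``cfg.include_original``.
    Raises :class:`ExpansionOverflowError` when the product exceeds
    ``cfg.max_output``.
    """
    cfg = cfg or ExpansionConfig()
    phrase = normalize_text(phrase)
    if not phrase:
        raise ValueError("empty phrase")
    units = _segment(phrase, vmap)
    n_product = 1
    for span, variants in units:
        n_product *= 1 + len(variants)
    if n_product > cfg.max_output:
        raise ExpansionOverflowError(
            f"{phrase!r} expands to {n_product} combinations, above the cap of {cfg.max_output}"
        )
    out = {
        " ".join(choice)
        for choice in itertools.product(*[(span, *variants) for span, variants in units])
    }
    if not cfg.include_original:
        out.discard(phrase)
    return out


def expansion_count(phrase: str, vmap: VariantMap, cfg: ExpansionConfig | None = None) -> int:
    """Closed-form size of :func:`expand_keyword`'s output:
    ∏(1 + v_i) over units, minus one when the original is excluded."""
    cfg = cfg or ExpansionConfig()
    phrase = normalize_text(phrase)
    if not phrase:
        raise ValueError("empty phrase")
    n = 1
    for _, variants in _segment(phrase, vmap):
        n *= 1 + len(variants)
    return n if cfg.include_original else n - 1


# ---------------------------------------------------------------------------
# Heuristic textspeak rules (fixture generation)
# ---------------------------------------------------------------------------

_VOWELS = set("aeiou")


def apply_textspeak_rules(word: str, i_to_y: bool = True) -> tuple[str, ...]:
    """Deterministic textspeak candidates for one token.

    Mimics common SMS abbreviation habits: internal-vowel deletion
    ("stop" → "stp", "asleep" → "aslp"), "to" → "2", terminal "ing" → "in"
    ("crying" → "cryin"), and optionally i → y with silent-e dropping
    ("life" → "lyf").  Tokens shorter than 3 characters yield nothing.
    """
    word = normalize_text(word)
    if len(word) < 3 and word != "to":
        return ()
    candidates: list[str] = []

    def add(c: str) -> None:
        if c and c != word and c not in candidates:
            candidates.append(c)

    if word == "to":
        add("2")
        return tuple(candidates)
    # drop vowels except a leading one
    add(word[0] + "".join(ch for ch in word[1:] if ch not in _VOWELS))
    if word.endswith("ing"):
        add(word[:-1])
    if i_to_y and "i" in word:
        swapped = word.replace("i", "y")
        add(swapped[:-1] if swapped.endswith("e") else swapped)
    return tuple(candidates)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def load_variant_map(path: str | Path) -> VariantMap:
    """Read a tab-separated variant map: key TAB |-joined variants."""
    options: dict[str, tuple[str, ...]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 'key<TAB>variant|variant|...'")
        key, cell = parts
        options[key] = tuple(v for v in (s.strip() for s in cell.split("|")) if v)
    return VariantMap(options)


def save_variant_map(vmap: VariantMap, path: str | Path) -> None:
    lines = [f"{k}\t{'|'.join(vs)}" for k, vs in vmap.options.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
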