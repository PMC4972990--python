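"""Seeded synthetic fixtures: toy lexica, rating panels and message streams.

Every other module is testable without any external data.  The generator
emulates the structural features the pipeline depends on — short
code-switched, abbreviation-heavy messages; multi-word keywords with
per-word spelling variants; complete 8-rater expert panels with a controlled
probability of an "essential" rating — without attempting realistic
morphology.  Keyword and filler vocabularies are pseudo-words drawn from
disjoint pools (checked at generation time), so the recorded ground truth of
injected keyword occurrences is exact rather than probabilistic.

All randomness flows from one seed through spawned NumPy generators, so each
artifact (lexicon, ratings, messages) is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .lexicon_model import CATEGORY_IDS, KeywordEntry, Lexicon
from .screening_engine import Message, MatchHit
from .content_validation import Rating, RatingTable
from .variant_expansion import VariantMap, apply_textspeak_rules

__all__ = ["FixtureSpec", "make_toy_lexicon", "make_variant_map", "simulate_ratings", "simulate_messages"]

_CONSONANTS = list("bcdfghklmnprstvwyz")
_VOWELS = list("aeiou")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults mirror the study setup where stated: an 8-expert validation
    panel, and a 0.9 chance that a rater calls a keyword essential (the
    validated lexicon's mean CVR was 0.90).  Structural sizes (2 entries per
    category, 1–3 words per keyword, up to 3 variants per word — the
    collection forms asked for at least 3 — and ~100 short messages) are
    desk-scale choices that exercise every code path.
    """

    seed: int = 0
    entries_per_category: int = 2
    words_per_keyword: tuple[int, int] = (1, 3)
    variants_per_word: tuple[int, int] = (0, 3)
    panel_size: int = 8
    essential_probability: float = 0.9
    injection_rate: float = 0.5
    n_messages: int = 100

    def __post_init__(self) -> None:
        if self.entries_per_category < 1 or self.panel_size < 1:
            raise ValueError("entries_per_category and panel_size must be positive")
        if not 0.0 <= self.essential_probability <= 1.0:
            raise ValueError("essential_probability must be in [0, 1]")
        if self.injection_rate < 0:
            raise ValueError("injection_rate must be nonnegative")
        if self.n_messages < 1:
            raise ValueError("cannot inject into a zero-length message stream")
        for lo, hi in (self.words_per_keyword, self.variants_per_word):
            if lo > hi or lo < 0:
                raise ValueError("ranges must be nonempty and nonnegative")
        if self.words_per_keyword[0] < 1:
            raise ValueError("keywords need at least one word")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(4)[stream])


def _pseudo_word(rng: np.random.Generator, syllables: int) -> str:
    return "".join(
        str(rng.choice(_CONSONANTS)) + str(rng.choice(_VOWELS)) for _ in range(syllables)
    )


def _word_pools(spec: FixtureSpec) -> tuple[list[str], list[str]]:
    """Disjoint keyword and filler vocabularies."""
    rng = spec._rng(0)
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < 400:
        w = _pseudo_word(rng, int(rng.integers(2, 4)))
        if w not in seen:
            seen.add(w)
            pool.append(w)
    keyword_words, filler_words = pool[:250], pool[250:]
    assert not set(keyword_words) & set(filler_words)
    return keyword_words, filler_words


def _is_subphrase(a: Sequence[str], b: Sequence[str]) -> bool:
    """True when word-sequence a occurs contiguously inside b."""
    n, m = len(a), len(b)
    return any(tuple(b[i : i + n]) == tuple(a) for i in range(m - n + 1))


def make_toy_lexicon(spec: FixtureSpec) -> tuple[Lexicon, pd.DataFrame]:
    """Deterministic toy lexicon plus its independently tallied summary.

    No phrase (surface, derivative or variation) is a contiguous
    sub-phrase of another, so exact matching with span consumption recovers
    injected occurrences one-for-one.  Returns ``(lexicon, summary)`` where
    the summary is tallied during generation, not via
    :func:`~lexiscreen.lexicon_model.count_summary`.
    """
    keyword_words, _ = _word_pools(spec)
    rng = spec._rng(1)
    entries: list[KeywordEntry] = []
    all_phrases: list[tuple[str, ...]] = []
    tally = {cid: [0, 0, 0] for cid in CATEGORY_IDS}

    def admissible(words: tuple[str, ...]) -> bool:
        return not any(
            _is_subphrase(words, other) or _is_subphrase(other, words) for other in all_phrases
        )

    for cid in CATEGORY_IDS:
        for i in range(spec.entries_per_category):
            lo, hi = spec.words_per_keyword
            for _ in range(200):
                n_words = int(rng.integers(lo, hi + 1))
                words = tuple(
                    str(keyword_words[j]) for j in rng.choice(len(keyword_words), n_words, replace=False)
                )
                if admissible(words):
                    break
            else:  # pragma: no cover - pool is ample for default sizes
                raise RuntimeError("could not draw a non-overlapping keyword phrase")
            phrases = [words]

            derivatives: set[str] = set()
            if len(words) > 1:
                reordered = tuple(reversed(words))
                if admissible(reordered):
                    derivatives.add(" ".join(reordered))
                    phrases.append(reordered)
            tensed = words[:-1] + (words[-1] + "ng",)
            if admissible(tensed):
                derivatives.add(" ".join(tensed))
                phrases.append(tensed)

            variations: set[str] = set()
            vlo, vhi = spec.variants_per_word
            per_word = [
                list(apply_textspeak_rules(w))[: int(rng.integers(vlo, vhi + 1))] for w in words
            ]
            for _ in range(3):  # a few random combinations, not the full product
                combo = tuple(
                    str(rng.choice([w, *opts])) if opts else w for w, opts in zip(words, per_word)
                )
                if combo != words and admissible(combo):
                    variations.add(" ".join(combo))
                    phrases.append(combo)

            entries.append(
                KeywordEntry(
                    entry_id=f"{cid}-{i:03d}",
                    category=cid,
                    surface=" ".join(words),
                    derivatives=frozenset(derivatives),
                    variations=frozenset(variations),
                    sources=frozenset({"focus_group", "researcher_extension"}),
                )
            )
            all_phrases.extend(phrases)
            t = tally[cid]
            t[0] += 1
            t[1] += len(derivatives)
            t[2] += len(variations)

    lex = Lexicon(entries=entries, metadata={"name": "toy", "seed": str(spec.seed)})
    summary = _tally_frame(tally)
    return lex, summary


def _tally_frame(tally: dict[str, list[int]]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(tally, orient="index", columns=["main", "derivatives", "variations"])
    df["total"] = df.sum(axis=1)
    df.loc["total"] = df.sum(axis=0)
    df.index.name = "category"
    return df.astype(int)


def make_variant_map(spec: FixtureSpec, lex: Lexicon) -> VariantMap:
    """Textspeak variant options for every word used by the lexicon surfaces."""
    words = sorted({w for e in lex.entries for w in e.surface.split()})
    return VariantMap({w: apply_textspeak_rules(w) for w in words if apply_textspeak_rules(w)})


def simulate_ratings(lex: Lexicon, spec: FixtureSpec) -> RatingTable:
    """Complete seeded rating panel.

    Each rater independently rates each entry essential with probability
    ``spec.essential_probability``; the remaining mass splits evenly between
    the other two levels.
    """
    rng = spec._rng(2)
    panel = tuple(f"rater-{k:02d}" for k in range(spec.panel_size))
    p = spec.essential_probability
    ratings: dict[tuple[str, str], Rating] = {}
    levels = (Rating.ESSENTIAL, Rating.USEFUL_NOT_ESSENTIAL, Rating.NOT_NECESSARY)
    probs = (p, (1 - p) / 2, (1 - p) / 2)
    for e in lex.entries:
        draws = rng.choice(3, size=len(panel), p=probs)
        for rid, d in zip(panel, draws):
            ratings[(e.entry_id, rid)] = levels[int(d)]
    return RatingTable(ratings=ratings, panel=panel)


def simulate_messages(
    lex: Lexicon, spec: FixtureSpec, start: str = "2024-01-01T08:00:00"
) -> tuple[list[Message], list[MatchHit]]:
    """Seeded message stream with exact ground truth.

    Messages are filler pseudo-words with keyword phrases injected at a
    Poisson(``injection_rate``) count per message, every injection separated
    by at least one filler word.  Because the filler vocabulary shares no
    word with any lexicon phrase, the returned hit list (with character
    offsets into the normalized message text) is exactly what exact matching
    must recover.
    """
    if spec.n_messages < 1:
        raise ValueError("cannot inject into a zero-length message stream")
    _, filler_words = _word_pools(spec)
    lex_words = {w for e in lex.entries for ph in e.all_phrases for w in ph.split()}
    filler = [w for w in filler_words if w not in lex_words]
    assert filler, "filler vocabulary exhausted"

    phrases: list[tuple[str, str, str]] = []  # (phrase, entry_id, category)
    for e in lex.entries:
        for ph in sorted(e.all_phrases):
            phrases.append((ph, e.entry_id, e.category))

    rng = spec._rng(3)
    t = datetime.fromisoformat(start)
    messages: list[Message] = []
    truth: list[MatchHit] = []
    for i in range(spec.n_messages):
        mid = f"msg-{i:05d}"
        n_inject = int(rng.poisson(spec.injection_rate))
        segments: list[str] = []

        def emit_filler(k: int) -> None:
            segments.extend(str(filler[j]) for j in rng.integers(0, len(filler), size=k))

        emit_filler(int(rng.integers(1, 5)))
        pos = len(" ".join(segments))
        for _ in range(n_inject):
            phrase, entry_id, category = phrases[int(rng.integers(0, len(phrases)))]
            start_off = pos + 1  # the joining space before the phrase
            segments.append(phrase)
            end_off = start_off + len(phrase)
            truth.append(MatchHit(mid, start_off, end_off, phrase, entry_id, category))
            pos = end_off
            n_fill = int(rng.integers(1, 4))
            emit_filler(n_fill)
            pos = len(" ".join(segments))
        messages.append(Message(message_id=mid, timestamp=t.isoformat(), text=" ".join(segments)))
        t += timedelta(minutes=float(rng.integers(5, 180)))
    return messages, truth
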