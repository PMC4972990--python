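"""Lexicon-based message screening.

Matching is exact on normalized text: the lexicon enumerates every surface,
derivative and spelling variation, so the engine never guesses — a phrase is
a hit only when it appears verbatim, flanked by token boundaries.  Tokens
come in two classes: word tokens (letters/digits/underscore/apostrophe, so
"i'm" is one token) and symbol tokens (runs of other non-space characters,
so the emoticon ":-(" is a token and can be a keyword).  A boundary exists
at string edges, at whitespace, and wherever the character class changes.

Overlapping candidate matches are resolved longest-match-first, then
leftmost, and a consumed span yields exactly one hit; an overlap-allowed
mode reports every candidate (used by equivalence checks against a naive
all-phrases-all-positions scan).
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

from .lexicon_model import CATEGORY_IDS, Lexicon, LexiconFormatError, normalize_text

__all__ = [
    "Message",
    "MatchHit",
    "ScreeningReport",
    "PhraseMatcher",
    "build_matcher",
    "screen",
    "aggregate_window",
    "read_messages",
    "write_messages",
    "parse_window",
]

_TOKEN_RE = re.compile(r"[\w']+|[^\w\s]+")


@dataclass(frozen=True)
class Message:
    """One record of a message stream (an EMA-style text sample)."""

    message_id: str
    timestamp: str | None
    text: str


@dataclass(frozen=True)
class MatchHit:
    """A single keyword occurrence; offsets are 0-based half-open character
    positions into the *normalized* message text."""

    message_id: str
    start: int
    end: int
    matched_surface: str
    entry_id: str
    category: str


@dataclass
class ScreeningReport:
    """Screening output: every hit, per-category tallies, and the normalized
    text of each message for auditability."""

    hits: list[MatchHit]
    category_counts: dict[str, int]
    normalized_texts: dict[str, str]
    message_times: dict[str, str | None]
    policy: str

    @property
    def flagged_categories(self) -> tuple[str, ...]:
        return tuple(cid for cid in CATEGORY_IDS if self.category_counts.get(cid, 0) > 0)

    @property
    def total_hits(self) -> int:
        return len(self.hits)

    def to_json(self) -> str:
        """Deterministic machine-readable form."""
        return json.dumps(
            {
                "policy": self.policy,
                "category_counts": {cid: self.category_counts.get(cid, 0) for cid in CATEGORY_IDS},
                "flagged_categories": list(self.flagged_categories),
                "hits": [
                    {
                        "message_id": h.message_id, "start": h.start, "end": h.end,
                        "matched_surface": h.matched_surface, "entry_id": h.entry_id,
                        "category": h.category,
                    }
                    for h in self.hits
                ],
                "normalized_texts": self.normalized_texts,
            },
            indent=1,
            ensure_ascii=False,
            sort_keys=True,
        )


def _tokenize(text: str) -> list[tuple[int, int]]:
    """Token (start, end) offsets of the two token classes."""
    return [m.span() for m in _TOKEN_RE.finditer(text)]


class PhraseMatcher:
    """Token-n-gram index over every matchable phrase of a lexicon."""

    def __init__(self, lex: Lexicon):
        if not lex.entries:
            raise LexiconFormatError("cannot build a matcher from an empty lexicon")
        # phrase -> sorted (entry_id, category) pairs; token count -> phrases
        self._owners: dict[str, list[tuple[str, str]]] = {}
        for e in lex.entries:
            for phrase in e.all_phrases:
                self._owners.setdefault(phrase, []).append((e.entry_id, e.category))
        for owners in self._owners.values():
            owners.sort()
        self._by_len: dict[int, set[str]] = {}
        for phrase in self._owners:
            self._by_len.setdefault(len(_tokenize(phrase)), set()).add(phrase)
        self.max_tokens = max(self._by_len, default=0)

    @property
    def phrases(self) -> frozenset[str]:
        return frozenset(self._owners)

    def find(self, normalized: str) -> list[tuple[int, int, str, str, str]]:
        """Every candidate occurrence in a normalized text, overlap allowed.

        Returns (start, end, phrase, entry_id, category) tuples sorted by
        position, longest first at ties.
        """
        tokens = _tokenize(normalized)
        out: list[tuple[int, int, str, str, str]] = []
        for i in range(len(tokens)):
            for k in range(1, min(self.max_tokens, len(tokens) - i) + 1):
                start, end = tokens[i][0], tokens[i + k - 1][1]
                candidate = normalized[start:end]
                if candidate in self._by_len.get(k, ()):
                    for entry_id, category in self._owners[candidate]:
                        out.append((start, end, candidate, entry_id, category))
        out.sort(key=lambda t: (t[0], -(t[1] - t[0]), t[3]))
        return out


def build_matcher(lex: Lexicon) -> PhraseMatcher:
    """Index every surface, derivative and variation for exact phrase
    matching on normalized text."""
    return PhraseMatcher(lex)


def screen(
    messages: Iterable[Message], matcher: PhraseMatcher, policy: str = "consume"
) -> ScreeningReport:
    """Match a message stream against the lexicon.

    ``policy="consume"`` (default) resolves overlaps longest-match-first,
    then leftmost, each consumed span yielding exactly one hit;
    ``policy="overlap"`` reports every candidate match.  Deterministic:
    identical inputs give byte-identical reports.
    """
    if policy not in ("consume", "overlap"):
        raise ValueError(f"policy must be 'consume' or 'overlap', got {policy!r}")
    hits: list[MatchHit] = []
    normalized_texts: dict[str, str] = {}
    message_times: dict[str, str | None] = {}
    counts: Counter[str] = Counter()
    for msg in messages:
        if msg.message_id in normalized_texts:
            raise LexiconFormatError(f"duplicate message_id {msg.message_id!r}")
        norm = normalize_text(msg.text)
        normalized_texts[msg.message_id] = norm
        message_times[msg.message_id] = msg.timestamp
        candidates = matcher.find(norm)
        if policy == "consume":
            chosen: list[tuple[int, int, str, str, str]] = []
            taken: list[tuple[int, int]] = []
            for cand in sorted(candidates, key=lambda t: (-(t[1] - t[0]), t[0], t[3])):
                s, e = cand[0], cand[1]
                if all(e <= ts or s >= te for ts, te in taken):
                    # one hit per consumed span: skip same-span duplicates too
                    chosen.append(cand)
                    taken.append((s, e))
            candidates = sorted(chosen, key=lambda t: (t[0], t[1], t[3]))
        for s, e, phrase, entry_id, category in candidates:
            hits.append(MatchHit(msg.message_id, s, e, phrase, entry_id, category))
            counts[category] += 1
    return ScreeningReport(
        hits=hits,
        category_counts={cid: counts.get(cid, 0) for cid in CATEGORY_IDS},
        normalized_texts=normalized_texts,
        message_times=message_times,
        policy=policy,
    )


def parse_window(window: str | timedelta) -> timedelta:
    """Parse a window length like ``"24h"``, ``"30m"``, ``"7d"``, ``"90s"``."""
    if isinstance(window, timedelta):
        if window <= timedelta(0):
            raise ValueError("window length must be positive")
        return window
    m = re.fullmatch(r"\s*(\d+(?:\.\d+)?)\s*(s|m|h|d)\s*", str(window))
    if not m:
        raise ValueError(f"cannot parse window length {window!r} (use e.g. '24h', '30m')")
    value = float(m.group(1))
    unit = {"s": "seconds", "m": "minutes", "h": "hours", "d": "days"}[m.group(2)]
    td = timedelta(**{unit: value})
    if td <= timedelta(0):
        raise ValueError("window length must be positive")
    return td


def aggregate_window(report: ScreeningReport, window: str | timedelta) -> dict[str, dict[str, int]]:
    """Per-category hit counts in consecutive half-open time windows.

    Windows are anchored at the earliest message timestamp; a hit at a
    window-boundary instant belongs to the later window ([start,
    start+len)).  Window keys are the ISO start instants; window totals sum
    to the overall totals.
    """
    length = parse_window(window)
    times: dict[str, datetime] = {}
    for mid, ts in report.message_times.items():
        if ts is None:
            raise LexiconFormatError(f"message {mid!r} has no timestamp")
        try:
            times[mid] = datetime.fromisoformat(ts)
        except ValueError:
            raise LexiconFormatError(f"message {mid!r} has unparseable timestamp {ts!r}") from None
    if not times:
        return {}
    t0 = min(times.values())
    windows: dict[str, dict[str, int]] = {}
    for hit in report.hits:
        idx = (times[hit.message_id] - t0) // length
        key = (t0 + idx * length).isoformat()
        bucket = windows.setdefault(key, {})
        bucket[hit.category] = bucket.get(hit.category, 0) + 1
    return dict(sorted(windows.items()))


# ---------------------------------------------------------------------------
# Message IO
# ---------------------------------------------------------------------------

def read_messages(path: str | Path, format: str = "structured") -> list[Message]:
    """Read a message log.

    ``structured``: one JSON record per line with message_id, timestamp,
    text.  ``plain``: each line is one message; ids are synthesized
    (``line-000001`` …) and timestamps are absent.
    """
    path = Path(path)
    messages: list[Message] = []
    if format == "plain":
        for i, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
            messages.append(Message(message_id=f"line-{i:06d}", timestamp=None, text=line))
        return messages
    if format != "structured":
        raise ValueError(f"format must be 'structured' or 'plain', got {format!r}")
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            messages.append(Message(str(rec["message_id"]), rec.get("timestamp"), str(rec["text"])))
        except (json.JSONDecodeError, KeyError) as err:
            raise LexiconFormatError(f"{path}: line {lineno}: bad message record ({err})") from None
    return messages


def write_messages(messages: Sequence[Message], path: str | Path) -> None:
    lines = [
        json.dumps(
            {"message_id": m.message_id, "timestamp": m.timestamp, "text": m.text},
            ensure_ascii=False,
        )
        for m in messages
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
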