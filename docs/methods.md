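# Methods

## The problem

Lexicon-based screening detects possible depressive symptoms in a stream of
short text messages by matching the text against an enumerated vocabulary of
symptom expressions. Unlike classifier-based sentiment analysis, the method
is fully transparent: every hit is a verbatim occurrence of a keyword that a
panel of clinicians has judged relevant to a specific DSM-5/ICD-10 symptom
category. The cost of that transparency is coverage — every tense variant
and every textspeak spelling must be enumerated — which is why the toolkit
couples the lexicon model with combinatorial variant expansion and a formal
content-validation procedure. The output is a per-category tally of matches,
screening support only; no diagnostic threshold is applied, because none has
been validated.

## Data model and normalization

Thirteen symptom categories are fixed, anchored one-for-one in the DSM-5
depressive-episode criteria and the ICD-10 clinical descriptions, plus the
associated features anxiety, alcohol/substance use and histrionic behaviour.
DSM-5 and ICD-10 put psychomotor agitation and retardation on a single
symptom line; the taxonomy splits them into two categories, so label lookup
on the shared wording requires an explicit qualifier rather than guessing.

Each entry carries one main keyword, a set of derivatives and a set of
spelling variations, and belongs to exactly one category. Single-category
assignment is an enforced invariant: the categorization tables this design
reproduces are additive (per-category rows sum to the grand totals), which
would be false under multiple assignment.

All text — lexicon and messages alike — passes through one normalization:
lower-case, trim, collapse whitespace runs, and map curly apostrophes to
`'`. Punctuation is otherwise preserved so that emoticons (`:-(`) survive
as matchable tokens; apostrophes are word characters so `i'm` is one token.
Normalization is idempotent, and all matching happens on normalized text.

Frequency tables round percent to 1 decimal and cumulative percent to 2
decimals (an integer mode covers tables printed at whole-percent
precision), with cumulation done on unrounded values so the last row is
exactly 100. Rounding is half-away-from-zero, the convention of printed
tables, not banker's rounding.

## Variant expansion

A phrase's spelling variations are the Cartesian product of per-word
options: each word contributes itself plus its mapped variants, and the
unmodified phrase is excluded from the result by default (variations are
counted separately from the main keyword). The closed form
∏ᵢ(1 + vᵢ) − 1 equals the enumerated set size exactly because variants are
single tokens distinct from their source word, making every combination a
distinct phrase. Multi-word map keys (`can not → cant`, the contraction
case) replace their whole span and are consumed greedily left-to-right
before per-word options apply. A per-keyword cap (default 10⁶) turns
runaway products into an explicit overflow error rather than a hung run.

The heuristic textspeak rules (internal-vowel deletion, `to → 2`, terminal
`ing → in`, optional `i → y` with silent-e dropping) exist to generate
plausible fixture variants deterministically; real studies collect variants
from respondents, and nothing in the pipeline depends on the rules'
linguistic fidelity.

## Content validation

With a complete panel of N raters per keyword (every keyword rated by every
rater, enforced), the content validity ratio is computed as the proportion
n_e/N of raters judging the keyword essential. This plain-ratio reading is
the default because it is how the procedure this toolkit reproduces defines
CVR; the classic Lawshe form (n_e − N/2)/(N/2) is offered as
`cvr_formula="lawshe_classic"` since the two differ materially (0.75 as a
proportion is 0.5 on the Lawshe scale). Keywords with CVR ≥ 0.75 are
retained. Derivatives and variations inherit their main keyword's decision;
they are not rated separately.

The rescue rule re-admits a keyword with CVR in the closed interval
[0, 0.5] when its mean judgment points strictly exceed 1.5. Judgment points
default to essential = 2, useful-but-not-essential = 1, not-necessary = 0;
awarding the middle level 1 point is a deliberate reading of an ambiguous
"2 points per acceptance" prescription, chosen because an essential-only
scheme makes the rule provably vacuous (mean > 1.5 already implies
CVR > 0.75). Even so, satisfiability depends on the CVR formula:

- **proportion + 2/1/0:** mean points = 2·p_e + p_u ≤ 1 + p_e ≤ 1.5
  whenever CVR = p_e ≤ 0.5, so the rule can *never* fire;
- **lawshe_classic + 2/1/0:** CVR in [0, 0.5] means p_e in [0.5, 0.75], and
  e.g. N = 8 with 6 essential + 1 useful gives CVR 0.5 and mean points
  1.625 — the rule fires.

Rather than hard-coding this analysis, `rescue_trigger_compositions`
enumerates every panel composition (n_e, n_u, n_n) up to N = 12
exhaustively, and `validate_lexicon` emits a `RescueVacuousWarning`
whenever the configured formula and points make rescue unreachable. The
default configuration therefore warns: the rule is stated, implemented and
reported honestly as inert there.

The CVI is the mean CVR over retained keywords; per-category CVRs average
over retained keywords within the category by default (`category_mean_over
="all"` switches to all rated keywords — the published tables do not say
which was used). Report rounding is 2 decimals, display-only.

## Screening

The matcher indexes every surface, derivative and variation as a token
sequence. Text is tokenized into word tokens (letters/digits/underscore/
apostrophe) and symbol tokens (runs of other non-space characters); a
boundary exists at string edges, whitespace, and class changes, so `sad:-(`
contains both the word `sad` and the emoticon `:-(`. A phrase matches when
its token sequence occurs at boundaries and the covered slice of normalized
text equals the phrase verbatim — exact matching only, since the design
handles spelling variation by enumeration, not fuzzing.

Overlaps are resolved longest-match-first, then leftmost, with consumed
spans (ties between entries sharing a phrase break on entry id, so reports
are deterministic and byte-identical across runs). An overlap-allowed mode
reports every candidate and is what the test suite compares against a naive
all-phrases-at-all-positions scan. Hit offsets are 0-based half-open into
the normalized text, which the report retains for audit. Time-window
summaries anchor half-open windows [start, start + len) at the earliest
message timestamp; a boundary instant belongs to the later window.

## Synthetic fixtures

The generator emulates the structural conditions of the study it supports:
an 8-expert panel; a per-rater essential probability defaulting to 0.9
(matching a validated lexicon whose mean CVR was 0.90), with the remaining
mass split evenly between the two lower ratings; short messages of filler
pseudo-words with keyword phrases injected at Poisson rate 0.5 per message
by default. Desk-scale structural sizes (2 entries per category, 1–3 words
per keyword, up to 3 variants per word, 100 messages) exercise every code
path in seconds; the acceptance study uses 4 entries per category and 200
messages. All randomness flows from one seed through spawned NumPy
generators, so each artifact is reproducible piecewise.

Two generation-time guarantees make ground truth exact rather than
probabilistic: the filler vocabulary shares no word with any lexicon
phrase, and no lexicon phrase is a contiguous sub-phrase of another (both
checked during generation). Injections are separated by at least one filler
word. Under these conditions the recorded injection list is provably the
complete match set, so end-to-end recovery is asserted as exact equality.

What the fixtures do *not* emulate: real Filipino/Taglish morphology,
code-switching semantics, misspellings outside the variant map, sarcasm or
negation ("not sad"), or message-length and diurnal-timing distributions of
real phone use. Passing tests demonstrate that the machinery is correct —
counting, validation arithmetic, exact matching, conservation — not that
the lexicon approach achieves any particular sensitivity on real messages;
that is what the content-validation statistics and, ultimately, clinical
studies are for.

## Numerical and degenerate-input choices

- CVR threshold comparison is ≥, rescue interval is closed, points cut-off
  is strict > — boundary semantics as stated by the procedure.
- An empty lexicon errors at matcher construction; an all-zero frequency
  table errors; an empty rater panel errors; unrated entries are listed by
  id.
- Duplicate derivatives/variations in input files are merged silently with
  a logged count; duplicate entry ids and duplicate message ids are errors.
- Dropping all entries yields CVI = NaN (no retained keywords), not 0.

## Known limitations

- Exact matching misses any spelling not enumerated; recall on real text is
  bounded by variant-map coverage.
- The matcher is an n-gram dictionary scan, O(tokens × max-phrase-length)
  per message with set lookups — ample for message streams; an automaton
  (Aho–Corasick) would be the next step for very large lexica on long
  documents.
- Category tallies count hits, not messages or persons; no prevalence or
  severity inference is provided by design.
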