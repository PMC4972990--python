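# lexiscreen

A toolkit for building, validating and applying a **depression-symptom
lexicon** for screening short text messages (SMS, chat, social-media posts —
the kind of ecological momentary assessment stream a mobile mental-health
app sees). It is aimed at researchers constructing symptom lexica for
text-analytics studies, particularly in code-switched, abbreviation-heavy
writing styles ("textspeak"/Taglish) where a fixed keyword list must be
extended to cover spelling variation.

It implements four pieces of machinery:

1. **Taxonomy and lexicon model** — 13 depressive-symptom categories anchored
   row-for-row in DSM-5 depressive-episode criteria and ICD-10 clinical
   descriptions (mood, interest, appetite/weight, sleep, psychomotor
   agitation, psychomotor retardation, fatigue, guilt/self-esteem,
   concentration, suicide, anxiety, alcohol/substance use, histrionic
   behaviour). Each entry is a *main keyword* with enumerated *derivatives*
   (tense/word-order variants) and *spelling variations* (textspeak forms),
   bound to exactly one category so per-category counts are additive.
2. **Variant expansion** — spelling variations of a multi-word keyword are
   all combinations of per-word spelling options: a phrase of words with
   v₁, …, v_k variants each expands to ∏ᵢ(1+vᵢ) − 1 variation phrases
   (excluding the unmodified original). Multi-word map keys
   (`can not → cant`) replace their whole span before per-word expansion.
3. **Content validation** — an expert panel rates every keyword *essential*,
   *useful but not essential* or *not necessary*. The content validity
   ratio per keyword is CVR = n_e / N (the proportion of the N panelists
   rating it essential; the classic Lawshe form (n_e − N/2)/(N/2) is
   available). Keywords with CVR ≥ 0.75 are retained; a keyword with CVR in
   [0, 0.5] whose mean judgment points (essential = 2, useful = 1, not
   necessary = 0) exceed 1.5 can be rescued. The content validity index is
   CVI = mean CVR over retained keywords. The toolkit proves by exhaustive
   search when the rescue rule is satisfiable and warns when a
   configuration makes it vacuous.
4. **Screening engine** — exact phrase matching of every surface, derivative
   and variation on normalized text at token boundaries (emoticons such as
   `:-(` are matchable tokens), with longest-match-first overlap resolution,
   per-category symptom tallies and time-window summaries.

A seeded synthetic-fixture module generates toy lexica, complete rating
panels and message streams with exact ground truth, so the whole pipeline is
testable without any external data (the original Filipino lexicon was never
published).

## Worked example

```python
import lexiscreen as lx

spec = lx.FixtureSpec(seed=3)                 # 8-rater panel, p(essential)=0.9
lex, summary = lx.make_toy_lexicon(spec)      # 2 entries x 13 categories
table = lx.simulate_ratings(lex, spec)
result, retained = lx.validate_lexicon(lex, table)
print(len(retained), round(result.cvi, 3))

msgs, truth = lx.simulate_messages(retained, spec)
report = lx.screen(msgs, lx.build_matcher(retained))
print(report.total_hits, len(truth))
print(dict(sorted(report.category_counts.items())[:2]))
```

prints

```
26 0.899
46 46
{'alcohol_substance': 6, 'anxiety': 4}
```

— all 26 toy keywords clear the 0.75 CVR threshold (CVI 0.899 under the
simulated 0.9 essential probability), and screening recovers all 46
injected keyword occurrences, here 6 of them in the alcohol/substance-use
category and 4 under anxiety. (The `validate_lexicon` call also emits a
`RescueVacuousWarning`: under the default proportion CVR and 2/1/0 points,
the mid-range rescue rule can never fire — see `docs/methods.md`.)

The same pipeline is available from the shell:

```sh
lexiscreen simulate --seed 7 --out-dir fixtures/
lexiscreen stats fixtures/lexicon.tsv
lexiscreen validate fixtures/lexicon.tsv fixtures/ratings.tsv -o retained.tsv
lexiscreen screen retained.tsv fixtures/messages.jsonl --window 24h --report report.json
```

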