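"""CVR/CVI computation, retention decisions and the rescue rule."""

import warnings

import pytest

import lexiscreen as lx
from lexiscreen import reference as ref
from lexiscreen.content_validation import Rating

E, U, N = Rating.ESSENTIAL, Rating.USEFUL_NOT_ESSENTIAL, Rating.NOT_NECESSARY
DEFAULT_POINTS = {E: 2.0, U: 1.0, N: 0.0}


def panel(n_e, n_u, n_n):
    return [E] * n_e + [U] * n_u + [N] * n_n


class TestCvr:
    @pytest.mark.parametrize(
        "ratings, formula, expected",
        [
            (panel(8, 0, 0), "proportion", 1.0),
            (panel(6, 1, 1), "proportion", 0.75),
            (panel(6, 1, 1), "lawshe_classic", 0.5),
            (panel(0, 4, 4), "lawshe_classic", -1.0),
            (panel(4, 2, 2), "lawshe_classic", 0.0),
        ],
    )
    def test_both_formulas(self, ratings, formula, expected):
        assert lx.cvr(ratings, formula) == pytest.approx(expected)

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError):
            lx.cvr([])

    def test_ranges_and_monotonicity(self):
        for n in (1, 5, 8, 12):
            prev_prop, prev_law = -1.0, -2.0
            for n_e in range(n + 1):
                p = lx.cvr(panel(n_e, n - n_e, 0), "proportion")
                l = lx.cvr(panel(n_e, n - n_e, 0), "lawshe_classic")
                assert 0.0 <= p <= 1.0 and -1.0 <= l <= 1.0
                assert p > prev_prop and l > prev_law
                prev_prop, prev_law = p, l


class TestMeanJudgmentPoints:
    def test_examples(self):
        assert lx.mean_judgment_points(panel(8, 0, 0), DEFAULT_POINTS) == 2.0
        assert lx.mean_judgment_points(panel(4, 4, 0), DEFAULT_POINTS) == 1.5
        assert lx.mean_judgment_points(panel(0, 0, 8), DEFAULT_POINTS) == 0.0

    def test_identity_with_default_points(self):
        # mean points = 2 n_e/N + n_u/N under the default map
        for n_e, n_u, n_n in [(3, 2, 3), (0, 8, 0), (5, 0, 3)]:
            n = n_e + n_u + n_n
            assert lx.mean_judgment_points(panel(n_e, n_u, n_n), DEFAULT_POINTS) == pytest.approx(
                2 * n_e / n + n_u / n
            )


class TestDecide:
    def test_threshold_boundary_inclusive(self):
        cfg = lx.ValidationConfig()
        assert lx.decide(0.75, 0.0, cfg) == "retained_threshold"
        assert lx.decide(1.0, 2.0, cfg) == "retained_threshold"

    def test_outside_rescue_interval_drops(self):
        cfg = lx.ValidationConfig()
        assert lx.decide(0.74, 2.0, cfg) == "dropped"

    def test_rescue_interval_closed_points_strict(self):
        cfg = lx.ValidationConfig()
        assert lx.decide(0.5, 1.625, cfg) == "retained_rescue"
        assert lx.decide(0.5, 1.5, cfg) == "dropped"  # strict > on points
        assert lx.decide(0.0, 1.6, cfg) == "retained_rescue"
        assert lx.decide(-0.1, 1.6, cfg) == "dropped"

    def test_rescue_disabled(self):
        cfg = lx.ValidationConfig(rescue_enabled=False)
        assert lx.decide(0.5, 1.9, cfg) == "dropped"


class TestRescueSatisfiability:
    """Exhaustive search over all (n_e, n_u, n_n) panels with N <= 12."""

    @staticmethod
    def oracle(formula, points, max_panel=12):
        # independent of cvr()/decide(): plain arithmetic on compositions
        hits = []
        for n in range(1, max_panel + 1):
            for n_e in range(n + 1):
                for n_u in range(n - n_e + 1):
                    n_n = n - n_e - n_u
                    c = n_e / n if formula == "proportion" else (n_e - n / 2) / (n / 2)
                    m = (points[E] * n_e + points[U] * n_u + points[N] * n_n) / n
                    if c < 0.75 and 0.0 <= c <= 0.5 and m > 1.5:
                        hits.append((n_e, n_u, n_n))
        return hits

    def test_proportion_default_points_is_vacuous(self):
        cfg = lx.ValidationConfig()
        assert lx.rescue_trigger_compositions(cfg) == []
        assert self.oracle("proportion", DEFAULT_POINTS) == []

    def test_lawshe_default_points_is_satisfiable(self):
        cfg = lx.ValidationConfig(cvr_formula="lawshe_classic")
        found = lx.rescue_trigger_compositions(cfg)
        assert found == self.oracle("lawshe_classic", DEFAULT_POINTS)
        assert found, "rescue must be reachable under the classic Lawshe formula"
        # the canonical mid-range example: 6/8 essential + 1 useful gives
        # CVR 0.5 and mean points 1.625
        assert (6, 1, 1) in found
        assert lx.cvr(panel(6, 1, 1), "lawshe_classic") == 0.5
        assert lx.mean_judgment_points(panel(6, 1, 1), DEFAULT_POINTS) == 1.625

    @pytest.mark.parametrize("formula", ["proportion", "lawshe_classic"])
    def test_essential_only_points_always_vacuous(self, formula):
        pts = {E: 2.0, U: 0.0, N: 0.0}
        cfg = lx.ValidationConfig(cvr_formula=formula, points=pts)
        assert lx.rescue_trigger_compositions(cfg) == []
        assert self.oracle(formula, pts) == []

    def test_vacuous_config_warns_at_validation(self, toy):
        _, lex, _ = toy
        spec = lx.FixtureSpec(seed=11)
        table = lx.simulate_ratings(lex, spec)
        with pytest.warns(lx.RescueVacuousWarning):
            lx.validate_lexicon(lex, table, lx.ValidationConfig(points={E: 2.0, U: 0.0, N: 0.0}))
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            lx.validate_lexicon(lex, table, lx.ValidationConfig(cvr_formula="lawshe_classic"))


class TestValidateLexicon:
    def test_all_essential_retains_everything_cvi_1(self, toy):
        _, lex, _ = toy
        spec = lx.FixtureSpec(seed=11, essential_probability=1.0)
        table = lx.simulate_ratings(lex, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", lx.RescueVacuousWarning)
            result, filtered = lx.validate_lexicon(lex, table)
        assert len(filtered) == len(lex)
        assert result.cvi == 1.0
        assert all(v == 1.0 for v in result.category_cvr.values())

    def test_zero_essential_drops_everything(self, toy):
        _, lex, _ = toy
        spec = lx.FixtureSpec(seed=11, essential_probability=0.0)
        table = lx.simulate_ratings(lex, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", lx.RescueVacuousWarning)
            result, filtered = lx.validate_lexicon(lex, table)
        assert len(filtered) == 0
        assert result.retained_ids == frozenset()

    def test_unrated_entry_errors_with_ids(self, toy):
        _, lex, _ = toy
        spec = lx.FixtureSpec(seed=11)
        table = lx.simulate_ratings(lex, spec)
        extra = lx.Lexicon(
            entries=lex.entries + [lx.KeywordEntry(entry_id="zz", category="mood", surface="qq zz")],
            metadata={},
        )
        with pytest.raises(lx.LexiconFormatError, match="zz"):
            lx.validate_lexicon(extra, table)

    def test_dropped_entries_lose_derivatives_and_variations(self, toy):
        _, lex, _ = toy
        spec = lx.FixtureSpec(seed=11, essential_probability=0.5)
        table = lx.simulate_ratings(lex, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", lx.RescueVacuousWarning)
            result, filtered = lx.validate_lexicon(lex, table)
        s = lx.count_summary(filtered)
        survivors = [e for e in lex.entries if e.entry_id in result.retained_ids]
        assert s.loc["total", "main"] == len(survivors)
        assert s.loc["total", "derivatives"] == sum(len(e.derivatives) for e in survivors)
        assert s.loc["total", "variations"] == sum(len(e.variations) for e in survivors)

    def test_cvi_invariant_to_entry_order(self, toy):
        _, lex, _ = toy
        spec = lx.FixtureSpec(seed=11, essential_probability=0.7)
        table = lx.simulate_ratings(lex, spec)
        rev = lx.Lexicon(entries=list(reversed(lex.entries)), metadata={})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", lx.RescueVacuousWarning)
            r1, _ = lx.validate_lexicon(lex, table)
            r2, _ = lx.validate_lexicon(rev, table)
        assert r1.cvi == pytest.approx(r2.cvi)
        assert r1.category_cvr == pytest.approx(r2.category_cvr)

    def test_retained_fraction_monotone_in_essential_probability(self):
        fractions = []
        for p in (0.0, 0.3, 0.6, 0.9, 1.0):
            spec = lx.FixtureSpec(seed=5, essential_probability=p, entries_per_category=4)
            lex, _ = lx.make_toy_lexicon(spec)
            table = lx.simulate_ratings(lex, spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", lx.RescueVacuousWarning)
                result, filtered = lx.validate_lexicon(lex, table)
            fractions.append(len(filtered) / len(lex))
        assert fractions == sorted(fractions)
        assert fractions[0] == 0.0 and fractions[-1] == 1.0


class TestPublishedCategoryCvrs:
    def test_cvi_is_mean_of_category_cvrs(self):
        vals = list(ref.CATEGORY_CVRS.values())
        assert len(vals) == 13
        assert round(sum(vals) / len(vals), 2) == 0.90


class TestRatingsIO:
    def test_round_trip(self, toy):
        _, lex, _ = toy
        spec = lx.FixtureSpec(seed=11)
        table = lx.simulate_ratings(lex, spec)
        import tempfile, pathlib

        with tempfile.TemporaryDirectory() as d:
            p = pathlib.Path(d) / "ratings.tsv"
            lx.save_ratings(table, p)
            loaded = lx.load_ratings(p)
        assert set(loaded.panel) == set(table.panel)
        assert loaded.ratings == table.ratings

    def test_bad_rating_token(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("e1\trater-1\tX\n", encoding="utf-8")
        with pytest.raises(lx.LexiconFormatError, match="line 1"):
            lx.load_ratings(p)

    def test_incomplete_panel_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            lx.RatingTable(
                ratings={("e1", "r1"): E, ("e1", "r2"): U, ("e2", "r1"): E},
                panel=("r1", "r2"),
            )
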