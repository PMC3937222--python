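import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clscreen import screen_stats as ss

from conftest import SEED


def _wt_pool(n=50, sd=0.01, seed=SEED):
    """WT replicate L values with sample SD scaled to exactly ``sd``."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n)
    x = (x - x.mean()) / x.std(ddof=1) * sd + 1.0
    return pd.DataFrame({"strain_id": ["WT"] * n, "L": x})


def _records(Ls, Gs=None):
    n = len(Ls)
    return pd.DataFrame({"strain_id": [f"g{i}" for i in range(n)], "L": Ls,
                         "G": Gs if Gs is not None else [np.nan] * n})


class TestCalling:
    def test_unit_lifespan_is_neutral_with_zero_z(self):
        calls = ss.call_phenotypes(_records([1.0]), _wt_pool())
        assert calls["Z"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert calls["class"].iloc[0] == "neutral"

    def test_z_and_two_tailed_p(self):
        calls = ss.call_phenotypes(_records([1.03]), _wt_pool(sd=0.01))
        assert calls["Z"].iloc[0] == pytest.approx(3.0, abs=1e-9)
        assert calls["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(3.0), rel=1e-9)
        assert calls["p"].iloc[0] == pytest.approx(0.0027, abs=1e-4)

    def test_bh_hand_example_yields_two_discoveries(self):
        """p-values {0.001, 0.02, 0.8} -> BH q {0.003, 0.03, 0.8}: 2 hits."""
        sd = 0.01
        zs = [stats.norm.isf(p / 2) for p in (0.001, 0.02, 0.8)]
        calls = ss.call_phenotypes(_records([1 + z * sd for z in zs]), _wt_pool(sd=sd))
        assert np.allclose(calls["q"], [0.003, 0.03, 0.8], atol=1e-6)
        assert int((calls["q"] < 0.05).sum()) == 2

    def test_growth_filter_applies_to_short_lived_only(self):
        wt = _wt_pool(sd=0.01)
        calls = ss.call_phenotypes(
            _records([0.9, 0.9, 1.1, 1.1], Gs=[0.90, 0.99, 0.90, 0.99]), wt)
        short = calls[calls["class"] == "short"]
        long_ = calls[calls["class"] == "long"]
        assert short.set_index("strain_id")["growth_filtered"].tolist() == [True, False]
        assert not long_["growth_filtered"].any()
        assert short["specific"].tolist() == [False, True]

    def test_four_sd_effects_recovered_with_high_sensitivity(self):
        """Planted effects of 4 WT-SD are called at q<0.05 with sensitivity
        above 0.9 (averaged over 10 simulated screens)."""
        rng = np.random.default_rng(SEED)
        sd = 0.002
        hits = total = 0
        for _ in range(20):
            n = 400
            cls = np.array(["short"] * 40 + ["long"] * 40 + ["neutral"] * 320)
            rng.shuffle(cls)
            wt_L = rng.normal(1, sd, 120)
            sd_hat = wt_L.std(ddof=1)  # the pool the Z-score actually uses
            shift = np.where(cls == "short", -4 * sd_hat,
                             np.where(cls == "long", 4 * sd_hat, 0.0))
            rec = _records(1 + shift + rng.normal(0, sd, n))
            wt = pd.DataFrame({"strain_id": ["WT"] * 120, "L": wt_L})
            calls = ss.call_phenotypes(rec, wt)
            planted = cls != "neutral"
            hits += int((calls.loc[planted, "class"].to_numpy() == cls[planted]).sum())
            total += int(planted.sum())
        assert hits / total > 0.9

    def test_wt_pool_size_enforced(self):
        with pytest.raises(ValueError, match=">=30"):
            ss.call_phenotypes(_records([1.0]), _wt_pool(n=10))


class TestNormalityCheck:
    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(SEED)
        ps = [ss.check_wt_normality(rng.normal(1.0, 0.01, 120)) for _ in range(150)]
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.005 < frac < 0.13
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_bimodal_pool_rejected(self):
        rng = np.random.default_rng(SEED)
        x = np.concatenate([rng.normal(0.95, 0.004, 100),
                            rng.normal(1.05, 0.004, 100)])
        assert ss.check_wt_normality(x) < 0.01


class TestScreenComparison:
    def test_self_comparison_is_perfect(self):
        rec = _records(np.linspace(0.9, 1.1, 20))
        for method in ("pearson", "spearman"):
            r, paired = ss.compare_screens(rec, rec, method=method)
            assert r == pytest.approx(1.0)
            assert len(paired) == 20

    def test_replicate_screens_correlate(self):
        """Two noise realizations of one truth at screen-scale noise."""
        rng = np.random.default_rng(SEED)
        truth = rng.normal(1.0, 0.02, 200)
        a = _records(truth + rng.normal(0, 0.006, 200))
        b = _records(truth + rng.normal(0, 0.006, 200))
        r, _ = ss.compare_screens(a, b)
        assert 0.8 < r < 1.0

    def test_too_few_shared_strains(self):
        with pytest.raises(ValueError, match=">=10"):
            ss.compare_screens(_records([1.0] * 5), _records([1.0] * 5))


class TestConfirmation:
    def test_exactly_wt_like_second_value_not_confirmed(self):
        calls = pd.DataFrame({"strain_id": ["a"], "class": ["short"]})
        second = pd.DataFrame({"strain_id": ["a"], "L": [1.0]})
        table, fracs, _ = ss.confirm_in_condition(calls, second, _wt_pool(n=57))
        assert not table["confirmed"].iloc[0]

    def test_planted_strong_effects_mostly_confirmed(self):
        """Effects of 3 WT-SD present in both conditions confirm >90%.

        The per-hit measurement error (half the WT well-to-well spread, as for
        replicated hits) leaves ~2 WT-SD of margin beyond the CI edge.
        """
        rng = np.random.default_rng(SEED)
        n = 120
        sd = 0.01
        cls = ["short"] * (n // 2) + ["long"] * (n // 2)
        calls = pd.DataFrame({"strain_id": [f"g{i}" for i in range(n)], "class": cls})
        shift = np.where(np.array(cls) == "short", -3 * sd, 3 * sd)
        second = pd.DataFrame({"strain_id": calls["strain_id"],
                               "L": 1 + shift + rng.normal(0, sd / 2, n)})
        table, fracs, p_cls = ss.confirm_in_condition(calls, second, _wt_pool(n=57, sd=sd))
        assert fracs["short"] > 0.9 and fracs["long"] > 0.9
        assert p_cls < 1e-10  # short vs long second-condition L distributions


class TestRankSum:
    @pytest.mark.parametrize("nx,ny", [(5, 12), (8, 17)])
    def test_exact_p_matches_brute_force_enumeration(self, nx, ny):
        """DP enumeration (with ties) equals exhaustive subset enumeration."""
        rng = np.random.default_rng(SEED + nx)
        x = np.round(rng.normal(0.0, 1.0, nx), 1)  # rounding forces ties
        y = np.round(rng.normal(0.4, 1.0, ny), 1)
        p_impl = ss.rank_sum_p(x, y)
        ranks = stats.rankdata(np.concatenate([x, y]))
        obs = ranks[:nx].sum()
        sums = np.fromiter((sum(c) for c in combinations(ranks, nx)),
                           dtype=float, count=math.comb(nx + ny, nx))
        p_le = np.mean(sums <= obs + 1e-9)
        p_ge = np.mean(sums >= obs - 1e-9)
        p_brute = min(1.0, 2.0 * min(p_le, p_ge))
        assert p_impl == pytest.approx(p_brute, abs=1e-12)

    def test_large_samples_use_tie_corrected_asymptotics(self):
        rng = np.random.default_rng(SEED)
        x = rng.normal(0.5, 1.0, 40)
        y = rng.normal(0.0, 1.0, 60)
        expect = stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert ss.rank_sum_p(x, y) == pytest.approx(expect, rel=1e-12)


class TestEnrichment:
    def _mapping(self, terms):
        rows = [(g, t) for t, genes in terms.items() for g in genes]
        return pd.DataFrame(rows, columns=["gene_id", "term_id"])

    def test_shifted_term_detected(self):
        rng = np.random.default_rng(SEED)
        n = 1000
        rec = _records(rng.normal(1.0, 0.01, n), Gs=np.ones(n))
        term_genes = [f"g{i}" for i in range(10)]
        rec.loc[rec["strain_id"].isin(term_genes), "L"] += 0.05
        enr = ss.go_enrichment(rec, self._mapping({"GO:X": term_genes}))
        row = enr.iloc[0]
        assert row["p"] < 1e-4
        assert row["direction"] == "long"
        assert row["n_genes"] == 10

    def test_random_terms_give_uniform_p(self):
        rng = np.random.default_rng(SEED)
        n = 400
        rec = _records(rng.normal(1.0, 0.01, n), Gs=np.ones(n))
        terms = {f"GO:{k}": rng.choice(rec["strain_id"], 12, replace=False)
                 for k in range(80)}
        enr = ss.go_enrichment(rec, self._mapping(terms))
        assert stats.kstest(enr["p"], "uniform").pvalue > 1e-3

    def test_size_bounds_and_growth_filter(self):
        rng = np.random.default_rng(SEED)
        rec = _records(rng.normal(1.0, 0.01, 100),
                       Gs=[0.5] * 50 + [1.0] * 50)
        small = {"GO:small": [f"g{i}" for i in range(50, 53)]}     # n=3 < 5
        slow = {"GO:slow": [f"g{i}" for i in range(40, 50)]}       # all G<0.9
        okay = {"GO:ok": [f"g{i}" for i in range(50, 60)]}
        enr = ss.go_enrichment(rec, self._mapping({**small, **slow, **okay}))
        assert list(enr["term_id"]) == ["GO:ok"]
        assert enr.attrs["n_skipped_size"] == 2
        assert enr.attrs["n_background"] == 50


class TestCfu:
    def _counts(self, series_by_rep):
        rows = [(d, rep, c) for rep, series in series_by_rep.items()
                for d, c in series]
        return pd.DataFrame(rows, columns=["day", "replicate", "cfu"])

    def test_halved_counts_are_fifty_percent(self):
        counts = self._counts({1: [(4, 500), (10, 250)]})
        out = ss.cfu_survival_curve(counts)
        assert out.set_index("day").loc[10, "mean"] == pytest.approx(50.0)

    def test_flat_curve_is_hundred_percent(self):
        counts = self._counts({1: [(4, 300), (8, 300), (12, 300)]})
        out = ss.cfu_survival_curve(counts)
        assert np.allclose(out["mean"], 100.0)

    def test_sem_matches_hand_computation(self):
        counts = self._counts({1: [(4, 100), (10, 50)],
                               2: [(4, 200), (10, 120)],
                               3: [(4, 100), (10, 70)]})
        out = ss.cfu_survival_curve(counts).set_index("day")
        pct = np.array([50.0, 60.0, 70.0])
        assert out.loc[10, "mean"] == pytest.approx(pct.mean())
        assert out.loc[10, "sem"] == pytest.approx(pct.std(ddof=1) / np.sqrt(3))

    def test_missing_reference_day_is_error(self):
        counts = self._counts({1: [(10, 50)]})
        with pytest.raises(ValueError, match="day 4"):
            ss.cfu_survival_curve(counts)
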