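"""Cross-method statistics: standardization, mixed model, Wilcoxon, LOO."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import fossilclock as fc
from fossilclock.compare import (effect_size_model, loo_sensitivity,
                                 paired_wilcoxon, prior_sensitivity_report,
                                 standardize_ages)


def _age_table(rng, methods=("m1", "m2"), n_trees=30, clades=("a", "b", "c"),
               offsets=None):
    rows = []
    for m in methods:
        delta = (offsets or {}).get(m, 0.0)
        for t in range(n_trees):
            shared = rng.normal(0, 0.1)  # tree-level random effect
            for c in clades:
                base = {"a": 10.0, "b": 25.0, "c": 60.0}[c]
                rows.append({"analysis": m, "tree": t, "clade": c,
                             "age": base * math.exp(delta + shared +
                                                    rng.normal(0, 0.1))})
    return pd.DataFrame(rows)


class TestStandardize:
    def test_pooled_mean_zero_sd_one(self, rng):
        z = standardize_ages(_age_table(rng))
        g = z.groupby("clade")["z"]
        assert np.allclose(g.mean(), 0.0, atol=1e-9)
        assert np.allclose(g.std(ddof=1), 1.0, atol=1e-9)

    def test_uniformly_older_method_positive_mean_z(self, rng):
        z = standardize_ages(_age_table(rng, offsets={"m2": 0.5}))
        means = z.groupby("analysis")["z"].mean()
        assert means["m2"] > 0 > means["m1"]

    def test_hand_computed_example(self):
        # 2 methods x 2 trees x 1 clade
        table = pd.DataFrame({
            "analysis": ["p", "p", "q", "q"], "tree": [0, 1, 0, 1],
            "clade": ["c"] * 4, "age": [10.0, 12.0, 20.0, 24.0]})
        logs = np.log([10.0, 12.0, 20.0, 24.0])
        expected = (logs - logs.mean()) / logs.std(ddof=1)
        z = standardize_ages(table)
        assert np.allclose(z["z"].values, expected)

    def test_relabeling_invariance(self, rng):
        t = _age_table(rng)
        z1 = standardize_ages(t)["z"].values
        t2 = t.copy()
        t2["analysis"] = t2["analysis"].map({"m1": "zzz", "m2": "aaa"})
        z2 = standardize_ages(t2)["z"].values
        assert np.allclose(z1, z2)

    def test_zero_variance_clade_errors(self):
        table = pd.DataFrame({"analysis": ["p", "q"], "tree": [0, 0],
                              "clade": ["c", "c"], "age": [10.0, 10.0]})
        with pytest.raises(ValueError, match="c"):
            standardize_ages(table)


class TestEffectSizes:
    def test_recovers_known_offsets(self, rng):
        offsets = {"m1": 0.0, "m2": 0.6, "m3": -0.4}
        table = _age_table(rng, methods=tuple(offsets), n_trees=60,
                           offsets=offsets)
        z = standardize_ages(table)
        res = effect_size_model(z, seed=1)
        eff = res.effects.set_index("analysis")["effect"]
        # z-scale offsets: differences of effects should mirror differences
        # of the log offsets, rescaled by the pooled per-clade sd
        sd = z.groupby("clade")["z"].std().mean()  # ~1 by construction
        spread = eff["m2"] - eff["m3"]
        pooled_log_sd = table.assign(l=np.log(table["age"])).groupby(
            "clade")["l"].std(ddof=1).mean()
        expected = (offsets["m2"] - offsets["m3"]) / pooled_log_sd
        assert spread == pytest.approx(expected, rel=0.15)
        assert res.tree_variance > 0

    def test_identical_analyses_overlap(self, rng):
        table = _age_table(rng, methods=("m1", "m2"), n_trees=40)
        res = effect_size_model(standardize_ages(table), seed=2)
        e = res.effects.set_index("analysis")
        assert e.loc["m1", "low95"] < e.loc["m2", "effect"] < e.loc["m1", "high95"]

    def test_gibbs_matches_mixedlm(self, rng):
        """Cross-check against statsmodels MixedLM point estimates."""
        import statsmodels.formula.api as smf
        table = _age_table(rng, methods=("m1", "m2"), n_trees=50,
                           offsets={"m2": 0.4})
        z = standardize_ages(table)
        res = effect_size_model(z, seed=3)
        z = z.assign(group=z["analysis"].astype(str) + ":" + z["tree"].astype(str))
        fit = smf.mixedlm("z ~ 0 + analysis", z, groups=z["group"]).fit()
        for m in ("m1", "m2"):
            assert res.effect(m) == pytest.approx(
                fit.params[f"analysis[{m}]"], abs=0.05)

    def test_tree_random_effect_widens_intervals(self, rng):
        """With strong tree-level correlation, intervals from the mixed model
        are wider than the naive iid standard error."""
        rows = []
        for m in ("m1", "m2"):
            for t in range(40):
                shared = rng.normal(0, 0.5)
                for c in ("a", "b", "c", "d", "e", "f"):
                    rows.append({"analysis": m, "tree": t, "clade": c,
                                 "age": 20 * math.exp(shared + rng.normal(0, 0.05))})
        z = standardize_ages(pd.DataFrame(rows))
        res = effect_size_model(z, seed=4)
        e = res.effects.set_index("analysis")
        width = e.loc["m1", "high95"] - e.loc["m1", "low95"]
        per = z[z["analysis"] == "m1"]["z"]
        naive = 2 * 1.96 * per.std(ddof=1) / math.sqrt(len(per))
        assert width > 1.5 * naive

    def test_moments_fallback_close_to_gibbs(self, rng):
        table = _age_table(rng, offsets={"m2": 0.3})
        z = standardize_ages(table)
        g = effect_size_model(z, seed=5)
        m = effect_size_model(z, method="moments")
        for a in ("m1", "m2"):
            assert g.effect(a) == pytest.approx(m.effect(a), abs=0.05)

    def test_single_analysis_rejected(self, rng):
        t = _age_table(rng, methods=("only",))
        with pytest.raises(ValueError):
            effect_size_model(standardize_ages(t))


class TestWilcoxon:
    def test_matches_exact_enumeration(self):
        """Two-sided signed-rank p-value equals full 2^n enumeration."""
        d = np.array([1.3, -0.6, 2.1, 0.4, -1.7, 0.9])
        res = paired_wilcoxon(d, np.zeros_like(d))
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        n = len(d)
        w_obs = ranks[d > 0].sum()
        stats_all = [sum(r for r, s in zip(ranks, signs) if s)
                     for signs in itertools.product([0, 1], repeat=n)]
        total = len(stats_all)
        mean_w = n * (n + 1) / 4
        more_extreme = sum(1 for w in stats_all
                           if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12)
        assert res.pvalue == pytest.approx(more_extreme / total, abs=1e-10)

    def test_zero_differences_dropped(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 2.5, 2.0, 4.0])
        res = paired_wilcoxon(a, b)
        assert res.n_used == 2

    def test_all_equal(self):
        res = paired_wilcoxon(np.ones(5), np.ones(5))
        assert res.pvalue == 1.0 and res.n_used == 0


class TestPriorSensitivity:
    def _dens(self):
        from fossilclock.fossils import FossilRecord
        rec = FossilRecord("f", "c", 10.0, None, "stem_branch", "small")
        return fc.build_ndb_density(rec, 5.0, 90.0)

    def test_self_comparison_zero_deviation(self, rng):
        dens = self._dens()
        samples = {"c": dens.sample(rng, 500)}
        rep = prior_sensitivity_report({"c": dens}, samples, samples)
        assert rep["deviation"].iloc[0] == 0.0

    def test_strong_data_regime_larger_deviations(self, rng):
        """Posterior pulled away from the prior scores a larger 1:1-line
        deviation than a posterior that equals the effective prior."""
        dens = self._dens()
        eff = {"c": dens.sample(rng, 500)}
        weak = prior_sensitivity_report({"c": dens}, eff, {"c": eff["c"]})
        shifted = {"c": eff["c"] + 4.0}
        strong = prior_sensitivity_report({"c": dens}, eff, shifted)
        assert strong["deviation"].iloc[0] > weak["deviation"].iloc[0] + 3.0

    def test_unmatched_nodes_error(self, rng):
        dens = self._dens()
        s = {"c": dens.sample(rng, 100)}
        with pytest.raises(KeyError, match="d"):
            prior_sensitivity_report({"c": dens, "d": dens}, s, s)

    def test_quantiles_cover_specified_density(self, rng):
        dens = self._dens()
        s = {"c": dens.sample(rng, 4000)}
        rep = prior_sensitivity_report({"c": dens}, s, s)
        assert rep["specified_q0.5"].iloc[0] == pytest.approx(
            rep["effective_q0.5"].iloc[0], rel=0.05)


class TestLOO:
    def test_excluding_nothing_gives_zero_table(self, rng):
        ages = pd.DataFrame({"clade": ["a"] * 30 + ["b"] * 30,
                             "age": np.r_[rng.uniform(5, 6, 30),
                                          rng.uniform(20, 22, 30)]})

        def run(excluded):
            return ages  # exclusion-independent stub

        out = loo_sensitivity(run, ["F1", "F2"])
        assert np.allclose(out[["d_median", "d_low", "d_high"]].values, 0.0)

    def test_not_applicable_exclusions_recorded(self):
        ages = pd.DataFrame({"clade": ["a"] * 30, "age": np.linspace(5, 6, 30)})

        def run(excluded):
            if excluded == "F_sole":
                raise ValueError("no fossils left")
            return ages

        out = loo_sensitivity(run, ["F_sole", "F2"])
        sole = out[out["excluded"] == "F_sole"]
        assert not sole["applicable"].any()
        assert out[out["excluded"] == "F2"]["applicable"].all()
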