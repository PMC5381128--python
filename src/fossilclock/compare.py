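"""Cross-method comparison statistics for divergence-time analyses.

Given per-tree ages of named clades from several dating analyses, this
module standardizes log-ages per clade (pooling all trees and analyses),
fits a mixed-effect model of method effect sizes with tree identity as a
random intercept, quantifies sensitivity to leaving out single fossils, and
compares specified / effective-prior / posterior calibration densities with
a paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "standardize_ages",
    "effect_size_model",
    "EffectSizeResult",
    "loo_sensitivity",
    "prior_sensitivity_report",
    "compare_prior_sensitivity",
    "paired_wilcoxon",
]


def standardize_ages(table: pd.DataFrame) -> pd.DataFrame:
    """Per-clade z-scores of log ages pooled across all trees and analyses.

    ``table`` needs columns analysis, tree, clade, age. For each clade,
    z = (ln age - mean(ln age)) / sd(ln age) with mean and sd over every
    (analysis, tree) pair, so each clade's pooled z has mean 0 and sd 1 and
    ages become comparable across clades of very different depths. Natural
    log is used; the base cancels in the z-score anyway.
    """
    required = {"analysis", "tree", "clade", "age"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"age table missing columns: {sorted(missing)}")
    if (table["age"] <= 0).any():
        raise ValueError("ages must be positive to log-transform")
    out = table.copy()
    out["log_age"] = np.log(out["age"])
    stats_ = out.groupby("clade")["log_age"].agg(["mean", "std", "count"])
    bad = stats_.index[(stats_["std"] == 0) | stats_["std"].isna()]
    if len(bad):
        raise ValueError(f"zero age variance for clades: {list(bad)}")
    per_clade = out["clade"].map(stats_["mean"])
    sd = out["clade"].map(stats_["std"])
    out["z"] = (out["log_age"] - per_clade) / sd
    return out.drop(columns="log_age")


@dataclass
class EffectSizeResult:
    """Per-analysis standardized effect sizes from the mixed model."""

    effects: pd.DataFrame          # analysis, effect, low95, high95
    tree_variance: float           # random-intercept variance
    residual_variance: float
    draws: pd.DataFrame | None = None  # posterior draws per analysis (Gibbs)

    def effect(self, analysis: str) -> float:
        row = self.effects.set_index("analysis").loc[analysis]
        return float(row["effect"])


def effect_size_model(z_table: pd.DataFrame, method: str = "gibbs",
                      n_iter: int = 3000, burnin: int = 500,
                      seed: int = 0) -> EffectSizeResult:
    """Mixed-effect model of standardized ages with a tree random intercept.

    Model: z_i = alpha_{analysis(i)} + u_{tree(i)} + e_i with
    u ~ N(0, s_u^2), e ~ N(0, s_e^2); the random intercept absorbs the
    dependence among the clades measured on the same posterior tree.

    ``method='gibbs'`` runs a conjugate Gibbs sampler (flat prior on the
    alphas, inverse-gamma(0.001, 0.001) on both variances) and reports
    posterior means with 95% credible intervals. ``method='moments'`` is a
    fast fallback: per-analysis means of per-tree means with a
    cluster-robust normal interval.
    """
    req = {"analysis", "tree", "clade", "z"}
    if req - set(z_table.columns):
        raise ValueError(f"need columns {sorted(req)}")
    analyses = sorted(z_table["analysis"].unique())
    if len(analyses) < 2:
        raise ValueError("need at least 2 analyses to compare")
    groups = z_table["analysis"].astype(str) + "::" + z_table["tree"].astype(str)
    if method == "moments":
        cluster_means = z_table.assign(_g=groups).groupby(["analysis", "_g"])["z"].mean()
        rows = []
        for a in analyses:
            m = cluster_means.loc[a]
            eff = float(m.mean())
            se = float(m.std(ddof=1) / math.sqrt(len(m))) if len(m) > 1 else float("nan")
            rows.append({"analysis": a, "effect": eff,
                         "low95": eff - 1.959963984540054 * se,
                         "high95": eff + 1.959963984540054 * se})
        resid = z_table["z"] - z_table["analysis"].map(
            {r["analysis"]: r["effect"] for r in rows})
        between = float(cluster_means.groupby(level=0).var(ddof=1).mean())
        return EffectSizeResult(pd.DataFrame(rows), between,
                                float(resid.var(ddof=1)))
    if method != "gibbs":
        raise ValueError(f"unknown method {method!r}")

    z = z_table["z"].to_numpy(float)
    a_idx = pd.Categorical(z_table["analysis"], categories=analyses).codes
    g_codes, g_labels = pd.factorize(groups)
    n_a = len(analyses)
    n_g = len(g_labels)
    n = z.size
    rng = np.random.default_rng(seed)
    # sufficient statistics
    count_a = np.bincount(a_idx, minlength=n_a).astype(float)
    count_g = np.bincount(g_codes, minlength=n_g).astype(float)
    alpha = np.array([z[a_idx == k].mean() for k in range(n_a)])
    u = np.zeros(n_g)
    s_e2, s_u2 = 1.0, 0.5
    a0 = b0 = 1e-3
    draws = np.empty((n_iter - burnin, n_a))
    su2_draws = np.empty(n_iter - burnin)
    se2_draws = np.empty(n_iter - burnin)
    for it in range(n_iter):
        resid_u = z - u[g_codes]
        mean_a = np.bincount(a_idx, weights=resid_u, minlength=n_a) / count_a
        alpha = mean_a + rng.normal(0, np.sqrt(s_e2 / count_a))
        resid_a = z - alpha[a_idx]
        prec = count_g / s_e2 + 1.0 / s_u2
        mu_u = (np.bincount(g_codes, weights=resid_a, minlength=n_g) / s_e2) / prec
        u = mu_u + rng.normal(0, np.sqrt(1.0 / prec))
        err = resid_a - u[g_codes]
        s_e2 = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + 0.5 * float(err @ err)))
        s_u2 = 1.0 / rng.gamma(a0 + n_g / 2.0, 1.0 / (b0 + 0.5 * float(u @ u)))
        if it >= burnin:
            draws[it - burnin] = alpha
            su2_draws[it - burnin] = s_u2
            se2_draws[it - burnin] = s_e2
    rows = []
    for k, a in enumerate(analyses):
        lo, hi = np.quantile(draws[:, k], [0.025, 0.975])
        rows.append({"analysis": a, "effect": float(draws[:, k].mean()),
                     "low95": float(lo), "high95": float(hi)})
    return EffectSizeResult(pd.DataFrame(rows), float(su2_draws.mean()),
                            float(se2_draws.mean()),
                            pd.DataFrame(draws, columns=analyses))


# ---------------------------------------------------------------------------
# leave-one-fossil-out sensitivity
# ---------------------------------------------------------------------------

def loo_sensitivity(run_analysis, fossils, clade_names=None) -> pd.DataFrame:
    """Re-run an analysis leaving out one fossil at a time.

    ``run_analysis(excluded_name_or_None)`` must return a clade-age table
    (columns clade, age over posterior trees) for the analysis with the
    named fossil excluded (``None`` = the full fossil set). For each fossil
    the per-clade shifts (kept minus removed) of the median and of the 95%
    HPD-ish quantile bounds are tabulated. A run that raises ``ValueError``
    (e.g. the exclusion empties a calibration set) is recorded as not
    applicable rather than failing.
    """
    base = run_analysis(None)

    def summary(table):
        g = table.groupby("clade")["age"]
        return pd.DataFrame({"median": g.median(),
                             "low": g.quantile(0.025),
                             "high": g.quantile(0.975)})

    base_s = summary(base)
    names = clade_names or list(base_s.index)
    rows = []
    for rec in fossils:
        name = getattr(rec, "name", rec)
        try:
            table = run_analysis(name)
        except ValueError:
            for clade in names:
                rows.append({"excluded": name, "clade": clade,
                             "applicable": False, "d_median": np.nan,
                             "d_low": np.nan, "d_high": np.nan})
            continue
        s = summary(table)
        for clade in names:
            rows.append({
                "excluded": name, "clade": clade, "applicable": True,
                "d_median": float(base_s.loc[clade, "median"] - s.loc[clade, "median"]),
                "d_low": float(base_s.loc[clade, "low"] - s.loc[clade, "low"]),
                "d_high": float(base_s.loc[clade, "high"] - s.loc[clade, "high"]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# specified / effective / posterior prior diagnostics
# ---------------------------------------------------------------------------

_QUANTS = (0.025, 0.25, 0.5, 0.75, 0.975)


def prior_sensitivity_report(specified: dict, effective: dict,
                             posterior: dict) -> pd.DataFrame:
    """Quantile table and 1:1-line deviations per calibration node.

    ``specified`` maps node name -> CalibrationDensity; ``effective`` and
    ``posterior`` map node name -> array of sampled ages (prior-only and
    full runs). All three must cover the same nodes. ``deviation`` is the
    absolute difference between the posterior and effective-prior medians —
    the node's distance from the 1:1 line; large values mean the sequence
    data, not the prior, drives the estimate.
    """
    keys = set(specified) | set(effective) | set(posterior)
    unmatched = [k for k in sorted(keys)
                 if k not in specified or k not in effective or k not in posterior]
    if unmatched:
        raise KeyError(f"calibration nodes not present in all sources: {unmatched}")
    rows = []
    for node in sorted(specified):
        dens = specified[node]
        eff = np.asarray(effective[node], float)
        post = np.asarray(posterior[node], float)
        row = {"node": node}
        for q in _QUANTS:
            row[f"specified_q{q}"] = dens.ppf(q)
            row[f"effective_q{q}"] = float(np.quantile(eff, q))
            row[f"posterior_q{q}"] = float(np.quantile(post, q))
        row["deviation"] = abs(row["posterior_q0.5"] - row["effective_q0.5"])
        row["effective_shift"] = row["effective_q0.5"] - row["specified_q0.5"]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class WilcoxonResult:
    statistic: float
    pvalue: float
    n_used: int


def paired_wilcoxon(a, b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's convention); the exact null
    distribution is used for up to 25 non-zero pairs, the normal
    approximation with continuity correction above.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(0.0, 1.0, 0)
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method,
                         correction=(method == "approx"), zero_method="wilcox")
    return WilcoxonResult(float(res.statistic), float(res.pvalue), int(d.size))


def compare_prior_sensitivity(devs_a, devs_b) -> WilcoxonResult:
    """Paired Wilcoxon on two methods' per-node 1:1-line deviations."""
    return paired_wilcoxon(devs_a, devs_b)
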