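"""Tree-prior densities: birth-death, FBD, relaxed clock.

Oracles: closed-form Yule densities, numeric quadrature (normalization),
forward Monte-Carlo simulation (density ratios), and scipy distributions
(UCLN terms). The FBD density must degenerate to the birth-death density at
psi = 0 although the two are computed through different parameterizations.
"""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import fossilclock as fc
from fossilclock.priors import (BDParams, FBDParams, bd_log_prior, bd_p0,
                                bd_p1, fbd_log_density, fbd_p0, fbd_q,
                                ucln_log_prior)
from fossilclock.tree import ValidationError


def two_tip(t):
    return fc.parse_tree(f"(A:{t},B:{t});")


class TestBirthDeath:
    def test_yule_two_tip_closed_form(self):
        """With mu=0, rho=1 the 2-tip root-age density is 2*lam*exp(-2*lam*t)."""
        lam = 0.3
        p = BDParams(lam, 0.0, 1.0)
        for t in (0.5, 2.0, 7.0):
            expected = math.log(2 * lam) - 2 * lam * t
            assert bd_log_prior(two_tip(t), p) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("lam,mu,rho", [
        (0.1, 0.0, 1.0), (0.2, 0.1, 1.0), (0.15, 0.05, 0.6)])
    def test_two_tip_density_integrates_to_one(self, lam, mu, rho):
        p = BDParams(lam, mu, rho)
        val, err = integrate.quad(lambda t: math.exp(bd_log_prior(two_tip(t), p)),
                                  0, np.inf, limit=200)
        assert val == pytest.approx(1.0, abs=max(1e-6, 3 * err))

    def test_rejects_non_ultrametric(self):
        t = fc.parse_tree("((A:1,F:0.5):1,B:2);")
        with pytest.raises(ValidationError):
            bd_log_prior(t, BDParams(0.1))

    def test_p0_p1_limits(self):
        p = BDParams(0.3, 0.1, 0.8)
        assert bd_p0(0.0, p) == pytest.approx(1 - 0.8)
        assert bd_p1(0.0, p) == pytest.approx(0.8)
        # long horizon: extinction-or-unsampled probability -> 1 - r/lambda
        assert bd_p0(1e4, p) == pytest.approx(1 - 0.2 / 0.3, abs=1e-9)

    def test_critical_process_rejected(self):
        with pytest.raises(ValueError):
            BDParams(0.1, 0.1)


class TestFBD:
    def test_degenerates_to_birth_death(self, rng):
        """psi=0, no fossils: FBD equals the BD density to 1e-8 on 100 trees."""
        bd = BDParams(0.2, 0.08, 0.9)
        fbd = FBDParams(0.2, 0.08, 0.9, 0.0)
        for _ in range(100):
            t = fc.fast_bd_tree(int(rng.integers(3, 9)), bd, rng)
            assert fbd_log_density(t, fbd) == pytest.approx(
                bd_log_prior(t, bd), abs=1e-8)

    def test_p0_q_reduce_to_bd_forms(self):
        bd = BDParams(0.25, 0.1, 0.7)
        fbd = FBDParams(0.25, 0.1, 0.7, 0.0)
        for t in (0.1, 1.0, 5.0, 20.0):
            assert fbd_p0(t, fbd) == pytest.approx(float(bd_p0(t, bd)), abs=1e-10)
            assert float(fbd_q(t, fbd)) * 0.7 == pytest.approx(
                float(bd_p1(t, bd)), abs=1e-10)

    def test_fossil_requires_positive_psi(self):
        t = fc.parse_tree("((A:2,F:1):1,B:3);")
        assert fbd_log_density(t, FBDParams(0.2, 0.05, 1.0, 0.0)) == -math.inf
        assert math.isfinite(fbd_log_density(t, FBDParams(0.2, 0.05, 1.0, 0.1)))

    def test_fossil_age_density_ratio_matches_forward_simulation(self):
        """On 2-extant + 1-fossil realizations where the fossil is a sampled
        ancestor on the stem lineage above the extant root, the analytic
        density ratio across two fossil-age bins matches the ratio of
        Monte-Carlo frequencies from forward simulation."""
        from fossilclock.simulate import _forward_once

        p = FBDParams(0.6, 0.15, 1.0, 0.3)
        bdp = BDParams(0.6, 0.15, 1.0)
        rng = np.random.default_rng(777)
        horizon = 20.0
        pairs = []  # (fossil age, extant root age)
        for _ in range(150_000):
            origin = float(rng.uniform(0, horizon))
            out = _forward_once(origin, bdp, rng, 60)
            if out is None:
                continue
            full, tips = out
            if len(tips) != 2:
                continue
            events = fc.simulate_fossil_events(full, p.psi, rng)
            if len(events) != 1:
                continue
            for i, t in enumerate(tips):
                t.label = f"t{i}"
            tree = fc.reconstruct_fbd_tree(full, [t.label for t in tips], events)
            root = tree.root
            if (root.is_sampled_ancestor and len(root.children) == 1
                    and not root.children[0].is_leaf):
                pairs.append((root.age, root.children[0].age))
        ages = np.asarray([y for y, _ in pairs])
        assert ages.size > 800
        y_lo, y_hi, w = 0.8, 2.8, 0.6
        n_lo = int(np.sum(np.abs(ages - y_lo) < w / 2))
        n_hi = int(np.sum(np.abs(ages - y_hi) < w / 2))
        assert min(n_lo, n_hi) > 40
        mc_ratio = n_lo / n_hi

        def marginal(y):
            # integrate the joint density over the extant root age
            def dens(xr):
                t = _sa_above_root(xr, y)
                return math.exp(fbd_log_density(t, p, condition_on_n=False))
            val, _ = integrate.quad(dens, 0.0, y, limit=100)
            return val

        def bin_mass(y):
            ys = np.linspace(y - w / 2, y + w / 2, 5)
            return integrate.simpson([marginal(v) for v in ys], x=ys)

        analytic_ratio = bin_mass(y_lo) / bin_mass(y_hi)
        se = mc_ratio * math.sqrt(1 / n_lo + 1 / n_hi)
        assert mc_ratio == pytest.approx(analytic_ratio,
                                         abs=4 * se + 0.08 * analytic_ratio)


def test_tip_attachment_density_continuous_at_fossil_age():
    """As the attachment age of an extinct side tip approaches the fossil's
    age, the density approaches a finite limit (lambda*psi*p0(y) times the
    remaining factors) rather than diverging; the sampled-ancestor state
    lives in a lower-dimensional subspace with its own psi factor."""
    p = FBDParams(0.3, 0.1, 1.0, 0.1)
    y, xr = 1.5, 4.0
    vals = [fbd_log_density(_two_plus_fossil(xr, y + eps, y), p)
            for eps in (1e-2, 1e-4, 1e-6, 1e-8)]
    assert all(math.isfinite(v) for v in vals)
    diffs = [abs(b - a) for a, b in zip(vals, vals[1:])]
    assert diffs[-1] < 1e-5 and diffs[-1] < diffs[0] + 1e-12


def _two_plus_fossil(x_root, x_att, y):
    """((tA, F):..., tB) with fossil F attached at x_att on tA's branch."""
    from fossilclock.tree import TimeTree, TreeNode
    root = TreeNode(None, x_root)
    att = root.add_child(TreeNode(None, x_att))
    att.add_child(TreeNode("A", 0.0))
    att.add_child(TreeNode("F", y, is_fossil=True))
    root.add_child(TreeNode("B", 0.0))
    return TimeTree(root)


def _sa_above_root(x_root, y):
    """Fossil F as a sampled ancestor on the stem above the extant root."""
    from fossilclock.tree import TimeTree, TreeNode
    sa = TreeNode("F", y)
    sa.is_sampled_ancestor = True
    root = sa.add_child(TreeNode(None, x_root))
    root.add_child(TreeNode("A", 0.0))
    root.add_child(TreeNode("B", 0.0))
    return TimeTree(sa)


class TestUCLN:
    def test_matches_scipy_lognorm(self, rng):
        sd = 0.5
        dist = stats.lognorm(s=sd, scale=math.exp(-0.5 * sd * sd))
        m = rng.lognormal(-0.125, sd, size=12)
        expected = float(np.sum(dist.logpdf(m)))
        assert ucln_log_prior(m, sd) == pytest.approx(expected, abs=1e-9)

    def test_mean_one_on_real_scale(self):
        # the density's mean is 1: location must be -sd^2/2
        sd = 0.7
        dist = stats.lognorm(s=sd, scale=math.exp(-0.5 * sd * sd))
        assert dist.mean() == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_at_median(self):
        sd = 0.4
        med = math.exp(-0.5 * sd * sd)
        expected = -math.log(med) - math.log(sd) - 0.5 * math.log(2 * math.pi)
        assert ucln_log_prior([med], sd) == pytest.approx(expected, abs=1e-12)

    def test_small_sd_concentrates_at_strict_clock(self):
        assert ucln_log_prior([1.0], 0.01) > ucln_log_prior([1.0], 0.5)
        assert ucln_log_prior([2.0], 0.01) < ucln_log_prior([2.0], 0.5)

    def test_nonpositive_multiplier(self):
        assert ucln_log_prior([1.0, -0.1], 0.3) == -math.inf
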