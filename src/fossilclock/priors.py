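"""Birth-death and fossilized-birth-death tree priors, and the relaxed clock.

Both tree priors use the same convention: the process starts from a single
lineage at an origin time with an (improper) uniform prior, extant tips are
Bernoulli(rho)-sampled at the present, fossils are Poisson(psi)-sampled
through time, and the density is conditioned on the number of extant samples
n. Because fossil sampling does not change the forward dynamics of the
lineage process, the conditioning constant depends only on (lambda, mu, rho,
n) and the FBD density degenerates exactly to the birth-death density as
psi -> 0 with no fossils.

Notation (per lineage, time t before present):

* ``p0(t)`` — probability of leaving no sampled descendants at all;
* ``p1(t)`` — probability of exactly one sampled extant descendant lineage
  (birth-death case);
* ``q(t)`` — probability density contribution of a lineage at time t that is
  ancestral to the observed sample, used in the standard product-form tree
  density: one factor ``lambda*q(x)`` per bifurcation at age x, ``rho`` per
  extant tip, ``psi*p0(y)/q(y)`` per fossil tip at age y, ``psi`` per
  sampled ancestor, and the integrated origin factor ``Q(x_root)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .tree import TimeTree, ValidationError

__all__ = [
    "BDParams",
    "FBDParams",
    "bd_log_prior",
    "fbd_log_density",
    "ucln_log_prior",
    "bd_p0",
    "bd_p1",
    "fbd_p0",
    "fbd_q",
]


@dataclass(frozen=True)
class BDParams:
    """Constant-rate birth-death with extant sampling fraction rho."""

    birth: float            # lambda, 1/Ma
    death: float = 0.0      # mu, 1/Ma
    rho: float = 1.0        # extant sampling probability

    def __post_init__(self) -> None:
        if self.birth <= 0:
            raise ValueError(f"birth rate must be > 0, got {self.birth}")
        if self.death < 0:
            raise ValueError(f"death rate must be >= 0, got {self.death}")
        if not 0 < self.rho <= 1:
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if abs(self.birth - self.death) < 1e-12:
            raise ValueError("critical process (lambda == mu) is not supported")


@dataclass(frozen=True)
class FBDParams:
    """Fossilized birth-death: BD plus fossil sampling rate psi (1/Ma)."""

    birth: float
    death: float = 0.0
    rho: float = 1.0
    psi: float = 0.0

    def __post_init__(self) -> None:
        BDParams(self.birth, self.death, self.rho)
        if self.psi < 0:
            raise ValueError(f"psi must be >= 0, got {self.psi}")

    @property
    def bd(self) -> BDParams:
        return BDParams(self.birth, self.death, self.rho)


# ---------------------------------------------------------------------------
# birth-death (psi = 0) building blocks
# ---------------------------------------------------------------------------

def _bd_terms(p: BDParams):
    r = p.birth - p.death
    A = p.rho * p.birth
    B = p.birth * (1.0 - p.rho) - p.death
    return r, A, B


def bd_p0(t, p: BDParams):
    """P(no sampled extant descendant) for a lineage at time t."""
    r, A, B = _bd_terms(p)
    return 1.0 - p.rho * r / (A + B * np.exp(-r * t))


def bd_p1(t, p: BDParams):
    """P(exactly one sampled extant descendant lineage)."""
    r, A, B = _bd_terms(p)
    denom = A + B * np.exp(-r * t)
    return p.rho * r * r * np.exp(-r * t) / (denom * denom)


def _bd_log_q(t, p: BDParams):
    r, A, B = _bd_terms(p)
    return (2.0 * math.log(abs(r)) - r * t
            - 2.0 * math.log(abs(A + B * math.exp(-r * t))))


def _bd_log_Q(x, p: BDParams):
    """log of Q(x) = integral of q from x to infinity."""
    r, A, B = _bd_terms(p)
    val = r * math.exp(-r * x) / (A * (A + B * math.exp(-r * x)))
    if val <= 0:  # numerical underflow at extreme ages
        return -math.inf
    return math.log(val)


_COND_CACHE: dict[tuple, float] = {}


def _log_cond_n(p: BDParams, n: int) -> float:
    """log integral over origin of P(exactly n extant samples | origin).

    P(n | t) is geometric: p1(t) * eta(t)**(n-1) with
    eta = 1 - p1 / (1 - p0). Independent of psi, so shared by BD and FBD.
    """
    key = (round(p.birth, 14), round(p.death, 14), round(p.rho, 14), n)
    if key not in _COND_CACHE:
        def integrand(t):
            p1 = bd_p1(t, p)
            if n == 1:
                return p1
            eta = 1.0 - p1 / (1.0 - bd_p0(t, p))
            return p1 * eta ** (n - 1)
        val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
        if val <= 0:
            raise ValueError("conditioning integral vanished; check parameters")
        _COND_CACHE[key] = math.log(val)
    return _COND_CACHE[key]


def bd_log_prior(tree: TimeTree, p: BDParams, condition_on_n: bool = True) -> float:
    """Log-density of an extant-only time-tree under the sampled birth-death.

    Uniform origin prior integrated out; conditioned on the number of sampled
    extant tips n. For a 2-tip tree this density integrates to 1 over the
    root age.
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValidationError("birth-death prior needs at least 2 tips")
    for leaf in leaves:
        if leaf.is_fossil or abs(leaf.age) > 1e-9:
            raise ValidationError(
                f"bd_log_prior requires an ultrametric extant-only tree; "
                f"tip {leaf.label!r} has age {leaf.age}")
    n = len(leaves)
    logf = _bd_log_Q(tree.root.age, p) + n * math.log(p.rho)
    log_lam = math.log(p.birth)
    for node in tree.internal_nodes():
        logf += log_lam + _bd_log_q(node.age, p)
    if condition_on_n:
        logf -= _log_cond_n(p, n)
    return logf


# ---------------------------------------------------------------------------
# fossilized birth-death
# ---------------------------------------------------------------------------

def _fbd_terms(p: FBDParams):
    lam, mu, psi, rho = p.birth, p.death, p.psi, p.rho
    c1 = math.sqrt((lam - mu - psi) ** 2 + 4.0 * lam * psi)
    c2 = -(lam - mu - 2.0 * lam * rho - psi) / c1
    return c1, c2


def fbd_p0(t, p: FBDParams):
    """P(lineage at time t leaves no samples at all: extant or fossil)."""
    lam, mu, psi = p.birth, p.death, p.psi
    c1, c2 = _fbd_terms(p)
    e = np.exp(-c1 * t)
    frac = (e * (1.0 - c2) - (1.0 + c2)) / (e * (1.0 - c2) + (1.0 + c2))
    return (lam + mu + psi + c1 * frac) / (2.0 * lam)


def fbd_q(t, p: FBDParams):
    c1, c2 = _fbd_terms(p)
    e = np.exp(-c1 * t)
    denom = e * (1.0 - c2) + (1.0 + c2)
    return 4.0 * e / (denom * denom)


def _fbd_log_q(t, p: FBDParams) -> float:
    c1, c2 = _fbd_terms(p)
    e = math.exp(-c1 * t)
    return math.log(4.0) - c1 * t - 2.0 * math.log(e * (1.0 - c2) + (1.0 + c2))


def _fbd_log_Q(x, p: FBDParams) -> float:
    """log integral of q from x to infinity (closed form)."""
    c1, c2 = _fbd_terms(p)
    a, b = 1.0 - c2, 1.0 + c2
    e = math.exp(-c1 * x)
    if abs(a) > 1e-10:
        val = (4.0 / c1) * (1.0 / a) * (1.0 / b - 1.0 / (a * e + b))
    else:  # c2 -> 1 limit (e.g. Yule with full sampling)
        val = (4.0 / c1) * e / (b * b)
    if val <= 0:  # numerical underflow at extreme ages
        return -math.inf
    return math.log(val)


def fbd_log_density(tree: TimeTree, p: FBDParams, condition_on_n: bool = True) -> float:
    """Log-density of a sampled tree (fossil tips / sampled ancestors allowed)
    under the fossilized birth-death process.

    rho-sampling at the present; not conditioned on sampled descendants on
    both sides of the root ("root sampling"), only on the number of extant
    samples. Fossil tips at age y contribute psi*p0(y)/q(y); sampled
    ancestors contribute psi; bifurcations at age x contribute lambda*q(x).
    """
    leaves = tree.leaves()
    extant = [l for l in leaves if not l.is_fossil]
    if len(extant) < 1:
        raise ValidationError("need at least one extant sample")
    fossils = [l for l in leaves if l.is_fossil]
    ancestors = [nd for nd in tree.preorder() if nd.is_sampled_ancestor]
    if (fossils or ancestors) and p.psi <= 0:
        return -math.inf
    n = len(extant)
    logf = _fbd_log_Q(tree.root.age, p) + n * math.log(p.rho)
    log_lam = math.log(p.birth)
    log_psi = math.log(p.psi) if p.psi > 0 else 0.0
    for node in tree.internal_nodes():
        if node.is_sampled_ancestor:
            continue  # degree-2 pass-through, not a birth event
        logf += log_lam + _fbd_log_q(node.age, p)
    for f in fossils:
        p0 = float(fbd_p0(f.age, p))
        if p0 <= 0:
            return -math.inf
        logf += log_psi + math.log(p0) - _fbd_log_q(f.age, p)
    logf += len(ancestors) * log_psi
    if condition_on_n:
        logf -= _log_cond_n(p.bd, n)
    return logf


# ---------------------------------------------------------------------------
# relaxed clock
# ---------------------------------------------------------------------------

def ucln_log_prior(multipliers, log_sd: float) -> float:
    """Log-prior of uncorrelated log-normal branch-rate multipliers.

    Multipliers are iid log-normal with mean 1 on the real scale, i.e.
    log-scale location -log_sd**2/2 and scale log_sd. Returns -inf for any
    non-positive multiplier; log_sd -> 0 concentrates on the strict clock.
    """
    m = np.asarray(multipliers, dtype=float)
    if np.any(m <= 0):
        return -math.inf
    if log_sd <= 0:
        raise ValueError(f"log_sd must be > 0, got {log_sd}")
    mu = -0.5 * log_sd * log_sd
    z = (np.log(m) - mu) / log_sd
    return float(np.sum(-np.log(m) - math.log(log_sd) - 0.5 * math.log(2 * math.pi)
                        - 0.5 * z * z))
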