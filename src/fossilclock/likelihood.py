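"""Substitution models, relaxed-clock bookkeeping and the pruning likelihood.

States are ordered A, C, G, T. Gaps and N are treated as fully ambiguous.
Branch lengths in expected substitutions per site are the product of branch
duration (Ma), the clock's mean rate (substitutions/site/Ma) and the
branch's rate multiplier (UCLN relaxed clock; 1.0 under a strict clock).
Tree tips absent from the alignment (fossils without sequence data) carry
fully ambiguous partials and therefore do not affect the likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignment import Alignment
from .tree import TimeTree, TreeNode

__all__ = [
    "SubstitutionModel",
    "ClockModel",
    "index_tree",
    "felsenstein_log_likelihood",
]

_STATES = "ACGT"
_STATE_INDEX = {c: i for i, c in enumerate(_STATES)}
# IUPAC-ish: everything not ACGT is fully ambiguous
_AMBIG = np.ones(4)

_GTR_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))  # AC AG AT CG CT GT
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible nucleotide substitution model (JC, HKY or GTR).

    ``rates`` are the six GTR exchangeabilities in order AC, AG, AT, CG, CT,
    GT (ignored for JC/HKY); ``kappa`` is the HKY transition/transversion
    rate ratio. ``gamma_shape`` switches on discrete-gamma rate variation
    with ``n_categories`` equal-probability categories (category rates are
    the means of the quantile bands).
    """

    family: str = "JC"
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 2.0
    rates: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    gamma_shape: float | None = None
    n_categories: int = 4

    def __post_init__(self) -> None:
        if self.family not in ("JC", "HKY", "GTR"):
            raise ValueError(f"unknown substitution model family {self.family!r}")
        f = np.asarray(self.freqs, float)
        if f.shape != (4,) or abs(f.sum() - 1.0) > 1e-8 or np.any(f <= 0):
            raise ValueError("base frequencies must be 4 positive values summing to 1")
        if self.family == "JC" and not np.allclose(f, 0.25):
            raise ValueError("JC requires equal base frequencies")
        if any(r <= 0 for r in self.rates) or self.kappa <= 0:
            raise ValueError("exchangeabilities must be positive")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    # -- rate matrix -------------------------------------------------------
    def _exchangeabilities(self) -> np.ndarray:
        s = np.zeros((4, 4))
        if self.family == "GTR":
            vals = self.rates
        elif self.family == "HKY":
            vals = [self.kappa if (i, j) in _TRANSITIONS else 1.0
                    for (i, j) in _GTR_PAIRS]
        else:
            vals = [1.0] * 6
        for (i, j), v in zip(_GTR_PAIRS, vals):
            s[i, j] = s[j, i] = v
        return s

    def rate_matrix(self) -> np.ndarray:
        """Q normalized to one expected substitution per site per unit time."""
        pi = np.asarray(self.freqs, float)
        q = self._exchangeabilities() * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -float(np.dot(pi, np.diag(q)))
        return q / scale

    def _eigen(self):
        cached = getattr(self, "_eigen_cache", None)
        if cached is not None:
            return cached
        pi = np.asarray(self.freqs, float)
        sq = np.sqrt(pi)
        sym = self.rate_matrix() * sq[:, None] / sq[None, :]
        w, v = np.linalg.eigh((sym + sym.T) / 2.0)
        left = v.T * sq[None, :]        # rows: v^T diag(sqrt pi)
        right = (v.T / sq[None, :]).T   # diag(1/sqrt pi) v
        object.__setattr__(self, "_eigen_cache", (w, right, left))
        return w, right, left

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt)."""
        if t < 0:
            raise ValueError(f"negative branch length {t}")
        w, right, left = self._eigen()
        p = (right * np.exp(w * t)[None, :]) @ left
        return np.clip(p, 0.0, None)

    def category_rates(self) -> np.ndarray:
        """Discrete-gamma category rates (mean 1), or [1] without gamma."""
        if self.gamma_shape is None:
            return np.ones(1)
        k = self.n_categories
        a = self.gamma_shape
        edges = stats.gamma.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        # mean within each band via the incomplete-gamma identity
        upper = stats.gamma.cdf(edges[1:], a + 1, scale=1.0 / a)
        lower = stats.gamma.cdf(edges[:-1], a + 1, scale=1.0 / a)
        rates = (upper - lower) * k
        return rates / rates.mean()


@dataclass
class ClockModel:
    """Partitioned UCLN relaxed clock.

    ``clock_of`` maps locus name -> clock id (all loci share one clock unless
    split); each clock has a mean rate (substitutions/site/Ma), a log-scale
    s.d. for its branch-rate multipliers, and a multiplier per branch keyed
    by the child node's stable index (see :func:`index_tree`); missing keys
    default to 1.0 (strict clock).
    """

    clock_of: dict = field(default_factory=dict)
    mean_rate: dict = field(default_factory=dict)      # clock id -> rate
    log_sd: dict = field(default_factory=dict)         # clock id -> sd
    multipliers: dict = field(default_factory=dict)    # clock id -> {node_id: m}

    def clock_for(self, locus: str) -> str:
        return self.clock_of.get(locus, "shared")

    def branch_rate(self, clock_id: str, node_index: int) -> float:
        mult = self.multipliers.get(clock_id, {}).get(node_index, 1.0)
        rate = self.mean_rate.get(clock_id, 1.0)
        if rate <= 0 or mult <= 0:
            raise ValueError("clock rates and multipliers must be positive")
        return rate * mult

    def copy(self) -> "ClockModel":
        return ClockModel(dict(self.clock_of), dict(self.mean_rate),
                          dict(self.log_sd),
                          {k: dict(v) for k, v in self.multipliers.items()})


def index_tree(tree: TimeTree) -> dict[int, int]:
    """Stable node indices: postorder with children visited in label order.

    Returns a mapping id(node) -> index. Indices are reproducible across
    copies of the same topology, which lets branch multipliers survive
    tree copies during MCMC.
    """
    order: list[TreeNode] = []

    def key(node: TreeNode) -> str:
        if node.is_leaf:
            return node.label or ""
        return min(key(c) for c in node.children)

    def walk(node: TreeNode) -> None:
        for child in sorted(node.children, key=key):
            walk(child)
        order.append(node)

    walk(tree.root)
    return {id(n): i for i, n in enumerate(order)}


def _tip_partials(aln: Alignment, locus: str) -> dict[str, np.ndarray]:
    cache = getattr(aln, "_partials_cache", None)
    if cache is None:
        cache = {}
        aln._partials_cache = cache
    if locus in cache:
        return cache[locus]
    sub = aln.columns(locus)
    out = {}
    for label, seq in zip(sub.labels, sub.sequences):
        arr = np.zeros((len(seq), 4))
        for s, ch in enumerate(seq):
            idx = _STATE_INDEX.get(ch)
            if idx is None:
                arr[s] = _AMBIG
            else:
                arr[s, idx] = 1.0
        out[label] = arr
    cache[locus] = out
    return out


def felsenstein_log_likelihood(aln: Alignment, tree: TimeTree,
                               clock: ClockModel,
                               models) -> float:
    """Pruning-algorithm log-likelihood of the alignment on the time-tree.

    ``models`` is a single :class:`SubstitutionModel` or a dict mapping locus
    name -> model. Raises if the alignment contains taxa missing from the
    tree; tree tips without sequences are fully ambiguous.
    """
    tip_labels = set(tree.tip_labels())
    orphans = [l for l in aln.labels if l not in tip_labels]
    if orphans:
        raise ValueError(f"alignment taxa not in tree: {sorted(orphans)}")
    node_index = index_tree(tree)
    total = 0.0
    for locus in aln.partitions:
        model = models[locus] if isinstance(models, dict) else models
        clock_id = clock.clock_for(locus)
        partials = _tip_partials(aln, locus)
        n_sites = next(iter(partials.values())).shape[0]
        pi = np.asarray(model.freqs, float)
        cat_rates = model.category_rates()
        site_lik = np.zeros(n_sites)
        for cat_rate in cat_rates:
            lik, log_scale = _prune(tree.root, partials, model, clock,
                                    clock_id, node_index, cat_rate, n_sites)
            site_lik += (lik @ pi) * np.exp(log_scale) / len(cat_rates)
        if np.any(site_lik <= 0):
            return -math.inf
        total += float(np.sum(np.log(site_lik)))
    return total


def _prune(node: TreeNode, partials, model, clock, clock_id,
           node_index, cat_rate, n_sites):
    """Post-order partial likelihoods with per-node rescaling.

    Returns (partials array [sites x 4], per-site log scaling factors).
    """
    if node.is_leaf:
        arr = partials.get(node.label)
        if arr is None:
            arr = np.ones((n_sites, 4))
        return arr, np.zeros(n_sites)
    acc = np.ones((n_sites, 4))
    log_scale = np.zeros(n_sites)
    children = list(node.children)
    if node.is_sampled_ancestor:
        pass  # the fossil label has no data; degree-2 node passes through
    for child in children:
        carr, cscale = _prune(child, partials, model, clock, clock_id,
                              node_index, cat_rate, n_sites)
        bl = child.branch_duration * clock.branch_rate(
            clock_id, node_index.get(id(child), -1)) * cat_rate
        p = model.transition_matrix(bl)
        acc *= carr @ p.T
        log_scale += cscale
    top = acc.max(axis=1)
    top[top == 0] = 1.0
    return acc / top[:, None], log_scale + np.log(top)
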