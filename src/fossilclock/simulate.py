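"""Synthetic data with known ground truth: trees, fossils, alignments.

Two birth-death simulators are provided. ``simulate_bd_tree`` runs the
process forward in time from a uniformly drawn origin, applies
Bernoulli(rho) sampling at the present and rejects until exactly n extant
tips are sampled — an implementation independent of the analytic tree
priors, usable as a simulation oracle at small n. ``fast_bd_tree`` builds a
tree of the same conditioned process directly (node ages drawn by inverse
CDF, ranked topology uniform), which scales to hundreds of tips and is used
for the larger fixtures.

Fossils are Poisson(psi * branch duration) events on the complete process
tree (extinct lineages included); each fossil is assigned the smallest
named clade containing its lineage, a placement mode (stem branch vs within
the crown group), and a reported minimum age slightly below its true age,
with the true attachment retained for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .fossils import FossilRecord
from .likelihood import ClockModel, SubstitutionModel
from .priors import BDParams, FBDParams, bd_p0, bd_p1
from .tree import CladeConstraint, TimeTree, TreeNode, mrca

__all__ = [
    "SimulationConfig",
    "BDSimResult",
    "FossilEvent",
    "simulate_bd_tree",
    "fast_bd_tree",
    "simulate_fossil_events",
    "simulate_fossil_record",
    "draw_ucln_multipliers",
    "simulate_alignment",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic data set."""

    n_extant: int = 15
    birth: float = 0.12          # 1/Ma
    death: float = 0.04
    rho: float = 1.0
    psi: float = 0.03            # fossil sampling rate, 1/Ma
    clock_rate: float = 2e-3     # subs/site/Ma
    clock_log_sd: float = 0.3
    length: int = 800            # bp
    n_partitions: int = 2
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_extant < 3:
            raise ValueError("need at least 3 extant tips")
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        for name in ("birth", "death", "psi", "clock_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class FossilEvent:
    """A fossilization event on the complete tree: which lineage, when."""

    lineage: TreeNode       # node below the branch carrying the event
    age: float


@dataclass
class BDSimResult:
    full: TimeTree              # complete tree, extinct lineages included
    tree: TimeTree              # reconstructed sampled extant tree
    origin_age: float
    sampled_labels: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def _forward_once(origin_age: float, p: BDParams, rng,
                  max_population: int = 2000):
    """One forward pass from a single lineage at ``origin_age``.

    Returns (complete tree with origin as a degree-1 root, surviving tips),
    or ``None`` if the standing population ever exceeds ``max_population``
    — such explosive realizations cannot plausibly end with a small sample
    and are treated as rejections by the conditioned simulator.
    """
    root = TreeNode(None, origin_age)
    active = [(root, origin_age)]
    tips = []
    total_rate = p.birth + p.death
    while active:
        if len(active) + len(tips) > max_population:
            return None
        node, age = active.pop()
        dt = rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
        new_age = age - dt
        if new_age <= 0:
            tip = node.add_child(TreeNode(None, 0.0))
            tips.append(tip)
            continue
        if rng.uniform() < p.birth / total_rate:
            mid = node.add_child(TreeNode(None, new_age))
            active.append((mid, new_age))
            active.append((mid, new_age))
        else:
            node.add_child(TreeNode(None, new_age))  # extinct tip, age > 0
    return TimeTree(root), tips


def _sampling_horizon(p: BDParams, tail: float = 1e-6) -> float:
    """Origin-age truncation: beyond this, the per-node age distribution of
    the conditioned process has < ``tail`` mass (plus a safety margin)."""
    r = p.birth - p.death
    A = p.rho * p.birth
    B = p.birth * (1.0 - p.rho) - p.death
    # solve 1 - F(t) = lambda*rho*r*u / (A*(A+B*u)) = tail for u = exp(-r t)
    lam = p.birth
    u = tail * A * A / (lam * p.rho * r - tail * A * B)
    u = min(max(u, 1e-300), 1.0)
    t = -math.log(u) / r
    return t + 5.0 / abs(r)


def simulate_bd_tree(n: int, p: BDParams, rng,
                     horizon: float | None = None,
                     max_retries: int = 2_000_000,
                     keep_full: bool = False,
                     require_shape=None,
                     max_population: int | None = None) -> BDSimResult:
    """Forward birth-death conditioned on exactly n sampled extant tips.

    The origin age is uniform on (0, horizon); realizations are rejected
    until rho-thinning leaves exactly ``n`` extant samples (and, optionally,
    until ``require_shape(sampled_tree)`` is true). Raises
    :class:`SimulationError` past ``max_retries``.
    """
    if horizon is None:
        horizon = _sampling_horizon(p)
    if max_population is None:
        # a lineage fails to leave a sampled extant descendant with
        # probability at most p0(inf) = 1 - r/lambda; once the standing
        # population exceeds this cap, P(exactly n samples) < ~1e-15 and the
        # realization is aborted cheaply
        p0_inf = min(max(1.0 - (p.birth - p.death) / p.birth, 0.05), 0.97)
        cap = n + int(math.ceil(50.0 / -math.log(p0_inf)))
    else:
        cap = max_population
    for _ in range(max_retries):
        origin = float(rng.uniform(0.0, horizon))
        out = _forward_once(origin, p, rng, max_population=cap)
        if out is None:
            continue
        full, tips = out
        sampled = [t for t in tips if p.rho >= 1.0 or rng.uniform() < p.rho]
        if len(sampled) != n:
            continue
        for i, t in enumerate(sampled):
            t.label = f"t{i + 1:02d}"
        tree = _reconstruct_extant(full, sampled)
        if require_shape is not None and not require_shape(tree):
            continue
        return BDSimResult(full if keep_full else None, tree, origin,
                           [t.label for t in sampled])
    raise SimulationError(
        f"no realization with exactly {n} sampled tips in {max_retries} tries")


def _reconstruct_extant(full: TimeTree, sampled: list[TreeNode]) -> TimeTree:
    keep = set(map(id, sampled))

    def rec(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            if id(node) in keep:
                return TreeNode(node.label, 0.0)
            return None
        parts = [rec(c) for c in node.children]
        parts = [x for x in parts if x is not None]
        if not parts:
            return None
        if len(parts) == 1:
            return parts[0]
        out = TreeNode(None, node.age)
        for x in parts:
            out.add_child(x)
        return out

    root = rec(full.root)
    if root is None:
        raise SimulationError("no sampled tips to reconstruct")
    tree = TimeTree(root)
    tree.validate()
    return tree


def _inverse_node_age_cdf(f: float, p: BDParams) -> float:
    """Quantile of the conditioned process's per-node age density lambda*p1."""
    r = p.birth - p.death
    A = p.rho * p.birth
    B = p.birth * (1.0 - p.rho) - p.death
    lam = p.birth
    tail = 1.0 - f
    u = tail * A * A / (lam * p.rho * r - tail * A * B)
    u = min(max(u, 1e-300), 1.0)
    return -math.log(u) / r

def fast_bd_tree(n: int, p: BDParams, rng, prefix: str = "t") -> TimeTree:
    """Conditioned birth-death tree built directly (scales to large n).

    Exact sampler for the same process as ``bd_log_prior`` (uniform origin
    integrated out, conditioned on n sampled tips): node ages are proposed
    iid from the normalized per-lineage density q (inverse CDF) and the
    vector is accepted with probability Q(max age)/Q(0) — the origin-branch
    weight; the ranked topology is uniform (lineages start as n tips at the
    present and pairs merge uniformly at successive ages).
    """
    if p.birth <= p.death:
        raise ValueError("fast_bd_tree requires a supercritical process")
    from .priors import _bd_log_Q
    log_q0 = _bd_log_Q(0.0, p)
    while True:
        ages = sorted(_inverse_node_age_cdf(float(rng.uniform()), p)
                      for _ in range(n - 1))
        if math.log(float(rng.uniform())) < _bd_log_Q(ages[-1], p) - log_q0:
            break
    digits = max(2, len(str(n)))
    lineages = [TreeNode(f"{prefix}{i + 1:0{digits}d}", 0.0) for i in range(n)]
    for age in ages:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        node = TreeNode(None, age)
        node.add_child(lineages[i])
        node.add_child(lineages[j])
        lineages[i] = node
        lineages.pop(j)
    tree = TimeTree(lineages[0])
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# fossils
# ---------------------------------------------------------------------------

def simulate_fossil_events(full: TimeTree, psi: float, rng) -> list[FossilEvent]:
    """Poisson(psi * duration) fossilization events on every branch of the
    complete tree (extinct lineages included). psi = 0 gives no events."""
    events = []
    if psi <= 0:
        return events
    for node in full.preorder():
        if node.parent is None:
            continue
        dur = node.branch_duration
        if dur <= 0:
            continue
        k = rng.poisson(psi * dur)
        for _ in range(k):
            events.append(FossilEvent(node, float(rng.uniform(node.age, node.parent.age))))
    events.sort(key=lambda e: -e.age)
    return events


def _sampled_descendants(node: TreeNode, sampled: set) -> set:
    return {l.label for l in node.leaves() if id(l) in sampled or l.label in sampled}


def simulate_fossil_record(sim: BDSimResult, psi: float,
                           clades: dict[str, CladeConstraint], rng,
                           reporting_error: float = 0.1,
                           set_split: float = 0.6):
    """Fossil events mapped to records with clade assignments.

    Each event is assigned the smallest named clade whose member set contains
    the event lineage's sampled extant descendants (walking up for extinct
    side branches); the placement mode is ``stem_branch`` when the lineage
    subtends the whole clade above its crown, else ``within_clade``. The
    reported minimum age is the true age minus a uniform reporting error of
    up to ``reporting_error`` (fractional). Returns ``(records, truth)``
    where truth maps fossil name -> (event age, clade, true attachment age).
    Events with no containing named clade are dropped.
    """
    if sim.full is None:
        raise ValueError("simulate_bd_tree must be run with keep_full=True")
    events = simulate_fossil_events(sim.full, psi, rng)
    sampled = set(sim.sampled_labels)
    # precompute each named clade's member set, smallest first
    order = sorted(clades.values(), key=lambda c: len(c.members))
    crown_ages = {c.name: mrca(sim.tree, c.members).age for c in order}
    records, truth = [], {}
    k = 0
    for ev in events:
        desc = {l.label for l in ev.lineage.leaves()
                if l.label in sampled}
        node = ev.lineage
        while not desc and node.parent is not None:
            node = node.parent
            desc = {l.label for l in node.leaves() if l.label in sampled}
        if not desc:
            continue
        home = next((c for c in order if desc <= c.members), None)
        if home is None:
            continue
        placement = ("stem_branch"
                     if desc == c_members(home) and ev.age > crown_ages[home.name]
                     else "within_clade")
        k += 1
        name = f"F{k:02d}"
        min_age = max(ev.age * (1.0 - reporting_error * float(rng.uniform())), 1e-3)
        records.append(FossilRecord(
            name=name, clade=home.name, min_age=min_age, max_age=None,
            placement=placement,
            set_membership="small" if rng.uniform() < set_split else "large_only",
            nd_usable=True))
        truth[name] = (ev.age, home.name, ev.lineage.parent.age
                       if ev.lineage.parent else math.inf)
    return records, truth


def c_members(clade: CladeConstraint) -> set:
    return set(clade.members)


def reconstruct_fbd_tree(full: TimeTree, sampled_labels: list[str],
                         events: list[FossilEvent],
                         fossil_prefix: str = "F") -> TimeTree:
    """The sampled tree of an FBD realization: extant samples plus fossils.

    Fossil events on lineages with later samples become sampled ancestors
    (degree-2 nodes); events on lineages with no further samples become
    fossil tips. Unsampled subtrees are dropped and single-child birth nodes
    suppressed; the root is the topmost node carrying samples on more than
    one side (or a top sampled ancestor).
    """
    sampled = set(sampled_labels)
    per_branch: dict[int, list[FossilEvent]] = {}
    for ev in events:
        per_branch.setdefault(id(ev.lineage), []).append(ev)
    counter = [0]

    def rec(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            below = (TreeNode(node.label, 0.0)
                     if node.label in sampled else None)
        else:
            parts = [rec(c) for c in node.children]
            parts = [x for x in parts if x is not None]
            if not parts:
                below = None
            elif len(parts) == 1:
                below = parts[0]
            else:
                below = TreeNode(None, node.age)
                for x in parts:
                    below.add_child(x)
        # thread fossil events on the branch above `node`, youngest first
        for ev in sorted(per_branch.get(id(node), []), key=lambda e: e.age):
            counter[0] += 1
            label = f"{fossil_prefix}{counter[0]:02d}"
            if below is None:
                below = TreeNode(label, ev.age, is_fossil=True)
            else:
                sa = TreeNode(label, ev.age)
                sa.is_sampled_ancestor = True
                sa.add_child(below)
                below = sa
        return below

    root = rec(full.root)
    if root is None:
        raise SimulationError("realization has no samples")
    tree = TimeTree(root)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def draw_ucln_multipliers(tree: TimeTree, log_sd: float, rng,
                          node_index=None) -> dict[int, float]:
    """Branch-rate multipliers iid log-normal with real-scale mean 1."""
    from .likelihood import index_tree
    if node_index is None:
        node_index = index_tree(tree)
    mu = -0.5 * log_sd * log_sd
    return {node_index[id(n)]: float(rng.lognormal(mu, log_sd))
            for n in tree.preorder() if n.parent is not None}


def simulate_alignment(tree: TimeTree, clock: ClockModel, models,
                       partitions: dict[str, tuple[int, int]], rng) -> Alignment:
    """Evolve sequences site-independently down the tree.

    ``models`` is a SubstitutionModel or dict locus -> model; branch lengths
    in expected substitutions are duration * clock rate * branch multiplier.
    Only extant tips receive sequences.
    """
    from .likelihood import index_tree
    node_index = index_tree(tree)
    states = "ACGT"
    tips = [l for l in tree.leaves() if not l.is_fossil]
    seqs = {l.label: [] for l in tips}
    for locus, (start, end) in partitions.items():
        model = models[locus] if isinstance(models, dict) else models
        L = end - start
        pi = np.asarray(model.freqs, float)
        clock_id = clock.clock_for(locus)
        cat = model.category_rates()
        site_cat = rng.integers(len(cat), size=L) if len(cat) > 1 else np.zeros(L, int)
        seq_at = {id(tree.root): rng.choice(4, size=L, p=pi)}
        for node in tree.preorder():
            if node.parent is None:
                continue
            rate = clock.branch_rate(clock_id, node_index.get(id(node), -1))
            parent_seq = seq_at[id(node.parent)]
            child_seq = np.empty(L, dtype=int)
            for ci, crate in enumerate(cat):
                mask = site_cat == ci
                if not mask.any():
                    continue
                pmat = model.transition_matrix(node.branch_duration * rate * crate)
                # normalize rows against clipping artifacts
                pmat = pmat / pmat.sum(axis=1, keepdims=True)
                sub = parent_seq[mask]
                u = rng.uniform(size=sub.size)
                cdf = np.cumsum(pmat, axis=1)
                child_seq[mask] = (u[:, None] > cdf[sub]).sum(axis=1)
            seq_at[id(node)] = child_seq
        for l in tips:
            seqs[l.label].extend(states[s] for s in seq_at[id(l)])
    labels = [l.label for l in tips]
    return Alignment(labels, ["".join(seqs[lab]) for lab in labels],
                     dict(partitions))


def apply_missing_data(aln: Alignment, dropout: dict[str, list[str]] | None,
                       rng=None, fraction: float = 0.0) -> Alignment:
    """Blank out whole loci per taxon (``dropout``: taxon -> loci to mask)
    and/or mask a random fraction of remaining sites with N."""
    seqs = {lab: list(s) for lab, s in zip(aln.labels, aln.sequences)}
    if dropout:
        for taxon, loci in dropout.items():
            for locus in loci:
                start, end = aln.partitions[locus]
                s = seqs[taxon]
                for i in range(start, end):
                    s[i] = "N"
    if fraction > 0 and rng is not None:
        for lab in aln.labels:
            mask = rng.uniform(size=aln.n_sites) < fraction
            s = seqs[lab]
            for i in np.nonzero(mask)[0]:
                s[i] = "N"
    return Alignment(list(aln.labels), ["".join(seqs[lab]) for lab in aln.labels],
                     dict(aln.partitions))
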