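"""Desk-scale Metropolis-Hastings MCMC over time-trees.

Two analysis modes share one chain driver:

* **ND** (node dating): the tree holds extant taxa only; fossils enter through
  parametric calibration densities on stem (or crown) nodes, multiplied onto
  a birth-death tree prior and a relaxed-clock likelihood.
* **FBD** (tip dating): fossils are part of the tree — extinct side tips or
  sampled ancestors attached inside their assigned clade — under the
  fossilized birth-death prior; fossil ages are fixed or sampled uniformly
  in a range.

The topology of the extant backbone is fixed to the starting tree (the
study design this package targets has a well-settled backbone); proposals
move node ages, clock parameters, tree-prior parameters, fossil attachments
and fossil ages. Runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alignment import Alignment
from .calibrate import CalibrationDensity, FBDAgeSpec
from .fossils import FossilRecord
from .likelihood import ClockModel, SubstitutionModel, felsenstein_log_likelihood, index_tree
from .priors import BDParams, FBDParams, bd_log_prior, fbd_log_density, ucln_log_prior
from .tree import CladeConstraint, TimeTree, TreeNode, mrca, write_tree_log

__all__ = [
    "FossilAttachment",
    "AnalysisModel",
    "ChainConfig",
    "MCMCResult",
    "attach_fossils",
    "materialize",
    "run_mcmc",
]


class InfeasibleStateError(ValueError):
    pass


class AttachmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# fossil attachments
# ---------------------------------------------------------------------------

@dataclass
class FossilAttachment:
    """Placement of one fossil on the extant backbone.

    ``edge_index`` is the stable index (see ``index_tree``) of the backbone
    node *below* the attachment edge; ``edge_index == ROOT_EDGE`` attaches
    above the root (the clade's stem when the clade spans the whole tree).
    ``attach_age == age`` with ``sampled_ancestor`` marks a sampled ancestor.
    """

    fossil: str
    age: float
    edge_index: int
    attach_age: float
    sampled_ancestor: bool = False

    ROOT_EDGE = -1


def _edges_of_clade(tree: TimeTree, clade: CladeConstraint,
                    placement: str, node_index) -> list[tuple[int, TreeNode, float]]:
    """Candidate attachment edges as (edge_index, child_node, parent_age).

    ``stem_branch``: the single edge above the clade's MRCA (parent age
    ``inf`` when the MRCA is the root — caller must cap). ``within_clade``:
    every edge inside the crown group, including the edges to its tips.
    """
    present = {m for m in clade.members if m in tree}
    crown = mrca(tree, present)
    if placement == "stem_branch":
        if crown.parent is None:
            return [(FossilAttachment.ROOT_EDGE, crown, math.inf)]
        return [(node_index[id(crown)], crown, crown.parent.age)]
    edges = []
    for node in crown.preorder():
        if node is crown:
            continue
        edges.append((node_index[id(node)], node, node.parent.age))
    return edges


def _feasible_segments(edges, fossil_age: float, stem_cap: float | None):
    """(edge_index, lo, hi) intervals where an attachment age may fall."""
    segs = []
    for edge_index, child, parent_age in edges:
        hi = parent_age
        if math.isinf(hi):
            if stem_cap is None:
                raise AttachmentError(
                    "attachment above the root requires a finite stem_cap")
            hi = stem_cap
        lo = max(fossil_age, child.age)
        if hi > lo:
            segs.append((edge_index, lo, hi))
    return segs


def attach_fossils(tree: TimeTree, fossils: list[FossilRecord],
                   clades: dict[str, CladeConstraint], rng,
                   ages: dict[str, float] | None = None,
                   stem_cap: float | None = None):
    """Draw an initial placement for each fossil on its assigned clade.

    Stem-branch fossils go on the clade's stem edge; within-clade fossils go
    on any branch inside the crown group, with attachment-age drawn
    uniformly over the feasible (branch, age) set. Returns
    ``(full_tree, attachments)``; raises :class:`AttachmentError` naming the
    fossil when no feasible attachment exists (e.g. fossil older than the
    stem node).
    """
    node_index = index_tree(tree)
    attachments = []
    for rec in fossils:
        clade = clades[rec.clade]
        y = ages[rec.name] if ages else rec.min_age
        edges = _edges_of_clade(tree, clade, rec.placement, node_index)
        segs = _feasible_segments(edges, y, stem_cap)
        if not segs:
            raise AttachmentError(
                f"fossil {rec.name!r} (age {y} Ma) has no feasible attachment "
                f"in clade {rec.clade!r} ({rec.placement})")
        lengths = np.array([hi - lo for _, lo, hi in segs])
        k = rng.choice(len(segs), p=lengths / lengths.sum())
        edge_index, lo, hi = segs[k]
        attach_age = float(rng.uniform(lo, hi))
        attachments.append(FossilAttachment(rec.name, y, edge_index, attach_age))
    return materialize(tree, attachments), attachments


def materialize(backbone: TimeTree, attachments: list[FossilAttachment]) -> TimeTree:
    """Build the full time-tree (fossil tips / sampled ancestors included)."""
    out = backbone.copy()
    node_index = index_tree(out)
    by_index = {idx: None for idx in node_index.values()}
    for node in out.preorder():
        by_index[node_index[id(node)]] = node
    # group attachments per edge, insert oldest-first from the top
    per_edge: dict[int, list[FossilAttachment]] = {}
    for att in attachments:
        per_edge.setdefault(att.edge_index, []).append(att)
    for edge_index, atts in per_edge.items():
        atts = sorted(atts, key=lambda a: -a.attach_age)
        if edge_index == FossilAttachment.ROOT_EDGE:
            child = out.root
            parent = None
        else:
            child = by_index[edge_index]
            parent = child.parent
        for att in atts:
            if att.attach_age < child.age - 1e-12 or (
                    parent is not None and att.attach_age > parent.age + 1e-12):
                raise AttachmentError(
                    f"attachment age {att.attach_age} for {att.fossil!r} "
                    f"outside its edge")
            if att.sampled_ancestor:
                joint = TreeNode(att.fossil, att.attach_age)
                joint.is_sampled_ancestor = True
            else:
                joint = TreeNode(None, att.attach_age)
            if parent is None:
                joint.add_child(out.root)
                out.root = joint
            else:
                idx = parent.children.index(child)
                parent.children[idx] = joint
                joint.parent = parent
                joint.add_child(child)
            if not att.sampled_ancestor:
                tip = TreeNode(att.fossil, att.age, is_fossil=True)
                joint.add_child(tip)
            parent = joint  # younger attachments nest below
    out.validate()
    return out


# ---------------------------------------------------------------------------
# model and chain configuration
# ---------------------------------------------------------------------------

def _default_rate_hyperprior():
    from scipy import stats
    return stats.lognorm(s=1.5, scale=1e-3)


def _default_birth_hyperprior():
    from scipy import stats
    return stats.lognorm(s=1.0, scale=math.exp(-1.0))


def _default_psi_hyperprior():
    from scipy import stats
    return stats.expon(scale=1.0)


@dataclass
class AnalysisModel:
    """Everything that defines one dating analysis except the chain length.

    ``mode`` is ``"nd"`` or ``"fbd"``. In ND mode ``calibrations`` carry the
    node densities; in FBD mode ``fossils`` + ``age_specs`` define the tips.
    Tree-prior parameters are fixed unless listed in ``sample_params``
    (subset of {"birth", "turnover", "psi", "clock_rate", "clock_sd"});
    sampled parameters get the declared hyperpriors (death is
    birth * turnover, rho is always fixed).
    """

    mode: str
    clades: dict[str, CladeConstraint] = field(default_factory=dict)
    calibrations: list[CalibrationDensity] = field(default_factory=list)
    fossils: list[FossilRecord] = field(default_factory=list)
    age_specs: dict[str, FBDAgeSpec] = field(default_factory=dict)
    birth: float = 0.1
    death: float = 0.0
    rho: float = 1.0
    psi: float = 0.0
    alignment: Alignment | None = None
    clock: ClockModel | None = None
    substitution: SubstitutionModel | dict | None = None
    sample_params: tuple = ()
    stem_cap: float | None = None
    hyperpriors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("nd", "fbd"):
            raise ValueError(f"mode must be 'nd' or 'fbd', got {self.mode!r}")
        defaults = {
            "birth": _default_birth_hyperprior(),
            "psi": _default_psi_hyperprior(),
            "clock_rate": _default_rate_hyperprior(),
        }
        for key, dist in defaults.items():
            self.hyperpriors.setdefault(key, dist)
        # turnover mu/lambda ~ Beta(1,1): flat on [0,1); clock_sd ~ Exp(mean 1/3)
        from scipy import stats
        self.hyperpriors.setdefault("turnover", stats.uniform(0, 1))
        self.hyperpriors.setdefault("clock_sd", stats.expon(scale=1.0 / 3.0))


@dataclass
class ChainConfig:
    """MCMC run configuration: N generations sampled every f, one proposal
    per generation; ``prior_only`` drops the sequence likelihood."""

    generations: int = 20000
    sample_every: int = 20
    seed: int = 1
    prior_only: bool = False
    proposal_weights: dict = field(default_factory=dict)
    scale_step: float = 0.3      # log-scale half-width of scale moves
    walk_step: float = 0.4       # sd of multiplier log-walks

    def __post_init__(self) -> None:
        if self.sample_every <= 0 or self.generations % self.sample_every:
            raise ValueError("generations must be a positive multiple of sample_every")


@dataclass
class MCMCResult:
    trace: pd.DataFrame
    trees: list[TimeTree]
    generations: list[int]
    acceptance: dict

    def trace_tsv(self) -> str:
        return self.trace.to_csv(sep="\t", index=False)

    def tree_log(self) -> str:
        return write_tree_log(self.trees, self.generations)


# ---------------------------------------------------------------------------
# the chain
# ---------------------------------------------------------------------------

class _Chain:
    def __init__(self, model: AnalysisModel, init: TimeTree, cfg: ChainConfig):
        self.model = model
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.backbone = init.copy()
        self.backbone.validate()
        if any(l.is_fossil for l in self.backbone.leaves()):
            raise InfeasibleStateError(
                "the starting tree must contain extant taxa only; fossils are "
                "attached by the engine")
        self.node_index = index_tree(self.backbone)
        self.nodes = {idx: None for idx in self.node_index.values()}
        for node in self.backbone.preorder():
            self.nodes[self.node_index[id(node)]] = node
        self.internal = [n for n in self.backbone.internal_nodes()]
        self.params = {"birth": model.birth, "psi": model.psi,
                       "turnover": (model.death / model.birth) if model.birth else 0.0}
        self.clock = (model.clock.copy() if model.clock is not None
                      else ClockModel(mean_rate={"shared": 1e-3},
                                      log_sd={"shared": 0.3}))
        # fossil state (FBD)
        self.attachments: list[FossilAttachment] = []
        if model.mode == "fbd":
            ages = {}
            for rec in model.fossils:
                spec = model.age_specs.get(rec.name)
                ages[rec.name] = spec.initial_age() if spec else rec.min_age
            _, self.attachments = attach_fossils(
                self.backbone, model.fossils, model.clades, self.rng,
                ages=ages, stem_cap=model.stem_cap)
        # resolve ND calibration targets once (fixed backbone topology)
        self.cal_targets: list[tuple[CalibrationDensity, int]] = []
        for cal in model.calibrations:
            clade = model.clades[cal.target]
            crown = mrca(self.backbone, clade.members)
            if cal.node_role == "stem" and crown.parent is not None:
                target = crown.parent
            else:
                target = crown
            self.cal_targets.append((cal, self.node_index[id(target)]))
        self.log_prior = self._log_prior()
        self.log_lik = self._log_likelihood()
        if not math.isfinite(self.log_prior):
            raise InfeasibleStateError(
                "initial state has zero prior probability; check that the "
                "starting tree satisfies every calibration floor and fossil "
                "age constraint")
        if not math.isfinite(self.log_lik):
            raise InfeasibleStateError("initial state has zero likelihood")
        self.accepted: dict[str, int] = {}
        self.proposed: dict[str, int] = {}

    # -- densities ---------------------------------------------------------
    def _tree_params(self):
        birth = self.params["birth"]
        death = birth * self.params["turnover"]
        if self.model.mode == "fbd":
            return FBDParams(birth, death, self.model.rho, self.params["psi"])
        return BDParams(birth, death, self.model.rho)

    def _log_prior(self) -> float:
        try:
            p = self._tree_params()
        except ValueError:
            return -math.inf
        total = 0.0
        if self.model.mode == "fbd":
            try:
                full = materialize(self.backbone, self.attachments)
            except Exception:
                return -math.inf
            total += fbd_log_density(full, p)
            for att in self.attachments:
                spec = self.model.age_specs.get(att.fossil)
                if spec is not None and spec.mode == "uniform_range":
                    if not spec.lower <= att.age <= spec.upper:
                        return -math.inf
                    total += -math.log(spec.upper - spec.lower)
        else:
            total += bd_log_prior(self.backbone, p)
            for cal, idx in self.cal_targets:
                total += cal.logpdf(self.nodes[idx].age)
        if not math.isfinite(total):
            return -math.inf
        # hyperpriors for sampled parameters
        for name in self.model.sample_params:
            if name in ("birth", "turnover", "psi"):
                total += float(self.model.hyperpriors[name].logpdf(self.params[name]))
            elif name == "clock_rate":
                for rate in self.clock.mean_rate.values():
                    total += float(self.model.hyperpriors["clock_rate"].logpdf(rate))
            elif name == "clock_sd":
                for sd in self.clock.log_sd.values():
                    total += float(self.model.hyperpriors["clock_sd"].logpdf(sd))
        # UCLN multiplier prior
        for clock_id, sd in self.clock.log_sd.items():
            mults = list(self.clock.multipliers.get(clock_id, {}).values())
            if mults:
                total += ucln_log_prior(mults, sd)
        return total

    def _log_likelihood(self) -> float:
        if self.cfg.prior_only or self.model.alignment is None:
            return 0.0
        return felsenstein_log_likelihood(self.model.alignment, self.backbone,
                                          self.clock, self.model.substitution)

    # -- proposals ---------------------------------------------------------
    def _proposals(self):
        w = dict(self.cfg.proposal_weights)
        moves = [("node_slide", 4.0, self._move_node_slide, True),
                 ("root_scale", 1.0, self._move_root_scale, True),
                 ("tree_scale", 1.0, self._move_tree_scale, True)]
        if self.clock.multipliers:
            moves.append(("ucln_walk", 2.0, self._move_ucln_walk, True))
        for name in self.model.sample_params:
            if name in ("birth", "turnover", "psi"):
                moves.append((f"{name}_scale", 1.0,
                              lambda rng, n=name: self._move_param_scale(n, rng),
                              False))
            elif name == "clock_rate":
                moves.append(("clock_rate_scale", 1.0, self._move_rate_scale, True))
            elif name == "clock_sd":
                moves.append(("clock_sd_scale", 1.0, self._move_sd_scale, False))
        if self.model.mode == "fbd" and self.attachments:
            moves.append(("reattach", 2.0, self._move_reattach, False))
            moves.append(("sa_toggle", 1.0, self._move_sa_toggle, False))
            if any(self.model.age_specs.get(a.fossil) is not None and
                   self.model.age_specs[a.fossil].mode == "uniform_range"
                   for a in self.attachments):
                moves.append(("fossil_age", 1.0, self._move_fossil_age, False))
        names = [m[0] for m in moves]
        weights = np.array([w.get(m[0], m[1]) for m in moves], float)
        return names, weights / weights.sum(), moves

    # each move mutates state and returns (undo, log_hastings, needs_lik)
    # or None when no feasible proposal exists (counts as rejection)

    def _attachment_bounds(self, node: TreeNode):
        """Age bounds on a backbone node imposed by fossil attachments on
        the adjacent edges."""
        idx = (FossilAttachment.ROOT_EDGE if node.parent is None
               else self.node_index[id(node)])
        child_idxs = {self.node_index[id(c)]: c for c in node.children}
        hi = math.inf
        lo = -math.inf
        for att in self.attachments:
            if att.edge_index == idx:
                hi = min(hi, att.attach_age)
            elif att.edge_index in child_idxs:
                lo = max(lo, att.attach_age)
        return lo, hi

    def _move_node_slide(self, rng):
        candidates = [n for n in self.internal if n.parent is not None]
        if not candidates:
            return None
        node = candidates[rng.integers(len(candidates))]
        a_lo, a_hi = self._attachment_bounds(node)
        lo = max([c.age for c in node.children] + [a_lo])
        hi = min(node.parent.age, a_hi)
        if hi <= lo:
            return None
        old = node.age
        node.age = float(rng.uniform(lo, hi))

        def undo():
            node.age = old
        return undo, 0.0, True

    def _move_root_scale(self, rng):
        root = self.backbone.root
        a_lo, a_hi = self._attachment_bounds(root)
        # also cap by attachments above the root
        base = max([c.age for c in root.children] + [a_lo])
        s = math.exp(rng.uniform(-self.cfg.scale_step, self.cfg.scale_step))
        old = root.age
        new = base + (old - base) * s
        if new >= a_hi:
            return None
        root.age = new

        def undo():
            root.age = old
        return undo, math.log(s), True

    def _move_tree_scale(self, rng):
        s = math.exp(rng.uniform(-self.cfg.scale_step, self.cfg.scale_step))
        olds = [(n, n.age) for n in self.internal]
        old_atts = [(a, a.attach_age) for a in self.attachments]
        for n, _ in olds:
            n.age *= s
        count = len(olds)
        for a, _ in old_atts:
            if not a.sampled_ancestor:
                a.attach_age *= s
                count += 1

        def undo():
            for n, v in olds:
                n.age = v
            for a, v in old_atts:
                a.attach_age = v
        # validity (fossil ages fixed) enforced by the prior / materialize
        for a in self.attachments:
            if a.attach_age < a.age:
                undo()
                return None
        return undo, count * math.log(s), True

    def _move_ucln_walk(self, rng):
        clock_id = list(self.clock.log_sd.keys())[rng.integers(len(self.clock.log_sd))]
        mults = self.clock.multipliers.setdefault(clock_id, {})
        if not mults:
            return None
        key = list(mults.keys())[rng.integers(len(mults))]
        old = mults[key]
        s = math.exp(rng.normal(0.0, self.cfg.walk_step))
        mults[key] = old * s

        def undo():
            mults[key] = old
        return undo, math.log(s), True

    def _move_rate_scale(self, rng):
        clock_id = list(self.clock.mean_rate.keys())[rng.integers(len(self.clock.mean_rate))]
        old = self.clock.mean_rate[clock_id]
        s = math.exp(rng.uniform(-self.cfg.scale_step, self.cfg.scale_step))
        self.clock.mean_rate[clock_id] = old * s

        def undo():
            self.clock.mean_rate[clock_id] = old
        return undo, math.log(s), True

    def _move_sd_scale(self, rng):
        clock_id = list(self.clock.log_sd.keys())[rng.integers(len(self.clock.log_sd))]
        old = self.clock.log_sd[clock_id]
        s = math.exp(rng.uniform(-self.cfg.scale_step, self.cfg.scale_step))
        self.clock.log_sd[clock_id] = old * s

        def undo():
            self.clock.log_sd[clock_id] = old
        return undo, math.log(s), False

    def _move_param_scale(self, name, rng):
        old = self.params[name]
        if old <= 0:
            return None
        s = math.exp(rng.uniform(-self.cfg.scale_step, self.cfg.scale_step))
        new = old * s
        if name == "turnover" and new >= 1.0:
            return None
        self.params[name] = new

        def undo():
            self.params[name] = old
        return undo, math.log(s), False

    def _fossil_record(self, name: str) -> FossilRecord:
        return next(r for r in self.model.fossils if r.name == name)

    def _move_reattach(self, rng):
        # sampled-ancestor states are entered/left only via sa_toggle, so
        # this move stays reversible within the tip-attachment subspace
        tips = [a for a in self.attachments if not a.sampled_ancestor]
        if not tips:
            return None
        att = tips[rng.integers(len(tips))]
        rec = self._fossil_record(att.fossil)
        clade = self.model.clades[rec.clade]
        edges = _edges_of_clade(self.backbone, clade, rec.placement, self.node_index)
        segs = _feasible_segments(edges, att.age, self.model.stem_cap)
        if not segs:
            return None
        lengths = np.array([hi - lo for _, lo, hi in segs])
        k = rng.choice(len(segs), p=lengths / lengths.sum())
        edge_index, lo, hi = segs[k]
        old = (att.edge_index, att.attach_age, att.sampled_ancestor)
        att.edge_index = edge_index
        att.attach_age = float(rng.uniform(lo, hi))
        att.sampled_ancestor = False

        def undo():
            att.edge_index, att.attach_age, att.sampled_ancestor = old
        # uniform over a feasible set that does not depend on the current
        # attachment: symmetric
        return undo, 0.0, False

    def _current_edge_interval(self, att: FossilAttachment):
        if att.edge_index == FossilAttachment.ROOT_EDGE:
            child = self.backbone.root
            hi = self.model.stem_cap
            if hi is None:
                return None
        else:
            child = self.nodes[att.edge_index]
            hi = child.parent.age
        lo = max(att.age, child.age)
        if hi <= lo:
            return None
        return lo, hi

    def _move_sa_toggle(self, rng):
        att = self.attachments[rng.integers(len(self.attachments))]
        interval = self._current_edge_interval(att)
        if interval is None:
            return None
        lo, hi = interval
        old = (att.attach_age, att.sampled_ancestor)
        if att.sampled_ancestor:
            # ancestor -> extinct side tip: draw an attachment age
            att.sampled_ancestor = False
            att.attach_age = float(rng.uniform(lo, hi))
            log_h = math.log(hi - lo)
        else:
            # tip -> sampled ancestor at the fossil's age (if on this edge)
            child_age = (self.backbone.root.age
                         if att.edge_index == FossilAttachment.ROOT_EDGE
                         else self.nodes[att.edge_index].age)
            parent_age = hi
            if not child_age <= att.age <= parent_age:
                return None
            att.sampled_ancestor = True
            att.attach_age = att.age
            log_h = -math.log(hi - lo)

        def undo():
            att.attach_age, att.sampled_ancestor = old
        return undo, log_h, False

    def _move_fossil_age(self, rng):
        ranged = [a for a in self.attachments
                  if self.model.age_specs.get(a.fossil) is not None and
                  self.model.age_specs[a.fossil].mode == "uniform_range"]
        if not ranged:
            return None
        att = ranged[rng.integers(len(ranged))]
        spec = self.model.age_specs[att.fossil]
        old = (att.age, att.attach_age)
        new_age = float(rng.uniform(spec.lower, spec.upper))
        att.age = new_age
        if att.sampled_ancestor:
            att.attach_age = new_age
        elif att.attach_age <= new_age:
            att.age, att.attach_age = old
            return None

        def undo():
            att.age, att.attach_age = old
        return undo, 0.0, False

    # -- driver ------------------------------------------------------------
    def run(self) -> MCMCResult:
        cfg = self.cfg
        names, probs, moves = self._proposals()
        trace_rows = []
        trees = []
        gens = []
        self._record(0, trace_rows, trees, gens)
        for gen in range(1, cfg.generations + 1):
            k = self.rng.choice(len(moves), p=probs)
            name, _, fn, needs_lik_default = moves[k]
            self.proposed[name] = self.proposed.get(name, 0) + 1
            out = fn(self.rng)
            if out is None:
                if gen % cfg.sample_every == 0:
                    self._record(gen, trace_rows, trees, gens)
                continue
            undo, log_h, needs_lik = out
            new_prior = self._log_prior()
            if not math.isfinite(new_prior):
                undo()
            else:
                new_lik = self._log_likelihood() if needs_lik else self.log_lik
                log_alpha = (new_prior + new_lik) - (self.log_prior + self.log_lik) + log_h
                if math.isfinite(new_lik) and math.log(self.rng.uniform()) < log_alpha:
                    self.log_prior, self.log_lik = new_prior, new_lik
                    self.accepted[name] = self.accepted.get(name, 0) + 1
                else:
                    undo()
            if gen % cfg.sample_every == 0:
                self._record(gen, trace_rows, trees, gens)
        trace = pd.DataFrame(trace_rows)
        acc = {n: self.accepted.get(n, 0) / max(self.proposed.get(n, 1), 1)
               for n in names}
        return MCMCResult(trace, trees, gens, acc)

    def _record(self, gen, trace_rows, trees, gens):
        row = {"generation": gen,
               "posterior": self.log_prior + self.log_lik,
               "prior": self.log_prior,
               "likelihood": self.log_lik,
               "birth": self.params["birth"],
               "death": self.params["birth"] * self.params["turnover"],
               "psi": self.params["psi"],
               "root_age": self.backbone.root.age}
        for clock_id, rate in self.clock.mean_rate.items():
            row[f"rate_{clock_id}"] = rate
        for clock_id, sd in self.clock.log_sd.items():
            row[f"ucld_sd_{clock_id}"] = sd
        for cal, idx in self.cal_targets:
            row[f"age_{cal.target}_{cal.node_role}"] = self.nodes[idx].age
        for att in self.attachments:
            row[f"fossil_age_{att.fossil}"] = att.age
            row[f"attach_age_{att.fossil}"] = att.attach_age
        trace_rows.append(row)
        if self.model.mode == "fbd":
            trees.append(materialize(self.backbone, self.attachments))
        else:
            trees.append(self.backbone.copy())
        gens.append(gen)


def run_mcmc(model: AnalysisModel, init: TimeTree, cfg: ChainConfig) -> MCMCResult:
    """Run one Metropolis-Hastings chain; see :class:`AnalysisModel`.

    Identical (model, init, cfg) including the seed give bit-identical trace
    and tree logs. In ``prior_only`` mode the likelihood term is zero and the
    chain samples the joint (effective) prior.
    """
    return _Chain(model, init, cfg).run()
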