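"""Self-contained synthetic study bundles and the analysis method matrix.

``make_pine_fixture`` builds a pine-like study at two scales: a ``small``
bundle (15 extant taxa, 5 fossils, 2 plastid-like loci, 800 bp) for fast
end-to-end runs, and a ``paper_shaped`` bundle (115 extant taxa, 21 fossils
of which 14 form the small fossil set, 8 concatenated loci, ~5.9 kb with a
taxon-coverage dropout profile) that reproduces the structure of a full
chloroplast supermatrix study. Every bundle carries configurations for the
full method matrix: {NDn, NDb, NDu, FBD_tip, FBD_range} x {small, large
fossil set}.

Fossil-set design (both scales): the large set adds younger duplicate
fossils and extra clades to the small set, plus — at paper scale — records
that are unusable for node dating (no defensible node assignment, or a stem
fossil of the whole in-group). Node dating retains only the oldest usable
fossil per clade, so the paper-shaped bundle yields 12 (small) and 15
(large) ND calibrations from its 14 and 21 fossils.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, write_fasta
from .calibrate import (CalibrationDensity, FBDAgeSpec, build_fbd_age_spec,
                        build_ndb_density, build_ndn_density, build_ndu_density)
from .fossils import (EpochInterval, FossilRecord, fossils_in_set,
                      select_oldest_per_clade, write_fossil_table)
from .likelihood import ClockModel, SubstitutionModel, index_tree
from .mcmc import AnalysisModel
from .priors import BDParams
from .simulate import (apply_missing_data, draw_ucln_multipliers, fast_bd_tree,
                       simulate_alignment)
from .tree import CladeConstraint, TimeTree, write_tree

__all__ = ["StudyBundle", "make_pine_fixture", "build_analysis_model",
           "calibrated_start_tree", "run_analysis_cell", "clade_age_table",
           "METHODS", "FOSSIL_SETS"]

METHODS = ("NDn", "NDb", "NDu", "FBD_tip", "FBD_range")
FOSSIL_SETS = ("small", "large")


@dataclass
class StudyBundle:
    """All inputs for one synthetic dating study, plus ground truth."""

    scale: str
    seed: int
    tree: TimeTree                       # true (and starting) extant tree
    alignment: Alignment
    clades: dict[str, CladeConstraint]
    fossils: list[FossilRecord]
    epochs: dict[str, EpochInterval]     # fossil name -> epoch
    clock: ClockModel                    # true clock used for simulation
    substitution: SubstitutionModel
    bd: BDParams
    fbd_cap: float                       # root-age ceiling for FBD ranges
    psi: float
    configs: dict = field(default_factory=dict)

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "alignment.fasta"), "w") as fh:
            fh.write(write_fasta(self.alignment))
        with open(os.path.join(outdir, "starting_tree.nwk"), "w") as fh:
            fh.write(write_tree(self.tree) + "\n")
        with open(os.path.join(outdir, "fossils.tsv"), "w") as fh:
            fh.write(write_fossil_table(self.fossils))
        with open(os.path.join(outdir, "epochs.tsv"), "w") as fh:
            fh.write("name\tmin_ma\tmax_ma\n")
            for name, ep in self.epochs.items():
                fh.write(f"{ep.name}\t{ep.min_age}\t{ep.max_age}\n")
        with open(os.path.join(outdir, "clades.json"), "w") as fh:
            json.dump({k: sorted(v.members) for k, v in self.clades.items()},
                      fh, indent=1)
        with open(os.path.join(outdir, "configs.json"), "w") as fh:
            json.dump(self.configs, fh, indent=1, default=str)


def _pick_clades(tree: TimeTree, k: int, min_tips: int = 2) -> dict[str, CladeConstraint]:
    """Deterministically name the k oldest internal clades (root excluded)."""
    nodes = [n for n in tree.internal_nodes() if n.parent is not None]
    nodes = [n for n in nodes if len(n.leaves()) >= min_tips]
    nodes.sort(key=lambda n: (-n.age, n.leaves()[0].label))
    out = {}
    seen = set()
    for n in nodes:
        tips = frozenset(l.label for l in n.leaves())
        if tips in seen:
            continue
        seen.add(tips)
        name = f"clade_{chr(ord('a') + len(out))}"
        out[name] = CladeConstraint(name, tips, node_role="crown")
        if len(out) == k:
            break
    if len(out) < k:
        raise ValueError(f"tree too small to name {k} clades")
    return out


def _stem_age(tree: TimeTree, clade: CladeConstraint) -> float:
    from .tree import mrca
    crown = mrca(tree, clade.members)
    return crown.parent.age if crown.parent is not None else crown.age


def _crown_age(tree: TimeTree, clade: CladeConstraint) -> float:
    from .tree import mrca
    return mrca(tree, clade.members).age


def _epoch_for(name: str, age: float) -> EpochInterval:
    return EpochInterval(f"epoch_{name}", round(0.85 * age, 2),
                         round(1.25 * age + 1.0, 2))


def _make_small(seed: int) -> StudyBundle:
    rng = np.random.default_rng(seed)
    bd = BDParams(birth=0.12, death=0.04, rho=1.0)
    tree = fast_bd_tree(15, bd, rng, prefix="pine_")
    clades = _pick_clades(tree, 4)
    names = sorted(clades)
    ca, cb, cc, cd = names  # oldest to youngest by construction

    def f(name, clade, frac, placement, fset, age_of="stem"):
        base = (_stem_age(tree, clades[clade]) if age_of == "stem"
                else _crown_age(tree, clades[clade]))
        return FossilRecord(name=name, clade=clade,
                            min_age=round(frac * base, 2), max_age=None,
                            placement=placement, set_membership=fset)

    fossils = [
        f("F_deep", ca, 0.60, "stem_branch", "small"),
        f("F_mid", cb, 0.55, "stem_branch", "small"),
        f("F_shallow", cc, 0.50, "within_clade", "small", age_of="crown"),
        f("F_dup", cb, 0.25, "stem_branch", "large_only"),
        f("F_extra", cd, 0.45, "within_clade", "large_only", age_of="crown"),
    ]
    epochs = {rec.name: _epoch_for(rec.name, rec.min_age) for rec in fossils}
    partitions = {"matK": (0, 400), "ycf1": (400, 800)}
    sub = SubstitutionModel(family="HKY", freqs=(0.31, 0.19, 0.21, 0.29), kappa=2.5)
    node_index = index_tree(tree)
    clock = ClockModel(
        clock_of={"matK": "shared", "ycf1": "ycf1"},
        mean_rate={"shared": 2e-3, "ycf1": 4e-3},
        log_sd={"shared": 0.3, "ycf1": 0.3},
        multipliers={
            "shared": draw_ucln_multipliers(tree, 0.3, rng, node_index),
            "ycf1": draw_ucln_multipliers(tree, 0.3, rng, node_index),
        })
    aln = simulate_alignment(tree, clock, sub, partitions, rng)
    aln = apply_missing_data(aln, None, rng, fraction=0.05)
    cap = round(1.3 * tree.root.age, 2)
    return StudyBundle(scale="small", seed=seed, tree=tree, alignment=aln,
                       clades=clades, fossils=fossils, epochs=epochs,
                       clock=clock, substitution=sub, bd=bd, fbd_cap=cap,
                       psi=0.03)


_PAPER_LOCI = (("ycf1", 1500), ("matK", 900), ("rbcL", 800), ("trnK", 700),
               ("rpl20_rps18", 600), ("trnV", 500), ("psbB", 500), ("rps4", 400))


def _make_paper_shaped(seed: int) -> StudyBundle:
    rng = np.random.default_rng(seed)
    bd = BDParams(birth=0.055, death=0.025, rho=1.0)
    tree = fast_bd_tree(115, bd, rng, prefix="pine_")
    clades = _pick_clades(tree, 15, min_tips=3)
    names = sorted(clades)  # clade_a .. clade_o, oldest first
    all_taxa = CladeConstraint("ingroup", tree.tip_labels(), node_role="crown")
    clades["ingroup"] = all_taxa

    def rec(name, clade, frac, placement, fset, usable=True, age=None):
        if age is None:
            base = (_stem_age(tree, clades[clade]) if placement == "stem_branch"
                    else _crown_age(tree, clades[clade]))
            age = round(frac * base, 2)
        return FossilRecord(name=name, clade=clade, min_age=age, max_age=None,
                            placement=placement, set_membership=fset,
                            nd_usable=usable)

    fossils = []
    # 12 unique-clade fossils in the small set (alternating placement modes)
    for i, cl in enumerate(names[:12]):
        placement = "stem_branch" if i % 2 == 0 else "within_clade"
        fossils.append(rec(f"F{i + 1:02d}", cl, 0.60 - 0.02 * i, placement, "small"))
    # 2 younger duplicates completing the 14-fossil small set
    fossils.append(rec("F13", names[0], 0.30, "within_clade", "small"))
    fossils.append(rec("F14", names[1], 0.28, "within_clade", "small"))
    # large-only additions: one more duplicate, three new clades
    fossils.append(rec("F15", names[2], 0.26, "within_clade", "large_only"))
    for j, cl in enumerate(names[12:15]):
        fossils.append(rec(f"F{16 + j:02d}", cl, 0.45, "within_clade", "large_only"))
    # unusable for node dating: a stem fossil of the whole in-group and two
    # records without defensible node assignments
    fossils.append(rec("F19", "ingroup", None, "stem_branch", "large_only",
                       usable=False, age=round(0.92 * tree.root.age, 2)))
    fossils.append(rec("F20", names[3], 0.22, "within_clade", "large_only",
                       usable=False))
    fossils.append(rec("F21", names[4], 0.20, "within_clade", "large_only",
                       usable=False))
    epochs = {r.name: _epoch_for(r.name, r.min_age) for r in fossils}
    partitions = {}
    pos = 0
    for locus, L in _PAPER_LOCI:
        partitions[locus] = (pos, pos + L)
        pos += L
    sub = SubstitutionModel(family="HKY", freqs=(0.31, 0.19, 0.21, 0.29), kappa=2.7)
    node_index = index_tree(tree)
    clock = ClockModel(
        clock_of={locus: ("ycf1" if locus == "ycf1" else "shared")
                  for locus, _ in _PAPER_LOCI},
        mean_rate={"shared": 8e-4, "ycf1": 1.6e-3},
        log_sd={"shared": 0.3, "ycf1": 0.3},
        multipliers={
            "shared": draw_ucln_multipliers(tree, 0.3, rng, node_index),
            "ycf1": draw_ucln_multipliers(tree, 0.3, rng, node_index),
        })
    aln = simulate_alignment(tree, clock, sub, partitions, rng)
    # locus dropout emulating a supermatrix coverage histogram: most taxa
    # complete, a tail of taxa missing 1..7 of the 8 loci
    loci = [l for l, _ in _PAPER_LOCI]
    dropout = {}
    taxa = sorted(aln.labels)
    tail = taxa[85:]
    for i, taxon in enumerate(tail):
        k = 1 + int(7 * i / max(len(tail) - 1, 1))
        dropout[taxon] = loci[-k:]
    aln = apply_missing_data(aln, dropout, rng, fraction=0.02)
    cap = round(1.25 * tree.root.age, 2)
    return StudyBundle(scale="paper_shaped", seed=seed, tree=tree,
                       alignment=aln, clades=clades, fossils=fossils,
                       epochs=epochs, clock=clock, substitution=sub, bd=bd,
                       fbd_cap=cap, psi=0.02)


def make_pine_fixture(scale: str = "small", seed: int = 1) -> StudyBundle:
    """Build a study bundle; see the module docstring for the two scales."""
    if scale == "small":
        bundle = _make_small(seed)
    elif scale == "paper_shaped":
        bundle = _make_paper_shaped(seed)
    else:
        raise ValueError(f"scale must be 'small' or 'paper_shaped', got {scale!r}")
    bundle.configs = {
        f"{method}_{fset[0]}": analysis_config(bundle, method, fset)
        for method in METHODS for fset in FOSSIL_SETS}
    return bundle


# ---------------------------------------------------------------------------
# the method matrix
# ---------------------------------------------------------------------------

def nd_calibrations(bundle: StudyBundle, method: str,
                    fossil_set: str) -> list[CalibrationDensity]:
    """Node-dating densities for one cell of the method matrix."""
    chosen = select_oldest_per_clade(fossils_in_set(bundle.fossils, fossil_set),
                                     nd_mode=True)
    chosen = [r for r in chosen if r.clade in bundle.clades]
    ages = [r.min_age for r in chosen]
    a_min, a_max = min(ages), max(ages)
    out = []
    for r in chosen:
        if method == "NDn":
            dens = build_ndn_density(r, bundle.epochs[r.name])
        else:
            dens = build_ndb_density(r, a_min, a_max)
            if method == "NDu":
                dens = build_ndu_density(dens)
        out.append(dens)
    return out


def fbd_age_specs(bundle: StudyBundle, method: str,
                  fossil_set: str) -> dict[str, FBDAgeSpec]:
    mode = "fixed_tip" if method == "FBD_tip" else "uniform_range"
    return {r.name: build_fbd_age_spec(r, mode, cap=bundle.fbd_cap)
            for r in fossils_in_set(bundle.fossils, fossil_set)}


def analysis_config(bundle: StudyBundle, method: str, fossil_set: str) -> dict:
    """JSON-able description of one analysis cell."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    cfg = {"method": method, "fossil_set": fossil_set,
           "birth": bundle.bd.birth, "death": bundle.bd.death,
           "rho": bundle.bd.rho}
    if method.startswith("ND"):
        cfg["calibrations"] = [d.to_dict() for d in
                               nd_calibrations(bundle, method, fossil_set)]
    else:
        cfg["psi"] = bundle.psi
        cfg["stem_cap"] = bundle.fbd_cap
        cfg["age_specs"] = {k: v.to_dict() for k, v in
                            fbd_age_specs(bundle, method, fossil_set).items()}
    return cfg


def build_analysis_model(bundle: StudyBundle, method: str, fossil_set: str,
                         with_data: bool = True,
                         sample_params: tuple = (),
                         exclude_fossil: str | None = None) -> AnalysisModel:
    """Instantiate the engine model for one cell of the method matrix.

    ``exclude_fossil`` drops one fossil before calibration construction
    (leave-one-out sensitivity). The clock starts at the true simulation
    clock with unit multipliers; mean rates are fixed unless listed in
    ``sample_params``.
    """
    fossils = fossils_in_set(bundle.fossils, fossil_set)
    if exclude_fossil is not None:
        if all(r.name != exclude_fossil for r in fossils):
            raise ValueError(f"fossil {exclude_fossil!r} not in the {fossil_set} set")
        fossils = [r for r in fossils if r.name != exclude_fossil]
    node_index = index_tree(bundle.tree)
    unit = {idx: 1.0 for idx in node_index.values()
            if idx != node_index[id(bundle.tree.root)]}
    clock = ClockModel(clock_of=dict(bundle.clock.clock_of),
                       mean_rate=dict(bundle.clock.mean_rate),
                       log_sd=dict(bundle.clock.log_sd),
                       multipliers={cid: dict(unit)
                                    for cid in bundle.clock.mean_rate})
    sub_bundle = StudyBundle(**{**bundle.__dict__, "fossils": fossils,
                                "configs": {}})
    if method.startswith("ND"):
        selected = select_oldest_per_clade(fossils, nd_mode=True)
        if not selected:
            raise ValueError("no usable fossils left for node dating")
        cals = nd_calibrations(sub_bundle, method, fossil_set)
        return AnalysisModel(
            mode="nd", clades=bundle.clades, calibrations=cals,
            birth=bundle.bd.birth, death=bundle.bd.death, rho=bundle.bd.rho,
            alignment=bundle.alignment if with_data else None,
            clock=clock, substitution=bundle.substitution,
            sample_params=sample_params)
    specs = fbd_age_specs(sub_bundle, method, fossil_set)
    return AnalysisModel(
        mode="fbd", clades=bundle.clades, fossils=fossils, age_specs=specs,
        birth=bundle.bd.birth, death=bundle.bd.death, rho=bundle.bd.rho,
        psi=bundle.psi, stem_cap=bundle.fbd_cap,
        alignment=bundle.alignment if with_data else None,
        clock=clock, substitution=bundle.substitution,
        sample_params=sample_params)


# ---------------------------------------------------------------------------
# running one analysis cell
# ---------------------------------------------------------------------------

def calibrated_start_tree(tree: TimeTree,
                          calibrations: list[CalibrationDensity],
                          clades: dict[str, CladeConstraint]) -> TimeTree:
    """A copy of the tree with calibrated node ages moved to their density
    medians (age monotonicity restored by pushing ancestors up and
    compressing descendants), giving the chain a feasible starting state
    even under narrow uniform calibrations."""
    from .tree import mrca
    out = tree.copy()
    targets = []
    for cal in calibrations:
        crown = mrca(out, clades[cal.target].members)
        node = (crown.parent if cal.node_role == "stem" and crown.parent is not None
                else crown)
        targets.append((node, cal))
    targets.sort(key=lambda t: -t[1].ppf(0.5))

    def violated(node, cal):
        import math
        return not math.isfinite(cal.logpdf(node.age))

    for _ in range(100):
        dirty = False
        for node, cal in targets:
            if not violated(node, cal):
                continue
            dirty = True
            node.age = float(cal.ppf(0.5))
            child, anc = node, node.parent
            while anc is not None and anc.age <= child.age:
                anc.age = child.age * 1.02 + 1e-6
                child, anc = anc, anc.parent
            _compress_below(node)
        if not dirty:
            break
    else:
        raise ValueError(
            "could not find a starting tree satisfying all calibrations; "
            "the densities may be mutually incompatible")
    out.validate()
    return out


def _compress_below(node) -> None:
    for c in node.children:
        if c.children and c.age >= node.age:
            c.age = node.age * 0.98
            _compress_below(c)


def run_analysis_cell(bundle: StudyBundle, method: str, fossil_set: str,
                      generations: int = 20000, sample_every: int = 20,
                      seed: int = 1, prior_only: bool = False,
                      burnin_fraction: float = 0.3,
                      exclude_fossil: str | None = None,
                      sample_params: tuple = ()):
    """Run one cell of the method matrix; returns (result, post_burnin_trees).

    A thin composition of :func:`build_analysis_model`,
    :func:`calibrated_start_tree` and the chain driver, with per-run burn-in
    applied to the tree log.
    """
    from .mcmc import ChainConfig, run_mcmc
    model = build_analysis_model(bundle, method, fossil_set,
                                 with_data=not prior_only,
                                 sample_params=sample_params,
                                 exclude_fossil=exclude_fossil)
    init = (calibrated_start_tree(bundle.tree, model.calibrations, bundle.clades)
            if model.mode == "nd" else bundle.tree)
    cfg = ChainConfig(generations=generations, sample_every=sample_every,
                      seed=seed, prior_only=prior_only)
    result = run_mcmc(model, init, cfg)
    n_keep = len(result.trees)
    burn = int(burnin_fraction * n_keep)
    return result, result.trees[burn:]


def clade_age_table(trees, bundle: StudyBundle, analysis: str = "run"):
    """Crown ages of every named bundle clade across a tree log."""
    from .summarize import extract_clade_ages
    clades = [c for name, c in sorted(bundle.clades.items())
              if name != "ingroup"]
    return extract_clade_ages(trees, clades, analysis=analysis)
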