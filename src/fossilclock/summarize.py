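"""Tree-log post-processing: resampling, ESS, MCC trees, HPDs, clade ages.

Conventions follow the common BEAST-era toolchain: a log of N generations
sampled every f contains N/f + 1 states (generation 0 included); burn-in
discards the first ``floor(b * N/f)`` of them. The maximum clade credibility
(MCC) tree is the sampled tree maximizing the product of clade posterior
frequencies, annotated with common-ancestor heights: each node's age is the
mean, over all input trees, of the age of the MRCA of that node's tip set.
Clade frequencies are computed on extant-tip bipartitions (fossil tips are
pruned first when present, since their placements carry no topological
signal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tree import CladeConstraint, TimeTree, mrca, prune_tips

__all__ = [
    "subsample_log",
    "ess",
    "hpd_interval",
    "mcc_tree",
    "write_mcc_nexus",
    "extract_clade_ages",
    "combine_logs",
]


def subsample_log(samples: Sequence, total_generations: int, frequency: int,
                  burnin_fraction: float) -> list:
    """Resample a log at ``frequency`` and discard a burn-in fraction.

    ``samples`` must hold the states at generations 0, f, 2f, ..., N of the
    original log (any stride that ``frequency`` is a multiple of). Retains
    states at generations {k * frequency} and then drops the first
    ``floor(b * N/frequency)`` of the N/frequency + 1 retained states.
    """
    if not 0 <= burnin_fraction < 1:
        raise ValueError(f"burn-in fraction must be in [0, 1), got {burnin_fraction}")
    if frequency <= 0 or total_generations % frequency:
        raise ValueError("total_generations must be a positive multiple of frequency")
    n_states = len(samples)
    if (n_states - 1) <= 0 or total_generations % (n_states - 1):
        raise ValueError(
            f"log with {n_states} states does not tile {total_generations} generations")
    stride_gen = total_generations // (n_states - 1)
    if frequency % stride_gen:
        raise ValueError(
            f"resampling frequency {frequency} is not a multiple of the log stride {stride_gen}")
    step = frequency // stride_gen
    kept = list(samples[::step])
    n_kept = total_generations // frequency + 1
    assert len(kept) == n_kept
    burn = math.floor(burnin_fraction * (total_generations // frequency))
    out = kept[burn:]
    if not out:
        raise ValueError("burn-in removed every sample")
    return out


def expected_subsample_count(total_generations: int, frequency: int,
                             burnin_fraction: float) -> int:
    """N/f + 1 - floor(b * N/f): the retained-tree count of the convention."""
    per = total_generations // frequency
    return per + 1 - math.floor(burnin_fraction * per)


def ess(series, stride: int = 1) -> tuple[float, bool]:
    """Effective sample size via the initial-positive-sequence estimator.

    Sums autocovariances in pairs (Geyer's initial positive sequence) until a
    pair sum goes non-positive; ESS = n / (1 + 2 * sum of autocorrelations).
    Returns ``(ess, zero_variance)``: a constant series is reported as ESS =
    n with the flag set.
    """
    x = np.asarray(series, float)
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    var = x.var()
    if var == 0:
        return float(n), True
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    tau_sum = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau_sum += pair
        t += 2
    return float(n / (1.0 + 2.0 * tau_sum)), False


def hpd_interval(values, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * n)`` of the sorted values."""
    x = np.sort(np.asarray(values, float))
    n = x.size
    if n < 20:
        raise ValueError(f"need at least 20 values for an HPD interval, got {n}")
    k = math.ceil(mass * n)
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


# ---------------------------------------------------------------------------
# MCC tree with common-ancestor heights
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedNode:
    """Node annotation written onto the MCC tree."""

    age: float
    hpd_low: float | None
    hpd_high: float | None
    support: float


def _topology_key(tree: TimeTree) -> str:
    def rec(node):
        if node.is_leaf:
            return node.label or ""
        return "(" + ",".join(sorted(rec(c) for c in node.children)) + ")"
    return rec(tree.root)


def _extant_clades(tree: TimeTree) -> dict[frozenset, float]:
    """Map from extant-tip set to node age for every internal node."""
    out = {}
    for node in tree.internal_nodes():
        tips = frozenset(l.label for l in node.leaves() if not l.is_fossil)
        if len(tips) >= 2:
            out.setdefault(tips, node.age)
    return out


def mcc_tree(trees: Sequence[TimeTree], annotate: bool = True) -> TimeTree:
    """Maximum clade credibility tree with common-ancestor node heights.

    Fossil tips are pruned before computing clade frequencies. The winning
    tree's internal node ages are replaced by the mean MRCA age of the
    node's extant tip set across all input trees; 95% HPD bounds and clade
    support are attached as ``node.annotation`` when ``annotate`` is set and
    enough trees are supplied.
    """
    if not trees:
        raise ValueError("no trees supplied")
    pruned = []
    for t in trees:
        fossils = t.fossil_labels()
        pruned.append(prune_tips(t, fossils) if fossils else t)
    tipset = set(pruned[0].tip_labels())
    for t in pruned[1:]:
        if set(t.tip_labels()) != tipset:
            raise ValueError("trees have differing extant tip sets")
    counts: dict[frozenset, int] = {}
    ages: dict[frozenset, list[float]] = {}
    per_tree = [_extant_clades(t) for t in pruned]
    for clades in per_tree:
        for cl in clades:
            counts[cl] = counts.get(cl, 0) + 1
    n = len(pruned)
    # ties in the product of clade frequencies are broken by a canonical
    # topology key so the choice is independent of input order
    best_idx, best = 0, None
    for i, clades in enumerate(per_tree):
        score = sum(math.log(counts[cl] / n) for cl in clades)
        key = (-score, _topology_key(pruned[i]))
        if best is None or key < best:
            best_idx, best = i, key
    winner = pruned[best_idx].copy()
    # common-ancestor heights: mean MRCA age of each node's tip set
    for node in winner.internal_nodes():
        tips = frozenset(l.label for l in node.leaves())
        samples = [float(mrca(t, tips).age) for t in pruned]
        node.age = float(np.mean(samples))
        if annotate:
            low, high = (hpd_interval(samples) if len(samples) >= 20
                         else (None, None))
            node.annotation = AnnotatedNode(node.age, low, high,
                                            counts.get(tips, n) / n)
    return winner


def write_mcc_nexus(tree: TimeTree) -> str:
    """NEXUS serialization of an annotated MCC tree with node comments
    carrying the common-ancestor height, 95% HPD bounds and clade support."""
    def rec(node):
        if node.is_leaf:
            s = node.label
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
        ann = getattr(node, "annotation", None)
        if ann is not None:
            parts = [f"age={ann.age:.6g}", f"posterior={ann.support:.4g}"]
            if ann.hpd_low is not None:
                parts.append(f"height_95%_HPD={{{ann.hpd_low:.6g},{ann.hpd_high:.6g}}}")
            s += "[&" + ",".join(parts) + "]"
        if node.parent is not None:
            s += f":{node.branch_duration:.12g}"
        return s

    labels = sorted(tree.tip_labels())
    lines = ["#NEXUS", "Begin taxa;", f"\tDimensions ntax={len(labels)};",
             "\tTaxlabels"]
    lines += [f"\t\t{lab}" for lab in labels]
    lines += ["\t\t;", "End;", "Begin trees;",
              f"tree MCC = {rec(tree.root)};", "End;"]
    return "\n".join(lines) + "\n"


def extract_clade_ages(trees: Sequence[TimeTree],
                       clades: Sequence[CladeConstraint],
                       analysis: str = "run") -> pd.DataFrame:
    """Crown MRCA ages of named clades across a tree log.

    One row per (analysis, tree, clade); monophyly is not required — the
    MRCA is taken regardless and a ``monophyly_ok`` flag records violations.
    """
    rows = []
    for k, tree in enumerate(trees):
        for clade in clades:
            present = {m for m in clade.members if m in tree}
            if not present:
                raise KeyError(f"clade {clade.name!r}: no members in tree {k}")
            missing = clade.members - present
            if missing:
                raise KeyError(
                    f"clade {clade.name!r}: taxa missing from tree {k}: {sorted(missing)}")
            node = mrca(tree, present)
            extant_desc = {l.label for l in node.leaves() if not l.is_fossil}
            ok = extant_desc == {m for m in present
                                 if not tree.find(m).is_fossil}
            rows.append({"analysis": analysis, "tree": k, "clade": clade.name,
                         "age": float(node.age), "monophyly_ok": ok})
    return pd.DataFrame(rows)


def combine_logs(logs: Sequence[Sequence], total_generations: int,
                 frequency: int, burnin_fraction: float) -> list:
    """Concatenate several runs after per-run resampling and burn-in."""
    out = []
    for log in logs:
        out.extend(subsample_log(log, total_generations, frequency, burnin_fraction))
    return out
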