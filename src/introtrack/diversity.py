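"""Genetic diversity of projected genotypes: IBS distance, NJ tree, summaries.

The distance between two diploid genotypes is 1 - IBS, where IBS (identity
by state) is the mean over pairwise-complete loci of the number of shared
alleles divided by two: identical homozygotes share 2, a heterozygote and
either constituent homozygote share 1, opposite homozygotes share 0.  The
distance is a semimetric bounded in [0, 1].

Trees are built with classical agglomerative neighbor-joining (Saitou-Nei
Q-criterion, standard branch-length and distance-update formulas), emitting
newick text.  Ties in Q are broken toward the lexicographically smallest id
pair and negative branch lengths are clamped to zero with the total deficit
recorded, so the output is deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .projection import ProjectedGenotypeMatrix

__all__ = ["DistanceMatrix", "PhyloTree", "ibs_distance", "neighbor_join",
           "group_distance_summary"]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1] plus per-pair locus counts."""

    ids: list[str]
    values: np.ndarray
    n_loci: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
                raise ValueError("distances must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def ibs_distance(genotypes: ProjectedGenotypeMatrix) -> DistanceMatrix:
    """1 - mean allele sharing between every pair of diploid genotypes.

    Loci missing in either sample of a pair are excluded from that pair's
    mean; a pair with zero complete loci gets NaN (flagged, not silently
    zero).
    """
    a1, a2 = genotypes.a1, genotypes.a2  # sorted within cell
    n = genotypes.n_samples
    if n < 2 or a1.shape[1] < 1:
        raise ValueError("need at least 2 samples and 1 locus")
    valid = a1 >= 0
    d = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        vi = valid[i]
        for j in range(i + 1, n):
            ok = vi & valid[j]
            m = int(ok.sum())
            counts[i, j] = counts[j, i] = m
            if m == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            x1, x2 = a1[i][ok], a2[i][ok]
            y1, y2 = a1[j][ok], a2[j][ok]
            same_pair = (x1 == y1) & (x2 == y2)
            any_common = (x1 == y1) | (x1 == y2) | (x2 == y1) | (x2 == y2)
            shared = np.where(same_pair, 2, np.where(any_common, 1, 0))
            dist = 1.0 - shared.mean() / 2.0
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(genotypes.sample_ids), d, counts)


@dataclass
class PhyloTree:
    """Unrooted NJ tree: newick text plus the clamped negative-length deficit."""

    newick: str
    leaf_ids: list[str]
    clamped_deficit: float = 0.0

    def __str__(self) -> str:  # pragma: no cover
        return self.newick


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label, children=()):
        self.label = label
        self.children = list(children)  # (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_join(d: DistanceMatrix) -> PhyloTree:
    """Classical neighbor-joining on a complete distance matrix.

    Pair selection minimises Q(i,j) = (m-2) d(i,j) - r_i - r_j; branch
    lengths use the standard formulas and the final three nodes are resolved
    with the closed-form three-point solution.  Requires >= 3 samples and no
    undefined (NaN) entries.
    """
    ids = list(d.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    if np.isnan(d.values).any():
        raise ValueError("distance matrix has undefined entries")
    nodes: dict[str, _Node] = {i: _Node(i) for i in ids}
    dist: dict[frozenset, float] = {frozenset((a, b)): d.get(a, b)
                                    for a, b in itertools.combinations(ids, 2)}
    active = sorted(ids)
    deficit = 0.0
    join_count = 0

    def D(a, b):
        return dist[frozenset((a, b))]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(D(a, b) for b in active if b != a) for a in active}
        best, best_q = None, np.inf
        for a, b in itertools.combinations(active, 2):  # active sorted -> lexicographic ties
            q = (m - 2) * D(a, b) - r[a] - r[b]
            if q < best_q - 1e-12:
                best_q, best = q, (a, b)
        a, b = best
        va = D(a, b) / 2 + (r[a] - r[b]) / (2 * (m - 2))
        vb = D(a, b) - va
        if va < 0:
            deficit += -va
            va = 0.0
        if vb < 0:
            deficit += -vb
            vb = 0.0
        join_count += 1
        label = f"_nj{join_count}"
        nodes[label] = _Node(label, [(nodes[a], va), (nodes[b], vb)])
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((label, c))] = (D(a, c) + D(b, c) - D(a, b)) / 2
        active = sorted([c for c in active if c not in (a, b)] + [label])

    a, b, c = active
    va = (D(a, b) + D(a, c) - D(b, c)) / 2
    vb = (D(a, b) + D(b, c) - D(a, c)) / 2
    vc = (D(a, c) + D(b, c) - D(a, b)) / 2
    lens = []
    for v in (va, vb, vc):
        if v < 0:
            deficit += -v
            v = 0.0
        lens.append(v)
    root = _Node("", [(nodes[a], lens[0]), (nodes[b], lens[1]), (nodes[c], lens[2])])
    return PhyloTree(root.newick() + ";", ids, clamped_deficit=deficit)


@dataclass
class GroupDistanceSummary:
    within: pd.DataFrame
    between: pd.DataFrame


def group_distance_summary(d: DistanceMatrix, groups: Mapping[str, str]
                           ) -> GroupDistanceSummary:
    """Within-group max/mean/min and between-group mean distances.

    Every sample must carry a group label.  Within-group statistics run over
    unordered pairs; singleton groups are flagged with NaN statistics.
    Groups are reported in sorted label order, so the output is deterministic
    regardless of sample order.
    """
    unlabeled = [s for s in d.ids if s not in groups]
    if unlabeled:
        raise ValueError(f"samples without group label: {unlabeled}")
    labels = sorted(set(groups[s] for s in d.ids))
    members = {g: [s for s in d.ids if groups[s] == g] for g in labels}
    idx = {s: i for i, s in enumerate(d.ids)}

    within_rows = {}
    for g in labels:
        ms = members[g]
        pairs = [d.values[idx[a], idx[b]] for a, b in itertools.combinations(ms, 2)]
        if pairs:
            within_rows[g] = {"n_samples": len(ms), "n_pairs": len(pairs),
                              "max": float(np.max(pairs)), "mean": float(np.mean(pairs)),
                              "min": float(np.min(pairs)), "singleton": False}
        else:
            within_rows[g] = {"n_samples": len(ms), "n_pairs": 0,
                              "max": np.nan, "mean": np.nan, "min": np.nan,
                              "singleton": True}
    between = pd.DataFrame(np.nan, index=labels, columns=labels)
    for g1, g2 in itertools.combinations_with_replacement(labels, 2):
        if g1 == g2:
            between.loc[g1, g2] = within_rows[g1]["mean"]
            continue
        vals = [d.values[idx[a], idx[b]] for a in members[g1] for b in members[g2]]
        between.loc[g1, g2] = between.loc[g2, g1] = float(np.mean(vals))
    return GroupDistanceSummary(pd.DataFrame.from_dict(within_rows, orient="index"),
                                between)
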