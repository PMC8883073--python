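import numpy as np
import pandas as pd
import pytest

from introtrack import FounderGenome, GeneticMap, demo_map
from introtrack.markerdesign import HOM_ALT, HOM_REF, ParentalVariantTable

BC1S1 = ("make_f1", "backcross_to_recipient", "self")


@pytest.fixture
def small_map() -> GeneticMap:
    """Three chromosomes, six loci each, 30 Mb / 90 cM."""
    return demo_map(n_chrom=3, loci_per_chrom=6)


@pytest.fixture
def unlinked_map() -> GeneticMap:
    """Twelve chromosomes with a single locus each: fully unlinked loci."""
    return demo_map(n_chrom=12, loci_per_chrom=1)


@pytest.fixture
def founders(small_map):
    donor = FounderGenome.inbred("B9008", small_map, 0)
    recipient = FounderGenome.inbred("R1", small_map, 1)
    return donor, recipient


def make_variant_table(positions, recipients=("R1", "R2"), donor_gt=HOM_REF,
                       recipient_gt=HOM_ALT, **overrides) -> ParentalVariantTable:
    """Tiny hand-built variant table; overrides patch single columns per locus.

    ``positions`` is a list of (chrom, pos); overrides map column name ->
    list of values (one per locus).
    """
    n = len(positions)
    df = pd.DataFrame({
        "chrom": [c for c, _ in positions],
        "pos": [p for _, p in positions],
        "ref": ["A"] * n,
        "alt": ["G"] * n,
        "gt_donor": [donor_gt] * n,
        "flag_flanking_variation": [False] * n,
        "flag_nigra_hit": [False] * n,
    })
    for r in recipients:
        df[f"gt_{r}"] = [recipient_gt] * n
        df[f"bjub_{r}"] = ["C"] * n
    for col, values in overrides.items():
        df[col] = values
    return ParentalVariantTable(df, list(recipients))


# ---------------------------------------------------------------------------
# independent brute-force oracles (used by unit and acceptance tests)
# ---------------------------------------------------------------------------

def brute_fill(calls: pd.DataFrame, markers: pd.DataFrame) -> pd.DataFrame:
    """Nearest-non-missing fill by explicit per-cell scan (tie -> left)."""
    out = calls.copy()
    for line in calls.index:
        for chrom in markers["chrom"].unique():
            cols = [m for m in calls.columns if markers.loc[m, "chrom"] == chrom]
            obs = [m for m in cols if calls.loc[line, m] != "D"]
            for m in cols:
                if calls.loc[line, m] != "D" or not obs:
                    continue
                bp = markers.loc[m, "bp"]
                best, best_d = None, None
                for o in obs:
                    dist = abs(markers.loc[o, "bp"] - bp)
                    better = best_d is None or dist < best_d or (
                        dist == best_d and markers.loc[o, "bp"] < markers.loc[best, "bp"])
                    if better:
                        best, best_d = o, dist
                out.loc[line, m] = calls.loc[line, best]
    return out


def brute_nearest_marker(markers: pd.DataFrame, chrom: str, pos: int):
    """Id of the nearest marker in bp on a chromosome (tie -> smaller bp)."""
    best, best_key = None, None
    for m in markers.index:
        if markers.loc[m, "chrom"] != chrom:
            continue
        key = (abs(markers.loc[m, "bp"] - pos), markers.loc[m, "bp"])
        if best_key is None or key < best_key:
            best, best_key = m, key
    return best


def random_additive_tree(n_leaves: int, rng: np.random.Generator) -> pd.DataFrame:
    """Exact leaf-to-leaf path distances of a random unrooted binary tree.

    Built by sequential leaf attachment with positive branch lengths.  An
    additive (tree-metric) matrix determines its generating tree uniquely, so
    recovering these distances from NJ output verifies both topology and
    branch lengths.
    """
    labels = [f"t{i}" for i in range(n_leaves)]
    # adjacency with branch lengths; internal nodes get negative ids
    edges: dict[tuple, float] = {}
    next_internal = [-1]

    def add_edge(a, b, w):
        edges[(a, b)] = w
        edges[(b, a)] = w

    def split_edge(a, b, leaf, rng):
        w = edges.pop((a, b)); edges.pop((b, a))
        mid = next_internal[0]; next_internal[0] -= 1
        u = rng.uniform(0.05, 0.95)
        add_edge(a, mid, w * u)
        add_edge(mid, b, w * (1 - u))
        add_edge(mid, leaf, float(rng.uniform(0.1, 1.0)))

    add_edge(labels[0], labels[1], float(rng.uniform(0.2, 1.5)))
    for leaf in labels[2:]:
        pairs = [e for e in edges if str(e[0]) < str(e[1])]
        a, b = pairs[rng.integers(0, len(pairs))]
        split_edge(a, b, leaf, rng)

    # all-pairs distances by BFS
    nodes = {x for e in edges for x in e}
    dist = pd.DataFrame(0.0, index=labels, columns=labels)
    adj: dict = {}
    for (a, b), w in edges.items():
        adj.setdefault(a, []).append((b, w))
    for src in labels:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nxt, w in adj[cur]:
                if nxt not in seen:
                    seen[nxt] = seen[cur] + w
                    stack.append(nxt)
        for dst in labels:
            dist.loc[src, dst] = seen[dst]
    return (dist + dist.T) / 2  # exact symmetry despite float path-sum order
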