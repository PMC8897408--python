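"""Per-window trees, bootstrap support and topology weighting.

Window trees are neighbor-joining trees on IUPAC-aware p-distances. NJ is a
consistent estimator of the tree under additive distances and, at the scale
of 10-kb windows, a faithful stand-in for likelihood searches when the
quantity of interest is the distribution of window topologies rather than
branch lengths. The joining order is fully deterministic: ties in the
Q-criterion resolve to the lexicographically smallest index pair.

Topology weighting follows the subsampling idea behind window-based
topology-weighting analyses: for each window tree, iterate over
combinations of one tip per group, prune to those tips, root on the
outgroup tip, and record the induced group-level topology; the weight of a
topology is the fraction of combinations supporting it. When the number of
combinations is large the iteration switches to uniform Monte-Carlo
sampling.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .consensus import Alignment, DistanceMatrix, p_distance
from .simulate import stage_rng


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree; negative branch lengths clamped to zero."""
    if dm.undefined_pairs:
        raise ValueError(f"undefined distances for pairs: {dm.undefined_pairs}")
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.astype(np.float64).copy()
    nodes = [_leaf_newick(lab) for lab in dm.labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie-break: argmin of the flattened row-major matrix
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        d_ij = sub[i, j]
        vi = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d_ij - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        ai, aj = active[i], active[j]
        new_dist = 0.5 * (D[ai, :] + D[aj, :] - d_ij)
        D = np.vstack([D, new_dist])
        D = np.hstack([D, np.append(new_dist, 0.0)[:, None]])
        nodes.append(f"({nodes[ai]}:{vi:.10g},{nodes[aj]}:{vj:.10g})")
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]
    # resolve the final three clusters onto one internal node
    a, b, c = active
    va = max(0.5 * (D[a, b] + D[a, c] - D[b, c]), 0.0)
    vb = max(0.5 * (D[a, b] + D[b, c] - D[a, c]), 0.0)
    vc = max(0.5 * (D[a, c] + D[b, c] - D[a, b]), 0.0)
    newick = f"({nodes[a]}:{va:.10g},{nodes[b]}:{vb:.10g},{nodes[c]}:{vc:.10g});"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


def _leaf_newick(label: str) -> str:
    if any(ch in label for ch in "(),:;'\" "):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# bipartitions and bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as canonical leaf-label sets.

    Each internal edge is represented by the side not containing the
    alphabetically first label, so rerooting cannot change the key.
    """
    labels = sorted(t.label for t in tree.taxon_namespace)
    anchor = labels[0]
    all_set = frozenset(labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = all_set - below if anchor in below else below
        if 1 < len(side) < len(labels) - 1:
            out.add(side)
    return out


def bootstrap_support(alignment: Alignment, n_reps: int = 100,
                      seed: int = 0) -> tuple[dendropy.Tree, dict]:
    """Nonparametric bootstrap over alignment columns for an NJ tree.

    Returns the point-estimate tree with internal-node labels set to the
    percentage of replicates containing each bipartition, plus the raw
    ``{bipartition: support}`` mapping. ``n_reps == 0`` returns the point
    tree with no supports.
    """
    if alignment.length == 0:
        raise ValueError("empty alignment")
    point = nj_tree(p_distance(alignment))
    if n_reps == 0:
        return point, {}
    target = _bipartitions(point)
    counts = Counter()
    rng = stage_rng(seed, "bootstrap", 0)
    for _ in range(n_reps):
        cols = rng.integers(0, alignment.length, size=alignment.length)
        rep_aln = Alignment(alignment.labels, alignment.seqs[:, cols])
        rep = nj_tree(p_distance(rep_aln))
        for bp in _bipartitions(rep):
            if bp in target:
                counts[bp] += 1
    support = {bp: 100.0 * counts[bp] / n_reps for bp in target}
    labels_all = frozenset(t.label for t in point.taxon_namespace)
    anchor = min(labels_all)
    for node in point.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = labels_all - below if anchor in below else below
        if side in support:
            node.label = f"{support[side]:.0f}"
    return point, support


# ---------------------------------------------------------------------------
# topology weighting
# ---------------------------------------------------------------------------

@dataclass
class TopologyWeights:
    window: str
    weights: dict[str, float]
    mode: str               # "exhaustive" | "sampled"
    n_combinations: int

    def __post_init__(self):
        total = sum(self.weights.values())
        if self.weights and abs(total - 1.0) > 1e-9:
            raise ValueError("topology weights must sum to 1")


def _edge_leafsets(tree: dendropy.Tree, leaf_index: Mapping[str, int]) -> list[int]:
    """Bitmask of leaves below each edge (child side), as python ints."""
    masks = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._mask = 1 << leaf_index[node.taxon.label]
        else:
            node._mask = 0
            for ch in node.child_nodes():
                node._mask |= ch._mask
        if node.parent_node is not None:
            masks.append(node._mask)
    return masks


def _canonical_nested(groups: frozenset, clades: set[frozenset]) -> str:
    """Sorted nested-parentheses label from a laminar clade family."""
    proper = [c for c in clades if c < groups]
    maximal = [c for c in proper
               if not any(c < d for d in proper)]
    covered = set().union(*maximal) if maximal else set()
    parts = [_canonical_nested(c, {d for d in clades if d < c}) for c in maximal]
    parts += sorted(groups - covered)
    if len(parts) == 1:
        return parts[0]
    return "(" + ",".join(sorted(parts)) + ")"


def _classify_combination(edge_masks: Sequence[int], combo_bits: Mapping[str, int],
                          outgroup: str) -> str:
    combo_mask = 0
    for b in combo_bits.values():
        combo_mask |= b
    o_bit = combo_bits[outgroup]
    ingroup = frozenset(g for g in combo_bits if g != outgroup)
    clades: set[frozenset] = set()
    for m in edge_masks:
        s = m & combo_mask
        if s == 0 or s == combo_mask:
            continue
        if s & o_bit:
            s = combo_mask & ~s
        names = frozenset(g for g, b in combo_bits.items() if b & s)
        if 2 <= len(names) <= len(ingroup):
            clades.add(names)
    clades.discard(ingroup)
    inner = _canonical_nested(ingroup, clades)
    return f"({inner},{outgroup})"


def topology_weights(tree: dendropy.Tree, group_map: Mapping[str, str],
                     outgroup: str, window: str = "",
                     max_exhaustive: int = 10_000, n_samples: int = 1000,
                     seed: int = 0) -> TopologyWeights:
    """Group-level topology weights for one window tree.

    ``group_map`` assigns every leaf to exactly one group; ``outgroup``
    names the group used to root each sampled subtree. All combinations of
    one leaf per group are enumerated exhaustively unless their number
    exceeds ``max_exhaustive``, in which case ``n_samples`` uniform draws
    are taken.
    """
    leaves = [t.label for t in tree.taxon_namespace]
    members: dict[str, list[str]] = {}
    for leaf in leaves:
        if leaf not in group_map:
            raise ValueError(f"leaf {leaf!r} missing from the group map")
        members.setdefault(group_map[leaf], []).append(leaf)
    groups = sorted(members)
    if outgroup not in members:
        raise ValueError(f"outgroup group {outgroup!r} has no sampled leaves")
    if len(groups) < 4:
        raise ValueError("topology weighting needs >= 4 groups incl. outgroup")
    for g, mem in members.items():
        if not mem:
            raise ValueError(f"group {g!r} has no sampled leaves")

    leaf_index = {lab: i for i, lab in enumerate(leaves)}
    edge_masks = _edge_leafsets(tree, leaf_index)

    sizes = [len(members[g]) for g in groups]
    total = int(np.prod(sizes))
    counts: Counter = Counter()
    if total <= max_exhaustive:
        mode = "exhaustive"
        n_comb = total
        for combo in itertools.product(*(members[g] for g in groups)):
            bits = {g: 1 << leaf_index[leaf] for g, leaf in zip(groups, combo)}
            counts[_classify_combination(edge_masks, bits, outgroup)] += 1
    else:
        mode = "sampled"
        n_comb = n_samples
        rng = stage_rng(seed, "topology", 0)
        for _ in range(n_samples):
            combo = [members[g][rng.integers(len(members[g]))] for g in groups]
            bits = {g: 1 << leaf_index[leaf] for g, leaf in zip(groups, combo)}
            counts[_classify_combination(edge_masks, bits, outgroup)] += 1
    weights = {topo: c / n_comb for topo, c in counts.items()}
    return TopologyWeights(window=window, weights=weights, mode=mode,
                           n_combinations=n_comb)


def weight_summary(weight_list: Sequence[TopologyWeights]):
    """Genome-wide mean weight and argmax-window count per topology."""
    import pandas as pd

    topologies = sorted({t for w in weight_list for t in w.weights})
    mat = np.array([[w.weights.get(t, 0.0) for t in topologies]
                    for w in weight_list])
    mean_w = mat.mean(axis=0) if len(mat) else np.zeros(len(topologies))
    argmax_counts = np.zeros(len(topologies), dtype=int)
    for row in mat:
        argmax_counts[int(row.argmax())] += 1
    return pd.DataFrame({
        "topology": topologies,
        "mean_weight": mean_w,
        "n_windows_best": argmax_counts,
    })


def write_weights_tsv(weight_list: Sequence[TopologyWeights], path) -> None:
    with open(path, "w") as fh:
        fh.write("window\ttopology\tweight\tmode\tn_combinations\n")
        for w in weight_list:
            for topo, val in sorted(w.weights.items()):
                fh.write(f"{w.window}\t{topo}\t{val:.6f}\t{w.mode}\t{w.n_combinations}\n")
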