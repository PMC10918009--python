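"""Distance-based phylogeny: NJ trees, bootstrap support, group assignment.

Candidate proviral loci are assigned to an ERV group by whether they form a
supported monophyletic cluster with that group's reference representative in
a neighbor-joining tree.  NJ is implemented in-package (Saitou-Nei) with
fixed tie-breaking (lowest current index pair) so that output is
deterministic; negative branch lengths are clamped to zero with a warning,
per common practice.  Bootstrap support resamples alignment columns with
replacement and reports the percentage of replicate trees containing each
internal split of the full-data tree.

Distances: uncorrected p (pairwise deletion), Jukes-Cantor, or Kimura
2-parameter.  An escape hatch writes the alignment for external
maximum-likelihood tools and re-imports their newick trees.
"""

from __future__ import annotations

import warnings

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .dating import p_distance

_VALID = set("ACGT")
_PURINES = set("AG")


def _pair_distance(a: str, b: str, model: str) -> float:
    if model == "p":
        return p_distance(a, b)
    compared = transitions = transversions = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _VALID and y in _VALID:
            compared += 1
            if x != y:
                if (x in _PURINES) == (y in _PURINES):
                    transitions += 1
                else:
                    transversions += 1
    if compared == 0:
        raise ValueError("no comparable sites between sequences")
    p = (transitions + transversions) / compared
    if model == "JC":
        if p >= 0.75:
            raise ValueError("saturated pair under Jukes-Cantor")
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    if model == "K2P":
        P = transitions / compared
        Q = transversions / compared
        inner1 = 1.0 - 2.0 * P - Q
        inner2 = 1.0 - 2.0 * Q
        if inner1 <= 0 or inner2 <= 0:
            raise ValueError("saturated pair under K2P")
        return -0.5 * np.log(inner1 * np.sqrt(inner2))
    raise ValueError(f"unknown distance model {model!r}")


def distance_matrix(alignment: dict[str, str], model: str = "p") -> DistanceMatrix:
    """Pairwise-deletion distance matrix over an aligned sequence dict."""
    names = list(alignment)
    if len(names) < 3:
        raise ValueError("distance matrix requires at least 3 taxa")
    length = len(alignment[names[0]])
    if any(len(alignment[n]) != length for n in names):
        raise ValueError("ragged alignment")
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = _pair_distance(alignment[names[i]], alignment[names[j]], model)
            except ValueError as exc:
                raise ValueError(
                    f"distance undefined for pair ({names[i]}, {names[j]}): {exc}"
                ) from exc
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, names)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; unrooted (trifurcating root) tree.

    Q-matrix ties break on the lowest (i, j) index pair in the current node
    order; negative branch lengths clamp to 0 with a warning.
    """
    mat = np.asarray(dm.data, dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")
    n = mat.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=str(name)) for name in dm.ids]
    d = mat.copy()

    def clamp(length: float) -> float:
        if length < 0:
            warnings.warn("negative NJ branch length clamped to 0", stacklevel=2)
            return 0.0
        return length

    while len(nodes) > 3:
        m = len(nodes)
        totals = d.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - totals[i] - totals[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        raw_li = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2 * (m - 2))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = clamp(raw_li)
        nodes[j].length = clamp(d[i, j] - raw_li)
        new_d = np.zeros((m - 1, m - 1))
        keep = [x for x in range(m) if x not in (i, j)]
        for a, x in enumerate(keep):
            for b, y in enumerate(keep):
                new_d[a, b] = d[x, y]
        for a, x in enumerate(keep):
            nd = 0.5 * (d[i, x] + d[j, x] - d[i, j])
            new_d[a, m - 2] = new_d[m - 2, a] = nd
        nodes = [nodes[x] for x in keep] + [parent]
        d = new_d
    # join the final three nodes at an unrooted trifurcation
    l0 = clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    l1 = clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    l2 = clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = length
    return TreeNode(children=list(nodes))


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Canonical internal splits (smaller side) of an unrooted tree."""
    leaves = frozenset(leaf.name for leaf in tree.tips())
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canonical = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        splits.add(canonical)
    return splits


def bootstrap_support(
    alignment: dict[str, str],
    model: str = "p",
    reps: int = 500,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree with bootstrap support on internal splits.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicate trees containing each full-data split.
    Replicates whose distances are undefined (saturation) count against
    support.  Internal node names of the returned tree carry the support.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    names = list(alignment)
    length = len(alignment[names[0]])
    if length < 2:
        raise ValueError("alignment must have at least 2 columns")
    tree = nj_tree(distance_matrix(alignment, model))
    target_splits = tree_splits(tree)
    counts = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    arrays = {n: np.array(list(alignment[n])) for n in names}
    for _ in range(reps):
        cols = rng.integers(0, length, size=length)
        resampled = {n: "".join(arrays[n][cols]) for n in names}
        try:
            rep_tree = nj_tree(distance_matrix(resampled, model))
        except ValueError:
            continue
        rep_splits = tree_splits(rep_tree)
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1
    supports = {s: 100.0 * c / reps for s, c in counts.items()}
    leaves = frozenset(names)
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        canonical = min(side, leaves - side, key=lambda s: (len(s), tuple(sorted(s))))
        if canonical in supports:
            node.name = f"{supports[canonical]:.1f}"
    return tree, supports


def assign_group(
    queries: dict[str, str],
    panel: dict[str, tuple[str, str]],
    model: str = "p",
    reps: int = 100,
    seed: int = 0,
    support_threshold: float = 70.0,
) -> dict[str, str]:
    """Label queries by supported clustering with reference representatives.

    ``panel`` maps reference name -> (aligned sequence, group label).  A
    query takes the label of the panel members in the smallest supported
    clade (support >= threshold) that contains the query and only
    same-labeled panel members; otherwise ``unassigned``.
    """
    if not panel:
        raise ValueError("reference panel must not be empty")
    if not queries:
        raise ValueError("at least one query required")
    alignment = {name: seq for name, (seq, _) in panel.items()}
    alignment.update(queries)
    tree, supports = bootstrap_support(alignment, model=model, reps=reps, seed=seed)
    labels = {name: label for name, (_, label) in panel.items()}
    leaves = frozenset(alignment)
    out: dict[str, str] = {}
    for query in queries:
        tip = tree.find(query)
        assigned = "unassigned"
        for ancestor in tip.ancestors():
            clade = frozenset(leaf.name for leaf in ancestor.tips())
            if clade == leaves:
                break
            panel_in = {labels[n] for n in clade if n in labels}
            if not panel_in:
                continue
            canonical = min(
                clade, leaves - clade, key=lambda s: (len(s), tuple(sorted(s)))
            )
            support = supports.get(canonical, 0.0)
            if len(panel_in) == 1 and support >= support_threshold:
                assigned = panel_in.pop()
            break
        out[query] = assigned
    return out


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_alignment_fasta(alignment: dict[str, str], path) -> None:
    """Escape hatch: export an alignment for external ML tree tools."""
    with open(path, "w") as handle:
        for name, seq in alignment.items():
            handle.write(f">{name}\n{seq}\n")


def write_alignment_phylip(alignment: dict[str, str], path) -> None:
    """Relaxed PHYLIP export (name, space, sequence)."""
    names = list(alignment)
    with open(path, "w") as handle:
        handle.write(f" {len(names)} {len(alignment[names[0]])}\n")
        for name in names:
            handle.write(f"{name}  {alignment[name]}\n")
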