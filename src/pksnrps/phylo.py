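"""Hybrid genealogy: distance matrix, UPGMA, Newick I/O, clade placement.

The tree over hybrids plus packaged references (characterized hybrids,
predicted-clade anchors, NR-PKS/FAS outgroups) is built by average-linkage
agglomeration (UPGMA) on p-distances, giving a rooted ultrametric tree.
Each unlabelled hybrid is then assigned the major clade of its nearest
reference leaf by path distance; hybrids nearest to an outgroup are
"unplaced".
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skbio.tree import TreeNode

from .align import p_distance
from .errors import ParseError, ValidationError
from .io import ProteinRecord, read_fasta


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.d.shape} does not match "
                f"{n} ids")
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("distance matrix contains non-finite values")
        if np.any(self.d < 0):
            raise ValidationError("distance matrix contains negative values")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")

    def to_tsv(self, path) -> None:
        with Path(path).open("w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, name in enumerate(self.ids):
                row = "\t".join(f"{x:.6f}" for x in self.d[i])
                fh.write(f"{name}\t{row}\n")


def build_distance_matrix(records: Sequence[ProteinRecord],
                          mode: str = "pairwise",
                          alignment_path=None,
                          backend: str = "edlib") -> DistanceMatrix:
    """All-vs-all p-distances.

    ``pairwise`` mode aligns each pair globally with the module's own
    aligner; ``msa`` mode computes column-wise distances on an externally
    produced aligned FASTA (e.g. a MAFFT alignment), whose row ids must
    match the record ids.
    """
    if len(records) < 2:
        raise ValidationError("need at least 2 records for a distance matrix")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate record ids in distance matrix input")
    n = len(ids)
    d = np.zeros((n, n))
    if mode == "pairwise":
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = p_distance(records[i], records[j],
                                               backend=backend)
    elif mode == "msa":
        if alignment_path is None:
            raise ValidationError("msa mode requires alignment_path")
        rows = {r.id: r.sequence for r in read_fasta(alignment_path)}
        missing = [i for i in ids if i not in rows]
        if missing:
            raise ValidationError(f"alignment lacks rows for {missing}")
        lengths = {len(rows[i]) for i in ids}
        if len(lengths) != 1:
            raise ValidationError("msa rows have unequal lengths")
        mat = np.frombuffer("".join(rows[i] for i in ids).encode(),
                            np.uint8).reshape(n, -1)
        gap, x = ord("-"), ord("X")
        ok = (mat != gap) & (mat != x)
        for i in range(n):
            for j in range(i + 1, n):
                valid = ok[i] & ok[j]
                nv = int(valid.sum())
                if nv == 0:
                    raise ValidationError(
                        f"no comparable columns between {ids[i]} and {ids[j]}")
                d[i, j] = d[j, i] = int(
                    (valid & (mat[i] != mat[j])).sum()) / nv
    else:
        raise ValidationError(f"unknown distance mode {mode!r}")
    return DistanceMatrix(ids=ids, d=d)


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Rooted tree with branch lengths, wrapping a scikit-bio TreeNode."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.root.tips()]

    def root_to_tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            acc += node.length or 0.0
            if node.is_tip():
                depths[node.name] = acc
            for child in node.children:
                walk(child, acc)

        walk(self.root, 0.0)
        return depths

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = list(self.root_to_tip_depths().values())
        return max(depths) - min(depths) <= tol

    def tip_distances(self) -> tuple[list[str], np.ndarray]:
        dm = self.root.tip_tip_distances()
        return list(dm.ids), np.asarray(dm.data)

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_tip():
                label = node.name or ""
            else:
                label = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.length is not None:
                label += f":{node.length:.6f}"
            return label

        return fmt(self.root) + ";"


def to_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; unbalanced parentheses raise a positioned
    :class:`ParseError`."""
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise ParseError(
            f"unbalanced parentheses: {depth} '(' left open at end of input")
    try:
        root = TreeNode.read(_io.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise ParseError(f"newick parse failure: {exc}") from exc
    return PhyloTree(root=root)


def write_newick(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(m: DistanceMatrix) -> PhyloTree:
    """Average-linkage (UPGMA) agglomeration.

    Cluster distances are size-weighted arithmetic means; a merge at
    distance d places the new node at height d/2, so the result is
    ultrametric by construction.  Ties are broken deterministically by
    merging the pair whose (smallest-leaf-label, smallest-leaf-label) key
    is lexicographically least.
    """
    if np.any(np.isnan(m.d)):
        raise ValidationError("distance matrix contains NaN")
    n = len(m.ids)
    if n < 2:
        raise ValidationError("UPGMA needs at least 2 leaves")

    d = m.d.astype(float).copy()
    nodes: list[Optional[TreeNode]] = [TreeNode(name=i) for i in m.ids]
    heights = [0.0] * n
    sizes = [1] * n
    keys = list(m.ids)  # smallest leaf label in each cluster
    active = list(range(n))

    while len(active) > 1:
        best: Optional[tuple] = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                dist = d[a, b]
                ka, kb = sorted((keys[a], keys[b]))
                cand = (dist, ka, kb, a, b)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        dist, _, _, a, b = best
        h = dist / 2.0
        na, nb = nodes[a], nodes[b]
        na.length = max(h - heights[a], 0.0)
        nb.length = max(h - heights[b], 0.0)
        parent = TreeNode(children=[na, nb])
        # merged cluster reuses slot a
        new_size = sizes[a] + sizes[b]
        for k in active:
            if k in (a, b):
                continue
            d[a, k] = d[k, a] = (sizes[a] * d[a, k] + sizes[b] * d[b, k]) / new_size
        nodes[a] = parent
        heights[a] = h
        sizes[a] = new_size
        keys[a] = min(keys[a], keys[b])
        active.remove(b)
        nodes[b] = None

    root = nodes[active[0]]
    root.length = None
    return PhyloTree(root=root)


# ---------------------------------------------------------------------------
# Major-clade assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CladePlacement:
    """Placement of one query hybrid relative to the reference leaves."""

    query_id: str
    major_clade: str              # Ia/Ib/II/III or "unplaced"
    nearest_reference: str        # nearest reference leaf overall
    nearest_np_clade: str         # NP clade of nearest non-outgroup reference
    reference_distances: dict = field(default_factory=dict)


def assign_major_clade(tree: PhyloTree,
                       reference_clades: dict[str, str],
                       reference_np_clades: Optional[dict[str, str]] = None,
                       outgroups: Sequence[str] = ()) -> dict[str, CladePlacement]:
    """Label each unlabelled leaf with its nearest reference's major clade.

    `reference_clades` maps reference leaf id -> major clade; `outgroups`
    lists NR-PKS/FAS leaf ids (a query nearest to one is "unplaced").
    Ties break toward the reference with the smallest id.  References and
    outgroups are never queries.
    """
    reference_np_clades = reference_np_clades or {}
    outgroup_set = set(outgroups)
    present = set(tree.leaf_names())
    missing = [c for c in ("Ia", "Ib", "II", "III")
               if not any(reference_clades.get(r) == c and r in present
                          for r in reference_clades)]
    if missing:
        raise ValidationError(
            f"tree lacks reference leaves for major clade(s): {missing}")

    ids, dmat = tree.tip_distances()
    index = {name: i for i, name in enumerate(ids)}
    ref_ids = sorted((set(reference_clades) | outgroup_set) & present)
    np_ref_ids = [r for r in ref_ids if r not in outgroup_set]
    out: dict[str, CladePlacement] = {}
    for name in ids:
        if name in reference_clades or name in outgroup_set:
            continue
        qi = index[name]
        dists = {r: float(dmat[qi, index[r]]) for r in ref_ids}
        nearest = min(ref_ids, key=lambda r: (dists[r], r))
        nearest_np = min(np_ref_ids, key=lambda r: (dists[r], r)) \
            if np_ref_ids else ""
        if nearest in outgroup_set:
            clade = "unplaced"
        else:
            clade = reference_clades[nearest]
        out[name] = CladePlacement(
            query_id=name, major_clade=clade, nearest_reference=nearest,
            nearest_np_clade=reference_np_clades.get(nearest_np, ""),
            reference_distances=dists)
    return out
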