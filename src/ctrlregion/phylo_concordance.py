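"""Distance trees and clade-concordance tests between alignments.

The question answered here: do a short segment, the excised remainder, and
the full control region place the same sequences into the same labelled
clades?  Trees are built with neighbor joining on p or Kimura-2-parameter
distances — a deliberately simple, deterministic estimator whose topological
claims can be checked property-wise; alignments can also be exported as
NEXUS for external Bayesian tools.

Concordance is operationalised as (a) per-group monophyly after outgroup
rooting, (b) Robinson–Foulds distances between trees, and (c) same-clade
assignment agreement: each unlabelled query sequence is assigned the group
of the smallest enclosing clade whose labelled members are all of one group,
and agreement is the fraction of queries identically assigned by two trees.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .diversity import GapPolicy, _matrix, analyzed_columns
from .seqio_coords import Alignment

__all__ = [
    "DistanceMatrix",
    "GroupLabeling",
    "ConcordanceReport",
    "distance_matrix",
    "nj_tree",
    "robinson_foulds",
    "root_on_outgroup",
    "is_monophyletic",
    "assign_queries",
    "concordance",
    "export_nexus",
]

_TRANSITIONS = {frozenset(b"AG"), frozenset(b"CT")}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with saturation bookkeeping.

    Pairs whose K2P logarithm argument is non-positive (saturated) are
    flagged and assigned the maximum finite distance observed in the matrix;
    NaN never survives construction.
    """

    ids: list[str]
    matrix: np.ndarray
    model: str = "p"
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if np.isnan(m).any():
            raise ValueError("NaN distances are forbidden")
        if not np.allclose(m, m.T) or (np.diag(m) != 0).any() or (m < 0).any():
            raise ValueError("matrix must be symmetric, non-negative, zero-diagonal")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


def distance_matrix(
    aln: Alignment,
    model: str = "p",
    policy: GapPolicy = GapPolicy.COMPLETE_DELETION,
) -> DistanceMatrix:
    """Pairwise p-distances or Kimura-2-parameter distances.

    p = differing sites / comparable sites per pair; K2P is the two-
    parameter closed form ``-ln(1-2P-Q)/2 - ln(1-2Q)/4`` from transition
    (P) and transversion (Q) proportions.  Under ``include_gaps`` a gap is a
    counted fifth state and gap-involving differences count as
    transversions.  A pair with zero comparable sites raises an error
    naming the pair.
    """
    if aln.n_records < 3:
        raise ValueError("distance matrix needs at least 3 records")
    if model not in ("p", "k2p"):
        raise ValueError(f"unknown model {model!r}")
    mat = _matrix(aln)
    col_idx = np.array([c - 1 for c in analyzed_columns(aln, policy)], dtype=int)
    missing = [c.encode() for c in policy.missing]
    n = aln.n_records
    out = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(n), 2):
        a, b = mat[i, col_idx], mat[j, col_idx]
        ok = np.ones(len(col_idx), dtype=bool)
        for e in missing:
            ok &= (a != e) & (b != e)
        comp = int(ok.sum())
        if comp == 0:
            raise ValueError(
                f"pair ({aln.ids[i]!r}, {aln.ids[j]!r}) has no comparable sites"
            )
        diff_mask = (a != b) & ok
        if model == "p":
            d = diff_mask.sum() / comp
        else:
            ts = sum(
                1
                for x, y in zip(a[diff_mask].tolist(), b[diff_mask].tolist())
                if frozenset(x + y) in _TRANSITIONS
            )
            tv = int(diff_mask.sum()) - ts
            P, Q = ts / comp, tv / comp
            w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
            if w1 <= 0 or w2 <= 0:
                saturated.append((aln.ids[i], aln.ids[j]))
                d = np.nan
            else:
                d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
        out[i, j] = out[j, i] = d
    if np.isnan(out).any():
        finite_max = np.nanmax(out) if np.isfinite(np.nanmax(out)) else 0.0
        out = np.nan_to_num(out, nan=finite_max)
    return DistanceMatrix(list(aln.ids), out, model, saturated)


# -------------------------------------------------------- neighbor joining

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining with deterministic tie-breaking.

    Ties in the Q-criterion are broken by the lexicographically smallest
    (sorted) pair of subtree labels, a subtree's label being its smallest
    leaf id.  Negative branch lengths are clamped to zero with the deficit
    transferred to the sibling branch (their sum is preserved); negative
    implied distances to the new node are clamped to zero.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # active nodes: label (min leaf id), newick fragment
    labels = list(dm.ids)
    frags = [_quote(t) for t in dm.ids]
    D = [[float(dm.matrix[i, j]) for j in range(n)] for i in range(n)]
    active = list(range(n))

    def join_lengths(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[i][k] for k in active if k != i) for i in active}
        best = None
        best_key = None
        for i, j in itertools.combinations(active, 2):
            q = (r - 2) * D[i][j] - R[i] - R[j]
            key = (q, tuple(sorted((labels[i], labels[j]))))
            if best_key is None or key < best_key:
                best_key = key
                best = (i, j)
        i, j = best
        li = D[i][j] / 2 + (R[i] - R[j]) / (2 * (r - 2))
        lj = D[i][j] - li
        li, lj = join_lengths(li, lj)
        new = len(D)
        row = [0.0] * (new + 1)
        for rowk in D:
            rowk.append(0.0)
        D.append(row)
        for k in active:
            if k in (i, j):
                continue
            d = max((D[i][k] + D[j][k] - D[i][j]) / 2, 0.0)
            D[new][k] = D[k][new] = d
        a, b = sorted((i, j), key=lambda x: labels[x])
        frags.append(f"({frags[a]}:{_fmt(li if a == i else lj)},{frags[b]}:{_fmt(lj if a == i else li)})")
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = sorted(active, key=lambda x: labels[x])
    li = (D[i][j] + D[i][k] - D[j][k]) / 2
    lj = (D[i][j] + D[j][k] - D[i][k]) / 2
    lk = (D[i][k] + D[j][k] - D[i][j]) / 2
    newick = (
        f"({frags[i]}:{_fmt(max(li, 0.0))},{frags[j]}:{_fmt(max(lj, 0.0))},"
        f"{frags[k]}:{_fmt(max(lk, 0.0))});"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def _fmt(x: float) -> str:
    return f"{x:.10f}"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------- tree utilities

def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def _clone_restricted(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.retain_taxa_with_labels(sorted(keep))
    return t


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted Robinson–Foulds distance on the common leaf set."""
    common = _leaf_labels(t1) & _leaf_labels(t2)
    if len(common) < 3:
        raise ValueError("trees share fewer than 3 leaves")
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=_clone_restricted(t1, common).as_string(schema="newick"),
                          schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=_clone_restricted(t2, common).as_string(schema="newick"),
                          schema="newick", taxon_namespace=tns)
    a.is_rooted = b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def root_on_outgroup(tree: dendropy.Tree, outgroup: list[str]) -> dendropy.Tree:
    """Root a copy of ``tree`` on the edge leading to the outgroup clade."""
    present = [o for o in outgroup if o in _leaf_labels(tree)]
    if not present:
        raise ValueError("no outgroup taxa present in tree")
    t = dendropy.Tree.get(data=tree.as_string(schema="newick"), schema="newick")
    t.is_rooted = True
    # reroot at one outgroup leaf first so the outgroup MRCA is well-defined
    leaf = next(lf for lf in t.leaf_node_iter() if lf.taxon.label == present[0])
    t.reroot_at_edge(leaf.edge, update_bipartitions=False)
    if len(present) > 1:
        mrca = t.mrca(taxon_labels=present)
        if mrca is not t.seed_node and mrca.parent_node is not None:
            t.reroot_at_edge(mrca.edge, update_bipartitions=False)
    return t


def is_monophyletic(tree: dendropy.Tree, labels: list[str]) -> bool:
    """Do the given leaves form an exclusive clade on this (rooted) tree?"""
    want = set(labels) & _leaf_labels(tree)
    if not want:
        raise ValueError("none of the labels are in the tree")
    if len(want) == 1:
        return True
    mrca = tree.mrca(taxon_labels=sorted(want))
    got = {lf.taxon.label for lf in mrca.leaf_iter()}
    return got == want


@dataclass
class GroupLabeling:
    """id -> subpopulation/clade label, with outgroup ids flagged."""

    groups: dict[str, str]
    outgroup: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.groups.values())) < 1:
            raise ValueError("at least one group required")

    @property
    def group_names(self) -> list[str]:
        return sorted(set(self.groups.values()))

    def members(self, group: str) -> list[str]:
        return sorted(i for i, g in self.groups.items() if g == group)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupLabeling":
        """Two-column TSV: id<TAB>group; the group 'outgroup' flags outgroups."""
        groups: dict[str, str] = {}
        outgroup: set[str] = set()
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            ident, grp = line.split("\t")[:2]
            if grp.lower() == "outgroup":
                outgroup.add(ident)
            else:
                groups[ident] = grp
        return cls(groups, outgroup)


def assign_queries(
    tree: dendropy.Tree, labels: GroupLabeling, queries: list[str]
) -> dict[str, str]:
    """Assign each query leaf the group of its smallest single-group clade.

    Walking rootward from the query leaf, the first ancestor containing any
    labelled leaves decides: one group -> that group; mixed -> "unassigned"
    (ambiguous placement is never silently attributed).
    """
    leaf_of = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    out: dict[str, str] = {}
    for q in queries:
        node = leaf_of[q].parent_node
        call = "unassigned"
        while node is not None:
            seen = {
                labels.groups[lf.taxon.label]
                for lf in node.leaf_iter()
                if lf.taxon.label in labels.groups
            }
            if seen:
                call = seen.pop() if len(seen) == 1 else "unassigned"
                break
            node = node.parent_node
        out[q] = call
    return out


@dataclass
class ConcordanceReport:
    tree_names: list[str]
    monophyly: dict[str, list[bool]]          # group -> per-tree yes/no
    rf: dict[tuple[int, int], int]            # unordered tree-index pairs
    assignments: list[dict[str, str]]         # per-tree query -> group
    agreement: dict[tuple[int, int], float]   # fraction identically placed


def concordance(
    trees: list[dendropy.Tree],
    labels: GroupLabeling,
    tree_names: list[str] | None = None,
) -> ConcordanceReport:
    """Monophyly, Robinson–Foulds and same-clade agreement across trees.

    Trees are restricted to their common leaf set and rooted on the flagged
    outgroup.  Queries are the common leaves that are neither labelled nor
    outgroup; agreement between two trees is the fraction of queries
    assigned to the same group by both (an ``unassigned`` call never counts
    as agreement).
    """
    if len(trees) < 2:
        raise ValueError("need at least two trees to compare")
    if len(set(labels.groups.values())) < 2:
        raise ValueError("concordance needs at least 2 groups")
    common = set.intersection(*[_leaf_labels(t) for t in trees])
    if len(common) < 4:
        raise ValueError("trees share fewer than 4 leaves")
    names = tree_names or [f"tree{i}" for i in range(len(trees))]

    rooted = []
    for t in trees:
        r = _clone_restricted(t, common)
        rooted.append(root_on_outgroup(r, sorted(labels.outgroup & common)))

    monophyly: dict[str, list[bool]] = {}
    for g in labels.group_names:
        members = [m for m in labels.members(g) if m in common]
        if not members:
            continue
        monophyly[g] = [is_monophyletic(t, members) for t in rooted]

    queries = sorted(common - set(labels.groups) - labels.outgroup)
    assignments = [assign_queries(t, labels, queries) for t in rooted]

    rf: dict[tuple[int, int], int] = {}
    agreement: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(len(trees)), 2):
        rf[(i, j)] = robinson_foulds(trees[i], trees[j])
        if queries:
            same = sum(
                1
                for q in queries
                if assignments[i][q] == assignments[j][q]
                and assignments[i][q] != "unassigned"
            )
            agreement[(i, j)] = same / len(queries)
        else:
            agreement[(i, j)] = float("nan")
    return ConcordanceReport(names, monophyly, rf, assignments, agreement)


# ------------------------------------------------------------ NEXUS export

def export_nexus(aln: Alignment, path: str | Path) -> None:
    """Write a sequential NEXUS DATA block (datatype=DNA, gap=-, missing=N).

    The format round-trips through standard phylogenetics readers, so the
    alignment can be fed to external Bayesian tree software unchanged.
    """
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={aln.n_records} NCHAR={aln.n_cols};\n")
        fh.write("    FORMAT DATATYPE=DNA GAP=- MISSING=N;\n")
        fh.write("    MATRIX\n")
        width = max(len(r.id) for r in aln.records) + 2
        for r in aln.records:
            name = _quote(r.id)
            fh.write(f"    {name:<{width}}{r.sequence}\n")
        fh.write("    ;\nEND;\n")
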