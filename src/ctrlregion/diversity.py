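"""Scalar diversity indices for control-region alignments.

Implements the classic per-alignment summary used to compare progressively
longer control-region segments: number of haplotypes *h*, number of
polymorphic (segregating) sites *S*, total number of mutations (eta, the
minimum-mutation count: distinct states minus one, summed over sites), and
the mean number of pairwise nucleotide differences *k* (with per-site
diversity pi = k / sites analysed).

Gap handling is explicit and pluggable because published analyses are often
ambiguous about it:

``complete_deletion``
    every column containing a gap or N in any record is removed before all
    computations (the default: segment tables whose "No. of sites" falls
    short of the alignment length imply exactly this);
``pairwise_deletion``
    each sequence pair is compared over its own gap/N-free columns;
``include_gaps``
    '-' is a counted fifth state, N remains missing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .seqio_coords import Alignment, collapse_haplotypes

__all__ = [
    "GapPolicy",
    "DiversitySummary",
    "analyzed_columns",
    "haplotype_mask",
    "segregating_sites",
    "mean_pairwise_differences",
    "diversity_summary",
]


class GapPolicy(str, Enum):
    COMPLETE_DELETION = "complete_deletion"
    PAIRWISE_DELETION = "pairwise_deletion"
    INCLUDE_GAPS = "include_gaps"

    @property
    def missing(self) -> frozenset[str]:
        """Characters treated as missing (never counted as a state)."""
        if self is GapPolicy.INCLUDE_GAPS:
            return frozenset("N")
        return frozenset("-N")


def _matrix(aln: Alignment) -> np.ndarray:
    """(n_records, n_cols) byte matrix of the alignment."""
    return np.frombuffer(
        "".join(r.sequence for r in aln.records).encode(), dtype="S1"
    ).reshape(aln.n_records, aln.n_cols)


def analyzed_columns(aln: Alignment, policy: GapPolicy) -> list[int]:
    """1-based columns entering the analysis under ``policy``.

    Complete deletion drops every column with any missing character; the
    other policies analyse all columns (missing data handled per site/pair).
    """
    if policy is not GapPolicy.COMPLETE_DELETION:
        return list(range(1, aln.n_cols + 1))
    mat = _matrix(aln)
    bad = np.zeros(aln.n_cols, dtype=bool)
    for ch in policy.missing:
        bad |= (mat == ch.encode()).any(axis=0)
    return [int(c) + 1 for c in np.nonzero(~bad)[0]]


def _require_pairs(aln: Alignment) -> None:
    if aln.n_records < 2:
        raise ValueError("diversity statistics need at least 2 records")


def segregating_sites(
    aln: Alignment, policy: GapPolicy = GapPolicy.COMPLETE_DELETION
) -> tuple[int, int, list[int]]:
    """(S, eta, polymorphic column list) under the given gap policy.

    A column is polymorphic iff at least two distinct counted states occur;
    its contribution to eta is (distinct counted states - 1), the minimum
    number of mutations explaining the column.  Columns are 1-based
    positions on the input alignment.
    """
    _require_pairs(aln)
    missing = {c.encode() for c in policy.missing}
    mat = _matrix(aln)
    cols = analyzed_columns(aln, policy)
    S = 0
    eta = 0
    sites: list[int] = []
    for c in cols:
        states = {b for b in mat[:, c - 1].tolist() if b not in missing}
        if len(states) >= 2:
            S += 1
            eta += len(states) - 1
            sites.append(c)
    return S, eta, sites


def _pair_differences(
    mat: np.ndarray, i: int, j: int, policy: GapPolicy, col_idx: np.ndarray
) -> tuple[int, int]:
    """(differences, comparable sites) for records i, j over col_idx."""
    a = mat[i, col_idx]
    b = mat[j, col_idx]
    ok = np.ones(len(col_idx), dtype=bool)
    for ch in policy.missing:
        e = ch.encode()
        ok &= (a != e) & (b != e)
    return int(((a != b) & ok).sum()), int(ok.sum())


def mean_pairwise_differences(
    aln: Alignment, policy: GapPolicy = GapPolicy.COMPLETE_DELETION
) -> float:
    """Mean count of differing sites over all unordered sequence pairs (*k*).

    Under pairwise deletion each pair is compared over its own comparable
    sites; under complete deletion all pairs share one column set.
    """
    _require_pairs(aln)
    mat = _matrix(aln)
    col_idx = np.array([c - 1 for c in analyzed_columns(aln, policy)], dtype=int)
    n = aln.n_records
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        d, _ = _pair_differences(mat, i, j, policy, col_idx)
        total += d
    return total / (n * (n - 1) / 2)


@dataclass(frozen=True)
class DiversitySummary:
    """One summary row: sample size, sites analysed, h, S, eta, k, pi."""

    n_records: int
    n_sites_analyzed: int
    h: int
    S: int
    eta: int
    k: float

    @property
    def pi(self) -> float:
        return self.k / self.n_sites_analyzed if self.n_sites_analyzed else 0.0

    def __post_init__(self) -> None:
        if self.S > self.eta:
            raise ValueError("eta must be >= S")
        if self.h > self.n_records:
            raise ValueError("h cannot exceed number of records")


def haplotype_mask(aln: Alignment, policy: GapPolicy) -> list[int]:
    """Columns over which haplotype identity is defined (1-based).

    Haplotype identity must be an equivalence relation, so per-pair site
    sets (pairwise deletion) cannot apply; instead identity always uses a
    shared column set from which missing data can never create or hide a
    difference: the gap/N-free columns under complete or pairwise deletion,
    and the N-free columns (gaps compare as a fifth state) when gaps are
    included.
    """
    if policy is GapPolicy.INCLUDE_GAPS:
        mat = _matrix(aln)
        ok = ~(mat == b"N").any(axis=0)
        return [int(c) + 1 for c in np.nonzero(ok)[0]]
    return analyzed_columns(aln, GapPolicy.COMPLETE_DELETION)


def diversity_summary(
    aln: Alignment, policy: GapPolicy = GapPolicy.COMPLETE_DELETION
) -> DiversitySummary:
    """Compute h, S, eta, k and pi on one shared analysed-column set.

    The haplotype count is taken over the shared analysed columns (see
    :func:`haplotype_mask`) so that a single summary is internally
    consistent.  An alignment whose every column is excluded by the policy
    degenerates to h = 1, S = eta = 0, k = 0 over zero analysed sites.
    """
    _require_pairs(aln)
    cols = analyzed_columns(aln, policy)
    n_sites = len(cols)
    hmask = haplotype_mask(aln, policy)
    if policy is GapPolicy.COMPLETE_DELETION and not cols:
        return DiversitySummary(aln.n_records, 0, 1, 0, 0, 0.0)
    S, eta, _ = segregating_sites(aln, policy)
    k = mean_pairwise_differences(aln, policy)
    h = collapse_haplotypes(aln, site_mask=hmask).h if hmask else 1
    return DiversitySummary(
        n_records=aln.n_records,
        n_sites_analyzed=n_sites,
        h=h,
        S=S,
        eta=eta,
        k=k,
    )


def segment_diversity_table(
    full_aln: Alignment,
    specs,
    policy: GapPolicy = GapPolicy.COMPLETE_DELETION,
):
    """One summary row per named segment, in the classic table layout.

    ``specs`` is an iterable of SegmentSpec (alignment frame).  Columns:
    segment, n_sites, extent_percent, positions, h, S, eta, k (k to three
    decimals, as conventionally printed).  Returns a pandas DataFrame.
    """
    import pandas as pd

    from .segments import coverage_percent, trim

    rows = []
    for spec in specs:
        sub = trim(full_aln, spec)
        s = diversity_summary(sub, policy)
        rows.append(
            {
                "segment": spec.name,
                "n_sites": s.n_sites_analyzed,
                "extent_percent": int(coverage_percent(spec, full_aln)),
                "positions": spec.positions_str(),
                "h": s.h,
                "S": s.S,
                "eta": s.eta,
                "k": round(s.k, 3),
            }
        )
    return pd.DataFrame(rows)
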