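"""Sliding-window diversity profiles and hypervariable-region delimitation.

Hypervariable regions of the mitochondrial control region have no fixed
definition; they are delimited per data set by scanning nucleotide diversity
in overlapping windows and contrasting each window against the conservation
expected if the alignment's segregating sites were scattered uniformly.

The profile (window midpoint vs per-site diversity) is the familiar
sliding-window plot; delimitation classifies each window by its observed
segregating-site count against ``multiplier x S * window_length / L`` and
merges same-class windows into labelled intervals.  The leftmost
hypervariable interval is conventionally the HVRI.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .diversity import GapPolicy, analyzed_columns, _matrix
from .seqio_coords import Alignment, CoordinateMap

__all__ = [
    "WindowPoint",
    "WindowProfile",
    "Region",
    "RegionSet",
    "window_profile",
    "conservation_threshold",
    "expected_sites_per_window",
    "delimit_regions",
    "profile_table",
    "plot_profile",
]


@dataclass(frozen=True)
class WindowPoint:
    start: int          # first column of the window (1-based)
    midpoint: float     # (start + end) / 2
    n_analyzed: int     # analysed columns inside the window
    s_window: int       # segregating sites inside the window
    pi_window: float    # mean pairwise differences / analysed columns
    empty: bool = False # no analysed columns (pi reported as 0)


@dataclass
class WindowProfile:
    window_length: int
    step: int
    n_cols: int
    points: list[WindowPoint]

    @property
    def n_windows(self) -> int:
        return len(self.points)

    def window_end(self, point: WindowPoint) -> int:
        return point.start + self.window_length - 1


@dataclass(frozen=True)
class Region:
    start: int
    end: int
    label: str  # "conserved" | "hypervariable"


@dataclass
class RegionSet:
    """Non-overlapping labelled intervals on alignment columns (1-based)."""

    intervals: list[Region]
    threshold_used: float

    @property
    def hypervariable(self) -> list[Region]:
        return [r for r in self.intervals if r.label == "hypervariable"]

    @property
    def conserved(self) -> list[Region]:
        return [r for r in self.intervals if r.label == "conserved"]

    @property
    def hvr1(self) -> Region | None:
        """The leftmost hypervariable interval (the HVRI), if any."""
        hv = self.hypervariable
        return hv[0] if hv else None

    def to_reference(self, cmap: CoordinateMap) -> list[tuple[int, int, str]]:
        """Intervals in reference coordinates (snapping gap ends inward)."""
        out = []
        for r in self.intervals:
            s, e = r.start, r.end
            while s <= e and s not in cmap.col_to_ref:
                s += 1
            while e >= s and e not in cmap.col_to_ref:
                e -= 1
            if s <= e:
                out.append((cmap.to_reference(s), cmap.to_reference(e), r.label))
        return out


def _window_starts(n_cols: int, window_length: int, step: int) -> list[int]:
    if window_length > n_cols:
        raise ValueError(f"window_length {window_length} exceeds alignment width {n_cols}")
    if step < 1:
        raise ValueError("step must be >= 1")
    # anchored at column 1, no partial trailing window
    return list(range(1, n_cols - window_length + 2, step))


def window_profile(
    aln: Alignment,
    window_length: int = 100,
    step: int = 25,
    policy: GapPolicy = GapPolicy.COMPLETE_DELETION,
) -> WindowProfile:
    """Per-window segregating sites and per-site diversity.

    ``pi_window`` is the mean count of pairwise differences over the window's
    analysed columns divided by the number of analysed columns, i.e. the
    nucleotide diversity of the window; a window whose columns are all
    excluded by the gap policy carries pi = 0 with ``empty=True``.
    """
    cols = set(analyzed_columns(aln, policy))
    mat = _matrix(aln)
    missing = {c.encode() for c in policy.missing}
    n = aln.n_records
    n_pairs = n * (n - 1) / 2
    points = []
    for start in _window_starts(aln.n_cols, window_length, step):
        end = start + window_length - 1
        wcols = [c for c in range(start, end + 1) if c in cols]
        mid = (start + end) / 2
        if not wcols:
            points.append(WindowPoint(start, mid, 0, 0, 0.0, empty=True))
            continue
        s_win = 0
        diff_total = 0
        idx = np.array([c - 1 for c in wcols])
        sub = mat[:, idx]
        for j in range(sub.shape[1]):
            col = sub[:, j].tolist()
            counts: dict[bytes, int] = {}
            for b in col:
                if b not in missing:
                    counts[b] = counts.get(b, 0) + 1
            if len(counts) >= 2:
                s_win += 1
            # per-column unordered mismatch count among counted states
            tot = sum(counts.values())
            same = sum(v * (v - 1) / 2 for v in counts.values())
            diff_total += tot * (tot - 1) / 2 - same
        pi = (diff_total / n_pairs) / len(wcols)
        points.append(WindowPoint(start, mid, len(wcols), s_win, pi))
    return WindowProfile(window_length, step, aln.n_cols, points)


def expected_sites_per_window(S: int, n_sites_analyzed: int, window_length: int) -> float:
    """Expected segregating sites per window under uniform scatter."""
    if n_sites_analyzed <= 0:
        return 0.0
    return S * window_length / n_sites_analyzed


def conservation_threshold(
    aln: Alignment,
    window_length: int = 100,
    policy: GapPolicy = GapPolicy.COMPLETE_DELETION,
) -> float:
    """S-derived conservation threshold for window classification.

    Equals the per-window segregating-site count expected if the alignment's
    S sites were uniformly scattered over its analysed columns; windows
    exceeding a multiple of it are called hypervariable.
    """
    from .diversity import segregating_sites

    S, _, _ = segregating_sites(aln, policy)
    return expected_sites_per_window(S, len(analyzed_columns(aln, policy)), window_length)


def delimit_regions(
    profile: WindowProfile,
    aln: Alignment,
    threshold_multiplier: float = 1.0,
    policy: GapPolicy = GapPolicy.COMPLETE_DELETION,
) -> RegionSet:
    """Classify windows against the conservation threshold and merge.

    The reference level is ``threshold_multiplier`` times the uniform-
    scatter expectation of segregating sites per window.  A column is
    labelled hypervariable when the mean observed segregating-site count of
    the windows covering it strictly exceeds that level — every covering
    window contributes its full-extent count (never its midpoint, which
    would shrink regions by half a window per side) — and maximal same-label
    runs become the intervals.  Averaging overlapping windows localises a
    boundary to about one step rather than a full window length.
    """
    if not profile.points:
        raise ValueError("empty window profile")
    thresh = threshold_multiplier * conservation_threshold(
        aln, profile.window_length, policy
    )
    starts = [p.start for p in profile.points]
    svals = [p.s_window for p in profile.points]
    covered_end = profile.window_end(profile.points[-1])

    wl = profile.window_length
    merged: list[list[int]] = []
    col_label: list[bool] = []
    for c in range(1, covered_end + 1):
        vals = [s for st, s in zip(starts, svals) if st <= c <= st + wl - 1]
        col_label.append(sum(vals) / len(vals) > thresh)
    for c, is_hv in enumerate(col_label, start=1):
        if is_hv:
            if merged and merged[-1][1] == c - 1:
                merged[-1][1] = c
            else:
                merged.append([c, c])

    intervals: list[Region] = []
    cursor = 1
    for s, e in merged:
        if s > cursor:
            intervals.append(Region(cursor, s - 1, "conserved"))
        intervals.append(Region(s, e, "hypervariable"))
        cursor = e + 1
    if cursor <= covered_end:
        intervals.append(Region(cursor, covered_end, "conserved"))
    return RegionSet(intervals, thresh)


def profile_table(profile: WindowProfile):
    """Profile as a DataFrame (start, midpoint, n_analyzed_sites, S_window, pi_window)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "start": [p.start for p in profile.points],
            "midpoint": [p.midpoint for p in profile.points],
            "n_analyzed_sites": [p.n_analyzed for p in profile.points],
            "S_window": [p.s_window for p in profile.points],
            "pi_window": [p.pi_window for p in profile.points],
        }
    )


def regions_table(regions: RegionSet):
    """RegionSet as a BED-like DataFrame (1-based inclusive coordinates)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "start": [r.start for r in regions.intervals],
            "end": [r.end for r in regions.intervals],
            "label": [r.label for r in regions.intervals],
        }
    )


def plot_profile(profile: WindowProfile, path: str, regions: RegionSet | None = None):
    """Midpoint-vs-pi polyline; optional shading of hypervariable intervals."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(
        [p.midpoint for p in profile.points],
        [p.pi_window for p in profile.points],
        "-o", ms=3, lw=1,
    )
    if regions is not None:
        for r in regions.hypervariable:
            ax.axvspan(r.start, r.end, alpha=0.15, color="tab:red")
    ax.set_xlabel("alignment position (window midpoint)")
    ax.set_ylabel("nucleotide diversity (pi)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
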