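"""Named control-region segments: trimming, excision and coverage.

Prior phylogenetic studies of orang-utans sequenced only short left-domain
segments of the mitochondrial control region.  This module carries a registry
of those published segment coordinates (on the alignment frame used for
reproduction, with reference-genome equivalents), and the two constructions
the comparison needs: trimming an alignment to a segment, and excising a
segment and concatenating the remainder (the "oft-ignored bases").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .seqio_coords import Alignment, CoordinateMap, SeqRecord

__all__ = [
    "SegmentRangeError",
    "SegmentSpec",
    "REGISTRY",
    "get_segment",
    "segment_names",
    "trim",
    "excise_and_concatenate",
    "coverage_percent",
    "cr_fraction_percent",
    "round_half_up",
]


class SegmentRangeError(ValueError):
    """A segment range falls outside the alignment it is applied to."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed tables conventionally do."""
    import math

    scale = 10**ndigits
    r = math.floor(abs(x) * scale + 0.5) / scale
    r = r if x >= 0 else -r
    return int(r) if ndigits == 0 else r


@dataclass(frozen=True)
class SegmentSpec:
    """A named set of 1-based inclusive column ranges on a stated frame.

    ``frame`` is ``"alignment"`` (columns of the working alignment) or
    ``"reference"`` (positions on a reference genome, convertible through a
    :class:`~ctrlregion.seqio_coords.CoordinateMap`).  ``estimated`` flags
    coordinates inferred from stated lengths rather than published sequence.
    """

    name: str
    ranges: tuple[tuple[int, int], ...]
    frame: str = "alignment"
    citation: str = ""
    nominal_bp: str = ""
    estimated: bool = False

    def __post_init__(self) -> None:
        if self.frame not in ("alignment", "reference"):
            raise ValueError(f"unknown frame {self.frame!r}")
        prev_end = 0
        for s, e in self.ranges:
            if s < 1 or e < s:
                raise ValueError(f"{self.name}: bad range {s}-{e}")
            if s <= prev_end:
                raise ValueError(f"{self.name}: ranges must be sorted, non-overlapping")
            prev_end = e
        if not self.ranges:
            object.__setattr__(self, "ranges", ())

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.ranges)

    def columns(self) -> list[int]:
        out: list[int] = []
        for s, e in self.ranges:
            out.extend(range(s, e + 1))
        return out

    def positions_str(self) -> str:
        return "; ".join(f"{s:03d}–{e:03d}" for s, e in self.ranges)

    def to_reference_frame(self, cmap: CoordinateMap) -> "SegmentSpec":
        """Convert alignment-frame ranges to reference positions (gap-free ends)."""
        if self.frame != "alignment":
            raise ValueError("spec is not on the alignment frame")
        ranges = tuple(
            (cmap.to_reference(s), cmap.to_reference(e)) for s, e in self.ranges
        )
        return SegmentSpec(self.name, ranges, "reference", self.citation,
                           self.nominal_bp, self.estimated)

    def to_alignment_frame(self, cmap: CoordinateMap) -> "SegmentSpec":
        if self.frame != "reference":
            raise ValueError("spec is not on the reference frame")
        ranges = tuple((cmap.to_column(s), cmap.to_column(e)) for s, e in self.ranges)
        return SegmentSpec(self.name, ranges, "alignment", self.citation,
                           self.nominal_bp, self.estimated)


def _spec(name, ranges, ref_ranges, citation, nominal_bp, estimated=False):
    return {
        "alignment": SegmentSpec(name, ranges, "alignment", citation, nominal_bp, estimated),
        "reference": SegmentSpec(name, ref_ranges, "reference", citation, nominal_bp, estimated),
    }


#: Published left-domain segments.  Alignment-frame ranges are on the
#: 38-sequence complete-control-region alignment used for reproduction;
#: reference-frame ranges are positions on the complete Sumatran mtDNA
#: genome (GenBank X97707), whose control region spans 15484-16499.
REGISTRY: dict[str, dict[str, SegmentSpec]] = {
    "warren2001": _spec(
        "warren2001", ((104, 381),), ((15605, 15844),),
        "Warren et al. (2001)", "~245 bp"),
    "jalil_arora": _spec(
        "jalil_arora", ((33, 355),), ((15516, 15836),),
        "Jalil et al. (2008); Arora et al. (2010)", "<=323 bp"),
    "nater2013": _spec(
        "nater2013", ((1, 386),), ((15484, 15866),),
        "Nater et al. (2013)", "<=385 bp"),
    "morrogh_bernard2010": _spec(
        "morrogh_bernard2010", ((1, 409),), ((15484, 15893),),
        "Morrogh-Bernard et al. (2010)", "<=410 bp", estimated=True),
    "rianti2015": _spec(
        "rianti2015", ((1, 422),), ((15484, 15905),),
        "Rianti et al. (2015)", "<=422 bp", estimated=True),
}

#: Reference span of the complete control region on X97707.
CONTROL_REGION_REFERENCE_SPAN = (15484, 16499)


def segment_names() -> list[str]:
    return list(REGISTRY)


def get_segment(name: str, frame: str = "alignment") -> SegmentSpec:
    try:
        return REGISTRY[name][frame]
    except KeyError:
        raise KeyError(f"unknown segment {name!r} (frame {frame!r}); "
                       f"known: {', '.join(REGISTRY)}") from None


def registry_to_json(path: str | Path) -> None:
    """Serialise the registry as editable JSON."""
    out = []
    for name, frames in REGISTRY.items():
        for frame, spec in frames.items():
            out.append({
                "name": name,
                "frame": frame,
                "ranges": [list(r) for r in spec.ranges],
                "citation": spec.citation,
                "nominal_bp": spec.nominal_bp,
                "estimated": spec.estimated,
            })
    Path(path).write_text(json.dumps(out, indent=2) + "\n")


def spec_from_json(obj: dict) -> SegmentSpec:
    return SegmentSpec(
        obj["name"],
        tuple(tuple(r) for r in obj["ranges"]),
        obj.get("frame", "alignment"),
        obj.get("citation", ""),
        obj.get("nominal_bp", ""),
        obj.get("estimated", False),
    )


def _check_bounds(aln: Alignment, spec: SegmentSpec) -> None:
    if spec.frame != "alignment":
        raise SegmentRangeError(
            f"segment {spec.name!r} is on the {spec.frame!r} frame; convert "
            "with to_alignment_frame() first"
        )
    for s, e in spec.ranges:
        if e > aln.n_cols:
            raise SegmentRangeError(
                f"segment {spec.name!r} range {s}-{e} exceeds alignment "
                f"width {aln.n_cols}"
            )


def trim(aln: Alignment, spec: SegmentSpec) -> Alignment:
    """Column-concatenation of the spec's ranges, record order preserved."""
    _check_bounds(aln, spec)
    return aln.take_columns(spec.columns())


def excise_and_concatenate(aln: Alignment, spec: SegmentSpec) -> Alignment:
    """Remove the segment's columns and concatenate what remains."""
    _check_bounds(aln, spec)
    inside = set(spec.columns())
    rest = [c for c in range(1, aln.n_cols + 1) if c not in inside]
    if not rest:
        raise SegmentRangeError(
            f"segment {spec.name!r} covers the whole alignment; remainder is empty"
        )
    return aln.take_columns(rest)


def complement_spec(aln: Alignment, spec: SegmentSpec, name: str | None = None) -> SegmentSpec:
    """The remainder of the alignment as a spec (for reporting positions)."""
    _check_bounds(aln, spec)
    inside = set(spec.columns())
    ranges = []
    start = None
    for c in range(1, aln.n_cols + 2):
        if c <= aln.n_cols and c not in inside:
            if start is None:
                start = c
        else:
            if start is not None:
                ranges.append((start, c - 1))
                start = None
    return SegmentSpec(name or f"{spec.name}_remainder", tuple(ranges))


def coverage_percent(spec: SegmentSpec, aln: Alignment, rounded: bool = True) -> float:
    """Segment length as a percentage of the alignment width.

    Reports round to integer percent (ties up), matching how extent-of-region
    columns are printed in segment tables.
    """
    _check_bounds(aln, spec)
    pct = 100.0 * spec.length / aln.n_cols
    return float(round_half_up(pct)) if rounded else pct


def cr_fraction_percent(cr_length: int = 1122, genome_length: int = 16569) -> float:
    """Control-region share of a mitochondrial genome, in percent (2 d.p.).

    Defaults are the human values (1122 bp of 16569 bp = 6.77%).
    """
    if not 0 < cr_length <= genome_length:
        raise ValueError("need 0 < cr_length <= genome_length")
    return round_half_up(100.0 * cr_length / genome_length, 2)
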