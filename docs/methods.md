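# Methods

This note records the statistical conventions, the model behind the
synthetic data, and the design choices made where more than one defensible
option existed.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and alphabet

All coordinates are 1-based with inclusive ranges, matching the
"positions 001–386" style of segment tables; any half-open arithmetic is
internal.  Sequences are canonicalised to {A, C, G, T, -, N}: lower case
and U are normalised, IUPAC ambiguity codes collapse to N, and N is missing
data throughout — it never creates or hides a difference in any statistic.
Coordinate maps tie alignment columns to ungapped positions of a chosen
reference row, with a configurable start offset (15484 for a control region
referenced against the X97707 complete genome).

## Diversity indices and gap handling

For an alignment of *n* sequences over a set of analysed columns:

* *S* — columns with ≥ 2 counted states;
* η — Σ over columns of (counted states − 1), the minimum number of
  mutations explaining each column, so η ≥ S with equality when every
  polymorphic site is biallelic;
* *k* — mean over all C(*n*, 2) pairs of the per-pair count of differing
  comparable sites;
* π = *k* / analysed sites;
* *h* — distinct strings over the identity columns.

Three gap policies are exposed because published analyses are often
ambiguous about gap treatment.  `complete_deletion` (default) removes every
column carrying a gap or N anywhere before all computations; it is the
default because segment tables whose "No. of sites" falls below the raw
column span imply exactly this. `pairwise_deletion` compares each pair over
its own gap/N-free sites. `include_gaps` counts '-' as a fifth state (an
indel difference then contributes to S, η and k) while N stays missing.

Haplotype identity must be an equivalence relation, so per-pair site sets
cannot define it; *h* always uses a shared column set: the gap/N-free
columns under complete or pairwise deletion, and the N-free columns (gaps
comparing as a fifth state) under `include_gaps`.  Gaps separating
haplotypes is deliberate — control-region species diagnostics include
indels — and can be disabled, in which case every gap-touched column is
dropped from the comparison.  An alignment whose every column is excluded
degenerates to one haplotype over zero analysed sites.

k is kept at full precision internally and printed to 3 decimals in
reports; extent percentages round half-up to integers as printed tables do.

## Sliding-window scan and region delimitation

Windows are anchored at column 1 with no partial trailing window (window
100, step 25 by default, the conventional profile parameters).  Per window
we report the analysed-column count, the observed segregating-site count
S_w, and π_w = mean pairwise differences within the window divided by its
analysed columns; a window with no analysed columns carries π = 0 and an
`empty` flag.

Delimitation compares S_w with the conservation threshold
`multiplier × S · window/L` — the per-window count expected if the
alignment's S segregating sites were scattered uniformly over its L
analysed columns.  The threshold is tied to counts, not π, and the
multiplier (default 1.0) is exposed.  A column is labelled hypervariable
when the *mean* S_w of the windows covering it strictly exceeds the
threshold; maximal same-label runs become the reported intervals, and the
leftmost hypervariable interval is the HVRI.  Every covering window
contributes its full extent (never its midpoint, which would shrink regions
by half a window per side).  Averaging rather than voting was chosen
because overlapping windows then localise a boundary to about one step
(±25 columns at the defaults) instead of a full window length; this is the
package's own boundary convention, verified by the planted-block recovery
test.  Windows with the multiplier lowered below 1 surface secondary
stretches that are elevated but below the HVRI-level threshold.

Both alignment-column and reference-position intervals are emitted, since
"the first 376 sites" of an alignment and the corresponding ungapped
reference extent legitimately differ.

## Segment registry

The registry stores the published orang-utan left-domain segments on the
alignment frame used for reproduction (104–381, 033–355, 001–386, 001–409,
001–422) together with reference-genome equivalents (15605–15844,
15516–15836, 15484–15866, 15484–15893, 15484–15905 on X97707) and each
study's nominal length.  Alignment-frame coordinates are authoritative for
reproduction; reference-frame specs are converted through a coordinate map
for users aligning to X97707.  Coordinates estimated from stated lengths
(sequences never deposited) are flagged `estimated`.  Note that a printed
"number of sites" can differ from the raw column span: positions 104–381
cover 278 alignment columns of which gap-free analysed sites remain after
complete deletion.

## Species classification and in-silico PCR

The diagnostic 15 bp deletion near the right end of the Bornean control
region is detected by its flanking 12-mers located on a deletion-free
reference: flanks directly adjacent in the query mean the segment is
deleted (bornean-like); the intervening segment present (±3 bp, allowing
point mutations) means sumatran-like.  Degapped length is the fallback,
split at 1005 bp — the midpoint of the printed species ranges (999–1000 vs
1011–1016 bp).  Locus evidence is primary; when locus and length disagree
the call is `indeterminate` with a warning, never a silent override.  The
locus itself is derived from a carrier/non-carrier reference pair by global
edit-distance alignment; equal-cost alignment paths can fragment a long
deletion, so nearby deletion runs are clustered and refined to an exact
contiguous placement when one exists.

In-silico PCR uses Hamming-only matching (no indels) with the 3′-terminal
3 bases required exact at any mismatch allowance — the simplest model
consistent with species-specific priming.  The unique best forward hit and
the unique best downstream reverse-complement hit define the product,
inclusive of primers.  No-hit, ambiguous equally-good hits, and products
outside 200–5000 bp raise descriptive failures; the size window is the
package's only representation of the nuclear-paralogue (numt) concern — no
paralogue detection is attempted.

## Distance trees and concordance

Distances are p (differences / comparable sites) or Kimura-2-parameter,
`d = −ln(1−2P−Q)/2 − ln(1−2Q)/4` from transition and transversion
proportions.  Saturated pairs (log argument ≤ 0) are flagged and assigned
the maximum finite distance in the matrix rather than NaN.  Under
`include_gaps`, gap-involving differences count as transversions.

Neighbor joining is implemented in-package because its determinism is part
of the contract: Q-criterion ties break on the lexicographically smallest
pair of subtree labels (a subtree is labelled by its smallest leaf id), and
negative branch lengths are clamped to zero with the deficit transferred to
the sibling so the pair's path length is preserved.  On additive inputs it
reproduces both topology and path lengths; an independent implementation
serves as a cross-check in the tests.  Bayesian tree inference is
deliberately out of scope — trees here support topological concordance
claims, which any consistent estimator recovers on clean signal — and the
NEXUS export (sequential, datatype=DNA, gap='-', missing='N') lets users
run external Bayesian software on identical data.

Concordance between trees is operationalised as (a) per-group monophyly
after rooting on the declared outgroup, (b) unweighted Robinson–Foulds
distance on the common leaf set, and (c) same-clade assignment agreement:
each unlabelled query leaf takes the group of its smallest ancestral clade
whose labelled members are all of one group; mixed first-labelled ancestors
give `unassigned`, which never counts as agreement.  Ambiguity is reported,
not attributed.

## Synthetic data generator

A star-of-stars genealogy — ancestor → clade stems → haplotypes, plus a
deep outgroup stem — rather than a coalescent: it plants exactly the
features the analyses must recover, with trivially exact truth.  Per-branch
per-site substitution probabilities are scaled by hotspot-block multipliers
(capped at 0.75) and substitutions carry a 4:1 transition:transversion
bias so p and K2P distances differ measurably.  Indels occur only at
configured positions, as gap columns in carrier rows, so the output is
already aligned and truth intervals are exact.

Defaults describe a ~1020-column, 27-sequence panel: five 5-haplotype
clades (stem divergence 0.0015/site, tip rate 0.0003/site — giving overall
S and k of the same order as a real ~25-sequence control-region panel), one
dominant left-domain block (columns 1–380 at ×8), the 15 bp deletion at
columns 950–964 carried by all ingroup clades, and a 2-sequence outgroup at
0.04/site.  Preset configurations add panel-style structure: the
"Bornean-style" preset has three hotspot blocks and carries the deletion;
the "Sumatran-style" preset has 13 sequences in four clades, two blocks and
no deletion.  At these rates multi-hit saturation is mild, so per-site
polymorphism in a ×m block tracks m× the baseline after the analytic
`(1−e^{−mλ})/(1−e^{−λ})` correction — asserted within 3 standard errors
over 100 replicates.

What the generator does **not** emulate: realistic mutation-rate
heterogeneity beyond block structure, recombination (absent from mtDNA),
heteroplasmy, numts, random indel processes, or alignment error (its output
is aligned by construction).  Passing tests therefore demonstrate correct
recovery of planted structure under clean alignment, not robustness to
alignment artefacts in real data.

## Problem sizes in the standard runs

The test suite and acceptance script run entirely at desk scale, chosen as
the smallest sizes at which the asserted properties are statistically
stable: 200 random toy alignments (≤ 8 × ≤ 60) for exact oracle agreement;
100 seeded default panels for hotspot-boundary recovery (±25 columns,
≥ 95% expected); 50 random 8-taxon additive matrices for NJ topology
recovery; 8 panels per divergence setting (0.01 vs 0.0005 stem divergence)
for the concordance contrast; 200 classifications for the deletion
diagnostic.

## Known limitations

* The conservation threshold is a uniform-scatter expectation, not a
  formal changepoint model; boundary precision is step-limited.
* K2P saturation handling (max-finite substitution) distorts very deep
  outgroup placements; use p-distances or a closer outgroup when saturation
  is flagged.
* The in-silico PCR mismatch model ignores indels and thermodynamics.
* Reproducing published per-segment site counts exactly requires the
  original alignment; a regenerated alignment shifts S, η and k by a few
  counts (haplotype counts are robust).
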