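# Methods

## The projection

A circular replicon of length *L* bp is linearized onto a fixed axis of
length 360, the degrees of a circle, so any chromosome or plasmid
occupies the same horizontal extent regardless of size. Base *b*
(1-based) occupies the half-open degree interval

    [360(b − 1)/L, 360 b/L)

This convention makes the first base's start exactly 0, the final base's
end exactly 360, and the map measure-preserving: non-overlapping
features tiling a replicon have degree lengths summing to exactly 360
(up to float rounding; the test tolerance is 1e-6). Coordinates stay
1-based inclusive (the GFF3/BLAST convention) everywhere upstream;
conversion to degrees happens only in the projection module.

The y axis indexes the replicons of a job, 1 … N. The canonical order
is: organism name ascending, then replicon length descending within an
organism, ties broken by replicon id. The spec'd record for a replicon
carries no chromosome/plasmid type field, but since bacterial
chromosomes are (essentially always) longer than co-resident plasmids,
length-descending ordering places each organism's chromosome before its
plasmids, which is the presentation a reader expects. The order is a
pure function of the input set, so reruns are reproducible.

## One hit, one glyph

For a hit resolved to an annotated gene on replicon index *y*:

- **dot** — at the strand-aware transcription start: the start boundary
  of the lowest base for `+` features, the end boundary of the highest
  base for `−` features. (Which end of the gene carries the dot is a
  design choice; anchoring it at the transcription start keeps the
  vector always pointing in the transcription sense.)
- **vector** — signed degrees; |v| = 360 · gene_length/L, sign = strand.
- **alignment segment** — the subject-coordinate interval
  min(s_start, s_end) … max(s_start, s_end) as a fraction of the subject
  length, scaled to |v| and offset from the dot. For protein subjects
  the fraction is over the residue count, taken as gene_length_bp // 3;
  codon-phase arithmetic is deliberately omitted because a one-residue
  discrepancy is invisible at 360-unit resolution.
- **color** — color_value = (bitscore − min)/(max − min), clipped to
  [0, 1], linearly interpolated per channel from yellow RGB(255,255,0)
  at 0 to dark blue RGB(0,0,139) at 1. When all bitscores are equal the
  value is defined as 1 (everything is "most significant"). The min/max
  are taken over the job's full capped result set, not per zoomed view,
  so colors are stable while panning.

Genome-database jobs (subject = whole replicon) need no annotation
join: x comes from the lower subject coordinate, the vector spans the
aligned interval, strand from the orientation of s_start/s_end, and the
segment covers the whole vector.

Subject resolution is two-stage — exact feature-ID match first, then
locus_tag — because gene/protein FASTA header styles vary. Unresolvable
subjects are counted and reported, never silently dropped.

Origin-spanning features (annotated end < start on a circular replicon)
are normalized to end + L with a wrap flag, preserving true length while
keeping start ≤ end; their vectors are split at the 360/0 seam for
rendering, and positions beyond L reduce modulo L before mapping.

## Table semantics and caps

"Contains" filtering is case-sensitive literal substring matching, with
AND composition across filters — the semantics that make underscore
query-naming conventions work (`SSI_` matches `SSI_HlyD` but not
`SSII_GspC`). Sorting is stable, numeric on numeric columns. Both
operations are pure and idempotent.

Two caps bound result volume: the display cap (default 50 000; more
saturates the plot) and the raw export cap (default 1 000 000). When a
cap binds, the most significant rows are kept under the canonical
ordering bitscore desc, e-value asc, y asc, x asc, input order — chosen
to match the significance-centric color semantics. `apply_result_cap`
returns the input unchanged when under the cap; the `*_Sorted` export
always imposes the canonical order itself.

The job's E-value cutoff (default 1e-08, the job-form default) is
applied to parsed hits whether they come from a live BLAST run or a
precomputed file, so a job is the same search either way.

Proximity clustering (`detect_clusters`) is single-linkage along x
within one replicon: sorted by x, a new cluster starts when the gap to
the previous dot exceeds the window (default 5°). The default suits
browsing at the ~25° zoom preset: operon-scale loci (a few kb on a
Mb-scale replicon, well under 5°) stay together while unrelated hits
several degrees away split off. Clusters partition the rows and never
span replicons.

## Rendering

The Graph layout is a main panel plus two overview selectors (bottom:
x range; right: y range). Overviews draw density summaries — 360 x-bins
and one bin per replicon — rather than all marks, to stay responsive at
the display cap. A result is visible in a view when any part of its
vector intersects the x range, not only its dot, so long genes do not
vanish when their origin sits just outside a zoomed window. The static
SVG (matplotlib) tags each visible result's dot/vector/segment with a
stable element id and is byte-deterministic for fixed input and
renderer version (fixed hash salt, no date metadata). The interactive
page is a single self-contained HTML file: the capped result set is
embedded as a JSON data island (the same schema as the results JSON's
`results` array), rendered client-side with zoom/drag, overview range
selection, a five-field hover payload (relative position, BitScore,
query header, organism, product) and a fuller click payload (plus
subject, replicon, e-value, subject coordinates). Segment strokes are
3× the vector stroke width — the "thicker line over the vector".

## Synthetic data

The generator stands in for a real multi-genome database at desk scale.
`GenomeSimSpec` places non-overlapping genes (lengths normal around a
900 bp mean, floor 90 bp — typical bacterial gene lengths) uniformly at
random via multinomially distributed intergenic gaps; genes belonging
to a tagged cluster instead get fixed 25 bp operon-style gaps so the
locus stays compact on the degree axis, as real operons are.
`HitSimSpec` plants one high-bitscore hit per (query, consecutive gene)
pair — query *i* paired with the *i*-th gene from the cluster start,
mirroring a four-query search against a four-gene locus — over a
Poisson background of low-bitscore hits. Bitscores are uniform in
[200, 400] (planted) and [40, 80] (background); the e-value is the
monotone stand-in 10^(−bitscore/10), since the pipeline needs ordering,
not BLAST statistics. All randomness flows from one seeded generator
per operation; identical specs and seeds give byte-identical files.

What the simulation does *not* emulate: sequence evolution, realistic
BLAST score/E-value statistics, paralogy structure, or annotation
noise. Passing tests therefore demonstrate the correctness of parsing,
projection, table semantics and rendering contracts — not biological
sensitivity or specificity of any search.

Problem sizes used by the test suite: pipelines run on 2 organisms × 2
replicons × 50 genes; cap behavior is exercised on 60 000 and 1 200 000
synthetic rows (the latter kept lean — minimal records, one bulk
generator call); property suites use 100–200 randomized cases each.

## Numerical and degenerate-input choices

- Projection arithmetic is one integer subtraction and one division per
  coordinate; segment invariants hold to 1e-9 relative tolerance.
- Empty BLAST files parse to empty lists (not errors); comment lines
  (`#`, outfmt 7) are skipped.
- An empty result set yields a valid header-only TSV, an empty JSON
  results array, and a valid axes-only SVG.
- A degenerate color scale (min = max) maps everything to dark blue.
- Floats in the results JSON are serialized at full precision
  (`repr`-level), so the JSON round trip is the exact identity.
- Sorting and capping are stable: ties preserve input order.

## Known limitations

- The y axis is discrete; jobs with thousands of replicons render, but
  individual tracks become sub-pixel (the original web tool shares this
  limit — hence the y-range selector).
- The optional BLAST wrapper shells out to installed BLAST+ binaries;
  it is a convenience, not a reimplementation, and its absence raises a
  distinct "blast not installed" error.
- No polar/circular rendering: the linearization *is* the method.
- Filtering offers exactly the shown functionality (case-sensitive
  contains, AND); no regex, numeric ranges or OR composition.
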