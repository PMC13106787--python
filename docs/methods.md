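# Methods

This note records the models, parameter choices and numerical decisions
behind curvemorph, in the order the pipeline runs them.

## Geometry: the bent-tube ventricle

The embryonic ventricle is modelled as a planar-bent tube — a circle of
radius *r* (`tube_radius`) swept through an angle Φ (`bend_angle`) around a
bend of radius *R* (`bend_radius`), i.e. a torus sector. The convex sweep
side is the outer curvature (OC), the concave side the inner curvature
(IC). The bend plane doubles as the lateral mounting plane: dropping the
out-of-plane coordinate gives the lateral view in which all landmarks and
boundaries are constructed, mirroring how specimens are mounted flat on one
side. Surface coordinates are the sweep angle φ ∈ [0, Φ] (AVC at φ = 0,
outflow tract at φ = Φ) and the circumferential angle θ (θ = 0 on the OC
midline). The OC- and IC-side arc lengths are Φ(R + r) and Φ(R − r); the
torus area element is r(R + r cos θ) dφ dθ.

This is the simplest surface with distinct convex and concave arcs and an
exact area formula. It deliberately omits torsion, chamber asymmetry,
trabeculation and wall-thickness gradients. Defaults (48 hpf): R = 100 µm,
r = 50 µm, Φ = 2.5 rad, chosen once so that the published regional cell
counts fit the delineated regions with headroom; 36–37 hpf presets are
~15% smaller. These geometry values are free choices, not published
measurements.

## Synthetic cells

Cells are laid down as a row-based brick tiling in (φ, θ): rows run along
the long axis, cells fill each row circumferentially. Each cell's angular
width is solved (Newton on the torus patch formula, then three fixed-point
corrections on the actual polygon) so that the **flat area of its 16-gon
apical outline** — the polygon's area in its best-fit plane — equals a
value drawn from the configured truncated normal (redraw at ≤ 1 µm²). That
flat polygon area is the stored per-cell truth, which makes the truth
round-trip through the tracer exact rather than biased by the ~0.5%
flattening loss of a curved patch. Thin gaps (`gap`, default 0.6 µm)
between cells absorb the mismatch between drawn areas and region area, so
outlines never overlap; a two-phase capacity/apportionment pass spreads
cells over the whole region instead of packing them proximally. Requests
that exceed the region's capacity raise `InfeasibleTilingError`.

Placement domains are insets (margin 2 µm) of the same lateral-view region
boundaries the delineation stage reconstructs, so generated labels and
downstream assignment agree except for deliberately constructed boundary
cases. A best-effort "neither" population fills part of the distal flank.
Basal outlines sit at tube radius r − h for a per-cell apicobasal height h
drawn per region (OC 4.5 ± 0.7 µm squamous, IC 7.5 ± 1.0 µm cuboidal —
free choices); the four lateral walls are radial, so each wall's length is
exactly h.

Membrane-intensity truth: per cell, one lognormal overall scale
(`intensity_scale` = 150 arbitrary units, jitter σ = 0.1) multiplied by the
region/channel fraction triplet (basal, lateral, apical; sums to 1). All
four lateral walls share one value, so renormalizing any cell's truth
recovers the configured triplet exactly. Only the OC apical-area
distribution (142 ± 43 µm²), the typical regional counts (~50–60 OC,
~25–30 IC), the tbx5a-mutant OC mean (108 µm²) and the 0.3 µm pixel pitch
are anchored to published values; the IC distributions, elongation ratios
(OC 1.8 circumferential, IC 1.1), fraction triplets (e.g. wild-type OC
F-actin 0.50/0.30/0.20 basal/lateral/apical vs IC 0.25/0.45/0.30) and
noise model are documented free choices that reproduce the qualitative
orderings (OC basal enrichment, IC lateral/apical accumulation) rather
than printed numbers.

Rendering: each cross-section quad (basal edge, apical edge, two laterals)
is rasterized at `pixel_size` = 0.3 µm/px; fluorescence channels place the
domain truth in a fixed 3-px band just inside each membrane (overlap
resolved by nearest edge) on top of a uniform background (default 5% of
the intensity scale), plus i.i.d. Gaussian noise (σ = 3) clipped at zero.
The membrane channel draws the contour. Ground-truth polylines are
returned in pixel coordinates. No point-spread function, depth attenuation
or photon statistics are simulated — so passing recovery tests show the
measurement chain is faithful, not that it is robust to realistic optics.

## Delineation

Landmark rules (48 hpf): PB_OC one cell diameter from the AVC along the
OC arc; DB_OC at 2/3 of PB_OC→DB_OFT(OC); PB_IC at the AVC; DB_IC at 1/2
of the IC arc; Point I at 1/2 of the PB_OC→DB_OC arc; Point II at 1/3 of
the straight segment PB_IC→Point I; Point III midway between DB_IC and
DB_OC. The OC predicate is the convex half-plane of the extruded cut
through PB_OC and DB_OC (the "oblique slicer" interpreted as a single
plane through both landmarks, perpendicular to the mount plane); the IC is
the polygon closed by PB_IC→II→III→DB_IC and the IC arc. At 36–37 hpf both
regions get explicit medial borders from thirds of the PB_OC→PB_IC and
DB_OC→DB_IC segments, and the strip between the medial borders belongs to
neither region. Any overlap between predicates is resolved by subtracting
the OC region from the IC polygon, so the predicates are disjoint by
construction.

Assignment: a cell's lateral-view apical polygon (repaired with
`make_valid` when the projection folds across the tube crest) is
intersected with each region; the cell joins a region at
`in_region_area_fraction` ≥ 0.5, ties counting as inside. "Half of its
body" is thus operationalized as projected apical area. The OC is split
into proximal and distal halves at the arc midpoint of PB_OC→DB_OC — the
published analyses use proximal/distal OC groups without stating a split
rule, so the midpoint is this package's choice. Mosaic selection keeps
donor cells inside either region and host cells inside a region within two
steps of a donor on the cell-contact graph (direct contact = 1, one
cell-distance = 2).

## Morphometrics

`trace_apical` projects the outline to its best-fit (SVD) plane. If the
maximum out-of-plane deviation exceeds `curvature_threshold` (default
1.0 µm), the outline is split by a plane perpendicular to its long axis at
the cut (searched over 17 candidates between the 15th and 85th percentile)
minimising the worse residual deviation of the two halves; each piece is
projected to its own plane and the pieces are rejoined along the shared
cut chord (reflection chosen so pieces land on opposite sides). Up to
`max_segments` − 1 splits are applied, worst piece first (default: one
split). For the two-piece case the rejoined border is assembled by chain
concatenation; self-intersection raises `StitchingError` rather than
returning a silently wrong area. Tangent-plane projection is only
approximately area-preserving: for a cylindrical patch of half-angle α the
flat area underestimates the curved area by ≈ α²/6 (0.7% for a default OC
cell), which is why the generator defines truth as the flat polygon area.

Cross-sections: cutting planes pass through the apical-outline centroid,
contain the apical-plane normal, and align with the outline's principal
axes (second moments of the projected vertices; the by-eye major/minor
axis of the original interactive workflow). Circularly symmetric outlines
(eigenvalue ratio within 10⁻⁶ of 1) fall back to fixed axes with a
warning. For extremely narrow cells whose basal outline misses the
apical-centroid plane, the basal tips are read from the parallel plane
through the basal centroid. Apicobasal length is the plain mean of the
four lateral lengths; volume is mean basal width × mean apical width ×
length. On the square-frustum family this box estimator undercounts the
true volume by exactly h/3 (w_basal − w_apical)², vanishing for the
cuboid; it is kept because it is the published estimator, and the exact
statement is property-tested.

## Intensity profiling

`band_mean` samples pixel centres within width/2 (default width 1.0 µm —
the "~1 µm" brush taken as exactly 1.0) of the corner-trimmed polyline
(default trim 1.0 µm per end), restricted to the interior of the cell
contour assembled from the four polylines; boundary-touching centres
count. The audited pixel set is returned and is asserted identical to a
brute-force enumeration in tests. Intensities stay at native float
precision (the original 8-bit conversion step is lossy and is not
reproduced). Background subtraction is an explicit argument; the pipeline
passes the generator's known background. Eight band means per channel
reduce to domain means, percentages (of the three-domain sum) and
basal/(apical + lateral). All-zero cells are flagged and excluded from
group statistics, never deleted. Sliver cells whose membranes vanish
after corner trimming are skipped with a warning at the pipeline level
(the per-band error is preserved at the API level).

Ventricle summaries: masked myocardium means per embryo; outliers flagged
with Tukey fences (k = 1.5 — the published analysis names no rule, so the
rule and k are configurable); rfu = 1 + 9 (x − min)/(max − min) per
replicate and channel over non-outlier embryos, undefined (error) for
constant input. In the synthetic pipeline the per-embryo "myocardium mean"
pools all rendered in-cell pixels of that embryo — a stand-in for a
whole-mount mask mean, labelled as such.

## Statistics

Rank-sum comparisons run through `scipy.stats.mannwhitneyu`: exact
enumeration when both groups have ≤ 8 tie-free values, otherwise the
normal approximation with mid-ranks and tie-corrected variance. Stars:
\* p < 0.05, \*\* p < 0.01, \*\*\* p < 0.001. Comparisons default to cell
level (matching how group sizes are reported), with an embryo-level mode
computed on per-embryo means; the pipeline writes both, and SuperPlot
summaries keep both levels visible. No multiple-testing correction is
applied, matching the source workflow; users running many comparisons
should correct downstream.

Cross-experiment normalization Z-scores each experimental cell against the
within-experiment control mean and sample SD (n − 1); mean_norm =
mean_ref + SD_ref × mean(Z). The group-mean shortcut
(mean_exp − mean_ctrl)/SD_ctrl gives the same mean_z algebraically. The
transform is exactly affine-equivariant (property-tested). When no
external reference is configured, the pipeline uses the control group's
own mean/SD as the reference scale, in which case mean_norm coincides
with the experimental mean by construction.

## Reproducibility and problem sizes

Every stage is driven by `numpy.random.Generator` seeded from the config;
per-embryo and per-image seeds derive from `SeedSequence` spawning, so
reruns are byte-identical (SVGs included, via a fixed hash salt and no
timestamps). Output CSVs carry `# key = value` headers with the tool
version, seed and config SHA-256.

Test-suite problem sizes are the package's own choices: populations of
280 wild-type and 220 mutant OC cells pooled over a handful of seeded
ventricles (matching the published group sizes), 100-geometry landmark
property sweeps, 100-seed single-heart runs for the OC-vs-IC ordering
check, and 500-seed power checks for the rank-sum test.

## Known limitations

- The tube model cannot represent the real chamber's torsion or the
  atrium; "neither" flank cells are opportunistic filler.
- Elongation is only approximately per-cell (row height is shared within
  a region), and extreme small-area draws produce sliver cells that the
  profiling stage legitimately rejects.
- Rendering is geometric, not optical; robustness to PSF blur,
  segmentation error or depth attenuation is out of scope.
- The delineation operates on the idealized lateral view; applying it to
  raw confocal stacks of real embryos would first require segmentation and
  mounting-plane estimation, which this package does not attempt.
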