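# Methods

## The local-entropy map

`lemap` maps the textural heterogeneity of a CT volume voxel by voxel. A
cubic kernel of side `k` voxels (default `k = 5`, 125 voxels) slides over
the volume with a one-voxel stride. Within each kernel the intensities are
treated as discrete symbols and the first-order Shannon entropy

    H = - Σ_i P(i) · ln P(i)

is evaluated in nats, where `P(i)` is the occurrence probability of symbol
`i` among the kernel's voxels. `H` is stored at the kernel's central voxel.
The entropy of a kernel lies in `[0, ln k³]`: 0 for a constant neighborhood,
`ln k³` only when all neighbors differ.

Symbols are integer HU values (`floor(value / bin_width)` with
`bin_width = 1`); a larger bin width merges adjacent intensities and can
only lower the entropy (coarsening monotonicity, property-tested). CT
intensities are integers by convention, so the default treats the scanner's
quantization as the symbol alphabet.

The fast implementation accumulates, for each symbol present in the volume,
a separable box-filtered occurrence count and sums the `-p ln p` terms in
ascending symbol order. Per voxel this performs the same floating-point
operations in the same order as evaluating the formula on the extracted
neighborhood, so the map equals a per-voxel brute force *exactly* (asserted
bit-for-bit in the tests), while running in `O(S · N · k)` for `S` symbols
and `N` voxels instead of `O(N · k³ log k)`.

Borders: by default the volume is mirrored at its faces (numpy `reflect`,
no edge duplication), so the map covers the full grid; `exclude-border`
instead marks the `(k-1)/2`-voxel shell as missing (NaN), which downstream
statistics drop with a logged count. The kernel is defined in voxels, not
millimetres; voxel spacing is carried as metadata but no anisotropy
correction is attempted.

## Smoothing and normalization

The map can be smoothed with a Gaussian filter (`σ = 1` voxel by default,
truncated at 4σ; missing-border voxels are excluded from the filter support
via normalized convolution) and normalized by dividing every voxel by the
mean map value inside a liver-parenchyma reference VOI (a "virtual biopsy"
remote from the lesion). After normalization the liver mean is exactly 1
and the map is invariant under any positive rescaling of its input.
Subtractive normalization is available behind a flag for users who read
"normalized over the mean" as centering. Smoothing and normalization
primarily serve display; histogram statistics and voxel classification
therefore consume the smoothed, unnormalized stage by default, and every
stage (raw / smoothed / normalized) is exposed because the choice is a
genuine degree of freedom.

## VOI histogram statistics

Eleven first-order statistics summarize the map values inside a VOI: mean,
median, standard deviation, variance, RMS, the 5th/25th/75th/95th
percentiles, and the numbers of zero and mean crossings. Conventions,
fixed for reproducibility:

- variance is the population (1/N) variance — a VOI is the whole population
  of its voxels — so `rms² = mean² + variance` holds to machine precision;
- percentiles interpolate linearly between order statistics;
- crossing counts are taken on the in-VOI voxel sequence in raster scan
  order (C order over the `(x, y, z)` array, last axis fastest). A mean
  crossing is a consecutive pair strictly straddling the VOI mean; a zero
  crossing is the same count on the mean-centered sequence. The two counts
  are therefore equal by construction — the only reading under which the
  two are a single number, which is how they behave in practice.

The identical machinery runs on raw HU inside the tumor VOI (the parallel
Hounsfield workflow) and on any map stage.

`global_entropy` is the first-order entropy of the in-VOI histogram over
`n_bins` equal-width bins (default 64) spanning the in-VOI min–max range,
in nats or bits. It is an equal-width-binned approximation: dedicated
radiomics packages use their own binning and log base, so absolute values
are comparable only within one convention; both knobs are exposed.

## Group comparison

`compare_groups` z-scores each statistic across subjects and applies the
two-sided Mann–Whitney U test per statistic (scipy's policy: exact null
distribution for small samples without ties, normal approximation with tie
correction otherwise). Raw p-values are reported at α = 0.05, uncorrected;
Benjamini–Hochberg adjustment is available behind a flag. Rank tests are
invariant under the z-scoring (and any monotone map), which is
property-tested; the standardization is kept because the tabulated group
summaries are then on a common scale. Statistics constant across all
subjects leave the test undefined and are flagged, not raised.

## Pattern classification

Tumor voxels are classed hyper-, iso- or hypo-entropic against the liver
reference: hyper above `liver_mean + z·liver_SD`, hypo below
`liver_mean − z·liver_SD`, `z = 1` by default (the taxonomy defines the
classes only visually, so the width of the iso band is an
operationalization choice). The lesion is split into a peripheral shell
(erosion residue, 6-connected, `rim_width = 2` iterations) and a core;
shell and core partition the VOI exactly.

Labels are assigned deterministically, in order:

1. **homogeneous** — the core's modal class is hyper with ≥ 75% occupancy
   and the shell is ≥ 75% hyper (a uniformly hyper lesion);
2. **peripheral_rim** — shell coverage ≥ 75% around a ≥ 75%-homogeneous
   iso/hypo core; *complete* if coverage ≥ 0.999 (total up to
   discretization), else *incomplete*;
3. **mixed** — such a rim around a core failing the 75% homogeneity vote;
4. **inhomogeneous** — everything else (scattered components, no rim).

Two resolution corrections make the visual taxonomy well-posed on a map
whose values summarize k-wide neighborhoods and are then smoothed:

- *Boundary margin.* Kernels centered within `(k−1)/2` voxels of the lesion
  surface mix lesion and liver intensities, and any HU contrast makes that
  ring hyper-entropic regardless of lesion texture. The VOI is therefore
  eroded by `boundary_margin` (default 2) before the rim/core split, so rim
  coverage measures rim texture, not the contrast artifact.
- *Core margin.* A genuine hyper rim smears inward by roughly
  `(k−1)/2 + 2σ` voxels; core homogeneity is judged after a further
  `core_margin` erosion (default 4). Each erosion falls back to the
  uneroded region when it would be empty, and a fully empty core is treated
  as a homogeneous iso core (rim-only lesion), flagged as such.

Rule 1 deliberately judges uniformity on the lesion interior rather than as
a ≥ 75% hyper share of the whole VOI: the rim's share of lesion volume is
scale-dependent (a 3-voxel rim is ~half of a radius-14 lesion but a sliver
of a centimetre-scale one), so a whole-volume vote would relabel every
small rim-bearing lesion homogeneous. The interior reading keeps the 75%
thresholds scale-invariant; the whole-VOI hyper fraction is still computed
and reported in every `PatternResult`.

All thresholds (`z_cutoff`, `rim_width`, margins, the 0.75 votes and the
0.999 completeness tolerance) are parameters with the stated defaults.

## Phantoms

The generator emulates a portal-phase liver CT at desk scale: a 64³ grid at
1 mm isotropic, liver parenchyma `N(100, 10²)` HU, one hypodense spherical
lesion (60 HU, radius 14 voxels; radii below 5 are rejected as carrying too
few voxels), optional straight vessels (radius 2, +150 HU) and a radius-8
biopsy-ball liver reference away from the lesion, vessels excluded. All HU
are rounded to integers. Randomness flows from a single integer seed;
identical specs are bit-identical.

Entropy patterns are induced through local texture SD, because with
integer HU a high-SD region spreads each kernel over more symbols:
hyper regions get SD 35, iso/hypo regions SD 5 (liver sits between at
SD 10, so low-SD cores read hypo). The five target constructions:
homogeneous (SD 35 throughout), peripheral rim complete (SD-35 shell of
thickness 3, SD-5 core), rim incomplete (the same minus a random azimuthal
wedge covering 20% of the shell — for a spherical shell the wedge's area
fraction equals its azimuth fraction), inhomogeneous (hyper patches
covering 40% of the lesion, cut from a σ=3-smoothed Gaussian random field),
and mixed (complete rim + scattered core). Scatter must be patch-scale, not
i.i.d. per voxel: an i.i.d. mixture is heterogeneous inside *every* kernel
and would read as uniformly hyper.

What the phantoms do not emulate: anatomy, partial-volume and
beam-hardening physics, scanner noise spectra, lesion shape irregularity,
breathing artifacts. Passing tests demonstrate that the pipeline measures
what it claims on controlled textures — not clinical performance.

Cohorts pair a "responder" group (hyper SD 35) against a "non-responder"
group (hyper SD 35 − effect, default effect 20), `n_per_pattern` lesions
per pattern per group, each subject with a derived seed.

## Validation experiments and problem sizes

- *Pattern recovery*: 20 phantoms per pattern (100 total, default 64³
  specs); the four-class label must match the construction's truth in
  ≥ 90% of lesions. Rim-subtype agreement is tracked separately because
  complete-vs-incomplete sits on a discretization-sensitive 0.999 coverage
  boundary.
- *Type-I error*: 200 repetitions of a null comparison (two groups of 20
  subjects drawn from one distribution of per-subject features); the
  map-mean rejection rate at α = 0.05 should sit near nominal (checked
  against [0.02, 0.09]).
- *Power*: 50 repetitions of a 10-vs-10 cohort at effect 20 (texture SD 35
  vs 15) on 40³ phantoms with radius-9 lesions; the tumor map-mean is a
  per-subject scalar whose group contrast does not depend on grid extent,
  and the smaller grid keeps the 1,000-subject simulation quick. Detection
  in ≥ 80% of repetitions is expected.
- *Kernel sweep*: for each k, per-volume wall time, a bytes-processed
  working-set proxy, the group-separation p-value and pattern-recovery
  accuracy, with mean ± SD over repetitions (SD flagged undefined for a
  single repetition). Time and bytes are hardware-dependent and are
  reported, never asserted. Maps computed inside the pipeline are cropped
  to the VOIs' bounding box padded by the map's support radius
  (`k//2 + ⌈4σ⌉ + 1`), which leaves in-VOI values exactly unchanged.

## Numerical choices and degenerate inputs

- Entropy accumulates in float64; counts from the box filter are exact
  integers after rounding (error ≪ 0.5 for counts ≤ k³).
- An all-zero mask is rejected wherever a VOI is required; masks binarize
  any nonzero voxel to true, idempotently.
- Normalization refuses a liver reference mean within 1e-12 of zero
  (constant liver: division undefined); voxel classification refuses a
  zero liver SD (thresholds undefined).
- `z_cutoff = 0` degenerates to a sharp mean threshold (iso only at exact
  equality) — allowed, tested.
- Grid compatibility uses an absolute tolerance of 1e-4 mm on spacing and
  origin. Volumes are reoriented to the closest canonical (RAS+)
  orientation on load, and all geometry is defined in voxel space of that
  orientation.
- Ties in the modal-class vote resolve in the fixed order hyper, iso, hypo.

## Known limitations

- The global-entropy values of external radiomics tools are not replicated,
  only approximated up to binning/base conventions.
- Patterns are assessed volumetrically in 3D; per-slice visual assessment
  by a radiologist can disagree near the 75% thresholds.
- Rim geometry assumes roughly convex lesions; highly irregular shapes
  erode unevenly and may shift the rim/core split.
- Hyper-entropy extending beyond the VOI contour is visible in fusion
  renders but no overshoot metric is defined.
- Vessel-related entropy is not removed; vessels appear uniformly
  hyper-entropic and should be excluded from reference VOIs (the phantom
  generator already does).
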