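# lemap — local-entropy mapping of volumetric CT

`lemap` turns a CT volume into a voxel-wise map of textural heterogeneity
and quantifies that map inside segmented lesions. It is aimed at
radiomics-oriented image analysts studying liver lesions (e.g. colorectal
liver metastases on portal-phase CT), where intra-tumoral heterogeneity
carries biological and prognostic meaning that plain size or density
measurements miss.

## The statistic at the core

A cubic kernel of side `k` voxels (default 5×5×5) slides across the volume
with a one-voxel stride. In each kernel the integer HU values are treated
as symbols and the first-order Shannon entropy

$$H = -\sum_{i=1}^{n} P(i)\,\ln P(i)$$

is computed, with `P(i)` the occurrence probability of intensity `i` among
the k³ kernel voxels; `H` (in nats, bounded by `ln k³`) is stored at the
central voxel. The map is optionally Gaussian-smoothed (σ = 1 voxel) and
normalized over the mean entropy of a liver-parenchyma reference VOI.
On top of the map, the package provides:

- the 11 first-order histogram statistics of a VOI (mean, median, SD,
  variance, RMS, 5th/25th/75th/95th percentiles, zero and mean crossings),
  for entropy maps and, in parallel, for raw HU;
- whole-VOI ("global") first-order entropy with configurable binning;
- a deterministic four-class classifier of intra-tumoral entropy patterns
  (homogeneous, inhomogeneous, peripheral rim complete/incomplete, mixed)
  against the liver reference;
- nonparametric group comparison (Mann–Whitney U after z-scoring) of the
  11 statistics across subjects;
- seeded digital liver phantoms carrying each pattern as ground truth, a
  kernel-size sensitivity sweep, slice rendering and CT-fusion overlays,
  and a CLI over NIfTI inputs.

See `docs/methods.md` for conventions, parameters and limitations.

## Worked example

```python
from lemap import (PhantomSpec, generate_phantom, local_entropy_map,
                   smooth_map, extract_histogram_stats, analyze_phantom)

ph = generate_phantom(PhantomSpec(pattern="peripheral_rim_complete", seed=3))
m = smooth_map(local_entropy_map(ph.ct))          # k=5, sigma=1

print(m.data[ph.liver.data].mean())               # 3.4818  (liver, nats)
print(m.data[ph.tumor.data].mean())               # 3.6665  (tumor, nats)

s = extract_histogram_stats(m, ph.tumor)
print(s.mean, s.p95, s.n_mean_crossings)          # 3.6665  4.1411  676

res = analyze_phantom(ph)
print(res.label, res.rim_subtype)                 # peripheral_rim complete
print(round(res.rim_coverage_fraction, 3))        # 1.0
```

The tumor's mean local entropy (3.67 nats) sits above the liver reference
(3.48 nats) because the lesion's high-SD rim spreads each kernel over more
distinct HU values; the classifier finds a hyper-entropic shell covering
the whole boundary around a homogeneous hypo-entropic core and labels the
lesion a complete peripheral rim — the construction's ground truth.

The same pipeline from the shell:

```bash
lemap phantom --pattern mixed --seed 7 -o run/
lemap compute run/ct.nii.gz -k 5 --sigma 1 -o run/map.nii.gz
lemap stats run/map.nii.gz --voi run/tumor.nii.gz -o run/stats.csv
lemap classify run/map.nii.gz --tumor run/tumor.nii.gz \
      --liver run/liver.nii.gz -o run/pattern.json
lemap render run/map.nii.gz --index 32 --ct run/ct.nii.gz -o run/fusion.png
```

Each script in `examples/` exercises one capability end to end and prints
what the numbers mean.

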