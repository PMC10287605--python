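"""Classify the intra-tumoral entropy pattern of each phantom type.

Each lesion's voxels are labeled hyper/iso/hypo-entropic against the liver
reference (mean +/- 1 SD), then the rim/core geometry decides one of four
patterns. The printed fractions are the evidence behind each label.
"""

from lemap import PHANTOM_PATTERNS, PhantomSpec, analyze_phantom, generate_phantom

for pattern in PHANTOM_PATTERNS:
    phantom = generate_phantom(PhantomSpec(pattern=pattern, seed=5))
    res = analyze_phantom(phantom)
    print(f"truth={pattern:28s} -> label={res.label:15s} rim={res.rim_subtype:10s} "
          f"coverage={res.rim_coverage_fraction:.2f} "
          f"core_homog={res.core_homogeneity_fraction:.2f} "
          f"hyper_frac={res.hyper_surface_fraction:.2f}")
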