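"""Compare entropy features between two synthetic response groups.

Builds a phantom cohort whose groups differ in lesion texture SD (35 vs
15 HU), extracts the 11 map statistics per subject, and runs the two-sided
Mann-Whitney U test per statistic after z-score standardization. Location
statistics (mean, median, percentiles, RMS) should separate the groups;
a p-value below 0.05 marks a detected difference.
"""

from lemap import PhantomSpec, compare_groups, generate_cohort, phantom_tumor_stats

base = PhantomSpec(shape=(40, 40, 40), lesion_radius=9, biopsy_radius=5)
cohort = generate_cohort(n_per_pattern=1, base_spec=base, effect=20.0, seed=3)

stats, labels = [], []
for member in cohort:
    stats.append(phantom_tumor_stats(member.generate()))
    labels.append(member.group)

comp = compare_groups(stats, labels)
print(comp.table[["statistic", "u_statistic", "p_value"]].to_string(index=False))
print(f"\nsignificant at alpha={comp.alpha}: {', '.join(comp.significant) or 'none'}")
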