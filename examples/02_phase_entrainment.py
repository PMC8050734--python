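"""Classify how completely inverted feeding re-times a tissue's rhythms.

Uses the VAT archetype (about 80% of dual-oscillating features generated
phase-inverted) and runs the full pipeline: per-condition detection,
joint comparison, circular folding of the phase shift onto 0-12 h, and
classification into phase-locked (0-4 h), intermediate (4-8 h) and
phase-inverted (8-12 h).
"""

from circashift import generate_dataset, phase_entrainment_analysis, tissue_archetype

spec = tissue_archetype("VAT", n_features=600, frac_rhythmic=0.5, seed=11)
matrix, design, truth = generate_dataset(spec)

result = phase_entrainment_analysis(matrix, design, "NRF", "DRF", seed=2)
summary = result.summary
print(f"dual-oscillating features (q < 0.05 in both conditions): {summary.n_dual}")
for label, pct in summary.percentages.items():
    print(f"  {label:15s} {summary.counts[label]:4d}  ({pct:.2f}%)")
print("folded phase-shift histogram (1-h bins, 0-12 h):")
print(" ", list(summary.histogram))

# The phase-inverted percentage is the tissue's degree of entrainment by
# feeding; the generative value here is 80.46%.
print(f"recovered inverted fraction: {summary.percentages['phase_inverted']:.2f}% "
      f"(generative 80.46%)")
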