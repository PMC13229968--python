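"""Derive whole-plant traits by 3-D reconstruction of the architecture.

Height, leaf area and the leaf-inclination distribution are not stored in
the tokens — they emerge from composing every rotation from the plant base
out to each leaf. Organ counts, by contrast, can be read straight off the
token sequence.
"""

from plantarch import (
    PlantMetadata, build_vocabulary, compute_traits, count_organs,
    generate_plant, tokenize_architecture,
)

vocab = build_vocabulary()
plant = generate_plant(seed=7, age_days=30)

traits = compute_traits(plant, n_bins=10)
print(f"plant height: {traits.height_m:.3f} m")
print(f"leaf count:   {traits.leaf_count}")
print(f"leaf area:    {traits.total_leaf_area_m2:.4f} m^2")
print("inclination histogram (9-degree bins, 0-90):")
print("  " + " ".join(f"{m:.3f}" for m in traits.inclination_histogram))
print(f"  (sums to {traits.inclination_histogram.sum():.1f})")

seq = tokenize_architecture(plant, PlantMetadata(0.5, 0.4, 0.05), vocab)
counts = count_organs(seq, vocab)
print(f"token tally: {counts.n_shoots} shoots, {counts.n_phytomers} phytomers, "
      f"{counts.n_leaves} leaves")
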