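"""Generate one seeded cowpea architecture and inspect its organ hierarchy.

The generator starts every plant as a day-0 seedling (one unifoliate
phytomer) and grows it day by day: new phytomers appear at each shoot apex
every phyllochron, lateral buds break stochastically, internodes elongate.
The same (seed, age) always yields the same plant.
"""

from plantarch import generate_plant, validate_architecture, write_architecture_xml

plant = generate_plant(seed=42, age_days=25)

n_phytomers = sum(len(s.phytomers) for s in plant.shoots)
n_leaves = sum(len(ph.leaves) for s in plant.shoots for ph in s.phytomers)
print(f"seed 42, day 25: {len(plant.shoots)} shoots, "
      f"{n_phytomers} phytomers, {n_leaves} leaves")
print(f"branching orders present: {sorted({s.branching_order for s in plant.shoots})}")
print(f"validation violations: {validate_architecture(plant)}")

# the XML dialect is the persistent form of the architecture
xml = write_architecture_xml(plant)
print("\nfirst lines of the XML document:")
print("\n".join(xml.splitlines()[:6]))
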