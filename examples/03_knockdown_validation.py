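"""Knockdown validation: from Cq tables to regulation calls.

Simulates a paired-design qPCR experiment (6 donors, three conditions)
for genes with known regulation, runs the relative-expression analysis
and paired tests, and crosschecks the calls against a ChIP-derived
gene classification.
"""

from stat5kit.qpcr import crosscheck, validate_all
from stat5kit.synthetic import RegulationTruth, simulate_qpcr

truths = [
    RegulationTruth("gene_redundant", "redundant", 0.45, 0.58),
    RegulationTruth("gene_a_target", "A-specific", 0.45, 0.0),
    RegulationTruth("gene_b_target", "B-specific", 0.0, 0.58),
    RegulationTruth("gene_bystander", "none", 0.0, 0.0),
]
cq = simulate_qpcr(truths, n_donors=6, sd_noise=0.15, seed=7)

frame, calls = validate_all(cq)
print(frame.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()

chip_labels = {
    "gene_redundant": "equal",
    "gene_a_target": "A-dominant",
    "gene_b_target": "B-specific",
    "gene_bystander": "equal",  # bound but not regulated: a real outcome
}
table, concordant, discordant = crosscheck(chip_labels, {g: c.label for g, c in calls.items()})
print("ChIP class x knockdown class:")
print(table.to_string())
print(f"concordant: {concordant}")
print(f"discordant: {discordant}")

# The same crosscheck over the packaged fixtures: binding classes computed
# from the shipped q-score table against the reported knockdown outcomes
# for the 27 candidate genes.
from stat5kit.comparative import classify_table4
from stat5kit.core_io import parse_kd_outcomes

chip_classes, _ = classify_table4()
table, concordant, discordant = crosscheck(
    {g: c.label for g, c in chip_classes.items()}, parse_kd_outcomes()
)
print()
print("packaged fixtures, binding class x knockdown outcome:")
print(table.to_string())
print(f"{len(concordant)}/27 genes concordant; discordant: {sorted(discordant)}")
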