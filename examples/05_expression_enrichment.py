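"""Expression integration and switched-compartment-gene enrichment.

Runs the full two-condition pipeline: compartments, switches, switched-
compartment genes (SCGs), per-compartment FPKM summaries, and the
hypergeometric over-representation test of the SCGs against a pathway
collection with one planted enriched set among 20 decoys.
"""

from hicplaid.pipeline import run_two_condition_analysis
from hicplaid.simulate import SimConfig

res = run_two_condition_analysis(SimConfig(), seed=7)

for cond in (1, 2):
    per = res.expression_summary[cond]["per_label"]
    p = res.expression_summary[cond]["ranksum_A_gt_B"]["p"]
    print(
        f"condition {cond}: {per['A']['count']} genes in A (median FPKM"
        f" {per['A']['median']:.1f}), {per['B']['count']} in B (median FPKM"
        f" {per['B']['median']:.1f}), rank-sum p(A > B) = {p:.2e}"
    )

print(f"switched-compartment genes: {len(res.scgs)}")
top = res.enrichment_table.head(3)[["term", "count", "pathway_size", "p_value"]]
print("top pathways by hypergeometric p:")
print(top.to_string(index=False))
print()
print("Compartment A is gene-rich and more highly expressed than B, and the")
print("pathway seeded with switched-bin genes ranks first, many orders of")
print("magnitude ahead of the best uniform decoy.")
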