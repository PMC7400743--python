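"""Three-step branch-length screen on a truth-labelled synthetic gene set.

Simulates 200 gene trees on the 19-taxon snake genome tree (10 genes carry a
3x acceleration of the pit-viper stem branch), computes the clade
branch-length metrics for each gene, applies the three filtering steps
(above the regression and 1:1 lines for the outgroup and viper comparisons,
above the 1:1 line for the stem-vs-longest-viper comparison), and compares
the survivors against the simulation truth.
"""

from pitscreen import (
    SimulationSpec,
    default_clade_config,
    simulate_gene_tree,
    compute_clade_metrics,
    run_three_step_screen,
)

spec = SimulationSpec(
    n_genes=200,
    accelerated_fraction=0.05,   # 10 truly accelerated genes
    acceleration_factor=3.0,     # pit-viper stem x3, the TRPA1-like pattern
    branch_noise_sigma=0.1,
    seed=42,
)
config = default_clade_config()

truth, metrics = {}, []
for g in range(spec.n_genes):
    tree, accelerated = simulate_gene_tree(spec, g)
    truth[tree.name] = accelerated
    metrics.append(compute_clade_metrics(tree, config))

records = run_three_step_screen(metrics)
survivors = {r.gene for r in records if r.final_pass}
tp = sum(truth[g] for g in survivors)
fp = len(survivors) - tp

print(f"{len(survivors)} of {spec.n_genes} genes survive all three steps")
print(f"recall: {tp}/{sum(truth.values())} truly accelerated genes recovered")
print(f"false positives: {fp} of {spec.n_genes - sum(truth.values())} null genes")
# recall near 1 and false positives near 0 show the filter isolates genes
# whose pit-viper ancestral branch outruns every comparison lineage
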