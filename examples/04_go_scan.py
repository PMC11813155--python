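"""Gene-set scan: find the GO term that predicts a trait best.

Simulates a trait whose 10 causal genes all sit inside one designated term,
scans 30 terms with GO-TBLUP (two variance components: term vs rest),
selects the most predictive terms and counts gene occurrences across them.
"""

import numpy as np

import txpred as tx

cfg = tx.SimulationConfig(n_lines=120, n_genes=500, architecture="go_enriched",
                          n_causal=10, target_H2m=0.8, seed=6)
ds = tx.simulate_dataset(cfg, n_terms=30, size_range=(5, 40))

plan = tx.make_splits(120, n_reps=3, base_seed=7)
scan = tx.scan_terms(ds.expression, ds.phenotype, ds.genesets, "go_tblup",
                     plan, sched=tx.MCMCSchedule(1500, 300, 4))

print(f"baseline (single-kernel TBLUP) mean r: {scan.baseline_mean_r:.3f}")
ranked = scan.terms.sort_values("mean_r", ascending=False)
print(ranked.head(5)[["term_id", "n_genes", "mean_r", "se_r"]]
      .to_string(index=False))
print(f"\ndesignated causal term: {ds.config.causal_term}")

top = tx.select_top_terms(scan.terms, pct=0.1)
genes = tx.gene_frequency(top, ds.genesets, threshold=2)
causal = {g for g, b in zip(ds.expression.gene_ids, ds.true_effects) if b != 0}
print(f"\ngenes in >=2 of the top {len(top)} terms "
      f"(* = truly causal):")
for _, row in genes.head(10).iterrows():
    mark = "*" if row.gene_id in causal else " "
    print(f"  {row.gene_id} {mark} count={row['count']}")
# A term whose mean r beats the baseline carries predictive signal beyond
# the genome-wide kernel; genes recurring across top terms are candidates
# for the trait's underlying biology.
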