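"""Simulate a day-7 labeling experiment and discover isotope phenotypes.

Generates 777 synthetic single-cell ROIs from the five-component day-7
mixture, scans clustering methods and cluster numbers with the
Calinski-Harabasz index, then partitions the cells with fuzzy c-means
(k=5) and prints the per-phenotype summary table.
"""

import isophene as ip
from isophene import phenotype as ph

mix = ip.preset_mixture("day7")
ratios, truth = ip.generate_ratio_table(mix, seed=1)
print(f"simulated {len(ratios)} ROIs from {len(mix.components)} phenotypes\n")

feats = ip.build_features(ratios)  # z-scored 5-ratio space

scan = ip.scan_methods(feats, ["kmeans", "fuzzy_cmeans", "ward", "pam"],
                       range(2, 8), seed=1, restarts=10)
print("CH validity scan (higher = tighter, better separated clusters):")
print(scan.grid.pivot(index="k", columns="method", values="ch").round(1))
print(f"best cell: method={scan.best[0]}, k={scan.best[1]}\n")

sol = ip.fuzzy_cmeans(feats.data, k=5, seed=1, restarts=20)
mapping = ip.canonicalize_labels(sol, ph.day7_archetypes(), feats)
labels = ip.apply_canonical(sol, mapping, ratios.index)

summary = ip.summarize_clusters(ratios, labels)
print("per-phenotype ratio summary (n, mean, sd per cluster):")
print(summary.round(4).to_string())
print("\nPhenotype e (high 15N/14N and 33S/32S) marks the most anabolically")
print("active, sulfate-reducing cells; c (high 13C/12C) the main acetate")
print("consumers. Cluster sizes need not match the generating components")
print("where components overlap in ratio space.")
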