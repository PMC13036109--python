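"""Attribution: which genes and modules drive the classifier's predictions.

Runs sampling-based Shapley attribution over genes and mean-ablation
contribution over modules on a small trained model, then checks the top
genes against the planted DEG list.
"""

import numpy as np

from cytomod import (ModelConfig, SimulationConfig, build_graph,
                     gene_importance, generate_cohort, louvain_partition,
                     module_contribution, stratified_split, train_model,
                     zscore_normalize)

cfg = SimulationConfig(n_genes=200, n_modules=5, n_deg_up=5, n_deg_down=5,
                       mu_up_range=(1.0, 2.0), mu_down_range=(-2.0, -1.0),
                       seed=0)
cohort = generate_cohort(cfg)
split = stratified_split(cohort, train_fraction=0.7, seed=0)
train_z = zscore_normalize(split.train)
test_z = zscore_normalize(split.test, reference=split.train)
graph = build_graph(train_z, fraction=0.02, gamma=4.0)
partition = louvain_partition(graph, seed=0)
trained = train_model(train_z, graph, partition, ModelConfig(seed=0, max_epochs=40))

genes = gene_importance(trained, train_z, n_background=16, n_explain=8,
                        n_permutations=8, seed=0)
deg_ids = set(cohort.gene_ids[cohort.deg_effect != 0])
top20 = genes.head(20)
hits = [g for g in top20["entity_id"] if g in deg_ids]
print("top 10 genes by mean |Shapley attribution|:")
print(top20.head(10).to_string(index=False))
print(f"\nplanted DEGs among the top 20: {len(hits)}/20 "
      f"(10 DEGs among {cohort.n_genes} genes -> strong enrichment)")

modules = module_contribution(trained, test_z)
print("\ntop modules by mean-ablation contribution:")
print(modules.head(5).to_string(index=False))
# A high contribution score means replacing that module's embedding with its
# training-set mean moves the decision logit substantially.
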