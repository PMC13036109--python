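"""In silico module perturbation: how predicted disease risk responds when a
cytokine-responsive gene module is up- or down-modulated in latent space.

Trains the full model on a graded-allocation cohort (designated modules
hold 40/25/15% of the DEGs), then shifts each designated module's embedding
by +/- 0.2 of its training-set standard deviation and reports Delta-p.
"""

import numpy as np

from cytomod import (ModelConfig, PerturbationSpec, build_graph,
                     generate_cohort, louvain_partition, perturb_module,
                     perturbation_screen, stratified_split, train_model,
                     zscore_normalize)
from cytomod.bench import reduced_profile

cohort = generate_cohort(reduced_profile(seed=0))
split = stratified_split(cohort, train_fraction=0.7, seed=0)
train_z = zscore_normalize(split.train)
test_z = zscore_normalize(split.test, reference=split.train)
graph = build_graph(train_z, fraction=0.01, gamma=4.0)
partition = louvain_partition(graph, seed=0)
trained = train_model(train_z, graph, partition, ModelConfig(seed=0))

names = cohort.provenance["designated_modules"]
print("designated module -> detected module, Delta-p at delta = 0.2:")
for truth_m, name in names.items():
    genes = np.flatnonzero(cohort.true_module_of_gene == truth_m)
    deg = genes[cohort.deg_effect[genes] != 0]  # follow the DEG-bearing fragment
    detected = int(np.bincount(partition.module_of_gene[deg]).argmax())
    row = []
    for direction in ("up", "down"):
        res = perturb_module(trained, test_z, PerturbationSpec(
            module_index=detected, direction=direction, delta=0.2))
        row.append(f"{direction} {res.mean_delta_p:+.4f} (p={res.p_value:.2g})")
    print(f"  {name:10s} (module {detected:3d}): " + ", ".join(row))

screen = perturbation_screen(trained, test_z, delta=0.2)
print("\ntop of the all-module screen (ranked by |mean Delta-p|):")
print(screen.head(5).to_string(index=False))
# Positive Delta-p on upregulation means pushing the module's embedding
# outward raises predicted disease probability; the designated modules
# should rank by their DEG share (IL6-like > TNFA-like > IL1B-like).
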