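"""Run the classifier-development pipeline on one synthetic cohort.

Prescreens node metrics (univariate rank test, random-forest importance,
L1-penalized selection), enumerates 2-to-4-node logistic combination
models, adjusts each AUROC for optimism by bootstrap, and prints the
top-ranked candidates — on a cohort with the planted 24 h apoptosis
effect, the AraC+Dauno -> cPARP Uu node should dominate the ranking.
"""

import numpy as np

import scnp
from scnp.classifiers import prescreen_nodes, enumerate_combination_models
from scnp.pipeline import (cohort_node_matrix, outcome_series,
                           classifier_feature_matrix)

cfg = scnp.SimulationConfig(n_patients=80, mean_events_per_well=1500,
                            seed=3, p_bm=1.0, p_pb=0.0)
patients, wells, beads = scnp.simulate_cohort(cfg)
matrix = cohort_node_matrix(wells, beads, scnp.load_default_panel(),
                            min_cells=100)
y = outcome_series(patients, matrix.index)
keep = y.notna()
feats = classifier_feature_matrix(matrix.loc[keep])
outcomes = y[keep].astype(int).to_numpy()

rng = np.random.default_rng(0)
selected = prescreen_nodes(feats, outcomes, alpha=0.05, rng=rng, min_keep=2)
print("prescreened node metrics (univariate p ascending):")
print(selected.round(4).to_string())

models = enumerate_combination_models(list(selected.index[:6]), feats,
                                      outcomes, kmax=4, B=100, rng=rng)
print(f"\n{len(models)} combination models fit; top 5 by adjusted AUROC:")
for m in models[:5]:
    print(f"  adj={m.adjusted_auroc:.3f} (apparent {m.apparent_auroc:.3f}, "
          f"n={m.n_used}) <- {', '.join(m.features)}")
# apparent minus adjusted is the estimated optimism (overfitting bias);
# ranking by the adjusted value prevents rewarding overfit combinations.
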