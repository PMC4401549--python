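"""Score the locked DX_SCNP classifier on a simulated cohort.

Runs the full path — simulation, bead calibration, gating, node metrics —
then evaluates the locked two-node model (24 h AraC+Dauno cPARP Uu and
CD34 Uu with hinge-squared transforms) and reports AUROC and the one-sided
exact p-value for CR/CRi vs RD.
"""

import scnp
from scnp.pipeline import (cohort_node_matrix, score_locked_classifier,
                           outcome_series, locked_classifier_performance)

cfg = scnp.SimulationConfig(n_patients=40, mean_events_per_well=2000,
                            seed=7, p_bm=1.0, p_pb=0.0)
patients, wells, beads = scnp.simulate_cohort(cfg)
panel = scnp.load_default_panel()
matrix = cohort_node_matrix(wells, beads, panel, min_cells=100)

scores = score_locked_classifier(matrix)
outcomes = outcome_series(patients, matrix.index)
print("first five patients:")
for (pid, tissue), score in scores.head(5).items():
    y = outcomes.loc[(pid, tissue)]
    label = {1.0: "CR/CRi", 0.0: "RD"}.get(y, "TRM")
    print(f"  {pid} {tissue}: score={score:.3f} outcome={label}")
# scores near 1 predict response: they need cPARP Uu > 0.5 (apoptosis
# induced by the drug) and CD34 Uu < 0.5 (blast depletion).

perf = locked_classifier_performance(patients, matrix, tissue="BM")
print(f"\nBM cohort (n={perf['n']}, {perf['n_responders']} responders): "
      f"AUROC={perf['auroc']:.3f}, one-sided exact p={perf['p_value']:.4f}")
# AUROC > 0.5 with a small p means the locked model separates responders
# from resistant disease on this simulated cohort.
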