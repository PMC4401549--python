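"""scnp — single-cell network profiling analysis pipeline.

From multi-well flow-cytometry events through bead (ERF) calibration,
hierarchical gating and node-metric computation to the locked DX_SCNP
induction-response classifier, its training procedure, and the
classifier-validation statistics suite — plus a synthetic-cohort
generator standing in for the private study samples.
"""

from importlib import resources

import yaml

from .io import EventTable, read_events, write_events
from .simulate import (PatientRecord, SimulationConfig, BeadPlateData,
                       simulate_cohort, simulate_well, simulate_beads,
                       CHANNELS, FLUOR_CHANNELS)
from .calibration import BeadCalibration, fit_erf_calibration, apply_calibration
from .gating import (GateParams, PopulationIndex, gate_hierarchy,
                     cparp_negative_gate)
from .metrics import (NodeDefinition, NodeMetricRecord, metric_basal,
                      metric_log2fold, metric_uu, metric_ua, metric_phintact,
                      amine_aqua_death_metric, compute_node_table,
                      node_table_to_frame, node_metric_matrix)
from .classifiers import (LockedScnpModel, CandidateModel, ClinicalModel,
                          load_locked_model, score_dx_scnp, prescreen_nodes,
                          fit_penalized_logistic, enumerate_combination_models,
                          adjust_auroc_optimism, oob_auroc, build_dx_clinical)
from .stats import (AurocResult, auroc_trapezoid, exact_mw_test, bca_ci,
                    delong_ci, combined_independence_test, power_simulation,
                    paired_concordance, subgroup_performance)
from .cohort import (AllocationState, AnalysisSet, minimization_assign,
                     build_analysis_sets, impute_clinical)

__version__ = "0.1.0"


def load_default_panel() -> list[NodeDefinition]:
    """The node panel shipped with the package (see panels/default_panel.yaml)."""
    text = (resources.files("scnp.panels") / "default_panel.yaml"
            ).read_text(encoding="utf-8")
    return load_panel_from_text(text)


def load_panel_from_text(text: str) -> list[NodeDefinition]:
    spec = yaml.safe_load(text)
    return [NodeDefinition(modulator=n["modulator"],
                           time_hours=float(n["time_hours"]),
                           readout=n["readout"],
                           population=n.get("population", "healthy_blast"),
                           u_modulator=n.get("u_modulator", "unmodulated"),
                           metrics=tuple(n.get("metrics", ("Uu",))))
            for n in spec["nodes"]]
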