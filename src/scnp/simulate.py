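"""Synthetic phospho-flow cohorts.

The study samples this pipeline was designed for are private, so this
module generates cohorts with the statistical structure the analysis
assumes: elderly-AML patients with an induction outcome (CR/CRi, RD, or
TRM), one or two tissue samples (bone marrow, peripheral blood), a plate
layout with multiplicative per-plate channel gains, an 8-peak rainbow-bead
well per plate, and per-well single-cell event tables drawn from a
four-component mixture (debris, dead cells, lymphocytes, leukemic blasts)
with log-normal channel intensities.

The simulation ground truth is a latent chemosensitivity score in [0, 1]
per patient, hidden from the classifiers.  It drives two things:

* the induction outcome, through a Bernoulli/logistic link whose default
  intercept/slope give a cohort response rate of about 72% (the response
  rate of the training analysis set the pipeline's defaults emulate); and
* the 24 h AraC+daunorubicin response: treated blasts shift cPARP up,
  CD34 down, and Amine Aqua up, each proportionally to the latent score,
  so chemosensitive (responding) patients show a larger apoptosis
  signature.  TRM outcomes are drawn independently of the latent score
  (the assay measures blast chemosensitivity, not comorbidities).

Short-term signaling nodes (FLT3L, IL-27, PMA) respond with a fixed shift
plus per-patient responsiveness noise that is independent of outcome, so
they act as biologically flavored negative controls for classifier
training.  Secondary-AML peripheral-blood samples can be decoupled from
the marrow latent score via ``secondary_discordance``, emulating the
observed BM/PB discordance of secondary AML.

All intensities are raw instrument units; log10 intensities are normal
within each subpopulation.  The intensity scale is documented in
``POPULATIONS`` and is the scale the default gate boundaries refer to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .io import EventTable

__all__ = [
    "PatientRecord", "SimulationConfig", "BeadPlateData",
    "simulate_cohort", "simulate_well", "simulate_beads",
    "CHANNELS", "FLUOR_CHANNELS", "WELL_PLAN",
]

CHANNELS = ["FSC", "SSC", "AquaAmine", "CD45", "CD34", "cPARP",
            "pAKT", "pERK", "pS6", "pSTAT1", "pSTAT3", "pSTAT5", "pCREB"]
FLUOR_CHANNELS = CHANNELS[2:]
READOUT_CHANNELS = CHANNELS[5:]

# log10-intensity (mean, sd) per channel per subpopulation; channels not
# listed fall back to "default".  Autofluorescence level is what an
# unstained cell shows on a fluorescence channel.
AUTOFLUOR = (1.8, 0.20)
POPULATIONS = {
    "debris": {"FSC": (1.8, 0.15), "SSC": (1.8, 0.15),
               "default": (1.6, 0.25)},
    "dead": {"FSC": (2.3, 0.12), "SSC": (2.4, 0.12),
             "AquaAmine": (3.5, 0.25), "CD45": (3.2, 0.20),
             "cPARP": (3.0, 0.30), "default": (2.3, 0.25)},
    "lymphocyte": {"FSC": (2.5, 0.10), "SSC": (2.2, 0.12),
                   "AquaAmine": (2.0, 0.25), "CD45": (3.6, 0.15),
                   "CD34": (1.8, 0.20), "cPARP": (2.0, 0.20),
                   "default": (2.5, 0.20)},
    "blast": {"FSC": (2.6, 0.12), "SSC": (2.35, 0.12),
              "AquaAmine": (2.0, 0.25), "CD45": (3.0, 0.15),
              "CD34": (3.1, 0.30), "cPARP": (2.0, 0.20),
              "default": (2.5, 0.20)},
}

# modulator -> (time h, {channel: response shift in log10 units})
SIGNALING_RESPONSES = {
    "FLT3L": (0.25, {"pAKT": 0.30, "pERK": 0.28, "pS6": 0.25}),
    "IL-27": (0.25, {"pSTAT1": 0.30, "pSTAT3": 0.32, "pSTAT5": 0.28}),
    "PMA": (0.25, {"pCREB": 0.35, "pERK": 0.30}),
}

# the wells laid out for every patient x tissue sample
WELL_PLAN = [
    ("autofluorescence", 0.25),
    ("unmodulated", 0.25),
    ("FLT3L", 0.25),
    ("IL-27", 0.25),
    ("PMA", 0.25),
    ("untreated", 24.0),
    ("AraC+Dauno", 24.0),
]
KNOWN_MODULATORS = {m for m, _ in WELL_PLAN}


class ConfigurationError(ValueError):
    pass


@dataclass
class PatientRecord:
    """Clinical record plus simulation ground truth.

    ``latent_chemosensitivity`` and ``latent_signaling`` are simulation
    internals hidden from classifiers; everything else mimics the clinical
    covariates available at diagnosis for an elderly AML induction cohort.
    """

    patient_id: str
    tissue_types: tuple[str, ...]
    onset: str                      # de_novo | secondary
    outcome: str                    # CR | CRi | RD | TRM
    age: float
    wbc: float                      # 10^9 cells/L
    bm_blast_pct: float
    pb_blast_pct: float
    anc_pct: float
    anc_abs: float
    mono_pct: float
    mono_abs: float
    hemoglobin: float
    platelets: float
    performance_status: str         # "0-1" | "2-3"
    fab_class: str                  # "M0/M1/M2/M7" | "other"
    cytogenetic_risk: str           # better | intermediate | poor | unknown
    flt3_itd: str                   # mutant | wildtype | unknown
    flt3_itd_ratio: float           # continuous allelic-ratio surrogate
    npm1: str                       # mutant | wildtype | unknown
    latent_chemosensitivity: float
    latent_signaling: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.tissue_types:
            raise ValueError("every patient needs at least one tissue type")
        for p in (self.bm_blast_pct, self.pb_blast_pct):
            if not 0.0 <= p <= 100.0:
                raise ValueError("blast percentages must lie in [0, 100]")

    @property
    def responder(self) -> bool:
        return self.outcome in ("CR", "CRi")


@dataclass
class SimulationConfig:
    """Cohort-generator settings; defaults are the emulated study design.

    The outcome link P(CR/CRi | s) = expit(response_intercept +
    response_slope * s) over s ~ Uniform(0,1) gives a response rate of
    ~0.72 at the defaults.  Effect sizes are log10-intensity shifts at
    latent chemosensitivity 1 and scale linearly with it.
    """

    n_patients: int = 20
    seed: int = 0
    # outcome model
    response_intercept: float = -0.4
    response_slope: float = 3.0
    trm_rate: float = 0.08
    cri_fraction: float = 0.2       # CRi share among responders
    # cohort composition
    secondary_fraction: float = 0.15
    p_bm: float = 0.75
    p_pb: float = 0.75
    # planted 24 h AraC+Dauno apoptosis effect (log10 shift at s = 1)
    cparp_effect: float = 0.5
    cd34_effect: float = 0.4
    aqua_death_effect: float = 0.35
    # short-term signaling responsiveness noise (per patient, outcome-free)
    signaling_noise_sd: float = 0.12
    # per-patient biological decoupling of the 24 h readouts from the latent
    # score: cPARP (apoptosis execution) tracks chemosensitivity tightly,
    # while CD34 depletion and bulk viability loss vary more between
    # patients at the same chemosensitivity
    apoptosis_noise_cparp: float = 0.05
    apoptosis_noise_cd34: float = 0.35
    apoptosis_noise_aqua: float = 0.25
    # optional planted association of cytogenetic risk with chemosensitivity
    cytogenetics_effect: float = 0.0
    # secondary-AML PB decoupling weight in [0, 1]
    secondary_discordance: float = 0.8
    # events
    mean_events_per_well: float = 10_000
    debris_frac: float = 0.08
    dead_frac: float = 0.07
    # plates and beads
    plate_size: int = 28
    plate_gain_sd: float = 0.08     # sd of log10 per-plate channel gain
    bead_events_per_peak: int = 200
    bead_noise_sd: float = 0.02
    bead_reference_erf: tuple[float, ...] = tuple(
        float(v) for v in np.logspace(1.0, 4.5, 8))

    def validate(self) -> None:
        probs = {"trm_rate": self.trm_rate, "cri_fraction": self.cri_fraction,
                 "secondary_fraction": self.secondary_fraction,
                 "p_bm": self.p_bm, "p_pb": self.p_pb,
                 "debris_frac": self.debris_frac, "dead_frac": self.dead_frac,
                 "secondary_discordance": self.secondary_discordance}
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if self.mean_events_per_well <= 0:
            raise ConfigurationError("mean_events_per_well must be positive")
        for name in ("cparp_effect", "cd34_effect", "aqua_death_effect"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if self.debris_frac + self.dead_frac >= 1.0:
            raise ConfigurationError("debris_frac + dead_frac must be < 1")


@dataclass
class BeadPlateData:
    """8-peak rainbow-bead well of one plate.

    ``peak_intensities``: channel -> list of 8 intensity sample arrays;
    ``reference_erf``: the 8 manufacturer-assigned values (strictly
    increasing)."""

    plate_id: str
    reference_erf: tuple[float, ...]
    peak_intensities: dict[str, list[np.ndarray]]


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _draw_patient(i: int, config: SimulationConfig,
                  rng: np.random.Generator) -> PatientRecord:
    s = float(rng.uniform())
    if rng.uniform() < config.trm_rate:
        outcome = "TRM"
    else:
        p_resp = _expit(config.response_intercept + config.response_slope * s)
        if rng.uniform() < p_resp:
            outcome = "CRi" if rng.uniform() < config.cri_fraction else "CR"
        else:
            outcome = "RD"

    bm = rng.uniform() < config.p_bm
    pb = rng.uniform() < config.p_pb
    if not (bm or pb):
        bm = True
    tissues = tuple(t for t, has in (("BM", bm), ("PB", pb)) if has)

    onset = "secondary" if rng.uniform() < config.secondary_fraction else "de_novo"

    if config.cytogenetics_effect > 0:
        # chemosensitive patients skew toward better-risk cytogenetics
        w = config.cytogenetics_effect * (s - 0.5)
        p = np.clip([0.10 + 0.3 * w, 0.55, 0.25 - 0.3 * w, 0.10], 0.01, None)
        p = p / p.sum()
    else:
        p = [0.10, 0.55, 0.25, 0.10]
    cyto = rng.choice(["better", "intermediate", "poor", "unknown"], p=p)

    flt3 = rng.choice(["mutant", "wildtype", "unknown"], p=[0.2, 0.7, 0.1])
    flt3_ratio = float(rng.uniform(0.1, 1.0)) if flt3 == "mutant" else 0.0
    wbc = float(np.round(10 ** rng.normal(1.0, 0.5), 1))
    anc_pct = float(np.round(rng.uniform(2, 40), 1))
    mono_pct = float(np.round(rng.uniform(0, 15), 1))
    sig = {mod: {ch: float(rng.normal(0.0, config.signaling_noise_sd))
                 for ch in shifts}
           for mod, (_, shifts) in SIGNALING_RESPONSES.items()}
    sig["AraC+Dauno"] = {
        "cPARP": float(rng.normal(0.0, config.apoptosis_noise_cparp)),
        "CD34": float(rng.normal(0.0, config.apoptosis_noise_cd34)),
        "AquaAmine": float(rng.normal(0.0, config.apoptosis_noise_aqua)),
    }

    return PatientRecord(
        patient_id=f"P{i:04d}",
        tissue_types=tissues,
        onset=onset,
        outcome=outcome,
        age=float(np.round(np.clip(rng.normal(70, 6), 60, 88), 1)),
        wbc=wbc,
        bm_blast_pct=float(np.round(rng.uniform(40, 95), 1)),
        pb_blast_pct=float(np.round(rng.uniform(20, 90), 1)),
        anc_pct=anc_pct,
        anc_abs=float(np.round(wbc * anc_pct / 100, 2)),
        mono_pct=mono_pct,
        mono_abs=float(np.round(wbc * mono_pct / 100, 2)),
        hemoglobin=float(np.round(rng.normal(9.5, 1.5), 1)),
        platelets=float(np.round(10 ** rng.normal(1.7, 0.3), 0)),
        performance_status="0-1" if rng.uniform() < 0.8 else "2-3",
        fab_class="M0/M1/M2/M7" if rng.uniform() < 0.55 else "other",
        cytogenetic_risk=str(cyto),
        flt3_itd=str(flt3),
        flt3_itd_ratio=flt3_ratio,
        npm1=str(rng.choice(["mutant", "wildtype", "unknown"],
                            p=[0.25, 0.65, 0.10])),
        latent_chemosensitivity=s,
        latent_signaling=sig,
    )


def _channel_params(pop: str, channel: str, stained: bool):
    """(mean, sd) of log10 intensity.  ``stained=False`` (autofluorescence
    well) drops only the readout antibodies; surface stains (CD45, CD34,
    Amine Aqua) are present in every well so the well can be gated."""
    params = POPULATIONS[pop]
    if channel in ("FSC", "SSC"):
        return params[channel]
    if not stained and channel in READOUT_CHANNELS:
        return AUTOFLUOR
    return params.get(channel, params["default"])


def simulate_well(patient: PatientRecord, tissue: str, modulator: str,
                  time_hours: float, config: SimulationConfig,
                  rng: np.random.Generator, plate_id: str = "plate000",
                  plate_gain: dict[str, float] | None = None,
                  n_events: int | None = None,
                  population_fractions: dict[str, float] | None = None,
                  latent_s: float | None = None) -> EventTable:
    """Draw one well's events for a patient sample.

    Events come from the debris/dead/lymphocyte/blast mixture; the blast
    share of live leukocytes follows the tissue's blast percentage.  The
    modulator determines which readout channels shift and by how much:

    * ``autofluorescence`` — surface stains (CD45, CD34, Amine Aqua)
      present, readout channels at autofluorescence level;
    * ``unmodulated`` / ``untreated`` — full stain, no modulation;
    * short-term modulators (FLT3L, IL-27, PMA) — pathway readouts shift on
      blasts by the canonical response plus the patient's responsiveness
      noise (outcome-independent);
    * ``AraC+Dauno`` at 24 h — blast cPARP up, CD34 down, Amine Aqua up,
      each scaled by the patient's latent chemosensitivity.

    ``population_fractions`` overrides the mixture weights (keys among
    debris/dead/lymphocyte/blast, must sum to 1).  ``latent_s`` overrides
    the latent chemosensitivity driving the drug effect (used for
    secondary-AML PB decoupling).  True population labels are returned in
    ``meta["labels"]`` for gate validation.
    """
    if modulator not in KNOWN_MODULATORS:
        raise ConfigurationError(f"unknown modulator {modulator!r}")
    if n_events is None:
        n_events = int(rng.poisson(config.mean_events_per_well))
    s = patient.latent_chemosensitivity if latent_s is None else latent_s

    if population_fractions is None:
        blast_pct = (patient.bm_blast_pct if tissue == "BM"
                     else patient.pb_blast_pct)
        live = 1.0 - config.debris_frac - config.dead_frac
        population_fractions = {
            "debris": config.debris_frac,
            "dead": config.dead_frac,
            "blast": live * blast_pct / 100.0,
            "lymphocyte": live * (1.0 - blast_pct / 100.0),
        }
    pops = [p for p, f in population_fractions.items() if f > 0]
    weights = np.array([population_fractions[p] for p in pops], dtype=float)
    weights = weights / weights.sum()
    labels = rng.choice(len(pops), size=n_events, p=weights)

    stained = modulator != "autofluorescence"
    # per-population modulation shifts (log10 units)
    shifts: dict[str, dict[str, float]] = {p: {} for p in pops}
    if stained and modulator in SIGNALING_RESPONSES:
        _, resp = SIGNALING_RESPONSES[modulator]
        noise = patient.latent_signaling.get(modulator, {})
        for ch, base in resp.items():
            if "blast" in shifts:
                shifts["blast"][ch] = base + noise.get(ch, 0.0)
            if "lymphocyte" in shifts:
                shifts["lymphocyte"][ch] = 0.5 * base
    if stained and modulator == "AraC+Dauno":
        eps = patient.latent_signaling.get("AraC+Dauno", {})

        def s_eff(ch):
            return float(np.clip(s + eps.get(ch, 0.0), 0.0, 1.0))

        for p in ("blast",):
            if p in shifts:
                shifts[p]["cPARP"] = config.cparp_effect * s_eff("cPARP")
                shifts[p]["CD34"] = -config.cd34_effect * s_eff("CD34")
        for p in ("blast", "lymphocyte"):
            if p in shifts:
                shifts[p]["AquaAmine"] = (config.aqua_death_effect
                                          * s_eff("AquaAmine"))

    gain = plate_gain or {}
    cols = {}
    log10 = np.empty(n_events)
    for channel in CHANNELS:
        for k, pop in enumerate(pops):
            mu, sd = _channel_params(pop, channel, stained)
            mu = mu + shifts[pop].get(channel, 0.0)
            idx = labels == k
            log10[idx] = rng.normal(mu, sd, size=int(idx.sum()))
        g = gain.get(channel, 0.0)  # log10 plate gain; 0 on scatter
        cols[channel] = (10.0 ** (log10 + g)).astype(np.float32)

    well_id = f"{patient.patient_id}-{tissue}-{modulator}-{time_hours:g}h"
    return EventTable(
        well_id=well_id, patient_id=patient.patient_id, tissue=tissue,
        modulator=modulator, time_hours=time_hours,
        data=pd.DataFrame(cols), plate_id=plate_id,
        meta={"labels": np.array([pops[k] for k in labels]),
              "seeded": True, "scale": "raw"})


def simulate_beads(plate_id: str, config: SimulationConfig,
                   rng: np.random.Generator,
                   plate_gain: dict[str, float]) -> BeadPlateData:
    """8-peak rainbow-bead well for one plate.

    Peak intensities are the reference ERF times the plate's channel gain,
    with log-normal measurement noise, so a correct calibration fit
    recovers slope 1 and intercept log10(gain)."""
    peaks: dict[str, list[np.ndarray]] = {}
    for channel in FLUOR_CHANNELS:
        g = plate_gain.get(channel, 0.0)
        peaks[channel] = [
            (10.0 ** (math.log10(erf) + g
                      + rng.normal(0.0, config.bead_noise_sd,
                                   size=config.bead_events_per_peak)))
            .astype(np.float32)
            for erf in config.bead_reference_erf]
    return BeadPlateData(plate_id=plate_id,
                         reference_erf=config.bead_reference_erf,
                         peak_intensities=peaks)


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[list[PatientRecord], list[EventTable],
                               list[BeadPlateData]]:
    """Generate a full cohort: patients, all wells, and per-plate beads.

    Reproducible byte-for-byte given ``config.seed``.  Samples (patient x
    tissue) are assigned to plates of ``plate_size`` in arrival order; each
    plate carries its own multiplicative channel gains (removable by bead
    calibration) and one bead well.  Secondary-AML PB samples mix their
    latent chemosensitivity with an independent draw according to
    ``secondary_discordance``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients = [_draw_patient(i, config, rng) for i in range(config.n_patients)]

    samples = [(p, t) for p in patients for t in p.tissue_types]
    n_plates = max(1, math.ceil(len(samples) / config.plate_size))
    gains = [{ch: float(rng.normal(0.0, config.plate_gain_sd))
              for ch in FLUOR_CHANNELS} for _ in range(n_plates)]

    wells: list[EventTable] = []
    beads = [simulate_beads(f"plate{j:03d}", config, rng, gains[j])
             for j in range(n_plates)]
    for k, (patient, tissue) in enumerate(samples):
        j = k // config.plate_size
        latent_s = None
        if (tissue == "PB" and patient.onset == "secondary"
                and config.secondary_discordance > 0):
            w = config.secondary_discordance
            latent_s = float((1 - w) * patient.latent_chemosensitivity
                             + w * rng.uniform())
        for modulator, t in WELL_PLAN:
            wells.append(simulate_well(
                patient, tissue, modulator, t, config, rng,
                plate_id=f"plate{j:03d}", plate_gain=gains[j],
                latent_s=latent_s))
    return patients, wells, beads


def patients_to_frame(patients: Iterable[PatientRecord]) -> pd.DataFrame:
    """Cohort manifest: one row per patient (latent fields dropped)."""
    rows = []
    for p in patients:
        d = asdict(p)
        d.pop("latent_chemosensitivity")
        d.pop("latent_signaling")
        d["tissue_types"] = "+".join(p.tissue_types)
        rows.append(d)
    return pd.DataFrame(rows)
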