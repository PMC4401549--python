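# Default SCNP node panel: (modulator, exposure time, readout) triples with
# the gated population and reference well each node's metrics use.
# Short-term signaling nodes are computed on cPARP-negative ("healthy")
# blasts against the 15 min unmodulated well; the 24 h drug nodes are
# computed on all viable blasts against the untreated 24 h well, and the
# viability node on intact cells.
nodes:
  - modulator: AraC+Dauno
    time_hours: 24
    readout: cPARP
    population: blast
    u_modulator: untreated
    metrics: [Uu, PhIntact]
  - modulator: AraC+Dauno
    time_hours: 24
    readout: CD34
    population: blast
    u_modulator: untreated
    metrics: [Uu]
  - modulator: AraC+Dauno
    time_hours: 24
    readout: AquaAmine
    population: intact
    u_modulator: untreated
    metrics: [Uu]
  - modulator: FLT3L
    time_hours: 0.25
    readout: pAKT
    population: healthy_blast
    u_modulator: unmodulated
    metrics: [Basal, log2Fold, Uu, Ua]
  - modulator: FLT3L
    time_hours: 0.25
    readout: pERK
    population: healthy_blast
    u_modulator: unmodulated
    metrics: [Basal, log2Fold, Uu, Ua]
  - modulator: FLT3L
    time_hours: 0.25
    readout: pS6
    population: healthy_blast
    u_modulator: unmodulated
    metrics: [Basal, log2Fold, Uu, Ua]
  - modulator: IL-27
    time_hours: 0.25
    readout: pSTAT1
    population: healthy_blast
    u_modulator: unmodulated
    metrics: [Basal, log2Fold, Uu, Ua]
  - modulator: IL-27
    time_hours: 0.25
    readout: pSTAT3
    population: healthy_blast
    u_modulator: unmodulated
    metrics: [Basal, log2Fold, Uu, Ua]
  - modulator: IL-27
    time_hours: 0.25
    readout: pSTAT5
    population: healthy_blast
    u_modulator: unmodulated
    metrics: [Basal, log2Fold, Uu, Ua]
  - modulator: PMA
    time_hours: 0.25
    readout: pCREB
    population: healthy_blast
    u_modulator: unmodulated
    metrics: [Basal, log2Fold, Uu, Ua]
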