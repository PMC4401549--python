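{
 "name": "DX_SCNP",
 "version": "1.0",
 "description": "Locked two-node logistic induction-response classifier for elderly AML: hinge-squared transforms of the 24 h AraC+daunorubicin cPARP and CD34 Uu node metrics.",
 "intercept": -1.26004,
 "components": [
  {
   "name": "C1",
   "coefficient": 95.60133,
   "node_id": "AraC+Dauno|24h|cPARP",
   "metric": "Uu",
   "transform": "hinge_sq_above",
   "center": 0.5
  },
  {
   "name": "C2",
   "coefficient": 34.94358,
   "node_id": "AraC+Dauno|24h|CD34",
   "metric": "Uu",
   "transform": "hinge_sq_below",
   "center": 0.5
  }
 ]
}
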