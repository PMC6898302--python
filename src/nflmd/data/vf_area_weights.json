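{
  "schema": "nflmd-vf-area-weights",
  "version": 1,
  "source": "figure-constants",
  "comment": "VF-area weights for the 16 peripapillary sectors (24-2 test-point counts mapped through the modified Garway-Heath scheme; total 52). The inferior-most inferotemporal sector weight (IT1 = 7.64) is anchored by the focal-loss worked example; its superior mirror and the remaining sectors follow the modified Garway-Heath allocation with arcuate sectors weighted most.",
  "weights": {
    "TU1": 1.5,
    "TU2": 2.5,
    "ST2": 5.5,
    "ST1": 7.5,
    "SN1": 4.0,
    "SN2": 2.0,
    "NU2": 1.25,
    "NU1": 1.0,
    "NL1": 1.0,
    "NL2": 1.25,
    "IN2": 2.0,
    "IN1": 4.25,
    "IT1": 7.64,
    "IT2": 5.75,
    "TL2": 2.75,
    "TL1": 2.11
  }
}
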