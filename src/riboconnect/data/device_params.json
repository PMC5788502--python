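{
  "note": "Calibration of the packaged reference devices. K (uM) and h are sensor occupancy parameters; Emax_r is maximal fractional repression; Fmax is maximal fold-activation, calibrated so the reference 2x-eIF4G activator reproduces its saturating 15-fold measurement at full efficacy and reference valency; kappa is the valency half-saturation constant in aptamer copies. Protein sensors use concentrations in arbitrary cellular units with K = 1.0.",
  "logic_high_uM": {
    "theophylline": 1000.0,
    "tetracycline": 100.0
  },
  "devices": {
    "theophylline_repressor_2x": {
      "mode": "repression",
      "K": 300.0,
      "h": 1.3,
      "Emax_r": 0.9,
      "Fmax": 1.0,
      "kappa": 0.5,
      "copies": 2
    },
    "tetracycline_repressor_2x": {
      "mode": "repression",
      "K": 20.0,
      "h": 1.3,
      "Emax_r": 0.9,
      "Fmax": 1.0,
      "kappa": 0.5,
      "copies": 2
    },
    "eif4g_activator_2x": {
      "mode": "activation",
      "K": 300.0,
      "h": 1.3,
      "Emax_r": 0.0,
      "Fmax": 15.0,
      "kappa": 0.5,
      "copies": 2
    },
    "theophylline_eif4g_switch_2x": {
      "mode": "activation",
      "K": 300.0,
      "h": 1.3,
      "Emax_r": 0.0,
      "Fmax": 15.0,
      "kappa": 0.5,
      "copies": 2
    },
    "tetracycline_eif4g_switch_2x": {
      "mode": "activation",
      "K": 20.0,
      "h": 1.3,
      "Emax_r": 0.0,
      "Fmax": 15.0,
      "kappa": 0.5,
      "copies": 2
    },
    "protein_sensor_repressor_2x": {
      "mode": "repression",
      "K": 1.0,
      "h": 1.5,
      "Emax_r": 0.9,
      "Fmax": 1.0,
      "kappa": 0.5,
      "copies": 2
    },
    "protein_sensor_activator_2x": {
      "mode": "activation",
      "K": 1.0,
      "h": 1.5,
      "Emax_r": 0.0,
      "Fmax": 15.0,
      "kappa": 0.5,
      "copies": 2
    }
  }
}
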