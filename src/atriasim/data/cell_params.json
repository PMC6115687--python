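{
  "_provenance": "Biophysically detailed human atrial myocyte formulation (Courtemanche-family ionic model, 21 state variables) with a crista-terminalis regional variant from the same model lineage (ICaL x1.68). Units: conductances nS/pF, currents pA/pF, concentrations mM, time ms, potential mV, volumes um^3. The phenomenological entry is a two-variable excitable model (Mitchell-Schaeffer form) used for cheap geometry tests only.",
  "atrial_detailed": {
    "constants": {
      "R": 8.3143,
      "T": 310.0,
      "F": 96.4867,
      "Cm_pF": 100.0,
      "Vi": 13668.0,
      "Vup": 1109.52,
      "Vrel": 96.48,
      "Ko": 5.4,
      "Nao": 140.0,
      "Cao": 1.8,
      "KQ10": 3.0,
      "gamma": 0.35,
      "KmNai": 10.0,
      "KmKo": 1.5,
      "KmNa": 87.5,
      "KmCa": 1.38,
      "ksat": 0.1,
      "kup": 0.00092,
      "Ca_up_max": 15.0,
      "Cmdn_max": 0.05,
      "Trpn_max": 0.07,
      "Csqn_max": 10.0,
      "KmCmdn": 0.00238,
      "KmTrpn": 0.0005,
      "KmCsqn": 0.8,
      "tau_tr": 180.0,
      "tau_u": 8.0,
      "tau_fca": 2.0
    },
    "conductances": {
      "gNa": 7.8,
      "gK1": 0.09,
      "gto": 0.1652,
      "gKr": 0.029411765,
      "gKs": 0.12941176,
      "gCaL": 0.12375,
      "gbCa": 0.001131,
      "gbNa": 0.0006744375,
      "INaK_max": 0.59933874,
      "INaCa_max": 1600.0,
      "IpCa_max": 0.275,
      "Iup_max": 0.005,
      "krel": 30.0
    },
    "variants": {
      "RA": {},
      "CT": {
        "gCaL": 1.68
      }
    },
    "initial_state": {
      "V": -81.18,
      "m": 0.002908,
      "h": 0.9649,
      "j": 0.9775,
      "oa": 0.03043,
      "oi": 0.9992,
      "ua": 0.004966,
      "ui": 0.9986,
      "xr": 3.296e-05,
      "xs": 0.01869,
      "d": 0.0001367,
      "f": 0.9996,
      "fca": 0.7755,
      "u": 0.0,
      "v": 1.0,
      "w": 0.9992,
      "Nai": 11.17,
      "Ki": 139.0,
      "Cai": 0.0001013,
      "Ca_up": 1.488,
      "Ca_rel": 1.488
    },
    "stable_dt_ms": 0.02
  },
  "phenomenological": {
    "constants": {
      "V_rest": -85.0,
      "V_amp": 105.0
    },
    "conductances": {
      "tau_in": 0.3,
      "tau_out": 6.0,
      "tau_open": 120.0,
      "tau_close": 150.0,
      "v_gate": 0.13
    },
    "variants": {
      "RA": {},
      "CT": {
        "tau_close": 1.2
      }
    },
    "initial_state": {
      "V": -85.0,
      "w_gate": 1.0
    },
    "stable_dt_ms": 0.05
  }
}
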