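{
  "version": 1,
  "comment": "CT-value to density to Young's-modulus mapping for mandibular bone, plus homogeneous constants. Units: HU, kg/m^3, MPa. The printed modulus ranges for the bone regimes are metadata only; the power laws are authoritative.",
  "bone_regimes": [
    {
      "name": "trabecular",
      "hu": [-1000.0, 500.0],
      "density": [0.0, 1000.0],
      "law_coefficient": 0.0004,
      "law_exponent": 2.01,
      "poisson": 0.3,
      "printed_modulus_range_MPa": [180.0, 380.0]
    },
    {
      "name": "cortical",
      "hu": [501.0, 1500.0],
      "density": [1001.0, 2000.0],
      "law_coefficient": 0.005,
      "law_exponent": 2.01,
      "poisson": 0.3,
      "printed_modulus_range_MPa": [11300.0, 22900.0]
    }
  ],
  "constants": {
    "titanium": {"E": 113800.0, "poisson": 0.342},
    "dentin": {"E": 24535.0, "poisson": 0.3},
    "enamel": {"E": 39605.0, "poisson": 0.3},
    "uniform_bone": {"E": 10000.0, "poisson": 0.3}
  },
  "tooth_split_hu": 2000.0,
  "modulus_floor_MPa": 0.01
}
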