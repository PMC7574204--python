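{
  "version": 1,
  "comment": "Biodiesel fuel-standard limits. Keys: property -> {min, max}; units match FuelPropertyReport (iv g I2/100 g; cn dimensionless; density g/cm3; kv40 mm2/s). The 'as-printed' set transcribes the study's comparison table, whose EN/ASTM columns for CN and KV appear swapped relative to the official standards; the 'literature' set carries the official limits.",
  "sets": {
    "as-printed": {
      "EN14214": {"iv": {"max": 120.0}, "cn": {"min": 47.0}, "kv40": {"min": 1.9, "max": 6.0}},
      "ASTMD6751": {"cn": {"min": 51.0}, "kv40": {"min": 3.5, "max": 5.0}, "density": {"min": 0.86, "max": 0.90}},
      "IS15607": {"cn": {"min": 51.0}, "kv40": {"min": 2.5, "max": 6.0}, "density": {"min": 0.86, "max": 0.89}}
    },
    "literature": {
      "EN14214": {"iv": {"max": 120.0}, "cn": {"min": 51.0}, "kv40": {"min": 3.5, "max": 5.0}, "density": {"min": 0.86, "max": 0.90}},
      "ASTMD6751": {"cn": {"min": 47.0}, "kv40": {"min": 1.9, "max": 6.0}},
      "IS15607": {"cn": {"min": 51.0}, "kv40": {"min": 2.5, "max": 6.0}, "density": {"min": 0.86, "max": 0.89}}
    }
  }
}
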