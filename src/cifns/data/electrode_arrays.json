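{
  "version": 1,
  "arrays": [
    {"name": "Standard", "array_length_mm": 31.5, "active_length_mm": 26.4, "spacing_mm": 2.4, "n_contacts": 12},
    {"name": "FLEXsoft", "array_length_mm": 31.5, "active_length_mm": 26.4, "spacing_mm": 2.4, "n_contacts": 12},
    {"name": "FLEX28", "array_length_mm": 28.0, "active_length_mm": 23.1, "spacing_mm": 2.1, "n_contacts": 12},
    {"name": "FLEX24", "array_length_mm": 24.0, "active_length_mm": 20.9, "spacing_mm": 1.9, "n_contacts": 12}
  ]
}
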