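{
  "version": 1,
  "note": "Per-subject study records: demographics, stimulation levels (CU) with printed charge levels (QU), shortest-EFND contact, insertion P estimates per channel, and post-insertion peak-contact sets at the 75% normalized-amplitude threshold.",
  "subjects": [
    {
      "id": "S1", "age": 34, "sex": "F", "electrode_type": "Standard", "etiology": "Otosclerosis",
      "insertion_current_cu": 614.25, "insertion_charge_qu_printed": 92.138,
      "postinsertion_current_cu": 519.75, "postinsertion_charge_qu_printed": 77.963,
      "shortest_efnd_contact": 6, "p_oculi": 6, "p_oris": 6,
      "peaks_periocular": [6], "peaks_perioral": [6]
    },
    {
      "id": "S2", "age": 29, "sex": "F", "electrode_type": "FLEX28", "etiology": "Neurofibromatosis type II",
      "insertion_current_cu": null, "insertion_charge_qu_printed": null,
      "postinsertion_current_cu": 1134.0, "postinsertion_charge_qu_printed": 170.1,
      "shortest_efnd_contact": 6, "p_oculi": null, "p_oris": null,
      "peaks_periocular": [6, 7], "peaks_perioral": [5, 6, 7]
    },
    {
      "id": "S3", "age": 84, "sex": "F", "electrode_type": "FLEX28", "etiology": "Idiopathic",
      "insertion_current_cu": 378.0, "insertion_charge_qu_printed": 56.7,
      "postinsertion_current_cu": 378.0, "postinsertion_charge_qu_printed": 56.7,
      "shortest_efnd_contact": 6, "p_oculi": 6, "p_oris": 6,
      "peaks_periocular": [4], "peaks_perioral": [2, 4, 5]
    },
    {
      "id": "S4", "age": 71, "sex": "M", "electrode_type": "FLEX28", "etiology": "Idiopathic",
      "insertion_current_cu": 472.5, "insertion_charge_qu_printed": 70.875,
      "postinsertion_current_cu": 661.5, "postinsertion_charge_qu_printed": 99.225,
      "shortest_efnd_contact": 6, "p_oculi": 6, "p_oris": 4,
      "peaks_periocular": [2, 5], "peaks_perioral": [2, 5]
    },
    {
      "id": "S5", "age": 57, "sex": "F", "electrode_type": "Standard", "etiology": "Idiopathic",
      "insertion_current_cu": 472.5, "insertion_charge_qu_printed": 70.875,
      "postinsertion_current_cu": 311.85, "postinsertion_charge_qu_printed": 46.778,
      "shortest_efnd_contact": 6, "p_oculi": 2, "p_oris": 2,
      "peaks_periocular": [6], "peaks_perioral": [4, 5, 6]
    },
    {
      "id": "S6", "age": 58, "sex": "F", "electrode_type": "FLEX28", "etiology": "Sudden sensorineural hearing loss",
      "insertion_current_cu": 472.5, "insertion_charge_qu_printed": 70.875,
      "postinsertion_current_cu": 519.75, "postinsertion_charge_qu_printed": 77.963,
      "shortest_efnd_contact": 6, "p_oculi": 6, "p_oris": 6,
      "peaks_periocular": [6], "peaks_perioral": [2]
    },
    {
      "id": "S7", "age": 76, "sex": "F", "electrode_type": "FLEXsoft", "etiology": "Sudden sensorineural hearing loss",
      "insertion_current_cu": 378.0, "insertion_charge_qu_printed": 56.7,
      "postinsertion_current_cu": 378.0, "postinsertion_charge_qu_printed": 56.7,
      "shortest_efnd_contact": 6, "p_oculi": 4, "p_oris": 4,
      "peaks_periocular": [2, 4, 10], "peaks_perioral": [2, 4, 6, 7]
    },
    {
      "id": "S8", "age": 32, "sex": "M", "electrode_type": "FLEX24", "etiology": "Idiopathic",
      "insertion_current_cu": 425.25, "insertion_charge_qu_printed": 63.788,
      "postinsertion_current_cu": 425.25, "postinsertion_charge_qu_printed": 63.788,
      "shortest_efnd_contact": 3, "p_oculi": 2, "p_oris": 2,
      "peaks_periocular": [1, 3, 4, 5], "peaks_perioral": [1, 3, 4, 5]
    },
    {
      "id": "S9", "age": 32, "sex": "F", "electrode_type": "FLEX24", "etiology": "Idiopathic",
      "insertion_current_cu": 378.0, "insertion_charge_qu_printed": 56.7,
      "postinsertion_current_cu": 330.75, "postinsertion_charge_qu_printed": 49.613,
      "shortest_efnd_contact": 4, "p_oculi": 4, "p_oris": 4,
      "peaks_periocular": [5], "peaks_perioral": [3]
    }
  ]
}
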