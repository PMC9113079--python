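{
  "comment": "Printed vFFR values cited in the study narrative, mapped to the unique sweep row that reproduces each. Entries with a target id are quantitative acceptance targets (tolerance 0.05); the remainder document the row mapping only.",
  "rows": [
    {"target": "t1", "row_id": "T2-ds70-conc-rounded-focal", "mvr_setting": "standard", "paper_vffr": 0.90},
    {"target": "t2", "row_id": "T2-ds80-conc-rounded-focal", "mvr_setting": "standard", "paper_vffr": 0.68},
    {"target": "t3", "row_id": "T2-ds70-conc-rect", "mvr_setting": "standard", "paper_vffr": 0.80},
    {"target": "t4", "row_id": "T2-ds80-conc-rect", "mvr_setting": "standard", "paper_vffr": 0.50},
    {"target": "t5", "row_id": "T3-L10-ds70-conc-rounded-focal", "mvr_setting": "standard", "paper_vffr": 0.89},
    {"target": "t6", "row_id": "T3-L10-ds70-conc-rounded-uniform", "mvr_setting": "standard", "paper_vffr": 0.77},
    {"target": "t7", "row_id": "T4-n2-ds70-conc-rounded-focal", "mvr_setting": "standard", "paper_vffr": 0.82},
    {"target": "t8", "row_id": "T4-n3-ds70-conc-rounded-focal", "mvr_setting": "standard", "paper_vffr": 0.77},
    {"target": "t9", "row_id": "T4-n3-ds70-conc-rounded-uniform", "mvr_setting": "standard", "paper_vffr": 0.63},
    {"target": null, "row_id": "T4-n2-ds70-conc-rounded-uniform", "mvr_setting": "standard", "paper_vffr": 0.70},
    {"target": null, "row_id": "T3-L30-ds70-conc-rounded-focal", "mvr_setting": "standard", "paper_vffr": 0.86},
    {"target": null, "row_id": "T3-L30-ds70-conc-rounded-uniform", "mvr_setting": "standard", "paper_vffr": 0.63},
    {"target": null, "row_id": "T3-L20-ds80-ecce-rounded-uniform", "mvr_setting": "standard", "paper_vffr": 0.75},
    {"target": null, "row_id": "T3-L30-ds80-ecce-rounded-uniform", "mvr_setting": "standard", "paper_vffr": 0.69},
    {"target": null, "row_id": "T4-n2-ds80-ecce-rounded-uniform", "mvr_setting": "standard", "paper_vffr": 0.78},
    {"target": null, "row_id": "T4-n3-ds80-ecce-rounded-uniform", "mvr_setting": "standard", "paper_vffr": 0.70},
    {"target": null, "row_id": "T5-low-T2-ds70-conc-rounded-focal", "mvr_setting": "low", "paper_vffr": 0.85},
    {"target": null, "row_id": "T5-high-T2-ds70-conc-rounded-focal", "mvr_setting": "high", "paper_vffr": 0.92},
    {"target": null, "row_id": "T5-standard-T4-n2-ds70-conc-rounded-focal", "mvr_setting": "standard", "paper_vffr": 0.82},
    {"target": null, "row_id": "T5-low-T4-n2-ds70-conc-rounded-focal", "mvr_setting": "low", "paper_vffr": 0.76},
    {"target": null, "row_id": "T5-high-T4-n2-ds70-conc-rounded-focal", "mvr_setting": "high", "paper_vffr": 0.86}
  ]
}
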