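{
  "schema": "filmdose-protocols-1",
  "protocols": [
    {"machine": "OBI_21eX", "site": "head", "technique": "Standard dose, FF (200deg)", "modality": "kV", "kvp": 100, "hvl_mm_al": 4.9, "mAs_or_MU": 145, "n_acquisitions_measured": 5, "reporting_unit": "per CBCT scan"},
    {"machine": "OBI_21eX", "site": "thorax", "technique": "Low Dose Thorax, HF (360deg)", "modality": "kV", "kvp": 110, "hvl_mm_al": 5.2, "mAs_or_MU": 262, "n_acquisitions_measured": 5, "reporting_unit": "per CBCT scan"},
    {"machine": "OBI_21eX", "site": "pelvis", "technique": "Pelvis, HF (360deg)", "modality": "kV", "kvp": 125, "hvl_mm_al": 5.8, "mAs_or_MU": 1049, "n_acquisitions_measured": 5, "reporting_unit": "per CBCT scan"},
    {"machine": "OBI_TrueBeam", "site": "head", "technique": "Standard dose, FF (200deg)", "modality": "kV", "kvp": 100, "hvl_mm_al": 6.9, "mAs_or_MU": 146, "n_acquisitions_measured": 5, "reporting_unit": "per CBCT scan"},
    {"machine": "OBI_TrueBeam", "site": "thorax", "technique": "Thorax Slow, HF (360deg)", "modality": "kV", "kvp": 125, "hvl_mm_al": 7.7, "mAs_or_MU": 252, "n_acquisitions_measured": 5, "reporting_unit": "per CBCT scan"},
    {"machine": "OBI_TrueBeam", "site": "pelvis", "technique": "Pelvis, HF (360deg)", "modality": "kV", "kvp": 125, "hvl_mm_al": 7.7, "mAs_or_MU": 1056, "n_acquisitions_measured": 5, "reporting_unit": "per CBCT scan"},
    {"machine": "CyberKnife", "site": "head", "technique": "6D Skull / 100 image pairs", "modality": "kV", "kvp": 100, "hvl_mm_al": 5.4, "mAs_or_MU": 1250, "n_acquisitions_measured": 1, "reporting_unit": "per 100 image pairs"},
    {"machine": "CyberKnife", "site": "thorax", "technique": "C-spine / 100 image pairs", "modality": "kV", "kvp": 110, "hvl_mm_al": 5.7, "mAs_or_MU": 1500, "n_acquisitions_measured": 1, "reporting_unit": "per 100 image pairs"},
    {"machine": "CyberKnife", "site": "pelvis", "technique": "L-Spine / 100 image pairs", "modality": "kV", "kvp": 125, "hvl_mm_al": 6.4, "mAs_or_MU": 4000, "n_acquisitions_measured": 1, "reporting_unit": "per 100 image pairs"},
    {"machine": "TomoTherapy", "site": "head", "technique": "Pitch 2 (TG 148)", "modality": "MV", "mv_nominal": 3.5, "mAs_or_MU": 6.4, "n_acquisitions_measured": 5, "reporting_unit": "per MVCT scan"},
    {"machine": "TomoTherapy", "site": "thorax", "technique": "Pitch 2 (TG 148)", "modality": "MV", "mv_nominal": 3.5, "mAs_or_MU": 6.4, "n_acquisitions_measured": 5, "reporting_unit": "per MVCT scan"},
    {"machine": "TomoTherapy", "site": "pelvis", "technique": "Pitch 2 (TG 148)", "modality": "MV", "mv_nominal": 3.5, "mAs_or_MU": 6.4, "n_acquisitions_measured": 5, "reporting_unit": "per MVCT scan"}
  ]
}
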