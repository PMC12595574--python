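[
 {"factor_id": "F1", "label": "Resident needs"},
 {"factor_id": "F2", "label": "Resident-level motivator F2 (placeholder label)"},
 {"factor_id": "F3", "label": "Residents' adherence"},
 {"factor_id": "F4", "label": "Residents' trust level"},
 {"factor_id": "F5", "label": "Professional identity of team members"},
 {"factor_id": "F6", "label": "Professional competence of team members"},
 {"factor_id": "F7", "label": "Teamwork"},
 {"factor_id": "F8", "label": "Team-level motivator F8 (placeholder label)"},
 {"factor_id": "F9", "label": "Team-level motivator F9 (placeholder label)"},
 {"factor_id": "F10", "label": "Institutional management measures"},
 {"factor_id": "F11", "label": "Resource allocation of personnel, finances, and materials"},
 {"factor_id": "F12", "label": "IT infrastructure development"},
 {"factor_id": "F13", "label": "Interdepartmental collaboration"},
 {"factor_id": "F14", "label": "Government-level motivator F14 (placeholder label)"},
 {"factor_id": "F15", "label": "Supervision and management"}
]
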