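"""Versioned default term pools for the synthetic corpus generator (v1).

Pools within one labeling scheme are pairwise disjoint and disjoint from the
shared pool, so that a zero-overlap configuration yields lexically separable
classes. Multi-word severity indicator phrases are emitted as consecutive
tokens; downstream bag-of-words modeling discards the order anyway.
"""

POOLS_VERSION = "1"

#: Ordered incident-type label scheme: ten priority problem areas plus a
#: catch-all class. The order is fixed; it drives DAG node layout.
TYPE_LABELS = (
    "falls",
    "medications",
    "pressure_injury",
    "aggression",
    "documentation",
    "blood_product",
    "patient_identification",
    "infection",
    "clinical_handover",
    "deteriorating_patient",
    "others",
)

#: Ordered severity scheme, extreme (SAC1) to low risk (SAC4).
SAC_LABELS = ("SAC1", "SAC2", "SAC3", "SAC4")

SHARED_TERMS = [
    "patient", "ward", "nurse", "staff", "doctor", "hospital", "bed",
    "room", "review", "noted", "reported", "observed", "during", "night",
    "morning", "care", "unit", "team", "family", "arrived", "called",
    "stated", "found", "later", "today",
]

TYPE_TERM_POOLS = {
    "falls": [
        "fell", "fall", "slipped", "tripped", "floor", "fracture", "bruise",
        "hip", "balance", "unwitnessed", "mobility", "walking", "frame",
        "toilet", "standing", "laceration",
    ],
    "medications": [
        "medication", "dose", "drug", "tablet", "insulin", "warfarin",
        "prescribed", "pharmacy", "milligrams", "overdose", "missed",
        "administered", "syringe", "antibiotic", "infusion", "dispensed",
    ],
    "pressure_injury": [
        "pressure", "ulcer", "sacrum", "heel", "skin", "wound", "dressing",
        "stage", "redness", "mattress", "repositioned", "blister", "bony",
        "tissue",
    ],
    "aggression": [
        "aggressive", "abusive", "punched", "hit", "shouting", "threatened",
        "violence", "security", "assaulted", "kicked", "abuse", "angry",
        "restrained", "swearing",
    ],
    "documentation": [
        "documentation", "chart", "form", "label", "paperwork", "signed",
        "entry", "incomplete", "missing", "filed", "consent", "notes",
        "illegible", "outdated",
    ],
    "blood_product": [
        "blood", "transfusion", "packed", "cells", "platelets", "crossmatch",
        "units", "group", "plasma", "haemoglobin", "bag", "compatibility",
    ],
    "patient_identification": [
        "identification", "wristband", "armband", "identity", "mismatch",
        "specimen", "labelled", "wrong", "verification", "birth", "surname",
        "misidentified",
    ],
    "infection": [
        "infection", "sepsis", "fever", "swab", "culture", "isolation",
        "mrsa", "cellulitis", "temperature", "infectious", "pus",
        "contaminated",
    ],
    "clinical_handover": [
        "handover", "shift", "communication", "informed", "briefing",
        "omitted", "relayed", "outgoing", "incoming", "unaware", "conveyed",
    ],
    "deteriorating_patient": [
        "deteriorating", "deteriorated", "unresponsive", "hypotension",
        "tachycardia", "saturation", "oxygen", "collapsed", "rapid",
        "response", "mews", "resuscitation", "cyanosed", "drowsy",
    ],
    "others": [
        "equipment", "faulty", "delay", "appointment", "food", "diet",
        "property", "lost", "cleaning", "maintenance", "telephone", "spill",
        "waste", "linen",
    ],
}

SAC_TERM_POOLS = {
    "SAC1": [
        "died", "fatal", "arrest", "emergency", "critical", "severe",
        "irreversible", "catastrophic", "coroner", "resuscitated",
    ],
    "SAC2": [
        "serious", "major", "harm", "injury", "permanent", "disability",
        "prolonged", "admission", "escalation", "urgent",
    ],
    "SAC3": [
        "moderate", "treatment", "required", "additional", "observation",
        "monitoring", "reviewed", "extended", "intervention", "temporary",
    ],
    "SAC4": [
        "minor", "minimal", "near", "miss", "avoided", "trivial",
        "superficial", "resolved", "reassured", "nil",
    ],
}

#: Indicator phrases injected into severity corpora; the extreme-risk pool
#: carries the canonical red-flag phrases (multi-word phrases stay contiguous).
SAC_KEYWORD_POOLS = {
    "SAC1": [
        "death", "suicide", "high risk", "police notified",
        "incorrect patient", "infection", "blood transfusion reaction",
        "aggression",
    ],
    "SAC2": [
        "significant harm", "urgent review", "specialist referral",
        "unplanned return",
    ],
    "SAC3": [
        "extra monitoring", "brief treatment", "additional observation",
    ],
    "SAC4": [
        "nil outcome", "near miss", "minimal impact",
    ],
}
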