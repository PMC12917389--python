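"""Standard 12-lead names and the lead-contiguity table.

Contiguity follows the anatomical chain convention used for ST-criteria:
inferior II-III-aVF, lateral I-aVL-V5-V6, anterior V1-V2-V3-V4, with V4-V5
linking the anterior and lateral chains.
"""

from __future__ import annotations

LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

LEAD_INDEX: dict[str, int] = {name: i for i, name in enumerate(LEADS)}

# Adjacent (contiguous) lead pairs.  An ischemia event requires the cutoff to
# be exceeded in at least one such pair.
CONTIGUOUS_PAIRS: tuple[tuple[str, str], ...] = (
    ("II", "III"), ("III", "aVF"),            # inferior chain
    ("I", "aVL"), ("aVL", "V5"), ("V5", "V6"),  # lateral chain
    ("V1", "V2"), ("V2", "V3"), ("V3", "V4"),   # anterior chain
    ("V4", "V5"),                               # anterior-lateral link
)

# Common alternative channel labels mapped to the standard names.
LEAD_ALIASES: dict[str, str] = {
    "AVR": "aVR", "AVL": "aVL", "AVF": "aVF",
    "LEAD I": "I", "LEAD II": "II", "LEAD III": "III",
    "ECG I": "I", "ECG II": "II", "ECG III": "III",
}
for _lead in LEADS:
    LEAD_ALIASES[_lead.upper()] = _lead
    LEAD_ALIASES[_lead] = _lead


def normalize_lead(label: str) -> str:
    """Map a channel label to its standard 12-lead name.

    Raises ``ValueError`` for labels that cannot be mapped (e.g. "MLII").
    """
    key = label.strip()
    if key in LEAD_ALIASES:
        return LEAD_ALIASES[key]
    if key.upper() in LEAD_ALIASES:
        return LEAD_ALIASES[key.upper()]
    raise ValueError(f"unmapped ECG channel label: {label!r}")


def pair_indices() -> list[tuple[int, int]]:
    return [(LEAD_INDEX[a], LEAD_INDEX[b]) for a, b in CONTIGUOUS_PAIRS]
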