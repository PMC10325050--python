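"""Canonical 10-20 electrode set, aliases, hemispheres, montage and scalp layout.

The pipeline standardizes every recording to the 19 electrodes of the
international 10-20 system, in a fixed canonical order that every downstream
stage (feature registry, topographic maps, sensor-fusion paths) relies on.
"""

from __future__ import annotations

# Canonical order. All channel-indexed quantities in the package follow it.
CANONICAL_19: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "FZ", "CZ", "PZ",
)

N_CHANNELS = len(CANONICAL_19)

# Legacy 10-20 names mapped to the modern nomenclature.
ALIASES: dict[str, str] = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

LEFT_HEMISPHERE: frozenset[str] = frozenset(
    {"FP1", "F3", "C3", "P3", "O1", "F7", "T7", "P7"}
)
RIGHT_HEMISPHERE: frozenset[str] = frozenset(
    {"FP2", "F4", "C4", "P4", "O2", "F8", "T8", "P8"}
)
MIDLINE: frozenset[str] = frozenset({"FZ", "CZ", "PZ"})

# Bipolar longitudinal ("double banana") montage: 18 chained pairs.
DOUBLE_BANANA: tuple[tuple[str, str], ...] = (
    ("FP1", "F7"), ("F7", "T7"), ("T7", "P7"), ("P7", "O1"),
    ("FP1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("FZ", "CZ"), ("CZ", "PZ"),
    ("FP2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("FP2", "F8"), ("F8", "T8"), ("T8", "P8"), ("P8", "O2"),
)

# Schematic 2-D scalp positions (azimuthal projection, head disc of radius 1,
# +x toward the right ear, +y toward the nasion). Approximate layout used for
# topographic-map interpolation; only relative geometry matters.
SCALP_POSITIONS: dict[str, tuple[float, float]] = {
    "FP1": (-0.28, 0.85), "FP2": (0.28, 0.85),
    "F7": (-0.72, 0.52), "F3": (-0.35, 0.48), "FZ": (0.0, 0.445),
    "F4": (0.35, 0.48), "F8": (0.72, 0.52),
    "T7": (-0.89, 0.0), "C3": (-0.445, 0.0), "CZ": (0.0, 0.0),
    "C4": (0.445, 0.0), "T8": (0.89, 0.0),
    "P7": (-0.72, -0.52), "P3": (-0.35, -0.48), "PZ": (0.0, -0.445),
    "P4": (0.35, -0.48), "P8": (0.72, -0.52),
    "O1": (-0.28, -0.85), "O2": (0.28, -0.85),
}


def normalize_name(name: str) -> str:
    """Normalize an electrode label: case, common prefixes/suffixes, aliases.

    Handles the labelling dialects seen in clinical EDF files, e.g.
    ``"EEG T3-REF"`` -> ``"T7"``.
    """
    s = name.strip().upper()
    if s.startswith("EEG "):
        s = s[4:]
    for suffix in ("-REF", "-LE", "-AVG"):
        if s.endswith(suffix):
            s = s[: -len(suffix)]
    s = s.strip()
    return ALIASES.get(s, s)


def canonical_index(name: str) -> int:
    return CANONICAL_19.index(normalize_name(name))
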