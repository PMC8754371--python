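"""Anatomical label -> region-of-interest assignment for bipolar sites.

The four core ROIs are the inferior occipital cortex (IOC), fusiform cortex
(FC), inferior temporal cortex (ITC), and superior temporal cortex (STC),
each defined as a fixed set of sulcal/gyral structures; the intraparietal
sulcus (IPS) is kept as a separate exploratory region.  Anything else maps
to "other" (never silently: a warning is emitted for labels outside the
controlled vocabulary).
"""

from __future__ import annotations

import warnings

ROI_VOCABULARY = {
    "FC": (
        "fusiform gyrus",
        "occipitotemporal sulcus",
        "collateral sulcus",
        "midfusiform sulcus",
    ),
    "IOC": (
        "inferior occipital gyrus",
        "inferior occipital sulcus",
        "lateral occipital sulcus",
        "midoccipital gyrus",
        "fourth occipital gyrus",
        "transverse posterior collateral sulcus",
    ),
    "STC": (
        "superior temporal sulcus",
        "middle temporal gyrus",
        "superior temporal gyrus",
    ),
    "ITC": (
        "inferior temporal sulcus",
        "inferior temporal gyrus",
    ),
    "IPS": ("intraparietal sulcus",),
}

_LABEL_TO_ROI = {
    label: roi for roi, labels in ROI_VOCABULARY.items() for label in labels
}


def assign_roi(label: str, mni=None) -> str:
    """Map an anatomical label to its ROI ("other" if not in any list)."""
    key = label.strip().lower()
    roi = _LABEL_TO_ROI.get(key)
    if roi is None:
        warnings.warn(f"anatomical label {label!r} not in ROI vocabulary; "
                      "assigning 'other'", stacklevel=2)
        return "other"
    return roi


def hemisphere_of(x: float) -> str:
    """Hemisphere from the sign of the MNI x coordinate (x < 0 -> left).

    A site exactly on the midline (x == 0) is assigned to the right
    hemisphere by convention (deterministic tie-break).
    """
    return "L" if x < 0 else "R"
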