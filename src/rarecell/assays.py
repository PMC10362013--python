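"""Assay panels, channel-group vocabulary and per-sample metadata.

Two immunofluorescence panels are supported:

* ``landscape`` — DAPI (nucleus), pan-cytokeratin (CK, epithelial),
  vimentin (Vim, mesenchymal) and a pooled CD45/CD31 channel
  (immune/endothelial).
* ``epcam`` — DAPI, pan-CK, EpCAM and CD45.

Every DAPI-positive rare cell is assigned to exactly one of eight
channel-based groups, one per combination of the three non-nuclear
marker positivities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

LANDSCAPE = "landscape"
EPCAM = "epcam"

SCLC = "SCLC"
ND = "ND"
COHORTS = (SCLC, ND)

#: intensity column -> display name, per assay (order is significant: the
#: positivity bitmask over this order maps bijectively onto the 8 groups)
ASSAY_MARKERS: dict[str, list[tuple[str, str]]] = {
    LANDSCAPE: [("ck", "CK"), ("vim", "Vim"), ("cd45cd31", "(CD45/CD31)")],
    EPCAM: [("ck", "CK"), ("epcam", "EpCAM"), ("cd45", "CD45")],
}

#: group enumeration order used in tables and reports
_GROUP_MASKS = [
    (True, False, False),
    (True, True, False),
    (True, False, True),
    (True, True, True),
    (False, True, False),
    (False, True, True),
    (False, False, True),
    (False, False, False),
]

#: morphometric feature-name prefixes, keyed by assay channel column
CHANNEL_PREFIXES = {"ck": "CK", "vim": "Vim", "cd45cd31": "CD45CD31", "dapi": "DAPI"}


def group_name(assay: str, positives: tuple[bool, bool, bool]) -> str:
    """Name of the channel group for a marker-positivity combination.

    An event with no positive marker beyond the nuclear stain falls in the
    ``DAPI`` group.
    """
    names = [disp for (_, disp), pos in zip(ASSAY_MARKERS[assay], positives) if pos]
    return "|".join(names) if names else "DAPI"


def assay_groups(assay: str) -> list[str]:
    """The eight channel-based group names of an assay, in canonical order."""
    if assay not in ASSAY_MARKERS:
        raise ValueError(f"unknown assay {assay!r}")
    return [group_name(assay, m) for m in _GROUP_MASKS]


@dataclass
class SampleMeta:
    """Per-sample metadata: identity, cohort, volume and slide totals.

    ``volume_ml`` is the blood-equivalent volume represented by one test
    (two slides); ``nucleated_cells`` is the total number of nucleated
    cells imaged across both slides, the denominator of the
    cells-per-million normalization.
    """

    sample_id: str
    cohort: str
    volume_ml: float = 1.0
    slide_ids: tuple[str, ...] = ()
    nucleated_cells: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        if not (self.volume_ml > 0):
            raise ValueError("volume_ml must be positive")
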