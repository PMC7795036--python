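"""The activation collective variable Delta = d1 - d2.

d1 is the C-alpha distance between the TM2 and TM6 anchor residues and
d2 the C-alpha distance between the TM3 and TM7 anchors.  GPCR
activation swings TM6 outward (d1 grows) while TM3 and TM7 move inward
(d2 shrinks), so Delta separates conformational states: on the beta-2
adrenergic receptor, active structures show Delta above ~8 Angstrom and
inactive structures negative Delta.  Those thresholds are an empirical
observation on that receptor, are configurable, and are used only for
reporting — never inside the coupling computation.

Anchor presets store author residue numbers for the receptors with
published anchor tables (beta2AR, GCGR, M2).  Generic-number (GPCRdb
"2x41") resolution needs an external lookup and is out of scope; other
receptors require explicit anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from allodyn.ensemble_io import ResidueID, StructureEnsemble

logger = logging.getLogger(__name__)

#: Anchor residues (TM2, TM6, TM3, TM7) by receptor preset: author number
#: and expected amino acid.
PRESETS: dict[str, dict] = {
    "beta2AR": {
        "receptor_class": "A",
        "anchors": [(70, "TYR"), (276, "GLY"), (125, "CYS"), (325, "ILE")],
    },
    "GCGR": {
        "receptor_class": "B",
        "anchors": [(175, "ALA"), (347, "LEU"), (243, "LEU"), (398, "VAL")],
    },
    "M2": {
        "receptor_class": "A",
        "anchors": [(60, "TYR"), (390, "LEU"), (115, "LEU"), (439, "CYS")],
    },
}

DEFAULT_ACTIVE_THRESHOLD = 8.0  # Angstrom
DEFAULT_INACTIVE_THRESHOLD = 0.0


@dataclass(frozen=True)
class DeltaSpec:
    """The four anchor residues defining Delta.

    d1 pairs ``tm2_anchor`` with ``tm6_anchor``; d2 pairs ``tm3_anchor``
    with ``tm7_anchor``.  All four anchors must be distinct and present
    in the ensemble's common residue set.
    """

    tm2_anchor: ResidueID
    tm6_anchor: ResidueID
    tm3_anchor: ResidueID
    tm7_anchor: ResidueID
    receptor_class: str = "custom"

    def __post_init__(self) -> None:
        anchors = [self.tm2_anchor, self.tm6_anchor, self.tm3_anchor, self.tm7_anchor]
        if len({a.key for a in anchors}) != 4:
            raise ValueError("the four Delta anchors must be distinct residues")

    @property
    def anchors(self) -> tuple[ResidueID, ResidueID, ResidueID, ResidueID]:
        return (self.tm2_anchor, self.tm6_anchor, self.tm3_anchor, self.tm7_anchor)


@dataclass
class DeltaSeries:
    """Per-frame d1, d2 and Delta = d1 - d2 (Angstrom)."""

    delta: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    frame_labels: list[str]
    spec: DeltaSpec | None = None

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.d1 = np.asarray(self.d1, dtype=float)
        self.d2 = np.asarray(self.d2, dtype=float)
        if not (len(self.delta) == len(self.d1) == len(self.d2) == len(self.frame_labels)):
            raise ValueError("delta, d1, d2 and frame_labels must have equal length")
        if np.any(self.d1 <= 0) or np.any(self.d2 <= 0):
            raise ValueError("anchor distances must be positive")

    def __len__(self) -> int:
        return len(self.delta)


def resolve_delta_spec(
    preset: str | None,
    ensemble: StructureEnsemble,
    *,
    anchors: tuple[ResidueID, ResidueID, ResidueID, ResidueID] | None = None,
    chain: str | None = None,
) -> DeltaSpec:
    """Resolve a receptor preset (or explicit anchors) against an ensemble.

    Presets look anchors up by author residue number; a residue-name
    mismatch against the preset's expected amino acid is a warning (the
    entry may carry a mutation), an absent anchor is an error.
    """
    if anchors is not None:
        resolved = []
        for a in anchors:
            if not any(r == a for r in ensemble.residues):
                raise KeyError(f"Delta anchor {a} absent from the ensemble")
            resolved.append(ensemble.residues[ensemble.index_of(a)])
        return DeltaSpec(*resolved, receptor_class="custom")
    if preset not in PRESETS:
        raise KeyError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)} "
            "or give explicit anchors"
        )
    entry = PRESETS[preset]
    resolved = []
    for number, expected_name in entry["anchors"]:
        rid = ensemble.find_residue(number, chain=chain)
        if rid.name and rid.name != expected_name:
            logger.warning(
                "preset %s expects %s at residue %d but ensemble has %s",
                preset,
                expected_name,
                number,
                rid.name,
            )
        resolved.append(rid)
    return DeltaSpec(*resolved, receptor_class=entry["receptor_class"])


def compute_delta(ensemble: StructureEnsemble, spec: DeltaSpec) -> DeltaSeries:
    """Per-frame Delta = d1 - d2 over the ensemble (Angstrom)."""
    idx = [ensemble.index_of(a) for a in spec.anchors]
    xyz = ensemble.calpha
    d1 = np.linalg.norm(xyz[:, idx[0]] - xyz[:, idx[1]], axis=1)
    d2 = np.linalg.norm(xyz[:, idx[2]] - xyz[:, idx[3]], axis=1)
    return DeltaSeries(
        delta=d1 - d2,
        d1=d1,
        d2=d2,
        frame_labels=ensemble.frame_labels,
        spec=spec,
    )


def classify_state(
    series: DeltaSeries,
    active_threshold: float = DEFAULT_ACTIVE_THRESHOLD,
    inactive_threshold: float = DEFAULT_INACTIVE_THRESHOLD,
) -> list[str]:
    """Label frames: Delta above the active threshold -> "active", below
    the inactive threshold -> "inactive", otherwise "intermediate"."""
    if not active_threshold > inactive_threshold:
        raise ValueError("active_threshold must exceed inactive_threshold")
    return [
        "active" if d > active_threshold
        else "inactive" if d < inactive_threshold
        else "intermediate"
        for d in series.delta
    ]
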