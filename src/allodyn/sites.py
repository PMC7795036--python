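"""Candidate binding sites: pocket-detector output and residue lists.

Pocket detection itself is delegated to an external detector
(fpocket/MDpocket); this module parses its dummy-atom output (STP
pseudo-atoms marking pocket volume, pocket index in the residue-number
field), applies the retention rule (pocket present in at least 40% of
frames) and assigns residues to each pocket (a residue belongs to a
site if any of its heavy atoms lies within 4.0 Angstrom — inclusive —
of any dummy atom, in at least one frame).  Both rules are inclusive
boundaries.  The ensemble must be superposed into the detector's frame
of reference before assignment.

Sites may equally be supplied directly as residue lists (plain text or
JSON), in which case the presence fraction is 1 by definition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from allodyn.ensemble_io import ResidueID, StructureEnsemble

logger = logging.getLogger(__name__)

DEFAULT_PRESENCE_FRACTION = 0.40
DEFAULT_ASSIGN_CUTOFF = 4.0  # Angstrom
DEFAULT_ORTHOSTERIC_OVERLAP = 0.50


@dataclass
class PocketCloud:
    """Per-frame dummy-atom point clouds of one detected pocket.

    ``frames[f]`` is an (k_f, 3) array, possibly empty where the
    detector did not find the pocket in frame f.
    """

    site_label: str
    frames: list[np.ndarray]
    source: str = "mdpocket"

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f, dtype=float).reshape(-1, 3) for f in self.frames]
        for f in self.frames:
            if f.size and not np.isfinite(f).all():
                raise ValueError(f"pocket {self.site_label}: non-finite dummy atoms")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def presence_fraction(self) -> float:
        """Fraction of frames in which the pocket was detected."""
        if not self.frames:
            return 0.0
        return sum(1 for f in self.frames if len(f) > 0) / len(self.frames)


@dataclass
class SiteDefinition:
    """A labelled residue set to be scored for coupling."""

    site_label: str
    residues: list[ResidueID]
    presence_fraction: float = 1.0
    origin: str = "residue_list"  # or "pocket_cloud"

    def __post_init__(self) -> None:
        self.residues = list(dict.fromkeys(self.residues))
        if len(self.residues) < 1:
            raise ValueError(f"site {self.site_label!r} has no residues")
        if not 0.0 <= self.presence_fraction <= 1.0:
            raise ValueError("presence_fraction must be in [0, 1]")

    @property
    def n_residues(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# Pocket-detector output


def _parse_stp_file(path: Path) -> list[dict[str, list[np.ndarray]]]:
    """Parse one fpocket/MDpocket dummy-atom PDB file.

    Returns one ``{pocket_label: points}`` dict per MODEL (a file with
    no MODEL records yields a single entry).  Only ATOM/HETATM records
    with residue name STP are read; other records are counted and
    ignored.
    """
    models: list[dict[str, list]] = []
    current: dict[str, list] = {}
    started = False
    ignored = 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                if started:
                    models.append(current)
                current = {}
                started = True
            elif rec in {"ATOM", "HETATM"}:
                if line[17:20].strip() != "STP":
                    ignored += 1
                    continue
                label = line[22:27].strip() or "0"  # pocket index field
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                current.setdefault(label, []).append(xyz)
    models.append(current)
    if ignored:
        logger.warning("%s: ignored %d non-STP atom records", path, ignored)
    return [
        {lab: np.asarray(pts, dtype=float) for lab, pts in m.items()} for m in models
    ]


def parse_pocket_output(
    paths: str | Path | list[str | Path],
    ensemble: StructureEnsemble | None = None,
    *,
    n_frames: int | None = None,
) -> list[PocketCloud]:
    """Read detector dummy-atom output into frame-aligned pocket clouds.

    ``paths`` may be a single file whose MODEL records correspond to
    ensemble frames, or one file per frame in ensemble frame order.
    A single single-model file against a multi-frame ensemble is read as
    a static pocket repeated in every frame.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    if n_frames is None:
        n_frames = ensemble.n_frames if ensemble is not None else None

    per_frame: list[dict[str, np.ndarray]] = []
    for p in paths:
        per_frame.extend(_parse_stp_file(p))
    if all(len(m) == 0 for m in per_frame):
        raise ValueError("no pocket dummy atoms in input (no STP records found)")

    if n_frames is not None and len(per_frame) != n_frames:
        if len(per_frame) == 1:
            per_frame = per_frame * n_frames  # static pocket definition
        else:
            raise ValueError(
                f"pocket input has {len(per_frame)} frame(s) but the ensemble "
                f"has {n_frames}"
            )

    labels = sorted({lab for m in per_frame for lab in m}, key=_label_key)
    empty = np.empty((0, 3))
    return [
        PocketCloud(
            site_label=lab,
            frames=[m.get(lab, empty) for m in per_frame],
        )
        for lab in labels
    ]


def _label_key(label: str):
    return (0, int(label)) if label.isdigit() else (1, label)


def presence_filter(
    clouds: list[PocketCloud], min_fraction: float = DEFAULT_PRESENCE_FRACTION
) -> list[PocketCloud]:
    """Retain pockets present in at least ``min_fraction`` of frames
    (inclusive: 4 of 10 frames passes the default 0.40)."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    kept = [c for c in clouds if c.presence_fraction >= min_fraction]
    for c in clouds:
        if c not in kept:
            logger.info(
                "pocket %s present in %.0f%% of frames: below %.0f%%, discarded",
                c.site_label,
                100 * c.presence_fraction,
                100 * min_fraction,
            )
    return kept


def assign_site_residues(
    cloud: PocketCloud,
    ensemble: StructureEnsemble,
    cutoff: float = DEFAULT_ASSIGN_CUTOFF,
    *,
    frames: list[int] | None = None,
) -> SiteDefinition:
    """Residues within ``cutoff`` of the pocket's dummy atoms.

    A residue is included if, in at least one frame, any of its heavy
    atoms lies within the cutoff (inclusive) of any dummy atom of that
    frame; the result is the union over frames (or over the ``frames``
    subset, e.g. a single representative frame).  Uses a KD-tree per
    frame; the boundary is made inclusive explicitly.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cloud.n_frames != ensemble.n_frames:
        raise ValueError(
            f"pocket {cloud.site_label}: {cloud.n_frames} frames vs ensemble "
            f"{ensemble.n_frames}"
        )
    if cloud.presence_fraction == 0.0:
        raise ValueError(f"pocket {cloud.site_label} is empty in every frame")
    frame_indices = range(ensemble.n_frames) if frames is None else frames

    hit_residues: set[int] = set()
    r_query = np.nextafter(float(cutoff), np.inf)  # boundary distance == cutoff counts
    for f in frame_indices:
        points = cloud.frames[f]
        if len(points) == 0:
            continue
        conf = ensemble.conformations[f]
        tree = cKDTree(points)
        dist, _ = tree.query(conf.atom_coords, k=1, distance_upper_bound=r_query)
        close = dist <= r_query
        hit_residues.update(np.unique(conf.atom_res_index[close]).tolist())

    residues = [ensemble.residues[i] for i in sorted(hit_residues)]
    if not residues:
        logger.warning("pocket %s: no residues within %.2f A", cloud.site_label, cutoff)
        raise ValueError(
            f"pocket {cloud.site_label}: no residues within {cutoff} Angstrom"
        )
    return SiteDefinition(
        site_label=cloud.site_label,
        residues=residues,
        presence_fraction=cloud.presence_fraction,
        origin="pocket_cloud",
    )


# ---------------------------------------------------------------------------
# Site curation


def filter_sites(
    sites: list[SiteDefinition],
    orthosteric_residues: set[ResidueID] | list[ResidueID] | None = None,
    exclude: list[str] | None = None,
    *,
    max_overlap: float = DEFAULT_ORTHOSTERIC_OVERLAP,
    keep_flags: dict[str, bool] | None = None,
) -> list[SiteDefinition]:
    """Drop orthosteric-overlapping, excluded or manually flagged sites.

    A site is dropped when its overlap with the orthosteric residue set
    reaches ``max_overlap`` of the smaller of the two sets.  Burial is
    not computed automatically; ``keep_flags`` carries per-site manual
    keep/drop decisions (e.g. for buried pockets).
    """
    exclude = set(exclude or [])
    ortho = set(orthosteric_residues) if orthosteric_residues else set()
    keep_flags = keep_flags or {}
    out = []
    for site in sites:
        if site.site_label in exclude:
            continue
        if keep_flags.get(site.site_label) is False:
            continue
        if ortho:
            overlap = len(set(site.residues) & ortho)
            smaller = min(len(site.residues), len(ortho))
            if smaller and overlap / smaller >= max_overlap:
                logger.info(
                    "site %s overlaps the orthosteric set (%d/%d residues): dropped",
                    site.site_label,
                    overlap,
                    smaller,
                )
                continue
        out.append(site)
    return out


# ---------------------------------------------------------------------------
# Residue-list files


def load_site_lists(
    path: str | Path, ensemble: StructureEnsemble, *, default_chain: str = "A"
) -> list[SiteDefinition]:
    """Read sites from a residue-list file.

    JSON: ``{"Site4": ["A:131", "A:141", ...], ...}``.  Plain text: one
    ``label: tok, tok, ...`` line per site; tokens are ``chain:number``
    or bare numbers (resolved with ``default_chain`` when the ensemble
    has that chain, else by unique author number).  Residues absent from
    the ensemble are dropped with a warning; duplicates are deduplicated.
    """
    path = Path(path)
    text = path.read_text()
    raw: dict[str, list[str]] = {}
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        data = json.loads(text)
        raw = {str(k): [str(t) for t in v] for k, v in data.items()}
    else:
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path}: cannot parse site line {line!r}")
            label, rest = line.split(":", 1)
            raw[label.strip()] = [t for t in rest.replace(",", " ").split() if t]

    known = {r.key: r for r in ensemble.residues}
    by_number: dict[int, list[ResidueID]] = {}
    for r in ensemble.residues:
        by_number.setdefault(r.number, []).append(r)

    sites = []
    for label, tokens in raw.items():
        residues = []
        missing = []
        for tok in tokens:
            rid = ResidueID.parse(tok, default_chain=default_chain)
            if rid.key in known:
                residues.append(known[rid.key])
            elif ":" not in tok and len(by_number.get(rid.number, [])) == 1:
                residues.append(by_number[rid.number][0])
            else:
                missing.append(tok)
        if missing:
            logger.warning(
                "site %s: %d residue(s) absent from the ensemble, dropped: %s",
                label,
                len(missing),
                ", ".join(missing),
            )
        if not residues:
            logger.warning("site %s: no residues matched the ensemble; skipped", label)
            continue
        sites.append(
            SiteDefinition(site_label=label, residues=residues, origin="residue_list")
        )
    if not sites:
        raise ValueError(f"{path}: no usable sites")
    return sites


def write_site_lists(sites: list[SiteDefinition], path: str | Path) -> Path:
    """Write sites as JSON ``{label: ["chain:number", ...]}``."""
    path = Path(path)
    payload = {
        s.site_label: [f"{r.chain}:{r.number}{r.insertion_code}" for r in s.residues]
        for s in sites
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
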