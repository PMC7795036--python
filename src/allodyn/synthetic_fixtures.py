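"""Toy two-state receptor ensembles with planted ground truth.

The generator builds an idealised 7-helix C-alpha bundle (ideal
alpha-helix trace: 1.5 Angstrom rise, 100 degrees per residue,
2.3 Angstrom helix radius, helices on a circular 7-spoke arrangement)
and emulates the statistical structure of a two-state GPCR ensemble:

* a latent activation coordinate lambda per frame (0 = inactive,
  1 = active);
* the four Delta anchor distances vary linearly with lambda so that
  Delta(active) - Delta(inactive) equals ``activation_gap``
  (TM6 moves outward along the d1 axis, TM7 moves inward along the d2
  axis, in a 3:1 split mirroring the dominant TM6 motion);
* one planted "coupled" site whose internal pairwise distances are
  linear in lambda (uniform scaling about the site centroid with mean
  slope ``coupling_slope`` Angstrom per Angstrom of Delta);
* decoy sites whose residues receive only i.i.d. Gaussian coordinate
  noise, as does every other residue.

Because the coupled site's internal distances are exactly linear in
lambda and Delta is too, the noiseless limit gives the coupled site
C_site = 1 while decoy pair correlations are undefined (zero variance).
Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

from allodyn.ensemble_io import (
    ResidueID,
    StructureEnsemble,
    ensemble_from_calpha,
    write_ensemble,
)
from allodyn.sites import SiteDefinition, write_site_lists

HELIX_RISE = 1.5  # Angstrom per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Angstrom
BUNDLE_RADIUS = 11.0  # Angstrom, helix axes from the bundle centre
MIN_CONTACT_DISTANCE = 1.0  # Angstrom, collision guard


@dataclass
class ToyReceptorSpec:
    """Parameters of the toy two-state receptor ensemble.

    Defaults plant an 8 Angstrom activation gap (the Delta separation
    between active and inactive experimental structures of the beta-2
    adrenergic receptor), 0.2 Angstrom coordinate noise, 50 frames per
    state and a coupled-site distance slope of 1 Angstrom per Angstrom
    of Delta.
    """

    n_helices: int = 7
    residues_per_helix: int = 10
    activation_gap: float = 8.0
    noise_sigma: float = 0.2
    n_frames_per_state: int = 50
    coupling_slope: float = 1.0
    anchor_assignment: tuple[int, int, int, int] | None = None  # 0-based residue idx
    coupled_site_residues: tuple[int, ...] | None = None
    decoy_site_residues: tuple[tuple[int, ...], ...] | None = None
    intermediate_lambda: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activation_gap <= 0:
            raise ValueError("activation_gap must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_frames_per_state < 1:
            raise ValueError("n_frames_per_state must be at least 1")
        n = self.n_helices * self.residues_per_helix
        if self.anchor_assignment is None:
            # middle residue of helices 2, 6, 3, 7 (1-based helix numbers)
            mid = self.residues_per_helix // 2
            h = self.residues_per_helix
            self.anchor_assignment = (1 * h + mid, 5 * h + mid, 2 * h + mid, 6 * h + mid)
        if self.coupled_site_residues is None:
            # a pocket straddling helices 4 and 5
            h = self.residues_per_helix
            self.coupled_site_residues = (
                3 * h + 1, 3 * h + 4, 3 * h + 7, 4 * h + 2, 4 * h + 5,
            )
        if self.decoy_site_residues is None:
            h = self.residues_per_helix
            self.decoy_site_residues = (
                (0 * h + 1, 0 * h + 4, 0 * h + 7, 1 * h + 8),
                (4 * h + 8, 5 * h + 1, 5 * h + 8, 6 * h + 1),
                (2 * h + 8, 2 * h + 3, 0 * h + 8, 6 * h + 8),
            )
        anchors = set(self.anchor_assignment)
        used = set(self.coupled_site_residues)
        for decoy in self.decoy_site_residues:
            used |= set(decoy)
        if anchors & used:
            raise ValueError("sites must be disjoint from the Delta anchors")
        all_idx = anchors | used
        if any(i < 0 or i >= n for i in all_idx):
            raise ValueError("residue index out of range for the bundle")
        if set(self.coupled_site_residues) & set().union(*map(set, self.decoy_site_residues)):
            raise ValueError("coupled and decoy sites must be disjoint")


@dataclass
class ToyGroundTruth:
    """What the generator planted: per-frame lambda and site labels."""

    lam: np.ndarray
    anchors: tuple[int, int, int, int]
    coupled_site: SiteDefinition
    decoy_sites: list[SiteDefinition]
    expected_top_site: str
    spec: ToyReceptorSpec

    @property
    def sites(self) -> list[SiteDefinition]:
        return [self.coupled_site] + list(self.decoy_sites)


def _ideal_bundle(n_helices: int, residues_per_helix: int) -> np.ndarray:
    """C-alpha trace of an idealised circular helix bundle, (N, 3)."""
    coords = []
    for h in range(n_helices):
        spoke = 2 * np.pi * h / n_helices
        centre = BUNDLE_RADIUS * np.array([np.cos(spoke), np.sin(spoke), 0.0])
        for k in range(residues_per_helix):
            phase = np.deg2rad(HELIX_TWIST * k) + spoke
            coords.append(
                centre
                + np.array(
                    [
                        HELIX_RADIUS * np.cos(phase),
                        HELIX_RADIUS * np.sin(phase),
                        HELIX_RISE * k - HELIX_RISE * residues_per_helix / 2,
                    ]
                )
            )
    return np.array(coords)


def generate_toy_ensemble(
    spec: ToyReceptorSpec | None = None,
) -> tuple[StructureEnsemble, ToyGroundTruth]:
    """Generate a two-state toy ensemble and its ground-truth record.

    Frames are ``n_frames_per_state`` inactive (lambda = 0) followed by
    the same number of active (lambda = 1) frames; a flag switches to
    uniform lambda sampling instead.  Raises if, after 10 attempts, a
    noise draw leaves two residues closer than 1 Angstrom.
    """
    spec = spec or ToyReceptorSpec()
    rng = np.random.default_rng(spec.seed)
    base = _ideal_bundle(spec.n_helices, spec.residues_per_helix)
    n_res = len(base)
    a2, a6, a3, a7 = spec.anchor_assignment

    n_frames = 2 * spec.n_frames_per_state
    if spec.intermediate_lambda:
        lam = rng.uniform(0.0, 1.0, size=n_frames)
    else:
        lam = np.repeat([0.0, 1.0], spec.n_frames_per_state)

    # unit displacement axes for the anchor motions
    u1 = base[a6] - base[a2]
    u1 /= np.linalg.norm(u1)  # TM6 outward: d1 grows
    u2 = base[a3] - base[a7]
    u2 /= np.linalg.norm(u2)  # TM7 inward: d2 shrinks
    gap_d1 = 0.75 * spec.activation_gap
    gap_d2 = 0.25 * spec.activation_gap
    d2_base = float(np.linalg.norm(base[a3] - base[a7]))
    if gap_d2 >= d2_base - 1.0:
        raise ValueError("activation_gap too large for the bundle geometry")

    site_idx = np.array(spec.coupled_site_residues)
    centroid = base[site_idx].mean(axis=0)
    radial = base[site_idx] - centroid
    mean_internal = _mean_pairwise_distance(base[site_idx])
    # uniform scaling: internal distances scale by (1 + s*lambda), so the
    # mean internal distance changes by coupling_slope per Angstrom of Delta
    s = spec.coupling_slope * spec.activation_gap / mean_internal

    clean = np.repeat(base[None, :, :], n_frames, axis=0).copy()
    clean[:, a6] += lam[:, None] * gap_d1 * u1[None, :]
    clean[:, a7] += lam[:, None] * gap_d2 * u2[None, :]
    clean[:, site_idx] = centroid + (1.0 + s * lam)[:, None, None] * radial
    # the deformed (noise-free) geometry must be collision-free: a clash
    # here means the planted motion itself is geometrically infeasible
    if _min_pairwise(clean) < MIN_CONTACT_DISTANCE:
        raise ValueError(
            "planted deformation causes residue collisions; reduce "
            "coupling_slope or activation_gap, or move the site"
        )
    frames = clean
    if spec.noise_sigma > 0:
        # noise is measurement-like jitter, not steric reality: retry a few
        # draws, then accept with a warning rather than fail
        for attempt in range(10):
            frames = clean + rng.normal(0.0, spec.noise_sigma, size=clean.shape)
            if _min_pairwise(frames) >= MIN_CONTACT_DISTANCE:
                break
        else:
            logger.warning(
                "noise draws keep placing residues closer than %.1f Angstrom "
                "(noise_sigma=%.2f); proceeding with the last draw",
                MIN_CONTACT_DISTANCE,
                spec.noise_sigma,
            )

    states = ["active" if l > 0.5 else "inactive" for l in lam]
    labels = [f"toy_{s}_{i + 1}" for i, s in enumerate(states)]
    ensemble = ensemble_from_calpha(frames, labels=labels, states=states)

    def _site(label: str, indices) -> SiteDefinition:
        return SiteDefinition(
            site_label=label,
            residues=[ensemble.residues[i] for i in indices],
            origin="residue_list",
        )

    truth = ToyGroundTruth(
        lam=lam,
        anchors=spec.anchor_assignment,
        coupled_site=_site("coupled", spec.coupled_site_residues),
        decoy_sites=[
            _site(f"decoy{i + 1}", idx)
            for i, idx in enumerate(spec.decoy_site_residues)
        ],
        expected_top_site="coupled",
        spec=spec,
    )
    return ensemble, truth


def _mean_pairwise_distance(coords: np.ndarray) -> float:
    from scipy.spatial.distance import pdist

    return float(pdist(coords).mean())


def _min_pairwise(frames: np.ndarray) -> float:
    diff = frames[:, :, None, :] - frames[:, None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    n = frames.shape[1]
    dist[:, np.arange(n), np.arange(n)] = np.inf
    return float(dist.min())


def delta_anchor_ids(
    ensemble: StructureEnsemble, truth: ToyGroundTruth
) -> tuple[ResidueID, ResidueID, ResidueID, ResidueID]:
    """The planted TM2/TM6/TM3/TM7 anchor residues of a toy ensemble."""
    return tuple(ensemble.residues[i] for i in truth.anchors)  # type: ignore[return-value]


def write_fixture_bundle(
    ensemble: StructureEnsemble,
    truth: ToyGroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the toy ensemble plus its site lists, ground truth and a
    synthetic pocket-cloud file (exercises the detector-output parser).

    The pocket file is labelled synthetic: its STP dummy atoms are
    placed at each site residue's C-alpha, pulled 30% toward the site
    centroid, in every frame — not the output of a real detector.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["ensemble"] = write_ensemble(ensemble, out_dir / "ensemble.pdb")
    paths["sites"] = write_site_lists(truth.sites, out_dir / "sites.json")

    anchors = delta_anchor_ids(ensemble, truth)
    truth_payload = {
        "lambda": truth.lam.tolist(),
        "anchors": [f"{r.chain}:{r.number}" for r in anchors],
        "coupled_site": truth.coupled_site.site_label,
        "decoy_sites": [s.site_label for s in truth.decoy_sites],
        "expected_top_site": truth.expected_top_site,
        "expected_ranking_first": truth.expected_top_site,
        "spec": asdict(truth.spec),
    }
    paths["ground_truth"] = out_dir / "ground_truth.json"
    paths["ground_truth"].write_text(json.dumps(truth_payload, indent=2) + "\n")

    paths["pockets"] = _write_synthetic_pockets(
        ensemble, truth, out_dir / "pockets_synthetic.pdb"
    )
    return paths


def _write_synthetic_pockets(
    ensemble: StructureEnsemble, truth: ToyGroundTruth, path: Path
) -> Path:
    """Synthetic MDpocket-style dummy-atom file: STP pseudo-atoms per
    site per frame (pocket index in the residue-number field)."""
    res_pos = {r.key: i for i, r in enumerate(ensemble.residues)}
    lines = []
    for f, conf in enumerate(ensemble.conformations):
        lines.append(f"MODEL     {f + 1:4d}")
        serial = 1
        for p, site in enumerate(truth.sites, start=1):
            idx = [res_pos[r.key] for r in site.residues]
            pts = conf.calpha[idx]
            centroid = pts.mean(axis=0)
            pts = centroid + 0.7 * (pts - centroid)
            for xyz in pts:
                lines.append(
                    f"ATOM  {serial:5d}  C   STP C{p:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  0.00  0.00"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
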