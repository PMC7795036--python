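"""Distance-Delta coupling matrix, site scores and ranking.

For residues i, j the coupling c_ij is the Pearson correlation, across
the ensemble, between the C-alpha distance d_ij and the activation
variable Delta:

    c_ij = cov(d_ij, Delta) / (sigma_dij * sigma_Delta)

A site with residues S (|S| = N >= 2) is scored by the mean absolute
coupling over its internal pairs,

    C_site = 2 / (N (N - 1)) * sum_{i<j in S} |c_ij|,

and candidate sites are ranked by C_site; sites above the arithmetic
mean of the ranking are flagged as potentially allosteric.

Entries where a distance does not fluctuate (zero variance) have no
defined correlation; they are flagged invalid and contribute 0 to
C_site sums while staying in the pair count, so a rigid pair dilutes
rather than inflates a site's score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from allodyn.delta import DeltaSeries
from allodyn.ensemble_io import ResidueID, StructureEnsemble

logger = logging.getLogger(__name__)

STRONG_COUPLING_THRESHOLD = 0.75
REPORT_DECIMALS = 2


@dataclass
class DistanceSeries:
    """Per-frame C-alpha distance for one residue pair (Angstrom)."""

    pair: tuple[ResidueID, ResidueID]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.pair[0] == self.pair[1]:
            raise ValueError("a distance series requires two distinct residues")
        if np.any(self.values <= 0):
            raise ValueError("inter-residue distances must be positive")


@dataclass
class CouplingMatrix:
    """Symmetric residue-pair table of correlations with Delta.

    ``c[i, j]`` is the Pearson correlation of d_ij with Delta;
    ``valid[i, j]`` is False exactly where the correlation is undefined
    (zero distance variance) and on the diagonal.
    """

    residues: list[ResidueID]
    c: np.ndarray
    valid: np.ndarray
    n_frames: int

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def index_of(self, residue: ResidueID) -> int:
        try:
            return self.residues.index(residue)
        except ValueError:
            raise KeyError(f"residue {residue} not in coupling matrix") from None

    def to_frame(self) -> pd.DataFrame:
        """Square table with residue-ID header row/column."""
        names = [str(r) for r in self.residues]
        return pd.DataFrame(self.c, index=names, columns=names)

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: res_i, res_j, c, valid for all unordered pairs."""
        rows = []
        for i in range(self.n_residues):
            for j in range(i + 1, self.n_residues):
                rows.append(
                    {
                        "res_i": str(self.residues[i]),
                        "res_j": str(self.residues[j]),
                        "c": self.c[i, j],
                        "valid": bool(self.valid[i, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class SiteCoupling:
    """C_site score of one site plus its coupling sub-matrix.

    ``top_pair`` is the residue pair whose |c| is largest within the
    site — the pairwise distance contributing most to the coupling.
    """

    site_label: str
    residues: list[ResidueID]
    c_site: float
    submatrix: np.ndarray | None = None
    top_pair: tuple[ResidueID, ResidueID, float] | None = None
    n_invalid_pairs: int = 0
    rank: int | None = None
    above_mean: bool | None = None

    @property
    def n_residues(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# Distances and correlations


def _distance_tensor(ensemble: StructureEnsemble) -> np.ndarray:
    """(n_frames, N, N) C-alpha distance matrices, one per frame."""
    xyz = ensemble.calpha
    diff = xyz[:, :, None, :] - xyz[:, None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def compute_distance_series(
    ensemble: StructureEnsemble,
    pairs: list[tuple[ResidueID, ResidueID]] | None = None,
) -> list[DistanceSeries]:
    """Per-frame C-alpha distances for the requested residue pairs.

    ``pairs=None`` yields every unordered pair of common residues, in
    canonical (i before j) order.
    """
    if ensemble.n_frames < 1:
        raise ValueError("ensemble has no frames")
    xyz = ensemble.calpha
    out: list[DistanceSeries] = []
    if pairs is None:
        n = ensemble.n_residues
        index_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        index_pairs = []
        for a, b in pairs:
            ia, ib = ensemble.index_of(a), ensemble.index_of(b)
            if ia == ib:
                raise ValueError(f"pair ({a}, {b}) refers to the same residue")
            index_pairs.append((min(ia, ib), max(ia, ib)))
    for i, j in index_pairs:
        values = np.linalg.norm(xyz[:, i] - xyz[:, j], axis=1)
        out.append(
            DistanceSeries(pair=(ensemble.residues[i], ensemble.residues[j]), values=values)
        )
    return out


def _sum_over_frames(arr: np.ndarray) -> np.ndarray:
    """Exactly-rounded sum over axis 0 (math.fsum per element).

    Correct rounding makes every reduction independent of frame order,
    so permuting frames (together with Delta) leaves the coupling
    matrix bitwise unchanged.
    """
    flat = arr.reshape(arr.shape[0], -1)
    out = np.array([math.fsum(col) for col in flat.T])
    return out.reshape(arr.shape[1:])


def compute_coupling_matrix(
    ensemble: StructureEnsemble,
    delta: DeltaSeries,
    *,
    min_frames: int = 3,
) -> CouplingMatrix:
    """Pearson correlation of every inter-residue distance with Delta.

    Computed by a numerically stable two-pass (centered-moment) formula
    with exactly-rounded frame sums; each unordered pair is computed
    once and mirrored, so the matrix is exactly symmetric.
    """
    n_frames = ensemble.n_frames
    if n_frames < min_frames:
        raise ValueError(
            f"coupling requires at least {min_frames} frames, got {n_frames}"
        )
    dvec = np.asarray(delta.delta, dtype=float)
    if len(dvec) != n_frames:
        raise ValueError("Delta series length does not match ensemble frame count")
    # a constant series is "constant" up to the rounding of its mean:
    # compare the fluctuation norm against machine epsilon at the series'
    # own scale, not against exact zero
    eps_scale = 4.0 * np.finfo(float).eps * np.sqrt(n_frames)

    mean_delta = math.fsum(dvec) / n_frames
    dc = dvec - mean_delta
    s_delta = np.sqrt(math.fsum(dc * dc))
    if s_delta <= eps_scale * abs(mean_delta):
        raise ValueError("collective variable constant over ensemble")

    dist = _distance_tensor(ensemble)  # (F, N, N)
    mean_dist = _sum_over_frames(dist) / n_frames
    centered = dist - mean_dist
    s_dist = np.sqrt(_sum_over_frames(centered * centered))  # (N, N)
    cov = _sum_over_frames(dc[:, None, None] * centered)

    n = ensemble.n_residues
    valid = s_dist > eps_scale * np.abs(mean_dist)
    np.fill_diagonal(valid, False)
    c = np.zeros((n, n))
    with np.errstate(invalid="ignore", divide="ignore"):
        c[valid] = cov[valid] / (s_dist[valid] * s_delta)
    c = np.clip(c, -1.0, 1.0)
    # symmetrise exactly: copy the upper triangle onto the lower
    iu = np.triu_indices(n, k=1)
    c[(iu[1], iu[0])] = c[iu]
    valid[(iu[1], iu[0])] = valid[iu]

    n_invalid = int(np.sum(~valid[iu]))
    if n_invalid:
        logger.info(
            "%d residue pair(s) have zero distance variance; their couplings "
            "are flagged invalid and count as 0 in site scores",
            n_invalid,
        )
    return CouplingMatrix(
        residues=list(ensemble.residues), c=c, valid=valid, n_frames=n_frames
    )


def strong_coupling_mask(
    matrix: CouplingMatrix, threshold: float = STRONG_COUPLING_THRESHOLD
) -> np.ndarray:
    """Boolean mask of strong couplings: |c| strictly above ``threshold``
    and defined.  The default 0.75 is the usual reporting cutoff."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return (np.abs(matrix.c) > threshold) & matrix.valid


# ---------------------------------------------------------------------------
# Site scores and ranking


def compute_csite(matrix: CouplingMatrix, site) -> SiteCoupling:
    """Mean absolute coupling over a site's internal residue pairs.

    ``site`` is any object with ``site_label`` and ``residues``
    (a SiteDefinition, typically).  Invalid entries contribute 0 to the
    sum while remaining in the N(N-1)/2 denominator.  Full precision is
    kept here; rounding to two decimals happens only in report tables.
    """
    residues = list(dict.fromkeys(site.residues))  # dedupe, keep order
    n = len(residues)
    if n < 2:
        raise ValueError(f"site {site.site_label!r} too small to score (N={n})")
    idx = [matrix.index_of(r) for r in residues]
    sub = matrix.c[np.ix_(idx, idx)].copy()
    sub_valid = matrix.valid[np.ix_(idx, idx)]
    sub[~sub_valid] = 0.0
    np.fill_diagonal(sub, 0.0)

    iu = np.triu_indices(n, k=1)
    abs_upper = np.abs(sub[iu])
    c_site = float(abs_upper.sum() * 2.0 / (n * (n - 1)))
    k = int(np.argmax(abs_upper))
    i, j = iu[0][k], iu[1][k]
    top_pair = (residues[i], residues[j], float(sub[i, j]))
    return SiteCoupling(
        site_label=str(site.site_label),
        residues=residues,
        c_site=c_site,
        submatrix=sub,
        top_pair=top_pair,
        n_invalid_pairs=int(np.sum(~sub_valid[iu])),
    )


def site_scores_from_values(values: dict[str, float]) -> list[SiteCoupling]:
    """Wrap bare ``{site_label: C_site}`` values (e.g. a published
    ranking table) as score records suitable for :func:`rank_sites`."""
    if len(values) == 0:
        raise ValueError("no site scores given")
    return [
        SiteCoupling(site_label=str(label), residues=[], c_site=float(v))
        for label, v in values.items()
    ]


def rank_sites(scores: list[SiteCoupling]) -> list[SiteCoupling]:
    """Rank sites by descending C_site and flag those above the mean.

    The mean is the unweighted arithmetic mean of the listed C_site
    values; ``above_mean`` uses a strict comparison on unrounded values.
    Ties are broken by site label ascending; ranks are 1-based.
    """
    if not scores:
        raise ValueError("no sites to rank")
    labels = [s.site_label for s in scores]
    if len(set(labels)) != len(labels):
        raise ValueError("site labels must be unique for ranking")
    mean = float(np.mean([s.c_site for s in scores]))
    ordered = sorted(scores, key=lambda s: (-s.c_site, s.site_label))
    for rank, score in enumerate(ordered, start=1):
        score.rank = rank
        score.above_mean = score.c_site > mean
    return ordered


def ranking_mean(scores: list[SiteCoupling]) -> float:
    """Unweighted mean C_site of a ranking."""
    return float(np.mean([s.c_site for s in scores]))


def ranking_table(ranked: list[SiteCoupling]) -> pd.DataFrame:
    """Machine twin of a published site-ranking table (two-decimal
    C_site, top contributing pair per site)."""
    rows = []
    for s in ranked:
        top_i, top_j, top_c = ("", "", np.nan)
        if s.top_pair is not None:
            top_i, top_j, top_c = str(s.top_pair[0]), str(s.top_pair[1]), round(s.top_pair[2], REPORT_DECIMALS)
        rows.append(
            {
                "site_label": s.site_label,
                "n_residues": s.n_residues,
                "c_site": round(s.c_site, REPORT_DECIMALS),
                "rank": s.rank,
                "above_mean": s.above_mean,
                "top_pair_i": top_i,
                "top_pair_j": top_j,
                "top_pair_c": top_c,
            }
        )
    return pd.DataFrame(rows)


def write_site_bfactor_pdb(
    ensemble: StructureEnsemble,
    ranked: list[SiteCoupling],
    path,
    frame: int = 0,
) -> None:
    """Write one frame as PDB with each site residue's B-factor set to
    100 * C_site of its site (visualisation aid; residues in several
    sites take the strongest site's score)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    conf = ensemble.conformations[frame]
    score_by_res: dict[tuple, float] = {}
    for s in sorted(ranked, key=lambda s: s.c_site):
        for r in s.residues:
            score_by_res[r.key] = s.c_site
    n = len(conf.atom_names)
    arr = struc.AtomArray(n)
    arr.coord = conf.atom_coords
    arr.atom_name = conf.atom_names.astype("U6")
    arr.chain_id = np.array(
        [conf.residues[i].chain for i in conf.atom_res_index], dtype="U4"
    )
    arr.res_id = np.array([conf.residues[i].number for i in conf.atom_res_index])
    arr.res_name = np.array(
        [conf.residues[i].name or "ALA" for i in conf.atom_res_index], dtype="U5"
    )
    arr.element = np.array(
        [(a[0] if a[:1].isalpha() else "C") for a in arr.atom_name], dtype="U2"
    )
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation(
        "b_factor",
        np.array(
            [
                100.0 * score_by_res.get(conf.residues[i].key, 0.0)
                for i in conf.atom_res_index
            ]
        ),
    )
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def strong_mask_frame(
    matrix: CouplingMatrix, threshold: float = STRONG_COUPLING_THRESHOLD
) -> pd.DataFrame:
    """Signed couplings where |c| exceeds the threshold, blank elsewhere."""
    mask = strong_coupling_mask(matrix, threshold)
    names = [str(r) for r in matrix.residues]
    out = np.full(matrix.c.shape, "", dtype=object)
    out[mask] = np.round(matrix.c[mask], 3).astype(str)
    return pd.DataFrame(out, index=names, columns=names)
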