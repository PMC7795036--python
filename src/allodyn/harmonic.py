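"""Elastic-network harmonic ensembles.

A coarse-grained anisotropic network model (ANM) over C-alpha atoms:
every pair of C-alphas within a cutoff (default 13 Angstrom) is joined
by a Hookean spring of uniform stiffness gamma.  Diagonalising the
3N x 3N Hessian yields normal modes; a harmonic trajectory is generated
as random linear combinations of the lowest-frequency internal modes,
with per-mode amplitude variance temperature_scale / lambda_k
(equipartition over the harmonic wells).  Concatenating trajectories
generated around an inactive and an active structure gives a two-state
ensemble suitable for the coupling analysis.

This is a deliberately coarse model of protein flexibility: it captures
low-frequency collective geometry changes around a reference structure
but none of the chemistry an all-atom force-field normal-mode analysis
would see.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from allodyn.ensemble_io import (
    Conformation,
    StructureEnsemble,
    concatenate_ensembles,
    ensemble_from_calpha,
)

DEFAULT_CUTOFF = 13.0  # Angstrom
DEFAULT_GAMMA = 1.0
DEFAULT_N_MODES = 100
_ZERO_MODE_RTOL = 1e-8


@dataclass
class ENModel:
    """Elastic-network eigenpairs for one reference structure.

    ``eigenvalues`` ascend and include the near-zero rigid-body modes
    (``n_zero_modes`` of them: 6 for a connected non-collinear network);
    ``eigenvectors[:, k]`` is the orthonormal shape of mode k over the
    3N C-alpha coordinates.
    """

    reference: Conformation
    cutoff: float
    gamma: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero_modes: int

    @property
    def n_residues(self) -> int:
        return self.reference.n_residues

    @property
    def internal_eigenvalues(self) -> np.ndarray:
        """Stiffnesses of the internal (non-rigid-body) modes, ascending."""
        return self.eigenvalues[self.n_zero_modes :]

    @property
    def internal_eigenvectors(self) -> np.ndarray:
        return self.eigenvectors[:, self.n_zero_modes :]


def _anm_hessian(coords: np.ndarray, cutoff: float, gamma: float) -> np.ndarray:
    """Assemble the 3N x 3N ANM Hessian from pairwise springs."""
    n = len(coords)
    dist = squareform(pdist(coords))
    contact = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            if not contact[i, j]:
                continue
            e = coords[j] - coords[i]
            block = -gamma * np.outer(e, e) / (dist[i, j] ** 2)
            hess[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            hess[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
            hess[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            hess[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return hess


def build_enm(
    structure: Conformation,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
) -> ENModel:
    """Build and diagonalise a C-alpha elastic network.

    Requires at least 4 C-alphas and a connected spring network at the
    chosen cutoff (a disconnected network has spurious zero modes and no
    meaningful global dynamics).
    """
    coords = structure.calpha
    n = len(coords)
    if n < 2:
        raise ValueError("elastic network needs at least 2 residues")
    dist = squareform(pdist(coords))
    contact = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    n_comp, _ = connected_components(contact, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"elastic network disconnected at cutoff {cutoff} Angstrom "
            f"({n_comp} components); increase the cutoff"
        )
    hess = _anm_hessian(coords, cutoff, gamma)
    eigenvalues, eigenvectors = eigh(hess)
    eigenvalues = np.clip(eigenvalues, 0.0, None)  # clip eigensolver noise
    tol = max(eigenvalues.max(), 1.0) * _ZERO_MODE_RTOL
    n_zero = int(np.sum(eigenvalues < tol))
    return ENModel(
        reference=structure,
        cutoff=cutoff,
        gamma=gamma,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        n_zero_modes=n_zero,
    )


def generate_harmonic_trajectory(
    model: ENModel,
    n_modes: int = DEFAULT_N_MODES,
    n_frames: int = 500,
    temperature_scale: float = 1.0,
    seed: int | np.random.Generator | None = None,
    *,
    amplitude_rule: str = "gaussian",
) -> StructureEnsemble:
    """Sample frames by displacing the reference along low-frequency modes.

    Frame f is ``x_ref + sum_k a_k(f) v_k`` over the ``n_modes`` lowest
    internal modes.  With the default Gaussian rule the amplitudes are
    independent normals with variance ``temperature_scale / lambda_k``,
    so the sample mean converges to the reference and per-mode variances
    follow equipartition.  ``amplitude_rule="sine"`` instead sweeps each
    mode deterministically with matching mean-square amplitude, the way
    normal-mode visualisation trajectories oscillate.
    """
    avail = len(model.internal_eigenvalues)
    n_modes = int(n_modes)
    if n_modes < 1 or n_modes > avail:
        raise ValueError(f"n_modes must be in [1, {avail}] for this model")
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    if temperature_scale < 0:
        raise ValueError("temperature_scale must be non-negative")

    lam = model.internal_eigenvalues[:n_modes]
    modes = model.internal_eigenvectors[:, :n_modes]  # (3N, K)
    sigma = np.sqrt(temperature_scale / lam)
    if amplitude_rule == "gaussian":
        rng = np.random.default_rng(seed)
        amplitudes = rng.standard_normal((n_frames, n_modes)) * sigma
    elif amplitude_rule == "sine":
        t = np.arange(n_frames)[:, None] / n_frames
        phase = 2 * np.pi * (np.arange(n_modes) + 1)
        amplitudes = np.sqrt(2.0) * sigma * np.sin(phase * t)
    else:
        raise ValueError(f"unknown amplitude_rule {amplitude_rule!r}")

    disp = amplitudes @ modes.T  # (F, 3N)
    ref = model.reference.calpha.reshape(-1)
    coords = (ref + disp).reshape(n_frames, model.n_residues, 3)
    tag = model.reference.state
    labels = [f"{model.reference.label}|mode_frame{f + 1}" for f in range(n_frames)]
    return ensemble_from_calpha(
        coords, residues=list(model.reference.residues), labels=labels, states=tag
    )


def make_two_state_harmonic_ensemble(
    inactive: Conformation,
    active: Conformation | None = None,
    *,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
    n_modes: int = DEFAULT_N_MODES,
    n_frames_per_state: int = 500,
    temperature_scale: float = 1.0,
    seed: int | None = None,
    amplitude_rule: str = "gaussian",
) -> StructureEnsemble:
    """Concatenated harmonic trajectories around each conformational state.

    With ``active=None`` a single-state harmonic ensemble is returned
    (the inactive-only experiment).  Seeds for the two trajectories are
    derived from ``seed`` so the pair is reproducible as a unit.
    """
    rng = np.random.default_rng(seed)
    states = [("inactive", inactive)] + ([("active", active)] if active is not None else [])
    parts = []
    for tag, structure in states:
        if structure.state == "unknown":
            structure = _retagged(structure, tag)
        model = build_enm(structure, cutoff=cutoff, gamma=gamma)
        k = min(n_modes, len(model.internal_eigenvalues))
        parts.append(
            generate_harmonic_trajectory(
                model,
                n_modes=k,
                n_frames=n_frames_per_state,
                temperature_scale=temperature_scale,
                seed=rng,
                amplitude_rule=amplitude_rule,
            )
        )
    if len(parts) == 1:
        return parts[0]
    return concatenate_ensembles(parts[0], parts[1])


def _retagged(structure: Conformation, state: str) -> Conformation:
    from dataclasses import replace

    return replace(structure, state=state)
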