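"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (explicit loops, textbook
formulas, quaternion superposition) and shares no code path with the
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_two_pass(x, y) -> float:
    """Textbook two-pass Pearson correlation coefficient."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return cov / (sx * sy)


def distance_matrix(frame_xyz: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distances of one frame, explicit loops."""
    n = len(frame_xyz)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = math.dist(frame_xyz[i], frame_xyz[j])
    return out


def coupling_matrix(calpha: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Brute-force distance-Delta correlation matrix (NaN where undefined)."""
    n_frames, n_res, _ = calpha.shape
    out = np.full((n_res, n_res), np.nan)
    for i in range(n_res):
        for j in range(n_res):
            if i == j:
                continue
            d = [math.dist(calpha[f, i], calpha[f, j]) for f in range(n_frames)]
            out[i, j] = pearson_two_pass(d, delta)
    return out


def csite(coupling: np.ndarray, indices: list[int]) -> float:
    """Mean |c| over a site's unordered pairs; NaN entries count as 0."""
    n = len(indices)
    total = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            c = coupling[indices[a], indices[b]]
            if not math.isnan(c):
                total += abs(c)
    return 2.0 * total / (n * (n - 1))


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD after optimal rigid superposition (Horn's quaternion
    method) — independent of the Kabsch/SVD route."""
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)
    s = p.T @ q
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(p * p) + np.sum(q * q) - 2.0 * lam) / len(p)
    return math.sqrt(max(msd, 0.0))


def assign_residues(
    dummy_frames: list[np.ndarray],
    atom_coords_per_frame: list[np.ndarray],
    atom_res_index: np.ndarray,
    cutoff: float,
) -> set[int]:
    """All-pairs residue-to-pocket assignment (union over frames)."""
    hits: set[int] = set()
    for points, atoms in zip(dummy_frames, atom_coords_per_frame):
        for a in range(len(atoms)):
            for p in range(len(points)):
                if math.dist(atoms[a], points[p]) <= cutoff:
                    hits.add(int(atom_res_index[a]))
                    break
    return hits


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random rotation matrix and a random translation."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-20, 20, size=3)
    return q, t
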