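"""Reading, harmonising and superposing conformational ensembles.

An ensemble is a set of conformations of one receptor: a directory of
single-model PDB files, one multi-MODEL PDB/mmCIF, or a DCD/XTC
trajectory with a PDB topology.  Heterogeneous experimental entries are
harmonised onto the residues common to every frame, identified by
(chain, author residue number, insertion code) — no renumbering and no
sequence alignment is attempted.  Coordinates are in Angstrom
throughout; residue numbering follows the author numbering of the
source files and ranges are inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

_STRUCTURE_SUFFIXES = {".pdb", ".ent", ".pdb1", ".cif", ".mmcif", ".pdbx"}
_TRAJ_SUFFIXES = {".dcd", ".xtc", ".trr", ".nc"}
_WATER_NAMES = {"HOH", "WAT", "TIP3", "SOL", "DOD"}


@dataclass(frozen=True)
class ResidueID:
    """Identity of one residue: chain, author number, insertion code.

    Equality and hashing use (chain, number, insertion_code) only; the
    3-letter ``name`` is an annotation and does not participate, so the
    same position carrying a mutation in one entry still harmonises.
    """

    chain: str
    number: int
    insertion_code: str = ""
    name: str = field(default="", compare=False)

    def __str__(self) -> str:
        tag = f"{self.chain}:{self.number}{self.insertion_code}"
        return f"{tag}({self.name})" if self.name else tag

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.insertion_code)

    @classmethod
    def parse(cls, token: str, default_chain: str = "A") -> "ResidueID":
        """Parse ``"A:131"``, ``"131"`` or ``"A:52B"`` (insertion code)."""
        token = token.strip()
        if ":" in token:
            chain, rest = token.split(":", 1)
        else:
            chain, rest = default_chain, token
        rest = rest.strip()
        icode = ""
        if rest and rest[-1].isalpha():
            rest, icode = rest[:-1], rest[-1]
        return cls(chain=chain.strip(), number=int(rest), insertion_code=icode)


@dataclass
class Conformation:
    """One frame: residues with their C-alpha and heavy-atom coordinates.

    ``calpha`` is (n_residues, 3); ``atom_coords`` is (n_atoms, 3) with
    ``atom_res_index`` mapping every atom to its residue index and
    ``atom_names`` carrying PDB atom names.  Every residue retained for
    analysis has exactly one C-alpha record.
    """

    label: str
    residues: list[ResidueID]
    calpha: np.ndarray
    atom_coords: np.ndarray
    atom_res_index: np.ndarray
    atom_names: np.ndarray
    state: str = "unknown"

    def __post_init__(self) -> None:
        self.calpha = np.asarray(self.calpha, dtype=float)
        self.atom_coords = np.asarray(self.atom_coords, dtype=float)
        self.atom_res_index = np.asarray(self.atom_res_index, dtype=int)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        if self.calpha.shape != (len(self.residues), 3):
            raise ValueError(
                f"{self.label}: calpha shape {self.calpha.shape} does not match "
                f"{len(self.residues)} residues"
            )
        if not np.isfinite(self.calpha).all() or not np.isfinite(self.atom_coords).all():
            raise ValueError(f"{self.label}: non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def restrict(self, indices: Sequence[int], residues: list[ResidueID]) -> "Conformation":
        """Reindex onto a residue subset given by positional ``indices``."""
        indices = np.asarray(indices, dtype=int)
        old_to_new = {int(old): new for new, old in enumerate(indices)}
        keep = np.array([i in old_to_new for i in self.atom_res_index], dtype=bool)
        new_res_idx = np.array(
            [old_to_new[int(i)] for i in self.atom_res_index[keep]], dtype=int
        )
        return Conformation(
            label=self.label,
            residues=list(residues),
            calpha=self.calpha[indices],
            atom_coords=self.atom_coords[keep],
            atom_res_index=new_res_idx,
            atom_names=self.atom_names[keep],
            state=self.state,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformation":
        """Apply the rigid motion x -> x @ R.T + t to all coordinates."""
        return replace(
            self,
            calpha=self.calpha @ rotation.T + translation,
            atom_coords=self.atom_coords @ rotation.T + translation,
        )


@dataclass
class StructureEnsemble:
    """Conformations harmonised onto a shared, ordered residue set.

    Every conformation is indexed over ``residues`` in identical order,
    so per-residue arrays align across frames.  ``provenance`` keeps the
    per-frame source label and state tag (inactive/active/unknown).
    """

    conformations: list[Conformation]
    residues: list[ResidueID]
    superposition_rmsd: np.ndarray | None = None

    def __post_init__(self) -> None:
        for conf in self.conformations:
            if conf.residues != self.residues:
                raise ValueError(
                    f"frame {conf.label} not indexed over the common residue set"
                )

    @property
    def n_frames(self) -> int:
        return len(self.conformations)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def calpha(self) -> np.ndarray:
        """(n_frames, n_residues, 3) C-alpha coordinate array in Angstrom."""
        return np.stack([c.calpha for c in self.conformations])

    @property
    def frame_labels(self) -> list[str]:
        return [c.label for c in self.conformations]

    @property
    def states(self) -> list[str]:
        return [c.state for c in self.conformations]

    @property
    def provenance(self) -> list[tuple[str, str]]:
        return [(c.label, c.state) for c in self.conformations]

    def index_of(self, residue: ResidueID) -> int:
        try:
            return self.residues.index(residue)
        except ValueError:
            raise KeyError(f"residue {residue} not in ensemble") from None

    def find_residue(self, number: int, chain: str | None = None) -> ResidueID:
        """Look up a residue by author number (and chain when ambiguous)."""
        hits = [
            r
            for r in self.residues
            if r.number == number and (chain is None or r.chain == chain)
        ]
        if not hits:
            where = f" in chain {chain}" if chain else ""
            raise KeyError(f"residue number {number}{where} not in ensemble")
        if len(hits) > 1:
            raise KeyError(
                f"residue number {number} is ambiguous across chains "
                f"{sorted({r.chain for r in hits})}; pass a chain"
            )
        return hits[0]


# ---------------------------------------------------------------------------
# Parsing


def _conformations_from_atom_array(atoms, label: str, state: str) -> Conformation | None:
    """Build a Conformation from a biotite AtomArray (one model)."""
    import biotite.structure as struc

    mask = (atoms.element != "H") & (atoms.element != "D")
    water = np.isin(atoms.res_name, list(_WATER_NAMES))
    atoms = atoms[mask & ~water]
    if atoms.array_length() == 0:
        return None

    icodes = (
        atoms.ins_code
        if "ins_code" in atoms.get_annotation_categories()
        else np.array([""] * atoms.array_length())
    )
    residues: list[ResidueID] = []
    res_index = np.full(atoms.array_length(), -1, dtype=int)
    ca_xyz: list[np.ndarray] = []
    seen: dict[tuple[str, int, str], int] = {}

    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for s, e in zip(starts[:-1], starts[1:]):
        ca = (atoms.atom_name[s:e] == "CA") & (atoms.element[s:e] == "C")
        if not ca.any():
            continue  # no C-alpha: not analysable as a residue
        rid = ResidueID(
            chain=str(atoms.chain_id[s]),
            number=int(atoms.res_id[s]),
            insertion_code=str(icodes[s]).strip(),
            name=str(atoms.res_name[s]),
        )
        if rid.key in seen:
            logger.warning("%s: duplicate residue %s ignored", label, rid)
            continue
        seen[rid.key] = len(residues)
        res_index[s:e] = len(residues)
        residues.append(rid)
        ca_xyz.append(atoms.coord[s:e][ca][0])

    keep = res_index >= 0
    return Conformation(
        label=label,
        residues=residues,
        calpha=np.array(ca_xyz, dtype=float),
        atom_coords=atoms.coord[keep].astype(float),
        atom_res_index=res_index[keep],
        atom_names=atoms.atom_name[keep].astype(object),
        state=state,
    )


def _read_structure_file(path: Path, state: str) -> list[Conformation]:
    """Read all models of a PDB or mmCIF file as Conformations."""
    suffix = path.suffix.lower()
    confs: list[Conformation] = []
    if suffix in {".cif", ".mmcif", ".pdbx"}:
        from biotite.structure.io.pdbx import CIFFile, get_structure

        cif = CIFFile.read(str(path))
        stack = get_structure(cif, altloc="occupancy")
        arrays = list(stack) if stack.stack_depth() > 1 else [stack[0]]
        for i, arr in enumerate(arrays):
            label = path.name if len(arrays) == 1 else f"{path.name}#{i + 1}"
            conf = _conformations_from_atom_array(arr, label, state)
            if conf is not None:
                confs.append(conf)
    else:
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
        for m in range(1, n_models + 1):
            arr = pdb.get_structure(model=m, altloc="occupancy")
            label = path.name if n_models == 1 else f"{path.name}#{m}"
            conf = _conformations_from_atom_array(arr, label, state)
            if conf is not None:
                confs.append(conf)
    if not confs:
        raise ValueError(f"could not parse any usable model from {path}")
    return confs


def _read_trajectory(path: Path, topology: Path, state: str) -> list[Conformation]:
    """Read a coordinate trajectory (DCD/XTC/...) with a PDB topology."""
    import mdtraj

    traj = mdtraj.load(str(path), top=str(topology))
    top = traj.topology
    confs: list[Conformation] = []
    residues = []
    atom_res_index = []
    atom_names = []
    ca_atom_for_res: list[int] = []
    res_counter = -1
    for res in top.residues:
        if res.is_water:
            continue
        ca = [a for a in res.atoms if a.name == "CA"]
        if not ca:
            continue
        res_counter += 1
        chain = res.chain.chain_id or chr(ord("A") + res.chain.index % 26)
        residues.append(
            ResidueID(chain=str(chain), number=int(res.resSeq), name=res.name)
        )
        ca_atom_for_res.append(ca[0].index)
        for a in res.atoms:
            if a.element.symbol == "H":
                continue
            atom_res_index.append(res_counter)
            atom_names.append(a.name)
    heavy_in_res = [
        a.index
        for res in top.residues
        if not res.is_water and any(x.name == "CA" for x in res.atoms)
        for a in res.atoms
        if a.element.symbol != "H"
    ]
    for f in range(traj.n_frames):
        xyz = traj.xyz[f] * 10.0  # nm -> Angstrom
        confs.append(
            Conformation(
                label=f"{path.name}#{f + 1}",
                residues=list(residues),
                calpha=xyz[ca_atom_for_res],
                atom_coords=xyz[heavy_in_res],
                atom_res_index=np.array(atom_res_index, dtype=int),
                atom_names=np.array(atom_names, dtype=object),
                state=state,
            )
        )
    return confs


def _expand_sources(sources) -> list[Path]:
    if isinstance(sources, (str, Path)):
        sources = [sources]
    paths: list[Path] = []
    for src in sources:
        p = Path(src)
        if p.is_dir():
            inside = sorted(
                q for q in p.iterdir() if q.suffix.lower() in _STRUCTURE_SUFFIXES
            )
            if not inside:
                raise ValueError(f"no structure files found in directory {p}")
            paths.extend(inside)
        else:
            paths.append(p)
    return paths


def _in_ranges(number: int, ranges: Sequence[tuple[int, int]]) -> bool:
    return any(lo <= number <= hi for lo, hi in ranges)


def load_ensemble(
    sources,
    *,
    chain: str | None = None,
    residue_ranges: Sequence[tuple[int, int]] | None = None,
    topology: str | Path | None = None,
    states: Sequence[str] | str | None = None,
) -> StructureEnsemble:
    """Load and harmonise a conformational ensemble.

    Parameters
    ----------
    sources
        A directory of structure files, one or more PDB/mmCIF paths
        (multi-MODEL files contribute one frame per model), or — when
        ``topology`` is given — trajectory file(s) read against a PDB
        topology.
    chain
        Restrict every conformation to one chain label.
    residue_ranges
        Inclusive author-number ranges, e.g. ``[(32, 227), (267, 342)]``.
    states
        Per-source (or single) state tag: "inactive", "active", "unknown".

    The common residue set is the intersection across all frames of
    (chain, author number, insertion code); residues missing a C-alpha
    anywhere drop out of the intersection with a logged warning.
    """
    paths = _expand_sources(sources)
    if isinstance(states, str):
        states = [states] * len(paths)
    if states is not None and len(states) != len(paths):
        raise ValueError("states must match the number of sources")

    confs: list[Conformation] = []
    for i, path in enumerate(paths):
        state = states[i] if states is not None else "unknown"
        if not path.exists():
            raise FileNotFoundError(f"input not found: {path}")
        try:
            if topology is not None or path.suffix.lower() in _TRAJ_SUFFIXES:
                if topology is None:
                    raise ValueError(f"trajectory {path} requires a topology")
                confs.extend(_read_trajectory(path, Path(topology), state))
            else:
                confs.extend(_read_structure_file(path, state))
        except Exception as exc:  # annotate with the offending file
            raise ValueError(f"failed to read {path}: {exc}") from exc

    if not confs:
        raise ValueError("no conformations loaded")

    if chain is not None:
        filtered = []
        for conf in confs:
            idx = [i for i, r in enumerate(conf.residues) if r.chain == chain]
            if not idx:
                raise ValueError(f"{conf.label}: chain {chain} absent")
            filtered.append(conf.restrict(idx, [conf.residues[i] for i in idx]))
        confs = filtered
    if residue_ranges:
        filtered = []
        for conf in confs:
            idx = [
                i
                for i, r in enumerate(conf.residues)
                if _in_ranges(r.number, residue_ranges)
            ]
            filtered.append(conf.restrict(idx, [conf.residues[i] for i in idx]))
        confs = filtered

    common = _common_residues(confs)
    if not common:
        raise ValueError("no common residues across the ensemble")
    dropped = {r.key for r in confs[0].residues} - {r.key for r in common}
    if dropped:
        logger.warning(
            "%d residue(s) of the first frame are not shared by every frame "
            "and were dropped from the analysis set",
            len(dropped),
        )
    if len(confs) < 3:
        logger.warning(
            "ensemble has %d frame(s); correlations require at least 3", len(confs)
        )

    harmonised = []
    for conf in confs:
        pos = {r.key: i for i, r in enumerate(conf.residues)}
        idx = [pos[r.key] for r in common]
        harmonised.append(conf.restrict(idx, common))
    return StructureEnsemble(conformations=harmonised, residues=common)


def _common_residues(confs: Iterable[Conformation]) -> list[ResidueID]:
    """Intersection of residue identities, ordered as in the first frame."""
    confs = list(confs)
    shared = set(r.key for r in confs[0].residues)
    for conf in confs[1:]:
        shared &= {r.key for r in conf.residues}
    return [r for r in confs[0].residues if r.key in shared]


# ---------------------------------------------------------------------------
# Superposition and concatenation


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal least-squares rotation + translation (Kabsch) mapping
    ``mobile`` onto ``reference``.  Returns (R, t) with x' = x @ R.T + t."""
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - mu_r, mobile - mu_m)
    R = rot.as_matrix()
    return R, mu_r - mu_m @ R.T


def superpose_ensemble(
    ensemble: StructureEnsemble, reference: int = 0
) -> StructureEnsemble:
    """Rigid-body superpose every frame onto the reference frame.

    Least-squares fit on the common-residue C-alpha coordinates; the
    reference frame is unchanged.  Per-frame RMSD after superposition is
    stored on the returned ensemble (``superposition_rmsd``).
    """
    if not 0 <= reference < ensemble.n_frames:
        raise IndexError(f"reference frame {reference} out of range")
    ref = ensemble.conformations[reference].calpha
    if ensemble.n_residues < 3:
        raise ValueError("superposition underdetermined: fewer than 3 residues")
    if np.linalg.matrix_rank(ref - ref.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("superposition underdetermined: collinear C-alpha set")

    out: list[Conformation] = []
    rmsds = np.empty(ensemble.n_frames)
    for i, conf in enumerate(ensemble.conformations):
        if i == reference:
            moved = conf
        else:
            R, t = _kabsch(conf.calpha, ref)
            moved = conf.transformed(R, t)
        rmsds[i] = float(np.sqrt(np.mean(np.sum((moved.calpha - ref) ** 2, axis=1))))
        out.append(moved)
    return StructureEnsemble(
        conformations=out, residues=list(ensemble.residues), superposition_rmsd=rmsds
    )


def concatenate_ensembles(
    a: StructureEnsemble, b: StructureEnsemble
) -> StructureEnsemble:
    """Frames of ``a`` followed by ``b``, on their common residue set."""
    shared = {r.key for r in a.residues} & {r.key for r in b.residues}
    if not shared:
        raise ValueError("ensembles share no residues")
    common = [r for r in a.residues if r.key in shared]
    out = []
    for ens in (a, b):
        pos = {r.key: i for i, r in enumerate(ens.residues)}
        idx = [pos[r.key] for r in common]
        for conf in ens.conformations:
            out.append(conf.restrict(idx, common))
    return StructureEnsemble(conformations=out, residues=common)


# ---------------------------------------------------------------------------
# Construction helpers and output


def ensemble_from_calpha(
    coords: np.ndarray,
    residues: Sequence[ResidueID] | None = None,
    *,
    labels: Sequence[str] | None = None,
    states: Sequence[str] | str = "unknown",
) -> StructureEnsemble:
    """Build a C-alpha-only ensemble from a (n_frames, n_residues, 3) array.

    Used by the harmonic and synthetic generators; each residue's single
    C-alpha doubles as its only heavy atom.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coords must have shape (n_frames, n_residues, 3)")
    n_frames, n_res, _ = coords.shape
    if residues is None:
        residues = [ResidueID("A", i + 1, name="ALA") for i in range(n_res)]
    residues = list(residues)
    if labels is None:
        labels = [f"frame{i + 1}" for i in range(n_frames)]
    if isinstance(states, str):
        states = [states] * n_frames
    confs = [
        Conformation(
            label=labels[f],
            residues=residues,
            calpha=coords[f],
            atom_coords=coords[f].copy(),
            atom_res_index=np.arange(n_res),
            atom_names=np.array(["CA"] * n_res, dtype=object),
            state=states[f],
        )
        for f in range(n_frames)
    ]
    return StructureEnsemble(conformations=confs, residues=residues)


def write_ensemble(ensemble: StructureEnsemble, path: str | Path) -> Path:
    """Write the ensemble as a multi-MODEL PDB file.

    All heavy atoms are written when every frame shares one atom layout;
    otherwise the C-alpha trace is written (heterogeneous experimental
    entries rarely agree atom-for-atom).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    first = ensemble.conformations[0]
    homogeneous = all(
        c.atom_names.shape == first.atom_names.shape
        and (c.atom_names == first.atom_names).all()
        and (c.atom_res_index == first.atom_res_index).all()
        for c in ensemble.conformations
    )

    def _array(conf: Conformation, calpha_only: bool):
        if calpha_only:
            names = np.array(["CA"] * conf.n_residues, dtype=object)
            res_idx = np.arange(conf.n_residues)
            coords = conf.calpha
        else:
            names, res_idx, coords = conf.atom_names, conf.atom_res_index, conf.atom_coords
        n = len(names)
        arr = struc.AtomArray(n)
        arr.coord = coords
        arr.atom_name = names.astype("U6")
        arr.chain_id = np.array([conf.residues[i].chain for i in res_idx], dtype="U4")
        arr.res_id = np.array([conf.residues[i].number for i in res_idx])
        arr.ins_code = np.array(
            [conf.residues[i].insertion_code for i in res_idx], dtype="U1"
        )
        arr.res_name = np.array(
            [conf.residues[i].name or "ALA" for i in res_idx], dtype="U5"
        )
        arr.element = np.array(
            [(n[0] if n[:1].isalpha() else "C") for n in arr.atom_name], dtype="U2"
        )
        arr.hetero = np.zeros(n, dtype=bool)
        return arr

    stack = struc.stack(
        [_array(c, calpha_only=not homogeneous) for c in ensemble.conformations]
    )
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    return path
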