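"""Trajectory frame I/O and named-selection resolution.

This module owns the two in-memory containers the rest of the package
consumes — :class:`TrajectoryFrames` (per-frame Cartesian coordinates with
atom metadata, always in Å) and :class:`SelectionSpec` (the mapping from
field-level names — Ballesteros–Weinstein positions such as ``6.51``, the
ligand chain atom quartet, aromatic ring atom names — to concrete atoms).

File formats (multi-model PDB with one MODEL per frame, and plain XYZ
trajectories) are read and written through MDAnalysis; a lightweight block
structure pre-scan runs first so that malformed files fail with an error
naming the offending MODEL or XYZ block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    EmptyInputError,
    FormatError,
    SelectionError,
    TrajectoryParseError,
)

__all__ = [
    "AtomRecord",
    "TrajectoryFrames",
    "SelectionSpec",
    "read_multimodel_pdb",
    "read_xyz_trajectory",
    "write_multimodel_pdb",
    "resolve_selection",
]

# First side-chain heavy atom beyond CB, tried in order: the standard chi1
# quartet is N-CA-CB-<gamma> with CG for Leu/Phe/Trp, CG1 for Val/Ile,
# OG/OG1 for Ser/Thr, SG for Cys.
_GAMMA_CANDIDATES = ("CG", "CG1", "OG", "OG1", "SG")

# %8.3f PDB coordinate columns admit -999.999 .. 9999.999
_PDB_COORD_MIN = -999.999
_PDB_COORD_MAX = 9999.999


@dataclass(frozen=True)
class AtomRecord:
    """Identity of one atom, constant across frames."""

    atom_name: str
    residue_name: str
    residue_id: int
    chain_id: str
    element: str

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be nonempty")
        if self.residue_id < 1:
            raise ValueError(f"residue_id must be >= 1, got {self.residue_id}")


@dataclass
class TrajectoryFrames:
    """An in-memory trajectory: fixed atom list, frames x atoms x 3 coords in Å."""

    atoms: list[AtomRecord]
    coords: np.ndarray
    replica_id: int = 0
    frame_stride_ns: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (frames, atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coords have {self.coords.shape[1]} atoms but metadata has "
                f"{len(self.atoms)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.frame_stride_ns <= 0:
            raise ValueError("frame_stride_ns must be positive")
        keys = [(a.residue_id, a.atom_name, a.chain_id) for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise ValueError(f"duplicate atom key {dup} within frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class SelectionSpec:
    """Named selections used by the analysis.

    ``bw_map`` maps Ballesteros–Weinstein positions (e.g. ``"6.51"``) to a
    ``(residue_id, residue_name)`` pair; the mapping is supplied by the user
    (typically from the receptor's GPCRdb annotation), never inferred.
    ``ligand_quartet`` lists the four ligand chain atoms, in 1→2→3→4 order,
    whose dihedral defines the chain binding mode.  ``ring_atoms`` are the
    aromatic ring atoms of the residue at ``ring_bw`` (the toggle-switch
    Phe at 3.36 by default).  ``receptor_fit_atoms`` is the atom-name filter
    used for rigid superposition (backbone alpha-carbons by default).
    """

    bw_map: dict[str, tuple[int, str]]
    ligand_quartet: list[str]
    ligand_terminal_atoms: list[str]
    ring_atoms: list[str]
    receptor_fit_atoms: list[str] = field(default_factory=lambda: ["CA"])
    ring_bw: str = "3.36"
    ligand_chain: str | None = None

    def __post_init__(self) -> None:
        if len(self.ligand_quartet) != 4 or len(set(self.ligand_quartet)) != 4:
            raise ValueError("ligand_quartet must hold exactly 4 distinct atom names")
        if len(self.ligand_terminal_atoms) < 1:
            raise ValueError("ligand_terminal_atoms must hold at least one name")
        if len(self.ring_atoms) < 3:
            raise ValueError("ring_atoms must hold at least 3 names")
        if not self.receptor_fit_atoms:
            raise ValueError("receptor_fit_atoms must hold at least one name")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SelectionSpec":
        bw_raw = data["bw_map"]
        if isinstance(bw_raw, Mapping):
            bw_map = {
                str(k): (int(v[0]), str(v[1])) for k, v in bw_raw.items()
            }
        else:  # list of (position, residue_id, residue_name) rows
            bw_map = {str(r[0]): (int(r[1]), str(r[2])) for r in bw_raw}
        return cls(
            bw_map=bw_map,
            ligand_quartet=list(data["ligand_quartet"]),
            ligand_terminal_atoms=list(data["ligand_terminal_atoms"]),
            ring_atoms=list(data["ring_atoms"]),
            receptor_fit_atoms=list(data.get("receptor_fit_atoms", ["CA"])),
            ring_bw=str(data.get("ring_bw", "3.36")),
            ligand_chain=data.get("ligand_chain"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SelectionSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "bw_map": {k: list(v) for k, v in self.bw_map.items()},
            "ligand_quartet": list(self.ligand_quartet),
            "ligand_terminal_atoms": list(self.ligand_terminal_atoms),
            "ring_atoms": list(self.ring_atoms),
            "receptor_fit_atoms": list(self.receptor_fit_atoms),
            "ring_bw": self.ring_bw,
            "ligand_chain": self.ligand_chain,
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _prescan_pdb_models(path: Path) -> None:
    """Validate MODEL block structure before handing the file to MDAnalysis."""
    counts: list[int] = []
    current: int | None = None
    saw_model = False
    n_records = 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current or 0)
                current = None
            elif rec in ("ATOM", "HETATM"):
                n_records += 1
                if current is not None:
                    current += 1
                elif saw_model:
                    # atom records outside MODEL blocks in a multi-model file
                    raise TrajectoryParseError(
                        f"{path}: ATOM/HETATM record outside MODEL/ENDMDL block"
                    )
    if current is not None:
        counts.append(current)
    if n_records == 0:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records found")
    if counts and len(set(counts)) > 1:
        ref = counts[0]
        bad = next(i for i, c in enumerate(counts, start=1) if c != ref)
        raise TrajectoryParseError(
            f"{path}: model {bad} has {counts[bad - 1]} atoms, "
            f"model 1 has {ref}; atom counts must match across models"
        )


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def read_multimodel_pdb(
    path: str | Path, replica_id: int = 0, frame_stride_ns: float = 1.0
) -> TrajectoryFrames:
    """Read a multi-model PDB file, one frame per MODEL record.

    HETATM records are accepted identically to ATOM records.  Raises
    :class:`TrajectoryParseError` naming the model index when atom counts
    differ between models, and :class:`EmptyInputError` for a file with no
    coordinate records.
    """
    import MDAnalysis as mda

    path = Path(path)
    _prescan_pdb_models(path)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords = np.array([ts.positions.copy() for ts in u.trajectory], dtype=float)

    try:
        chain_ids = [str(c) for c in u.atoms.chainIDs]
    except AttributeError:
        chain_ids = [str(s) for s in u.atoms.segids]
    try:
        elements = [str(e) if str(e) else _guess_element(n)
                    for e, n in zip(u.atoms.elements, u.atoms.names)]
    except AttributeError:
        elements = [_guess_element(n) for n in u.atoms.names]

    atoms = [
        AtomRecord(
            atom_name=str(name),
            residue_name=str(resname),
            residue_id=int(resid),
            chain_id=chain,
            element=elem,
        )
        for name, resname, resid, chain, elem in zip(
            u.atoms.names, u.atoms.resnames, u.atoms.resids, chain_ids, elements
        )
    ]
    return TrajectoryFrames(
        atoms=atoms,
        coords=coords,
        replica_id=replica_id,
        frame_stride_ns=frame_stride_ns,
    )


def _prescan_xyz_blocks(path: Path) -> int:
    lines = Path(path).read_text().splitlines()
    # drop trailing blank lines only; blanks inside a block are malformed
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise EmptyInputError(f"{path}: empty XYZ file")
    i = 0
    block = 0
    while i < len(lines):
        block += 1
        try:
            n = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise TrajectoryParseError(
                f"{path}: block {block} does not start with an atom count "
                f"(line {i + 1}: {lines[i]!r})"
            ) from None
        body = lines[i + 2 : i + 2 + n]
        ok = len(body) == n and all(len(l.split()) >= 4 for l in body)
        if not ok:
            raise TrajectoryParseError(
                f"{path}: block {block} declares {n} atoms but "
                f"{len([l for l in body if l.strip()])} atom lines follow"
            )
        i += 2 + n
    return block


def read_xyz_trajectory(
    path: str | Path, replica_id: int = 0, frame_stride_ns: float = 1.0
) -> TrajectoryFrames:
    """Read a concatenated-block XYZ trajectory.

    Element symbols are recorded; atom names are synthesized as
    ``<element><index>`` (1-based file order) so atom keys stay unique.
    """
    import MDAnalysis as mda

    path = Path(path)
    _prescan_xyz_blocks(path)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="XYZ", topology_format="XYZ")
        coords = np.array([ts.positions.copy() for ts in u.trajectory], dtype=float)

    atoms = [
        AtomRecord(
            atom_name=f"{str(name)}{i + 1}",
            residue_name="UNK",
            residue_id=1,
            chain_id="X",
            element=str(name),
        )
        for i, name in enumerate(u.atoms.names)
    ]
    return TrajectoryFrames(
        atoms=atoms,
        coords=coords,
        replica_id=replica_id,
        frame_stride_ns=frame_stride_ns,
    )


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------


def write_multimodel_pdb(frames: TrajectoryFrames, path: str | Path) -> None:
    """Write frames as a multi-model PDB (MODEL/ENDMDL per frame).

    Coordinates are emitted in the fixed %8.3f PDB columns; values outside
    that range raise :class:`FormatError`.  The write → read round trip
    preserves atom names, residue ids and chain ids exactly and coordinates
    to ±0.001 Å.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    if frames.n_atoms == 0:
        raise EmptyInputError("cannot write a trajectory with no atoms")
    lo, hi = frames.coords.min(), frames.coords.max()
    if lo < _PDB_COORD_MIN or hi > _PDB_COORD_MAX:
        raise FormatError(
            f"coordinate range [{lo:.3f}, {hi:.3f}] Å exceeds the PDB "
            f"%8.3f column range [{_PDB_COORD_MIN}, {_PDB_COORD_MAX}]"
        )

    # group consecutive atoms into residues by (chain, resid, resname)
    res_keys: list[tuple[str, int, str]] = []
    atom_resindex = np.empty(frames.n_atoms, dtype=int)
    for i, a in enumerate(frames.atoms):
        key = (a.chain_id, a.residue_id, a.residue_name)
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex[i] = len(res_keys) - 1

    seg_keys = sorted({k[0] for k in res_keys})
    seg_index = {c: i for i, c in enumerate(seg_keys)}
    residue_segindex = np.array([seg_index[k[0]] for k in res_keys], dtype=int)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=frames.n_atoms,
            n_residues=len(res_keys),
            n_segments=len(seg_keys),
            atom_resindex=atom_resindex,
            residue_segindex=residue_segindex,
            trajectory=False,
        )
        u.add_TopologyAttr("names", [a.atom_name for a in frames.atoms])
        u.add_TopologyAttr("elements", [a.element for a in frames.atoms])
        u.add_TopologyAttr("chainIDs", [a.chain_id for a in frames.atoms])
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
        u.add_TopologyAttr("segids", seg_keys)
        u.add_TopologyAttr("occupancies", np.ones(frames.n_atoms))
        u.add_TopologyAttr("tempfactors", np.zeros(frames.n_atoms))
        u.load_new(frames.coords.astype(np.float32), format=MemoryReader)

        with mda.Writer(
            str(path), n_atoms=frames.n_atoms, multiframe=True, bonds=None
        ) as writer:
            for _ in u.trajectory:
                writer.write(u.atoms)


# ---------------------------------------------------------------------------
# selection resolution
# ---------------------------------------------------------------------------

_ROLES = (
    "ligand_quartet",
    "ligand_terminal_atoms",
    "ring_atoms",
    "receptor_fit_atoms",
)


def _find_named_atom(
    frames: TrajectoryFrames,
    name: str,
    chain: str | None = None,
    residue_id: int | None = None,
) -> int:
    hits = [
        i
        for i, a in enumerate(frames.atoms)
        if a.atom_name == name
        and (chain is None or a.chain_id == chain)
        and (residue_id is None or a.residue_id == residue_id)
    ]
    scope = f"atom name {name!r}"
    if chain is not None:
        scope += f" on chain {chain!r}"
    if residue_id is not None:
        scope += f" in residue {residue_id}"
    if not hits:
        raise SelectionError(f"no atom matching {scope}")
    if len(hits) > 1:
        raise SelectionError(
            f"{len(hits)} atoms match {scope}; scope the selection with a "
            "chain or residue"
        )
    return hits[0]


def _resolve_chi1(frames: TrajectoryFrames, spec: SelectionSpec, bw: str) -> list[int]:
    if bw not in spec.bw_map:
        raise SelectionError(
            f"Ballesteros-Weinstein position {bw!r} absent from bw_map "
            f"(known: {sorted(spec.bw_map)})"
        )
    resid, resname = spec.bw_map[bw]
    res_atoms = {
        a.atom_name: i
        for i, a in enumerate(frames.atoms)
        if a.residue_id == resid and a.residue_name == resname
    }
    if not res_atoms:
        raise SelectionError(
            f"residue {resname} {resid} (BW {bw}) not found in trajectory"
        )
    quartet = []
    for name in ("N", "CA", "CB"):
        if name not in res_atoms:
            raise SelectionError(
                f"residue {resname} {resid} (BW {bw}) lacks atom {name!r} "
                "needed for chi1"
            )
        quartet.append(res_atoms[name])
    gamma = next((g for g in _GAMMA_CANDIDATES if g in res_atoms), None)
    if gamma is None:
        raise SelectionError(
            f"residue {resname} {resid} (BW {bw}) has no gamma atom among "
            f"{_GAMMA_CANDIDATES}; cannot build chi1 quartet"
        )
    quartet.append(res_atoms[gamma])
    return quartet


def resolve_selection(
    frames: TrajectoryFrames, spec: SelectionSpec, key: str
) -> list[int]:
    """Resolve a named selection to atom indices in file order.

    ``key`` is either one of the roles ``ligand_quartet``,
    ``ligand_terminal_atoms``, ``ring_atoms``, ``receptor_fit_atoms`` — or a
    Ballesteros–Weinstein position present in ``spec.bw_map`` (e.g.
    ``"6.51"``), which resolves to that residue's chi1 quartet
    N, CA, CB, first gamma atom.
    """
    if key == "ligand_quartet":
        return [
            _find_named_atom(frames, n, chain=spec.ligand_chain)
            for n in spec.ligand_quartet
        ]
    if key == "ligand_terminal_atoms":
        return [
            _find_named_atom(frames, n, chain=spec.ligand_chain)
            for n in spec.ligand_terminal_atoms
        ]
    if key == "ring_atoms":
        if spec.ring_bw not in spec.bw_map:
            raise SelectionError(
                f"ring_bw {spec.ring_bw!r} absent from bw_map"
            )
        resid, _ = spec.bw_map[spec.ring_bw]
        return [
            _find_named_atom(frames, n, residue_id=resid) for n in spec.ring_atoms
        ]
    if key == "receptor_fit_atoms":
        wanted = set(spec.receptor_fit_atoms)
        idx = [i for i, a in enumerate(frames.atoms) if a.atom_name in wanted]
        if not idx:
            raise SelectionError(
                f"no atoms matching receptor_fit_atoms {sorted(wanted)}"
            )
        return idx
    if key in _ROLES:  # pragma: no cover - exhaustive above
        raise SelectionError(f"unhandled role {key!r}")
    return _resolve_chi1(frames, spec, key)
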