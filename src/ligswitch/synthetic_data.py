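"""Synthetic trajectories with the statistical structure the analysis assumes.

The generator emulates the regimes seen in cannabinoid-receptor MD runs
without any physics: the ligand chain dihedral switches between two states
by a first-order Markov chain (−anticlinal/L-shape vs +anticlinal/I-shape),
the 6.51 side-chain chi1 rotamer probabilistically tracks the chain state
(``p_couple`` spans independence → lockstep), angles are emitted from von
Mises distributions around the canonical centers (−90°/+90° for the chain,
180°/−60° for t/g+), and the ligand-terminal-to-ring-centroid distance is
Gaussian with a state-dependent mean straddling the 5 Å contact criterion.

Two receptor variants are provided: ``CB1-like`` (chain switching enabled,
Leu at 6.51) and ``CB2-like`` (chain locked in the −anticlinal state, Val
at 6.51) — mirroring that the pentyl chain rarely reaches the +anticlinal
pose in CB2R.

``series_to_coordinates`` realizes each frame as 3-D coordinates — a
4-atom ligand chain and side-chain quartet built by internal-coordinate
placement (bonds 1.53 Å, angles 111°) whose dihedrals equal the emitted
angles exactly, a 6-atom aromatic ring placed so the terminal-atom-to-
centroid distance equals the emitted distance, and static backbone
alpha-carbons for superposition — so the whole pipeline can run from
multi-model PDB files with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .geometry import (
    DistanceSeries,
    TorsionSeries,
    build_torsion_quartet,
    place_fourth_atom,
    wrap_degrees,
)
from .states import CHAIN_STATES, ROTAMER_STATES, StateSeries
from .structures_io import AtomRecord, SelectionSpec, TrajectoryFrames, write_multimodel_pdb

__all__ = [
    "SyntheticParams",
    "ReplicaSeries",
    "simulate_series",
    "series_to_coordinates",
    "synthetic_selection_spec",
    "write_synthetic_dataset",
]

_VARIANTS = ("CB1-like", "CB2-like")

# minimum emitted distance: the Gaussian tail is truncated here so emitted
# distances stay physical (> 0); at the default mean/sd this never triggers
_MIN_DISTANCE = 1e-3

_BOND = 1.53  # aliphatic C-C, Å
_ANGLE = 111.0  # sp3 C-C-C, degrees
_RING_RADIUS = 1.39  # aromatic C-C ring circumradius, Å


@dataclass
class SyntheticParams:
    """Full parameterization of the coupled-Markov / von Mises generator.

    ``chain_transition`` is row-stochastic over (MINUS_AC, PLUS_AC); the
    default 0.99 self-transition gives dwell times of ~100 frames, long
    enough for clean two-state traces at the default 1000-frame length.
    ``p_couple`` is the per-frame probability that the rotamer state copies
    the chain state (otherwise it resamples from the chain's stationary
    marginal, which makes the two series exactly independent at 0).
    ``distance_mean`` maps chain state → mean emitted distance in Å; the
    defaults (L-shape 7.0, I-shape 4.0) straddle the 5 Å gate criterion.
    """

    seed: int
    n_frames: int = 1000
    n_replicas: int = 3
    chain_transition: tuple[tuple[float, float], tuple[float, float]] = (
        (0.99, 0.01),
        (0.01, 0.99),
    )
    p_couple: float = 0.9
    chain_centers: tuple[float, float] = (-90.0, 90.0)  # MINUS_AC, PLUS_AC
    rotamer_centers: tuple[float, float] = (180.0, -60.0)  # T, GPLUS
    kappa: float = 8.0
    distance_mean: tuple[float, float] = (7.0, 4.0)  # per chain state, Å
    distance_sd: float = 0.5
    receptor_variant: str = "CB1-like"
    frame_stride_ns: float = 1.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ConfigError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.n_replicas < 1:
            raise ConfigError(f"n_replicas must be >= 1, got {self.n_replicas}")
        matrix = np.asarray(self.chain_transition, dtype=float)
        if matrix.shape != (2, 2) or np.any(matrix < 0) or np.any(matrix > 1):
            raise ConfigError("chain_transition must be a 2x2 matrix of probabilities")
        if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError(
                f"chain_transition rows must sum to 1, got {matrix.sum(axis=1)}"
            )
        if not 0.0 <= self.p_couple <= 1.0:
            raise ConfigError(f"p_couple must be in [0, 1], got {self.p_couple}")
        if self.kappa <= 0:
            raise ConfigError(f"kappa must be > 0, got {self.kappa}")
        if self.distance_sd <= 0:
            raise ConfigError(f"distance_sd must be > 0, got {self.distance_sd}")
        if any(m <= 0 for m in self.distance_mean):
            raise ConfigError(f"distance_mean must be > 0, got {self.distance_mean}")
        for name in ("chain_centers", "rotamer_centers"):
            centers = getattr(self, name)
            if any(c <= -180.0 or c > 180.0 for c in centers):
                raise ConfigError(f"{name} must lie in (-180, 180], got {centers}")
        if self.receptor_variant not in _VARIANTS:
            raise ConfigError(
                f"receptor_variant must be one of {_VARIANTS}, "
                f"got {self.receptor_variant!r}"
            )

    @property
    def transition_matrix(self) -> np.ndarray:
        return np.asarray(self.chain_transition, dtype=float)

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the chain Markov matrix.

        CB2-like runs are locked in MINUS_AC, so their stationary
        distribution is the point mass (1, 0) regardless of the matrix.
        """
        if self.receptor_variant == "CB2-like":
            return np.array([1.0, 0.0])
        matrix = self.transition_matrix
        vals, vecs = np.linalg.eig(matrix.T)
        stat = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
        stat = np.abs(stat)
        return stat / stat.sum()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chain_transition"] = [list(r) for r in self.chain_transition]
        for k in ("chain_centers", "rotamer_centers", "distance_mean"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticParams":
        data = dict(data)
        for k in ("chain_centers", "rotamer_centers", "distance_mean"):
            if k in data:
                data[k] = tuple(data[k])
        if "chain_transition" in data:
            data["chain_transition"] = tuple(tuple(r) for r in data["chain_transition"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"invalid generator parameters: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class ReplicaSeries:
    """Ground-truth series bundle for one synthetic replica."""

    chain_torsion: TorsionSeries
    rotamer_torsion: TorsionSeries
    distance: DistanceSeries
    chain_states: StateSeries
    rotamer_states: StateSeries
    replica_id: int


def _simulate_replica(params: SyntheticParams, replica_id: int) -> ReplicaSeries:
    # documented seed-derivation rule: replica r uses seed + r
    rng = np.random.default_rng(params.seed + replica_id)
    n = params.n_frames
    matrix = params.transition_matrix

    chain = np.zeros(n, dtype=int)  # trajectories start in the docked L-shape
    if params.receptor_variant == "CB1-like":
        draws = rng.random(n - 1) if n > 1 else np.empty(0)
        for t in range(1, n):
            chain[t] = int(draws[t - 1] > matrix[chain[t - 1], 0])

    stationary = params.stationary_distribution()
    copy_mask = rng.random(n) < params.p_couple
    resampled = rng.choice(2, size=n, p=stationary)
    rotamer = np.where(copy_mask, chain, resampled)

    chain_angles = wrap_degrees(
        np.degrees(
            rng.vonmises(np.radians(np.take(params.chain_centers, chain)), params.kappa)
        )
    )
    rot_angles = wrap_degrees(
        np.degrees(
            rng.vonmises(
                np.radians(np.take(params.rotamer_centers, rotamer)), params.kappa
            )
        )
    )
    distances = np.clip(
        rng.normal(np.take(params.distance_mean, chain), params.distance_sd),
        _MIN_DISTANCE,
        None,
    )

    return ReplicaSeries(
        chain_torsion=TorsionSeries(chain_angles, label="chain_1234", replica_id=replica_id),
        rotamer_torsion=TorsionSeries(rot_angles, label="chi1_6.51", replica_id=replica_id),
        distance=DistanceSeries(distances, label="terminal_to_ring", replica_id=replica_id),
        chain_states=StateSeries(
            np.take(np.array(CHAIN_STATES, dtype=object), chain),
            scheme="chain_mode",
            replica_id=replica_id,
        ),
        rotamer_states=StateSeries(
            np.take(np.array(ROTAMER_STATES, dtype=object), rotamer),
            scheme="rotamer",
            replica_id=replica_id,
        ),
        replica_id=replica_id,
    )


def simulate_series(params: SyntheticParams) -> list[ReplicaSeries]:
    """Simulate the per-replica ground-truth series bundles.

    Identical parameters (including seed) give identical output.
    """
    return [_simulate_replica(params, r) for r in range(params.n_replicas)]


# ---------------------------------------------------------------------------
# coordinate realization
# ---------------------------------------------------------------------------

_RESIDUE_NUMBERING = {
    # (ring residue id, 6.51 residue id, 6.51 residue name)
    "CB1-like": (200, 359, "LEU"),
    "CB2-like": (117, 196, "VAL"),
}


def synthetic_selection_spec(params: SyntheticParams) -> SelectionSpec:
    """The SelectionSpec matching the atom names built by series_to_coordinates."""
    ring_resid, res651, resname651 = _RESIDUE_NUMBERING[params.receptor_variant]
    return SelectionSpec(
        bw_map={"3.36": (ring_resid, "PHE"), "6.51": (res651, resname651)},
        ligand_quartet=["C1", "C2", "C3", "C4"],
        ligand_terminal_atoms=["C4"],
        ring_atoms=["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
        receptor_fit_atoms=["CA"],
        ring_bw="3.36",
        ligand_chain="L",
    )


def _atom_records(params: SyntheticParams) -> list[AtomRecord]:
    ring_resid, res651, resname651 = _RESIDUE_NUMBERING[params.receptor_variant]
    gamma = "CG" if resname651 == "LEU" else "CG1"
    records = [
        AtomRecord("CA", "GLY", i + 1, "A", "C") for i in range(4)
    ]
    records += [
        AtomRecord(name, resname651, res651, "A", name[0])
        for name in ("N", "CA", "CB", gamma)
    ]
    records += [
        AtomRecord(name, "PHE", ring_resid, "A", "C")
        for name in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    ]
    records += [AtomRecord(f"C{i + 1}", "THC", 1, "L", "C") for i in range(4)]
    return records


# static scaffold positions (Å): four backbone alpha-carbons spread out so
# the superposition fit is well conditioned, plus anchors for the side chain
# and ligand far enough apart that selections never collide spatially
_FIT_CA = np.array(
    [[0.0, 0.0, 0.0], [8.0, 0.0, 0.0], [0.0, 8.0, 0.0], [0.0, 0.0, 8.0]]
)
_SIDECHAIN_ORIGIN = np.array([20.0, 0.0, 0.0])
_LIGAND_ORIGIN = np.array([35.0, 10.0, 0.0])

# hexagonal ring template in the xy-plane, centered at the origin
_RING_TEMPLATE = _RING_RADIUS * np.array(
    [
        [np.cos(k * np.pi / 3.0), np.sin(k * np.pi / 3.0), 0.0]
        for k in range(6)
    ]
)
_RING_DIRECTION = np.array([0.0, 0.0, 1.0])  # centroid offset from terminal atom


def series_to_coordinates(
    replica: ReplicaSeries, params: SyntheticParams
) -> TrajectoryFrames:
    """Realize a series bundle as 3-D coordinates (one frame per time point).

    Per frame the builder places (i) the 4-atom ligand chain whose 1-2-3-4
    dihedral equals the emitted chain torsion, (ii) the side-chain quartet
    N-CA-CB-Cγ realizing the emitted chi1, (iii) the aromatic ring hexagon
    with its centroid at the emitted distance from the ligand terminal atom,
    and (iv) four static alpha-carbons for superposition. Re-analyzing the
    output reproduces the input series to ~1e-6 precision.
    """
    n = len(replica.chain_torsion)
    atoms = _atom_records(params)
    coords = np.empty((n, len(atoms), 3))

    # side-chain N, CA, CB are static; only the gamma atom moves with chi1
    side_base = build_torsion_quartet(180.0, origin=_SIDECHAIN_ORIGIN)[:3]

    for f in range(n):
        d = replica.distance.values[f]
        if d < 0:
            raise ConfigError(f"frame {f}: infeasible negative distance {d}")
        ligand = build_torsion_quartet(
            float(replica.chain_torsion.values[f]), origin=_LIGAND_ORIGIN
        )
        gamma = place_fourth_atom(
            side_base[0],
            side_base[1],
            side_base[2],
            _BOND,
            _ANGLE,
            float(replica.rotamer_torsion.values[f]),
        )
        centroid = ligand[3] + d * _RING_DIRECTION
        coords[f, 0:4] = _FIT_CA
        coords[f, 4:7] = side_base
        coords[f, 7] = gamma
        coords[f, 8:14] = _RING_TEMPLATE + centroid
        coords[f, 14:18] = ligand

    return TrajectoryFrames(
        atoms=atoms,
        coords=coords,
        replica_id=replica.replica_id,
        frame_stride_ns=params.frame_stride_ns,
    )


def write_synthetic_dataset(params: SyntheticParams, outdir: str | Path) -> dict:
    """Generate, realize, and write a full synthetic dataset to disk.

    Writes one multi-model PDB per replica (``replica_<r>.pdb``), a ground
    truth CSV (frame, replica, true chain state, true rotamer state, and the
    emitted angle/distance series), and the matching SelectionSpec YAML.
    Returns a manifest of written paths. Re-running with identical params
    reproduces identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    replicas = simulate_series(params)
    pdb_paths = []
    truth_rows = []
    for rep in replicas:
        frames = series_to_coordinates(rep, params)
        path = outdir / f"replica_{rep.replica_id}.pdb"
        write_multimodel_pdb(frames, path)
        pdb_paths.append(str(path))
        truth_rows.append(
            pd.DataFrame(
                {
                    "replica_id": rep.replica_id,
                    "frame": np.arange(len(rep.chain_torsion)),
                    "chain_state": rep.chain_states.labels,
                    "rotamer_state": rep.rotamer_states.labels,
                    "chain_torsion_deg": rep.chain_torsion.values,
                    "chi1_deg": rep.rotamer_torsion.values,
                    "distance_angstrom": rep.distance.values,
                }
            )
        )
    truth_path = outdir / "ground_truth.csv"
    pd.concat(truth_rows, ignore_index=True).to_csv(truth_path, index=False)
    spec = synthetic_selection_spec(params)
    spec_path = outdir / "selection.yaml"
    spec.to_yaml(spec_path)
    params_path = outdir / "params.yaml"
    params.to_yaml(params_path)
    return {
        "pdb": pdb_paths,
        "ground_truth": str(truth_path),
        "selection": str(spec_path),
        "params": str(params_path),
    }
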