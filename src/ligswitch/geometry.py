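"""Geometric kernels: signed torsions, ring centroids, distances, Kabsch RMSD.

Angles are signed IUPAC torsions in degrees on the half-open range
(−180, +180], with +180 preferred over −180. Distances and RMSDs are in Å.
Rigid superposition uses the Kabsch algorithm (proper rotations only) via
``scipy.spatial.transform.Rotation.align_vectors``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ConfigError, GeometryError
from .structures_io import TrajectoryFrames

__all__ = [
    "TorsionSeries",
    "DistanceSeries",
    "RmsdSeries",
    "torsion",
    "torsion_series",
    "ring_centroid",
    "min_distance_series",
    "kabsch_superpose",
    "ligand_rmsd_series",
    "wrap_degrees",
    "build_torsion_quartet",
    "place_fourth_atom",
    "series_to_frame",
]

_COLLINEAR_TOL = 1e-10


def wrap_degrees(angle):
    """Wrap angle(s) in degrees onto (−180, +180], preferring +180 over −180."""
    wrapped = np.mod(np.asarray(angle, dtype=float), 360.0)
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return float(wrapped) if np.isscalar(angle) or np.ndim(angle) == 0 else wrapped


@dataclass
class TorsionSeries:
    """Per-frame signed torsion in degrees, range (−180, +180]."""

    values: np.ndarray
    label: str = ""
    replica_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a nonempty 1-D array")
        if np.any(self.values <= -180.0) or np.any(self.values > 180.0):
            raise ValueError("torsion values must lie in (-180, 180]")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class DistanceSeries:
    """Per-frame distance in Å (nonnegative, finite)."""

    values: np.ndarray
    label: str = ""
    replica_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a nonempty 1-D array")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite and >= 0")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class RmsdSeries:
    """Per-frame RMSD in Å versus a reference frame of the same trajectory."""

    values: np.ndarray
    reference_frame: int = 0
    label: str = ""
    replica_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be >= 0")

    def __len__(self) -> int:
        return self.values.size


def series_to_frame(series) -> pd.DataFrame:
    """Export a per-frame series as a DataFrame (replica_id, frame, label, value)."""
    return pd.DataFrame(
        {
            "replica_id": series.replica_id,
            "frame": np.arange(len(series)),
            "label": series.label,
            "value": series.values,
        }
    )


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------


def _torsion_batch(p1, p2, p3, p4, context: str = "") -> np.ndarray:
    """Signed torsion for (N,3) point batches, degrees in (−180, 180]."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n_b2 = np.linalg.norm(b2, axis=-1)
    if np.any(n_b2 < _COLLINEAR_TOL):
        bad = int(np.argmax(n_b2 < _COLLINEAR_TOL))
        raise GeometryError(f"central bond atoms coincide{context or f' (entry {bad})'}")
    c1 = np.cross(b1, b2)
    c2 = np.cross(b2, b3)
    scale = n_b2 * np.maximum(
        np.linalg.norm(b1, axis=-1) * np.linalg.norm(b3, axis=-1), _COLLINEAR_TOL
    )
    degenerate = (np.linalg.norm(c1, axis=-1) < _COLLINEAR_TOL * scale) | (
        np.linalg.norm(c2, axis=-1) < _COLLINEAR_TOL * scale
    )
    if np.any(degenerate):
        bad = int(np.argmax(degenerate))
        raise GeometryError(
            f"collinear atom triple: torsion undefined{context or f' (entry {bad})'}"
        )
    # atan2 cross/dot formulation; sign follows the IUPAC right-hand rule
    # (positive = clockwise rotation of bond 3->4 sighting down the 2->3 axis)
    x = np.einsum("...i,...i", c1, c2)
    y = np.einsum("...i,...i", np.cross(c1, c2), b2 / n_b2[..., None])
    return wrap_degrees(np.degrees(np.arctan2(y, x)))


def torsion(p1, p2, p3, p4) -> float:
    """Signed IUPAC torsion angle (degrees) of four points, in (−180, +180].

    Positive angles are clockwise rotations of the 3→4 bond relative to the
    1→2 bond when sighting down the 2→3 axis (right-hand convention).
    Raises :class:`GeometryError` when either atom triple is collinear or
    the central atoms coincide.
    """
    pts = [np.asarray(p, dtype=float).reshape(1, 3) for p in (p1, p2, p3, p4)]
    return float(_torsion_batch(*pts)[0])


def torsion_series(
    frames: TrajectoryFrames,
    quartet: Sequence[int],
    label: str = "",
) -> TorsionSeries:
    """Per-frame signed torsion of an atom quartet (indices in 1→4 order)."""
    if len(quartet) != 4:
        raise ConfigError(f"torsion quartet needs 4 atom indices, got {len(quartet)}")
    xyz = frames.coords[:, list(quartet), :]
    values = np.empty(frames.n_frames)
    # framewise loop keeps the degenerate-geometry error attributable to a frame
    for f in range(frames.n_frames):
        try:
            values[f] = _torsion_batch(
                xyz[f, 0:1], xyz[f, 1:2], xyz[f, 2:3], xyz[f, 3:4]
            )[0]
        except GeometryError as exc:
            raise GeometryError(f"frame {f}: {exc}") from exc
    return TorsionSeries(values=values, label=label, replica_id=frames.replica_id)


# ---------------------------------------------------------------------------
# centroids and distances
# ---------------------------------------------------------------------------


def ring_centroid(frames: TrajectoryFrames, ring_indices: Sequence[int]) -> np.ndarray:
    """Per-frame unweighted centroid (frames × 3) of ≥3 ring atoms."""
    if len(ring_indices) < 3:
        raise ConfigError(
            f"ring centroid needs at least 3 atoms, got {len(ring_indices)}"
        )
    return frames.coords[:, list(ring_indices), :].mean(axis=1)


def min_distance_series(
    frames: TrajectoryFrames,
    group_a: Sequence[int],
    target,
    label: str = "",
) -> DistanceSeries:
    """Per-frame minimum distance from any atom of ``group_a`` to ``target``.

    ``target`` is either a sequence of atom indices or a per-frame point
    array of shape (frames, 3) — e.g. a ring-centroid track. Reducing by the
    minimum handles multi-candidate groups (a dimethyl pair, Leu's two
    delta-carbons) with one rule.
    """
    if len(group_a) == 0:
        raise ConfigError("distance group_a is empty")
    a = frames.coords[:, list(group_a), :]  # (F, Na, 3)
    target = np.asarray(target)
    if target.ndim == 2 and target.shape == (frames.n_frames, 3):
        b = target[:, None, :]  # (F, 1, 3) per-frame point track
    else:
        idx = np.atleast_1d(target)
        if idx.size == 0:
            raise ConfigError("distance target group is empty")
        if idx.ndim != 1 or not np.issubdtype(idx.dtype, np.integer):
            raise ConfigError(
                "target must be atom indices or a (frames, 3) point array"
            )
        b = frames.coords[:, idx.tolist(), :]
    diff = a[:, :, None, :] - b[:, None, :, :]  # (F, Na, Nb, 3)
    dist = np.sqrt(np.einsum("fabx,fabx->fab", diff, diff))
    return DistanceSeries(
        values=dist.min(axis=(1, 2)), label=label, replica_id=frames.replica_id
    )


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` in the
    least-squares sense. The rotation is always proper (det +1); reflections
    are excluded, as standard for molecular superposition.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ConfigError(
            f"point sets must share shape (N, 3); got {mobile.shape} vs "
            f"{reference.shape}"
        )
    if mobile.shape[0] < 3:
        raise ConfigError("superposition needs at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    matrix = rot.as_matrix()
    translation = rc - matrix @ mc
    moved = mobile @ matrix.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return matrix, translation, rmsd


def ligand_rmsd_series(
    frames: TrajectoryFrames,
    fit_indices: Sequence[int],
    ligand_indices: Sequence[int],
    reference_frame: int = 0,
    label: str = "",
) -> RmsdSeries:
    """Ligand heavy-atom RMSD after receptor-only superposition.

    Each frame is rigidly fitted onto ``reference_frame`` using
    ``fit_indices`` (receptor alpha-carbons by default in the pipeline); the
    RMSD is then computed over ``ligand_indices`` with no further fitting,
    so genuine ligand pose changes are measured in the receptor frame.
    """
    if not (0 <= reference_frame < frames.n_frames):
        raise ConfigError(
            f"reference_frame {reference_frame} outside [0, {frames.n_frames})"
        )
    if len(fit_indices) == 0 or len(ligand_indices) == 0:
        raise ConfigError("fit and ligand selections must be nonempty")
    fit_idx = list(fit_indices)
    lig_idx = list(ligand_indices)
    ref_fit = frames.coords[reference_frame, fit_idx, :]
    ref_lig = frames.coords[reference_frame, lig_idx, :]
    values = np.empty(frames.n_frames)
    for f in range(frames.n_frames):
        matrix, trans, _ = kabsch_superpose(frames.coords[f, fit_idx, :], ref_fit)
        moved = frames.coords[f, lig_idx, :] @ matrix.T + trans
        values[f] = np.sqrt(np.mean(np.sum((moved - ref_lig) ** 2, axis=1)))
    return RmsdSeries(
        values=values,
        reference_frame=reference_frame,
        label=label,
        replica_id=frames.replica_id,
    )


# ---------------------------------------------------------------------------
# internal-coordinate construction (shared by the synthetic generator)
# ---------------------------------------------------------------------------


def place_fourth_atom(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    bond_length: float,
    bond_angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom 4 from atoms 1-3 given internal coordinates (NeRF).

    ``bond_angle_deg`` is the 3-4 bond's angle at atom 3 (against the 2→3
    direction); ``torsion_deg`` is the signed 1-2-3-4 dihedral the placed
    atom realizes exactly.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    bc = p3 - p2
    bc_n = np.linalg.norm(bc)
    if bc_n < _COLLINEAR_TOL:
        raise GeometryError("atoms 2 and 3 coincide; cannot place atom 4")
    bc = bc / bc_n
    ab = p2 - p1
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < _COLLINEAR_TOL:
        raise GeometryError("atoms 1-2-3 collinear; torsion reference undefined")
    n = n / n_norm
    m = np.cross(n, bc)
    theta = np.radians(180.0 - bond_angle_deg)
    phi = np.radians(torsion_deg)
    d = bond_length * np.array(
        [
            np.cos(theta),
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
        ]
    )
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def build_torsion_quartet(
    torsion_deg: float,
    bond_length: float = 1.53,
    bond_angle_deg: float = 111.0,
    origin=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Build a 4-point chain with standard sp3 geometry realizing a torsion.

    Bond lengths default to the aliphatic C–C value (1.53 Å) and bond angles
    to 111°; the returned (4, 3) array has the requested signed 1-2-3-4
    dihedral exactly.
    """
    origin = np.asarray(origin, dtype=float)
    theta = np.radians(180.0 - bond_angle_deg)
    p1 = origin
    p2 = origin + np.array([bond_length, 0.0, 0.0])
    p3 = p2 + bond_length * np.array([np.cos(theta), np.sin(theta), 0.0])
    p4 = place_fourth_atom(p1, p2, p3, bond_length, bond_angle_deg, torsion_deg)
    return np.vstack([p1, p2, p3, p4])
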