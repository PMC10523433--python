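import numpy as np
import pytest

import ligswitch as ls


def make_frames(coords, replica_id=0):
    """Wrap raw (frames, atoms, 3) coordinates with dummy atom metadata."""
    coords = np.asarray(coords, dtype=float)
    atoms = [
        ls.AtomRecord(f"A{i + 1}", "UNK", 1, "X", "C")
        for i in range(coords.shape[1])
    ]
    return ls.TrajectoryFrames(atoms=atoms, coords=coords, replica_id=replica_id)


def torsion_oracle(p1, p2, p3, p4):
    """Independent signed-dihedral oracle: projection formulation.

    Projects the outer bonds onto the plane perpendicular to the central
    bond and takes the signed angle between the projections (right-hand
    rule along the 2->3 axis). Sign convention fixed against MDAnalysis,
    mdtraj and biotite on the canonical +90 degree configuration.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    b2h = b2 / np.linalg.norm(b2)
    v = -b1 + np.dot(b1, b2h) * b2h
    w = b3 - np.dot(b3, b2h) * b2h
    x = np.dot(v, w)
    y = np.dot(np.cross(b2h, v), w)
    return np.degrees(np.arctan2(y, x))


def wrapped_diff(a, b):
    """Smallest absolute angular difference in degrees."""
    return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)


@pytest.fixture(scope="session")
def cb1_dataset(tmp_path_factory):
    """A small CB1-like dataset written to disk: (params, manifest)."""
    outdir = tmp_path_factory.mktemp("cb1_dataset")
    params = ls.SyntheticParams(seed=7, n_frames=300, n_replicas=2)
    manifest = ls.write_synthetic_dataset(params, outdir)
    return params, manifest
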