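import numpy as np
import pytest

from sitecraft.io import AtomRecord, Ensemble, Snapshot


def _hexagon(radius=1.39, centre=(0.0, 0.0, 0.0)):
    angles = np.radians(np.arange(6) * 60.0)
    pts = np.zeros((6, 3))
    pts[:, 0] = radius * np.cos(angles)
    pts[:, 1] = radius * np.sin(angles)
    return pts + np.asarray(centre)


@pytest.fixture
def hexagon():
    return _hexagon()


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)


def make_toy_ensemble(n_snapshots=3, n_residues=5, chain="G", jitter=0.0, seed=0):
    """Tiny CA-per-residue ensemble for selection/RMSD plumbing tests."""
    rng = np.random.default_rng(seed)
    atoms = [
        AtomRecord(serial=i + 1, name="CA", residue_name="GLY", chain=chain,
                   residue_number=100 + i, element="C")
        for i in range(n_residues)
    ]
    base = np.column_stack([
        np.arange(n_residues, dtype=float) * 3.8,
        np.zeros(n_residues),
        np.zeros(n_residues),
    ])
    snaps = []
    for m in range(n_snapshots):
        coords = base + (rng.standard_normal(base.shape) * jitter if jitter else 0.0)
        snaps.append(Snapshot(atoms=atoms, coords=coords, time_ps=float(m)))
    return Ensemble(snapshots=snaps, stride_ps=1.0, label="toy")


@pytest.fixture
def toy_ensemble():
    return make_toy_ensemble()


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation vector."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-50.0, 50.0, size=3)
    return rot, trans
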