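import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.spatial.transform import Rotation

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def rotation_grid(step_deg: float = 2.0, n_axes: int = 40000) -> np.ndarray:
    """Axis-angle rotation grid: Fibonacci-sphere axes x uniform angles."""
    i = np.arange(n_axes)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1 - 2 * (i + 0.5) / n_axes
    r = np.sqrt(1 - z * z)
    axes = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    angles = np.deg2rad(np.arange(step_deg, 180.0 + 1e-9, step_deg))
    rotvecs = (axes[:, None, :] * angles[None, :, None]).reshape(-1, 3)
    R = Rotation.from_rotvec(rotvecs).as_matrix()
    return np.concatenate([np.eye(3)[None], R])


def brute_force_aligned_rmsd(ref: np.ndarray, mob: np.ndarray, grid: np.ndarray) -> float:
    """Minimum unweighted RMSD over a rotation grid (after centering).

    Uses rmsd^2(R) = (ssq - 2 tr(R M)) / N with M = Q^T P, so each rotation
    costs 9 multiplies; independent of the Kabsch code path it checks.
    """
    N = ref.shape[0]
    P = ref - ref.mean(axis=0)
    Q = mob - mob.mean(axis=0)
    ssq = float((P * P).sum() + (Q * Q).sum())
    M = Q.T @ P
    tr = np.einsum("rab,ba->r", grid, M)
    return float(np.sqrt(np.maximum(ssq - 2 * tr, 0.0) / N).min())


@pytest.fixture(scope="session")
def rotation_grid_2deg():
    return rotation_grid(step_deg=2.0, n_axes=40000)


PDB_3x5 = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  N   ALA A   1       0.000   1.000   0.000  1.00  0.00           N
ATOM      4  C   ALA A   1       0.000   0.000   1.000  1.00  0.00           C
ATOM      5  O   ALA A   1       1.000   1.000   0.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       0.100   0.000   0.000  1.00  0.00           C
ATOM      2  CB  ALA A   1       1.100   0.000   0.000  1.00  0.00           C
ATOM      3  N   ALA A   1       0.100   1.000   0.000  1.00  0.00           N
ATOM      4  C   ALA A   1       0.100   0.000   1.000  1.00  0.00           C
ATOM      5  O   ALA A   1       1.100   1.000   0.000  1.00  0.00           O
ENDMDL
MODEL        3
ATOM      1  CA  ALA A   1       0.200   0.000   0.000  1.00  0.00           C
ATOM      2  CB  ALA A   1       1.200   0.000   0.000  1.00  0.00           C
ATOM      3  N   ALA A   1       0.200   1.000   0.000  1.00  0.00           N
ATOM      4  C   ALA A   1       0.200   0.000   1.000  1.00  0.00           C
ATOM      5  O   ALA A   1       1.200   1.000   0.000  1.00  0.00           O
ENDMDL
END
"""


@pytest.fixture
def pdb_3x5(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(PDB_3x5)
    return str(p)
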