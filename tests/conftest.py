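import numpy as np
import pytest

from helix8.metrics import HBondCriterion, HelixDefinition
from helix8.synthetic import HelixBuildSpec, build_ideal_helix


@pytest.fixture(scope="session")
def helix_spec():
    return HelixBuildSpec()


@pytest.fixture(scope="session")
def ideal_helix(helix_spec):
    """One-frame ideal 11-residue helix trajectory (7 reference bonds)."""
    return build_ideal_helix(helix_spec)


@pytest.fixture(scope="session")
def helixdef():
    return HelixDefinition()


@pytest.fixture(scope="session")
def criterion():
    return HBondCriterion()


def horn_rmsd(P, Q):
    """Independent minimum RMSD via Horn's quaternion method.

    Builds the 4x4 key matrix from the coordinate correlation and takes
    its largest eigenvalue; shares no code with the SVD path under test.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    msd = ((P0**2).sum() + (Q0**2).sum() - 2.0 * lam) / len(P)
    return float(np.sqrt(max(msd, 0.0)))
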