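import numpy as np
import pytest

from varidyn import synthetic as syn
from varidyn import resolve_selection


@pytest.fixture(scope="session")
def template():
    return syn.build_template()


@pytest.fixture(scope="session")
def planted_modes():
    return syn.default_planted_modes()


@pytest.fixture(scope="session")
def chain_a_sel(template):
    return resolve_selection(template, "chain A and name CA")


@pytest.fixture(scope="session")
def chain_b_sel(template):
    return resolve_selection(template, "chain B and name CA")


def horn_fit(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Independent rigid-fit oracle: Horn's quaternion method.

    Builds the 4x4 Davenport K matrix from the cross-covariance of the
    centered point sets; the eigenvector of the largest eigenvalue is the
    optimal rotation quaternion. Shares no code with the SVD implementation.
    """
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    s = mc.T @ rc
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
    vals, vecs = np.linalg.eigh(k)
    w, x, y, z = vecs[:, np.argmax(vals)]
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def horn_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal superposition RMSD according to the quaternion oracle."""
    rot = horn_fit(mobile, reference)
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    fitted = mc @ rot.T
    return float(np.sqrt(np.mean(np.sum((fitted - rc) ** 2, axis=1))))


def brute_force_energy(coords_a, coords_b, charge_a, charge_b, eps_a, eps_b,
                       rmin_a, rmin_b, r_on=10.0, r_off=12.0, kc=332.0636):
    """All-pairs double-loop nonbonded energy, written independently."""
    import math

    total = 0.0
    for i in range(len(coords_a)):
        for j in range(len(coords_b)):
            dx = coords_a[i][0] - coords_b[j][0]
            dy = coords_a[i][1] - coords_b[j][1]
            dz = coords_a[i][2] - coords_b[j][2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r > r_off:
                continue
            if r <= r_on:
                s = 1.0
            else:
                s = ((r_off**2 - r * r) ** 2 * (r_off**2 + 2 * r * r - 3 * r_on**2)) / (
                    (r_off**2 - r_on**2) ** 3
                )
            coul = kc * charge_a[i] * charge_b[j] / r
            rmin = rmin_a[i] + rmin_b[j]
            eps = math.sqrt(eps_a[i] * eps_b[j])
            ratio6 = (rmin / r) ** 6
            lj = eps * (ratio6 * ratio6 - 2.0 * ratio6)
            total += s * (coul + lj)
    return total
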