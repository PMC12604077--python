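"""Independent brute-force oracle for two-spin echo simulations.

Deliberately coded differently from the package simulator: operators are
built from literal Pauli matrices, every propagator is an explicit
``scipy.linalg.expm`` call, and the FID is sampled by stepwise
propagation through the acquisition dwell time. Used only as a
cross-check on tiny problems.
"""

import numpy as np
from scipy.linalg import expm

_SX = 0.5 * np.array([[0, 1], [1, 0]], dtype=complex)
_SY = 0.5 * np.array([[0, -1j], [1j, 0]], dtype=complex)
_SZ = 0.5 * np.array([[1, 0], [0, -1]], dtype=complex)
_E2 = np.eye(2, dtype=complex)


def _two_spin_ops():
    ax = np.kron(_SX, _E2)
    ay = np.kron(_SY, _E2)
    az = np.kron(_SZ, _E2)
    bx = np.kron(_E2, _SX)
    by = np.kron(_E2, _SY)
    bz = np.kron(_E2, _SZ)
    return ax, ay, az, bx, by, bz


def two_spin_echo_fid(nu_a_hz, nu_b_hz, j_hz, segments_ms, dwell_s, n_points):
    """FID of a two-spin echo train: 90x - [evolve - 180y]* - evolve - acquire.

    Normalized so an uncoupled spin contributes exp(+i 2 pi nu t); same
    convention as the package simulator but derived independently.
    """
    ax, ay, az, bx, by, bz = _two_spin_ops()
    h = 2 * np.pi * (
        nu_a_hz * az
        + nu_b_hz * bz
        + j_hz * (ax @ bx + ay @ by + az @ bz)
    )
    rho = az + bz
    p90 = expm(-1j * (np.pi / 2) * (ax + bx))
    p180 = expm(-1j * np.pi * (ay + by))
    rho = p90 @ rho @ p90.conj().T
    for k, d_ms in enumerate(segments_ms):
        u = expm(-1j * h * d_ms * 1e-3)
        rho = u @ rho @ u.conj().T
        if k < len(segments_ms) - 1:
            rho = p180 @ rho @ p180.conj().T
    obs = (ax + bx) + 1j * (ay + by)
    u_dwell = expm(-1j * h * dwell_s)
    fid = np.empty(n_points, dtype=complex)
    for k in range(n_points):
        fid[k] = 1j * np.trace(rho @ obs)
        rho = u_dwell @ rho @ u_dwell.conj().T
    return fid
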