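"""Independent reference computations used by the tests.

These are deliberately written without touching the package's FEM path:
the disk solution is a truncated Fourier series of the continuum problem,
evaluated with the same arc-average electrode readout.
"""

import numpy as np


def disk_series_voltages(domain, electrodes, protocol, gamma: float,
                         modes: int = 4000) -> np.ndarray:
    """Boundary voltages for a homogeneous disk, by separation of variables.

    The Neumann data is a uniform current density on each drive arc; the
    potential is a harmonic series u = sum_n (R/(gamma*n)) (a_n cos + b_n
    sin) (r/R)^n and electrode voltages are arc averages at r = R.
    """
    R = domain.params["radius"]
    phis = electrodes.centers / R  # electrode angular centers
    alpha = electrodes.width / (2 * R)  # half-width in angle
    n = np.arange(1, modes + 1)
    dens = protocol.I / (2 * R * alpha)
    sinc = np.sin(n * alpha) / (n * alpha)
    out = []
    for (jp, jm), meas in zip(protocol.drive_pairs, protocol.meas_pairs_per_drive):
        an = dens * 2 * np.sin(n * alpha) / (np.pi * n) * (
            np.cos(n * phis[jp]) - np.cos(n * phis[jm])
        )
        bn = dens * 2 * np.sin(n * alpha) / (np.pi * n) * (
            np.sin(n * phis[jp]) - np.sin(n * phis[jm])
        )
        coef = R / (gamma * n)
        for ip, im in meas:
            avg_p = sinc * (np.cos(n * phis[ip]) * an + np.sin(n * phis[ip]) * bn)
            avg_m = sinc * (np.cos(n * phis[im]) * an + np.sin(n * phis[im]) * bn)
            out.append(float(np.sum(coef * (avg_p - avg_m))))
    return np.asarray(out)


def brute_force_protocol(E: int):
    """Enumerate drive pairs and disjoint measurement pairs by double loop."""
    drives = []
    for a in range(E):
        for b in range(a + 1, E):
            drives.append((a, b))
    meas = []
    for d in drives:
        rows = []
        for a in range(E):
            for b in range(a + 1, E):
                if a not in d and b not in d:
                    rows.append((a, b))
        meas.append(rows)
    return drives, meas


def polygon_area_shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
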