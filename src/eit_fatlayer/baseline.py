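"""Conventional comparator: linearized sensitivity matrix + Tikhonov solve.

The sensitivity method linearizes the voltage-conductivity relation around a
reference conductivity (homogeneous, since the true one is unknown): the
entry for data index ``(j, i)`` and layer ``l`` is the energy overlap of the
two drive potentials restricted to that layer,

    S_{(j,i), l} = (1/I) * integral_{Omega_l} grad(u_j) . grad(u_i).

Per-layer conductivity is then recovered from ``V ~ S gamma`` by regularized
least squares.  The matrix is severely ill-conditioned, which is exactly why
this baseline fails to localize the fat-muscle border that the learned
inverse map finds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SolverError, ValidationError
from .forward import FEMOperator, VoltageVector
from .geometry import LayerPartition


@dataclass
class SensitivityMatrix:
    """Dense (n_measurements, L) linearized sensitivity, canonical row order."""

    matrix: np.ndarray
    gamma_ref: np.ndarray
    mesh_hash: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def assemble_sensitivity(
    op: FEMOperator,
    partition: LayerPartition,
    gamma_ref: np.ndarray | float = 1.0,
) -> SensitivityMatrix:
    """Assemble the layer-restricted sensitivity matrix at ``gamma_ref``.

    Row sums reproduce the full-domain energy form exactly (the layers
    partition the element set), which serves as the assembly self-check.
    """
    if len(partition.layer_of_element) != op.mesh.n_elements:
        raise ValidationError("layer partition does not match the mesh")
    if np.isscalar(gamma_ref):
        gamma_ref = np.full(op.mesh.n_elements, float(gamma_ref))
    U = op.solve_all(gamma_ref)
    prot = op.protocol
    L = partition.L
    S = np.empty((prot.n_measurements, L))
    for l, Kl in enumerate(op.layer_stiffness(partition.layer_of_element, L)):
        El = (U.T @ (Kl @ U)) / prot.I  # (n_drives, n_drives) layer energies
        k = 0
        for j, meas in enumerate(prot.meas_pairs_per_drive):
            for pair in meas:
                S[k, l] = El[j, prot.pair_number(pair)]
                k += 1
    return SensitivityMatrix(
        matrix=S, gamma_ref=gamma_ref, mesh_hash=op.mesh.content_hash()
    )


def solve_regularized(
    S: SensitivityMatrix,
    V: VoltageVector | np.ndarray,
    lam: float | None = None,
    reg: str = "tikhonov_identity",
) -> np.ndarray:
    """Tikhonov-regularized least squares: min ||S g - V||^2/2 + lam*|R g|^2/2.

    ``reg`` selects the penalty: ``tikhonov_identity`` (default) or
    ``tikhonov_smooth`` (first differences in layer index).  ``lam`` defaults
    to ``1e-3 * trace(S^T S) / L``.  Solved via the normal equations; the
    regularized system is positive definite for any lam > 0.
    """
    A = S.matrix
    v = V.values if isinstance(V, VoltageVector) else np.asarray(V, dtype=float)
    if v.shape != (A.shape[0],):
        raise ValidationError("data length does not match sensitivity rows")
    L = A.shape[1]
    AtA = A.T @ A
    if lam is None:
        lam = 1e-3 * np.trace(AtA) / L
    if lam <= 0:
        raise ValidationError("regularization parameter must be positive")
    if reg == "tikhonov_identity":
        R = np.eye(L)
    elif reg == "tikhonov_smooth":
        D = np.diff(np.eye(L), axis=0)
        R = D.T @ D
    else:
        raise ValidationError(f"unknown regularizer {reg!r}")
    try:
        return np.linalg.solve(AtA + lam * R, A.T @ v)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise SolverError(f"regularized system is singular: {exc}") from exc
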