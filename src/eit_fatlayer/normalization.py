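"""Geometry-dependency-reducing normalization of current-voltage data.

Measured voltages depend strongly on the body outline and electrode
positions, which are known (the electrode belt geometry is fixed), while the
conductivity is not.  The normalization map divides that known dependency
out: with reference potentials ``v_j`` solved on the same mesh for unit
conductivity and the same drive currents, the weights

    S_{j,i} = (1/I) * integral grad(v_j) . grad(v_i)

are pure geometry numbers, and the normalized data

    Vhat_{j,i} = S_{j,i} / V_{j,i}

are in conductivity units: each entry is a weighted harmonic-type average of
the conductivity along the current paths of the (j, i) pair.  For a
homogeneous conductivity ``gamma = c`` every entry equals ``c`` exactly,
regardless of the body shape or electrode placement — which is what makes a
network trained on one geometry transferable to another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NormalizationError, ValidationError
from .forward import FEMOperator, Protocol, VoltageVector


@dataclass
class ReferenceSolutionSet:
    """Unit-conductivity reference solutions and their energy weights.

    ``S`` holds the weights in the canonical voltage ordering; ``energies``
    is the full (n_drives, n_drives) energy matrix between reference
    potentials, symmetric up to solver roundoff.
    """

    S: np.ndarray
    energies: np.ndarray
    protocol: Protocol
    mesh_hash: str


def reference_set(op: FEMOperator) -> ReferenceSolutionSet:
    """Solve the unit-conductivity references and assemble the S weights.

    The energy matrix is computed via the discrete Green identity
    ``v_j^T K v_i = v_j^T b_i`` which keeps S and the simulated voltages on
    exactly the same discretization (any mesh bias cancels in the ratio).
    """
    U = op.solve_all(np.ones(op.mesh.n_elements))
    energies = (U.T @ op.loads) / op.protocol.I
    prot = op.protocol
    S = np.empty(prot.n_measurements)
    k = 0
    for j, meas in enumerate(prot.meas_pairs_per_drive):
        for pair in meas:
            S[k] = energies[j, prot.pair_number(pair)]
            k += 1
    return ReferenceSolutionSet(
        S=S, energies=energies, protocol=prot, mesh_hash=op.mesh.content_hash()
    )


def normalize(V: VoltageVector, ref: ReferenceSolutionSet) -> VoltageVector:
    """Apply the normalization map: Vhat = S / V, entrywise.

    Raises :class:`NormalizationError` when a voltage entry is closer to zero
    than ``1e-12 * max|V|`` (the ratio would blow up; with the disjoint-pair
    protocol this does not happen for physical conductivities).
    """
    if V.normalized:
        raise ValidationError("voltage vector is already normalized")
    if V.mesh_hash != ref.mesh_hash:
        raise ValidationError(
            "voltage vector and reference set come from different meshes"
        )
    if len(V.values) != len(ref.S):
        raise ValidationError("voltage vector length does not match reference set")
    floor = 1e-12 * np.max(np.abs(V.values))
    bad = np.flatnonzero(np.abs(V.values) <= floor)
    if bad.size:
        pair = ref.protocol.index[bad[0]]
        raise NormalizationError(
            f"voltage entry {bad[0]} (drive {pair[0]}, measurement {pair[1]}) "
            "is too close to zero to normalize"
        )
    return VoltageVector(
        values=ref.S / V.values,
        protocol=V.protocol,
        mesh_hash=V.mesh_hash,
        normalized=True,
    )
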