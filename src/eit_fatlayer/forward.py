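"""FEM forward model: drive currents, potentials, and the voltage vector.

The electric potential ``u`` for conductivity ``gamma`` solves the
generalized Laplace problem

    div(gamma grad u) = 0   in Omega,
    n . gamma grad u  = g   on dOmega,

with Neumann data ``g`` equal to a uniform current density ``+I/|e+|`` on the
positive drive electrode, ``-I/|e-|`` on the negative one, and zero elsewhere
(a gap/shunt-free electrode model; drive-electrode voltages are never used,
which side-steps contact impedance).  The pure Neumann problem is grounded by
a zero mass-weighted mean-potential gauge imposed via a Lagrange multiplier.

Voltages are read out as arc-averaged electrode potentials; a measurement
protocol drives every unordered electrode pair and, per drive, measures every
pair of the remaining electrodes, so for E=10 there are 45 drives with 28
voltages each, 1260 in total.  All index orderings are lexicographic and
bit-stable: the same ordering is used for simulation, normalization,
training, and inference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import SolverError, ValidationError
from .geometry import FEMesh


@dataclass
class Protocol:
    """Drive/measurement schedule and current amplitude.

    ``drive_pairs`` are all C(E,2) unordered electrode pairs (0-based,
    lexicographic).  ``meas_pairs_per_drive[j]`` lists the C(E-2,2) pairs of
    electrodes disjoint from drive ``j``, lexicographic.  ``index`` flattens
    the retained (drive, measurement) combinations into the canonical order
    of the voltage vector.
    """

    E: int
    I: float
    drive_pairs: list[tuple[int, int]]
    meas_pairs_per_drive: list[list[tuple[int, int]]]

    @property
    def index(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        return [
            (d, m)
            for d, meas in zip(self.drive_pairs, self.meas_pairs_per_drive)
            for m in meas
        ]

    @property
    def n_drives(self) -> int:
        return len(self.drive_pairs)

    @property
    def n_measurements(self) -> int:
        return sum(len(m) for m in self.meas_pairs_per_drive)

    def pair_number(self, pair: tuple[int, int]) -> int:
        """Position of an unordered pair in the lexicographic drive list."""
        return self.drive_pairs.index((min(pair), max(pair)))


def make_protocol(E: int = 10, I: float = 1.0) -> Protocol:
    """All-pairs drive protocol with disjoint-pair measurements."""
    if E < 4:
        raise ValidationError("E >= 4 required: no measurement pair is disjoint")
    if I <= 0:
        raise ValidationError("drive current must be positive")
    drives = list(itertools.combinations(range(E), 2))
    meas = [
        list(itertools.combinations([e for e in range(E) if e not in d], 2))
        for d in drives
    ]
    return Protocol(E=E, I=I, drive_pairs=drives, meas_pairs_per_drive=meas)


@dataclass
class ConductivityField:
    """Per-element conductivity, in relative units or S/m."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValidationError("conductivity must be finite and positive")

    @classmethod
    def homogeneous(cls, mesh: FEMesh, value: float = 1.0) -> "ConductivityField":
        return cls(np.full(mesh.n_elements, float(value)))


@dataclass
class PotentialField:
    """Nodal potential for one drive, zero-mean gauged."""

    u: np.ndarray
    drive: tuple[int, int]
    mesh_hash: str


@dataclass
class VoltageVector:
    """Ordered voltage data V with its (drive, measurement) index."""

    values: np.ndarray
    protocol: Protocol
    mesh_hash: str
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        idx = self.protocol.index
        return pd.DataFrame(
            {
                "j_plus": [d[0] for d, _ in idx],
                "j_minus": [d[1] for d, _ in idx],
                "i_plus": [m[0] for _, m in idx],
                "i_minus": [m[1] for _, m in idx],
                "V": self.values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class FEMOperator:
    """Piecewise-linear FEM assembly and factorized solves on one mesh.

    Precomputes the element stiffness pattern once; ``stiffness(gamma)``
    then reweights element contributions, and :meth:`solve_all` factorizes
    the gauged system once per conductivity and reuses it for all drives.
    """

    def __init__(self, mesh: FEMesh, protocol: Protocol):
        if protocol.E != mesh.electrodes.E:
            raise ValidationError("protocol electrode count does not match mesh")
        self.mesh = mesh
        self.protocol = protocol
        self._assemble_pattern()
        self._assemble_electrodes()
        self._lu_cache: tuple[bytes, object] | None = None

    # -- assembly ---------------------------------------------------------
    def _assemble_pattern(self) -> None:
        mesh = self.mesh
        tri = mesh.triangles
        p = mesh.nodes[tri]
        # edge vectors opposite each vertex; grad(phi_i) = rot90(e_i)/(2A)
        e = p[:, [2, 0, 1], :] - p[:, [1, 2, 0], :]
        areas = mesh.areas
        grads = np.stack([-e[..., 1], e[..., 0]], axis=-1) / (2 * areas[:, None, None])
        # K_e[i,j] = A * grad_i . grad_j, element-wise conductivity applied later
        ke = np.einsum("eid,ejd->eij", grads, grads) * areas[:, None, None]
        self._ke = ke
        rows = np.repeat(tri, 3, axis=1).reshape(-1, 3, 3)
        cols = np.tile(tri[:, None, :], (1, 3, 1))
        self._rows = rows.ravel()
        self._cols = cols.ravel()
        self.n = mesh.n_nodes
        # lumped mass vector for the mean-potential gauge
        m = np.zeros(self.n)
        np.add.at(m, tri.ravel(), np.repeat(areas / 3, 3))
        self._mass = m

    def _assemble_electrodes(self) -> None:
        """Per-electrode boundary quadrature weights (sum to 1 on each)."""
        mesh = self.mesh
        E = mesh.electrodes.E
        W = np.zeros((E, self.n))
        pts = mesh.nodes
        for (a, b), lab in zip(mesh.boundary_edges, mesh.boundary_labels):
            if lab == 0:
                continue
            le = np.linalg.norm(pts[a] - pts[b])
            W[lab - 1, a] += le / 2
            W[lab - 1, b] += le / 2
        lengths = W.sum(axis=1)
        if np.any(lengths <= 0):
            raise ValidationError("an electrode has no boundary edges")
        self.electrode_weights = W / lengths[:, None]
        # load matrix: column j is the Neumann load of drive pair j at unit I
        B = np.zeros((self.n, self.protocol.n_drives))
        for j, (ep, em) in enumerate(self.protocol.drive_pairs):
            B[:, j] = self.electrode_weights[ep] - self.electrode_weights[em]
        self.loads = B * self.protocol.I

    def stiffness(self, gamma: ConductivityField | np.ndarray) -> sp.csr_matrix:
        vals = gamma.values if isinstance(gamma, ConductivityField) else np.asarray(gamma)
        if len(vals) != self.mesh.n_elements:
            raise ValidationError("conductivity length does not match element count")
        data = (self._ke * vals[:, None, None]).ravel()
        K = sp.coo_matrix((data, (self._rows, self._cols)), shape=(self.n, self.n))
        return K.tocsr()

    def layer_stiffness(self, layer_of_element: np.ndarray, L: int) -> list[sp.csr_matrix]:
        """Unit-conductivity stiffness restricted to each layer's elements."""
        mats = []
        for l in range(1, L + 1):
            mask = (layer_of_element == l).astype(float)
            mats.append(self.stiffness(mask + 0.0) if mask.any() else
                        sp.csr_matrix((self.n, self.n)))
        return mats

    # -- solving ----------------------------------------------------------
    def _factorize(self, gamma) -> object:
        K = self.stiffness(gamma)
        m = self._mass
        A = sp.bmat([[K, m[:, None]], [m[None, :], None]], format="csc")
        try:
            return splu(A)
        except RuntimeError as exc:  # pragma: no cover - singular systems
            raise SolverError(f"sparse factorization failed: {exc}") from exc

    def solve_all(self, gamma: ConductivityField | np.ndarray) -> np.ndarray:
        """Nodal potentials for every drive; shape (n_nodes, n_drives)."""
        lu = self._factorize(gamma)
        rhs = np.vstack([self.loads, np.zeros((1, self.protocol.n_drives))])
        sol = lu.solve(rhs)
        u = sol[:-1]
        if not np.all(np.isfinite(u)):
            raise SolverError("solver returned non-finite potentials")
        return u

    def electrode_potentials(self, U: np.ndarray) -> np.ndarray:
        """Arc-averaged potential of every electrode; shape (E, n_drives)."""
        return self.electrode_weights @ U

    def voltages(self, U: np.ndarray) -> np.ndarray:
        """Canonically ordered voltage vector from the drive potentials."""
        ep = self.electrode_potentials(U)
        out = np.empty(self.protocol.n_measurements)
        k = 0
        for j, meas in enumerate(self.protocol.meas_pairs_per_drive):
            for ip, im in meas:
                out[k] = ep[ip, j] - ep[im, j]
                k += 1
        return out

    def simulate(self, gamma: ConductivityField | np.ndarray) -> VoltageVector:
        """Solve all drives and assemble the voltage vector."""
        return VoltageVector(
            values=self.voltages(self.solve_all(gamma)),
            protocol=self.protocol,
            mesh_hash=self.mesh.content_hash(),
        )


def solve_drive(
    op: FEMOperator, gamma: ConductivityField, drive: tuple[int, int]
) -> PotentialField:
    """Potential for a single drive pair (convenience wrapper)."""
    if drive[0] == drive[1]:
        raise ValidationError("drive electrodes must be distinct")
    U = op.solve_all(gamma)
    j = op.protocol.pair_number(drive)
    return PotentialField(u=U[:, j], drive=tuple(drive), mesh_hash=op.mesh.content_hash())


def measure(op: FEMOperator, U: np.ndarray) -> VoltageVector:
    """Assemble the ordered voltage vector from solved drive potentials."""
    if U.shape != (op.n, op.protocol.n_drives):
        raise ValidationError("need one potential column per drive")
    return VoltageVector(
        values=op.voltages(U), protocol=op.protocol, mesh_hash=op.mesh.content_hash()
    )


def energy_form(
    op: FEMOperator,
    gamma: ConductivityField | np.ndarray,
    u_j: np.ndarray,
    u_i: np.ndarray,
) -> float:
    """The bilinear energy (1/I) * integral of gamma grad(u_j).grad(u_i)."""
    if len(u_j) != op.n or len(u_i) != op.n:
        raise ValidationError("potential vectors do not match the mesh")
    K = op.stiffness(gamma)
    return float(u_j @ (K @ u_i)) / op.protocol.I


def add_noise(V: VoltageVector, rel_level: float, seed: int) -> VoltageVector:
    """Multiplicative Gaussian noise: V * (1 + rel_level * z), seeded."""
    if rel_level < 0:
        raise ValidationError("noise level must be non-negative")
    if rel_level == 0:
        return VoltageVector(V.values.copy(), V.protocol, V.mesh_hash, V.normalized)
    z = np.random.default_rng(seed).standard_normal(len(V.values))
    return VoltageVector(
        values=V.values * (1 + rel_level * z),
        protocol=V.protocol,
        mesh_hash=V.mesh_hash,
        normalized=V.normalized,
    )
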