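"""Layered-conductivity training corpus: enumeration, simulation, packaging.

The inverse map is trained on simulated pairs ``(gamma, Vhat)`` where
``gamma`` is a three-region layered conductivity — fat in the outermost
layers ``1..l_f``, muscle in ``l_f+1..l_m``, a single background value in the
rest — and ``Vhat`` is the normalized voltage vector simulated for that
distribution.  Fat conductivity is fixed at 1 (relative units); muscle and
background values are enumerated on grids honoring gamma_f < gamma_m <=
10*gamma_f.  With L=15 layers there are C(14,2)=91 (l_f, l_m) partitions and
the default grids (17 muscle x 9 background values) give 13923 specifications.

The simulated corpus doubles as the synthetic-data backbone of the package:
it defines the study conditions under which the estimator is trained and
evaluated.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import ValidationError
from .forward import ConductivityField, FEMOperator, Protocol, add_noise
from .geometry import FEMesh, LayerPartition
from .normalization import ReferenceSolutionSet, normalize, reference_set

logger = logging.getLogger(__name__)

GAMMA_M_GRID = np.round(np.arange(2.0, 10.01, 0.5), 10)  # 17 values
GAMMA_R_GRID = np.round(np.arange(1.5, 9.51, 1.0), 10)  # 9 values
GAMMA_R_GRID_FINE = np.round(np.arange(1.5, 9.51, 0.5), 10)  # 17 values


@dataclass(frozen=True)
class LayeredConductivity:
    """One training specification: border indices and region conductivities."""

    l_f: int
    l_m: int
    gamma_f: float
    gamma_m: float
    gamma_r: float

    def validate(self, L: int) -> None:
        if not 1 <= self.l_f < self.l_m <= L - 1:
            raise ValidationError(
                f"need 1 <= l_f < l_m <= L-1, got l_f={self.l_f}, l_m={self.l_m}"
            )
        if not self.gamma_f < self.gamma_m <= 10 * self.gamma_f:
            raise ValidationError(
                f"need gamma_f < gamma_m <= 10*gamma_f, got "
                f"{self.gamma_f}, {self.gamma_m}"
            )
        if self.gamma_r <= 0:
            raise ValidationError("gamma_r must be positive")

    def layer_vector(self, L: int) -> np.ndarray:
        g = np.full(L, self.gamma_r)
        g[: self.l_f] = self.gamma_f
        g[self.l_f : self.l_m] = self.gamma_m
        return g

    def fat_thickness(self, d0: float) -> float:
        return d0 * self.l_f

    def muscle_thickness(self, d0: float) -> float:
        return d0 * (self.l_m - self.l_f)


def enumerate_partitions(L: int) -> list[tuple[int, int]]:
    """All (l_f, l_m) with 1 <= l_f < l_m <= L-1, lexicographic."""
    if L < 3:
        raise ValidationError("need L >= 3 for fat + muscle + rest")
    return [(lf, lm) for lf in range(1, L - 1) for lm in range(lf + 1, L)]


def enumerate_conductivities(
    gamma_f: float = 1.0,
    gamma_m_grid: np.ndarray = GAMMA_M_GRID,
    gamma_r_grid: np.ndarray = GAMMA_R_GRID,
    enforce_order: bool = False,
) -> list[tuple[float, float, float]]:
    """Cartesian grid of (gamma_f, gamma_m, gamma_r) triples.

    ``enforce_order=True`` additionally filters to gamma_f < gamma_r <
    gamma_m (the anatomical ordering); the default keeps the full product,
    which is what the stated corpus size corresponds to.
    """
    gm = np.atleast_1d(np.asarray(gamma_m_grid, dtype=float))
    gr = np.atleast_1d(np.asarray(gamma_r_grid, dtype=float))
    if gm.size == 0 or gr.size == 0:
        raise ValidationError("conductivity grids must be non-empty")
    if np.any(gm <= gamma_f) or np.any(gm > 10 * gamma_f):
        raise ValidationError("gamma_m grid must satisfy gamma_f < gamma_m <= 10*gamma_f")
    out = [
        (gamma_f, float(m), float(r))
        for m, r in itertools.product(gm, gr)
        if not enforce_order or gamma_f < r < m
    ]
    return out


def enumerate_specs(
    L: int = 15,
    gamma_f: float = 1.0,
    gamma_m_grid: np.ndarray = GAMMA_M_GRID,
    gamma_r_grid: np.ndarray = GAMMA_R_GRID,
    enforce_order: bool = False,
) -> list[LayeredConductivity]:
    """Full corpus enumeration: partitions x conductivity triples."""
    parts = enumerate_partitions(L)
    trips = enumerate_conductivities(gamma_f, gamma_m_grid, gamma_r_grid, enforce_order)
    return [
        LayeredConductivity(lf, lm, gf, gm, gr)
        for (lf, lm) in parts
        for (gf, gm, gr) in trips
    ]


def spec_to_field(
    spec: LayeredConductivity, partition: LayerPartition
) -> tuple[ConductivityField, np.ndarray]:
    """Per-element conductivity field and per-layer target vector."""
    spec.validate(partition.L)
    target = spec.layer_vector(partition.L)
    return ConductivityField(target[partition.layer_of_element - 1]), target


@dataclass
class TrainingDataset:
    """Row-aligned (normalized input, per-layer target) training corpus.

    ``inputs`` are normalized voltage vectors (conductivity units),
    ``inputs_raw`` the un-normalized voltages (kept for the normalization
    ablation), ``targets`` the per-layer conductivity vectors.
    """

    inputs: np.ndarray
    inputs_raw: np.ndarray
    targets: np.ndarray
    specs: list[LayeredConductivity]
    provenance: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.inputs)

    def content_hash(self) -> str:
        h = hashlib.sha1()
        h.update(self.inputs.tobytes())
        h.update(self.targets.tobytes())
        return h.hexdigest()[:16]

    def split(self, val_frac: float, seed: int):
        """Seeded random train/validation row split (indices)."""
        rng = np.random.default_rng(seed)
        perm = rng.permutation(self.n_rows)
        n_val = int(round(val_frac * self.n_rows))
        return perm[n_val:], perm[:n_val]

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("inputs", data=self.inputs, compression="gzip")
            f.create_dataset("inputs_raw", data=self.inputs_raw, compression="gzip")
            f.create_dataset("targets", data=self.targets, compression="gzip")
            spec_arr = np.array(
                [(s.l_f, s.l_m, s.gamma_f, s.gamma_m, s.gamma_r) for s in self.specs]
            )
            f.create_dataset("specs", data=spec_arr)
            f.attrs["provenance"] = json.dumps(self.provenance)

    @classmethod
    def load(cls, path) -> "TrainingDataset":
        with h5py.File(path, "r") as f:
            specs = [
                LayeredConductivity(int(a), int(b), c, d, e)
                for a, b, c, d, e in f["specs"][...]
            ]
            return cls(
                inputs=f["inputs"][...],
                inputs_raw=f["inputs_raw"][...],
                targets=f["targets"][...],
                specs=specs,
                provenance=json.loads(f.attrs["provenance"]),
            )


def generate_dataset(
    op: FEMOperator,
    partition: LayerPartition,
    specs: list[LayeredConductivity],
    ref: ReferenceSolutionSet | None = None,
    noise: float | None = None,
    seed: int = 0,
) -> TrainingDataset:
    """Simulate and normalize voltages for every specification.

    Each spec is forward-solved on the operator's mesh (all drives per spec,
    one sparse factorization each), measured, optionally perturbed with
    multiplicative Gaussian noise, and normalized with the shared reference
    set.  Deterministic given the seed.
    """
    if len({(s.l_f, s.l_m, s.gamma_f, s.gamma_m, s.gamma_r) for s in specs}) != len(specs):
        raise ValidationError("duplicate specifications in the corpus")
    for s in specs:
        s.validate(partition.L)
    if ref is None:
        ref = reference_set(op)
    n = op.protocol.n_measurements
    X = np.empty((len(specs), n))
    Xraw = np.empty((len(specs), n))
    Y = np.empty((len(specs), partition.L))
    for k, spec in enumerate(specs):
        field_k, target = spec_to_field(spec, partition)
        V = op.simulate(field_k)
        if noise:
            V = add_noise(V, noise, seed + k)
        Xraw[k] = V.values
        X[k] = normalize(V, ref).values
        Y[k] = target
        if (k + 1) % 100 == 0 or k + 1 == len(specs):
            logger.info("simulated %d/%d specifications", k + 1, len(specs))
    prov = {
        "mesh_hash": op.mesh.content_hash(),
        "E": op.protocol.E,
        "I": op.protocol.I,
        "L": partition.L,
        "d0": partition.d0,
        "seed": seed,
        "noise": noise,
        "n_specs": len(specs),
    }
    return TrainingDataset(
        inputs=X, inputs_raw=Xraw, targets=Y, specs=list(specs), provenance=prov
    )
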