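"""Imaging domains, electrode arrays, triangular meshes, and distance layers.

The imaging domain is a bounded 2D region ``Omega`` with a smooth, simple,
star-shaped boundary ``dOmega``.  Electrodes are arcs on the boundary, placed
on the "front" of the body (the +y direction).  The mesh is a structured
boundary-fitted triangulation: rings of nodes obtained by shrinking the
boundary toward the centroid, stitched together ring by ring.  Ring depths are
aligned with the constant-thickness conductivity layers so that every layer is
resolved by at least one full row of elements.

Distance layers partition the domain into ``L`` bands of thickness ``d0``
measured from the boundary; the innermost band absorbs the remainder of the
domain.  Fat occupies the outermost bands, muscle the next ones, and the rest
of the interior carries a single background conductivity.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.interpolate import CubicSpline

from .errors import GeometryError, MeshingError, ValidationError

_DENSE = 8192  # boundary samples used for the arc-length parametrization

# Default harmonic outline of the abdomen surrogate: a smooth closed curve
# about 30.6 cm wide and 19.4 cm deep, slightly fuller on the front (+y).
_ABDOMEN_HARMONICS = (12.0, 0.6, 2.8, 0.5)


def _abdomen_radius(theta: np.ndarray) -> np.ndarray:
    r0, s1, c2, c4 = _ABDOMEN_HARMONICS
    return r0 + s1 * np.sin(theta) + c2 * np.cos(2 * theta) + c4 * np.cos(4 * theta)


@dataclass
class Domain2D:
    """A 2D imaging domain with an arc-length parametrized boundary.

    Attributes
    ----------
    kind:
        One of ``disk``, ``ellipse``, ``abdomen``.
    params:
        Length parameters in cm (``radius`` for the disk, semi-axes ``a``/``b``
        for the ellipse, ``control_points`` for the abdomen outline).
    """

    kind: str
    params: dict
    _pts: np.ndarray = field(repr=False, default=None)
    _arclen: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        theta = np.linspace(0.0, 2 * np.pi, _DENSE, endpoint=False)
        if self.kind == "disk":
            r = float(self.params["radius"])
            pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        elif self.kind == "ellipse":
            a, b = float(self.params["a"]), float(self.params["b"])
            pts = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
        elif self.kind == "abdomen":
            cp = np.asarray(self.params["control_points"], dtype=float)
            if cp.ndim != 2 or cp.shape[0] < 6 or cp.shape[1] != 2:
                raise ValidationError("abdomen outline needs >=6 (x, y) control points")
            t = np.linspace(0.0, 1.0, cp.shape[0] + 1)
            closed = np.vstack([cp, cp[:1]])
            spl = CubicSpline(t, closed, bc_type="periodic")
            pts = spl(np.linspace(0.0, 1.0, _DENSE, endpoint=False))
        else:
            raise ValidationError(f"unknown domain kind {self.kind!r}")
        self._pts = pts
        seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        self._arclen = np.concatenate([[0.0], np.cumsum(seg)])
        self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        poly = self.polygon
        if not poly.is_valid or not poly.is_simple:
            raise GeometryError("boundary outline is not a simple closed curve")
        if poly.area <= 0:
            raise GeometryError("boundary encloses no area")
        # star-shapedness w.r.t. the centroid: polar angle strictly increasing
        c = self.centroid
        rel = self._pts - c
        ang = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
        if np.any(np.diff(ang) <= 0) or not math.isclose(
            ang[-1] - ang[0], 2 * np.pi * (1 - 1 / _DENSE), rel_tol=0.05
        ):
            raise GeometryError("outline is not star-shaped about its centroid")

    # -- basic quantities -------------------------------------------------
    @property
    def perimeter(self) -> float:
        return float(self._arclen[-1])

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self._pts)

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])

    @property
    def inradius(self) -> float:
        """Minimum distance from the centroid to the boundary."""
        return float(np.min(np.linalg.norm(self._pts - self.centroid, axis=1)))

    @property
    def front_arclength(self) -> float:
        """Arc length of the frontmost boundary point (the +y direction)."""
        i = int(np.argmax(self._pts[:, 1]))
        return float(self._arclen[i])

    def point_at_arclength(self, s) -> np.ndarray:
        """Boundary point(s) at arc length ``s`` (wraps around)."""
        s = np.mod(np.asarray(s, dtype=float), self.perimeter)
        pts = np.vstack([self._pts, self._pts[:1]])
        x = np.interp(s, self._arclen, pts[:, 0])
        y = np.interp(s, self._arclen, pts[:, 1])
        return np.stack([x, y], axis=-1)


def make_domain(kind: str, **params) -> Domain2D:
    """Construct an imaging domain.

    ``make_domain("disk", radius=10)`` — circular model of radius 10 cm.
    ``make_domain("ellipse", a=7.5, b=4.5)`` — elliptical model (semi-axes cm).
    ``make_domain("abdomen")`` — smooth abdomen-like surrogate outline,
    roughly 30 cm wide and 20 cm deep; pass ``control_points`` to override.
    """
    if kind == "disk":
        params.setdefault("radius", 10.0)
        if params["radius"] <= 0:
            raise ValidationError("radius must be positive")
    elif kind == "ellipse":
        params.setdefault("a", 7.5)
        params.setdefault("b", 4.5)
        if params["a"] <= 0 or params["b"] <= 0:
            raise ValidationError("semi-axes must be positive")
    elif kind == "abdomen":
        if "control_points" not in params:
            th = np.linspace(0.0, 2 * np.pi, 24, endpoint=False)
            r = _abdomen_radius(th)
            params["control_points"] = np.column_stack(
                [r * np.cos(th), r * np.sin(th)]
            )
    else:
        raise ValidationError(f"unknown domain kind {kind!r}")
    return Domain2D(kind=kind, params=params)


@dataclass
class ElectrodeArray:
    """``E`` electrode arcs on the boundary, ordered by arc length.

    ``centers`` are arc-length positions of electrode midpoints; each
    electrode covers ``[center - width/2, center + width/2]`` on the boundary.
    """

    E: int
    centers: np.ndarray
    width: float
    arc_span: float
    perimeter: float

    def intervals(self) -> np.ndarray:
        """(E, 2) array of arc-length intervals, possibly wrapping at 0."""
        return np.column_stack(
            [self.centers - self.width / 2, self.centers + self.width / 2]
        )

    @property
    def total_length(self) -> float:
        return self.E * self.width

    def contains(self, s: np.ndarray) -> np.ndarray:
        """Electrode index (1-based) covering arc length ``s``, else 0."""
        s = np.mod(np.asarray(s, dtype=float), self.perimeter)
        out = np.zeros(s.shape, dtype=int)
        for k, (lo, hi) in enumerate(self.intervals()):
            lo_m, hi_m = lo % self.perimeter, hi % self.perimeter
            if lo_m <= hi_m:
                inside = (s >= lo_m) & (s <= hi_m)
            else:  # wraps through 0
                inside = (s >= lo_m) | (s <= hi_m)
            out[inside] = k + 1
        return out


def place_electrodes(
    domain: Domain2D, E: int = 10, arc_span: float = 0.5, width: float = 1.0
) -> ElectrodeArray:
    """Place ``E`` equally spaced electrodes on the frontal arc.

    The electrodes are centered on an arc of length ``arc_span * perimeter``
    around the frontmost boundary point; ``arc_span=1`` spreads them over the
    whole boundary.
    """
    if width <= 0 or not 0 < arc_span <= 1:
        raise ValidationError("width must be positive and 0 < arc_span <= 1")
    if E < 2:
        raise ValidationError("need at least two electrodes")
    P = domain.perimeter
    span = arc_span * P
    pitch = span / E
    if width >= pitch:
        raise GeometryError(
            f"electrodes overlap: width {width} cm >= pitch {pitch:.3f} cm "
            f"({E} electrodes on a {span:.1f} cm arc)"
        )
    if E < 4:
        raise ValidationError("E >= 4 required (no disjoint measurement pair)")
    s0 = domain.front_arclength - span / 2
    centers = np.mod(s0 + (np.arange(E) + 0.5) * pitch, P)
    order = np.argsort(centers)
    return ElectrodeArray(
        E=E, centers=centers[order], width=width, arc_span=arc_span, perimeter=P
    )


@dataclass
class FEMesh:
    """Conforming triangulation of a domain with labelled boundary edges.

    ``boundary_edges`` is an (nb, 2) array of node indices on ``dOmega``;
    ``boundary_labels`` gives the covering electrode (1-based) or 0 off the
    electrodes.  ``element_markers`` holds the distance-layer index per
    triangle once :func:`compute_layers` has been applied (0 before).
    """

    nodes: np.ndarray
    triangles: np.ndarray
    boundary_edges: np.ndarray
    boundary_labels: np.ndarray
    domain: Domain2D
    electrodes: ElectrodeArray
    element_markers: np.ndarray = None

    def __post_init__(self):
        if self.element_markers is None:
            self.element_markers = np.zeros(len(self.triangles), dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    @property
    def areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    @property
    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def content_hash(self) -> str:
        """Stable fingerprint of the discretization (nodes + topology)."""
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.nodes).tobytes())
        h.update(np.ascontiguousarray(self.triangles).tobytes())
        h.update(np.ascontiguousarray(self.boundary_labels).tobytes())
        return h.hexdigest()[:16]


def _boundary_stations(domain: Domain2D, electrodes: ElectrodeArray, h: float):
    """Arc-length stations on the boundary, refined on the electrodes."""
    P = domain.perimeter
    ivals = electrodes.intervals()
    breaks = np.sort(np.mod(ivals.ravel(), P))
    stations: list[float] = []
    segs = np.column_stack([breaks, np.roll(breaks, -1)])
    segs[-1, 1] += P  # close the loop
    for lo, hi in segs:
        length = hi - lo
        if length <= 1e-12:
            continue
        mid = (lo + hi) / 2
        if electrodes.contains(np.array([mid]))[0] > 0:
            n = max(4, int(math.ceil(length / (h / 2))))
        else:
            n = max(1, int(math.ceil(length / h)))
        stations.extend((lo + length * np.arange(n) / n).tolist())
    s = np.unique(np.mod(np.asarray(stations), P))
    # drop near-duplicate stations produced by the modular wrap
    keep = np.concatenate([[True], np.diff(s) > 1e-9])
    return s[keep]


def _stitch(ring_a: np.ndarray, frac_a: np.ndarray, ring_b: np.ndarray,
            frac_b: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate the band between two closed rings of node indices.

    ``frac_*`` are monotone parameters in [0, 1) for the two rings; the band is
    zipped by always advancing the ring whose next parameter is smaller.
    """
    na, nb = len(ring_a), len(ring_b)
    tris = []
    i = j = 0
    # start both rings near parameter 0
    while i + j < na + nb:
        next_a = frac_a[(i + 1) % na] + (1.0 if i + 1 >= na else 0.0)
        next_b = frac_b[(j + 1) % nb] + (1.0 if j + 1 >= nb else 0.0)
        a0, a1 = ring_a[i % na], ring_a[(i + 1) % na]
        b0, b1 = ring_b[j % nb], ring_b[(j + 1) % nb]
        if (next_a <= next_b and i < na) or j >= nb:
            tris.append((a0, a1, b0))
            i += 1
        else:
            tris.append((a0, b1, b0))
            j += 1
    return tris


def _ring_depths(r_front: float, r_min: float, h: float, d0: float,
                 n_layers: int, align_layers: bool) -> np.ndarray:
    """Depths (cm, measured along the frontal ray) of the mesh rings."""
    if align_layers:
        base = [0.0]
        sub = max(1, int(math.ceil(d0 / h)))
        for k in range(1, n_layers):
            lo = d0 * (k - 1)
            base.extend((lo + d0 * np.arange(1, sub + 1) / sub).tolist())
        depths = [t for t in base if 1 - t / r_front > 0.02]
    else:
        depths = np.arange(0.0, 0.92 * r_front, h).tolist()
    # graded continuation toward the center
    t, step = depths[-1], max(h, d0 if align_layers else h)
    while True:
        step *= 1.6
        t_new = t + step
        sigma = 1 - t_new / r_front
        if sigma <= 0.02 or sigma * r_min < 1.5 * step:
            break
        depths.append(t_new)
        t = t_new
    return np.asarray(depths)


def build_mesh(
    domain: Domain2D,
    electrodes: ElectrodeArray,
    h: float,
    *,
    d0: float = 0.3,
    n_layers: int = 15,
    align_layers: bool = True,
) -> FEMesh:
    """Triangulate the domain with electrode-refined boundary resolution.

    ``h`` is the target edge length (cm); electrode arcs are resolved with
    edges no longer than ``h/2`` and at least 4 edges per electrode.  With
    ``align_layers`` (default) the ring depths coincide with the boundaries of
    the ``n_layers`` distance layers of thickness ``d0`` so layer bands are
    exactly one or more element rows deep near the front of the domain.
    """
    if h <= 0:
        raise ValidationError("target edge length h must be positive")
    P = domain.perimeter
    c = domain.centroid
    stations = _boundary_stations(domain, electrodes, h)
    ring0 = domain.point_at_arclength(stations)
    r_front = float(np.linalg.norm(domain.point_at_arclength(domain.front_arclength) - c))
    depths = _ring_depths(r_front, domain.inradius, h, d0, n_layers, align_layers)

    nodes: list[np.ndarray] = [ring0]
    ring_idx: list[np.ndarray] = [np.arange(len(ring0))]
    ring_frac: list[np.ndarray] = [stations / P]
    n_total = len(ring0)
    for t in depths[1:]:
        sigma = 1 - t / r_front
        circ = sigma * P
        n_k = min(len(ring0), max(8, int(math.ceil(circ / h))))
        # subsample the boundary stations to keep radial edges roughly aligned
        pick = np.unique((np.arange(n_k) * len(stations) // n_k))
        frac = stations[pick] / P
        pts = c + sigma * (domain.point_at_arclength(stations[pick]) - c)
        nodes.append(pts)
        ring_idx.append(n_total + np.arange(len(pts)))
        ring_frac.append(frac)
        n_total += len(pts)
    center_idx = n_total
    nodes.append(c[None, :])
    all_nodes = np.vstack(nodes)

    tris: list[tuple[int, int, int]] = []
    for k in range(len(ring_idx) - 1):
        tris.extend(_stitch(ring_idx[k], ring_frac[k], ring_idx[k + 1], ring_frac[k + 1]))
    last = ring_idx[-1]
    for i in range(len(last)):
        tris.append((last[i], last[(i + 1) % len(last)], center_idx))
    triangles = np.asarray(tris, dtype=np.int64)

    # enforce counter-clockwise orientation
    p = all_nodes[triangles]
    signed = 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    flip = signed < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]
    if np.any(np.abs(signed) < 1e-12):
        raise MeshingError("degenerate (zero-area) triangle produced")

    nb = len(stations)
    boundary_edges = np.column_stack([np.arange(nb), (np.arange(nb) + 1) % nb])
    mids = np.mod(stations + np.diff(np.append(stations, stations[0] + P)) / 2, P)
    labels = electrodes.contains(mids)
    for e in range(1, electrodes.E + 1):
        if np.sum(labels == e) < 4:
            raise MeshingError(f"electrode {e} covered by fewer than 4 edges")

    return FEMesh(
        nodes=all_nodes,
        triangles=triangles,
        boundary_edges=boundary_edges,
        boundary_labels=labels,
        domain=domain,
        electrodes=electrodes,
    )


@dataclass
class LayerPartition:
    """Partition of the mesh elements into ``L`` distance-to-boundary layers.

    Layer ``l`` (1-based) collects elements whose centroid distance ``d`` to
    the boundary satisfies ``d0*(l-1) <= d < d0*l`` (half-open convention);
    layer ``L`` absorbs the remainder of the domain, including everything
    outside the frontal region of interest when one is set.
    """

    L: int
    d0: float
    layer_of_element: np.ndarray
    roi: str | None = None

    def elements_in_layer(self, l: int) -> np.ndarray:
        return np.flatnonzero(self.layer_of_element == l)

    def layer_areas(self, mesh: FEMesh) -> np.ndarray:
        areas = mesh.areas
        return np.array(
            [areas[self.layer_of_element == l].sum() for l in range(1, self.L + 1)]
        )


def compute_layers(
    mesh: FEMesh, d0: float = 0.3, L: int = 15, roi: str | None = None
) -> LayerPartition:
    """Assign each element to a distance layer by its centroid.

    ``roi="frontal"`` restricts the layered region to the angular sector
    subtended by the electrode array (recommended for abdomen domains);
    elements outside the sector fall into layer ``L``.
    """
    if L < 3:
        raise ValidationError("need at least 3 layers (fat + muscle + rest)")
    if d0 <= 0:
        raise ValidationError("layer thickness d0 must be positive")
    if d0 * (L - 1) >= mesh.domain.inradius:
        raise ValidationError(
            f"layered band d0*(L-1) = {d0 * (L - 1):.2f} cm does not fit inside "
            f"the domain (inradius {mesh.domain.inradius:.2f} cm)"
        )
    nb = len(mesh.boundary_edges)
    boundary = shapely.LinearRing(mesh.nodes[:nb])
    cent = mesh.centroids
    dist = shapely.distance(shapely.points(cent), boundary)
    layer = np.minimum(np.floor(dist / d0).astype(int) + 1, L)

    if roi == "frontal":
        c = mesh.domain.centroid
        front = mesh.domain.point_at_arclength(mesh.domain.front_arclength) - c
        a0 = math.atan2(front[1], front[0])
        epts = mesh.domain.point_at_arclength(
            np.ravel(mesh.electrodes.intervals())
        ) - c
        rel = np.angle(np.exp(1j * (np.arctan2(epts[:, 1], epts[:, 0]) - a0)))
        half = float(np.max(np.abs(rel)))
        cang = np.angle(np.exp(1j * (np.arctan2(cent[:, 1] - c[1], cent[:, 0] - c[0]) - a0)))
        layer[np.abs(cang) > half] = L
    elif roi is not None:
        raise ValidationError(f"unknown roi {roi!r}")

    part = LayerPartition(L=L, d0=d0, layer_of_element=layer, roi=roi)
    mesh.element_markers = layer.copy()
    return part
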