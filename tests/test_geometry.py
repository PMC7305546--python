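import math

import numpy as np
import pytest

from eit_fatlayer import (
    GeometryError,
    MeshingError,
    ValidationError,
    build_mesh,
    compute_layers,
    make_domain,
    place_electrodes,
)
from oracles import polygon_area_shoelace


class TestDomains:
    def test_disk_perimeter_and_area(self):
        d = make_domain("disk", radius=10)
        assert d.perimeter == pytest.approx(2 * math.pi * 10, rel=1e-6)
        assert d.area == pytest.approx(math.pi * 100, rel=1e-6)

    def test_ellipse_defaults_and_area(self):
        d = make_domain("ellipse")
        assert d.params == {"a": 7.5, "b": 4.5}
        assert d.area == pytest.approx(math.pi * 7.5 * 4.5, rel=1e-6)

    def test_abdomen_area_matches_shoelace_and_bounding_ellipse(self):
        d = make_domain("abdomen")
        assert d.area == pytest.approx(polygon_area_shoelace(d._pts), rel=1e-9)
        pts = d._pts
        a = (pts[:, 0].max() - pts[:, 0].min()) / 2
        b = (pts[:, 1].max() - pts[:, 1].min()) / 2
        assert abs(d.area - math.pi * a * b) / (math.pi * a * b) < 0.10

    @pytest.mark.parametrize("kind,params", [
        ("disk", {"radius": -1}),
        ("ellipse", {"a": 0.0, "b": 2.0}),
        ("nonsense", {}),
    ])
    def test_invalid_domains_raise(self, kind, params):
        with pytest.raises(ValidationError):
            make_domain(kind, **params)

    def test_non_star_shaped_outline_rejected(self):
        t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        pts = np.column_stack([10 * np.cos(t), 10 * np.sin(t)])
        pts[3] = [25.0, 25.0]  # spike far outside makes the spline loop back
        with pytest.raises(GeometryError):
            make_domain("abdomen", control_points=pts)


class TestElectrodes:
    def test_full_circle_equal_spacing(self):
        d = make_domain("disk", radius=10)
        e = place_electrodes(d, E=10, arc_span=1.0, width=1.0)
        gaps = np.diff(np.sort(e.centers)) - e.width
        expected_gap = (d.perimeter - 10 * 1.0) / 10
        assert gaps == pytest.approx(expected_gap, rel=1e-9)

    def test_frontal_third_span(self):
        d = make_domain("disk", radius=10)
        e = place_electrodes(d, E=10, arc_span=1 / 3, width=0.8)
        span = d.perimeter / 3
        lo = d.front_arclength - span / 2
        rel = (e.centers - lo) % d.perimeter
        assert np.all(rel < span)

    def test_total_covered_arc_equals_E_times_width(self):
        d = make_domain("ellipse")
        e = place_electrodes(d, E=10, arc_span=0.5, width=1.0)
        ivals = e.intervals()
        covered = float(np.sum(ivals[:, 1] - ivals[:, 0]))
        assert covered == pytest.approx(e.E * e.width, rel=1e-12)

    def test_overlap_raises(self):
        d = make_domain("disk", radius=10)
        with pytest.raises(GeometryError):
            place_electrodes(d, E=2, arc_span=0.1, width=5.0)

    def test_too_few_electrodes(self):
        d = make_domain("disk", radius=10)
        with pytest.raises(ValidationError):
            place_electrodes(d, E=3, arc_span=1.0, width=1.0)


class TestMesh:
    def test_postconditions(self, disk):
        m = disk.mesh
        assert m.areas.min() > 0
        assert m.areas.sum() == pytest.approx(m.domain.area, rel=5e-3)
        for e in range(1, 11):
            assert np.sum(m.boundary_labels == e) >= 4

    def test_nonpositive_h_raises(self):
        d = make_domain("disk", radius=10)
        e = place_electrodes(d, 10, 0.5, 1.0)
        with pytest.raises(ValidationError):
            build_mesh(d, e, 0.0)

    def test_refinement_changes_voltage_below_one_percent(self, disk):
        from eit_fatlayer import ConductivityField, FEMOperator

        d, e, prot = disk.domain, disk.electrodes, disk.protocol
        fine = build_mesh(d, e, 0.3)
        op_f = FEMOperator(fine, prot)
        v_coarse = disk.op.simulate(
            ConductivityField.homogeneous(disk.mesh)).values
        v_fine = op_f.simulate(ConductivityField.homogeneous(fine)).values
        num = np.abs(v_fine - v_coarse).max()
        assert num / np.abs(v_fine).max() < 0.01


class TestLayers:
    def test_disk_layer_radii_and_areas(self, disk):
        part = disk.partition
        cent = disk.mesh.centroids
        r = np.linalg.norm(cent, axis=1)
        lay = part.layer_of_element
        # annulus 9.7 < r < 10 is layer 1; r < 5.8 is layer 15
        assert np.all(lay[r > 9.71] == 1)
        assert np.all(lay[r < 5.79] == 15)
        areas = part.layer_areas(disk.mesh)
        for l in range(1, 15):
            exact = math.pi * ((10 - 0.3 * (l - 1)) ** 2 - (10 - 0.3 * l) ** 2)
            assert abs(areas[l - 1] - exact) / exact < 0.02

    def test_partition_is_exact_cover(self, disk):
        lay = disk.partition.layer_of_element
        union = np.concatenate(
            [disk.partition.elements_in_layer(l) for l in range(1, 16)]
        )
        assert np.array_equal(np.sort(union), np.arange(disk.mesh.n_elements))
        assert lay.min() >= 1 and lay.max() == 15

    @pytest.mark.parametrize("L", [1, 2])
    def test_too_few_layers(self, disk, L):
        with pytest.raises(ValidationError):
            compute_layers(disk.mesh, 0.3, L)

    def test_band_must_fit_inside_domain(self, disk):
        with pytest.raises(ValidationError):
            compute_layers(disk.mesh, 1.0, 15)

    def test_frontal_roi_pushes_back_into_rest_layer(self):
        from conftest import make_setup

        full = make_setup(kind="abdomen", h=0.6, arc_span=0.35, width=1.5)
        roi = compute_layers(full.mesh, 0.3, 15, roi="frontal")
        cent = full.mesh.centroids
        behind = cent[:, 1] < full.domain.centroid[1] - 1.0
        assert np.all(roi.layer_of_element[behind] == 15)
        # frontal shallow elements keep their distance layer
        assert (roi.layer_of_element == 1).sum() > 0
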