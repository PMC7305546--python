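import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eit_fatlayer import (
    ConductivityField,
    FEMOperator,
    ValidationError,
    add_noise,
    build_mesh,
    energy_form,
    make_protocol,
    measure,
    solve_drive,
)
from oracles import brute_force_protocol, disk_series_voltages


class TestProtocol:
    @pytest.mark.parametrize("E,n_drives,n_per,total", [
        (10, 45, 28, 1260),
        (4, 6, 1, 6),
        (5, 10, 3, 30),
    ])
    def test_counts(self, E, n_drives, n_per, total):
        p = make_protocol(E)
        assert p.n_drives == n_drives
        assert len(p.meas_pairs_per_drive[0]) == n_per
        assert p.n_measurements == total

    def test_matches_brute_force_enumeration(self):
        p = make_protocol(5)
        drives, meas = brute_force_protocol(5)
        assert p.drive_pairs == drives
        assert p.meas_pairs_per_drive == meas

    def test_too_few_electrodes(self):
        with pytest.raises(ValidationError):
            make_protocol(3)

    @settings(deadline=None, max_examples=10)
    @given(E=st.integers(min_value=4, max_value=9))
    def test_measurement_pairs_disjoint_from_drive(self, E):
        p = make_protocol(E)
        for d, meas in zip(p.drive_pairs, p.meas_pairs_per_drive):
            for m in meas:
                assert not set(d) & set(m)


class TestSolver:
    def test_matches_analytic_disk_series(self, disk):
        V = disk.op.simulate(ConductivityField.homogeneous(disk.mesh)).values
        V_exact = disk_series_voltages(
            disk.domain, disk.electrodes, disk.protocol, 1.0
        )
        assert np.abs(V - V_exact).max() / np.abs(V_exact).max() < 0.01

    def test_conductivity_scaling(self, disk):
        V1 = disk.op.simulate(ConductivityField.homogeneous(disk.mesh, 1.0)).values
        for c in (0.5, 2.0, 10.0):
            Vc = disk.op.simulate(
                ConductivityField.homogeneous(disk.mesh, c)).values
            assert np.abs(Vc - V1 / c).max() / np.abs(V1).max() < 1e-12

    def test_reciprocity(self, disk):
        V = disk.op.simulate(ConductivityField.homogeneous(disk.mesh)).values
        vals = dict(zip(disk.protocol.index, V))
        worst = max(
            abs(vals[(d, m)] - vals[(m, d)])
            for (d, m) in vals if (m, d) in vals
        )
        assert worst / np.abs(V).max() < 1e-8

    def test_charge_conservation_and_gauge(self, disk):
        assert np.abs(disk.op.loads.sum(axis=0)).max() < 1e-12 * disk.protocol.I
        U = disk.op.solve_all(np.ones(disk.mesh.n_elements))
        assert np.abs(disk.op._mass @ U).max() < 1e-9

    def test_convergence_order(self):
        from conftest import make_setup

        base = make_setup(h=1.2)
        V_exact = disk_series_voltages(
            base.domain, base.electrodes, base.protocol, 1.0
        )
        errs = []
        hs = [1.2, 0.6, 0.3]
        for h in hs:
            mesh = build_mesh(base.domain, base.electrodes, h,
                              align_layers=False)
            op = FEMOperator(mesh, base.protocol)
            V = op.simulate(ConductivityField.homogeneous(mesh)).values
            errs.append(np.abs(V - V_exact).max() / np.abs(V_exact).max())
        order = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert order >= 1.5

    def test_nonpositive_conductivity_rejected(self, disk):
        with pytest.raises(ValidationError):
            ConductivityField(np.zeros(disk.mesh.n_elements))

    def test_solve_drive_single(self, disk):
        f = solve_drive(disk.op, ConductivityField.homogeneous(disk.mesh),
                        (0, 5))
        assert f.drive == (0, 5)
        assert np.isfinite(f.u).all()
        with pytest.raises(ValidationError):
            solve_drive(disk.op, ConductivityField.homogeneous(disk.mesh),
                        (2, 2))


class TestMeasurement:
    def test_vector_length_and_order(self, disk):
        U = disk.op.solve_all(np.ones(disk.mesh.n_elements))
        V = measure(disk.op, U)
        assert len(V) == 1260
        df = V.to_frame()
        assert list(df.columns) == ["j_plus", "j_minus", "i_plus", "i_minus", "V"]
        # canonical order: first drive (0,1), first measurement (2,3)
        assert tuple(df.iloc[0][:4]) == (0, 1, 2, 3)

    def test_measure_rejects_wrong_shape(self, disk):
        with pytest.raises(ValidationError):
            measure(disk.op, np.zeros((3, 3)))

    def test_energy_form_equals_voltage(self, disk):
        gamma = ConductivityField.homogeneous(disk.mesh)
        U = disk.op.solve_all(gamma)
        V = measure(disk.op, U)
        vals = dict(zip(disk.protocol.index, V.values))
        drive, meas = disk.protocol.index[100]
        j = disk.protocol.pair_number(drive)
        i = disk.protocol.pair_number(meas)
        ef = energy_form(disk.op, gamma, U[:, j], U[:, i])
        assert ef == pytest.approx(vals[(drive, meas)], rel=2e-2)
        # self-energy is positive, and the form is linear in gamma
        assert energy_form(disk.op, gamma, U[:, j], U[:, j]) > 0
        doubled = ConductivityField(2 * gamma.values)
        assert energy_form(disk.op, doubled, U[:, j], U[:, i]) == pytest.approx(
            2 * ef, rel=1e-12
        )


class TestNoise:
    def test_zero_level_is_identity(self, disk):
        V = disk.op.simulate(ConductivityField.homogeneous(disk.mesh))
        out = add_noise(V, 0.0, seed=3)
        assert np.array_equal(out.values, V.values)

    def test_seeded_reproducibility(self, disk):
        V = disk.op.simulate(ConductivityField.homogeneous(disk.mesh))
        a = add_noise(V, 0.01, seed=7).values
        b = add_noise(V, 0.01, seed=7).values
        assert np.array_equal(a, b)
        assert not np.array_equal(a, add_noise(V, 0.01, seed=8).values)

    def test_empirical_level(self, disk):
        V = disk.op.simulate(ConductivityField.homogeneous(disk.mesh))
        out = add_noise(V, 0.05, seed=0)
        level = np.std(out.values / V.values - 1)
        assert level == pytest.approx(0.05, rel=0.10)
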