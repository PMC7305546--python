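import numpy as np
import pytest

from eit_fatlayer import (
    GAMMA_M_GRID,
    GAMMA_R_GRID,
    LayeredConductivity,
    TrainingDataset,
    ValidationError,
    enumerate_conductivities,
    enumerate_partitions,
    enumerate_specs,
    generate_dataset,
    spec_to_field,
)


class TestEnumeration:
    def test_partition_counts(self):
        assert len(enumerate_partitions(15)) == 91
        assert enumerate_partitions(3) == [(1, 2)]
        # brute-force double loop for L=5
        brute = [(a, b) for a in range(1, 4) for b in range(a + 1, 5)]
        assert enumerate_partitions(5) == brute
        assert len(brute) == 6

    def test_partition_validation(self):
        with pytest.raises(ValidationError):
            enumerate_partitions(2)

    def test_default_grids_match_study_counts(self):
        assert len(GAMMA_M_GRID) == 17
        assert len(GAMMA_R_GRID) == 9
        assert len(enumerate_conductivities()) == 17 * 9
        assert len(enumerate_specs()) == 13923

    def test_single_value_grids(self):
        out = enumerate_conductivities(1.0, [2.0], [1.5])
        assert out == [(1.0, 2.0, 1.5)]

    def test_order_constraint_filter(self):
        out = enumerate_conductivities(1.0, [2.0], [1.5, 2.5],
                                       enforce_order=True)
        assert out == [(1.0, 2.0, 1.5)]

    def test_grid_violating_contrast_bound(self):
        with pytest.raises(ValidationError):
            enumerate_conductivities(1.0, [11.0], [1.5])


class TestSpecToField:
    def test_layer_vector_and_thicknesses(self, tiny_disk):
        spec = LayeredConductivity(3, 7, 1.0, 5.0, 2.0)
        field, target = spec_to_field(spec, tiny_disk.partition)
        expected = np.array([1, 1, 1, 5, 5, 5, 5] + [2] * 8, dtype=float)
        assert np.array_equal(target, expected)
        assert spec.fat_thickness(0.3) == pytest.approx(0.9)
        assert spec.muscle_thickness(0.3) == pytest.approx(1.2)
        lay = tiny_disk.partition.layer_of_element
        assert np.array_equal(field.values, expected[lay - 1])

    @pytest.mark.parametrize("spec", [
        LayeredConductivity(7, 7, 1.0, 5.0, 2.0),   # l_f == l_m
        LayeredConductivity(0, 7, 1.0, 5.0, 2.0),   # l_f out of range
        LayeredConductivity(3, 15, 1.0, 5.0, 2.0),  # l_m too deep
        LayeredConductivity(3, 7, 1.0, 11.0, 2.0),  # contrast bound
        LayeredConductivity(3, 7, 1.0, 0.5, 2.0),   # muscle below fat
    ])
    def test_invalid_specs(self, tiny_disk, spec):
        with pytest.raises(ValidationError):
            spec_to_field(spec, tiny_disk.partition)


class TestGenerateDataset:
    @pytest.fixture(scope="class")
    def small(self, tiny_disk):
        specs = [
            LayeredConductivity(3, 7, 1.0, 5.0, 2.0),
            LayeredConductivity(7, 14, 1.0, 6.0, 4.5),
            LayeredConductivity(1, 2, 1.0, 2.0, 1.5),
        ]
        return generate_dataset(
            tiny_disk.op, tiny_disk.partition, specs, ref=tiny_disk.ref, seed=5
        )

    def test_shapes_and_alignment(self, small):
        assert small.inputs.shape == (3, 1260)
        assert small.inputs_raw.shape == (3, 1260)
        assert small.targets.shape == (3, 15)
        assert small.n_rows == len(small.specs) == 3

    def test_deterministic_regeneration(self, tiny_disk, small):
        again = generate_dataset(
            tiny_disk.op, tiny_disk.partition, small.specs,
            ref=tiny_disk.ref, seed=5,
        )
        assert again.content_hash() == small.content_hash()
        assert np.array_equal(again.inputs, small.inputs)

    def test_bracketing_on_well_coupled_pairs(self, tiny_disk, small):
        strong = np.abs(tiny_disk.ref.S) >= np.quantile(
            np.abs(tiny_disk.ref.S), 0.5
        )
        for x, y in zip(small.inputs, small.targets):
            assert x[strong].min() > y.min() * 0.95
            assert x[strong].max() < y.max() * 1.05

    def test_duplicates_rejected(self, tiny_disk, small):
        with pytest.raises(ValidationError):
            generate_dataset(
                tiny_disk.op, tiny_disk.partition,
                [small.specs[0], small.specs[0]], ref=tiny_disk.ref,
            )

    def test_hdf5_roundtrip(self, small, tmp_path):
        p = tmp_path / "ds.h5"
        small.save(p)
        back = TrainingDataset.load(p)
        assert np.array_equal(back.inputs, small.inputs)
        assert np.array_equal(back.targets, small.targets)
        assert back.specs == small.specs
        assert back.provenance == small.provenance

    def test_split_is_seeded_partition(self, small):
        tr, val = small.split(0.34, seed=2)
        assert sorted(np.concatenate([tr, val])) == [0, 1, 2]
        tr2, val2 = small.split(0.34, seed=2)
        assert np.array_equal(tr, tr2) and np.array_equal(val, val2)

    def test_count_identity_property(self):
        for L, nm, nr in [(6, 2, 3), (15, 5, 3)]:
            gm = np.linspace(2, 10, nm)
            gr = np.linspace(1.5, 9.5, nr)
            specs = enumerate_specs(L, 1.0, gm, gr)
            assert len(specs) == (L - 1) * (L - 2) // 2 * nm * nr
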