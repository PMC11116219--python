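"""Phantom generation and controlled defect simulation."""

import numpy as np
import pytest

import cranioshape as cs
from cranioshape.errors import PhantomSpecError
from cranioshape.metrics import surface_mask
from cranioshape.synthetic import analytic_shell_volume, sample_spec

from .conftest import SMALL_SPEC


class TestPhantoms:
    def test_deterministic(self):
        assert cs.generate_phantom(SMALL_SPEC) == cs.generate_phantom(SMALL_SPEC)

    def test_volume_matches_analytic_shell_volume(self):
        for spec in [SMALL_SPEC,
                     cs.PhantomSpec(grid_shape=(64, 64, 64), radii=(24, 20, 22),
                                    thickness=4.0, rotation=(0.1, 0.2, -0.1))]:
            vol = cs.generate_phantom(spec)
            expected = analytic_shell_volume(spec)
            assert abs(vol.foreground_count / expected - 1.0) <= 0.15

    def test_thin_shell_is_all_surface(self):
        spec = cs.PhantomSpec(grid_shape=(40, 40, 40), radii=(14, 12, 13), thickness=1.0)
        vol = cs.generate_phantom(spec)
        assert not vol.is_empty
        surf = surface_mask(vol.data)
        assert np.array_equal(surf, vol.data.astype(bool))

    def test_shell_is_hollow(self, small_phantom):
        center = tuple(np.asarray(small_phantom.shape) // 2)
        assert small_phantom.data[center] == 0

    def test_facial_lobe_adds_material(self):
        base = cs.generate_phantom(SMALL_SPEC)
        lobed = cs.generate_phantom(
            cs.PhantomSpec(**{**SMALL_SPEC.__dict__, "facial_lobe": True})
        )
        assert lobed.foreground_count > base.foreground_count
        assert np.all(lobed.data >= base.data)

    @pytest.mark.parametrize("bad", [
        dict(thickness=0.5),
        dict(radii=(3.0, 15.0, 16.0), thickness=3.5),
        dict(radii=(30.0, 15.0, 16.0)),  # exceeds 48-voxel grid
        dict(translation=(10.0, 0.0, 0.0)),
    ])
    def test_invalid_specs_rejected(self, bad):
        spec = cs.PhantomSpec(**{**SMALL_SPEC.__dict__, **bad})
        with pytest.raises(PhantomSpecError):
            cs.generate_phantom(spec)


class TestDefects:
    @pytest.mark.parametrize("kind,count", [
        ("sphere", 1), ("cube", 1), ("multi_lobe", 2), ("border_crossing", 1),
    ])
    def test_partition_identity(self, small_phantom, kind, count):
        spec = cs.DefectSpec(kind=kind, size_fraction=0.2, count=count, seed=3)
        defective, implant = cs.apply_defect(small_phantom, spec)
        assert np.array_equal(defective.data | implant.data, small_phantom.data)
        assert not np.any(defective.data & implant.data)
        assert not implant.is_empty

    def test_defect_size_tracks_fraction(self, small_phantom):
        total = small_phantom.foreground_count
        for frac in (0.1, 0.2, 0.3):
            _, implant = cs.apply_defect(
                small_phantom, cs.DefectSpec(kind="sphere", size_fraction=frac, seed=1))
            assert abs(implant.foreground_count / total - frac) <= 0.05

    def test_tiny_defect_is_a_few_voxels(self, small_phantom):
        _, implant = cs.apply_defect(
            small_phantom, cs.DefectSpec(kind="sphere", size_fraction=0.001, seed=2))
        assert 1 <= implant.foreground_count <= 30

    def test_two_lobes_make_two_components(self, small_phantom):
        _, implant = cs.apply_defect(
            small_phantom,
            cs.DefectSpec(kind="multi_lobe", size_fraction=0.15, count=2, seed=8))
        n, sizes = cs.count_components(implant, connectivity=26)
        assert n == 2
        assert sizes.sum() == implant.foreground_count

    def test_defect_is_deterministic_per_seed(self, small_phantom):
        spec = cs.DefectSpec(kind="sphere", size_fraction=0.2, seed=4)
        d1, i1 = cs.apply_defect(small_phantom, spec)
        d2, i2 = cs.apply_defect(small_phantom, spec)
        assert d1 == d2 and i1 == i2

    @pytest.mark.parametrize("bad", [
        dict(kind="torus"), dict(size_fraction=0.0),
        dict(size_fraction=0.6), dict(count=0),
    ])
    def test_invalid_defect_specs_rejected(self, small_phantom, bad):
        with pytest.raises(PhantomSpecError):
            cs.apply_defect(small_phantom, cs.DefectSpec(**bad))


class TestCohorts:
    def test_reproducible_per_seed(self):
        a = cs.generate_cohort(4, base_spec=SMALL_SPEC, seed=9)
        b = cs.generate_cohort(4, base_spec=SMALL_SPEC, seed=9)
        assert all(x == y for x, y in zip(a, b))
        c = cs.generate_cohort(4, base_spec=SMALL_SPEC, seed=10)
        assert any(x != y for x, y in zip(a, c))

    def test_minimum_size_enforced(self):
        with pytest.raises(PhantomSpecError):
            cs.generate_cohort(1)

    def test_members_vary_but_remain_valid_shells(self):
        cohort = cs.generate_cohort(4, base_spec=SMALL_SPEC, seed=2)
        volumes = {v.foreground_count for v in cohort}
        assert len(volumes) == 4  # inter-subject variation present
        for v in cohort:
            assert not v.is_empty

    def test_sampled_specs_stay_within_population_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            spec = sample_spec(SMALL_SPEC, rng)
            spec.validate()
            ratio = np.asarray(spec.radii) / np.asarray(SMALL_SPEC.radii)
            # global size (±8 %) times per-axis jitter (±2 %)
            assert np.all((ratio >= 0.92 * 0.98) & (ratio <= 1.08 * 1.02))

    def test_cohort_members_register_to_each_other(self, small_cohort):
        """After mutual registration, cohort members overlap strongly."""
        fixed = small_cohort[0]
        for moving in small_cohort[1:3]:
            tr = cs.register_similarity(moving, fixed)
            assert cs.dsc(cs.warp(moving, tr), fixed) >= 0.85

    def test_cohort_mean_is_a_plausible_shell(self, small_pool):
        template = cs.mean_template(small_pool)
        assert not template.is_empty
        center = tuple(np.asarray(template.shape) // 2)
        assert template.data[center] == 0  # hollow interior
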