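"""Kinetic phantom: exact ground truth, determinism, noise statistics and
stylized degradations."""

import numpy as np
import pytest

from petgan import phantom as ph
from petgan.errors import ConfigError
from petgan.phantom import (OrganSpec, PhantomSpec, apply_degradation,
                            default_phantom_spec, render_stack, simulate_pair,
                            tac_value, vary_spec)


class TestTacValue:
    def test_constant_term(self):
        org = OrganSpec("o", (1, 1), (1, 1), (0, 1), tac=[(1.0, 0.0)])
        for t in (0.0, 5.0, 500.0):
            assert tac_value(org, t) == 1.0

    def test_half_life_evaluation(self):
        # A=2, k=ln2/10 → one half-life at t=10
        org = OrganSpec("o", (1, 1), (1, 1), (0, 1),
                        tac=[(2.0, np.log(2) / 10)])
        assert tac_value(org, 10.0) == pytest.approx(1.0, rel=1e-12)

    def test_fast_component_vanishes(self):
        org = OrganSpec("o", (1, 1), (1, 1), (0, 1),
                        tac=[(1.0, 0.0), (1.0, 50.0)])
        assert tac_value(org, 60.0) == pytest.approx(1.0, abs=1e-12)

    def test_negative_time_rejected(self):
        org = OrganSpec("o", (1, 1), (1, 1), (0, 1), tac=[(1.0, 0.0)])
        with pytest.raises(ConfigError):
            tac_value(org, -1.0)


class TestRenderStack:
    def test_noiseless_voxels_equal_tac_exactly(self, tiny_spec):
        stack, lab = render_stack(tiny_spec, t=14.0)
        for i, org in enumerate(tiny_spec.organs):
            sel = lab == i + 1
            assert sel.any()
            assert np.all(stack.voxels[sel] == tac_value(org, 14.0))
        assert np.all(stack.voxels[lab == 0] == 0.1)

    def test_every_voxel_has_exactly_one_label(self, tiny_spec):
        _, lab = render_stack(tiny_spec, t=5.0)
        assert lab.shape == (6, 16, 16)
        assert set(np.unique(lab)) <= {0, 1, 2}

    def test_same_seed_bit_identical(self, tiny_spec):
        spec = tiny_spec
        spec.poisson_scale = 100.0
        spec.gaussian_sigma = 0.05
        a, _ = render_stack(spec, t=14.0)
        b, _ = render_stack(spec, t=14.0)
        assert np.array_equal(a.voxels, b.voxels)

    def test_empty_organ_list_gives_pure_background(self):
        spec = PhantomSpec(n_slices=2, slice_shape=(4, 4), organs=[],
                           background_activity=0.3)
        stack, lab = render_stack(spec, t=1.0)
        assert np.all(stack.voxels == 0.3)
        assert np.all(lab == 0)

    def test_poisson_noise_is_unbiased(self):
        """Mean of repeated renders of one organ voxel is within 3 standard
        errors of the noiseless value."""
        org = OrganSpec("o", (1.0, 1.0), (3.0, 3.0), (0, 1),
                        tac=[(2.0, 0.0)])
        spec = PhantomSpec(n_slices=1, slice_shape=(3, 3), organs=[org],
                           poisson_scale=50.0, seed=0)
        n = 4000
        rng = np.random.default_rng(7)
        draws = np.array([render_stack(spec, 10.0, rng=rng)[0].voxels[0, 1, 1]
                          for _ in range(n)])
        se = np.sqrt(2.0 / spec.poisson_scale) / np.sqrt(n)
        assert abs(draws.mean() - 2.0) < 3 * se

    def test_psf_preserves_total_activity(self, tiny_spec):
        ref, _ = render_stack(tiny_spec, t=14.0)
        tiny_spec.psf_sigma = 1.0
        blurred, _ = render_stack(tiny_spec, t=14.0)
        assert blurred.voxels.sum() == pytest.approx(ref.voxels.sum(),
                                                     rel=0.01)
        assert not np.array_equal(blurred.voxels, ref.voxels)


class TestSimulatePair:
    def test_decaying_organ_darker_at_late_time(self, tiny_spec):
        early, late, lab = simulate_pair(tiny_spec, 5.0, 52.0)
        liver = lab == 1
        assert np.all(late.voxels[liver] < early.voxels[liver])

    def test_rising_bladder_brighter_at_late_time(self, tiny_spec):
        early, late, lab = simulate_pair(tiny_spec, 5.0, 52.0)
        bladder = lab == 2
        assert np.all(late.voxels[bladder] > early.voxels[bladder])

    def test_equal_times_rejected(self, tiny_spec):
        with pytest.raises(ConfigError):
            simulate_pair(tiny_spec, 14.0, 14.0)

    def test_time_ordering_enforced(self, tiny_spec):
        with pytest.raises(ConfigError):
            simulate_pair(tiny_spec, 52.0, 14.0)


class TestDegradation:
    def test_none_is_identity(self, tiny_spec):
        stack, _ = render_stack(tiny_spec, 5.0)
        out = apply_degradation(stack, None)
        assert out is stack
        out2 = apply_degradation(stack, {"kind": "none"})
        assert np.array_equal(out2.voxels, stack.voxels)

    def test_blur_sigma_zero_limit(self, tiny_spec):
        stack, _ = render_stack(tiny_spec, 5.0)
        out = apply_degradation(stack, {"kind": "blur", "sigma": 1e-6})
        assert np.max(np.abs(out.voxels - stack.voxels)) < 1e-6

    def test_blur_conserves_activity_within_1pct(self, tiny_spec):
        stack, _ = render_stack(tiny_spec, 5.0)
        out = apply_degradation(stack, {"kind": "blur", "sigma": 2.0})
        assert out.voxels.sum() == pytest.approx(stack.voxels.sum(),
                                                 rel=0.01)

    def test_streak_amplitude_bounds_pattern(self):
        from petgan.io import ImageStack
        zero = ImageStack(np.zeros((2, 16, 16)))
        out = apply_degradation(zero, {"kind": "streak", "amplitude": 0.25,
                                       "n_angles": 6},
                                rng=np.random.default_rng(0))
        assert np.max(np.abs(out.voxels)) <= 0.25 + 1e-12
        assert np.max(np.abs(out.voxels)) > 0.0

    def test_unknown_kind_rejected(self, tiny_spec):
        stack, _ = render_stack(tiny_spec, 5.0)
        with pytest.raises(ConfigError, match="osem"):
            apply_degradation(stack, {"kind": "osem"})


class TestSpecValidation:
    def test_negative_semi_axis_rejected(self):
        org = OrganSpec("bad", (1, 1), (-1.0, 1.0), (0, 1), tac=[(1.0, 0.0)])
        with pytest.raises(ConfigError, match="bad"):
            PhantomSpec(n_slices=2, slice_shape=(4, 4),
                        organs=[org]).validate()

    def test_slice_range_outside_stack_rejected(self):
        org = OrganSpec("o", (1, 1), (1.0, 1.0), (0, 9), tac=[(1.0, 0.0)])
        with pytest.raises(ConfigError):
            PhantomSpec(n_slices=2, slice_shape=(4, 4),
                        organs=[org]).validate()

    def test_negative_tac_rejected(self):
        org = OrganSpec("o", (1, 1), (1.0, 1.0), (0, 1),
                        tac=[(-1.0, 0.0), (0.5, 0.1)])
        with pytest.raises(ConfigError):
            PhantomSpec(n_slices=2, slice_shape=(4, 4),
                        organs=[org]).validate()

    def test_roundtrip_through_dict(self, tiny_spec):
        d = tiny_spec.to_dict()
        back = PhantomSpec.from_dict(d)
        assert back == tiny_spec


class TestDefaultPhantom:
    def test_has_the_seven_reference_organs(self):
        spec = default_phantom_spec(n_slices=40, slice_shape=(32, 32))
        names = {o.name for o in spec.organs}
        assert names == {"muscle", "brain", "heart", "liver", "spleen",
                         "kidney", "bladder"}
        spec.validate()

    def test_monotone_organ_means_across_time(self):
        spec = default_phantom_spec(n_slices=40, slice_shape=(32, 32))
        times = [5.0, 14.0, 31.0, 52.0]
        stacks = [render_stack(spec, t)[0] for t in times]
        _, lab = render_stack(spec, 5.0)
        idx = {o.name: i + 1 for i, o in enumerate(spec.organs) if
               o.name != "muscle"}
        for name, sign in [("bladder", +1), ("brain", +1), ("liver", -1),
                           ("heart", -1), ("kidney", -1)]:
            means = [s.voxels[lab == idx[name]].mean() for s in stacks]
            diffs = np.diff(means) * sign
            assert np.all(diffs > 0), name

    def test_vary_spec_is_deterministic_and_valid(self):
        base = default_phantom_spec(n_slices=40, slice_shape=(32, 32))
        a = vary_spec(base, seed=11)
        b = vary_spec(base, seed=11)
        c = vary_spec(base, seed=12)
        assert a == b
        assert a != c
        a.validate()

    def test_bladder_varies_most_between_subjects(self):
        base = default_phantom_spec(n_slices=40, slice_shape=(32, 32))
        late = []
        for seed in range(30):
            v = vary_spec(base, seed=seed)
            late.append({o.name: tac_value(o, 52.0) for o in v.organs})
        cv = {}
        for name in ("bladder", "liver", "brain"):
            vals = np.array([d[name] for d in late])
            cv[name] = vals.std() / vals.mean()
        assert cv["bladder"] > 3 * cv["liver"]
        assert cv["bladder"] > 3 * cv["brain"]
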