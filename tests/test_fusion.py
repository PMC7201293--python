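import numpy as np
import pytest

from segfuse import (
    BinaryMask,
    FusionParams,
    ValidationError,
    binarize,
    fuse,
    majority,
    mav,
    simple,
    simple_fuse_class,
    validate_ensemble,
    weighted_majority,
)
from conftest import make_seg
from reference_impl import brute_force_weighted_majority, reference_simple_loop


def masks_from(arrays, label=1):
    return [BinaryMask(np.asarray(a, bool), label) for a in arrays]


def random_ensemble(rng, shape, k):
    return [rng.random(shape) < rng.uniform(0.2, 0.8) for _ in range(k)]


class TestWeightedMajority:
    def test_two_of_three_equal_weights(self):
        ms = masks_from(
            [np.array([[[1, 0]]]), np.array([[[1, 1]]]), np.array([[[0, 0]]])]
        )
        out = weighted_majority(ms, [1, 1, 1])
        assert out.voxels.ravel().tolist() == [True, False]

    def test_exactly_half_counts_as_agreement(self):
        ms = masks_from([np.array([[[1]]]), np.array([[[0]]])])
        out = weighted_majority(ms, [1, 1])
        assert bool(out.voxels[0, 0, 0]) is True

    def test_degenerate_weighting_copies_first_mask(self):
        rng = np.random.default_rng(3)
        arrays = random_ensemble(rng, (4, 4, 2), 3)
        out = weighted_majority(masks_from(arrays), [1, 0, 0])
        np.testing.assert_array_equal(out.voxels, arrays[0])

    def test_all_zero_weights_rejected(self):
        ms = masks_from([np.ones((1, 1, 1))])
        with pytest.raises(ValidationError, match="zero"):
            weighted_majority(ms, [0.0])

    def test_length_mismatch_rejected(self):
        ms = masks_from([np.ones((1, 1, 1)), np.ones((1, 1, 1))])
        with pytest.raises(ValidationError):
            weighted_majority(ms, [1.0])

    def test_matches_per_voxel_brute_force(self):
        """Exact agreement with an independent per-voxel tally."""
        rng = np.random.default_rng(2024)
        for _ in range(30):
            k = int(rng.integers(2, 8))
            arrays = random_ensemble(rng, (8, 8, 4), k)
            weights = rng.uniform(0.1, 2.0, size=k).tolist()
            ours = weighted_majority(masks_from(arrays), weights).voxels
            ref = brute_force_weighted_majority(arrays, weights)
            np.testing.assert_array_equal(ours, ref)


class TestMav:
    def test_unanimity_is_identity(self):
        seg = make_seg([0, 1, 2, 4, 0, 2])
        ens = validate_ensemble([seg] * 5)
        fused, report = mav(ens)
        np.testing.assert_array_equal(fused.voxels, seg.voxels)
        assert set(report.traces) == {"2", "1", "4"}

    def test_hand_counted_per_voxel_majority(self):
        # 1x1x3 grid, three candidates: (1,1,0) / (1,0,0) / (0,0,0)
        segs = [
            make_seg([1, 1, 0], label_set=(1,)),
            make_seg([1, 0, 0], label_set=(1,)),
            make_seg([0, 0, 0], label_set=(1,)),
        ]
        ens = validate_ensemble(segs)
        fused, _ = mav(ens, FusionParams(labels=(1,)))
        assert fused.voxels.ravel().tolist() == [1, 0, 0]

    def test_minority_blob_removed(self, small_phantom):
        """A structure present in 4 of 10 candidates does not survive the vote."""
        from segfuse import add_blob

        gt = small_phantom
        with_blob = add_blob(gt, (4, 4, 4), 2, 2)
        segs = [with_blob] * 4 + [gt] * 6
        fused, _ = mav(validate_ensemble(segs))
        blob_voxels = (with_blob.voxels == 2) & (gt.voxels == 0)
        assert blob_voxels.any()
        assert not fused.voxels[blob_voxels].any()


class TestSimpleFuseClass:
    def test_unanimity_fixed_point(self):
        rng = np.random.default_rng(5)
        base = rng.random((6, 6, 3)) < 0.4
        ms = masks_from([base] * 4)
        fused, trace = simple_fuse_class(ms, list("abcd"), FusionParams())
        np.testing.assert_array_equal(fused.voxels, base)
        assert trace.converged
        assert trace.iterations_run <= 2
        assert trace.retained_final == list("abcd")

    def test_empty_noise_candidate_dropped(self):
        """5 copies of a target + 1 empty mask: the empty rater scores 0,
        falls below the threshold and is dropped; output equals the target."""
        target = np.zeros((8, 8, 1), bool)
        target[2:6, 2:6, 0] = True
        ms = masks_from([target] * 5 + [np.zeros_like(target)])
        names = [f"good{i}" for i in range(5)] + ["noise"]
        fused, trace = simple_fuse_class(ms, names, FusionParams())
        np.testing.assert_array_equal(fused.voxels, target)
        assert "noise" not in trace.retained_final
        assert trace.converged
        # hand-computed threshold: phi = (1,1,1,1,1,0), mean 5/6, pstd sqrt(5)/6
        assert trace.iterations[0].tau == pytest.approx(5 / 6 - np.sqrt(5) / 6)

    def test_all_empty_class_converges_immediately(self):
        ms = masks_from([np.zeros((3, 3, 2), bool)] * 4)
        fused, trace = simple_fuse_class(ms, list("abcd"), FusionParams())
        assert not fused.voxels.any()
        assert trace.converged
        assert trace.iterations_run == 1
        assert trace.retained_final == list("abcd")
        assert all(v == 1.0 for v in trace.iterations[0].phi.values())

    @pytest.mark.parametrize("alpha,exponent", [(1.0, 1.0), (0.5, 2.0)])
    def test_matches_straight_line_reference(self, alpha, exponent):
        """Bit-identical to an independently written version of the loop."""
        rng = np.random.default_rng(99)
        params = FusionParams(alpha=alpha, weight_exponent=exponent)
        for _ in range(15):
            k = int(rng.integers(2, 7))
            arrays = random_ensemble(rng, (6, 6, 2), k)
            fused, trace = simple_fuse_class(
                masks_from(arrays), [str(i) for i in range(k)], params
            )
            ref, ref_history, ref_conv = reference_simple_loop(
                arrays, alpha=alpha, exponent=exponent
            )
            np.testing.assert_array_equal(fused.voxels, ref)
            got_history = [
                [int(n) for n in rec.retained] for rec in trace.iterations
            ]
            assert got_history == ref_history
            assert trace.converged == ref_conv

    def test_empty_mask_list_rejected(self):
        with pytest.raises(ValidationError):
            simple_fuse_class([], [], FusionParams())


class TestSimple:
    def test_unanimity_is_identity(self):
        seg = make_seg([0, 1, 2, 4, 2, 0])
        fused, report = simple(validate_ensemble([seg] * 3))
        np.testing.assert_array_equal(fused.voxels, seg.voxels)
        assert all(t.converged for t in report.traces.values())

    def test_absent_label_fused_as_empty(self):
        seg = make_seg([0, 2, 2, 0])  # no label 4 anywhere
        fused, report = simple(validate_ensemble([seg] * 4))
        assert not (fused.voxels == 4).any()
        trace4 = report.traces["4"]
        assert trace4.converged and trace4.iterations_run == 1
        assert trace4.retained_final == [f"c{i + 1:02d}" for i in range(4)]

    def test_region_mode_recovers_nested_labels(self, small_phantom):
        params = FusionParams(mode="regions")
        fused, report = simple(validate_ensemble([small_phantom] * 3), params)
        np.testing.assert_array_equal(fused.voxels, small_phantom.voxels)
        assert set(report.traces) == {"whole_tumor", "tumor_core", "enhancing_tumor"}


@pytest.fixture(scope="module")
def noisy_ensemble():
    from segfuse import PhantomParams, generate_ensemble, generate_phantom
    from segfuse.phantom import RaterProfile, _child_seeds

    gt = generate_phantom(PhantomParams(shape=(32, 32, 20),
                                        edema_radii=(10, 8, 6),
                                        core_radii=(6, 5, 4),
                                        necrosis_radii=(3, 2.5, 2),
                                        seed=7))
    profiles = [
        RaterProfile(boundary_noise=1, fp_blob_count=1, fn_rate=0.05, seed=s)
        for s in _child_seeds(7, 5)
    ]
    return gt, generate_ensemble(gt, profiles)


class TestFusionProperties:
    @pytest.mark.parametrize("method", ["mav", "simple"])
    def test_permutation_invariance(self, noisy_ensemble, method):
        _, ens = noisy_ensemble
        params = FusionParams(method=method)
        fused, _ = fuse(ens, params)
        perm = [3, 0, 4, 2, 1]
        ens_perm = validate_ensemble(
            [ens.candidates[i] for i in perm], [ens.names[i] for i in perm]
        )
        fused_perm, _ = fuse(ens_perm, params)
        np.testing.assert_array_equal(fused.voxels, fused_perm.voxels)

    @pytest.mark.parametrize("method", ["mav", "simple"])
    def test_no_hallucination(self, noisy_ensemble, method):
        """Fused positives for each label lie within the candidates' union."""
        _, ens = noisy_ensemble
        fused, _ = fuse(ens, FusionParams(method=method))
        for label in (1, 2, 4):
            union = np.zeros(ens.shape, bool)
            for c in ens.candidates:
                union |= c.voxels == label
            assert not ((fused.voxels == label) & ~union).any()

    @pytest.mark.parametrize("method", ["mav", "simple"])
    def test_determinism(self, noisy_ensemble, method):
        _, ens = noisy_ensemble
        a, _ = fuse(ens, FusionParams(method=method))
        b, _ = fuse(ens, FusionParams(method=method))
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_retained_set_monotone_non_increasing(self, noisy_ensemble):
        _, ens = noisy_ensemble
        _, report = simple(ens, FusionParams(alpha=1.0))
        for trace in report.traces.values():
            sets = [set(rec.retained) for rec in trace.iterations]
            for earlier, later in zip(sets, sets[1:]):
                assert later <= earlier
            assert trace.iterations_run <= 25

    def test_report_json_serializable(self, noisy_ensemble, tmp_path):
        _, ens = noisy_ensemble
        _, report = simple(ens)
        path = tmp_path / "report.json"
        report.to_json(path)
        import json

        data = json.loads(path.read_text())
        assert data["method"] == "simple"
        assert set(data["traces"]) == {"1", "2", "4"}
        for tr in data["traces"].values():
            assert tr["iterations_run"] >= 1
            assert isinstance(tr["retained_final"], list)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(method="staple"),
            dict(alpha=-0.1),
            dict(weight_exponent=0.0),
            dict(max_iter=0),
            dict(labels=()),
            dict(labels=(1, 1)),
            dict(mode="soft"),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            FusionParams(**kwargs)
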