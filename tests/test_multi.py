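"""Multi-slice joint localization: series arithmetic, pooling, γ estimation."""

import numpy as np
import pytest

from slicemapper import (ContractError, GammaEstimationError, MultiSliceSpec,
                         PoolingFailureError, ProtocolInfeasibleError,
                         Transform2D, estimate_gamma, locate_multi,
                         locate_slices, make_multislice_set, pooled_position,
                         propagate_positions, slice_range_series,
                         template_distance)
from slicemapper.multi import MultiSliceResult
from slicemapper.single import CandidateRecord, LocalizationResult, \
    SimilarityProfile


class TestTemplateDistance:
    @pytest.mark.parametrize("d_r,gamma,e_t,d_t,step", [
        (500.0, 1.0, 100.0, 500.0, 5),
        (450.0, 0.9, 100.0, 500.0, 5),
        (500.0, 0.9, 100.0, 500.0 / 0.9, 6),
    ])
    def test_conversion_and_rounding(self, d_r, gamma, e_t, d_t, step):
        got_dt, got_step = template_distance(d_r, gamma, e_t)
        assert got_dt == pytest.approx(d_t)
        assert got_step == step

    def test_sub_slice_spacing_is_degenerate(self):
        with pytest.raises(ContractError):
            template_distance(30.0, 1.0, 100.0)


class TestSliceRangeSeries:
    def test_first_slice_starts_at_one(self):
        assert slice_range_series(1, 3, 132, 5) == (1, 122)

    @pytest.mark.parametrize("s,expect", [(1, (1, 122)), (2, (6, 127)),
                                          (3, (11, 132))])
    def test_window_series(self, s, expect):
        assert slice_range_series(s, 3, 132, 5) == expect

    def test_equal_window_lengths(self):
        lens = {v - u for s in (1, 2, 3)
                for u, v in [slice_range_series(s, 3, 132, 5)]}
        assert len(lens) == 1

    def test_protocol_exceeding_template_is_infeasible(self):
        with pytest.raises(ProtocolInfeasibleError):
            slice_range_series(1, 2, 8, 10)


def _profile_from_curve(candidates, scores):
    recs = [CandidateRecord(a=a, s_rig=s, s_aff=s, s_w=s)
            for a, s in zip(candidates, scores)]
    return SimilarityProfile(records=recs, w=0.5)


class TestPooledPosition:
    def _two_profiles(self, step=5, peak=10, lo=1, hi=30):
        cand1 = list(range(lo, hi + 1))
        cand2 = [c + step for c in cand1]
        curve1 = [1.0 + (0.5 if c == peak else 0.0) for c in cand1]
        curve2 = [1.0 + (0.5 if c == peak + step else 0.0) for c in cand2]
        return (_profile_from_curve(cand1, curve1),
                _profile_from_curve(cand2, curve2))

    def test_single_profile_degenerates_to_argmax(self):
        prof = _profile_from_curve(range(1, 20), np.sin(np.arange(1, 20)))
        z_m, _ = pooled_position([prof], [1.0], step=5)
        assert z_m == prof.argmax()

    def test_aligned_peaks_pool_to_common_position(self):
        p1, p2 = self._two_profiles()
        z_m, curve = pooled_position([p1, p2], [0.5, 0.5], step=5)
        assert z_m == 10
        # exhaustive-scan oracle over the pooled curve
        assert z_m == max(curve, key=lambda c: (curve[c], -c))

    def test_zero_weight_excludes_a_slice(self):
        p1, p2 = self._two_profiles()
        # slice 2 gets a bogus huge peak elsewhere; with pi=(1,0) it cannot move z_m
        bogus = _profile_from_curve([c + 5 for c in range(1, 31)],
                                    [9.9 if c == 25 else 1.0
                                     for c in range(6, 36)])
        z_m, _ = pooled_position([p1, bogus], [1.0, 0.0], step=5)
        assert z_m == 10

    def test_one_hot_weights_match_shifted_single_curve(self):
        p1, p2 = self._two_profiles()
        _, curve = pooled_position([p1, p2], [0.0, 1.0], step=5)
        for c, score in curve.items():
            assert score == pytest.approx(p2.record(c + 5).s_w / 2.0)

    def test_failed_mass_renormalized(self):
        cand = [1, 2, 3]
        p1 = _profile_from_curve(cand, [1.0, 2.0, 1.0])
        recs = [CandidateRecord(a=a, status="failed") for a in cand]
        p2 = SimilarityProfile(records=recs, w=0.5)
        z_m, curve = pooled_position([p1, p2], [0.5, 0.5], step=0)
        assert z_m == 2
        assert curve[2] == pytest.approx(2.0 / 2.0)  # p1's score, full pi mass

    def test_all_failed_is_pooling_failure(self):
        recs = [CandidateRecord(a=a, status="failed") for a in (1, 2)]
        prof = SimilarityProfile(records=recs, w=0.5)
        with pytest.raises(PoolingFailureError):
            pooled_position([prof], [1.0], step=0)


class TestPropagatePositions:
    def test_series_from_first_position(self):
        z_s, clamped = propagate_positions(20, 3, step=5, N=60)
        assert z_s == [20, 25, 30]
        assert clamped == [False] * 3

    def test_overflow_clamped_and_flagged(self):
        z_s, clamped = propagate_positions(55, 3, step=5, N=60)
        assert z_s == [55, 60, 60]
        assert clamped == [False, False, True]

    def test_single_slice(self):
        assert propagate_positions(7, 1, step=5, N=60)[0] == [7]


class TestEstimateGamma:
    def test_exact_unit_line(self):
        gamma, r2 = estimate_gamma([20, 25, 30, 35, 40], 500.0, 100.0)
        assert gamma == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_shrinkage_slope(self):
        t = [20, 25.56, 31.1, 36.7, 42.2]
        gamma, _ = estimate_gamma(t, 500.0, 100.0)
        assert gamma == pytest.approx(0.9, abs=0.005)

    def test_decreasing_series_rejected(self):
        with pytest.raises(GammaEstimationError):
            estimate_gamma([40, 30, 20], 500.0, 100.0)

    def test_too_few_estimates(self):
        with pytest.raises(ContractError):
            estimate_gamma([10, 20], 500.0, 100.0)


class TestMultiSliceSpec:
    def test_gap_list_length_checked(self, atlas_small):
        slices = [atlas_small.template(a) for a in (4, 8, 12)]
        with pytest.raises(ContractError):
            MultiSliceSpec(slices=slices, e_r=20.0, d_r=[400.0])

    def test_pi_validation(self, atlas_small):
        slices = [atlas_small.template(a) for a in (4, 8)]
        with pytest.raises(ContractError):
            MultiSliceSpec(slices=slices, e_r=20.0, d_r=400.0, pi=[0.0, 0.0])

    def test_bad_gamma(self, atlas_small):
        slices = [atlas_small.template(a) for a in (4, 8)]
        with pytest.raises(ContractError):
            MultiSliceSpec(slices=slices, e_r=20.0, d_r=400.0, gamma=-1.0)


class TestLocateMulti:
    def test_noise_free_protocol_recovered_exactly(self, atlas60):
        slices, truth = make_multislice_set(
            atlas60, z_start=20, d_r=500.0, gamma_star=1.0, n=3,
            perturbations=[Transform2D.identity()] * 3)
        spec = MultiSliceSpec(slices=slices, e_r=20.0, d_r=500.0, gamma=1.0)
        res = locate_multi(spec, atlas60, w=0.5)
        assert res.z_s == truth.z_star
        assert res.z_m == truth.z_star[0]
        assert res.z_s == sorted(res.z_s)

    def test_gamma_auto_estimates_scaling(self, atlas60):
        slices, truth = make_multislice_set(
            atlas60, z_start=15, d_r=500.0, gamma_star=1.0, n=3,
            rotation_deg=(1.0, 3.0), translation_um=200.0, rng=5)
        spec = MultiSliceSpec(slices=slices, e_r=20.0, d_r=500.0, gamma="auto")
        res = locate_multi(spec, atlas60, w=0.5, with_labels=False)
        assert abs(res.gamma_used - 1.0) <= 0.05
        assert res.gamma_r2 is not None and res.gamma_r2 > 0.97
        assert res.z_s == truth.z_star


class TestDispatcher:
    def test_single_slice_dispatch(self, atlas_small):
        out = locate_slices([atlas_small.template(10)], atlas_small, w=0.5)
        assert isinstance(out, LocalizationResult)

    def test_multi_slice_dispatch(self, atlas_small):
        slices = [atlas_small.template(a) for a in (6, 10, 14)]
        spec = MultiSliceSpec(slices=slices, e_r=20.0, d_r=400.0, gamma=1.0)
        out = locate_slices(slices, atlas_small, spec=spec, w=0.5, s_star=3)
        assert isinstance(out, MultiSliceResult)

    def test_empty_input_is_contract_error(self, atlas_small):
        with pytest.raises(ContractError):
            locate_slices([], atlas_small)
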