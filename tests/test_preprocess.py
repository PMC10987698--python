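"""Drift correction, outlier screening and shot averaging."""

import numpy as np
import pytest

from dwmrs.basis import fid_to_spectrum, make_basis, spectrum_to_fid
from dwmrs.pipeline import PipelineConfig, run_pipeline
from dwmrs.preprocess import (
    average_shots,
    correct_drifts,
    preprocess_shots,
    reject_outliers,
)


@pytest.fixture(scope="module")
def clean_stack(small_protocol):
    """Eight identical metabolite-like shots with faint noise."""
    bs = make_basis(["NAA", "tCr", "Ins"], small_protocol, 6.0)
    spec = sum(bs.spectra.values())
    rng = np.random.default_rng(0)
    stack = np.tile(spec, (8, 1))
    stack += 0.02 * np.abs(spec).max() * (
        rng.standard_normal(stack.shape) + 1j * rng.standard_normal(stack.shape)
    ) / 50
    return stack


def _shift_shot(spec, protocol, freq_hz=0.0, phase_rad=0.0):
    fid = spectrum_to_fid(spec[None, :])[0]
    fid = fid * np.exp(2j * np.pi * freq_hz * protocol.time_axis + 1j * phase_rad)
    return fid_to_spectrum(fid[None, :])[0]


class TestCorrectDrifts:
    def test_clean_shots_report_zero_offsets(self, clean_stack, small_protocol):
        _, est = correct_drifts(clean_stack, small_protocol)
        assert np.all(np.abs(est.freq) < 0.1)
        assert np.all(np.abs(np.degrees(est.phase)) < 1.0)

    def test_recovers_injected_frequency_offset(self, clean_stack, small_protocol):
        stack = clean_stack.copy()
        stack[3] = _shift_shot(stack[3], small_protocol, freq_hz=2.0)
        _, est = correct_drifts(stack, small_protocol)
        assert est.freq[3] == pytest.approx(2.0, abs=0.2)

    def test_recovers_injected_phase(self, clean_stack, small_protocol):
        stack = clean_stack.copy()
        stack[5] = _shift_shot(stack[5], small_protocol, phase_rad=np.radians(30))
        corrected, est = correct_drifts(stack, small_protocol)
        assert np.degrees(est.phase[5]) == pytest.approx(30.0, abs=3.0)

    def test_idempotent(self, clean_stack, small_protocol):
        stack = clean_stack.copy()
        stack[2] = _shift_shot(stack[2], small_protocol, 3.0, np.radians(20))
        once, _ = correct_drifts(stack, small_protocol)
        _, second = correct_drifts(once, small_protocol)
        assert np.all(np.abs(second.freq) < 0.15)
        assert np.all(np.abs(np.degrees(second.phase)) < 1.5)

    def test_all_zero_shot_flagged_untouched(self, clean_stack, small_protocol):
        stack = clean_stack.copy()
        stack[1] = 0.0
        corrected, est = correct_drifts(stack, small_protocol)
        assert est.flagged[1]
        np.testing.assert_array_equal(corrected[1], 0.0)


class TestRejectOutliers:
    def test_manifest_drop_removed(self, clean_stack, small_protocol):
        stack = clean_stack.copy()
        stack[4] *= 0.40  # a 60% signal drop
        kept, report = reject_outliers(stack, small_protocol)
        assert report.removed == (4,)
        assert kept.shape[0] == stack.shape[0] - 1

    def test_equal_shots_none_removed(self, clean_stack, small_protocol):
        _, report = reject_outliers(clean_stack, small_protocol)
        assert report.removed == ()

    def test_exact_half_drop_retained(self, small_protocol):
        bs = make_basis(["NAA"], small_protocol, 6.0)
        stack = np.tile(bs.spectra["NAA"], (5, 1))
        stack[0] *= 0.5  # exactly at the boundary: strict inequality keeps it
        _, report = reject_outliers(stack, small_protocol)
        assert report.removed == ()
        stack[0] *= 0.999
        _, report = reject_outliers(stack, small_protocol)
        assert report.removed == (0,)

    def test_permutation_invariant(self, clean_stack, small_protocol):
        stack = clean_stack.copy()
        stack[0] *= 0.3
        perm = np.random.default_rng(3).permutation(stack.shape[0])
        _, r1 = reject_outliers(stack, small_protocol)
        _, r2 = reject_outliers(stack[perm], small_protocol)
        assert {int(perm[i]) for i in r2.removed} == set(r1.removed)

    def test_majority_drop_shifts_median_nothing_removed(self, clean_stack, small_protocol):
        # a majority of dropped shots drags the median down with it, so the
        # median-referenced criterion cannot (and should not) remove them
        stack = clean_stack.copy()
        stack[:5] *= 0.1
        _, report = reject_outliers(stack, small_protocol)
        assert report.removed == ()

    def test_needs_three_shots(self, clean_stack, small_protocol):
        with pytest.raises(ValueError):
            reject_outliers(clean_stack[:2], small_protocol)


class TestAverageShots:
    def test_identical_shots_average_to_themselves(self, clean_stack):
        mean, n = average_shots(np.tile(clean_stack[0], (6, 1)))
        np.testing.assert_allclose(mean, clean_stack[0])
        assert n == 6

    def test_clt_noise_scaling(self, small_protocol, rng):
        n_shots, n_rep = 16, 200
        sd = 1.0
        means = []
        for _ in range(n_rep):
            shots = sd * (
                rng.standard_normal((n_shots, 64)) + 1j * rng.standard_normal((n_shots, 64))
            )
            means.append(average_shots(shots)[0])
        observed = np.std(np.real(means))
        assert observed == pytest.approx(sd / np.sqrt(n_shots), rel=0.15)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            average_shots(np.empty((0, 8), dtype=complex))


class TestPipelineComposition:
    def test_chain_matches_manual_composition(self, clean_stack, small_protocol):
        stack = clean_stack.copy()
        stack[2] = _shift_shot(stack[2], small_protocol, 1.5, 0.2)
        stack[6] *= 0.3
        mean, n_eff, _, report = preprocess_shots(stack, small_protocol)
        corrected, _ = correct_drifts(stack, small_protocol)
        kept, report2 = reject_outliers(corrected, small_protocol)
        manual, n2 = average_shots(kept)
        assert report.removed == report2.removed
        assert n_eff == n2
        np.testing.assert_allclose(mean, manual)

    def test_artifact_correction_recovers_clean_quantification(self, small_protocol):
        """End to end: default-magnitude artifacts change the quantified
        amplitudes by <2% relative to an artifact-free run with the same
        noise realization."""
        from dwmrs.simulate import default_truth

        clean_truth = default_truth(seed=21).model_copy(
            update={"phase_drift": 0.0, "freq_drift": 0.0, "dropout_p": 0.0}
        )
        res_clean = run_pipeline(
            PipelineConfig(seed=21, protocol=small_protocol, n_animals=2,
                           truth=clean_truth)
        )
        res_artifact = run_pipeline(
            PipelineConfig(seed=21, protocol=small_protocol, n_animals=2,
                           truth=default_truth(seed=21))
        )
        a = res_clean.quant.set_index(["animal", "week", "b_value", "metabolite"])
        b = res_artifact.quant.set_index(["animal", "week", "b_value", "metabolite"])
        # compare at well-conditioned low/mid b-values, skipping cells where
        # a dropout shot was (correctly) rejected — there the two runs
        # average different shot subsets, so they differ by noise alone
        rejected = {(r["animal"], r["week"], r["b_value"]) for r in res_artifact.rejections}
        keep = [
            idx for idx in a.index
            if idx[2] <= 9.3 and (idx[0], idx[1], idx[2]) not in rejected
        ]
        rel = (b.loc[keep, "amplitude"] - a.loc[keep, "amplitude"]) / a.loc[keep, "amplitude"]
        assert len(keep) > 50
        assert np.abs(rel).max() < 0.02
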