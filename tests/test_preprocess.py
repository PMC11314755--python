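"""Baseline correction, normalisation, alignment and joint co-processing."""

import numpy as np
import pytest

from gcvoc.io import MalformedChromatogramError, read_chromatogram, write_chromatogram
from gcvoc.preprocess import (
    Chromatogram,
    DegenerateSampleError,
    PipelineOrderError,
    PreprocessConfig,
    align,
    baseline_correct,
    co_process,
    normalize,
)

T = np.arange(0, 2400.5, 0.5)


def raw(values, sample_id="s", batch=""):
    return Chromatogram(sample_id=sample_id, tick_s=0.5, values=np.asarray(values, float), batch=batch)


def gauss(centre, width=10.0, amp=1.0):
    return amp * np.exp(-0.5 * ((T - centre) / width) ** 2)


class TestIO:
    def test_read_simple_file(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("0.0 10\n0.5 12\n1.0 11\n")
        c = read_chromatogram(p)
        assert len(c.values) == 3 and c.tick_s == 0.5
        np.testing.assert_allclose(c.values, [10, 12, 11])

    def test_round_trip(self, tmp_path):
        v = 10.0 + gauss(600.0)
        p = tmp_path / "rt.txt"
        write_chromatogram(p, v, 0.5)
        c = read_chromatogram(p)
        np.testing.assert_allclose(c.values, v, rtol=1e-9)
        assert c.tick_s == 0.5

    def test_nonuniform_ticks_name_offending_row(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0.0 10\n0.5 12\n1.5 11\n")
        with pytest.raises(MalformedChromatogramError, match="row 3"):
            read_chromatogram(p)

    def test_negative_resistance_rejected(self, tmp_path):
        p = tmp_path / "neg.txt"
        p.write_text("0.0 10\n0.5 -1\n1.0 11\n")
        with pytest.raises(MalformedChromatogramError, match="non-positive"):
            read_chromatogram(p)


class TestBaselineCorrect:
    def test_linear_ramp_removed(self):
        c = raw(5.0 + 0.002 * T)
        out = baseline_correct(c)
        assert out.values.max() < 0.01 * (c.values.max() - c.values.min())
        assert out.baseline_corrected

    def test_peak_apex_preserved_on_zero_baseline(self):
        c = raw(1e-6 + gauss(600.0, amp=2.0))
        out = baseline_correct(c)
        assert out.values.max() == pytest.approx(2.0, rel=0.02)

    def test_constant_series_becomes_zero(self):
        out = baseline_correct(raw(np.full(4801, 7.0)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-6)

    def test_output_floored_at_zero(self):
        rng = np.random.default_rng(0)
        out = baseline_correct(raw(10 + 0.001 * T + rng.normal(0, 0.1, len(T))))
        assert np.all(out.values >= 0)

    def test_double_correction_rejected(self):
        out = baseline_correct(raw(10 + 0.001 * T))
        with pytest.raises(PipelineOrderError):
            baseline_correct(out)

    def test_short_series_rejected(self):
        with pytest.raises(DegenerateSampleError, match="shorter"):
            baseline_correct(raw([1.0, 2.0, 3.0]))


class TestNormalize:
    def test_values_divided_by_max(self):
        c = raw([2.0, 4.0, 8.0] + [1.0] * 7).copy_with(baseline_corrected=True)
        out = normalize(c)
        np.testing.assert_allclose(out.values[:3], [0.25, 0.5, 1.0])
        assert out.values.max() == 1.0

    def test_idempotent(self):
        c = raw(gauss(600.0) + 1e-9).copy_with(baseline_corrected=True)
        once = normalize(c)
        twice = normalize(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_scale_invariance(self):
        base = gauss(600.0) + 0.01
        outs = []
        for k in (0.5, 1.0, 37.0):
            c = raw(k * base).copy_with(baseline_corrected=True)
            outs.append(normalize(c).values)
        np.testing.assert_allclose(outs[0], outs[1], rtol=1e-12)
        np.testing.assert_allclose(outs[0], outs[2], rtol=1e-12)

    def test_argmax_position_unchanged(self):
        c = raw(gauss(600.0) + 0.3 * gauss(900.0)).copy_with(baseline_corrected=True)
        assert np.argmax(normalize(c).values) == np.argmax(c.values)

    def test_requires_baseline_first(self):
        with pytest.raises(PipelineOrderError):
            normalize(raw(gauss(600.0)))

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            normalize(raw(np.zeros(100) + 0.0).copy_with(baseline_corrected=True))


def processed(values, sample_id="s", batch=""):
    return Chromatogram(
        sample_id=sample_id, tick_s=0.5, values=np.asarray(values, float), batch=batch,
        baseline_corrected=True, normalised=True,
    )


class TestAlign:
    def test_shifted_copy_realigned_within_one_tick(self):
        v = gauss(600.0)
        shifted = np.roll(v, 5)
        out = align([processed(v, "a"), processed(shifted, "b")])
        apexes = [np.argmax(c.values) for c in out]
        assert abs(apexes[0] - apexes[1]) <= 1

    def test_identical_traces_zero_shift(self):
        v = gauss(600.0)
        out = align([processed(v, "a"), processed(v, "b")])
        assert all(c.applied_shift_ticks == 0 for c in out)
        for c in out:
            np.testing.assert_array_equal(c.values, v)

    def test_planted_jitter_apex_sd_reduced(self):
        rng = np.random.default_rng(4)
        samples = [processed(gauss(600.0 + rng.normal(0, 2.0)), f"s{i}") for i in range(12)]
        pre_sd = np.std([np.argmax(c.values) for c in samples])
        out = align(samples)
        post_sd = np.std([np.argmax(c.values) for c in out])
        assert post_sd <= pre_sd

    @pytest.mark.parametrize("seed", range(5))
    def test_alignment_never_increases_apex_sd(self, seed):
        rng = np.random.default_rng(seed)
        samples = [
            processed(gauss(600.0 + rng.normal(0, 3.0)) + 0.3 * gauss(1200.0 + rng.normal(0, 3.0)), f"s{i}")
            for i in range(8)
        ]
        pre = np.std([np.argmax(c.values) for c in samples])
        post = np.std([np.argmax(c.values) for c in align(samples)])
        assert post <= pre + 1e-9

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="truncate"):
            align([processed(gauss(600)), processed(gauss(600)[:-10], "b")])

    def test_requires_normalised(self):
        with pytest.raises(PipelineOrderError):
            align([raw(gauss(600.0)).copy_with(baseline_corrected=True)])

    def test_output_lengths_preserved(self):
        v = gauss(600.0)
        out = align([processed(v, "a"), processed(np.roll(v, 30), "b")], max_shift_s=30.0)
        assert all(len(c.values) == len(v) for c in out)


class TestCoProcess:
    def _cohort(self, jitter=0.0, n=4, seed=0):
        rng = np.random.default_rng(seed)
        tr = [
            raw(10 + 0.001 * T + 3 * gauss(600 + rng.normal(0, jitter)), f"t{i}", "training")
            for i in range(n)
        ]
        va = [
            raw(10 + 0.001 * T + 3 * gauss(600 + rng.normal(0, jitter)), f"v{i}", "validation")
            for i in range(n)
        ]
        return tr, va

    def test_pooled_equals_training_only_without_jitter(self):
        tr, va = self._cohort(jitter=0.0)
        pooled_t, _ = co_process(tr, va)
        alone_t, _ = co_process([c.copy_with() for c in tr], [])
        for a, b in zip(pooled_t, alone_t):
            np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_training_output_independent_of_validation_content(self):
        tr, va = self._cohort(jitter=0.0)
        out1, _ = co_process([c.copy_with() for c in tr], [c.copy_with() for c in va])
        va_perturbed = [c.copy_with(values=c.values * 1.7) for c in va]
        out2, _ = co_process([c.copy_with() for c in tr], va_perturbed)
        for a, b in zip(out1, out2):
            np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_empty_validation_ok(self):
        tr, _ = self._cohort()
        out_t, out_v = co_process(tr, [])
        assert len(out_t) == len(tr) and out_v == []

    def test_overlapping_ids_rejected(self):
        tr, va = self._cohort()
        va[0] = va[0].copy_with(sample_id=tr[0].sample_id)
        with pytest.raises(ValueError, match="overlapping"):
            co_process(tr, va)

    def test_partition_labels_preserved(self):
        tr, va = self._cohort()
        out_t, out_v = co_process(tr, va)
        assert {c.batch for c in out_t} == {"training"}
        assert {c.batch for c in out_v} == {"validation"}
        assert all(c.aligned and c.normalised and c.baseline_corrected for c in out_t + out_v)
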