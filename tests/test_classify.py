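"""Classification rules: per-class calls, strict thresholds, matrix-level invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from patterngene import core_stats as cs
from patterngene.classify import (
    PatternThresholds,
    call_housekeeping,
    call_repressed,
    call_selective,
    call_specific,
    classify_matrix,
    classify_profile,
)
from patterngene.core_stats import ProfileValidationError

DEFAULTS = PatternThresholds()

profiles = st.lists(
    st.floats(min_value=0.0, max_value=1e6, allow_nan=False), min_size=2, max_size=50
).filter(lambda xs: any(v > 0 for v in xs))


class TestSpecific:
    def test_spike_called_on_its_sample(self):
        (call,) = call_specific((0, 0, 5, 0), DEFAULTS)
        assert call.samples == ("S3",) and call.spm_values == (1.0,)

    def test_uniform_profile_not_called(self):
        assert call_specific((1, 1, 1, 1), DEFAULTS) == []

    def test_dominant_but_not_exclusive_sample_called(self):
        (call,) = call_specific((9.5, 1, 1, 1), DEFAULTS)
        assert call.samples == ("S1",)
        assert call.spm_values[0] == pytest.approx(9.5 / np.sqrt(90.25 + 3), abs=1e-9)

    def test_threshold_is_strict_at_exact_spm(self):
        # (27, 11, 7, 1) has norm exactly 30, so SPM_1 is exactly 0.9
        assert cs.spm((27, 11, 7, 1), 0) == 0.9
        assert call_specific((27, 11, 7, 1), DEFAULTS) == []


class TestHousekeeping:
    def test_uniform_profile_called_with_all_samples(self):
        (call,) = call_housekeeping((2, 2, 2, 2, 2), DEFAULTS)
        assert call.scores["DPM"] == pytest.approx(0.0, abs=1e-12)
        assert call.samples == ("S1", "S2", "S3", "S4", "S5")

    def test_spike_not_called(self):
        assert call_housekeeping((0, 0, 5, 0), DEFAULTS) == []

    def test_moderate_dispersion_passes_default(self):
        (call,) = call_housekeeping((3, 4), DEFAULTS)
        assert call.scores["DPM"] == pytest.approx(0.2, abs=1e-12)

    def test_threshold_is_strict_at_exact_dpm(self):
        t = DEFAULTS.replace(housekeeping_dpm_max=cs.dpm((3, 4)))
        assert call_housekeeping((3, 4), t) == []

    def test_optional_minimum_expression_filter(self):
        assert call_housekeeping((2, 2, 2, 2, 2), DEFAULTS, min_mean_expression=10.0) == []
        assert len(call_housekeeping((2, 2, 2, 2, 2), DEFAULTS, min_mean_expression=1.0)) == 1


class TestSelective:
    def test_two_sample_enrichment(self):
        (call,) = call_selective((5, 5, 0, 0, 0, 0, 0), DEFAULTS)
        assert call.k == 2 and set(call.samples) == {"S1", "S2"}
        assert call.scores["CTM"] == pytest.approx(1.0, abs=1e-12)

    def test_uniform_ten_samples_not_called(self):
        # best top-6 CTM is sqrt(6/10) ~ 0.775 < 0.9
        assert call_selective([3.0] * 10, DEFAULTS) == []

    def test_single_spike_fails_second_sample_spm(self):
        assert call_selective((0, 0, 5, 0), DEFAULTS) == []

    def test_smallest_qualifying_k_reported_and_all_k_recoverable(self):
        # top-3 CTM = sqrt(8427/9976) ~ 0.919 and top-4 CTM ~ 0.984 both pass,
        # with all four top SPMs above 0.3; the 5th SPM (~0.09) stops k=5
        x = (53, 53, 53, 35, 9, 9, 9, 9)
        (call,) = call_selective(x, DEFAULTS)
        assert call.k == 3
        all_k = call_selective(x, DEFAULTS, report_all_k=True)
        assert [c.k for c in all_k] == [3, 4]

    def test_threshold_is_strict_at_exact_ctm(self):
        x = (5, 5, 1, 1, 1, 1, 1)
        (call,) = call_selective(x, DEFAULTS)
        t = DEFAULTS.replace(selective_ctm_min=call.scores["CTM"])
        assert call_selective(x, t) == []

    def test_per_sample_spm_clause_is_strict(self):
        x = (5, 5, 1, 1, 1, 1, 1)
        s = cs.spm_profile(x)
        t = DEFAULTS.replace(selective_spm_min=float(s[0]))
        assert call_selective(x, t) == []


class TestRepressed:
    def test_single_silent_sample(self):
        (call,) = call_repressed((0, 10, 10, 10, 10), DEFAULTS)
        assert call.k == 1 and call.samples == ("S1",)
        assert call.scores["RPM"] == 0.0

    def test_uniform_profile_not_called(self):
        assert call_repressed([4.0] * 8, DEFAULTS) == []

    def test_low_but_nonzero_sample_at_k1_boundary(self):
        # SPM_1 = 1/sqrt(301) ~ 0.058 < 0.1 and RPM = 0.1 < 0.2: call IS emitted
        (call,) = call_repressed((1, 10, 10, 10), DEFAULTS)
        assert call.k == 1 and call.samples == ("S1",)
        assert call.scores["RPM"] == pytest.approx(0.1, abs=1e-12)

    def test_threshold_is_strict_at_exact_rpm(self):
        t = DEFAULTS.replace(repressed_rpm_max=cs.rpm((2, 40, 40), [0]),
                             repressed_spm_max=0.2)
        assert call_repressed((2, 40, 40), t) == []

    def test_spm_clause_strict_at_exact_value(self):
        x = (1, 10, 10, 10)
        t = DEFAULTS.replace(repressed_spm_max=cs.spm(x, 0))
        assert call_repressed(x, t) == []

    def test_undefined_rpm_skips_k_until_zeros_absorbed(self):
        # two zero samples: k=1 leaves a zero in the expression group (RPM
        # undefined) but k=2 absorbs both and qualifies
        (call,) = call_repressed((0, 0, 10, 10, 10, 10), DEFAULTS)
        assert call.k == 2 and set(call.samples) == {"S1", "S2"}


class TestClassifyMatrix:
    def test_spike_gene_enumeration(self):
        # exhaustive rule check for (0,0,5,0): specific on S3; housekeeping
        # fails (DPM 1); selective fails (second SPM 0); repressed qualifies
        # only at k=3 where the expression group is the positive sample
        calls = classify_profile((0, 0, 5, 0), DEFAULTS)
        assert [(c.pattern_class, c.k) for c in calls] == [("specific", 1), ("repressed", 3)]

    def test_all_zero_gene_skipped_with_log(self, caplog):
        m = pd.DataFrame([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]], index=["Z", "G"],
                         columns=["a", "b", "c"])
        with caplog.at_level("INFO", logger="patterngene.classify"):
            calls = classify_matrix(m)
        assert all(c.gene_id != "Z" for c in calls)
        assert any("all-zero" in r.message for r in caplog.records)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ProfileValidationError):
            classify_matrix(pd.DataFrame())

    def test_row_order_and_rescaling_invariance(self, rng):
        m = pd.DataFrame(
            rng.gamma(1.0, 100.0, size=(20, 8)),
            index=[f"G{i}" for i in range(20)],
            columns=[f"S{j}" for j in range(8)],
        )
        base = {(c.gene_id, c.pattern_class, c.samples, c.k) for c in classify_matrix(m)}
        shuffled = m.sample(frac=1.0, random_state=1)
        scaled = shuffled.mul(rng.uniform(0.1, 10.0, size=20), axis=0)
        again = {(c.gene_id, c.pattern_class, c.samples, c.k) for c in classify_matrix(scaled)}
        assert base == again

    def test_deterministic_output_order(self, rng):
        m = pd.DataFrame(
            rng.gamma(1.0, 100.0, size=(30, 10)),
            index=[f"G{i:02d}" for i in range(30)],
            columns=[f"S{j}" for j in range(10)],
        )
        a = classify_matrix(m)
        b = classify_matrix(m.copy())
        assert [(c.gene_id, c.pattern_class, c.k) for c in a] == [
            (c.gene_id, c.pattern_class, c.k) for c in b
        ]


@settings(derandomize=True, max_examples=300)
@given(profiles)
def test_specific_and_housekeeping_mutually_exclusive_under_defaults(xs):
    """A profile concentrated enough for a specific call (SPM > 0.9) is far
    too dispersed on the SPM sphere to pass DPM < 0.3."""
    specific = call_specific(xs, DEFAULTS)
    housekeeping = call_housekeeping(xs, DEFAULTS)
    assert not (specific and housekeeping)


@settings(derandomize=True, max_examples=300)
@given(profiles)
def test_at_most_one_specific_call_under_defaults(xs):
    """Squared SPM values sum to 1, so only one can exceed 0.9 > sqrt(0.5)."""
    assert len(call_specific(xs, DEFAULTS)) <= 1
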