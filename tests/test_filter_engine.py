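"""Filter rule evaluation, presets, sequence post-filtering, consensus."""

import dataclasses

import numpy as np
import pytest

from zcbat import synthetic as syn
from zcbat.filter_engine import (
    FilterSpec,
    Range,
    SyntheticLineSpec,
    apply_filter,
    consensus,
    load_preset,
    pulse_passes,
    sequence_postfilter,
    synthetic_line_value,
)
from zcbat.pulse_metrics import extract_features
from zcbat.zc_data import CallLibrary

from conftest import log_linear_pulse, make_pulse


WEST_LINE_1 = SyntheticLineSpec(
    x_var="dur_ms", y_var="sweep_khz", p1=(6, 0), p2=(0, 3.5), min=0, max=60,
)


class TestPresets:
    def test_west2_settings(self):
        s = load_preset("WEST2")
        assert s.duration_ms == Range(2, 30)
        assert s.pmc_pct == Range(8, 9999)
        assert s.min_calls == 5 and s.time_for_calls_s == 5
        assert s.smoothness_max_pct == 10
        assert s.s1_oct_s == Range(30, 9999)
        assert len(s.synthetic_lines) == 2

    def test_bcid_settings(self):
        s = load_preset("BCID")
        assert s.fmax_khz == Range(17, 120)
        assert s.time_for_calls_s == 15
        assert s.join_fragments_us == 2000
        assert s.ignore_fragments_us == 2200
        assert s.body_over_us == 2400

    def test_bm_settings(self):
        s = load_preset("BM")
        assert s.smoothness_max_pct == 15
        assert s.body_over_us == 240
        assert s.synthetic_lines == ()
        assert s.fc_khz is None  # no characteristic-frequency bound

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="BM.*BCID.*WEST1.*WEST2"):
            load_preset("nope")


class TestSyntheticLine:
    @pytest.mark.parametrize("dur,sweep,expected", [
        (6.0, 0.0, 0.0),      # first anchor: on the line
        (0.0, 3.5, 0.0),      # second anchor
        (3.0, 10.0, 8.25),    # 10 - 1.75
    ])
    def test_values(self, dur, sweep, expected):
        v = synthetic_line_value({"dur_ms": dur, "sweep_khz": sweep}, WEST_LINE_1)
        assert v == pytest.approx(expected)

    def test_vertical_line_rejected(self):
        with pytest.raises(ValueError):
            SyntheticLineSpec("dur_ms", "sweep_khz", (1, 0), (1, 5), 0, 10)


class TestPulsePasses:
    def test_short_pulse_fails_west2_duration(self):
        p = log_linear_pulse(60, 45, 1.5, n_dots=9)
        spec = load_preset("WEST2")
        feats = extract_features(p, spec.body_over_us)
        ok, violated = pulse_passes(p, feats, spec)
        assert not ok and "duration" in violated

    def test_fc_within_west1_range_passes_fc_rule(self):
        p = log_linear_pulse(60, 44, 4.0, n_dots=21)
        spec = load_preset("WEST1")
        feats = extract_features(p, spec.body_over_us)
        _, violated = pulse_passes(p, feats, spec)
        assert "fc" not in violated

    def test_max_change_violation(self):
        p = make_pulse([0, 200, 400], [50e3, 45e3, 44e3])
        spec = FilterSpec(max_change_up_khz=2, max_change_down_khz=4, body_over_us=100)
        feats = extract_features(p, 100)
        ok, violated = pulse_passes(p, feats, spec)
        assert not ok and violated == ["max_change"]

    def test_high_start_requires_fmax_at_first_dot(self):
        up_then_down = make_pulse([0, 200, 400, 600], [40e3, 50e3, 45e3, 42e3])
        spec = FilterSpec(high_start=True, body_over_us=100)
        feats = extract_features(up_then_down, 100)
        ok, violated = pulse_passes(up_then_down, feats, spec)
        assert not ok and "high_start" in violated


class TestSequencePostfilter:
    def _train(self, n, step_ms=800.0):
        return [
            make_pulse([int(i * step_ms * 1e3), int(i * step_ms * 1e3) + 3000],
                       [45e3, 40e3])
            for i in range(n)
        ]

    def test_five_calls_within_window_retained(self):
        spec = load_preset("WEST2")
        kept = sequence_postfilter(self._train(5), spec)
        assert len(kept) == 5

    def test_four_calls_rejected(self):
        spec = load_preset("WEST2")
        assert sequence_postfilter(self._train(4), spec) == ()

    def test_reject_gap_removes_both_pulses(self):
        spec = FilterSpec(reject_gap_ms=2, body_over_us=100)
        a = make_pulse([0, 1000], [45e3, 40e3])
        b = make_pulse([2000, 3000], [45e3, 40e3])  # 1 ms after a ends
        assert sequence_postfilter([a, b], spec) == ()

    def test_min_time_between_calls_thins_counting(self):
        # 9 pulses 25 ms apart: only every other one is countable at 50 ms,
        # leaving 5 countable pulses -> retained
        spec = FilterSpec(min_calls=5, time_for_calls_s=5,
                          min_time_between_calls_ms=50, body_over_us=100)
        kept = sequence_postfilter(self._train(9, step_ms=25.0), spec)
        assert len(kept) == 9
        # with only 8 pulses there are 4 countable -> rejected
        assert sequence_postfilter(self._train(8, step_ms=25.0), spec) == ()


def _bat_library(rng, n_species=2, n_seq=4):
    presets = syn.species_presets()
    keys = ("MYSO", "EPFU", "LABO")[:n_species]
    recipe = syn.LibraryRecipe(
        species={k: presets[k] for k in keys}, sequences_per_species=n_seq,
    )
    lib, _ = syn.synth_library(recipe, rng)
    return lib


class TestApplyFilter:
    def test_clean_bat_library_fully_retained_by_west1(self, rng):
        lib = _bat_library(rng)
        res = apply_filter(lib, load_preset("WEST1"))
        assert res.n_sequences == len(lib.files)

    def test_empty_library_empty_result(self):
        lib = CallLibrary(name="x", files={}, labels={})
        res = apply_filter(lib, load_preset("WEST2"))
        assert res.n_sequences == 0 and res.n_pulses == 0

    def test_deterministic(self, rng):
        lib = _bat_library(rng, n_species=1, n_seq=2)
        spec = load_preset("WEST2")
        r1 = apply_filter(lib, spec)
        r2 = apply_filter(lib, spec)
        assert r1.pulse_keys() == r2.pulse_keys()
        assert r1.features.equals(r2.features)

    def test_no_rules_retains_every_segmentable_pulse(self, rng):
        lib = _bat_library(rng, n_species=1, n_seq=2)
        bare = FilterSpec(name="bare", body_over_us=1000)
        res = apply_filter(lib, bare)
        expected = sum(
            len(ps) for ps in lib.segmented(bare.segmentation()).values()
        )
        assert res.n_pulses == expected

    def test_adding_any_rule_never_increases_counts(self, rng):
        lib = _bat_library(rng)
        base = load_preset("WEST1")
        baseline = apply_filter(lib, base)
        tighter = {
            "smoothness_max_pct": 5,
            "duration_ms": Range(3, 30),
            "fc_khz": Range(40, 60),
            "pmc_pct": Range(50, 9999),
            "min_time_between_calls_ms": 200,
        }
        for field, value in tighter.items():
            spec = dataclasses.replace(base, **{field: value})
            res = apply_filter(lib, spec)
            assert res.n_pulses <= baseline.n_pulses
            assert res.n_sequences <= baseline.n_sequences


class TestConsensus:
    def test_single_result_is_identity(self, rng):
        lib = _bat_library(rng, n_species=1, n_seq=2)
        r = apply_filter(lib, load_preset("WEST1"))
        c = consensus([r])
        assert c.pulse_keys() == r.pulse_keys()
        assert c.n_sequences == r.n_sequences

    def test_disjoint_results_empty_consensus(self, rng):
        lib = _bat_library(rng, n_species=1, n_seq=2)
        short = dataclasses.replace(
            load_preset("WEST1"), name="short", duration_ms=Range(0.1, 2.0),
        )
        long = dataclasses.replace(
            load_preset("WEST1"), name="long", duration_ms=Range(4.0, 30.0),
        )
        c = consensus([apply_filter(lib, short), apply_filter(lib, long)])
        assert c.n_pulses == 0

    def test_mixed_library_errors(self, rng):
        a = _bat_library(rng, n_species=1, n_seq=2)
        b = CallLibrary(name="other", files={}, labels={})
        ra = apply_filter(a, load_preset("WEST1"))
        rb = apply_filter(b, load_preset("WEST1"))
        with pytest.raises(ValueError, match="different libraries"):
            consensus([ra, rb])

    def test_consensus_is_intersection_and_below_min(self, rng):
        lib = _bat_library(rng, n_species=2, n_seq=3)
        results = [apply_filter(lib, load_preset(n)) for n in
                   ("BM", "BCID", "WEST1", "WEST2")]
        c = consensus(results)
        keys = [r.pulse_keys() for r in results]
        assert c.pulse_keys() == set.intersection(*keys)
        assert c.n_pulses <= min(r.n_pulses for r in results)
        assert c.n_sequences <= min(r.n_sequences for r in results)
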