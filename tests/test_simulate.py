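"""Synthetic library generator: mutation load, noise calibration, determinism."""

import numpy as np
import pytest

from mutsplice.hill import HillParams, hill_curve
from mutsplice.kinetics import ISOFORMS
from mutsplice.simulate import (
    GroundTruth,
    Mutation,
    calibrate_noise,
    default_reference_sequence,
    default_wt_rates,
    expected_frequencies,
    generate_dose_response,
    generate_library,
    library_from_frame,
    library_to_frame,
    simulate_counts,
)


class TestLibrary:
    def test_mean_mutation_load_matches_request(self):
        lib, _ = generate_library(5200, 591, 3.6, seed=0)
        counts = [len(v.mutations) for v in lib if not v.is_wt]
        assert abs(np.mean(counts) - 3.6) < 0.1
        assert min(counts) >= 1

    def test_positions_are_densely_covered(self):
        lib, _ = generate_library(5200, 10, 3.6, seed=0)
        per_position = np.zeros(708)
        for v in lib:
            for m in v.mutations:
                per_position[m.position] += 1
        assert np.mean(per_position[1:] >= 10) >= 0.97

    def test_seed_determinism_and_barcode_uniqueness(self):
        a, ta = generate_library(300, 30, 3.6, seed=5)
        b, tb = generate_library(300, 30, 3.6, seed=5)
        assert [v.barcode for v in a] == [v.barcode for v in b]
        assert [v.labels for v in a] == [v.labels for v in b]
        assert {l: tuple(e) for l, e in ta.effect.items()} == \
               {l: tuple(e) for l, e in tb.effect.items()}
        barcodes = [v.barcode for v in a]
        assert len(set(barcodes)) == len(barcodes)
        assert all(len(bc) == 15 for bc in barcodes)

    def test_distinct_seeds_give_distinct_barcode_sets(self):
        a, _ = generate_library(100, 10, 3.6, seed=1)
        b, _ = generate_library(100, 10, 3.6, seed=2)
        assert {v.barcode for v in a} != {v.barcode for v in b}

    def test_wt_flag_matches_empty_mutation_list(self):
        lib, _ = generate_library(50, 20, 3.6, seed=3)
        assert sum(v.is_wt for v in lib) == 20
        for v in lib:
            assert v.is_wt == (len(v.mutations) == 0)

    def test_library_tsv_round_trip(self):
        lib, _ = generate_library(20, 5, 3.6, seed=9)
        back = library_from_frame(library_to_frame(lib))
        assert [(v.barcode, v.labels) for v in back] == \
               [(v.barcode, v.labels) for v in lib]

    def test_mutation_label_round_trip(self):
        m = Mutation(305, "G", "A")
        assert m.label == "G305A"
        assert Mutation.from_label("G305A") == m


class TestCounts:
    def test_rows_sum_to_depth(self):
        lib, truth = generate_library(50, 10, 3.6, seed=4)
        counts = simulate_counts(lib, truth, depth=500, overdispersion=0.004,
                                 n_replicates=2, seed=1)
        assert (counts[list(ISOFORMS)].sum(axis=1) == 500).all()
        assert set(counts["replicate"]) == {1, 2}

    def test_null_truth_reproduces_wt_frequencies(self):
        lib, _ = generate_library(400, 100, 3.6, seed=6, effect_fraction=0.0)
        truth = GroundTruth(effect={l: np.zeros(5) for v in lib for l in v.labels})
        counts = simulate_counts(lib, truth, depth=1000, overdispersion=0.0,
                                 n_replicates=1, seed=2)
        incl = counts["incl"] / 1000
        se = incl.std() / np.sqrt(len(incl))
        assert abs(incl.mean() - 0.80) < 3 * se + 1e-3

    def test_planted_skip_effect_scales_ratio_by_e(self):
        lib, _ = generate_library(1, 1, 3.6, seed=8)
        single = [v for v in lib if not v.is_wt][0]
        # keep only its first mutation to make a clean single-mutation minigene
        from mutsplice.simulate import MinigeneVariant
        single = MinigeneVariant(single.barcode, single.mutations[:1])
        truth = GroundTruth(effect={single.labels[0]: np.array([1.0, 0, 0, 0, 0])})
        p = expected_frequencies(single, truth, default_wt_rates())
        wt = default_wt_rates().K / default_wt_rates().K.sum()
        assert p[1] / p[0] == pytest.approx(np.e * wt[1] / wt[0], rel=1e-9)

    def test_missing_truth_label_raises_with_names(self):
        lib, truth = generate_library(5, 2, 3.6, seed=10)
        missing = lib[0].labels[0]
        del truth.effect[missing]
        with pytest.raises(KeyError, match=missing):
            simulate_counts(lib, truth, depth=500, seed=0)

    def test_kd_condition_shifts_skip_ratio(self):
        lib, truth = generate_library(5, 200, 3.6, seed=12,
                                      kd_global=float(np.log(2.0)),
                                      effect_fraction=0.0)
        wt = [v for v in lib if v.is_wt]
        p_ctrl = expected_frequencies(wt[0], truth, default_wt_rates(), "ctrl")
        p_kd = expected_frequencies(wt[0], truth, default_wt_rates(), "kd")
        assert (p_kd[1] / p_kd[0]) / (p_ctrl[1] / p_ctrl[0]) == pytest.approx(2.0)


class TestNoiseCalibration:
    def test_calibrated_wt_sd_hits_three_percent(self, rho_default):
        lib, _ = generate_library(5, 591, 3.6, seed=20, effect_fraction=0.0)
        truth = GroundTruth(effect={l: np.zeros(5) for v in lib for l in v.labels})
        counts = simulate_counts(lib, truth, depth=1000,
                                 overdispersion=rho_default,
                                 n_replicates=1, seed=21)
        wt_rows = counts[counts["barcode"].isin(
            {v.barcode for v in lib if v.is_wt})]
        sd = (wt_rows["incl"] / 1000).std()
        assert 0.027 <= sd <= 0.033

    def test_unreachable_target_reports_multinomial_floor(self):
        with pytest.raises(ValueError, match="floor"):
            calibrate_noise(target_wt_sd=0.001, depth=200)

    def test_more_depth_never_increases_wt_sd(self):
        def sd_at(depth):
            rng = np.random.default_rng(30)
            p = default_wt_rates().K / default_wt_rates().K.sum()
            gam = rng.gamma(np.tile(p / 0.005, (2000, 1)))
            probs = gam / gam.sum(axis=1, keepdims=True)
            counts = rng.multinomial(depth, probs)
            return (counts[:, 0] / depth).std()

        assert sd_at(2000) <= sd_at(1000) + 0.002


class TestDoseResponse:
    PARAMS = HillParams(-0.11, 0.36, 0.93, 17.4)

    def test_zero_sigma_points_lie_on_curve(self):
        x = np.geomspace(0.3, 2.0, 11)
        pts = generate_dose_response(self.PARAMS, x, sigma=0.0, seed=0)
        np.testing.assert_allclose([p.y for p in pts],
                                   hill_curve(x, self.PARAMS), atol=1e-12)

    def test_midpoint_at_ec50(self):
        y = hill_curve(self.PARAMS.ec50, self.PARAMS)
        assert y == pytest.approx((self.PARAMS.y_max + self.PARAMS.y_min) / 2)

    def test_reference_sequence_is_deterministic(self):
        assert default_reference_sequence() == default_reference_sequence()
        assert len(default_reference_sequence()) == 707
        assert set(default_reference_sequence()) <= set("ACGT")
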