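"""Knockdown synergy: recovery, null calibration, filters, Fig-style contrast."""

import numpy as np
import pandas as pd
import pytest

from mutsplice.inference import predict_frequencies_batch
from mutsplice.synergy import (
    SPLICE_SITE_POSITIONS,
    call_synergistic,
    compute_synergy,
    global_kd_effect,
    wt_kd_response,
)


@pytest.fixture(scope="module")
def synergy_records(kd_screen):
    rec = compute_synergy(kd_screen["fit_ctrl"], kd_screen["fit_kd"],
                          kd_screen["wt_response"])
    return rec


class TestGlobalKd:
    def test_planted_fold_recovered(self, kd_screen):
        fold = global_kd_effect(kd_screen["wt_response"])
        assert 2.3 <= fold <= 2.5

    def test_no_knockdown_gives_unit_fold(self, ctrl_screen, rho_default):
        from mutsplice.quantify import compute_frequencies
        from mutsplice.simulate import simulate_counts

        lib, truth = ctrl_screen["library"], ctrl_screen["truth"]
        # 'kd' condition with kd_global = 0 equals ctrl in expectation
        counts = simulate_counts(lib, truth, depth=1000,
                                 overdispersion=rho_default, n_replicates=3,
                                 condition="kd", seed=555)
        fk, _ = compute_frequencies(counts)
        wt_resp = wt_kd_response(ctrl_screen["freqs"], fk, lib)
        assert global_kd_effect(wt_resp) == pytest.approx(1.0, abs=0.05)


class TestSynergyRecovery:
    def test_planted_synergies_dominate_ranking(self, kd_screen, synergy_records):
        sk = synergy_records[synergy_records["ratio"] == "skip_vs_incl"]
        top = sk.reindex(sk["z_stouffer"].abs().sort_values(ascending=False).index)
        planted_big = {l for l, s in kd_screen["truth"].synergy.items()
                       if abs(s) > 0.5}
        hits = sum(l in planted_big for l in top["label"].head(20))
        assert hits >= 15

    def test_strongest_planted_synergy_ranks_first(self, kd_screen, synergy_records):
        sk = synergy_records[synergy_records["ratio"] == "skip_vs_incl"]
        top5 = set(sk.reindex(sk["z_stouffer"].abs()
                              .sort_values(ascending=False).index)["label"].head(5))
        strongest = max(kd_screen["truth"].synergy,
                        key=lambda l: abs(kd_screen["truth"].synergy[l]))
        assert strongest in top5

    def test_call_precision_on_planted_synergy(self, kd_screen, synergy_records):
        calls = call_synergistic(synergy_records, kd_screen["fit_ctrl"])
        sk = calls[calls["ratio"] == "skip_vs_incl"]
        assert len(sk) > 10
        planted = set(kd_screen["truth"].synergy)
        assert np.mean([l in planted for l in sk["label"]]) >= 0.7


class TestNullCalibration:
    def test_no_planted_synergy_controls_calls(self, rho_default):
        from mutsplice.inference import fit_effects
        from mutsplice.quantify import compute_frequencies
        from mutsplice.simulate import generate_library, simulate_counts

        lib, truth = generate_library(5200, 591, 3.6, seed=808,
                                      kd_global=float(np.log(2.4)),
                                      synergy_fraction=0.0)
        fc, _ = compute_frequencies(simulate_counts(
            lib, truth, depth=1000, overdispersion=rho_default,
            n_replicates=3, condition="ctrl", seed=809))
        fk, _ = compute_frequencies(simulate_counts(
            lib, truth, depth=1000, overdispersion=rho_default,
            n_replicates=3, condition="kd", seed=810))
        fit_c = fit_effects(lib, fc)
        fit_k = fit_effects(lib, fk)
        wt_resp = wt_kd_response(fc, fk, lib)
        rec = compute_synergy(fit_c, fit_k, wt_resp)
        calls = call_synergistic(rec, fit_c)
        assert len(calls) / len(rec) <= 0.005
        # z-scores are approximately standardised (unit scale, not exact:
        # regression averaging deflates high-occurrence scores)
        sk = rec[rec["ratio"] == "skip_vs_incl"]
        assert 0.3 <= sk["z_stouffer"].std() <= 2.5

    def test_wt_minigenes_self_normalise(self, kd_screen):
        resp = kd_screen["wt_response"]
        z = ((resp["d_log_skip_vs_incl"] - resp["d_log_skip_vs_incl"].mean())
             / resp["d_log_skip_vs_incl"].std())
        assert abs(z.mean()) < 1e-9


class TestCallFilters:
    @staticmethod
    def neutral_label(kd_screen):
        """A fitted, well-covered mutation with no planted main effect."""
        fit = kd_screen["fit_ctrl"]
        truth = kd_screen["truth"]
        from mutsplice.simulate import Mutation

        for lab, occ, ok in zip(fit.labels, fit.occurrence, fit.identifiable):
            pos = Mutation.from_label(lab).position
            if (occ >= 10 and ok and pos not in SPLICE_SITE_POSITIONS
                    and not np.any(truth.effect[lab])):
                return lab, pos
        raise AssertionError("no neutral label found")

    def base_record(self, kd_screen, **kw):
        lab, pos = self.neutral_label(kd_screen)
        rec = {
            "label": lab, "position": pos, "ratio": "skip_vs_incl",
            "delta": 1.0, "z_rep1": 3.0, "z_rep2": 3.0, "z_rep3": 3.0,
            "z_mean": 3.0, "z_stouffer": 5.2, "p": 1e-7, "p_adj": 1e-6,
            "direction_ok": True,
        }
        rec.update(kw)
        return pd.DataFrame([rec])

    def test_well_behaved_significant_record_is_called(self, kd_screen):
        calls = call_synergistic(self.base_record(kd_screen),
                                 kd_screen["fit_ctrl"])
        assert len(calls) == 1

    def test_splice_site_positions_excluded(self, kd_screen):
        rec = self.base_record(kd_screen, label="G209A", position=209)
        calls = call_synergistic(rec, kd_screen["fit_ctrl"])
        assert calls.empty

    def test_direction_inconsistency_fails(self, kd_screen):
        rec = self.base_record(kd_screen, direction_ok=False)
        calls = call_synergistic(rec, kd_screen["fit_ctrl"])
        assert calls.empty

    def test_tiers_are_nested(self, kd_screen):
        rec = self.base_record(kd_screen, z_stouffer=4.0)
        calls = call_synergistic(rec, kd_screen["fit_ctrl"])
        row = calls.iloc[0]
        assert row["tier_gt2"] and row["tier_gt3"] and not row["tier_gt5"]

    def test_excluded_positions_are_configurable(self, kd_screen):
        lab, _ = self.neutral_label(kd_screen)
        rec = self.base_record(kd_screen, label=lab, position=209)
        assert call_synergistic(rec, kd_screen["fit_ctrl"]).empty
        calls = call_synergistic(rec, kd_screen["fit_ctrl"],
                                 excluded_positions=frozenset())
        assert len(calls) == 1


class TestRatioVersusFrequencyContrast:
    def test_ratio_level_kd_response_independent_of_background(self, kd_screen):
        """The knockdown moves every minigene's log skip:incl ratio by the
        same amount, so the inferred Delta for non-synergistic mutations is
        flat in control inclusion — whereas the frequency-level KD response
        varies strongly with the mutational background."""
        from mutsplice.simulate import (MinigeneVariant, Mutation,
                                        default_wt_rates,
                                        expected_frequencies)

        fit_c, fit_k = kd_screen["fit_ctrl"], kd_screen["fit_kd"]
        truth = kd_screen["truth"]
        shared = [l for l, o, k in zip(fit_c.labels, fit_c.occurrence,
                                       fit_c.identifiable)
                  if o >= 5 and k and not truth.synergy.get(l)]
        idx = np.array([fit_c.index_of(l) for l in shared])
        inc = np.zeros((len(shared), len(fit_c.labels)))
        inc[np.arange(len(shared)), idx] = 1.0
        p_ctrl = predict_frequencies_batch(fit_c, inc)
        delta_ratio = (fit_k.beta[[fit_k.index_of(l) for l in shared], 0]
                       - fit_c.beta[idx, 0])
        x = p_ctrl[:, 0]
        # inferred ratio-level synergy is centred on 0 and uncorrelated
        # with the control inclusion background
        assert abs(np.mean(delta_ratio)) < 0.1
        assert abs(np.corrcoef(x, delta_ratio)[0, 1]) < 0.3

        # the same mutations' true frequency-level KD responses span a wide
        # range purely because of their background inclusion level
        rates = default_wt_rates()
        d_freq = []
        for lab in shared[:500]:
            v = MinigeneVariant("T" * 15, (Mutation.from_label(lab),))
            pc = expected_frequencies(v, truth, rates, "ctrl")
            pk = expected_frequencies(v, truth, rates, "kd")
            d_freq.append(pk[0] - pc[0])
        assert max(d_freq) - min(d_freq) > 0.1
        assert np.std(delta_ratio) < 1.0  # ratio deltas stay tight
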