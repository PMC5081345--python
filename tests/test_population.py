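import numpy as np
import pytest

from fusiform.engine import ProtocolSpec, Segment, run_spontaneous
from fusiform.parameters import (ModelParameters, active_preset, quiet_preset,
                                 density_to_nS)
from fusiform.population import (ClassDistributions, PopulationConfig,
                                 sample_population, emulate_pharmacology,
                                 generate_recording, population_manifest)
from fusiform.scans import ProportionRecord, proportion_analysis, \
    classify_by_kir_share
from fusiform.ephys import steady_state_value


def zero_dispersion_config(n=6, seed=0):
    area = ModelParameters().area_cm2
    leak = density_to_nS(0.15, area)
    classes = {
        "quiet": ClassDistributions(
            g_h_mean=density_to_nS(0.54, area), g_h_sd=0.0,
            g_Kir_mean=density_to_nS(1.0, area), g_Kir_cv=0.0,
            g_leak_mean=leak, g_leak_cv=0.0),
        "active": ClassDistributions(
            g_h_mean=density_to_nS(0.54, area), g_h_sd=0.0,
            g_Kir_mean=density_to_nS(0.5, area), g_Kir_cv=0.0,
            g_leak_mean=leak, g_leak_cv=0.0),
    }
    return PopulationConfig(n_per_class=n, classes=classes, seed=seed)


class TestSampling:
    def test_zero_dispersion_reproduces_presets_and_labels(self):
        """With dispersion 0 every neuron equals its class preset, the
        simulated firing label matches the drawn class, and the 50%
        Kir-share rule agrees with the simulated label."""
        recs = sample_population(zero_dispersion_config(n=2))
        for r in recs:
            preset = quiet_preset() if r.drawn_class == "quiet" else active_preset()
            assert r.params.g_Kir == pytest.approx(preset.g_Kir, rel=1e-9)
            assert r.params.g_h == pytest.approx(preset.g_h, rel=1e-9)
            assert r.label == r.drawn_class
            pr = ProportionRecord(g_Kir=r.g_Kir_nS, g_h=r.g_h_nS,
                                  g_leak=r.g_leak_nS)
            assert classify_by_kir_share(pr) == r.label

    def test_same_seed_identical_population(self):
        cfg = PopulationConfig(n_per_class=3, seed=11)
        a = sample_population(cfg)
        b = sample_population(PopulationConfig(n_per_class=3, seed=11))
        for ra, rb in zip(a, b):
            assert ra.params == rb.params
            assert ra.label == rb.label

    def test_active_class_draws_larger_gh_on_average(self, default_population):
        gh_q = [r.g_h_nS for r in default_population if r.drawn_class == "quiet"]
        gh_a = [r.g_h_nS for r in default_population if r.drawn_class == "active"]
        assert np.mean(gh_a) > np.mean(gh_q)

    def test_all_conductances_positive(self, default_population):
        for r in default_population:
            assert min(r.g_h_nS, r.g_Kir_nS, r.g_leak_nS) > 0

    def test_degenerate_distribution_rejected(self):
        cfg = zero_dispersion_config(n=1)
        bad = ClassDistributions(g_h_mean=-1.0, g_h_sd=0.0, g_Kir_mean=5.0,
                                 g_Kir_cv=0.1, g_leak_mean=2.0, g_leak_cv=0.1)
        cfg.classes["quiet"] = bad
        with pytest.raises(ValueError):
            sample_population(cfg)


class TestPharmacology:
    def test_agents_remove_the_right_conductances(self):
        p = active_preset()
        assert emulate_pharmacology(p, "ZD7288").g_h == 0.0
        assert emulate_pharmacology(p, "Ba").g_Kir == 0.0
        ttx = emulate_pharmacology(p, "TTX")
        assert ttx.g_Na == 0.0 and ttx.g_NaP == 0.0
        assert p.g_h > 0  # original untouched

    def test_low_na_shifts_leak_reversal_by_measured_amount(self):
        p = active_preset().replace(E_leak=-49.7)
        shifted = emulate_pharmacology(p, "low-Na")
        assert shifted.E_leak == pytest.approx(-66.2)

    def test_unknown_agent_rejected(self):
        with pytest.raises(ValueError, match="unknown agent"):
            emulate_pharmacology(active_preset(), "caffeine")

    def test_ttx_silences_the_active_preset(self):
        p = emulate_pharmacology(active_preset(), "TTX")
        _, spikes = run_spontaneous(p)
        assert len(spikes) == 0


class TestRecordings:
    protocol = ProtocolSpec(mode="current-clamp",
                            segments=(Segment(500.0, -20.0),), settle=500.0)

    def test_zero_noise_matches_clean_engine_output(self):
        from fusiform.engine import integrate
        p = quiet_preset()
        clean = integrate(p, self.protocol)
        rec = generate_recording(p, self.protocol, noise_sd=0.0, seed=5)
        np.testing.assert_array_equal(rec.signal, clean.signal)

    def test_same_seed_same_noise(self):
        p = quiet_preset()
        a = generate_recording(p, self.protocol, noise_sd=0.5, seed=9)
        b = generate_recording(p, self.protocol, noise_sd=0.5, seed=9)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            generate_recording(quiet_preset(), self.protocol, noise_sd=-1.0)

    def test_estimator_spread_grows_with_noise(self):
        """SD of a steady-state readout across 50 noise seeds increases
        monotonically with the configured noise level."""
        from fusiform.engine import integrate
        p = quiet_preset()
        clean = integrate(p, self.protocol)
        spreads = []
        for sd in (0.1, 0.5, 2.0):
            rng_est = []
            for seed in range(50):
                rng = np.random.default_rng(seed)
                noisy = clean.copy(signal=clean.signal
                                   + rng.normal(0, sd, clean.signal.shape))
                rng_est.append(steady_state_value(noisy, 0.0, 499.0))
            spreads.append(np.std(rng_est))
        assert spreads[0] < spreads[1] < spreads[2]


class TestPopulationStructure:
    def test_gh_share_anticorrelates_with_kir_share(self, default_population):
        """The compositional structure of the cohorts: the HCN share falls
        as the Kir share rises across neurons, while absolute values are
        not constrained to correlate."""
        recs = [ProportionRecord(g_Kir=r.g_Kir_nS, g_h=r.g_h_nS,
                                 g_leak=r.g_leak_nS, firing_label=r.label)
                for r in default_population]
        out = proportion_analysis(recs)
        assert out["gh_vs_gkir"]["slope"] < 0

    def test_manifest_has_one_row_per_neuron(self, default_population):
        df = population_manifest(default_population)
        assert len(df) == len(default_population)
        assert {"g_h_nS", "g_Kir_nS", "g_leak_nS", "label",
                "seed"} <= set(df.columns)


class TestRecovery:
    def test_noise_free_recovery_within_2_percent(self, recovery_table):
        """Emulated ZD7288/Ba subtractions plus the residual-leak fit
        reproduce every neuron's true conductances within 2%."""
        df = recovery_table
        for g in ("g_h", "g_Kir", "g_leak"):
            rel = np.abs(df[f"{g}_est"] / df[f"{g}_true"] - 1.0)
            assert rel.max() < 0.02, f"{g}: {rel.max():.4f}"

    def test_leak_reversal_recovered(self, recovery_table):
        np.testing.assert_allclose(recovery_table["E_leak_est"],
                                   recovery_table["E_leak_true"], atol=0.2)
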