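"""Protocol emulators: single turnover, pulse pair, elemental substitution,
temperature mapping, viscosity series."""

import math

import numpy as np
import pytest

import polbkin as pk
from polbkin.constants import KB_OVER_H, R_CAL


class TestSingleTurnover:
    def test_no_substrate_no_product(self, xl_scheme, xl_rates):
        cfg = pk.ProtocolConfig(dNTP_uM=0.0)
        tc = pk.simulate_single_turnover(xl_scheme, xl_rates, cfg)
        assert np.allclose(tc.signal, 0.0, atol=1e-9)

    def test_kobs_tracks_configured_kp(self, xl_scheme, xl_rates):
        """At saturating nucleotide the fitted k_obs approximates k_p."""
        fit = pk.fit_single_exponential(
            pk.simulate_single_turnover(xl_scheme, xl_rates, pk.ProtocolConfig())
        )
        assert fit.converged
        assert abs(fit.k_obs - xl_rates.kp) / xl_rates.kp < 0.15

    def test_signal_bounded_by_enzyme(self, xl_scheme, xl_rates):
        tc = pk.simulate_single_turnover(xl_scheme, xl_rates, pk.ProtocolConfig())
        assert np.all(tc.signal <= 30.0 + 1e-6)

    def test_exponential_saturation_at_ten_halftimes(self, xl_rates):
        # with reopening blocked the signal levels at the partition plateau
        rates = xl_rates.with_entries({"k7": 0.0})
        scheme = pk.build_scheme("crosslinked", rates)
        k_eff = 0.64
        cfg = pk.ProtocolConfig(quench_times_s=(0.0, 10.0 / k_eff, 30.0 / k_eff))
        tc = pk.simulate_single_turnover(scheme, rates, cfg)
        assert tc.signal[1] == pytest.approx(tc.signal[2], rel=1e-3)


class TestPulsePair:
    def test_zero_time_zero_product(self, xl_scheme, xl_rates):
        cfg = pk.ProtocolConfig(protocol="pulse_quench", dNTP_uM=1.5)
        tc = pk.simulate_pulse_quench(xl_scheme, xl_rates, cfg)
        assert tc.signal[0] == pytest.approx(0.0, abs=1e-9)

    def test_quench_plateau_substoichiometric(self, xl_scheme, xl_rates):
        # the pre-chemistry intermediate holds part of the label
        cfg = pk.ProtocolConfig(protocol="pulse_quench", dNTP_uM=1.5)
        fit = pk.fit_single_exponential(pk.simulate_pulse_quench(xl_scheme, xl_rates, cfg))
        assert fit.amplitude < 30.0

    def test_zero_chase_equals_pulse_quench(self, xl_scheme, xl_rates):
        grid = tuple(np.concatenate([[0.0], np.geomspace(0.1, 6.0, 8)]))
        pq = pk.simulate_pulse_quench(
            xl_scheme, xl_rates,
            pk.ProtocolConfig(protocol="pulse_quench", dNTP_uM=1.5, quench_times_s=grid),
        )
        pc = pk.simulate_pulse_chase(
            xl_scheme, xl_rates,
            pk.ProtocolConfig(protocol="pulse_chase", dNTP_uM=1.5, quench_times_s=grid,
                              chase_duration_s=0.0),
        )
        assert np.allclose(pc.signal, pq.signal, rtol=1e-6, atol=1e-6)

    def test_chase_at_least_quench_everywhere(self, xl_scheme, xl_rates):
        grid = tuple(np.concatenate([[0.0], np.geomspace(0.05, 6.0, 10)]))
        pq = pk.simulate_pulse_quench(
            xl_scheme, xl_rates,
            pk.ProtocolConfig(protocol="pulse_quench", dNTP_uM=1.5, quench_times_s=grid),
        )
        pc = pk.simulate_pulse_chase(
            xl_scheme, xl_rates,
            pk.ProtocolConfig(protocol="pulse_chase", dNTP_uM=1.5, quench_times_s=grid),
        )
        assert np.all(pc.signal >= pq.signal - 1e-6)

    def test_committed_fast_chemistry_limit_ratio_one(self, xl_rates):
        """With no accumulating pre-chemistry intermediate (k5 fast, chemical
        step committed) the chase adds nothing: amplitude ratio -> 1."""
        rates = xl_rates.with_entries({"k5": 1000.0, "k-6": 0.0})
        scheme = pk.build_scheme("crosslinked", rates)
        grid = tuple(np.concatenate([[0.0], np.geomspace(0.005, 0.3, 9)]))
        pq = pk.simulate_pulse_quench(
            scheme, rates,
            pk.ProtocolConfig(protocol="pulse_quench", dNTP_uM=25.0, quench_times_s=grid),
        )
        pc = pk.simulate_pulse_chase(
            scheme, rates,
            pk.ProtocolConfig(protocol="pulse_chase", dNTP_uM=25.0, quench_times_s=grid),
        )
        assert pc.signal[-1] / pq.signal[-1] == pytest.approx(1.0, rel=0.02)

    def test_quasi_equilibrium_closed_form_ratio(self, xl_rates):
        """Slow reopening plus a chase that fully commits the intermediate
        reproduce the closed-form amplitude ratio 1 + k-6/k6."""
        rates = xl_rates.with_entries({"k7": 0.002})
        scheme = pk.build_scheme("crosslinked", rates)
        grid = tuple(np.concatenate([[0.0], np.geomspace(0.2, 8.0, 9)]))
        pq = pk.simulate_pulse_quench(
            scheme, rates,
            pk.ProtocolConfig(protocol="pulse_quench", dNTP_uM=25.0, quench_times_s=grid),
        )
        pc = pk.simulate_pulse_chase(
            scheme, rates,
            pk.ProtocolConfig(protocol="pulse_chase", dNTP_uM=25.0, quench_times_s=grid,
                              chase_duration_s=5000.0),
        )
        expected = 1.0 + rates["k-6"] / rates["k6"]
        assert pc.signal[-1] / pq.signal[-1] == pytest.approx(expected, rel=0.02)


class TestElementalSubstitution:
    def test_identity_factor(self, xl_rates):
        assert pk.apply_elemental_substitution(xl_rates, 1.0).entries == xl_rates.entries

    def test_only_chemistry_labels_touched(self, xl_rates):
        thio = pk.apply_elemental_substitution(xl_rates, 10.0)
        for label, value in xl_rates.entries.items():
            if label in ("k6", "k-6"):
                assert thio[label] == pytest.approx(value / 10.0)
            else:
                assert thio[label] == value

    def test_factor_below_one_rejected(self, xl_rates):
        with pytest.raises(ValueError, match=">= 1"):
            pk.apply_elemental_substitution(xl_rates, 0.5)

    def test_masked_effect_when_conformational_step_limits(self, xl_scheme, xl_rates):
        """Intrinsic 50-fold chemistry slowdown barely shows in k_obs when a
        pre-chemical step is rate-limiting."""
        thio = pk.apply_elemental_substitution(xl_rates, 50.0)
        cfg = pk.ProtocolConfig()
        f_o = pk.fit_single_exponential(pk.simulate_single_turnover(xl_scheme, xl_rates, cfg))
        f_s = pk.fit_single_exponential(pk.simulate_single_turnover(xl_scheme, thio, cfg))
        observed = f_o.k_obs / f_s.k_obs
        assert observed < 10.0  # far below the intrinsic 50-fold

    def test_full_effect_when_chemistry_limits(self, xl_rates):
        chem = xl_rates.with_entries({"k6": 0.0072, "k-6": 0.0})
        scheme = pk.build_scheme("crosslinked", chem)
        cfg_o = pk.ProtocolConfig(quench_times_s=tuple(pk.rfq_time_grid(0.0072)))
        f_o = pk.fit_single_exponential(pk.simulate_single_turnover(scheme, chem, cfg_o))
        thio = pk.apply_elemental_substitution(chem, 50.0)
        cfg_s = pk.ProtocolConfig(quench_times_s=tuple(pk.rfq_time_grid(0.0072 / 50)))
        f_s = pk.fit_single_exponential(pk.simulate_single_turnover(scheme, thio, cfg_s))
        assert f_o.k_obs / f_s.k_obs == pytest.approx(50.0, rel=0.10)

    def test_substitution_never_speeds_kobs(self, xl_scheme, xl_rates):
        cfg = pk.ProtocolConfig()
        base = pk.fit_single_exponential(
            pk.simulate_single_turnover(xl_scheme, xl_rates, cfg)
        ).k_obs
        for factor in (2.0, 10.0, 50.0):
            thio = pk.apply_elemental_substitution(xl_rates, factor)
            k = pk.fit_single_exponential(
                pk.simulate_single_turnover(xl_scheme, thio, cfg)
            ).k_obs
            assert k <= base * (1.0 + 1e-9)


class TestTemperatureMapping:
    def test_bare_prefactor(self, xl_rates):
        warm = pk.apply_temperature(xl_rates, 300.0, activation={"k5": (0.0, 0.0)})
        assert warm["k5"] == pytest.approx(KB_OVER_H * 300.0)

    def test_rate_consistent_with_activation_free_energy(self):
        # dH=21.5 kcal/mol, dS=11.5 cal/(mol K) at 310.15 K <=> dG = 17.93
        k = pk.eyring_rate(21.5, 11.5, 310.15)
        dg = 21.5 - 310.15 * 11.5 / 1000.0
        k_from_g = KB_OVER_H * 310.15 * math.exp(-dg * 1000.0 / (R_CAL * 310.15))
        assert k == pytest.approx(k_from_g, rel=1e-12)

    def test_two_point_round_trip(self, xl_rates):
        dh, ds = 21.5, 11.5
        pairs = []
        for t in (293.15, 310.15):
            warm = pk.apply_temperature(xl_rates, t, activation={"k5": (dh, ds)})
            pairs.append((t, warm["k5"]))
        fit = pk.fit_eyring(pairs)
        assert fit.dH_kcal == pytest.approx(dh, rel=1e-9)
        assert fit.dS_cal == pytest.approx(ds, rel=1e-9)

    def test_undesignated_rates_unchanged(self, xl_rates):
        warm = pk.apply_temperature(xl_rates, 293.15, activation={"k5": (21.5, 11.5)})
        for label in xl_rates.entries:
            if label != "k5":
                assert warm[label] == xl_rates[label]

    def test_invalid_temperature(self, xl_rates):
        with pytest.raises(ValueError):
            pk.apply_temperature(xl_rates, -5.0, activation={"k5": (21.5, 11.5)})


class TestViscosity:
    def test_identity(self, xl_rates):
        assert pk.apply_viscosity(xl_rates, 1.0).entries == pytest.approx(xl_rates.entries)

    def test_flat_kobs_with_default_assignment(self, xl_scheme, xl_rates):
        """Binding steps are fast at saturation, so slowing them leaves the
        conformationally limited k_obs flat (< 5% over eta 1 -> 3)."""
        cfg = pk.ProtocolConfig()
        ks = []
        for eta in (1.0, 2.0, 3.0):
            visc = pk.apply_viscosity(xl_rates, eta)
            ks.append(
                pk.fit_single_exponential(
                    pk.simulate_single_turnover(xl_scheme, visc, cfg)
                ).k_obs
            )
        assert max(ks) / min(ks) - 1.0 < 0.05

    def test_inverse_scaling_when_binding_limits(self, xl_rates):
        rates = xl_rates.with_entries({"k4": 4e-4, "k-4": 0.0, "k7": 10.0})
        scheme = pk.build_scheme("crosslinked", rates)
        ks = []
        for eta in (1.0, 2.0, 3.0):
            visc = pk.apply_viscosity(rates, eta)
            cfg = pk.ProtocolConfig(quench_times_s=tuple(pk.rfq_time_grid(0.005 / eta)))
            ks.append(
                pk.fit_single_exponential(
                    pk.simulate_single_turnover(scheme, visc, cfg)
                ).k_obs
            )
        for eta, k in zip((1.0, 2.0, 3.0), ks):
            assert ks[0] / k == pytest.approx(eta, rel=0.10)

    def test_below_one_rejected(self, xl_rates):
        with pytest.raises(ValueError):
            pk.apply_viscosity(xl_rates, 0.9)


class TestProtocolConfig:
    def test_unknown_protocol(self):
        with pytest.raises(ValueError, match="unknown protocol"):
            pk.ProtocolConfig(protocol="stopped_flow")

    def test_nonpositive_enzyme(self):
        with pytest.raises(ValueError):
            pk.ProtocolConfig(enzyme_complex_nM=0.0)

    def test_chase_pool_must_exceed_pulse(self):
        with pytest.raises(ValueError, match="chase pool"):
            pk.ProtocolConfig(protocol="pulse_chase", dNTP_uM=2000.0, chase_dNTP_uM=1500.0)
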