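"""Heme binding: isotherm model and fits, kinetics, spectra, turnover."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from reamp.binding import (
    IsothermModel,
    KineticsModel,
    Spectrum,
    TitrationSeries,
    abts_turnovers,
    bound_ligand,
    classify_soret,
    simulate_isotherm,
)
from reamp.simulate import gen_isotherm, gen_kinetics, gen_spectrum


def _bound_oracle(kd, p, ligand):
    """Root-find the single-site mass-balance instead of the closed form."""
    if ligand == 0 or p == 0:
        return 0.0
    f = lambda b: (p - b) * (ligand - b) - kd * b
    return brentq(f, 0.0, min(p, ligand), xtol=1e-14)


class TestForwardModel:
    def test_tight_binding_limit_is_stoichiometric(self):
        p = 0.7
        lig = np.array([0.0, 0.2, 0.5, 0.7, 1.0, 3.0])
        bound = bound_ligand(1e-12, 0.5, 1.4, lig)
        assert bound == pytest.approx(np.minimum(lig, p), abs=1e-5)

    def test_zero_ligand_gives_zero_signal(self):
        s = simulate_isotherm(2.2, 0.5, 1.4, [0.0], 0.08, 0.003)
        assert s.signal[0] == 0.0

    def test_closed_form_matches_rootfinding_oracle(self):
        kd = p = lig = 1.4  # kd = P = L regime
        assert bound_ligand(kd, 1.0, p, lig) == pytest.approx(
            _bound_oracle(kd, p, lig), abs=1e-10
        )

    @given(st.floats(0.01, 20), st.floats(0.1, 2), st.floats(0.01, 50))
    @settings(deadline=None)
    def test_mass_conservation_and_bounds(self, kd, n, lig):
        p = n * 1.4
        bound = float(bound_ligand(kd, n, 1.4, lig))
        assert 0.0 <= bound <= min(lig, p) + 1e-9
        assert bound == pytest.approx(_bound_oracle(kd, p, lig), abs=1e-8)


class TestIsothermFit:
    @pytest.mark.parametrize("kd", [0.5, 2.2, 2.9, 5.6])
    @pytest.mark.parametrize("n_sites", [0.5, 1.0])
    def test_noise_free_recovery_across_grid(self, kd, n_sites):
        series = gen_isotherm(1, kd=kd, n_sites=n_sites).payload
        res = IsothermModel(series).fit()
        assert res.kd == pytest.approx(kd, rel=1e-4)
        assert res.n_sites == pytest.approx(n_sites, rel=1e-4)

    def test_stoichiometric_breakpoint_readout(self):
        # tight binding: fitted sites match the titration breakpoint,
        # i.e. the 1:1 / 0.5:1 heme:His readout
        for n_sites, his in [(1.0, 1), (0.5, 2)]:
            series = gen_isotherm(2, kd=0.01, n_sites=n_sites).payload
            res = IsothermModel(series, his_per_protomer=his).fit()
            assert res.n_sites == pytest.approx(n_sites, rel=0.02)
            assert res.heme_per_his == pytest.approx(n_sites / his, rel=0.02)

    def test_control_subtraction_removes_background(self):
        sig = gen_isotherm(3, kd=2.2, n_sites=0.5, background_slope=0.004).payload
        ctrl_raw = gen_isotherm(3, kd=2.2, n_sites=0.5, background_slope=0.004).payload
        control = TitrationSeries(
            sig.protein_conc, ctrl_raw.ligand,
            0.004 * ctrl_raw.ligand,  # pure partitioning, no specific sites
        )
        res = IsothermModel(sig, control=control).fit(fit_background=False)
        # the subtracted background is slightly over-corrected (control has
        # no depletion) but kd survives to a few percent
        assert res.kd == pytest.approx(2.2, rel=0.05)

    def test_series_equal_to_control_is_rejected(self):
        s = gen_isotherm(4, kd=2.2, n_sites=0.5).payload
        with pytest.raises(ValueError, match="flat"):
            IsothermModel(s, control=s).fit()

    def test_insufficient_points_rejected(self):
        s = TitrationSeries(1.4, [0, 1, 2], [0, 0.1, 0.2])
        with pytest.raises(ValueError):
            IsothermModel(s)

    def test_summary_reports_both_stoichiometry_conventions(self):
        res = IsothermModel(gen_isotherm(5, kd=2.2, n_sites=0.5).payload).fit()
        text = res.summary()
        assert "heme/protomer" in text and "heme:His" in text


class TestKinetics:
    def test_kinetic_kd_is_koff_over_kon(self):
        res = KineticsModel(gen_kinetics(1, kon=1.0, koff=1.7).payload).fit()
        assert res.kon == pytest.approx(1.0, rel=1e-4)
        assert res.koff == pytest.approx(1.7, rel=1e-4)
        assert res.kd_kinetic == pytest.approx(1.7, rel=1e-4)

    def test_zero_koff_gives_zero_kd(self):
        res = KineticsModel(gen_kinetics(2, kon=0.8, koff=0.0).payload).fit()
        assert res.kd_kinetic == pytest.approx(0.0, abs=1e-6)

    def test_trace_order_invariance(self):
        traces = gen_kinetics(3).payload
        a = KineticsModel(traces).fit()
        b = KineticsModel(traces[::-1]).fit()
        assert a.kon == pytest.approx(b.kon, rel=1e-12)
        assert a.koff == pytest.approx(b.koff, abs=1e-12)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            KineticsModel(gen_kinetics(4).payload[:2])

    def test_negative_intercept_clamped_and_flagged(self):
        t = np.linspace(0, 2, 100)
        # rates decreasing slower than kon*L would: force negative intercept
        traces = [(L, t, 1 - np.exp(-(2.0 * L - 1.0) * t)) for L in (1.0, 2.0, 4.0)]
        res = KineticsModel(traces).fit()
        assert res.koff == 0.0 and res.koff_clamped


class TestSoret:
    @pytest.mark.parametrize("state", ["free_aqueous", "bound_oxidized",
                                       "bound_reduced"])
    def test_synthetic_states_classified(self, state):
        cls = classify_soret(gen_spectrum(1, state=state).payload)
        assert cls.label == state

    def test_flat_spectrum_unclassified(self):
        wl = np.arange(350, 701, 1.0)
        cls = classify_soret(Spectrum(wl, np.ones_like(wl)))
        assert cls.label == "unclassified" and cls.peak_nm is None

    def test_dominant_reduced_peak_with_secondary(self):
        wl = np.arange(350, 701, 1.0)
        ab = (0.4 * np.exp(-0.5 * ((wl - 394) / 10) ** 2)
              + 1.0 * np.exp(-0.5 * ((wl - 427) / 10) ** 2))
        cls = classify_soret(Spectrum(wl, ab))
        assert cls.label == "bound_reduced"
        assert cls.secondary_peak_nm == pytest.approx(394, abs=2)

    def test_window_not_covered_errors(self):
        wl = np.arange(400, 500, 1.0)
        with pytest.raises(ValueError):
            classify_soret(Spectrum(wl, np.ones_like(wl)))

    def test_off_reference_peak_unclassified(self):
        wl = np.arange(350, 701, 1.0)
        ab = np.exp(-0.5 * ((wl - 405) / 8) ** 2)  # between 394 and 415 bands
        assert classify_soret(Spectrum(wl, ab)).label == "unclassified"


class TestTurnovers:
    def test_zero_endpoint_gives_zero(self):
        assert abts_turnovers(0.0, 1.0, 1.0) == 0.0

    def test_seven_turnovers_endpoint(self):
        assert abts_turnovers(0.252, 1.0, 1.0) == pytest.approx(7.0)

    @given(st.floats(0.001, 2.0), st.floats(0.2, 5.0))
    @settings(deadline=None)
    def test_beer_lambert_linearity(self, da, path):
        one = abts_turnovers(da, path, 1.0)
        assert abts_turnovers(2 * da, path, 1.0) == pytest.approx(2 * one)
        assert abts_turnovers(da, 2 * path, 1.0) == pytest.approx(one / 2)

    def test_zero_pathlength_rejected(self):
        with pytest.raises(ValueError):
            abts_turnovers(0.1, 0.0, 1.0)
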