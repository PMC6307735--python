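"""Quantifiers: ROI integration, deconvolution, integration, 31P, pH, weight."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isoflux.core import NATURAL_ABUNDANCE, Spectrum1D, Spectrum2D
from isoflux.roi_template import default_template
from isoflux.spectral_quant import (PH_PKA, deconvolve_lactate,
                                    estimate_ph, integrate_glutamine,
                                    integrate_roi, normalize_to_weight,
                                    pi_shift_from_ph, quantify_p31)
from isoflux.synthetic_data import (EffectSpec, assign_true_state, make_cohort,
                                    cohort_config_for_group, render_cpmg,
                                    render_hsqc, render_p31)
from isoflux.isotopomer_analysis import pools_from_cpmg

from conftest import make_sample


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------

def test_default_template_has_60_metabolite_and_4_noise_regions(template):
    assert len(template.metabolite_rois) == 60
    assert len(template.noise_rois) == 4


def test_template_file_round_trip(template, tmp_path):
    path = tmp_path / "roi.tsv"
    template.to_file(path)
    loaded = type(template).from_file(path)
    assert [r.name for r in loaded] == [r.name for r in template]
    assert loaded["Lac C3"].h_window == pytest.approx(template["Lac C3"].h_window)


def test_overlapping_windows_are_flagged_not_hidden(template):
    pairs = template.overlapping_pairs()
    # the crowded choline/creatine regions overlap by construction
    assert 0 < len(pairs) < 15


# ---------------------------------------------------------------------------
# 2D ROI integration
# ---------------------------------------------------------------------------

def test_hsqc_round_trip_recovers_volumes_within_2pct(template, ace_brain_sample,
                                                      ace_brain_state):
    spec = render_hsqc(ace_brain_state, template, 0.0)
    q = integrate_roi(spec, template, ace_brain_sample).set_index("roi")
    st = ace_brain_state
    for pos, pool in st.basal_pool.items():
        true = pool * st.labeled_fraction[pos]
        assert q.loc[pos, "norm_volume"] == pytest.approx(true, rel=0.02), pos


def test_all_zero_spectrum_gives_zero_volumes(template, ace_brain_sample):
    h = np.arange(0.8, 5.4, 0.004)
    c = np.arange(5.0, 105.0, 0.2)
    spec = Spectrum2D(ppm_h=h, ppm_c=c, grid=np.zeros((c.size, h.size)))
    q = integrate_roi(spec, template, ace_brain_sample)
    assert np.allclose(q["raw_volume"], 0.0)


def test_noise_only_rois_scatter_around_zero(template, ace_brain_sample, rng):
    spec = render_hsqc(assign_true_state(make_sample(group="CTR"), None,
                                         EffectSpec(), master_seed=1, cv=0.0),
                       template, 15.0, rng=rng)
    q = integrate_roi(spec, template, ace_brain_sample).set_index("roi")
    px = spec.pixel_area
    for roi in template.noise_rois:
        v = q.loc[roi.name, "raw_volume"]
        n_px = q.loc[roi.name, "raw_volume"] * 0 + (0.08 / 0.004) * (2.0 / 0.2)
        sd = 15.0 * np.sqrt(n_px) * px
        assert abs(v) < 3 * sd * 1.5   # plane baseline adds a little variance


def test_integration_invariant_to_constant_offset(template, ace_brain_sample,
                                                  ace_brain_state):
    spec = render_hsqc(ace_brain_state, template, 0.0)
    shifted = Spectrum2D(ppm_h=spec.ppm_h.copy(), ppm_c=spec.ppm_c.copy(),
                         grid=spec.grid + 7.5)
    q0 = integrate_roi(spec, template, ace_brain_sample).set_index("roi")
    q1 = integrate_roi(shifted, template, ace_brain_sample).set_index("roi")
    for pos in ace_brain_state.basal_pool:
        assert q1.loc[pos, "raw_volume"] == pytest.approx(
            q0.loc[pos, "raw_volume"], rel=1e-3, abs=1e-6), pos


def test_roi_outside_spectrum_reports_missing_with_warning(template,
                                                           ace_brain_sample):
    h = np.arange(1.0, 3.0, 0.004)     # truncated 1H axis
    c = np.arange(10.0, 80.0, 0.2)
    spec = Spectrum2D(ppm_h=h, ppm_c=c, grid=np.zeros((c.size, h.size)))
    with pytest.warns(UserWarning, match="outside the spectrum"):
        q = integrate_roi(spec, template, ace_brain_sample).set_index("roi")
    assert np.isnan(q.loc["Glc C1a", "raw_volume"])
    assert q.loc["Glc C1a", "flagged"]


def test_quantification_unbiased_over_noisy_replicates(template,
                                                       ace_brain_sample,
                                                       ace_brain_state):
    rng = np.random.default_rng(77)
    true = (ace_brain_state.basal_pool["Glu C4"]
            * ace_brain_state.labeled_fraction["Glu C4"])
    errs = []
    for _ in range(60):
        spec = render_hsqc(ace_brain_state, template, 15.0, rng=rng)
        q = integrate_roi(spec, template, ace_brain_sample).set_index("roi")
        errs.append(q.loc["Glu C4", "norm_volume"] - true)
    errs = np.asarray(errs)
    se = errs.std(ddof=1) / np.sqrt(errs.size)
    assert abs(errs.mean()) < 3 * se


# ---------------------------------------------------------------------------
# lactate deconvolution
# ---------------------------------------------------------------------------

def test_deconvolution_recovers_satellite_fraction_within_1pct(ace_brain_sample):
    st = assign_true_state(ace_brain_sample, None, EffectSpec(),
                           master_seed=7, cv=0.0, drift=False)
    st.labeled_fraction["Lac C3"] = 0.06
    dec = deconvolve_lactate(render_cpmg(st, 0.0))
    ratio = dec.lac_13ch3_right / (dec.lac_ch3 + 2 * dec.lac_13ch3_right)
    assert dec.success
    assert ratio == pytest.approx(0.06 / 2, rel=0.01)


def test_zero_labeled_pool_fits_zero_satellite(ace_brain_state):
    st = copy.deepcopy(ace_brain_state)
    st.labeled_fraction["Lac C3"] = 0.0
    dec = deconvolve_lactate(render_cpmg(st, 0.0))
    assert dec.lac_13ch3_right < 1e-3 * dec.lac_ch3


def test_labeled_pool_is_twice_the_right_satellite():
    class Dec:
        lac_ch3, lac_13ch3_right, flagged = 90.0, 5.0, False
    pools = pools_from_cpmg(Dec())
    assert pools["lac_13c"] == 10.0
    assert pools["lac_total"] == 100.0


def test_deconvolution_window_must_be_covered():
    spec = Spectrum1D(ppm=np.arange(2.0, 3.0, 0.001),
                      intensity=np.zeros(1000))
    with pytest.raises(ValueError):
        deconvolve_lactate(spec)


# ---------------------------------------------------------------------------
# glutamine integration
# ---------------------------------------------------------------------------

def test_glutamine_multiplet_recovered_within_3pct(ace_brain_sample):
    st = assign_true_state(ace_brain_sample, None, EffectSpec(),
                           master_seed=7, cv=0.0, drift=False)
    st.basal_pool = {"Gln C4": st.basal_pool["Gln C4"]}
    st.labeled_fraction = {"Gln C4": NATURAL_ABUNDANCE}
    spec = render_cpmg(st, 0.0, mm_baseline_scale=0.0)
    area = integrate_glutamine(spec)
    true = st.basal_pool["Gln C4"] * st.net_weight_mg
    assert area == pytest.approx(true, rel=0.03)


def test_succinate_singlet_is_excluded(ace_brain_sample):
    st = assign_true_state(ace_brain_sample, None, EffectSpec(),
                           master_seed=7, cv=0.0, drift=False)
    st.basal_pool = {"Succ C2": 5.0}
    st.labeled_fraction = {"Succ C2": NATURAL_ABUNDANCE}
    spec = render_cpmg(st, 0.0, mm_baseline_scale=0.0)
    area = integrate_glutamine(spec)
    assert abs(area) < 0.02 * 5.0 * st.net_weight_mg


def test_flat_spectrum_integrates_to_zero():
    x = np.arange(0.9, 2.7, 0.0005)
    spec = Spectrum1D(ppm=x, intensity=np.zeros_like(x))
    assert integrate_glutamine(spec) == pytest.approx(0.0, abs=1e-9)


def test_truncated_glutamine_window_errors():
    spec = Spectrum1D(ppm=np.arange(2.41, 2.46, 0.0005),
                      intensity=np.zeros(100))
    with pytest.raises(ValueError, match="truncated"):
        integrate_glutamine(spec)


# ---------------------------------------------------------------------------
# 31P quantification and pH
# ---------------------------------------------------------------------------

def test_brain_p31_areas_within_3pct(ace_brain_sample, ace_brain_state):
    pq = quantify_p31(render_p31(ace_brain_state, 0.0), "brain_cortex")
    w = ace_brain_state.net_weight_mg
    for sp in ("PE", "PC", "GPE", "GPC"):
        assert pq.areas[sp] / w == pytest.approx(
            ace_brain_state.p31_pool[sp], rel=0.03), sp


def test_heart_pc_reported_missing():
    s = make_sample("heart_apex", "ACE")
    st = assign_true_state(s, None, EffectSpec(), master_seed=2, cv=0.0)
    pq = quantify_p31(render_p31(st, 0.0), "heart_apex")
    assert np.isnan(pq.areas["PC"])
    assert "diphosphoglycerate" in pq.flags["PC"]


def test_pde_ratio_recovered_at_default_effects():
    eff = EffectSpec()
    sums = {}
    for horn in ("AGA", "FGR"):
        s = make_sample("heart_apex", "ACE", horn)
        st = assign_true_state(s, None, eff, master_seed=2, cv=0.0)
        pq = quantify_p31(render_p31(st, 0.0), "heart_apex")
        sums[horn] = pq.areas["GPE"] + pq.areas["GPC"]
    assert sums["FGR"] / sums["AGA"] == pytest.approx(1.5, rel=0.02)


def test_missing_gpe_reference_is_an_error(ace_brain_state):
    st = copy.deepcopy(ace_brain_state)
    st.p31_pool["GPE"] = 0.0
    with pytest.raises(ValueError, match="reference"):
        quantify_p31(render_p31(st, 0.0), "brain_cortex")


def test_ph_equation_properties():
    mid = (3.27 + 5.69) / 2
    assert estimate_ph(mid) == pytest.approx(PH_PKA)
    deltas = np.linspace(3.4, 5.5, 30)
    phs = [estimate_ph(d) for d in deltas]
    assert all(b > a for a, b in zip(phs, phs[1:]))
    with pytest.raises(ValueError):
        estimate_ph(3.0)
    with pytest.raises(ValueError):
        estimate_ph(5.8)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(ph=st.floats(5.6, 7.7))
def test_ph_shift_inverse_pair(ph):
    assert estimate_ph(pi_shift_from_ph(ph)) == pytest.approx(ph, abs=1e-9)


# ---------------------------------------------------------------------------
# weight normalization
# ---------------------------------------------------------------------------

def test_normalization_arithmetic_and_invariance():
    s = make_sample(net=50.0)
    assert normalize_to_weight(100.0, s) == 2.0
    s2 = make_sample(net=100.0, fetus_id="T-M1-AGA-F2")
    assert normalize_to_weight(200.0, s2) == normalize_to_weight(100.0, s)


def test_missing_weight_is_an_error():
    s = make_sample()
    s.net_tissue_weight_mg = np.nan
    with pytest.raises(ValueError):
        normalize_to_weight(1.0, s)


def test_cohort_mean_net_weight_matches_configured_49_7_mg():
    records = make_cohort(cohort_config_for_group("GLC", seed=3)).records
    weights = np.array([r.net_tissue_weight_mg for r in records])
    se = 3.0 / np.sqrt(weights.size)
    assert abs(weights.mean() - 49.7) < 3 * se
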