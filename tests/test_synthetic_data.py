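"""Cohort generator, ground-truth states and spectrum renderers."""

import numpy as np
import pytest

from isoflux.core import NATURAL_ABUNDANCE, ROI, ROITemplate, records_to_manifest
from isoflux.synthetic_data import (CohortConfig, EffectSpec,
                                    assign_true_state, cohort_config_for_group,
                                    default_flux, make_cohort, render_cpmg,
                                    render_hsqc, render_p31)
from isoflux.spectral_quant import quantify_p31

from conftest import make_sample

NA = NATURAL_ABUNDANCE


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def test_cohort_is_deterministic_under_fixed_seed():
    cfg = cohort_config_for_group("ACE", seed=1)
    m1 = records_to_manifest(make_cohort(cfg).records)
    m2 = records_to_manifest(make_cohort(cfg).records)
    assert m1.equals(m2)


def test_zero_stillbirth_keeps_every_fetus():
    cfg = CohortConfig(group="GLC", n_mothers=3, fetuses_per_horn=5,
                       stillbirth_prob_fgr=0.0, stillbirth_prob_aga=0.0,
                       n_select_per_horn=None, seed=4)
    cohort = make_cohort(cfg)
    fetuses = {r.fetus_id for r in cohort.records}
    assert len(fetuses) == 3 * 5 * 2
    assert len(cohort.records) == len(fetuses) * 2   # two tissues each
    assert cohort.n_stillborn == {"AGA": 0, "FGR": 0}


def test_certain_stillbirth_flags_empty_horns_without_crashing():
    cfg = CohortConfig(group="ACE", n_mothers=2, fetuses_per_horn=4,
                       stillbirth_prob_fgr=1.0, stillbirth_prob_aga=0.0,
                       n_select_per_horn=None, seed=0)
    cohort = make_cohort(cfg)
    assert {(m, h) for m, h in cohort.empty_horns} == {
        ("ACE-M1", "FGR"), ("ACE-M2", "FGR")}
    assert all(r.horn == "AGA" for r in cohort.records)


def test_control_group_has_no_fgr_horn():
    cohort = make_cohort(cohort_config_for_group("CTR", seed=2))
    assert all(r.horn == "AGA" for r in cohort.records)
    assert "FGR" not in cohort.n_induced


def test_expected_stillbirths_match_bernoulli_rate():
    # 55% of 60 induced FGR fetuses ~ 33 stillbirths on average
    counts = [make_cohort(CohortConfig(group="ACE", n_mothers=10,
                                       fetuses_per_horn=6, seed=s,
                                       n_select_per_horn=None)).n_stillborn["FGR"]
              for s in range(40)]
    assert np.mean(counts) == pytest.approx(0.55 * 60, abs=1.5)


def test_fgr_birthweights_below_aga():
    cohort = make_cohort(cohort_config_for_group("GLC", seed=9))
    bw = {h: [r.birthweight_g for r in cohort.records if r.horn == h]
          for h in ("AGA", "FGR")}
    assert np.mean(bw["FGR"]) < np.mean(bw["AGA"])


# ---------------------------------------------------------------------------
# true states
# ---------------------------------------------------------------------------

def test_control_state_sits_at_natural_abundance():
    s = make_sample(group="CTR", horn="AGA")
    st = assign_true_state(s, None, EffectSpec(), master_seed=3)
    assert all(v == NA for v in st.labeled_fraction.values())


def test_fgr_effect_scales_labeled_excess_multiplicatively():
    eff = EffectSpec(label_effects={("brain_cortex", "Lac C2"): 0.77},
                     label_groups=("ACE",))
    aga = assign_true_state(make_sample(horn="AGA"), None, eff,
                            master_seed=5, cv=0.0)
    fgr = assign_true_state(make_sample(horn="FGR"), None, eff,
                            master_seed=5, cv=0.0)
    ex_aga = aga.labeled_fraction["Lac C2"] - NA
    ex_fgr = fgr.labeled_fraction["Lac C2"] - NA
    assert ex_fgr == pytest.approx(0.77 * ex_aga, rel=1e-9)
    # untouched position unaffected
    assert fgr.labeled_fraction["Glu C4"] == aga.labeled_fraction["Glu C4"]


def test_unit_effect_leaves_horns_identical_in_expectation():
    eff = EffectSpec(label_effects={}, label_groups=("ACE",),
                     pde_factor={})
    aga = assign_true_state(make_sample(horn="AGA"), None, eff,
                            master_seed=5, cv=0.0)
    fgr = assign_true_state(make_sample(horn="FGR"), None, eff,
                            master_seed=5, cv=0.0)
    assert aga.labeled_fraction == fgr.labeled_fraction


def test_unknown_effect_key_is_a_configuration_error():
    eff = EffectSpec(label_effects={("brain_cortex", "Foo C9"): 0.5})
    with pytest.raises(ValueError, match="Foo C9"):
        assign_true_state(make_sample(), None, eff, master_seed=1)


def test_pde_pools_exceed_infused_aga_hearts_by_factor():
    eff = EffectSpec()
    aga = assign_true_state(make_sample("heart_apex", "ACE", "AGA"), None, eff,
                            master_seed=2, cv=0.0)
    fgr = assign_true_state(make_sample("heart_apex", "ACE", "FGR"), None, eff,
                            master_seed=2, cv=0.0)
    ctr = assign_true_state(make_sample("heart_apex", "CTR", "AGA"), None, eff,
                            master_seed=2, cv=0.0)
    for sp in ("GPE", "GPC"):
        assert fgr.p31_pool[sp] / aga.p31_pool[sp] == pytest.approx(1.5)
        assert ctr.p31_pool[sp] / aga.p31_pool[sp] == pytest.approx(1.5)


# ---------------------------------------------------------------------------
# CPMG renderer
# ---------------------------------------------------------------------------

def _state_with(sample, overrides_frac=None, cv=0.0, **kw):
    st = assign_true_state(sample, None, EffectSpec(), master_seed=7, cv=cv, **kw)
    if overrides_frac:
        st.labeled_fraction.update(overrides_frac)
    return st


def test_unlabeled_lactate_renders_no_satellites(ace_brain_sample):
    st = _state_with(ace_brain_sample, {"Lac C3": NA * 0})
    st.labeled_fraction["Lac C3"] = 0.0
    spec = render_cpmg(st, 0.0, mm_baseline_scale=0.0)
    # right satellite region (1.13-1.19 ppm) empty; CH3 doublet present
    sat = spec.integrate(1.13, 1.19)
    main = spec.integrate(1.28, 1.36)
    assert abs(sat) < 1e-3 * main
    assert main == pytest.approx(
        st.basal_pool["Lac C3"] * st.net_weight_mg, rel=0.03)


def test_satellite_area_fraction_matches_f_over_2(ace_brain_sample):
    # numeric-integration oracle on the rendered model, zero noise
    st = _state_with(ace_brain_sample, {"Lac C3": 0.08})
    spec = render_cpmg(st, 0.0, mm_baseline_scale=0.0)
    x, y = spec.ppm[::-1], spec.intensity[::-1]

    def integral(lo, hi):
        m = (x >= lo) & (x < hi)
        base = np.interp([lo, hi], x, y).mean()   # linear edge baseline
        return float(np.trapezoid(y[m] - base, x[m]))

    sat = integral(1.13, 1.19)
    total = st.basal_pool["Lac C3"] * st.net_weight_mg
    assert sat / total == pytest.approx(0.08 / 2, rel=0.03)


def test_drifting_glutamine_area_grows_linearly(ace_brain_sample):
    st = _state_with(ace_brain_sample, drift=True)
    areas = []
    for t in (0.0, 2.6, 5.2):
        spec = render_cpmg(st, 0.0, time_h=t)
        areas.append(spec.integrate(2.40, 2.50))
    assert areas[1] > areas[0]
    # linear: midpoint is the average of the endpoints
    assert areas[1] == pytest.approx((areas[0] + areas[2]) / 2, rel=1e-6)
    assert areas[2] / areas[0] == pytest.approx(1.10, rel=0.02)


def test_negative_noise_rejected(ace_brain_state):
    with pytest.raises(ValueError):
        render_cpmg(ace_brain_state, -1.0)
    with pytest.raises(ValueError):
        render_hsqc(ace_brain_state, None, -1.0)


# ---------------------------------------------------------------------------
# HSQC renderer
# ---------------------------------------------------------------------------

def test_ctr_hsqc_volumes_proportional_to_natural_abundance(template):
    s = make_sample(group="CTR")
    st = assign_true_state(s, None, EffectSpec(), master_seed=3, cv=0.0)
    spec = render_hsqc(st, template, 0.0)
    from isoflux.spectral_quant import integrate_roi
    q = integrate_roi(spec, template, s).set_index("roi")
    for pos, pool in st.basal_pool.items():
        assert q.loc[pos, "norm_volume"] == pytest.approx(NA * pool, rel=0.02), pos


def test_hsqc_volume_linear_in_labeled_fraction(template, ace_brain_sample):
    st1 = _state_with(ace_brain_sample, {"Glu C4": 0.05})
    st2 = _state_with(ace_brain_sample, {"Glu C4": 0.10})
    from isoflux.spectral_quant import integrate_roi
    v = []
    for st in (st1, st2):
        q = integrate_roi(render_hsqc(st, template, 0.0), template,
                          ace_brain_sample).set_index("roi")
        v.append(q.loc["Glu C4", "raw_volume"])
    assert v[1] == pytest.approx(2 * v[0], rel=0.01)


def test_peak_outside_spectral_width_names_the_roi(ace_brain_state):
    bad = ROITemplate(rois=[ROI("Lac C3", "Lac", "C3", (6.9, 7.1), (20.0, 22.0))])
    with pytest.raises(ValueError, match="Lac C3"):
        render_hsqc(ace_brain_state, bad, 0.0)


def test_renderers_deterministic_with_seeded_rng(ace_brain_state, template):
    a = render_hsqc(ace_brain_state, template, 10.0,
                    rng=np.random.default_rng(3))
    b = render_hsqc(ace_brain_state, template, 10.0,
                    rng=np.random.default_rng(3))
    assert np.array_equal(a.grid, b.grid)


# ---------------------------------------------------------------------------
# 31P renderer
# ---------------------------------------------------------------------------

def test_p31_round_trips_ph(ace_brain_sample):
    st = _state_with(ace_brain_sample)
    st.tissue_ph = 6.44
    pq = quantify_p31(render_p31(st, 0.0), st.tissue)
    assert pq.ph == pytest.approx(6.44, abs=0.01)


def test_heart_p31_has_dpg_contribution_in_pc_region():
    heart = _state_with(make_sample("heart_apex", "ACE"))
    brain = _state_with(make_sample("brain_cortex", "ACE"))
    brain.p31_pool = dict(heart.p31_pool)
    brain.p31_pool.pop("DPG", None)
    sp_h = render_p31(heart, 0.0)
    sp_b = render_p31(brain, 0.0)
    extra = sp_h.integrate(3.55, 3.95) - sp_b.integrate(3.55, 3.95)
    assert extra == pytest.approx(heart.p31_pool["DPG"] * heart.net_weight_mg,
                                  rel=0.1)


def test_zero_pools_give_flat_spectrum(ace_brain_state):
    import copy
    st = copy.deepcopy(ace_brain_state)
    st.p31_pool = {k: 0.0 for k in st.p31_pool}
    spec = render_p31(st, 0.0)
    assert np.allclose(spec.intensity, 0.0)


def test_out_of_range_ph_rejected(ace_brain_state):
    import copy
    st = copy.deepcopy(ace_brain_state)
    st.tissue_ph = 5.0
    with pytest.raises(ValueError):
        render_p31(st, 0.0)
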