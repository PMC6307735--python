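"""Synthetic cohorts, ground-truth metabolic states and rendered spectra.

This module generates everything the analysis consumes, with the statistical
structure the study design assumes: littermate AGA/FGR horns with differential
stillbirth and birthweight, a natural-abundance (1.1%) 13C baseline in
non-infused controls, group effect sizes on the labeled pools (brain Lac C2
-23% and Lac C3 -20%, heart Gln C4 -23% in growth-restricted fetuses of the
acetate group; phosphodiesters +50% in FGR and control hearts relative to
infused AGA hearts), and a slow linear accumulation of Gln C4 / Lac C2 /
Lac C3 during the spinning session.

Randomness: one RNG stream per sample, derived from (master seed, fetus id,
tissue), so cohorts are extensible without reshuffling earlier samples.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import lineshapes as ls
from .core import (D2O_WEIGHT_MG, EMPTY_ROTOR_MG, H_FREQ_MHZ,
                   NATURAL_ABUNDANCE, FluxParams, ROITemplate, SampleRecord,
                   Spectrum1D, Spectrum2D, SUBSTRATE_BY_GROUP)
from .label_propagation import IsotopomerProfile, propagate
from .spectral_quant import (GPE_REF_OFFSET, J_CH_HZ, J_HH_HZ, P31_SHIFTS_STD,
                             pi_shift_from_ph)

#: relative accumulation per hour for the drifting isotopomers
#: (chosen so a 5.2 h session accumulates ~10%)
DRIFT_RATE_PER_H = 0.10 / 5.2

#: default per-sample biological coefficient of variation on pools and
#: labeled excesses.  Together with the enrichment levels below this puts
#: the FGR-vs-AGA effect sizes of the headline contrasts in the d ~ 1.5-2.5
#: range implied by the study's reported p-values at n = 6/6.
BIOLOGICAL_CV = 0.06

#: effective 13C enrichment of the tissue precursor pool per substrate.
#: The infusions only partially label the circulating substrate (blood
#: glucose roughly doubles over an unlabeled basal pool) and tissue pools
#: dilute further; under acetate the labeled lactate excess runs several
#: fold above the 1.1% natural-abundance baseline, as in the reported
#: CTR-referenced levels.
EFFECTIVE_ENRICHMENT = {"glc_1_13C": 0.15, "ace_2_13C": 0.45}

_TISSUE_CODE = {"brain_cortex": 1, "heart_apex": 2}

# rendered metabolite-carbon positions -> parent metabolite pool
POSITION_METABOLITE = {
    "Lac C2": "Lac", "Lac C3": "Lac", "Ala C3": "Ala",
    "Glu C2": "Glu", "Glu C3": "Glu", "Glu C4": "Glu",
    "Gln C2": "Gln", "Gln C3": "Gln", "Gln C4": "Gln",
    "Pyr C3": "Pyr", "Mal C2": "Mal", "Mal C3": "Mal",
    "AcCar C2": "AcCar", "Ace C2": "Ace", "Succ C2": "Succ",
    "NAA C6": "NAA", "NAA C3": "NAA", "Cr C4": "Cr", "Cr C2": "Cr",
}

# basal metabolite pools, a.u. per mg of tissue
BASAL_POOLS = {
    "brain_cortex": {"Lac": 12.0, "Ala": 4.0, "Glu": 10.0, "Gln": 6.0,
                     "Pyr": 1.2, "Mal": 1.0, "AcCar": 0.2, "Ace": 0.6,
                     "Succ": 0.8, "NAA": 8.0, "Cr": 7.0},
    "heart_apex": {"Lac": 10.0, "Ala": 4.5, "Glu": 9.0, "Gln": 7.0,
                   "Pyr": 1.6, "Mal": 1.4, "AcCar": 1.2, "Ace": 0.8,
                   "Succ": 1.0, "NAA": 0.5, "Cr": 6.0},
}

# 31P species pools, a.u. per mg; the DPG entry only exists in heart
P31_POOLS = {
    "brain_cortex": {"PE": 6.0, "PC": 5.0, "GPE": 3.0, "GPC": 4.0, "Pi": 8.0},
    "heart_apex": {"PE": 5.0, "PC": 4.0, "GPE": 3.5, "GPC": 4.5, "Pi": 9.0,
                   "DPG": 3.0},
}

TISSUE_PH = {"brain_cortex": (6.44, 0.08), "heart_apex": (6.35, 0.09)}

# calibration fluxes per (group, tissue); chosen to reproduce the qualitative
# labeling patterns of each infusion (glycolytic lactate dominant under
# 1-13C-glucose; Glx dominant with near-equal Lac C2/C3 under 2-13C-acetate,
# with the glial GS transfer above 1 in brain)
DEFAULT_FLUXES = {
    ("GLC", "brain_cortex"): FluxParams(pdh=1.0, pc=0.2, me=0.05, gs=0.5,
                                        acetate_uptake=0.0, glycolysis=1.0,
                                        dilution_unlabeled=0.5),
    ("GLC", "heart_apex"): FluxParams(pdh=1.0, pc=0.02, me=0.03, gs=0.4,
                                      acetate_uptake=0.0, glycolysis=1.0,
                                      dilution_unlabeled=0.5),
    ("ACE", "brain_cortex"): FluxParams(pdh=1.0, pc=0.2, me=0.35, gs=1.3,
                                        acetate_uptake=1.2, glycolysis=1.0,
                                        dilution_unlabeled=0.4),
    ("ACE", "heart_apex"): FluxParams(pdh=1.0, pc=0.02, me=0.12, gs=0.45,
                                      acetate_uptake=1.5, glycolysis=1.0,
                                      dilution_unlabeled=0.4),
}


def default_flux(group: str, tissue: str) -> FluxParams:
    return DEFAULT_FLUXES[(group, tissue)]


# ---------------------------------------------------------------------------
# cohort configuration and generation
# ---------------------------------------------------------------------------

class CohortConfig(BaseModel):
    """One experimental group's cohort parameters (study-design defaults)."""

    group: Literal["CTR", "GLC", "ACE"]
    n_mothers: int = Field(ge=1)
    fetuses_per_horn: int = Field(default=7, ge=1)
    stillbirth_prob_fgr: float = Field(default=0.55, ge=0.0, le=1.0)
    stillbirth_prob_aga: float = Field(default=0.14, ge=0.0, le=1.0)
    birthweight_aga_g: tuple[float, float] = (48.2, 0.9)     # mean, sd
    birthweight_fgr_g: tuple[float, float] = (34.3, 4.1)
    placental_aga_g: tuple[float, float] = (6.9, 0.3)
    placental_fgr_g: tuple[float, float] = (4.3, 1.7)
    net_weight_mg: tuple[float, float] = (49.7, 3.0)
    n_select_per_horn: int | None = None   # HRMAS sub-cohort size per horn (group total)
    tissues: tuple[str, ...] = ("brain_cortex", "heart_apex")
    seed: int = 0

    @model_validator(mode="after")
    def _check_sds(self):
        for name in ("birthweight_aga_g", "birthweight_fgr_g",
                     "placental_aga_g", "placental_fgr_g", "net_weight_mg"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name}: SD must be >= 0")
        return self


#: per-group study-design defaults (mothers, selected fetuses per horn, weights)
def cohort_config_for_group(group: str, seed: int = 0) -> CohortConfig:
    presets = {
        "CTR": dict(n_mothers=2, n_select_per_horn=3,
                    birthweight_aga_g=(48.2, 0.9), placental_aga_g=(6.9, 0.3)),
        "GLC": dict(n_mothers=4, n_select_per_horn=6,
                    birthweight_aga_g=(55.5, 5.8), birthweight_fgr_g=(34.3, 4.1),
                    placental_aga_g=(5.7, 1.3), placental_fgr_g=(4.3, 1.7)),
        "ACE": dict(n_mothers=3, n_select_per_horn=6,
                    birthweight_aga_g=(51.0, 2.4), birthweight_fgr_g=(33.1, 5.5),
                    placental_aga_g=(5.1, 2.0), placental_fgr_g=(5.5, 1.6)),
    }
    return CohortConfig(group=group, seed=seed, **presets[group])


@dataclass
class Cohort:
    """Surviving, HRMAS-selected samples plus cohort bookkeeping."""

    records: list[SampleRecord]
    n_induced: dict[str, int]          # horn -> fetuses at induction
    n_stillborn: dict[str, int]
    empty_horns: list[tuple[str, str]]  # (mother_id, horn) with no survivors

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lower: float) -> float:
    if sd == 0:
        return max(mean, lower)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)
    return lower


def sample_rng(master_seed: int, fetus_id: str, tissue: str) -> np.random.Generator:
    """Per-sample RNG stream derived from (master seed, fetus, tissue)."""
    return np.random.default_rng(
        [int(master_seed), zlib.crc32(fetus_id.encode()),
         _TISSUE_CODE[tissue]])


def make_cohort(config: CohortConfig) -> Cohort:
    """Simulate one experimental group's litters and HRMAS sample selection.

    Stillbirth is Bernoulli per fetus; birth and placental weights are
    truncated normals.  The control group has no FGR horn (no ligation was
    needed to provide natural-abundance reference tissue).  A horn whose
    fetuses all die is recorded in ``empty_horns`` rather than raising.
    """
    rng = np.random.default_rng([int(config.seed), zlib.crc32(config.group.encode())])
    horns = ("AGA",) if config.group == "CTR" else ("AGA", "FGR")
    records: list[SampleRecord] = []
    n_induced = {h: 0 for h in horns}
    n_still = {h: 0 for h in horns}
    empty = []
    survivors: dict[str, list[tuple[str, int]]] = {h: [] for h in horns}
    for m in range(1, config.n_mothers + 1):
        mother_id = f"{config.group}-M{m}"
        for horn in horns:
            p_still = (config.stillbirth_prob_fgr if horn == "FGR"
                       else config.stillbirth_prob_aga)
            n_induced[horn] += config.fetuses_per_horn
            alive = [k for k in range(1, config.fetuses_per_horn + 1)
                     if rng.random() >= p_still]
            n_still[horn] += config.fetuses_per_horn - len(alive)
            if not alive:
                empty.append((mother_id, horn))
                continue
            survivors[horn].extend((mother_id, k) for k in alive)
    for horn in horns:
        chosen = survivors[horn]
        if config.n_select_per_horn is not None and len(chosen) > config.n_select_per_horn:
            idx = sorted(rng.choice(len(chosen), config.n_select_per_horn,
                                    replace=False).tolist())
            chosen = [chosen[i] for i in idx]
        bw_mean, bw_sd = (config.birthweight_fgr_g if horn == "FGR"
                          else config.birthweight_aga_g)
        pl_mean, pl_sd = (config.placental_fgr_g if horn == "FGR"
                          else config.placental_aga_g)
        for mother_id, k in chosen:
            fetus_id = f"{mother_id}-{horn}-F{k}"
            bw = _truncnorm(rng, bw_mean, bw_sd, 5.0)
            pl = _truncnorm(rng, pl_mean, pl_sd, 0.5)
            for tissue in config.tissues:
                net = _truncnorm(rng, *config.net_weight_mg, 5.0)
                records.append(SampleRecord(
                    fetus_id=fetus_id, mother_id=mother_id, horn=horn,
                    group=config.group, tissue=tissue,
                    rotor_total_weight_mg=EMPTY_ROTOR_MG + D2O_WEIGHT_MG + net,
                    net_tissue_weight_mg=net,
                    birthweight_g=bw, placental_weight_g=pl))
    return Cohort(records=records, n_induced=n_induced, n_stillborn=n_still,
                  empty_horns=empty)


# ---------------------------------------------------------------------------
# ground-truth metabolic states
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Multiplicative FGR effect factors on the synthetic ground truth.

    ``label_effects`` scale the tracer-derived labeled *excess* of specific
    metabolite carbons in FGR samples of the groups listed in
    ``label_groups``.  ``pde_factor`` is the phosphodiester accumulation
    factor: infused AGA hearts carry GPE/GPC pools divided by it, so FGR and
    non-infused control hearts exceed them by that factor.
    """

    label_effects: dict[tuple[str, str], float] = field(default_factory=lambda: {
        ("brain_cortex", "Lac C2"): 0.77,
        ("brain_cortex", "Lac C3"): 0.80,
        ("heart_apex", "Gln C4"): 0.77,
    })
    label_groups: tuple[str, ...] = ("ACE",)
    pde_factor: dict[str, float] = field(default_factory=lambda: {
        "ACE": 1.5, "GLC": 1.05})
    pde_species: tuple[str, ...] = ("GPE", "GPC")

    def validate_positions(self) -> None:
        for (tissue, pos) in self.label_effects:
            if tissue not in _TISSUE_CODE:
                raise ValueError(f"unknown tissue in effects: {tissue!r}")
            if pos not in POSITION_METABOLITE:
                raise ValueError(f"unknown metabolite position in effects: {pos!r}")


@dataclass
class TrueMetabolicState:
    """Ground truth for one sample: pools, labeled fractions, 31P, pH, drift."""

    tissue: str
    group: str
    horn: str
    net_weight_mg: float
    basal_pool: dict[str, float]          # position -> a.u. per mg
    labeled_fraction: dict[str, float]    # position -> fraction in [na, 1]
    p31_pool: dict[str, float]            # species -> a.u. per mg
    tissue_ph: float
    drift_rates: dict[str, float] = field(default_factory=dict)  # relative / h

    def __post_init__(self) -> None:
        for k, v in self.labeled_fraction.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"labeled fraction out of range for {k}: {v}")
        for k, v in self.basal_pool.items():
            if v < 0:
                raise ValueError(f"negative pool for {k}")

    def drift_factor(self, position: str, time_h: float) -> float:
        return 1.0 + self.drift_rates.get(position, 0.0) * time_h


def default_drift_rates() -> dict[str, float]:
    return {"Gln C4": DRIFT_RATE_PER_H, "Lac C2": DRIFT_RATE_PER_H,
            "Lac C3": DRIFT_RATE_PER_H}


def assign_true_state(sample: SampleRecord, flux: FluxParams | None,
                      effects: EffectSpec, *, master_seed: int = 0,
                      profile: IsotopomerProfile | None = None,
                      cv: float = BIOLOGICAL_CV,
                      drift: bool = True) -> TrueMetabolicState:
    """Draw one sample's ground truth given fluxes and FGR effect factors.

    Control samples sit at natural abundance everywhere.  For infused
    samples the positional labeled excess comes from
    :func:`isoflux.label_propagation.propagate` (or a precomputed
    ``profile``), with per-sample lognormal biological variation of
    coefficient ``cv``, then FGR samples are scaled by the configured
    effect factors.
    """
    effects.validate_positions()
    rng = sample_rng(master_seed, sample.fetus_id, sample.tissue)
    na = NATURAL_ABUNDANCE
    substrate = SUBSTRATE_BY_GROUP[sample.group]

    def jitter() -> float:
        return float(np.exp(rng.normal(0.0, cv))) if cv > 0 else 1.0

    met_factor = {met: jitter() for met in BASAL_POOLS[sample.tissue]}
    pools = {pos: BASAL_POOLS[sample.tissue][met] * met_factor[met]
             for pos, met in POSITION_METABOLITE.items()
             if met in BASAL_POOLS[sample.tissue]}

    fractions = {pos: na for pos in pools}
    if substrate is not None:
        if profile is None:
            if flux is None:
                flux = default_flux(sample.group, sample.tissue)
            profile = propagate(substrate, flux,
                                enrichment=EFFECTIVE_ENRICHMENT[substrate])
        for pos in pools:
            if pos in profile.fractions:
                excess = profile.excess(pos)
            elif pos == "Ace C2" and substrate == "ace_2_13C":
                excess = EFFECTIVE_ENRICHMENT[substrate] - na  # free acetate
            else:
                continue
            excess *= jitter()
            if sample.horn == "FGR" and sample.group in effects.label_groups:
                excess *= effects.label_effects.get((sample.tissue, pos), 1.0)
            fractions[pos] = min(na + excess, 1.0)

    p31 = {sp: v * jitter() for sp, v in P31_POOLS[sample.tissue].items()}
    if (substrate is not None and sample.horn == "AGA"
            and sample.tissue == "heart_apex"):
        f = effects.pde_factor.get(sample.group, 1.0)
        for sp in effects.pde_species:
            p31[sp] /= f

    ph_mean, ph_sd = TISSUE_PH[sample.tissue]
    # ex-vivo tissue pH stays well inside the phosphate titration range
    ph = float(np.clip(rng.normal(ph_mean, ph_sd), 6.05, 7.4))
    return TrueMetabolicState(
        tissue=sample.tissue, group=sample.group, horn=sample.horn,
        net_weight_mg=sample.net_tissue_weight_mg,
        basal_pool=pools, labeled_fraction=fractions, p31_pool=p31,
        tissue_ph=ph,
        drift_rates=default_drift_rates() if drift else {})


def state_from_incorporation(percents: dict[str, float], tissue: str, *,
                             total_excess_au: float = 2.0,
                             net_weight_mg: float = 49.7,
                             rng: np.random.Generator | None = None,
                             cv: float = BIOLOGICAL_CV,
                             group: str = "ACE", horn: str = "AGA") -> TrueMetabolicState:
    """Ground truth whose labeled-excess *volumes* follow given percent shares.

    Used to generate cohorts directly from an incorporation table: position
    ``i`` receives excess volume ``total_excess_au * percents[i] / 100`` a.u.
    per mg, converted to a fraction through its basal pool.
    """
    na = NATURAL_ABUNDANCE
    jitter = ((lambda: float(np.exp(rng.normal(0.0, cv))))
              if rng is not None and cv > 0 else (lambda: 1.0))
    met_factor = {met: jitter() for met in BASAL_POOLS[tissue]}
    pools = {pos: BASAL_POOLS[tissue][met] * met_factor[met]
             for pos, met in POSITION_METABOLITE.items()
             if met in BASAL_POOLS[tissue]}
    fractions = {pos: na for pos in pools}
    for pos, pct in percents.items():
        if pos not in pools:
            raise KeyError(f"unknown position {pos!r}")
        excess = total_excess_au * pct / 100.0 / pools[pos] * jitter()
        fractions[pos] = min(na + excess, 1.0)
    return TrueMetabolicState(
        tissue=tissue, group=group, horn=horn, net_weight_mg=net_weight_mg,
        basal_pool=pools, labeled_fraction=fractions,
        p31_pool=dict(P31_POOLS[tissue]),
        tissue_ph=TISSUE_PH[tissue][0], drift_rates={})


# ---------------------------------------------------------------------------
# spectrum renderers
# ---------------------------------------------------------------------------

def render_cpmg(state: TrueMetabolicState, noise_sd: float = 30.0,
                window: tuple[float, float] = (0.9, 2.7), *,
                rng: np.random.Generator | None = None,
                time_h: float = 0.0, dppm: float = 0.0005,
                fwhm_hz: float = ls.FWHM_1D_HZ, eta: float = ls.ETA_1D,
                j_hh_hz: float = J_HH_HZ, j_ch_hz: float = J_CH_HZ,
                mm_baseline_scale: float = 0.25) -> Spectrum1D:
    """Render a 1H CPMG spectrum (400.13 MHz) of the lactate/glutamine region.

    Lactate appears as a J = 6.9 Hz CH3 doublet at 1.32 ppm for the unlabeled
    pool plus two satellite doublets displaced +/- half the one-bond C-H
    coupling for the labeled pool; alanine CH3 sits at 1.47 ppm, the
    glutamine C4 multiplet at 2.45 ppm, succinate at 2.41 ppm, and two broad
    Gaussians model the residual lipid/macromolecule background of the
    1.54-1.14 ppm region.  Amplitudes are pools x net tissue weight, so the
    weight normalization of the quantifiers is exercised.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not (window[0] <= 1.14 and window[1] >= 2.50):
        raise ValueError("window must cover 1.14-2.50 ppm")
    rng = rng or np.random.default_rng()
    x = np.arange(window[0], window[1] + dppm / 2, dppm)
    y = np.zeros_like(x)
    fwhm = fwhm_hz / H_FREQ_MHZ
    j_hh = j_hh_hz / H_FREQ_MHZ
    j_ch = j_ch_hz / H_FREQ_MHZ
    w = state.net_weight_mg

    lac_pool = state.basal_pool.get("Lac C3", 0.0) * w * state.drift_factor("Lac C3", time_h)
    f_lac = state.labeled_fraction.get("Lac C3", NATURAL_ABUNDANCE)
    y += ls.doublet(x, lac_pool * (1 - f_lac), 1.32, j_hh, fwhm, eta)
    y += ls.doublet(x, lac_pool * f_lac / 2, 1.32 - j_ch / 2, j_hh, fwhm, eta)
    y += ls.doublet(x, lac_pool * f_lac / 2, 1.32 + j_ch / 2, j_hh, fwhm, eta)

    ala_pool = state.basal_pool.get("Ala C3", 0.0) * w
    f_ala = state.labeled_fraction.get("Ala C3", NATURAL_ABUNDANCE)
    y += ls.doublet(x, ala_pool * (1 - f_ala), 1.47, j_hh, fwhm, eta)

    gln_pool = state.basal_pool.get("Gln C4", 0.0) * w * state.drift_factor("Gln C4", time_h)
    y += ls.multiplet(x, gln_pool, 2.45, 0.0075, (1, 2, 1), fwhm, eta)
    glu_pool = state.basal_pool.get("Glu C4", 0.0) * w
    y += ls.multiplet(x, glu_pool, 2.34, 0.0075, (1, 2, 1), fwhm, eta)
    for pos, center in (("Succ C2", 2.41), ("Ace C2", 1.92), ("NAA C6", 2.01)):
        pool = state.basal_pool.get(pos, 0.0) * w
        if pool > 0:
            y += ls.pseudo_voigt(x, pool, center, fwhm, eta)

    mm = mm_baseline_scale * lac_pool
    y += ls.gaussian(x, mm, 1.25, 40.0 / H_FREQ_MHZ)
    y += ls.gaussian(x, mm, 1.43, 40.0 / H_FREQ_MHZ)

    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, x.size)
    return Spectrum1D(ppm=x, intensity=y, nucleus="1H",
                      meta={"time_h": time_h, "tissue": state.tissue})


def render_hsqc(state: TrueMetabolicState, template: ROITemplate,
                noise_sd: float = 20.0, *,
                rng: np.random.Generator | None = None, time_h: float = 0.0,
                h_range: tuple[float, float] = (0.8, 5.4),
                c_range: tuple[float, float] = (5.0, 105.0),
                dh: float = 0.004, dc: float = 0.2,
                fwhm_h: float = 0.01, fwhm_c: float = 0.5) -> Spectrum2D:
    """Render a 2D 1H-13C HSQC grid from positional labeled fractions.

    Each metabolite carbon contributes a 2D Gaussian centered in its template
    ROI with volume = pool x labeled fraction x net weight (x drift), so only
    13C-attached protons are visible, as in the experiment.  Noise regions
    contain only noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = rng or np.random.default_rng()
    h_axis = np.arange(h_range[0], h_range[1] + dh / 2, dh)
    c_axis = np.arange(c_range[0], c_range[1] + dc / 2, dc)
    grid = np.zeros((c_axis.size, h_axis.size))
    w = state.net_weight_mg
    sh = fwhm_h / (2 * np.sqrt(2 * np.log(2)))
    sc = fwhm_c / (2 * np.sqrt(2 * np.log(2)))

    for pos, pool in state.basal_pool.items():
        try:
            roi = template[pos]
        except KeyError:
            continue
        hc, cc = roi.h_center, roi.c_center
        if not (h_range[0] < hc < h_range[1]) or not (c_range[0] < cc < c_range[1]):
            raise ValueError(f"peak center of ROI {pos!r} outside spectral width")
        vol = pool * w * state.labeled_fraction[pos] * state.drift_factor(pos, time_h)
        if vol <= 0:
            continue
        ih = slice(np.searchsorted(h_axis, hc - 6 * sh),
                   np.searchsorted(h_axis, hc + 6 * sh))
        ic = slice(np.searchsorted(c_axis, cc - 6 * sc),
                   np.searchsorted(c_axis, cc + 6 * sc))
        grid[ic, ih] += ls.gaussian2d(h_axis[ih], c_axis[ic], vol, hc, cc,
                                      fwhm_h, fwhm_c)
    if noise_sd > 0:
        grid = grid + rng.normal(0.0, noise_sd, grid.shape)
    return Spectrum2D(ppm_h=h_axis, ppm_c=c_axis, grid=grid,
                      meta={"time_h": time_h, "tissue": state.tissue})


def render_p31(state: TrueMetabolicState, noise_sd: float = 5.0, *,
               rng: np.random.Generator | None = None,
               window: tuple[float, float] = (-1.0, 6.5),
               dppm: float = 0.002, fwhm: float = 0.03,
               eta: float = ls.ETA_1D) -> Spectrum1D:
    """Render a 1H-decoupled 31P spectrum referenced to GPE at 1.00 ppm.

    PE, PC, GPE, GPC and Pi appear as narrow peaks; the Pi position encodes
    tissue pH through the phosphate titration curve.  Heart spectra carry an
    extra 2,3-diphosphoglycerate contribution overlapping the PC region.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not (5.5 <= state.tissue_ph <= 7.8):
        raise ValueError(f"pH {state.tissue_ph} outside titration range [5.5, 7.8]")
    rng = rng or np.random.default_rng()
    x = np.arange(window[0], window[1] + dppm / 2, dppm)
    y = np.zeros_like(x)
    w = state.net_weight_mg
    for sp in ("PE", "PC", "GPE", "GPC"):
        pool = state.p31_pool.get(sp, 0.0)
        if pool > 0:
            y += ls.pseudo_voigt(x, pool * w, P31_SHIFTS_STD[sp] - GPE_REF_OFFSET,
                                 fwhm, eta)
    pi_pool = state.p31_pool.get("Pi", 0.0)
    if pi_pool > 0:
        pi_pos = pi_shift_from_ph(state.tissue_ph) - GPE_REF_OFFSET
        y += ls.pseudo_voigt(x, pi_pool * w, pi_pos, fwhm, eta)
    dpg = state.p31_pool.get("DPG", 0.0)
    if dpg > 0 and state.tissue == "heart_apex":
        y += ls.pseudo_voigt(x, dpg * w / 2, 3.70, fwhm, eta)
        y += ls.pseudo_voigt(x, dpg * w / 2, 3.82, fwhm, eta)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, x.size)
    return Spectrum1D(ppm=x, intensity=y, nucleus="31P",
                      meta={"tissue": state.tissue, "true_ph": state.tissue_ph})
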