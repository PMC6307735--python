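"""End-to-end orchestration: simulate -> quantify -> analyze -> compare.

The bundled "study-default" scenario reproduces the study design: 9 mothers
(2 non-infused controls, 4 glucose-infused, 3 acetate-infused), littermate
AGA/FGR horns, brain cortex and heart apex samples per fetus, 3 samples
dropped at random (mirroring spectrometer-loading losses), HRMAS session
rendered with drift between the initial and final proton spectra.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import cohort_stats, isotopomer_analysis as iso, spectral_quant as sq
from .core import SUBSTRATE_BY_GROUP, SampleRecord, records_to_manifest
from .roi_template import default_template
from .synthetic_data import (CohortConfig, EffectSpec, assign_true_state,
                             cohort_config_for_group, default_flux,
                             make_cohort, render_cpmg, render_hsqc, render_p31)

log = logging.getLogger(__name__)

#: labeled positions compared between FGR and AGA per substrate
COMPARED_POSITIONS = {
    "GLC": ("Ala C3", "Lac C3", "Lac C2", "Gln C4", "Glu C4", "Glu C3", "Glu C2"),
    "ACE": ("Ala C3", "Lac C3", "Lac C2", "Gln C4", "Glu C4", "Glu C3", "Glu C2"),
}


class NoiseConfig(BaseModel):
    cpmg: float = Field(default=30.0, ge=0)
    hsqc: float = Field(default=20.0, ge=0)
    p31: float = Field(default=5.0, ge=0)


class RunConfig(BaseModel):
    """Fully serializable configuration of one pipeline run."""

    scenario: str = "study-default"
    seed: int = 0
    groups: tuple[str, ...] = ("CTR", "GLC", "ACE")
    cohorts: dict[str, CohortConfig] = {}
    noise: NoiseConfig = NoiseConfig()
    drift: bool = True
    lactate_method: str = "deconvolution"   # or "integration"
    n_dropped_samples: int = 3
    t_initial_h: float = 0.57               # first CPMG, h of HRMAS time
    t_hsqc_h: float = 2.2
    t_final_h: float = 3.4
    write_spectra: bool = False

    def model_post_init(self, _ctx) -> None:
        for g in self.groups:
            if g not in self.cohorts:
                self.cohorts[g] = cohort_config_for_group(g, seed=self.seed)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def study_default_config(seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed)


def _measurement_rng(seed: int, sample: SampleRecord) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(sample.sample_id.encode()), 7])


@dataclass
class PipelineResult:
    manifest: pd.DataFrame
    truth: pd.DataFrame
    quant: pd.DataFrame
    enrichment: pd.DataFrame | None
    incorporation: dict[tuple[str, str], object]
    p31: pd.DataFrame
    cpmg: pd.DataFrame
    comparisons: list
    flux_ratios: dict
    report: str
    failed_samples: list[str] = dc_field(default_factory=list)


def _process_sample(sample, config, template, effects) -> dict:
    flux = None
    if SUBSTRATE_BY_GROUP[sample.group] is not None:
        flux = default_flux(sample.group, sample.tissue)
    state = assign_true_state(sample, flux, effects, master_seed=config.seed,
                              drift=config.drift)
    rng = _measurement_rng(config.seed, sample)
    t_hsqc = config.t_hsqc_h if config.drift else 0.0
    hsqc = render_hsqc(state, template, config.noise.hsqc, rng=rng, time_h=t_hsqc)
    quant = sq.integrate_roi(hsqc, template, sample)

    out = {"state": state, "quant": quant, "spectra": {}}
    t0 = config.t_initial_h if config.drift else 0.0
    t1 = config.t_final_h if config.drift else 0.0
    cpmg_rows = []
    if sample.group == "ACE":
        for label, t in (("initial", t0), ("final", t1)):
            spec = render_cpmg(state, config.noise.cpmg, rng=rng, time_h=t)
            out["spectra"][f"cpmg_{label}"] = spec
            row = {"sample_id": sample.sample_id, "phase": label}
            if sample.tissue == "brain_cortex":
                dec = sq.deconvolve_lactate(spec)
                pools = iso.pools_from_cpmg(dec)
                row.update(variable="lactate",
                           lac_total=sq.normalize_to_weight(pools["lac_total"], sample),
                           lac_13c=sq.normalize_to_weight(pools["lac_13c"], sample),
                           flagged=pools["flagged"])
            else:
                area = sq.integrate_glutamine(spec)
                row.update(variable="glutamine",
                           gln_total=sq.normalize_to_weight(area, sample),
                           flagged=False)
            cpmg_rows.append(row)
    out["cpmg_rows"] = cpmg_rows

    p31_spec = render_p31(state, config.noise.p31, rng=rng)
    out["spectra"]["p31"] = p31_spec
    pq = sq.quantify_p31(p31_spec, sample.tissue)
    p31_row = {"sample_id": sample.sample_id, "ph": pq.ph,
               "pi_shift_ppm": pq.pi_shift_std}
    for sp, area in pq.areas.items():
        p31_row[sp] = (sq.normalize_to_weight(area, sample)
                       if np.isfinite(area) else np.nan)
    p31_row["GPE+GPC"] = p31_row["GPE"] + p31_row["GPC"]
    out["p31_row"] = p31_row
    return out


def run_pipeline(config: RunConfig, outdir: str | Path | None = None,
                 effects: EffectSpec | None = None) -> PipelineResult:
    """Run the full synthetic study and FGR-vs-AGA analysis.

    Deterministic given ``config.seed``.  Per-sample failures are isolated
    and flagged; the run fails only if more than 20% of samples flag.
    """
    effects = effects or EffectSpec()
    template = default_template()
    rng = np.random.default_rng([config.seed, 101])

    records: list[SampleRecord] = []
    for g in config.groups:
        cohort_cfg = config.cohorts[g].model_copy(update={"seed": config.seed})
        records.extend(make_cohort(cohort_cfg).records)
    if config.n_dropped_samples and len(records) > config.n_dropped_samples:
        drop = set(rng.choice(len(records), config.n_dropped_samples,
                              replace=False).tolist())
        records = [r for i, r in enumerate(records) if i not in drop]
    manifest = records_to_manifest(records)

    quant_parts, p31_rows, cpmg_rows, truth_rows = [], [], [], []
    failed = []
    spectra_out = {}
    for sample in records:
        try:
            res = _process_sample(sample, config, template, effects)
        except Exception as exc:   # isolate per-sample failures
            log.error("sample %s failed: %s", sample.sample_id, exc)
            failed.append(sample.sample_id)
            continue
        quant_parts.append(res["quant"])
        p31_rows.append(res["p31_row"])
        cpmg_rows.extend(res["cpmg_rows"])
        spectra_out[sample.sample_id] = res["spectra"]
        st = res["state"]
        for pos, frac in st.labeled_fraction.items():
            truth_rows.append({"sample_id": sample.sample_id, "position": pos,
                               "pool_au_per_mg": st.basal_pool[pos],
                               "labeled_fraction": frac})
    if failed and len(failed) > 0.2 * len(records):
        raise RuntimeError(f"more than 20% of samples failed: {failed}")

    quant = pd.concat(quant_parts, ignore_index=True)
    p31 = pd.DataFrame(p31_rows)
    cpmg = pd.DataFrame(cpmg_rows)
    truth = pd.DataFrame(truth_rows)

    infused = [g for g in config.groups if SUBSTRATE_BY_GROUP[g] is not None]
    enrichment = None
    incorporation = {}
    fluxr = {}
    comparisons = []
    if infused and "CTR" in config.groups:
        ctr_ref = iso.ctr_reference(quant, manifest)
        enrichment = iso.enrichment_table(quant, manifest, ctr_ref)
        meta = manifest.set_index("sample_id")
        for g in infused:
            for tissue in ("brain_cortex", "heart_apex"):
                ids = meta.index[(meta["group"] == g) & (meta["tissue"] == tissue)]
                sub = quant[quant["sample_id"].isin(ids)]
                if sub.empty:
                    continue
                try:
                    ctr_means = ctr_ref.loc[tissue]
                    incorporation[(g, tissue)] = iso.incorporation_fractions(
                        sub, ctr_means)
                except (ValueError, KeyError) as exc:
                    log.warning("incorporation for %s/%s skipped: %s", g, tissue, exc)
        # FGR vs AGA on labeled excess, per group/tissue/position
        for g in infused:
            for tissue in ("brain_cortex", "heart_apex"):
                for pos in COMPARED_POSITIONS[g]:
                    sub = enrichment[(enrichment["group"] == g)
                                     & (enrichment["tissue"] == tissue)
                                     & (enrichment["roi"] == pos)]
                    a = sub[sub["horn"] == "AGA"]["excess"].to_numpy()
                    f = sub[sub["horn"] == "FGR"]["excess"].to_numpy()
                    if a.size >= 2 and f.size >= 2:
                        comparisons.append(cohort_stats.compare_groups(
                            a, f, variable=pos, tissue=tissue, group=g))
        # PC/PDH and PC/ME from glucose-infused brains (mean AGA enrichment)
        if "GLC" in infused:
            sub = enrichment[(enrichment["group"] == "GLC")
                             & (enrichment["tissue"] == "brain_cortex")
                             & (enrichment["horn"] == "AGA")]
            means = sub.groupby("roi")["positional_enrichment_pct"].mean()
            if {"Glu C2", "Glu C3", "Glu C4"} <= set(means.index):
                fluxr["GLC brain (AGA)"] = iso.flux_ratios(means.to_dict())

    # 31P contrasts
    p31m = p31.merge(manifest[["sample_id", "group", "tissue", "horn"]],
                     on="sample_id")
    for g in infused:
        for tissue in ("brain_cortex", "heart_apex"):
            sub = p31m[(p31m["group"] == g) & (p31m["tissue"] == tissue)]
            for sp in ("PE", "PC", "GPE", "GPC", "Pi", "GPE+GPC"):
                a = sub[sub["horn"] == "AGA"][sp].dropna().to_numpy()
                f = sub[sub["horn"] == "FGR"][sp].dropna().to_numpy()
                if a.size >= 2 and f.size >= 2:
                    comparisons.append(cohort_stats.compare_groups(
                        a, f, variable=f"31P {sp}", tissue=tissue, group=g))

    # CPMG-derived pools (acetate group)
    if not cpmg.empty:
        cm = cpmg.merge(manifest[["sample_id", "tissue", "horn", "group"]],
                        on="sample_id")
        ini = cm[cm["phase"] == "initial"]
        for var, col, tissue in (("Lac total", "lac_total", "brain_cortex"),
                                 ("Lac 13C", "lac_13c", "brain_cortex"),
                                 ("Gln total", "gln_total", "heart_apex")):
            sub = ini[ini["tissue"] == tissue]
            a = sub[sub["horn"] == "AGA"][col].dropna().to_numpy()
            f = sub[sub["horn"] == "FGR"][col].dropna().to_numpy()
            if a.size >= 2 and f.size >= 2:
                comparisons.append(cohort_stats.compare_groups(
                    a, f, variable=f"1H {var}", tissue=tissue, group="ACE"))

    report = _format_report(config, manifest, comparisons, fluxr,
                            enrichment is not None)
    result = PipelineResult(manifest=manifest, truth=truth, quant=quant,
                            enrichment=enrichment, incorporation=incorporation,
                            p31=p31, cpmg=cpmg, comparisons=comparisons,
                            flux_ratios=fluxr, report=report,
                            failed_samples=failed)
    if outdir is not None:
        _write_outputs(result, config, Path(outdir), spectra_out)
    return result


def _format_report(config, manifest, comparisons, fluxr, has_enrichment) -> str:
    lines = [f"scenario: {config.scenario}", f"seed: {config.seed}",
             f"samples: {len(manifest)}", ""]
    lines.append(f"statistical tests performed: {len(comparisons)} "
                 "(no multiple-testing correction applied)")
    sig = [c for c in comparisons if c.significant]
    lines.append("")
    lines.append("significant FGR vs AGA contrasts (p < 0.05):")
    if not sig:
        lines.append("  none")
    for c in sorted(sig, key=lambda c: c.p_value):
        stars = "***" if c.p_value < 0.001 else "**" if c.p_value < 0.01 else "*"
        lines.append(f"  {stars:3s} {c.group} {c.tissue} {c.variable}: "
                     f"{c.percent_difference:+.1f}% (p = {c.p_value:.4f}, "
                     f"n = {c.n_aga}/{c.n_fgr})")
    if has_enrichment:
        lines.append("")
        lines.append("enrichment vs natural-abundance controls computed "
                     "(see enrichment.csv)")
    for name, fr in fluxr.items():
        lines.append(f"{name}: PC/PDH = {fr.pc_over_pdh:.2f}, "
                     f"PC/ME = {fr.pc_over_me:.2f}  [{fr.formulas['pc_over_pdh']}]")
    return "\n".join(lines) + "\n"


def _write_outputs(result: PipelineResult, config: RunConfig, outdir: Path,
                   spectra: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    result.manifest.to_csv(outdir / "manifest.csv", index=False)
    result.truth.to_csv(outdir / "truth.csv", index=False)
    result.quant.to_csv(outdir / "quant.csv", index=False)
    result.p31.to_csv(outdir / "p31.csv", index=False)
    if not result.cpmg.empty:
        result.cpmg.to_csv(outdir / "cpmg_pools.csv", index=False)
    if result.enrichment is not None:
        result.enrichment.to_csv(outdir / "enrichment.csv", index=False)
    for (g, tissue), table in result.incorporation.items():
        table.summary.to_csv(outdir / f"incorporation_{g}_{tissue}.csv")
    if result.comparisons:
        pd.DataFrame([vars(c) | {"significant": c.significant}
                      for c in result.comparisons]).to_csv(
            outdir / "comparisons.csv", index=False)
    (outdir / "report.txt").write_text(result.report)
    if config.write_spectra:
        sdir = outdir / "spectra"
        sdir.mkdir(exist_ok=True)
        for sid, specs in spectra.items():
            for name, spec in specs.items():
                spec.to_txt(sdir / f"{sid}_{name}.txt")


# ---------------------------------------------------------------------------
# incorporation parameter recovery
# ---------------------------------------------------------------------------

def simulate_incorporation_recovery(percents: dict[str, float], tissue: str,
                                    seed: int, *, n_samples: int = 12,
                                    n_ctr: int = 3,
                                    noise: NoiseConfig | None = None):
    """Generate a cohort whose true labeling follows ``percents`` and re-measure it.

    Renders HSQC spectra for ``n_samples`` infused samples (true labeled-excess
    volumes proportional to the given percent shares, with biological
    variability) plus ``n_ctr`` natural-abundance controls, quantifies them,
    and returns the measured incorporation table over the same isotopomer set.
    """
    from .synthetic_data import state_from_incorporation
    noise = noise or NoiseConfig()
    template = default_template()
    rng = np.random.default_rng([seed, 55])
    quant_parts, ctr_parts = [], []
    for i in range(n_samples + n_ctr):
        is_ctr = i >= n_samples
        sample = SampleRecord(
            fetus_id=f"REC-M1-AGA-F{i}", mother_id="REC-M1", horn="AGA",
            group="CTR" if is_ctr else "ACE", tissue=tissue,
            rotor_total_weight_mg=530.22 + 49.7, net_tissue_weight_mg=49.7,
            birthweight_g=50.0, placental_weight_g=5.0)
        state = state_from_incorporation({} if is_ctr else percents, tissue,
                                         rng=rng)
        spec = render_hsqc(state, template, noise.hsqc, rng=rng)
        q = sq.integrate_roi(spec, template, sample)
        (ctr_parts if is_ctr else quant_parts).append(q)
    ctr = pd.concat(ctr_parts)
    ctr_means = ctr.groupby("roi")["norm_volume"].mean()
    quant = pd.concat(quant_parts, ignore_index=True)
    return iso.incorporation_fractions(quant, ctr_means,
                                       isotopomer_set=tuple(percents))


# ---------------------------------------------------------------------------
# headline-effect power helper
# ---------------------------------------------------------------------------

HEADLINE_CONTRASTS = (
    ("brain_cortex", "Lac C2"), ("brain_cortex", "Lac C3"),
    ("heart_apex", "Gln C4"), ("heart_apex", "GPE+GPC"),
)


def headline_effect_pvalues(seed: int, *, effects: EffectSpec | None = None,
                            noise: NoiseConfig | None = None,
                            reference_ctr: bool = False) -> dict:
    """FGR-vs-AGA p-values for the four headline effects, acetate group only.

    Renders and quantifies the acetate cohort (6 AGA / 6 FGR fetuses) at the
    given seed and runs the unpaired two-tailed tests on normalized ROI
    volumes (shifting by the control mean does not change the t statistic)
    and on the 31P phosphodiester sum.  With ``reference_ctr`` a non-infused
    control cohort is also rendered and the labeled-metabolite contrasts are
    expressed on the labeled-excess scale (volume minus control mean), which
    is how the study reports its percent differences.
    """
    effects = effects or EffectSpec()
    noise = noise or NoiseConfig()
    template = default_template()
    cfg = cohort_config_for_group("ACE", seed=seed)
    cohort = make_cohort(cfg)
    records = list(cohort.records)
    if reference_ctr:
        ctr_cohort = make_cohort(cohort_config_for_group("CTR", seed=seed))
        records.extend(ctr_cohort.records)
    rows = []
    for sample in records:
        flux = (default_flux(sample.group, sample.tissue)
                if sample.group != "CTR" else None)
        state = assign_true_state(sample, flux, effects, master_seed=seed)
        rng = _measurement_rng(seed, sample)
        hsqc = render_hsqc(state, template, noise.hsqc, rng=rng)
        q = sq.integrate_roi(hsqc, template, sample).set_index("roi")
        if sample.tissue == "brain_cortex":
            rows.append({"horn": sample.horn, "group": sample.group,
                         "tissue": sample.tissue,
                         "Lac C2": q.loc["Lac C2", "norm_volume"],
                         "Lac C3": q.loc["Lac C3", "norm_volume"]})
        else:
            pq = sq.quantify_p31(render_p31(state, noise.p31, rng=rng),
                                 sample.tissue)
            rows.append({"horn": sample.horn, "group": sample.group,
                         "tissue": sample.tissue,
                         "Gln C4": q.loc["Gln C4", "norm_volume"],
                         "GPE+GPC": sq.normalize_to_weight(
                             pq.areas["GPE"] + pq.areas["GPC"], sample)})
    df = pd.DataFrame(rows)
    ace = df[df["group"] == "ACE"]
    ctr = df[df["group"] == "CTR"]
    out = {}
    for tissue, var in HEADLINE_CONTRASTS:
        sub = ace[ace["tissue"] == tissue]
        a = sub[sub["horn"] == "AGA"][var].dropna().to_numpy()
        f = sub[sub["horn"] == "FGR"][var].dropna().to_numpy()
        if reference_ctr and var != "GPE+GPC":
            ctr_mean = float(ctr[ctr["tissue"] == tissue][var].mean())
            a, f = a - ctr_mean, f - ctr_mean
        res = cohort_stats.compare_groups(a, f, variable=var, tissue=tissue)
        out[(tissue, var)] = {"p": res.p_value,
                              "percent_difference": res.percent_difference}
    return out
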