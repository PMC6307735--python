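"""Derived isotopomer quantities: enrichments, incorporation fractions,
lactate partition, flux ratios and glutamine-synthetase activity.

The central convention: positional 13C enrichment of an infused sample is
computed against the non-infused control group, which measures the 1.1%
natural-abundance baseline::

    ratio_excess            = (I_infused - I_control_mean) / I_control_mean
    positional_enrichment_% = 1.1 * ratio_excess

For 1-13C-glucose only half of de-novo three-carbon units are labeled
(C1/C6 symmetry of the fructose-1,6-bisphosphate cleavage), so the total
de-novo pool is twice the positional enrichment; for 2-13C-acetate the
correction factor is 1.

Incorporation fractions express each isotopomer's labeled excess as percent
of the summed excess over the quantified isotopomer set, with the derived
partitions::

    Lac C3' (glycolytic lactate)  = Lac C3 - Lac C2
    Lac C2C3 (TCA-cycle lactate)  = 2 * Lac C2
    TCAc                          = Glx + Lac C2C3
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import NATURAL_ABUNDANCE

log = logging.getLogger(__name__)

#: the seven principal isotopomers of the incorporation table
MAIN_ISOTOPOMERS = ("Ala C3", "Lac C3", "Lac C2", "Gln C4",
                    "Glu C4", "Glu C3", "Glu C2")
GLX_ISOTOPOMERS = ("Gln C4", "Glu C4", "Glu C3", "Glu C2")

#: minor labeled positions included in the default normalization set
MINOR_ISOTOPOMERS = ("Pyr C3", "Mal C2", "Mal C3", "AcCar C2")

CORRECTION_BY_SUBSTRATE = {"glc_1_13C": 2.0, "ace_2_13C": 1.0}


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRecord:
    sample_id: str
    position: str
    i_inf: float
    i_ctr_mean: float
    substrate: str
    ratio_excess: float = field(init=False)
    positional_enrichment_pct: float = field(init=False)
    denovo_total_pct: float = field(init=False)
    correction: float = field(init=False)

    def __post_init__(self) -> None:
        if self.i_ctr_mean <= 0:
            raise ValueError("control mean must be > 0 (no natural-abundance reference)")
        self.correction = CORRECTION_BY_SUBSTRATE[self.substrate]
        self.ratio_excess = max((self.i_inf - self.i_ctr_mean) / self.i_ctr_mean, -1.0)
        self.positional_enrichment_pct = 100.0 * NATURAL_ABUNDANCE * self.ratio_excess
        self.denovo_total_pct = self.correction * self.positional_enrichment_pct


def positional_enrichment(i_inf: float, i_ctr_mean: float,
                          substrate: str, *, sample_id: str = "",
                          position: str = "") -> EnrichmentRecord:
    """Enrichment of one ROI of one infused sample against the control mean."""
    return EnrichmentRecord(sample_id=sample_id, position=position,
                            i_inf=i_inf, i_ctr_mean=i_ctr_mean,
                            substrate=substrate)


def ctr_reference(quant: pd.DataFrame, manifest: pd.DataFrame) -> pd.Series:
    """Control-group mean normalized volume per (tissue, roi)."""
    merged = quant.merge(manifest[["sample_id", "group", "tissue"]], on="sample_id")
    ctr = merged[merged["group"] == "CTR"]
    if ctr.empty:
        raise ValueError("no control samples in quantification table")
    return ctr.groupby(["tissue", "roi"])["norm_volume"].mean()


def enrichment_table(quant: pd.DataFrame, manifest: pd.DataFrame,
                     ctr_ref: pd.Series, substrate_by_group=None) -> pd.DataFrame:
    """Per-sample, per-ROI enrichment of all infused samples."""
    from .core import SUBSTRATE_BY_GROUP
    substrate_by_group = substrate_by_group or SUBSTRATE_BY_GROUP
    merged = quant.merge(manifest[["sample_id", "group", "tissue", "horn"]],
                         on="sample_id")
    rows = []
    for _, r in merged.iterrows():
        substrate = substrate_by_group.get(r["group"])
        if substrate is None:
            continue
        key = (r["tissue"], r["roi"])
        if key not in ctr_ref.index or not ctr_ref[key] > 0:
            continue
        rec = positional_enrichment(r["norm_volume"], ctr_ref[key], substrate,
                                    sample_id=r["sample_id"], position=r["roi"])
        rows.append({"sample_id": r["sample_id"], "group": r["group"],
                     "tissue": r["tissue"], "horn": r["horn"], "roi": r["roi"],
                     "excess": r["norm_volume"] - ctr_ref[key],
                     "ratio_excess": rec.ratio_excess,
                     "positional_enrichment_pct": rec.positional_enrichment_pct,
                     "denovo_total_pct": rec.denovo_total_pct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# incorporation fractions
# ---------------------------------------------------------------------------

@dataclass
class IncorporationTable:
    """Per-sample isotopomer percentages and their pooled summary."""

    per_sample: pd.DataFrame    # index sample_id; columns isotopomers + derived
    summary: pd.DataFrame       # rows isotopomers + derived; columns mean, sd
    excluded: list[str] = field(default_factory=list)


def _derived_rows(pcts: pd.DataFrame) -> pd.DataFrame:
    out = pcts.copy()
    out["SUM (Ala+Lac+Glx)"] = pcts[list(MAIN_ISOTOPOMERS)].sum(axis=1)
    out["Glycolysis (Lac C3')"] = pcts["Lac C3"] - pcts["Lac C2"]
    out["TCAc (Glx+LacC2C3)"] = (pcts[list(GLX_ISOTOPOMERS)].sum(axis=1)
                                 + 2.0 * pcts["Lac C2"])
    return out


def incorporation_fractions(quant: pd.DataFrame, ctr_means: pd.Series | dict,
                            isotopomer_set: tuple[str, ...] = MAIN_ISOTOPOMERS + MINOR_ISOTOPOMERS,
                            ) -> IncorporationTable:
    """Percent-of-total-labeling incorporation per isotopomer.

    ``quant`` holds the normalized ROI volumes of the infused samples of one
    tissue and group (FGR and AGA pooled, as in the published table);
    ``ctr_means`` the control reference per ROI.  Per sample, excesses below
    zero are floored at zero; samples with no positive excess at all are
    excluded with a log entry.
    """
    missing = [r for r in isotopomer_set if r not in dict(ctr_means)]
    if missing:
        raise ValueError(f"control means missing for ROIs: {missing}")
    sub = quant[quant["roi"].isin(isotopomer_set)]
    wide = sub.pivot_table(index="sample_id", columns="roi", values="norm_volume")
    excess = wide.sub(pd.Series(dict(ctr_means))[list(isotopomer_set)], axis=1)
    excess = excess.clip(lower=0.0)
    total = excess.sum(axis=1)
    excluded = total.index[total <= 0].tolist()
    for s in excluded:
        log.warning("sample %s: no positive labeled excess; excluded from "
                    "incorporation table", s)
    excess = excess.loc[total > 0]
    pcts = 100.0 * excess.div(excess.sum(axis=1), axis=0)
    pcts = _derived_rows(pcts)
    summary = pd.DataFrame({"mean": pcts.mean(axis=0), "sd": pcts.std(axis=0, ddof=1)})
    return IncorporationTable(per_sample=pcts, summary=summary, excluded=excluded)


def lac_partition(lac_c3_pct: float, lac_c2_pct: float) -> dict:
    """Split lactate labeling into glycolytic (C3') and TCA-cycle (C2C3) pools."""
    if lac_c3_pct < 0 or lac_c2_pct < 0:
        raise ValueError("percent inputs must be >= 0")
    prime = lac_c3_pct - lac_c2_pct
    flagged = prime < 0
    return {"lac_c3_prime": max(prime, 0.0), "lac_c2c3": 2.0 * lac_c2_pct,
            "flagged": flagged}


def tcac_fraction(glx_pcts: dict[str, float], lac_c2_pct: float) -> float:
    """TCA-cycle share: Glx isotopomers plus the C2C3 lactate pool."""
    missing = [k for k in GLX_ISOTOPOMERS if k not in glx_pcts]
    if missing:
        raise KeyError(f"missing Glx isotopomers: {missing}")
    return sum(glx_pcts[k] for k in GLX_ISOTOPOMERS) + 2.0 * lac_c2_pct


# ---------------------------------------------------------------------------
# flux ratios and GS activity
# ---------------------------------------------------------------------------

@dataclass
class FluxRatios:
    pc_over_pdh: float
    pc_over_me: float
    formulas: dict[str, str]
    flagged: bool = False


def flux_ratios(enrichments: dict[str, float]) -> FluxRatios:
    """Relative PC/PDH and PC/ME fluxes from glucose-infusion enrichments.

    The PC/PDH estimator uses the C2-C3 asymmetry that pyruvate carboxylase
    imprints on the glutamate pool (cycle-derived label is symmetrized by
    succinate scrambling, carboxylase-derived label enters oxaloacetate after
    the scrambling point)::

        PC/PDH = (Glu C2 - Glu C3) / Glu C4

    The ME proxy uses the TCA-exported lactate signal relative to the
    first-turn cycle label: ME/PDH = 2 * Lac C2 / Glu C4, so
    PC/ME = (Glu C2 - Glu C3) / (2 * Lac C2).  Both are heuristic estimators
    validated against the propagation model; the formulas travel with the
    result so downstream reports are auditable.
    """
    formulas = {"pc_over_pdh": "(GluC2 - GluC3) / GluC4",
                "pc_over_me": "(GluC2 - GluC3) / (2 * LacC2)"}
    glu_c4 = enrichments.get("Glu C4", 0.0)
    if glu_c4 <= 0:
        return FluxRatios(np.nan, np.nan, formulas, flagged=True)
    asym = enrichments["Glu C2"] - enrichments["Glu C3"]
    pc_pdh = asym / glu_c4
    lac_c2 = enrichments.get("Lac C2", 0.0)
    pc_me = asym / (2.0 * lac_c2) if lac_c2 > 0 else np.nan
    return FluxRatios(pc_over_pdh=pc_pdh, pc_over_me=pc_me, formulas=formulas)


@dataclass
class GSActivity:
    ratio: float                # Gln C4 / Glu C4 (primary)
    alt_ratio: float            # Gln C4 / (Gln C4 + Glu C4)
    flagged: bool = False


def gs_relative_activity(gln_c4: float, glu_c4: float) -> GSActivity:
    """Glutamine-synthetase relative activity from the C4 isotopomer ratio."""
    if glu_c4 <= 0:
        return GSActivity(np.nan, np.nan, flagged=True)
    return GSActivity(ratio=gln_c4 / glu_c4,
                      alt_ratio=gln_c4 / (gln_c4 + glu_c4))


# ---------------------------------------------------------------------------
# 1H-derived lactate pools
# ---------------------------------------------------------------------------

def pools_from_cpmg(deconv) -> dict:
    """Total and labeled lactate pools from the methyl-region deconvolution.

    The labeled pool is twice the right-satellite area (each satellite holds
    half of it); the total pool adds the unlabeled CH3 doublet.
    """
    lac_13c = 2.0 * deconv.lac_13ch3_right
    return {"lac_13c": lac_13c,
            "lac_total": deconv.lac_ch3 + lac_13c,
            "flagged": bool(deconv.flagged)}
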