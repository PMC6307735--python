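"""Positional 13C label propagation through glycolysis and the TCA cycle.

The model tracks, for every carbon position of the pools of interest, the
probability that the position carries 13C (isotopomer correlations are
ignored: 2D 1H-13C HSQC measures positional enrichment only).  Pools are
flux-weighted mixtures of their inflows:

* pyruvate <- glycolysis + malic enzyme (ME);
* acetyl-CoA <- PDH + acetate uptake + unlabeled dilution;
* oxaloacetate <- pyruvate carboxylase (PC) + cycle return (at the
  citrate-synthase flux) + unlabeled dilution;
* glutamate exchanges completely with alpha-ketoglutarate, and glutamine
  receives glutamate labeling scaled by the GS transfer ratio.

One "turn" applies the atom-map system once in pathway order; the second
turn carries the first-turn C4 label of glutamate into C2/C3 through
succinate scrambling.  Steady state is the fixed point of the turn map.

Unlabeled inflows carry the 13C natural abundance (1.1%), so with infinite
dilution every fraction relaxes to natural abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atom_maps import AtomMap, default_atom_maps
from .core import FluxParams, NATURAL_ABUNDANCE, SUBSTRATE_ENRICHMENT

SUBSTRATES = ("glc_1_13C", "ace_2_13C")

#: positions reported in an IsotopomerProfile
PROFILE_POSITIONS = (
    "Pyr C2", "Pyr C3", "AcCoA C1", "AcCoA C2",
    "OAA C2", "OAA C3", "Mal C2", "Mal C3",
    "Glu C2", "Glu C3", "Glu C4",
    "Gln C2", "Gln C3", "Gln C4",
    "Lac C2", "Lac C3", "Ala C3", "AcCar C2",
)


class ConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_turns: int):
        super().__init__(
            f"label propagation did not converge after {max_turns} turns "
            f"(residual {residual:.3e})")
        self.residual = residual


@dataclass
class IsotopomerProfile:
    """Per-carbon labeled fractions plus propagation diagnostics."""

    fractions: dict[str, float]
    substrate: str
    n_turns_used: int
    converged: bool = True
    residual: float = 0.0
    per_turn: list[dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for k, v in self.fractions.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"fraction out of [0,1] for {k}: {v}")

    def __getitem__(self, key: str) -> float:
        return self.fractions[key]

    def excess(self, key: str, natural_abundance: float = NATURAL_ABUNDANCE) -> float:
        """Tracer-derived labeling above the natural-abundance baseline."""
        return max(self.fractions[key] - natural_abundance, 0.0)


def _mix(components: list[tuple[float, dict[str, float]]]) -> dict[str, float]:
    """Flux-weighted mixture of positional-fraction dicts (same keys)."""
    total = sum(w for w, _ in components)
    if total <= 0:
        raise ValueError("mixture with no inflow")
    keys = components[0][1].keys()
    return {k: sum(w * frac[k] for w, frac in components) / total for k in keys}


def propagate(substrate: str, flux: FluxParams, *,
              natural_abundance: float = NATURAL_ABUNDANCE,
              enrichment: float = SUBSTRATE_ENRICHMENT,
              tol: float = 1e-9, max_turns: int = 1000,
              maps: dict[str, AtomMap] | None = None,
              keep_turns: bool = False) -> IsotopomerProfile:
    """Predict positional labeled fractions for the given substrate and fluxes.

    Parameters
    ----------
    substrate : "glc_1_13C" or "ace_2_13C".
    flux : relative pathway fluxes; ``flux.n_turns`` selects a per-turn
        output (int) or the fixed point ("steady_state", tolerance `tol`).
    keep_turns : record the Glu/Gln/Lac snapshot after every turn.
    """
    if substrate not in SUBSTRATES:
        raise ValueError(f"unknown substrate {substrate!r}")
    if flux.pdh <= 0 and flux.acetate_uptake <= 0:
        raise ValueError("at least one of pdh / acetate_uptake must be > 0")
    maps = maps or default_atom_maps()
    na = natural_abundance

    glucose = {f"Glc C{i}": na for i in range(1, 7)}
    acetate = {"Ace C1": na, "Ace C2": na}
    if substrate == "glc_1_13C":
        glucose["Glc C1"] = enrichment
    else:
        acetate["Ace C2"] = enrichment

    pyr_glycolytic = maps["glycolysis"].apply(glucose)          # Pyr C1..C3
    accoa_from_ace = maps["acetyl_coa_synthetase"].apply(acetate)
    na_accoa = {"AcCoA C1": na, "AcCoA C2": na}
    na_oaa = {f"OAA C{i}": na for i in range(1, 5)}

    mal = {f"Mal C{i}": na for i in range(1, 5)}
    state = np.full(16, na)
    n_turns = None if flux.n_turns == "steady_state" else int(flux.n_turns)
    cs_flux = flux.pdh + flux.acetate_uptake + flux.dilution_unlabeled
    per_turn: list[dict[str, float]] = []

    turn = 0
    residual = np.inf
    while True:
        turn += 1
        pyr = _mix([(flux.glycolysis, pyr_glycolytic),
                    (flux.me, {f"Pyr C{i}": mal[f"Mal C{i}"] for i in range(1, 4)})])
        accoa = _mix([
            (flux.pdh, maps["pdh"].apply(pyr)),
            (flux.acetate_uptake, accoa_from_ace),
            (flux.dilution_unlabeled, na_accoa)])
        oaa = _mix([
            (flux.pc, maps["pc"].apply({**pyr, "CO2 C1": na})),
            (cs_flux, {f"OAA C{i}": mal[f"Mal C{i}"] for i in range(1, 5)}),
            (flux.dilution_unlabeled, na_oaa)])
        akg = maps["cs_idh"].apply({**oaa, **accoa})
        glu = maps["akg_glu_exchange"].apply(akg)
        gln = {f"Gln C{i}": min(na + flux.gs * (glu[f"Glu C{i}"] - na), enrichment)
               for i in (2, 3, 4)}
        succ = maps["akgdh_scs"].apply(akg)
        s = flux.scrambling
        sym = {
            "Succ C1": (1 - s) * succ["Succ C1"] + s * 0.5 * (succ["Succ C1"] + succ["Succ C4"]),
            "Succ C4": (1 - s) * succ["Succ C4"] + s * 0.5 * (succ["Succ C1"] + succ["Succ C4"]),
            "Succ C2": (1 - s) * succ["Succ C2"] + s * 0.5 * (succ["Succ C2"] + succ["Succ C3"]),
            "Succ C3": (1 - s) * succ["Succ C3"] + s * 0.5 * (succ["Succ C2"] + succ["Succ C3"]),
        }
        oaa_ret = maps["fum_mdh"].apply(sym)
        mal = {f"Mal C{i}": oaa_ret[f"OAA C{i}"] for i in range(1, 5)}

        new_state = np.array([
            pyr["Pyr C2"], pyr["Pyr C3"], accoa["AcCoA C1"], accoa["AcCoA C2"],
            oaa["OAA C2"], oaa["OAA C3"], mal["Mal C2"], mal["Mal C3"],
            glu["Glu C2"], glu["Glu C3"], glu["Glu C4"],
            gln["Gln C2"], gln["Gln C3"], gln["Gln C4"],
            pyr["Pyr C2"], pyr["Pyr C3"]])
        residual = float(np.max(np.abs(new_state - state)))
        state = new_state
        if keep_turns:
            per_turn.append({k: glu[k] for k in ("Glu C2", "Glu C3", "Glu C4")}
                            | {k: gln[k] for k in ("Gln C2", "Gln C3", "Gln C4")})
        if n_turns is not None:
            if turn >= n_turns:
                converged = True
                break
        elif residual < tol:
            converged = True
            break
        elif turn >= max_turns:
            raise ConvergenceError(residual, max_turns)

    lac = maps["ldh"].apply(pyr)
    ala = maps["alt"].apply(pyr)
    fractions = {
        "Pyr C2": pyr["Pyr C2"], "Pyr C3": pyr["Pyr C3"],
        "AcCoA C1": accoa["AcCoA C1"], "AcCoA C2": accoa["AcCoA C2"],
        "OAA C2": oaa["OAA C2"], "OAA C3": oaa["OAA C3"],
        "Mal C2": mal["Mal C2"], "Mal C3": mal["Mal C3"],
        "Glu C2": glu["Glu C2"], "Glu C3": glu["Glu C3"], "Glu C4": glu["Glu C4"],
        "Gln C2": gln["Gln C2"], "Gln C3": gln["Gln C3"], "Gln C4": gln["Gln C4"],
        "Lac C2": lac["Lac C2"], "Lac C3": lac["Lac C3"], "Ala C3": ala["Ala C3"],
        # acetylcarnitine mirrors the acetyl-CoA methyl
        "AcCar C2": accoa["AcCoA C2"],
    }
    return IsotopomerProfile(fractions=fractions, substrate=substrate,
                             n_turns_used=turn, converged=converged,
                             residual=residual, per_turn=per_turn)


def predict_roi_volumes(profile: IsotopomerProfile, pools: dict[str, float], *,
                        natural_abundance: float = NATURAL_ABUNDANCE) -> dict[str, float]:
    """Expected HSQC ROI volumes: pool x max(labeled fraction, natural abundance).

    ``pools`` maps metabolite-carbon names ("Lac C3") to pool sizes in a.u.
    Positions absent from the profile are an error; the observed floor at
    natural abundance applies because the CTR baseline is never below 1.1%.
    """
    out = {}
    for key, pool in pools.items():
        if pool < 0:
            raise ValueError(f"negative pool for {key}")
        if key not in profile.fractions:
            raise KeyError(f"metabolite position {key!r} missing from profile")
        out[key] = pool * max(profile.fractions[key], natural_abundance)
    return out
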