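"""Independent molecule-by-molecule Monte-Carlo oracle for label propagation.

Simulates individual molecules through the same pathway semantics as the
deterministic model — source pools chosen with probability proportional to
flux, aldolase symmetry and succinate scrambling as coin flips — so per-turn
positional label probabilities can be cross-checked without sharing any code
with the implementation under test.  Restricted to gs <= 1 (no glial
over-transfer) which is all the cross-check needs.
"""

from __future__ import annotations

import numpy as np


def mc_propagate(substrate: str, flux, n_turns: int, n_mol: int = 100_000,
                 seed: int = 0, na: float = 0.011, enrichment: float = 0.99) -> dict:
    """Positional labeled fractions (with standard errors) by direct simulation."""
    assert flux.gs <= 1.0, "oracle restricted to gs <= 1"
    rng = np.random.default_rng(seed)
    N = n_mol

    def bern(p):
        return rng.random(N) < p

    def pick(pool):
        return pool[:, rng.integers(0, N, N)]

    def pyr_from_glycolysis():
        c1 = bern(enrichment) if substrate == "glc_1_13C" else bern(na)
        c6, c2, c5, c3, c4 = (bern(na) for _ in range(5))
        top = bern(0.5)   # which triose of the F1,6BP cleavage
        return np.stack([np.where(top, c3, c4),    # Pyr C1
                         np.where(top, c2, c5),    # Pyr C2
                         np.where(top, c1, c6)])   # Pyr C3

    mal = np.stack([bern(na) for _ in range(4)])   # C1..C4
    pyr = glu = gln = None
    for _ in range(n_turns):
        use_gly = rng.random(N) < flux.glycolysis / (flux.glycolysis + flux.me)
        pyr = np.where(use_gly, pyr_from_glycolysis(), pick(mal)[:3])

        tot_a = flux.pdh + flux.acetate_uptake + flux.dilution_unlabeled
        u = rng.random(N) * tot_a
        ppick = pick(pyr)
        ace2 = bern(enrichment) if substrate == "ace_2_13C" else bern(na)
        from_pdh = u < flux.pdh
        from_ace = ~from_pdh & (u < flux.pdh + flux.acetate_uptake)
        accoa = np.stack([
            np.where(from_pdh, ppick[1], np.where(from_ace, bern(na), bern(na))),
            np.where(from_pdh, ppick[2], np.where(from_ace, ace2, bern(na)))])

        cs = tot_a
        u = rng.random(N) * (flux.pc + cs + flux.dilution_unlabeled)
        ppick2, mpick = pick(pyr), pick(mal)
        from_pc = u < flux.pc
        from_ret = ~from_pc & (u < flux.pc + cs)
        oaa = np.stack([
            np.where(from_pc, ppick2[0], np.where(from_ret, mpick[0], bern(na))),
            np.where(from_pc, ppick2[1], np.where(from_ret, mpick[1], bern(na))),
            np.where(from_pc, ppick2[2], np.where(from_ret, mpick[2], bern(na))),
            np.where(from_pc, bern(na), np.where(from_ret, mpick[3], bern(na)))])

        opick, apick = pick(oaa), pick(accoa)
        akg = np.stack([bern(na), opick[2], opick[1], apick[1], apick[0]])
        glu = akg[1:4]                      # C2, C3, C4

        take = rng.random(N) < flux.gs
        gln = np.where(take, pick(glu), np.stack([bern(na) for _ in range(3)]))

        kpick = pick(akg)
        succ = kpick[1:5]
        flip = (rng.random(N) < flux.scrambling) & bern(0.5)
        mal = np.stack([np.where(flip, succ[3], succ[0]),
                        np.where(flip, succ[2], succ[1]),
                        np.where(flip, succ[1], succ[2]),
                        np.where(flip, succ[0], succ[3])])

    out = {}
    names = {"Pyr C2": pyr[1], "Pyr C3": pyr[2],
             "Lac C2": pyr[1], "Lac C3": pyr[2], "Ala C3": pyr[2],
             "Glu C2": glu[0], "Glu C3": glu[1], "Glu C4": glu[2],
             "Gln C2": gln[0], "Gln C3": gln[1], "Gln C4": gln[2],
             "Mal C2": mal[1], "Mal C3": mal[2]}
    for k, arr in names.items():
        p = float(arr.mean())
        out[k] = (p, float(np.sqrt(max(p * (1 - p), 1e-12) / N)))
    return out
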