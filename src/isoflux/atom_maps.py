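"""Carbon atom maps for glycolysis and the TCA cycle.

Each :class:`AtomMap` records, for one (lumped) reaction, where every product
carbon comes from.  A product carbon may draw from several substrate carbons
with weights summing to one (used for the fructose-1,6-bisphosphate cleavage
symmetry, where glucose C1 and C6 each contribute half of pyruvate C3).
Carbons released as CO2 are declared explicitly so maps are mass-conserving.

The registry is serializable as a plain-text table (reaction, src -> dst,
weight) so the pathway model is auditable and replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class AtomMap:
    """Atom transitions of one reaction: (substrate carbon, product carbon, weight)."""

    name: str
    pairs: tuple[tuple[str, str, float], ...]   # (src "Pool Cn", dst "Pool Cn", weight)
    lost: tuple[str, ...] = field(default_factory=tuple)  # substrate carbons lost as CO2

    def __post_init__(self) -> None:
        weights: dict[str, float] = {}
        for _, dst, w in self.pairs:
            if w <= 0:
                raise ValueError(f"{self.name}: nonpositive weight on {dst}")
            weights[dst] = weights.get(dst, 0.0) + w
        for dst, total in weights.items():
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.name}: weights into {dst} sum to {total}, expected 1")

    def product_positions(self) -> list[str]:
        return sorted({dst for _, dst, _ in self.pairs})

    def apply(self, fractions: dict[str, float]) -> dict[str, float]:
        """Map substrate positional label fractions onto product positions.

        ``fractions`` keys are "Pool Cn" substrate positions; missing keys
        raise, so an incomplete source state is caught early.
        """
        out: dict[str, float] = {}
        for src, dst, w in self.pairs:
            out[dst] = out.get(dst, 0.0) + w * fractions[src]
        return out


def _pairs(*triples):
    return tuple((s, d, float(w)) for s, d, w in triples)


def default_atom_maps() -> dict[str, AtomMap]:
    """The canonical mapping used by the propagation model.

    Notable conventions:

    * glycolysis: aldolase/TPI symmetry makes glucose C1 and C6 each feed half
      of pyruvate C3 (so 1-13C-glucose labels at most 50% of pyruvate C3);
    * PDH: pyruvate C3 (methyl) -> acetyl-CoA C2, C2 -> C1, C1 lost as CO2;
    * condensation through alpha-ketoglutarate: OAA C2 -> aKG C3,
      OAA C3 -> aKG C2, AcCoA C2 -> aKG C4, AcCoA C1 -> aKG C5; one OAA
      carboxyl is lost at isocitrate dehydrogenase and aKG C1 at
      succinyl-CoA synthesis;
    * malic enzyme: malate C1..C3 -> pyruvate C1..C3, C4 lost as CO2.
    """
    maps = [
        AtomMap("glycolysis", _pairs(
            ("Glc C1", "Pyr C3", 0.5), ("Glc C6", "Pyr C3", 0.5),
            ("Glc C2", "Pyr C2", 0.5), ("Glc C5", "Pyr C2", 0.5),
            ("Glc C3", "Pyr C1", 0.5), ("Glc C4", "Pyr C1", 0.5))),
        AtomMap("ldh", _pairs(
            ("Pyr C1", "Lac C1", 1), ("Pyr C2", "Lac C2", 1),
            ("Pyr C3", "Lac C3", 1))),
        AtomMap("alt", _pairs(
            ("Pyr C1", "Ala C1", 1), ("Pyr C2", "Ala C2", 1),
            ("Pyr C3", "Ala C3", 1))),
        AtomMap("pdh", _pairs(
            ("Pyr C2", "AcCoA C1", 1), ("Pyr C3", "AcCoA C2", 1)),
            lost=("Pyr C1",)),
        AtomMap("acetyl_coa_synthetase", _pairs(
            ("Ace C1", "AcCoA C1", 1), ("Ace C2", "AcCoA C2", 1))),
        AtomMap("pc", _pairs(
            ("Pyr C1", "OAA C1", 1), ("Pyr C2", "OAA C2", 1),
            ("Pyr C3", "OAA C3", 1), ("CO2 C1", "OAA C4", 1))),
        AtomMap("cs_idh", _pairs(
            ("OAA C1", "aKG C1", 1), ("OAA C2", "aKG C3", 1),
            ("OAA C3", "aKG C2", 1), ("AcCoA C2", "aKG C4", 1),
            ("AcCoA C1", "aKG C5", 1)),
            lost=("OAA C4",)),
        AtomMap("akg_glu_exchange", _pairs(
            ("aKG C1", "Glu C1", 1), ("aKG C2", "Glu C2", 1),
            ("aKG C3", "Glu C3", 1), ("aKG C4", "Glu C4", 1),
            ("aKG C5", "Glu C5", 1))),
        AtomMap("gs", _pairs(
            ("Glu C2", "Gln C2", 1), ("Glu C3", "Gln C3", 1),
            ("Glu C4", "Gln C4", 1))),
        AtomMap("akgdh_scs", _pairs(
            ("aKG C2", "Succ C1", 1), ("aKG C3", "Succ C2", 1),
            ("aKG C4", "Succ C3", 1), ("aKG C5", "Succ C4", 1)),
            lost=("aKG C1",)),
        AtomMap("fum_mdh", _pairs(
            ("Succ C1", "OAA C1", 1), ("Succ C2", "OAA C2", 1),
            ("Succ C3", "OAA C3", 1), ("Succ C4", "OAA C4", 1))),
        AtomMap("me", _pairs(
            ("Mal C1", "Pyr C1", 1), ("Mal C2", "Pyr C2", 1),
            ("Mal C3", "Pyr C3", 1)),
            lost=("Mal C4",)),
    ]
    return {m.name: m for m in maps}


def registry_to_file(maps: dict[str, AtomMap], path: str | Path) -> None:
    rows = []
    for m in maps.values():
        for src, dst, w in m.pairs:
            rows.append({"reaction": m.name, "src": src, "dst": dst, "weight": w})
        for src in m.lost:
            rows.append({"reaction": m.name, "src": src, "dst": "CO2", "weight": 1.0})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def registry_from_file(path: str | Path) -> dict[str, AtomMap]:
    df = pd.read_csv(path, sep="\t")
    maps = {}
    for name, sub in df.groupby("reaction", sort=False):
        pairs = [(r["src"], r["dst"], r["weight"])
                 for _, r in sub.iterrows() if r["dst"] != "CO2"]
        lost = tuple(r["src"] for _, r in sub.iterrows() if r["dst"] == "CO2")
        maps[name] = AtomMap(name, tuple(pairs), lost)
    return maps
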