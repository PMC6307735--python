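"""Shared containers: spectra, ROI templates, sample records, flux parameters.

Conventions
-----------
* ppm axes are stored high -> low (standard NMR display order).
* All spectral windows are half-open ``[low, high)`` in ppm.
* Metabolite-carbon positions are keyed by strings like ``"Lac C3"``.
* 1D spectra are written as two-column ASCII (ppm, intensity); 2D grids as a
  dense matrix with row/column ppm headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: fractional natural abundance of 13C (the non-infused baseline)
NATURAL_ABUNDANCE = 0.011
#: isotopic enrichment of the infused substrates (99% 13C)
SUBSTRATE_ENRICHMENT = 0.99
#: 1H spectrometer frequency, MHz (400 MHz instrument)
H_FREQ_MHZ = 400.13
#: 31P frequency at the same field, MHz
P_FREQ_MHZ = 161.98
#: D2O added to every rotor, mg (constant across samples)
D2O_WEIGHT_MG = 2.22
#: empty rotor weight used by the simulator, mg (constant; arbitrary origin)
EMPTY_ROTOR_MG = 528.0

GROUPS = ("CTR", "GLC", "ACE")
HORNS = ("AGA", "FGR")
TISSUES = ("brain_cortex", "heart_apex")
SUBSTRATE_BY_GROUP = {"CTR": None, "GLC": "glc_1_13C", "ACE": "ace_2_13C"}


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class Spectrum1D:
    """A 1D NMR spectrum on a ppm axis (stored high -> low)."""

    ppm: np.ndarray
    intensity: np.ndarray
    nucleus: str = "1H"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must have the same shape")
        if self.ppm.size > 1 and self.ppm[0] < self.ppm[-1]:
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()

    def window_mask(self, low: float, high: float) -> np.ndarray:
        """Boolean mask selecting points with ``low <= ppm < high``."""
        return (self.ppm >= low) & (self.ppm < high)

    def integrate(self, low: float, high: float) -> float:
        """Trapezoidal integral of intensity over [low, high) in ppm units."""
        m = self.window_mask(low, high)
        if m.sum() < 2:
            raise ValueError(f"window [{low}, {high}) not covered by spectrum")
        # axis is descending; integrate on the ascending view
        return float(np.trapezoid(self.intensity[m][::-1], self.ppm[m][::-1]))

    def to_txt(self, path: str | Path) -> None:
        header = f"nucleus={self.nucleus}"
        np.savetxt(path, np.column_stack([self.ppm, self.intensity]),
                   fmt="%.6f %.8e", header=header)

    @classmethod
    def from_txt(cls, path: str | Path) -> "Spectrum1D":
        nucleus = "1H"
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and "nucleus=" in first:
            nucleus = first.split("nucleus=")[1].strip()
        arr = np.loadtxt(path)
        return cls(ppm=arr[:, 0], intensity=arr[:, 1], nucleus=nucleus)


@dataclass
class Spectrum2D:
    """A 2D heteronuclear grid: ``grid[i_c, i_h]`` over (13C, 1H) ppm axes."""

    ppm_h: np.ndarray
    ppm_c: np.ndarray
    grid: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm_h = np.asarray(self.ppm_h, dtype=float)
        self.ppm_c = np.asarray(self.ppm_c, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (self.ppm_c.size, self.ppm_h.size):
            raise ValueError("grid shape must be (len(ppm_c), len(ppm_h))")
        if self.ppm_h.size > 1 and self.ppm_h[0] < self.ppm_h[-1]:
            self.ppm_h = self.ppm_h[::-1].copy()
            self.grid = self.grid[:, ::-1].copy()
        if self.ppm_c.size > 1 and self.ppm_c[0] < self.ppm_c[-1]:
            self.ppm_c = self.ppm_c[::-1].copy()
            self.grid = self.grid[::-1, :].copy()

    @property
    def pixel_area(self) -> float:
        dh = abs(float(np.mean(np.diff(self.ppm_h))))
        dc = abs(float(np.mean(np.diff(self.ppm_c))))
        return dh * dc

    def window_masks(self, h_low: float, h_high: float,
                     c_low: float, c_high: float) -> tuple[np.ndarray, np.ndarray]:
        mh = (self.ppm_h >= h_low) & (self.ppm_h < h_high)
        mc = (self.ppm_c >= c_low) & (self.ppm_c < c_high)
        return mc, mh

    def to_txt(self, path: str | Path) -> None:
        df = pd.DataFrame(self.grid, index=self.ppm_c, columns=self.ppm_h)
        df.index.name = "ppm13C\\ppm1H"
        df.to_csv(path, sep="\t", float_format="%.6e")

    @classmethod
    def from_txt(cls, path: str | Path) -> "Spectrum2D":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ppm_h=df.columns.astype(float).to_numpy(),
                   ppm_c=df.index.to_numpy(dtype=float),
                   grid=df.to_numpy())


# ---------------------------------------------------------------------------
# ROI template
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROI:
    """A rectangular HSQC region assigned to one metabolite carbon."""

    name: str                      # e.g. "Lac C3"
    metabolite: str                # e.g. "Lac"
    carbon: str                    # e.g. "C3"
    h_window: tuple[float, float]  # (low, high) ppm, half-open
    c_window: tuple[float, float]
    is_noise: bool = False

    @property
    def h_center(self) -> float:
        return 0.5 * (self.h_window[0] + self.h_window[1])

    @property
    def c_center(self) -> float:
        return 0.5 * (self.c_window[0] + self.c_window[1])


@dataclass
class ROITemplate:
    """Named rectangular regions mapping metabolite isotopomers to windows.

    The reference anchor is the lactate methyl cross-peak (1H 1.32 ppm,
    13C 21.3 ppm), to which all spectra are assumed referenced.
    """

    rois: list[ROI]
    anchor_h: float = 1.32
    anchor_c: float = 21.3

    def __post_init__(self) -> None:
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ValueError("duplicate ROI names in template")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def __getitem__(self, name: str) -> ROI:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def metabolite_rois(self) -> list[ROI]:
        return [r for r in self.rois if not r.is_noise]

    @property
    def noise_rois(self) -> list[ROI]:
        return [r for r in self.rois if r.is_noise]

    def overlapping_pairs(self) -> list[tuple[str, str]]:
        """Pairs of metabolite ROIs whose rectangles intersect."""
        out = []
        rois = self.metabolite_rois
        for i, a in enumerate(rois):
            for b in rois[i + 1:]:
                if (a.h_window[0] < b.h_window[1] and b.h_window[0] < a.h_window[1]
                        and a.c_window[0] < b.c_window[1] and b.c_window[0] < a.c_window[1]):
                    out.append((a.name, b.name))
        return out

    def to_file(self, path: str | Path) -> None:
        rows = []
        for r in self.rois:
            rows.append({"name": r.name, "metabolite": r.metabolite,
                         "carbon": r.carbon,
                         "h_low": r.h_window[0], "h_high": r.h_window[1],
                         "c_low": r.c_window[0], "c_high": r.c_window[1],
                         "is_noise": int(r.is_noise)})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_file(cls, path: str | Path) -> "ROITemplate":
        df = pd.read_csv(path, sep="\t")
        rois = [ROI(name=row["name"], metabolite=row["metabolite"],
                    carbon=str(row["carbon"]),
                    h_window=(row["h_low"], row["h_high"]),
                    c_window=(row["c_low"], row["c_high"]),
                    is_noise=bool(row["is_noise"]))
                for _, row in df.iterrows()]
        return cls(rois=rois)


# ---------------------------------------------------------------------------
# Cohort records
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "sample_id", "fetus_id", "mother_id", "horn", "group", "tissue",
    "rotor_weight_mg", "net_weight_mg", "birthweight_g", "placental_weight_g",
]


@dataclass
class SampleRecord:
    """One HRMAS tissue sample from one fetus."""

    fetus_id: str
    mother_id: str
    horn: str        # AGA | FGR
    group: str       # CTR | GLC | ACE
    tissue: str      # brain_cortex | heart_apex
    rotor_total_weight_mg: float
    net_tissue_weight_mg: float
    birthweight_g: float
    placental_weight_g: float
    d2o_weight_mg: float = D2O_WEIGHT_MG

    def __post_init__(self) -> None:
        if self.horn not in HORNS:
            raise ValueError(f"unknown horn {self.horn!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.net_tissue_weight_mg <= 0:
            raise ValueError("net tissue weight must be positive")
        expected = EMPTY_ROTOR_MG + self.d2o_weight_mg + self.net_tissue_weight_mg
        if abs(self.rotor_total_weight_mg - expected) > 1e-6:
            raise ValueError("rotor_total != empty rotor + D2O + net tissue")

    @property
    def sample_id(self) -> str:
        return f"{self.fetus_id}-{self.tissue}"


def records_to_manifest(records: Iterable[SampleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        rows.append({
            "sample_id": r.sample_id, "fetus_id": d["fetus_id"],
            "mother_id": d["mother_id"], "horn": d["horn"], "group": d["group"],
            "tissue": d["tissue"], "rotor_weight_mg": d["rotor_total_weight_mg"],
            "net_weight_mg": d["net_tissue_weight_mg"],
            "birthweight_g": d["birthweight_g"],
            "placental_weight_g": d["placental_weight_g"],
        })
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def manifest_to_records(df: pd.DataFrame) -> list[SampleRecord]:
    out = []
    for _, row in df.iterrows():
        out.append(SampleRecord(
            fetus_id=row["fetus_id"], mother_id=row["mother_id"],
            horn=row["horn"], group=row["group"], tissue=row["tissue"],
            rotor_total_weight_mg=row["rotor_weight_mg"],
            net_tissue_weight_mg=row["net_weight_mg"],
            birthweight_g=row["birthweight_g"],
            placental_weight_g=row["placental_weight_g"]))
    return out


# ---------------------------------------------------------------------------
# Flux parameters
# ---------------------------------------------------------------------------

@dataclass
class FluxParams:
    """Relative pathway fluxes for the label-propagation model.

    All fluxes are nonnegative and dimensionless: only ratios matter.
    ``gs`` is the glutamine/glutamate labeling transfer ratio; values above 1
    encode the glial compartment in which glutamine synthetase draws on an
    acetate-enriched glutamate pool.  ``dilution_unlabeled`` is the entry of
    unlabeled carbon at acetyl-CoA and oxaloacetate.  ``scrambling`` is the
    degree of succinate/fumarate symmetrization (1 = full).
    """

    pdh: float = 1.0
    pc: float = 0.2
    me: float = 0.05
    gs: float = 0.5
    acetate_uptake: float = 0.0
    glycolysis: float = 1.0
    dilution_unlabeled: float = 0.5
    n_turns: int | str = "steady_state"
    scrambling: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pdh", "pc", "me", "gs", "acetate_uptake",
                     "glycolysis", "dilution_unlabeled"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.scrambling <= 1.0):
            raise ValueError("scrambling must be in [0, 1]")
        if isinstance(self.n_turns, str):
            if self.n_turns != "steady_state":
                raise ValueError("n_turns must be a count or 'steady_state'")
        elif self.n_turns < 1:
            raise ValueError("n_turns must be >= 1")
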