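"""Default HSQC ROI template: 60 metabolite regions + 4 noise regions.

The published template's numeric boundaries are not available, so the default
is generated from a bundled assignment table of 1H/13C cross-peak positions
(literature-style shifts for the metabolites visible in fetal brain/heart
HSQC spectra), with default half-widths of +/-0.04 ppm (1H) x +/-1.0 ppm
(13C).  A few entries in crowded regions carry narrower 1H half-widths so
that the regions assigned to distinct rendered peaks do not overlap.  The
template is user-replaceable via :meth:`isoflux.core.ROITemplate.from_file`.
"""

from __future__ import annotations

from .core import ROI, ROITemplate

# (name, 1H ppm, 13C ppm, [1H half-width], [13C half-width])
_ASSIGNMENTS: list[tuple] = [
    ("Lac C3", 1.32, 21.3),
    ("Lac C2", 4.10, 69.3),
    ("Ala C3", 1.47, 17.0),
    ("Ala C2", 3.77, 51.5),
    ("Glu C4", 2.34, 34.4),
    ("Glu C3", 2.08, 27.9, 0.02),
    ("Glu C2", 3.74, 55.6, 0.018),
    ("Gln C4", 2.44, 31.8),
    ("Gln C3", 2.13, 27.2, 0.02),
    ("Gln C2", 3.78, 55.3, 0.018),
    ("Asp C3", 2.80, 37.4),
    ("Asp C2", 3.89, 53.2),
    ("NAA C6", 2.01, 22.8),
    ("NAA C3", 2.49, 40.3),
    ("NAA C2", 4.38, 54.0),
    ("GABA C2", 2.29, 35.2),
    ("GABA C3", 1.88, 24.5, 0.015),
    ("GABA C4", 3.00, 40.1),
    ("Cr C4", 3.03, 39.6),
    ("Cr C2", 3.92, 56.5),
    ("PCr C4", 3.05, 39.5, 0.015),
    ("Cho C5", 3.19, 54.9, 0.012),
    ("PCho C5", 3.22, 54.8, 0.012),
    ("GPC C5", 3.25, 55.0, 0.012),
    ("GPC C1", 4.32, 60.3),
    ("PE C1", 3.98, 61.8),
    ("PE C2", 3.13, 41.6),
    ("mIns C1", 3.53, 73.2),
    ("mIns C2", 4.06, 74.9),
    ("mIns C4", 3.62, 71.9),
    ("mIns C5", 3.28, 75.1),
    ("sIns C1", 3.34, 74.2),
    ("Tau C1", 3.42, 48.2),
    ("Tau C2", 3.26, 36.1),
    ("Gly C2", 3.56, 42.3),
    ("Glc C1a", 5.23, 92.8),
    ("Glc C1b", 4.65, 96.6),
    ("Glc C2b", 3.24, 74.9, 0.015),
    ("Glc C3a", 3.70, 73.5, 0.018),
    ("Glc C4", 3.40, 70.4),
    ("Glc C6", 3.86, 61.4),
    ("Pyr C3", 2.37, 27.1, 0.02),
    ("Mal C2", 4.30, 71.2),
    ("Mal C3", 2.67, 43.5),
    ("Succ C2", 2.40, 34.9, 0.015),
    ("AcCar C2", 2.14, 21.4, 0.02),
    ("Ace C2", 1.92, 24.0, 0.015),
    ("bHB C4", 1.20, 22.4),
    ("bHB C2", 2.40, 47.5, 0.015),
    ("GSH C4g", 2.55, 32.5),
    ("GSH C3c", 2.95, 26.3),
    ("GSH C2g", 3.78, 44.5, 0.018),
    ("Car C3", 2.44, 43.5, 0.015),
    ("Car C2", 3.23, 70.8, 0.012),
    ("EA C1", 3.82, 58.4, 0.015),
    ("EA C2", 3.15, 42.0),
    ("Asc C4", 4.52, 79.0),
    ("Thr C3", 4.25, 68.7, 0.02),
    ("Thr C4", 1.25, 22.2, 0.02),
    ("Ser C2", 3.95, 59.2, 0.02),
]

# noise regions: empty corners of the spectral window
_NOISE = [
    ("noise 1", 0.95, 95.0),
    ("noise 2", 1.70, 62.0),
    ("noise 3", 3.10, 90.0),
    ("noise 4", 4.50, 12.0),
]

DEFAULT_HW_H = 0.04
DEFAULT_HW_C = 1.0


def default_template() -> ROITemplate:
    """Build the default 60-metabolite + 4-noise ROI template."""
    rois = []
    for entry in _ASSIGNMENTS:
        name, h, c = entry[0], entry[1], entry[2]
        hw_h = entry[3] if len(entry) > 3 else DEFAULT_HW_H
        hw_c = entry[4] if len(entry) > 4 else DEFAULT_HW_C
        met, carbon = name.rsplit(" ", 1)
        rois.append(ROI(name=name, metabolite=met, carbon=carbon,
                        h_window=(h - hw_h, h + hw_h),
                        c_window=(c - hw_c, c + hw_c)))
    for name, h, c in _NOISE:
        rois.append(ROI(name=name, metabolite="noise", carbon="-",
                        h_window=(h - DEFAULT_HW_H, h + DEFAULT_HW_H),
                        c_window=(c - DEFAULT_HW_C, c + DEFAULT_HW_C),
                        is_noise=True))
    return ROITemplate(rois=rois)
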