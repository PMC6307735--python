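# Methods

## Label-propagation model

The model tracks, for each carbon position of a set of metabolite pools, the
probability that the position carries ¹³C. Isotopomer correlations are
ignored: per-position probabilities are sufficient for everything the
analysis measures, because 2D ¹H-¹³C HSQC reads out positional enrichment
only. Pools are flux-weighted mixtures of their inflows:

* **pyruvate** ← glycolysis (weight `glycolysis`) + malic enzyme (`me`);
* **acetyl-CoA** ← PDH (`pdh`) + acetate uptake (`acetate_uptake`) +
  unlabeled dilution (`dilution_unlabeled`);
* **oxaloacetate** ← pyruvate carboxylase (`pc`) + cycle return + the same
  unlabeled dilution.

The cycle-return weight into OAA is set equal to the citrate-synthase flux
(`pdh + acetate_uptake + dilution_unlabeled`). Anaplerosis/cataplerosis
mass balance is *not* enforced — the fluxes are relative mixing weights for
positional probabilities, not a stoichiometric flux map. All atom
transitions live in a serializable registry (`isoflux.atom_maps`), with the
canonical condensation mapping OAA C2→αKG C3, OAA C3→αKG C2,
AcCoA C2→αKG C4, AcCoA C1→αKG C5, and αKG C1 lost as CO₂ at succinyl-CoA.

One **turn** applies the system once in pathway order; `n_turns=1` stops
after the first condensation (acetate labels Glu C4 only), `n_turns=2` adds
the scrambled return (equal Glu C2/C3), and `"steady_state"` iterates the
turn map to a fixed point (tolerance 1e-9, typically 20–30 turns; a
configurable turn cap raises a `ConvergenceError` carrying the residual).
Unlabeled inflows carry the 1.1% ¹³C natural abundance, so infinite dilution
relaxes every cycle-derived position exactly to the natural-abundance
baseline. Glycolytic labeling of lactate/alanine C3 enters upstream of the
two dilution points and is therefore not attenuated by `dilution_unlabeled`;
overall precursor dilution is instead expressed through the effective
substrate enrichment (below).

**Succinate scrambling** (`scrambling`, default 1.0) symmetrizes C1↔C4 and
C2↔C3 with the given probability. Full scrambling is the physically expected
default; it is exposed because the PC/PDH estimator
(GluC2 − GluC3)/GluC4 only isolates the carboxylase label under (near-)full
scrambling — without it, second-turn cycle label itself creates a C2/C3
asymmetry and the estimator saturates regardless of PC. At steady state with
full scrambling the estimator returns the PC share of OAA inflow,
pc/(pc + cycle return), which underestimates pc/pdh by ~17% at pc/pdh = 0.2;
the formula metadata travels with every result so this is auditable.

**Glutamine synthetase** is a transfer ratio: Gln excess = `gs` × Glu excess,
clipped at isotopic purity. Values of `gs` above 1 stand in for the glial
compartment, in which GS draws on an acetate-enriched glutamate pool rather
than the volume-averaged one; `gs > 1` is exactly the threshold at which
Gln C4 exceeds Glu C4 (the pattern expected for acetate, a glial substrate).
This is a modeling convenience, not a claim that GS exceeds unit efficiency.

## Synthetic cohorts and spectra

The generator emulates the study design: per experimental group (CTR
non-infused, GLC = 1-¹³C-glucose, ACE = 2-¹³C-acetate) litters with an AGA
and an FGR uterine horn (no FGR horn in CTR), Bernoulli stillbirth
(defaults 0.55 FGR / 0.14 AGA), truncated-normal birth, placental and net
tissue weights (49.7 ± 3.0 mg with a constant 2.22 mg D₂O load), and random
sub-selection to the HRMAS cohort sizes (3 CTR AGA; 6 + 6 per infused
group). Each sample owns an RNG stream derived from (master seed, fetus id,
tissue), so extending a cohort never reshuffles existing samples.

Ground truth per sample: basal pools (a.u./mg, per tissue), positional
labeled fractions from the propagation model, ³¹P species pools, tissue pH
(6.44 ± 0.08 brain, 6.35 ± 0.09 heart, clipped to the ex-vivo range
6.05–7.4), and linear accumulation rates for Gln C4 / Lac C2 / Lac C3
(+10% over a 5.2 h session — the published drift figure gives no numbers, so
this "slight accumulation" magnitude is a placeholder and configurable).

Key chosen-once conditions, set by design-time power analysis against the
study's reported statistics rather than tuned to tests:

* per-sample biological CV **6%** on pools and labeled excesses — the
  reported p-values (0.003–0.046 at n = 6/6 for 20–23% effects) imply
  standardized effects d ≈ 1.3–2.2, which this CV reproduces;
* effective precursor enrichment **0.15 (glucose) / 0.45 (acetate)** — the
  infusions label the circulating substrate only partially (blood glucose
  roughly doubles over an unlabeled basal pool), and the control-referenced
  levels place acetate-derived lactate excess several-fold above the 1.1%
  baseline;
* FGR effect factors on labeled excess (ACE group): brain Lac C2 × 0.77,
  Lac C3 × 0.80, heart Gln C4 × 0.77; phosphodiester (GPE, GPC) pools of
  infused AGA hearts divided by 1.5 (ACE) or 1.05 (GLC), so FGR and
  non-infused control hearts exceed them by +50% (ACE) with only a weak
  GLC tendency, matching the pattern of reported significances.

Spectra: 1D peaks are pseudo-Voigt (FWHM 1.5 Hz, Lorentzian fraction 0.3 —
a pure Lorentzian's fat tails would leak ~4–6% out of the narrow integration
windows the protocol prescribes, which is lineshape physics the quantifiers
should not silently absorb); HSQC peaks are 2D Gaussians (0.01 ppm ¹H ×
0.5 ppm ¹³C FWHM) centered in their template ROIs; the lactate ¹³C satellites
sit at ±½·¹J_CH with ¹J_CH = 127 Hz (literature methyl value, configurable);
two broad Gaussians (FWHM 40 Hz) model the residual lipid/macromolecule
background of the 1.54–1.14 ppm region. Alanine's own satellites are below
the rendered detection floor and are omitted; the left lactate satellite is
rendered (it overlaps alanine and is deliberately *not* fitted
independently, matching the quantification protocol). Heart ³¹P spectra add
a 2,3-diphosphoglycerate doublet overlapping the PC region, which is why PC
is reported missing in heart.

What the generator does **not** emulate: relaxation and lineshape
distortions, spinning sidebands, water suppression, vendor raw formats,
absolute concentrations in mM, litter (mother-level) random effects, or a
genuine neuron/glia compartment model. Passing tests therefore demonstrate
the correctness and statistical calibration of the analysis chain under the
declared noise model — not robustness to every artifact of real HRMAS data.
A further known simplification: with a single dilution pathway the
glutamate/glutamine positional enrichments run higher (≈15–25%) than the
sub-10% levels seen in tissue; the effect-size and share-based quantities the
pipeline reports are ratios and are insensitive to this scale.

## Quantification choices

* ROI integration subtracts a local plane baseline (median of the ROI border
  pixels) — robust to constant offsets and gentle gradients; SNR is taken
  against the pooled SD of the four noise regions, and values below SNR 3
  are kept but flagged.
* The 60-ROI template is generated from a bundled assignment table
  (±0.04 ppm ¹H × ±1.0 ppm ¹³C half-widths; a few crowded regions carry
  narrower ¹H widths so that distinct rendered peaks own disjoint windows).
  Overlapping rectangles are reported by `ROITemplate.overlapping_pairs`
  rather than forbidden. The template is user-replaceable via a TSV file.
* Lactate deconvolution constrains positions to ±0.01 ppm of nominal and
  shares one linewidth across the sharp components, keeping the fit
  identifiable at low satellite SNR; areas are bounded nonnegative and a
  non-converged fit returns flagged diagnostics instead of raising.
* Glutamine integration uses flank medians placed clear of the succinate
  singlet for its linear baseline; the succinate exclusion leaves < 2% of a
  pure succinate signal in the window.
* ³¹P quantification re-references the axis to the fitted GPE peak at
  1.00 ppm. The GPE search window is [0.88, 1.12) ppm with a peak-prominence
  check against the window edges, because at acidic pH the Pi resonance
  approaches 1.2 ppm and must not be mistaken for the reference. The pH
  calibration (pK_a 6.75, δ_acid 3.27, δ_base 5.69 ppm on the
  phosphocreatine-referenced scale) is a documented literature default — the
  calibration actually used in the source protocol is unstated — and the
  constants are exposed as parameters.
* Enrichment floors negative excesses at zero (with a flag) rather than
  letting them subtract from the normalization denominator; incorporation
  percentages are normalized over the quantified isotopomer set only.
* Statistics follow the declared design: pooled-variance Student's t-tests
  (Welch by flag), two-tailed unpaired between horns, one-tailed paired for
  initial-vs-final HRMAS timepoints with the accumulation direction fixed a
  priori; Shapiro-Wilk normality is reported per arm, never auto-switched;
  no multiple-testing correction is applied (the report carries the test
  count so users can post-correct). Fetuses from the same mother are treated
  as independent, replicating the source design; a mixed-effects extension
  is out of scope.

Where the source's exact supplementary formulas are unavailable (PC/PDH,
PC/ME, GS activity), canonical estimators are implemented and labeled:
PC/PDH = (GluC2 − GluC3)/GluC4; PC/ME = (GluC2 − GluC3)/(2·LacC2);
GS = GlnC4/GluC4 primary, GlnC4/(GlnC4 + GluC4) also computed. Each result
carries its formula string.

## Problem sizes

The test suite and acceptance script use the study's own sizes: n = 6/6
fetuses per horn in the infused groups (3 controls), 12 pooled samples for
incorporation recovery, 10⁴ null simulations for type-I calibration,
1–1.5 × 10⁵ molecules for the Monte-Carlo oracle, and 11 seeds for the
multi-seed power checks. The full default pipeline (51 samples, three
nuclei) runs in a few seconds; the whole suite in well under a minute.
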