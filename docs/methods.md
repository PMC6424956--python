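# Methods

## The quantification model

An analyte peptide and its internal standard are the same sequence carrying
two isotopic versions of an N-terminal acetyl group: light CH₃-CO- and
heavy CD₃-¹³CO-. The heavy version adds, net of the displaced amine
hydrogen, {C:1, ¹³C:1, ²H:3, O:1} against the light {C:2, H:2, O:1}, a
mass difference of (m(¹³C) − m(¹²C)) + 3(m(²H) − m(¹H)) = 4.022185 Da,
nominally +4 amu. Labelled positions are chemically defined, so they are
modelled as explicit-isotope pseudo-elements (¹³C, ²H) with unit abundance
rather than as perturbed natural abundances.

Because the pair co-crystallizes in the matrix and desorbs/ionizes with the
same probability, the ratio of their spectral responses equals the ratio of
their molar amounts. Quantification uses peak **areas** (apex heights are
available but non-default): for each enabled adduct the first `k_range`
isotopologue peaks of each envelope are integrated and summed, and each
species' sum is divided by the theoretical envelope fraction those offsets
cover. This rescaling makes the measured ratio an estimate of the
full-envelope area ratio, so the small difference between the light and
heavy envelope shapes (the heavy species has one fewer natural carbon and
three fewer natural hydrogens) cancels exactly, and a missing isotopologue
degrades precision rather than biasing the ratio.

### Why +4 is enough, and when it is not

The natural-abundance envelope of a ≲1.5 kDa peptide has ~0.3–0.5 % of its
area at offsets k ≥ 4, which lands on the heavy monoisotopic peak.
`overlap_risk` reports this tail; for the peptides this method was designed
for it is negligible against typical replicate scatter, so the overlap
correction is **off by default**. When switched on, the predicted light
contribution at heavy offset j — light k=0 area × a(4+j)/a(0) — is
subtracted from the heavy areas (clipped at zero and flagged). The
noiseless round-trip tests enable it because they assert recovery to 1e-6,
far below the 0.4 % tail; at that tolerance the correction (or an analyte
with no k ≥ 4 tail) is required, and with it the simulator round-trip
recovers ratios over 0.01–100 to ~1e-13.

## Isotopologue envelopes

Envelopes are computed per element as the distribution of nominal-mass
offsets of `n` atoms (single-atom distribution raised to the n-th power by
repeated squaring under convolution) and combined across elements by
convolution, tracking per-bin probability and first mass moment so each
bin reports an abundance-weighted exact mass. Bins are unit-nominal-mass,
matching MALDI-TOF resolving power; fine structure within a bin is
abundance-averaged. The envelope is pruned past the last bin above the
truncation threshold (default 1e-10) and renormalized to sum to 1. An
exhaustive isotopologue enumeration (probability product per assignment,
grouped by nominal mass) serves as the test oracle for ≤10-atom formulas;
agreement is at machine precision. Isotope masses and abundances are an
embedded IUPAC-standard table so results do not depend on external
resources; pyteomics is used in the tests as an independent mass oracle.

Adduct m/z values (H⁺, Na⁺, K⁺, singly charged only) include the
electron-mass correction.

## Spectrum simulator

The simulator is the package's test substrate and demo data source. Each
(species, adduct, isotopologue) contributes a Gaussian of area
∝ molar abundance × adduct fraction × isotopologue abundance ×
`intensity_scale`, with FWHM = m/z ÷ resolution. Defaults: resolving power
10 000 (reflector TOF in the 1–2 kDa range), sampling step 0.01 Da
(≤ FWHM/10, which keeps numerical area conservation within 0.1 %), adduct
propensities H:Na:K = 1.0:0.3:0.1 (a qualitative match to peptide spectra
in an α-cyano matrix; identical for light and heavy, which is the premise
of the method), flat baseline 0, additive Gaussian noise sd 0 plus an
optional intensity-proportional term (coefficient 0). Negative intensities
are clipped. All randomness flows through one numpy generator seeded from
the config; dilution-series members use child seeds derived via
`SeedSequence([seed, index])`, so series are reproducible member-by-member.

What the simulator does **not** emulate: chemical-noise structure, matrix
clusters and spot-to-spot crystallization heterogeneity, detector
saturation and dead time, mass-calibration drift, and isotope effects on
ionization. Passing tests therefore demonstrate the correctness of the
numerical pipeline under an idealized instrument, not robustness to every
artefact of real MALDI spectra; the matching tolerance (±0.15 Da) and the
SNR-threshold design are where those real-world effects would be absorbed.

## Peak picking and matching

Local maxima above `snr_threshold` (default 3) × a robust noise estimate
(1.4826 × MAD of the intensities after excluding the top 5 %) are
centroided by intensity-weighted mean m/z within ±`window` (default
0.3 Da, wide enough for ~±7σ of a peptide peak yet below the 0.5 Da
half-spacing of adjacent isotopologues) and integrated by the trapezoid
rule over the same window. Envelope matching assigns, for k = 0..k_range−1,
the nearest picked peak within ±0.15 Da of the theoretical m/z, ties
broken toward lower m/z; a peak is assigned at most once, and the light
envelope is matched before the heavy one so the shared-peak guard favors
the analyte. `k_range` defaults to 3 — the high-abundance peaks inside the
overlap-free zone guaranteed by the +4 design. Only [M+H]⁺ is quantified
by default: adduct fractions vary spot-to-spot even when they are equal
between light and heavy, so pooling adducts adds variance; when several
adducts are enabled the combined ratio is the heavy-area-weighted
combination of per-adduct ratios, and an adduct whose heavy envelope is
absent is excluded rather than allowed to bias the pool.

Degenerate inputs: an all-zero or empty spectrum picks no peaks; a
spectrum with no heavy-envelope match raises a missing-internal-standard
error (with the overlap correction on, a bare light tail masquerading as
the standard is also caught); a spectrum with heavy but no light signal
returns ratio 0 with a below-detection flag.

## Transport and permeability

The MALDI transport form divides the acceptor/donor ratio-of-ratios by
R = S_D/S_A and multiplies by the well-volume ratio and 100; this is
algebraically identical to T = Q_A(t)/Q_D(t₀) × 100 on amounts, which the
suite verifies to 1e-9, and reproduces the design scenario (200 μM donor,
2 μM acceptor, R = 100, V_A/V_D = 4 → T = 4 %). A literal "as-printed"
variant that multiplies the donor heavy amount by R inside the denominator
is kept behind an explicit flag for auditability; it over-scales T by R²
and is not used. Papp = (V_D/t)(1/A)(T/100) in cm/s with volumes converted
μL → cm³. The transwell area never has a silent default in outputs: it is
config (1.12 cm² = standard 12-well insert) and echoed in provenance.
PAMPA Pe uses the double-sink closed form with the base-10 logarithm —
consistent with the printed constant 218.3 — time in hours, and the
poor (< 2×10⁻⁶ cm/s) / uncertain / excellent (> 4×10⁻⁶ cm/s)
classification; boundary values classify as uncertain. TEER and
Lucifer-yellow QC are experimental controls outside the computational
scope; only threshold constants would belong in a config.

## Limit of quantification

The response statistic is R_i (light/heavy ratio, or A×d/V for HPLC data,
reading A = area, d = fold-dilution, V = injected volume). The reference
mean R̄ excludes trailing members — 1 for MALDI, 5 for HPLC by default,
matching how each mode's noisy tail behaves — and deviations
(R_i/R̄ − 1) × 100 % are computed for every member including the excluded
ones. The LOQ call rule is deliberately strict: the lowest concentration
down to which **every** member stays within the threshold (default 8 %,
applied two-sided). This is the strictest rule consistent with a single
well-defined LOQ; a per-member rule is selectable for exploratory use.
Raising the threshold can then only lower (or keep) the LOQ, a property
the suite checks. A fully compliant series returns the lowest tested
concentration flagged "below lowest tested"; a series whose top member
already fails returns no LOQ, flagged "above highest tested".

### The planted-LOQ study

The stochastic end-to-end test needs a series whose deviation crosses the
8 % bound at a known concentration c*. A mean-zero noise term alone cannot
plant a sharp crossing: adjacent 1/3 dilutions change the relative error
only 3-fold, which leaves one member straddling the bound with ~50 %
exceedance probability. Instead the simulation uses the deterministic bias
of a flat chemical baseline B: with light area A and heavy area 2A per
member, the measured ratio is (A+B)/(2A+B), biased toward 1 by
≈ B/(2A+B), which grows 3-fold per dilution step. Baseline and noise
levels are chosen from this closed form so the bias is ≈ 4 % one step
above c* and ≈ 12–13 % one step below, with noise sd well under 1 % of the
ratio — margins of several sd on both sides of the bound. The recovery
criterion (correct member called in ≥ 90 % of 100 seeded series) then
measures the caller and the quantification chain, not the luck of a
borderline member. The acceptance script applies the same design scaled to
the full 200 μM → 1.1 nM series, where the call lands on the penultimate
member, ≈ 3.4 nM.

## Problem sizes and numerical choices

Simulated acquisitions use 30–60 Da windows at 0.01 Da steps (3 000–6 000
points), 200 replicates for the noisy-ratio study and 100 series × 8
members for the planted-LOQ study — sizes at which the statistical
assertions are stable across seeds while the whole suite runs in well
under a minute. Floating-point ties in the overlap correction are treated
as exact absorption (clip-and-flag) within 1e-12 relative. Compositions
are validated to non-negative integer counts; subtraction below zero is an
error rather than a clamp.

## Known limitations

- Singly charged adducts only; no fragmentation, no charge-state
  deconvolution, no fine isotope structure within a nominal-mass bin.
- The LOQ procedure is the serial-dilution deviation definition; it is not
  the 3σ LOD or the 10σ/slope calibration-curve LOQ, which answer
  different questions.
- Papp uses the single-timepoint form (valid in the initial-slope,
  sink-condition regime); multi-timepoint slope fitting is out of scope.
- Non-natural residues must be supplied as user formulas; the built-in
  table covers the 20 canonical residues, and D-residues share their
  L-form compositions (stereochemistry does not affect mass).
- The mzML reader is minimal by design: m/z and intensity arrays, 32/64-bit
  floats, zlib or no compression — the encodings common converters write.
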