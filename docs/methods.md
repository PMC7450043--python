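# Methods

## The measurement model

The assay reports nascent-chain compaction as the acceptor-dependent
quenching of a CFP donor on ribosome-nascent-chain complexes. One
experiment is a matched quadruple of cell-free translation reactions:
donor-only (D), donor+acceptor (DA), and two blanks (BD/BDA) translated
from a non-fluorescent CFP variant lacking the internal amber codon.
Because the ¹⁴C-lysine label rides on the suppressor tRNA, scintillation
counts measure only readthrough chains, while CFP fluorescence comes from
readthrough *and* stalled chains (terminated at the amber codon, donor
mature, no acceptor). The pipeline therefore computes, per reaction pair:

- peak fluorescence: mean of the five highest intensities of the
  450–600 nm scan (ties resolved toward lower wavelength);
- `[RNC] = (cpm_S − cpm_B)/(CE·SA·vol)` in nM;
- net per-nM fluorescence `F = (peak_sample − peak_blank)/[RNC]`
  (D corrected by BD, DA by BDA);
- `E = 1 − F_DA/F_D`.

Stalled chains inflate per-nM donor fluorescence by the
stall-to-readthrough ratio `s` of the reaction, so the measured value is
the *apparent* efficiency

    E_app = 1 − ((1 − E_chain) + s_DA)/(1 + s_D)
          = E_chain/(1 + s)          (matched stalls, s_D = s_DA = s).

This identity is the package's central oracle: the noise-free simulator
round-trips through the full measurement chain to `E_app` at < 1e−9, and
the readthrough-ratio QC bands (0.80–1.20 at probe Arg487, 0.85–1.15 at
Asp567, inclusive; Thr389 reuses the Arg487 band since no tighter band is
defined for the control) bound the bias
`(1 − r)·((1 − E) + s_DA)/(1 + s_DA)` incurred when suppression
efficiency differs between D and DA (`r` is the D/DA readthrough ratio,
modeled as `(1 + s_DA)/(1 + s_D)`; how the ratio is measured
experimentally is not specified by the assay description, so the
simulator derives it from generative truth and the pipeline consumes it
as sample metadata).

Negative efficiencies, negative net intensities and non-positive
concentrations are flagged, never clipped — clipping would bias replicate
means. QC failure flags a result but does not suppress it; exclusion
happens at the aggregation stage, mirroring the assay practice of
excluding band-violating samples from statistics while retaining the raw
measurement.

## Synthetic data generator

`nascentfret.synthetic` emulates the assay's generative process:

- **Line shape.** CFP emission is a fixed two-Gaussian mixture (main peak
  476 nm, σ 12 nm; shoulder 503 nm, relative amplitude 0.85, σ 18 nm)
  normalized to unit peak. The grid argmax lands at 480 nm and the top
  five points span 478–482 nm, a realistic "~475 nm" averaging window.
  The exact shape cancels in the FRET ratio by construction.
- **Signal model.** intensity(λ) = brightness(T) · (fluorescent chain
  nM) · S(λ) + background, with chain terms `rnc·(1+s_D)` for D,
  `rnc·((1−E_chain)+s_DA)` for DA, zero for blanks. Per-wavelength
  Gaussian noise with sd = noise_cv × clean intensity.
- **Counts.** Expected cpm = CE·SA·vol·rnc + background for D/DA,
  background for blanks; realized values Poisson.
- **Defaults** (chosen once as realistic assay values): rnc_conc 100 nM,
  CE 0.95 (¹⁴C), SA 300 dpm/pmol (typical for uniformly labeled
  ¹⁴C-lysine), vol 0.5 ml, donor brightness 120 units/nM, background 500
  units, cpm background 100, matched stall ratio s = 0.1 (the
  accepted-sample regime), noise_cv 0.02. The 2% spectral CV plus Poisson
  counting noise yields replicate-to-replicate FRET scatter of ~0.7
  percentage points, i.e. SEMs of well under 1 point at n = 4, matching
  the smooth error bars typical of the assay.
- **Temperature.** Donor brightness falls linearly by 1%/°C from the
  25 °C reference — a reversible CFP effect that cancels in the FRET
  ratio (the behavior of the Thr389 tether control). Denaturation is
  fixture-specified: per-condition piecewise-linear `E_app(T)` knots,
  monotone non-increasing over the 4–50 °C assay range, with the
  intermediate's transition placed above 35 °C. No functional form
  (two-state, Tm fit) is assumed because the assay reports none.
- **Seeding.** A master seed plus a CRC32 hash of the condition label and
  the replicate index feed a `numpy` `SeedSequence`, giving bit-identical
  reaction sets per (seed, condition, replicate) and independent streams
  across replicates and conditions.
- **Ground truth.** `reference_truth_table()` stores target apparent FRET
  per condition. Values that correspond to reported condition means are
  tagged `source="reported"`; truncations without reported means are linear
  interpolations along the wild-type compaction profile (4.1% at 500 →
  39.6% at 624, plateau to 654) or mutant-deficit interpolations between
  reported anchors, tagged `source="fixture-only"`. The generator inverts
  each target through `E_chain = E_app·(1+s)` so the pipeline recovers
  the target exactly in the noise-free limit.

What the generator does *not* emulate: acceptor (sensitized) emission
(negligible in this assay), Förster-distance/orientation physics,
translation-elongation kinetics, chaperone effects, day-to-day batch
variation, or spectrometer drift. Passing tests therefore demonstrate
that the measurement math, QC logic and statistics recover a known
generative truth under realistic counting and spectral noise — not that
the model captures every systematic error of real instruments.

## Statistics

- Profiles: mean, n−1 standard deviation, SEM = sd/√n over QC-passing
  replicates. n = 1 profiles carry SEM = 0 with a `low_n` flag and are
  excluded from significance tests.
- Contrasts: two-sample pooled-variance Student's *t* (df = n_a+n_b−2),
  matching the assay's stated convention; Welch and paired variants are
  available behind flags (each experiment ran wild type and mutant in
  parallel, but whether the published tests were paired is not stated —
  unpaired is the default here). One-tailed tests are directional for
  wild type > mutant, as used for the thermal difference curves.
- α = 0.05 with no multiple-testing correction across truncations or
  temperatures, matching the per-point asterisk convention; this is a
  deliberate reproduction choice, not a general recommendation.
- Folding window: the maximal contiguous truncation run with p < α and
  mutant mean below wild type; empty windows are legal, and the window is
  invariant to appending non-significant flanking truncations.
- Bound/released pairing: a bound chain truncated at L exposes residues
  to L − offset, with 30–40 residues sequestered in the exit tunnel
  (default offset 35). A pairing is valid when the implied offset lies in
  the 30–40 band, which admits the study's 568/604 and 664/704 pairings;
  anything else raises a pairing error naming both exposed ranges.
- Difference curves propagate SEM as √(SEM_WT² + SEM_mut²).

## Maturation

Band C (mature, post-Golgi) relative to wild type is computed as each
mutant lane's band C / loading control, expressed as a percentage of the
mean wild-type ratio. Normalizing to the loading control (rather than to
band B + C within the lane) makes the readout proportional to absolute
mature protein per cell equivalent; the within-lane percent-C readout is
also provided (`maturation_efficiency`). The alternative normalization is
switchable by computing percent-C ratios directly.

## Numerical and design notes

- Blank correction subtracts at the peak-intensity level rather than per
  wavelength; for the flat background model these are identical, and the
  peak-level rule matches the definition of F as a peak quantity.
- Top-5 selection runs over the full grid rather than a fixed window
  around 475 nm; with the documented line shape the two coincide and the
  full-grid rule has no free parameter.
- Serialization uses `%.17g` floats and round-trip parsing, so
  write→read round trips are exact and reruns are byte-identical
  (verified by content hashes in the run manifest).
- Problem sizes: acceptance and calibration suites use n = 4 replicates
  per condition, 1000-point oracle grids, and 200–1000 Monte-Carlo
  repeats — sizes at which the binomial noise on calibration checks
  (type-I error ±2% at 1000 repeats) is small relative to the asserted
  tolerances, while the whole suite runs in seconds.

## Known limitations

- Fixture values for unreported truncations are interpolations; they make
  the length scans well-posed but carry no evidential weight.
- The thermal fixture curves are qualitative (monotone, converging at
  high temperature); only their structure, not their knot values, is
  meaningful.
- The stall model treats stalled chains as fully fluorescent mature CFP;
  if a fraction of stalled chains were chromophore-immature the effective
  stall ratio would simply rescale, which the QC band already absorbs.
- No acceptor-emission (sensitized) FRET channel is modeled or measured.
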