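# Methods

## Scope and model

`abepitope` implements the computational side of a peptide-microarray
workflow for fingerprinting the sequence and modification specificity of
anti-amyloid-beta (Aβ) antibodies. The wet-lab stages (SPOT synthesis,
image quantification, instrument operation) are out of scope; the pipeline
starts from probe-level intensity tables and peptide library definitions
and ends at core-motif calls, variant impact reports, binding constants,
and theoretical mass/pI annotations.

## Coordinates and sequences

Aβ positions are numbered −23..51 with no position 0: the canonical Aβ1–42
sits inside the 74-residue APP770 region 649–722, with 23 N-terminal and 9
C-terminal APP residues flanking it. `abeta_to_app`/`app_to_abeta` is an
exact bijection over those 74 positions. The omission of position 0 follows
the field's Aβ(−3-x)/Aβ1-x convention for N-terminally elongated species.

Modified peptides carry one tag per residue (phosphorylation on S/T/Y,
N-terminal pyroglutamate on E/Q, D-stereo and iso-aspartate forms of Asp)
plus termini states (free amine vs. pyroglutamate-cyclized; free acid vs.
amide). Two text dialects exist: a canonical bracket-tag form
(`DAEFRHDS[p]GYEVHHQ`, optional `-NH2` suffix) that round-trips through the
writer, and the compact array-export form in which the digit `2` denotes a
phosphoserine. The digit form is accepted on input only; the canonical form
is the storage format.

## Masses

Neutral mass = Σ residue masses + water + Σ modification deltas, with
+79.96633 Da (monoisotopic HPO3) for phosphorylation, −18.010565 Da for
pyroglutamate from Glu, −17.026549 Da for pyroglutamate from Gln,
−0.984016 Da for C-terminal amidation, and exactly 0 for the stereo/isomer
forms of Asp (isobaric). [M+H]+ adds one proton (1.00728 Da). Residue
masses and formula deltas are taken from pyteomics; average masses use its
isotope-averaged atomic weights. Only singly protonated species are
annotated — the MALDI spectra this emulates show no multiply charged ions —
and isotope patterns and fragment ions are out of scope.

## Isoelectric points

The pI is the pH where the Henderson–Hasselbalch net charge
Q(pH) = Σ cationic fractions − Σ anionic fractions crosses zero, found by
bisection on pH 0..14 to |Q| < 1e−6. Q is strictly decreasing, so the root
is unique whenever both charge signs are present; otherwise a `ChargeError`
is raised. The default pKa set is the Bjellqvist table (side chains
D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0; termini 7.5/3.55
with first/last-residue adjustments), the set behind the familiar ExPASy
values; it reproduces the conventional theoretical pI 5.31 for Aβ1–40. The
set is swappable (`PkaSet`). A phosphate monoester is treated as diprotic
with pKa 1.2 and 6.5. Pyroglutamate formation removes both the N-terminal
amine charge and (for Glu) the side-chain carboxyl consumed by the lactam;
amidation removes the C-terminal carboxyl.

Caveat: printed pI values for Aβ species in the capillary-IEF literature
are instrument readouts on a calibrated gradient and can deviate from any
Henderson–Hasselbalch model by ~0.2 pH units. For the pair Aβ2–40/Aβ3–40
(which differ only by a non-ionizable alanine) such models necessarily give
near-identical values, so an instrument-reported ordering between them is
not reproducible theoretically. We therefore treat the theoretical value as
exact only where it is known to coincide with the conventional calculation
(Aβ1–40, 5.31).

## Library design

* **Tiling**: contiguous windows left to right; count
  `floor((L − window)/step) + 1`. The default window 15 / step 1 over the
  74-residue region yields 60 probes overlapping by 14 residues, and
  overlaying the tiles reconstructs the input exactly.
* **Positional scans**: every position of an unmodified wildtype times
  every other proteinogenic letter (cysteine included), plus one wildtype
  reference probe — `L × 19 + 1` probes, 343 for an 18-mer. Probe ids encode
  provenance (`scan:H6R` style) so analysis never re-parses sequences.
* **PTM panels**: each supported modification (pSer8, pSer26, pE3, D-Asp1,
  iso-Asp1, C-amide) is emitted beside an unmodified control of the same
  residue string for head-to-head comparison. pE3 demands a span starting
  at Aβ3 because cyclization is an N-terminal event.

## Array analysis

Replicates are aggregated by the arithmetic mean of raw intensities; an
optional background column is subtracted first, and no other preprocessing
is applied. Each substitution probe is normalized against the wildtype
probe of the same scan, `r = mean(variant)/mean(wildtype)`; ratios are not
clipped above 1. The wildtype mean must exceed a floor of 1% of the
antibody's maximum probe mean (configurable), otherwise the matrix is
refused as degenerate rather than producing unstable ratios.

A substitution is **dominant negative** when it reduces binding by more
than half: `r < 0.5`, strict, so `r = 0.50` is not flagged and gains of
binding never are. A position is part of the **core motif** when at least
10 of its 19 substitutions are dominant negative — the smallest integer
count exceeding half of them; the count threshold is a config knob. The
motif string shows the wildtype letter at core positions and `X` elsewhere.
Both rules are monotone: lowering any ratio can only add flags, and
lowering the count threshold can only grow the core set.

Named variants (the familial-AD set A2V, A2T, H6R, D7H, D7N, K16Q, L17V
and the rodent differences R5G, Y10F) are classified `binding-reducing`
(`r < 0.5`), `tolerated`, or `not covered` when outside the scanned span.

Titrations are fitted by least squares with a Boltzmann sigmoid on
x = log10(concentration): `bottom + (top − bottom)/(1 + exp((x50 − x)/slope))`,
with EC50 = 10^x50 and an unconstrained (positive) slope. At least five
points spanning more than one decade are required; an exactly flat series
is returned with a `no_transition` flag instead of a spurious midpoint. A
selectivity ratio EC50_a/EC50_b is reported only when both fits converge.

Display heatmaps use per-antibody min-max scaling to [0, 1] (each antibody
scaled independently, probe order preserved); an all-equal profile scales
to zeros with a warning. Min-max was chosen over max-only scaling as the
more common display normalization; it affects rendering only, never the
ratio matrix.

## Binding kinetics

The 1:1 Langmuir model in closed form: association
`R(t) = Req (1 − exp(−(kon·C + koff) t))` with `Req = Rmax·C/(C + KD)`,
dissociation `R(t) = R(t1) exp(−koff (t − t1))`, `KD = koff/kon`. Default
phase durations are 1200 s association and 1500 s dissociation at 2 s
sampling. No mass-transport limitation, drift, bulk-shift, or
bivalent-analyte terms are modelled.

The global fit shares one (kon, koff, Rmax) triple across all traces of a
concentration series, optimizing in log-parameter space by
Levenberg–Marquardt (lmfit). Initialization is deterministic: koff from a
log-linear fit of the dissociation tail of the highest-concentration trace,
kon from that trace's observed association rate via `kobs = kon·C + koff`,
Rmax from 1.5× the largest observed response. Fewer than three distinct
concentrations trigger an "ill-conditioned" warning but still return a fit.
Steady-state analysis fits `Req(C) = Rmax·C/(KD + C)`; the steady-state
read of a simulated trace is the mean over a configurable end-of-association
window. A flat series, or a fitted KD more than two orders of magnitude
outside the sampled concentration range (saturated-only or linear-only
data), raises `UnidentifiableError`.

## Variant panel and peak assignment

The built-in ten-member panel mirrors a typical synthetic Aβ mixture:
Aβ1–40, Aβ1–42, the N-terminal truncations 2–40, 3–40, pE3–40, 4–40, 5–40,
11–40, the elongated Aβ(−3)–40, and C-terminally amidated pSer8-Aβ1–40.
Peaks are picked as local maxima above `min_snr` (default 3) times the
median intensity, then matched to the nearest panel [M+H]+ mass within a
tolerance (default 1.0 Da, average masses — appropriate for unresolved
isotope envelopes of 3–5 kDa peptides in MALDI; monoisotopic matching is
available). Ties go to the smallest absolute error and are flagged
ambiguous when two panel masses fall inside the tolerance. Per-variant
relative intensities are peak-height fractions of the summed assigned
heights and are semi-quantitative only (no correction for ionization
efficiency). Assignment is deterministic and invariant to peak order, and
shrinking the tolerance can only unassign peaks.

## Synthetic data

The generators emulate the statistical structure of the real inputs, not
their physics:

* **DMS arrays**: intensity = wildtype level × effect ratio ×
  LogNormal(0, σ) per replicate — positive, right-skewed multiplicative
  noise as appropriate for chemiluminescent readouts. Defaults: an 18-mer
  Aβ1–18 wildtype, a planted contiguous core at Aβ3–7 with effect ratio 0.1
  (strong attenuation for every substitution at core positions, ratio 1
  elsewhere), wildtype level 10⁴, σ = 0.2, 3 replicates. The replicate
  count is a free parameter; 3 is a deliberately conservative stand-in for
  arrays that spot each probe many times.
* **Titrations**: the same Boltzmann form the fitter uses, sampled on a
  log-spaced grid with optional Gaussian noise.
* **Sensorgrams**: the closed-form 1:1 model plus Gaussian noise; presets
  span the low-nanomolar to low-micromolar affinities typical of
  antibody–peptide interactions.
* **Spectra**: sums of Gaussian peaks at the panel [M+H]+ masses with
  configurable FWHM, baseline, additive noise, and per-peak centre jitter
  emulating calibration error.

Every generator is a pure function of (parameters, seed) and returns a
ground-truth record that can be written as a sidecar JSON; tests consume
only that record. Because the noise model is exactly the model family the
fitters assume, passing recovery tests demonstrates correctness of the
estimation code, not robustness to real-array artefacts (spatial effects,
saturation, batch variation), which remain out of scope.

## Problem sizes and numerics

The recovery checks use 100 seeded repetitions (core-motif recovery with
3 replicates and σ = 0.2 must find the exact planted span in ≥95;
KD recovery at 5%-of-Rmax noise stays within 10%), 5-concentration series
at 0.25–4× KD, and 2–5 s sensorgram sampling; these sizes keep the full
suite under a minute while leaving the statistical conclusions stable.
Bisection tolerances are 1e−6 in charge units; kinetic fits optimize log
parameters to keep everything positive; Boltzmann plateaus are normalized
so `top ≥ bottom` after fitting (the form is symmetric under swapping the
plateaus with a slope sign change).

## Known limitations

* No inter-array batch correction or significance testing of
  per-substitution effects — the procedure is intentionally rule-based.
* The kinetics module cannot represent avidity/bivalent binding, which is
  known to matter for IgG binding to densely immobilized peptides; fitted
  KDs are apparent constants of the 1:1 approximation.
* Peak assignment ignores isotope structure, adducts, and matrix clusters.
* Printed instrument pI values can differ from theoretical ones (see
  above); the calculator is a theoretical annotator, not a CIEF simulator.
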