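# Methods

`docklink` quantifies the two-state conformational ensemble of an Hsp70-class
chaperone (the ER chaperone BiP is the motivating system) from three kinds of
data, and couples them through a thermodynamic linkage model. This note
records the models, the numerical choices, and what the synthetic data do and
do not emulate.

## 1. The two-state ensemble picture

The chaperone is modelled as co-existing in exactly two conformations: the
nucleotide-binding and substrate-binding domains either dock against each
other (D) or tumble independently (U). Interconversion is slow on the NMR
chemical-shift timescale, so in a 2D methyl spectrum every probe shows one
resolved peak per conformation, and the docked fraction is read from peak
heights:

    p_D = I_D / (I_D + I_U) x 100 %

A transient linker-bound intermediate is deliberately out of scope: it is
never resolved as a third peak set in the data this pipeline targets, and a
two-state treatment is the minimal model the measurements can constrain.

## 2. Population quantification (`nmr`)

**Peak heights, not volumes.** Intensities are interpolated peak heights via
the three-point parabolic method applied independently per dimension — the
scheme NMR analysis suites use. Heights and volumes give identical ratios for
equal-linewidth doublet partners; heights are far more robust on crowded
planes. For a Lorentzian sampled at ≥10 points per linewidth the parabolic
height estimate is accurate to ~0.1% (worst-case node phase), which keeps the
noiseless population error below 0.1 percentage points.

**U/D assignment by overlay.** The doublet member that coincides with the
corresponding isolated-domain peak is U; its partner is D. Matching is greedy
in order of increasing combined chemical-shift perturbation
`sqrt(dH^2 + (0.25 * dC)^2)` (the usual methyl 13C weight, configurable),
with each full-length peak used at most once. Defaults: U-match tolerance
0.02 ppm; doublet search window 0.15 ppm combined. The window must exceed the
canonical splittings of 0.03 ppm (1H) / 0.4 ppm (13C), which combine to
0.1044 ppm — a 0.1 ppm window would reject exactly the doublets the analysis
exists for. Doublets with two or more D candidates in the window are flagged
"overlapped" and excluded, mirroring the practice of quantifying only
non-overlapping doublets.

**Error model.** The reported error is
`max(SD of per-doublet p_D, propagated intensity error)`. The propagated term
takes a per-peak height uncertainty equal to the spectral noise sd (local RMS
of the signal-free region when not supplied), pushes it through the ratio to
first order, and reports the RMS over doublets *without* the 1/sqrt(N)
reduction — a deliberately conservative single-measurement error bar. With
N = 3 doublets an SD-only error bar would cover the truth in only ~77% of
repeats (it is a t-statistic with 2 degrees of freedom); the conservative
propagated floor restores ≥90% empirical coverage, which the acceptance suite
verifies by Monte Carlo.

**Exchange timescale.** Resolved doublets imply interconversion slower than
the shift difference. Each offset is converted to Hz on its own axis
(`dnu = ddelta_ppm * carrier_MHz`) and the bound is reported as
`tau = 1/dnu_min` (44 ms for 0.03 ppm 1H at 750 MHz — tens of milliseconds),
with the stricter textbook `1/(2*pi*dnu)` logged alongside, since the
literature is inconsistent about the convention.

## 3. Single-site ITC (`itc`)

Integrated injection heats are fitted to the standard single-site isotherm
with the perfusion-cell dilution convention (cumulative injected volume `dv`
into cell volume `V0`):

    P_t = P0 (1 - dv/2V0) / (1 + dv/2V0),   L_t = L_syr (dv/V0) / (1 + dv/2V0)
    PL  = ((nP_t + L_t + Kd) - sqrt((nP_t + L_t + Kd)^2 - 4 nP_t L_t)) / 2
    Q_i = V0 * dH * PL_i
    q_i = Q_i - Q_{i-1} + (dV_i/V0)(Q_i + Q_{i-1})/2

Free parameters: `n`, `Kd` (optimised as log10 Kd, bounded to [1e-12, 1e-1] M),
`dH`, and a constant per-injection dilution heat (always free — no blank
subtraction is assumed). The first injection is excluded by default (partial
delivery is endemic to the instrument class). Initial guesses: n = 1, dH from
the first retained injection per mole injected, Kd at the cell concentration.
A c-value (`n*P0/Kd`) outside [1, 1000], or a log10(Kd) uncertainty above one
decade, flags the Kd as poorly constrained. The closed-form equilibrium is
cross-checked in the tests against an independent bisection solver of the
same mass-action problem (agreement ~1e-14 relative).

State functions use `dG = RT ln(Kd/1M)` and the exact identity
`-TdS = dG - dH`, with R = 1.987e-3 kcal/(mol K) and T = 298 K unless
overridden; rounding happens only in the presentation table.

**A note on the published ledger.** Re-deriving dG and -TdS from the
published (Kd, dH) pairs reproduces the full-length and NBD(1-413) rows to
the printed 0.1 kcal/mol. The NBD(1-417) rows are internally inconsistent at
that precision: the ATP row's own (dG, dH) = (-8.1, 14.7) gives -TdS = -22.8,
not the printed -22.3, and the ADP row gives -1.0, not +1.0 (a likely sign
slip). `recompute_state_functions` reports recomputed values and flags the
mismatch; the package never forces agreement with an inconsistent cell.

## 4. Thermodynamic linkage (`linkage`)

In reduced RT units:

    dG_dock/RT = -ln(p_D / (1 - p_D))
    dG_bind/RT =  ln(p_D Kd_D + (1 - p_D) Kd_U)

i.e. the observed dissociation constant is the population-weighted sum of the
pure docked- and undocked-state constants. Plotted against each other these
trace a sigmoid between asymptotes `ln Kd_U` (undocked limit) and `ln Kd_D`
(docked limit); constructs that shift the docking equilibrium walk along one
curve per nucleotide if the two-state picture holds. Note the asymptote is
approached like `e^{-|x|} (Kd_U/Kd_D - 1)`, so for extreme constant ratios
(e.g. 800) the curve at |x| = 20 still sits ~1.6e-6 away on the tight side.

`fit_state_constants` minimises `sum[ln Kd_obs - ln Kd_model]^2` over
`(ln Kd_D, ln Kd_U)` — log space buys positivity and scale invariance; the
objective the original analysis used is not documented, so this is the
package's own choice. Constructs with no detectable docked population enter
with p_D = 0 (the binding equation, unlike the docking energy, is defined
there); p_D ∈ {0, 1} is excluded everywhere the docking energy itself is
needed. The populations entering the fit are those measured in the
corresponding nucleotide-bound state — an explicit modelling assumption, as
they are the only populations available. A weighted-sum-of-affinities
(1/Kd) convention exists behind a flag for sensitivity analysis and is never
the default. Panels whose p_D spread is below 0.2 trigger an identifiability
warning; identical populations are an error (the two constants collapse onto
one degree of freedom).

## 5. Synthetic data (`synthetic`)

The study this package models deposited no raw spectra or titrations, so
every stage is validated against generators with known ground truth:

* **Spectra.** Peaks are 2D Lorentzians (product of 1D absorption shapes —
  analytic maxima make exact oracles easy), on a 256 x 512 grid spanning
  2 ppm (13C) x 0.8 ppm (1H) at a 750 MHz 1H / 188.6 MHz 13C field. Default
  probes: three well-separated Ile-region doublets with ±0.03/±0.4 ppm
  offsets and 15 Hz linewidths (~10 grid points per linewidth on both axes).
  Noise is i.i.d. Gaussian per grid point; the default sd of 0.01 against
  per-peak amplitude 1 puts doublet-member heights near 0.5, i.e. peak
  signal-to-noise ~50 — a realistic methyl-TROSY regime that yields
  per-doublet population errors under 1 pp. Not emulated: relaxation,
  apodization artefacts, lineshape coalescence (slow exchange is assumed),
  peak-position assignment errors, baseline distortions. Passing tests
  therefore demonstrate estimator correctness, not robustness to processing
  artefacts.
* **Titrations.** The generator forward-models heats with the same
  single-site convention the fitter uses (the fitter is still validated
  against the independent bisection oracle), then adds a constant dilution
  heat and Gaussian heat noise. Defaults — 40 µM cell, 0.3 mM syringe,
  200 µL cell, 25 x 1.5 µL injections, 25 C — sit in the study's stated
  concentration regime, give c = 50 and a final molar ratio of 1.4.
  "1% heat noise" means sd = 1% of the largest model injection heat
  (~0.05 µcal here).
* **Panels.** Construct panels place points on a known linkage curve and
  perturb `dG_bind/RT` with Gaussian scatter (sd 0.3 ≈ 35% Kd scatter, a
  deliberately harsh repeatability assumption). The default docked fractions
  (0.02, 0.15, 0.4, 0.6, 0.85, 0.98) anchor both pure states — a standard
  identifiability-driven design, since a panel confined to mid-range p_D
  cannot pin either constant. The default constants (1.5 / 7 µM) are the
  ADP-like pair; at this 4.7x ratio the recovery study's median log-space
  error stays near 20% (D) / 10% (U). The reported best-fit ATP constants
  (1 nM / 800 nM) are kept as reference context only: recovering a pure-state
  constant 800-fold below every observable mixture Kd is not an identifiable
  desk-scale experiment, and the variant-construct Kd inputs behind that fit
  were never printed.

All randomness in a generator flows from one integer seed
(`numpy.random.default_rng`); fixed seed means bit-identical output, which
the pipeline exploits for byte-stable reruns.

## 6. Pipeline and formats

The `docklink` CLI orchestrates simulate → quantify → fit-ITC → link from a
single YAML config (unknown keys are errors). Per-stage seeds derive from the
master seed via `SeedSequence.spawn`. Artifacts: Sparky-style peak lists
(`Assignment w1 w2 Data Height`, w1 = 13C), plain-text grid matrices with
JSON axis sidecars (bit-exact round trip), ITC CSVs with `#key=value`
headers, panel CSVs (`construct,nucleotide,p_D_percent,Kd_uM`, `undocked`
flagging p_D = 0), full-precision JSON results, and a presentation-rounded
thermodynamics table. Floats are serialised with `repr` so identical
config + seed reproduces every CSV/JSON byte for byte; the run manifest
stores a config hash, the seeds and relative artifact paths.

## 7. Known limitations

* Heights-vs-volumes: if an experimental dataset's doublet partners have
  unequal linewidths (differential exchange broadening), height ratios bias
  p_D; the generator deliberately uses equal linewidths per probe.
* The error model treats spectral noise as the only intensity uncertainty;
  systematic overlap biases are flagged (overlapped doublets excluded), not
  corrected.
* The linkage fit assumes one (Kd_D, Kd_U) pair per nucleotide shared by all
  constructs — mutations are assumed to shift only the docking equilibrium,
  not the pure-state affinities.
* The ITC module fits integrated heats only; baseline integration of raw
  power traces, multi-site and competitive models are out of scope.
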