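# Methods

## Growth model

A cell population driven by Bcr-Abl1 kinase activity grows at a fraction

    f_v(C) = 1 / (1 + (C / IC50)^m)

of its drug-free rate under an inhibitor at concentration `C`.  The Hill
coefficient `m` is treated as scenario-wide (not per drug or per mutant,
since mutant-specific slopes are rarely reported); the default is `m = 2`,
a representative value for Ba/F3-derived dose-response curves, and every
entry point accepts 0.5 or 1 instead.

Combinations distinguish the drugs' binding sites.  ATP-pocket inhibitors
(imatinib, nilotinib, dasatinib, bosutinib, ponatinib, axitinib) compete
for one site and combine **exclusively**: their potency-scaled
concentrations `C_i / IC50_i` add inside the Hill form.  Asciminib binds
the allosteric myristoyl pocket and combines **nonexclusively**: the sum
gains the product term `(C_1/IC50_1)(C_2/IC50_2)`.  For two ATP-pocket
drugs plus asciminib we use the mixed form

    base = atp + allo + atp * allo,      atp = sum of ATP-pocket terms,

which reduces exactly to the pair equations when any one concentration
vanishes.  No published closed form exists for the mixed triple; the
single cross term between the competing pair's sum and the allosteric term
is this package's documented choice (no axitinib x bosutinib product, as
those two compete).

Resistance mutations enter through relative IC50 values
(mutant / wildtype).  The packaged matrix covers 16 Bcr-Abl1 variants and
7 drugs; blank cells are genuinely missing data and are carried as such,
never imputed.  Values from multiple sources are combined by geometric
mean, excluding entries that are only bounds or approximations.

## Pharmacokinetics

Plasma concentrations follow the standard one-compartment oral model at
steady state, periodic with the dosing interval τ:

    C(t) = (D k_a) / (V_s (k_a − k_e)) [ e^(−k_e t)/(1 − e^(−k_e τ)) − e^(−k_a t)/(1 − e^(−k_a τ)) ]

with `V_s = V_d / (S F)` absorbing salt factor and bioavailability as a
single fitted constant.  Units: days, mg, m³, hence concentrations in
µg/L.  Parameters are determined from clinical steady-state observables
(c_max, t_max, terminal half-life at the reference dose and interval) by a
deterministic three-step solve: `k_e = ln2 / half_life`; `k_a` from the
stationarity condition of the profile at `t_max` by Brent root-finding;
`V_s` from linearity in `D / V_s`.  The packaged PK config stores both the
observables (primary; loading refits from them) and the resulting
parameters as a checkpoint.  Typographic ambiguity in the source table
motivated making the config editable rather than hard-coding constants.
Axitinib and asciminib doses are estimates of a tolerable dose, not
established standards.  Drugs with τ = 0.5 d (nilotinib) tile their
periodic profile twice across the daily grid; administration offsets are
defined modulo the dosing interval.

The analytic AUC over one interval, `D / (V_s k_e)`, is verified
numerically to 1e−6 in the test suite.

## Effect normalisation and dose reduction

Treatment effectiveness is summarised by the daily mean of `f_v` (for a
periodic profile, equal daily means imply equal total growth of an
exponentially growing population — verified numerically by integrating
`dN/dt = f_v(t) g N`).  Each drug's dose is scaled so this mean equals a
common effect target, 0.1 by default (a 90 % reduction, motivated by
estimates that stem-cell reproduction is reduced to at most ~1/7 under
effective therapy).  Normalisation stands in for everything separating
plasma concentration from realised inhibition (transport, protein
binding); it is a modelling device, not a dose recommendation.

For two normalised drugs mixed as `x` effect-wise parts of A and `1 − x`
of B, the dose-reduction factor ζ solves

    mean_t 1/(1 + (xζ r_A + (1−x)ζ r_B + x(1−x)ζ² r_A r_B)^m) = target

(nonexclusive; drop the cross term for exclusive), where `r(t)` is the
normalised potency-scaled profile.  The cross term carries ζ² because it
is the product of the two administered concentrations.  ζ = 1 exactly at
x ∈ {0, 1}.  All scalar solves use bounded Brent iteration to relative
tolerance ~1e−15 (the objectives are strictly monotone in the scalar, so
nothing is gained by a quasi-Newton minimiser); integrals use the mean of
a uniform 1000-point daily grid, which is the periodic trapezoid rule.

The ratio/offset scan covers 21 equidistant ratios and 24 hourly offsets;
ties at the argmin break toward the smallest offset, then the smallest
|x − 0.5|.  With the packaged PK the imatinib–asciminib optimum sits at
x = 0.5, 12 h offset, ζ = 0.615 (each drug at ~31 % of its normalised
standard dose); bosutinib and ponatinib behave alike, while
dasatinib–asciminib is timing-sensitive and optimises off the even split
(x = 0.4, 14 h) because of dasatinib's fast elimination.

Mutation sensitivity of an optimised design uses the effective IC50 of the
fixed-ratio mixture — harmonic combination for exclusive, positive
quadratic root for nonexclusive (computed in the cancellation-free form
`2/(β + sqrt(β² + 4α))`) — normalised by the wildtype effective value.  A
mutant is flagged as *shape-enhanced* when the reduced-dose combination
inhibits it less than **either** full-dose monodrug would: the
dose-response curves of nonexclusive mixtures are steeper near the
operating point, so shifting them by a resistance factor costs more
inhibition than the effective-IC50 ratio alone suggests.

## Selection ratio χ

For a mutant and treatment, `χ(t) = f_v_mutant(t) / f_v_wildtype(t)` on a
240-point daily grid; mutant and wildtype are assumed equally fit without
drug, so χ = 1 untreated and χ > 1 means the mutant is selected for.
Supplement (axitinib) timing is optimised over 48 half-hour offsets under
either the minimum instantaneous χ or the minimum daily-mean χ (arithmetic
mean over the grid); ties break toward the smallest offset.  Scenarios use
either plasma-scale doses (profiles divided by absolute wildtype IC50
values; the packaged values are literature-representative Ba/F3 numbers,
converted µM → µg/L, needed only on this path) or effect-normalised doses:
a single backbone drug normalised to the 0.1 target, or a
backbone pair (e.g. bosutinib–asciminib) normalised jointly at an even
simultaneous split, with axitinib normalised to a 5 % growth reduction —
close to what its plasma levels support against unmutated cells.

With plasma dosing, minimising instantaneous χ places axitinib at t = 22 h
for imatinib, dasatinib and bosutinib backbones (2–3 h before the next
backbone dose, so axitinib's absorption peak coincides with the backbone
trough), while the average-χ criterion favours dosing with or shortly
after the backbone.

## Synergy analysis

Synthetic MTS plates emulate the wet-lab geometry: 96-well plates, twofold
dilution series (8 steps), triplicates, monodrug curves for imatinib,
dasatinib and asciminib plus fixed-ratio mixtures at top-concentration
ratios 6.31:0.0130, 6.31:0.0524 and 0.0130:0.0524 µM.  Truth potencies
(synthetic stand-ins; IC50 1.26, 0.0026 and 0.0105 µM, m = 2) place those
tops at ~5 x IC50 so each series spans fa ≈ 0.05–0.95.  Noise is
multiplicative Gaussian on the signal (sd 5 % by default — absorbance
noise is roughly proportional; the assay description gives no noise
model), deterministic per seed.  Rows beyond 96 wells spill onto a second
labelled plate.  The generator does not emulate edge effects, evaporation
or cell-line heterogeneity, so passing tests validate the analysis chain,
not robustness to such plate artefacts.

Fractional inhibition is `1 − signal/mean(control)` after blank
subtraction.  Median-effect fits use the classic log-linear regression of
`log(fa/fu)` on `log D` (excluding wells outside (1e−3, 1−1e−3)) as
initialisation, refined by default with least squares on the fa scale over
all dosed wells: the logit transform amplifies noise near fa = 0 and its
one-sided exclusion of out-of-range wells biases the fitted slope low at
realistic noise (simulated across 40 seeds, the log-linear slope errs by
>15 % in 80 % of runs versus 3 % for the fa-scale fit).  Both variants are
exact on noiseless data; `method="loglinear"` restores the classic
behaviour.

The combination index at effect level fa is `CI = D1/Dx1 + D2/Dx2` with
`(D1, D2)` the components of the mixture dose reaching fa under the
combination fit and `Dx_i` the monodrug doses reaching the same fa; the
three-term nonexclusive variant is available.  CI is scale-invariant, and
a perfectly exclusive mixture with shared slope gives CI ≡ 1.  Uncertainty
comes from a nonparametric bootstrap: wells are resampled with replacement
within every group of nominally identical wells (including controls and
blanks), all three curves are refitted jointly, and pointwise 89 %
percentile intervals are reported on a 50-point fa grid over
[0.05, 0.95].  This replaces the original Bayesian fitting with comparable
interval semantics at deterministic cost; whether monodrug-fit uncertainty
was propagated in the original analysis is unknown, so the bootstrap here
resamples all curves jointly.

## Numerical and design notes

- Degenerate inputs raise typed errors: k_a = k_e (singular PK form),
  unreachable effect targets, unbracketable ζ, all-saturated dose-response
  curves, missing mutant data for an active drug.
- Problem sizes: 1000-point grids for normalisation/ζ, 240-point grids and
  48 offsets for χ, 21 × 24 scan grids, 50-point fa grids; chosen to match
  the analysis protocol the package reproduces, and small enough that the
  full suite runs in minutes.
- Determinism: every pipeline output is a pure function of configuration,
  seed and packaged fixtures; workflow tables carry a version+seed header.

## Known limitations

- One-compartment PK without absorption lag or inter-patient variability;
  effect normalisation deliberately absorbs those factors.
- A single shared Hill coefficient; per-mutant slopes await published data.
- χ is a per-time-point growth-rate ratio, not a clonal dynamics model; it
  says nothing about mutation acquisition rates or outcome probabilities.
- The mixed triple interaction form is an assumption (see above).
- Synthetic plates validate the pipeline qualitatively; measured KCL-22
  combination-index curves are known to show a slight antagonistic bias
  relative to ideal nonexclusive simulations, which is not modelled.
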