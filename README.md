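# tkicombo

Median-effect modelling of tyrosine-kinase-inhibitor (TKI) combinations in
chronic myeloid leukaemia (CML), for computational pharmacologists studying
how drug combinations — in particular the allosteric Bcr-Abl1 inhibitor
asciminib with an ATP-pocket TKI, and axitinib supplementation against the
T315I gatekeeper mutation — affect dose requirements and the selection of
resistance mutations.

## The model

Growth of Bcr-Abl1-driven cells under an inhibitor at concentration *C*
follows the median-effect (Hill) relation

    f_v = 1 / (1 + (C / IC50)^m)

with *m* the Hill coefficient (default 2, scenario-wide).  Two drugs combine
*exclusively* when they compete for the ATP pocket (their potency-scaled
concentrations add) and *nonexclusively* when one binds the allosteric
myristoyl pocket (the sum gains the product cross term); a mixed triple form
covers two ATP-pocket drugs plus asciminib.  Resistance mutations enter as
relative IC50 values (mutant / wildtype; the packaged table covers 16
Bcr-Abl1 variants across 7 drugs).

On top of this sit:

* **Steady-state oral PK** (one-compartment, first-order absorption):
  periodic plasma profiles per drug, with (k_a, k_e, V_d·S⁻¹·F⁻¹) fitted
  from clinical c_max, t_max and half-life.
* **Effect normalisation**: each drug's dose is scaled so its daily mean
  f_v equals a common target (default 0.1, i.e. 90 % inhibition).
* **Dose-reduction factor ζ**: the scalar by which a mixture of *x*
  effect-wise parts of drug A and 1 − *x* parts of drug B can be shrunk
  while preserving the effect target, scanned over 21 dose ratios and 24
  hourly administration offsets; plus the effective IC50 of the optimal
  combination against each mutation.
* **Selection ratio χ = f_v(mutant) / f_v(wildtype)** over the day: χ > 1
  means the mutant (default T315I) outgrows wildtype; the administration
  offset of supplemental axitinib is optimised over 48 half-hour steps.
* **Chou–Talalay combination index** from (synthetic) triplicate MTS
  plates: median-effect fits per curve and CI(fa) with bootstrap 89 %
  compatibility intervals.  CI < 1 indicates synergy.

## Worked example

```
$ tkicombo optimize-combo --drug-a imatinib --drug-b asciminib --mode nonexclusive
optimum: x=0.50 offset=12.0 h zeta=0.6149 per-drug doses 30.7% / 30.7%
```

Read: splitting the treatment evenly between imatinib and asciminib
(effect-wise, x = 0.5), taking the two drugs 12 h apart, lets the combined
mixture be reduced to ζ = 0.61 of the normalised monodrug amounts — each
drug at ~31 % of its standard effect-normalised dose — while still holding
the daily mean growth at 10 % of the drug-free rate.

```
$ tkicombo chi-scan --backbone dasatinib --criterion instantaneous
best axitinib offset: 22.0 h | chi min 0.820, mean 1731.289, fraction of day below 1: 0.02
```

Read: with plasma-dosed dasatinib (taken at t = 0) supplemented by
axitinib, dosing axitinib at t = 22 h (about two hours before the next
dasatinib dose) transiently pushes the T315I selection ratio below one
(χ_min = 0.82), but the mutant keeps a growth advantage for ~98 % of the
day — axitinib supplementation cannot stop T315I selection.

Other entry points: `tkicombo simulate-plate` (synthetic triplicate MTS
plates), `tkicombo ci-analysis` (combination-index curves with bootstrap
intervals), `tkicombo fit-pk`, `tkicombo normalize`, and
`tkicombo run-scenario --config <yaml>` which bundles the analyses and
writes seed-stamped TSV tables.

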