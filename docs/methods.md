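# Methods

## Model

A single biallelic autosomal locus with mutated-allele frequency `q`
(normal allele `p = 1 − q`) in Hardy-Weinberg equilibrium: genotype
frequencies `q²` (two mutated alleles), `2pq` (heterozygous carrier), `p²`
(non-carrier).  Disease is assigned per individual by a genotype-specific
penetrance `(f_hom, f_het, f_non)`; `f_non` is the phenocopy rate.  The
null hypothesis "heterozygosity carries no risk" is `f_het = f_non`; the
strict recessive model is `(f_hom, 0, 0)`.  Net prevalence is
`q²·f_hom + 2pq·f_het + p²·f_non`.

Everything in the package is a view of this model: prevalence bounds
compare an observed prevalence with `q²` and `2pq + q² = 1 − p²`;
heterozygote-excess tests compare the carrier ratio `R = 2pq/p²` in
clinically ascertained patients with the population value; the risk
reconstruction inverts a prevalence plus genotype distributions into
penetrance estimates; the sibling analysis conditions the same penetrance
model on Mendelian segregation within a family.

## Rounding conventions (and why they are part of the contract)

The published tables this package validates against were computed with
explicit decimal rounding at intermediate display boundaries, so exact
reproduction requires fixing those conventions:

* All rounding is **half-up** (ties away from zero), implemented on the
  shortest decimal representation of the float via `decimal.Decimal`.
  Banker's rounding would break the published cells (`0.0025 → 0.003`,
  `0.150537 → 0.15`).
* **Expected carrier/non-carrier counts** in a size-`n` population sample:
  round `R` to 2 decimals, then `expected_het = round(n·R/(1+R), 2)`, then
  `expected_none = n − expected_het`.  This is the unique order that
  reproduces all four published pairs (5.74/38.26, 11/55, 10.07/125.93,
  3.86/35.14).  A full-precision variant is always computed alongside,
  because for the Turkish cohort the published p-value bound (<3×10⁻³) is
  met only by the full-precision variant (p ≈ 2.8×10⁻³ vs 3.2×10⁻³) while
  the published expected counts come from the rounded one.  Internally all
  chained arithmetic is unrounded; rounding happens only at these declared
  boundaries.
* **Risk reconstruction** takes the carrier ratio at its published
  one-decimal precision (default `carrier_ratio_digits=1`): for `q = 0.05`
  that is `R = 0.1`, which is what yields the published healthy
  compartments 9,082/90,818.  Compartments are rounded to integers
  (half-up, with the largest compartment absorbing the ±1 discrepancy so
  partitions always conserve the population).  Risks are displayed at two
  significant figures and relative risks at one decimal; the relative risk
  is computed from the **unrounded** risks (2.0877×10⁻³ / 3.3022×10⁻⁴ =
  6.32 → 6.3).

## Statistical tests

* **Heterozygote excess**: the observed patient pair (het, none) and the
  expected pair form a 2×2 table; Pearson chi-square without continuity
  correction, 1 df upper tail (Yates correction would break the Armenian
  bound).  Fisher's exact test (two-sided, expected pair rounded to
  integers) is available as an alternative; the tests agree within a small
  factor on well-filled tables.
* The expected pair is **deterministic** (it is an expectation, not a
  sample), while the test treats it as an equal-size pseudo-control sample.
  Under the null this roughly halves the variance the statistic assumes, so
  p-values from this construction are conservative.  That is harmless for
  the published comparisons (all strongly significant) but matters for
  calibration checks: the simulator's null-calibration property therefore
  compares simulated patients against the simulated *healthy cohort* —
  two genuine samples — for which the p-values are uniform under
  `f_het = f_non`.
* **Sibling excess**: for mating type with offspring genotype distribution
  `(P_mm, P_het, P_none)`, the expected heterozygous fraction among
  affected siblings is `P_het·f_het / (P_mm·f_hom + P_het·f_het +
  P_none·f_non)`; the observed count is tested with a two-sided exact
  binomial test.  The default mating is het×het (the generic recessive
  family); het×two_mut covers pseudo-dominant families.  A strict-diagnosis
  option removes heterozygous affected siblings whose FMF diagnosis was not
  retained on review.

## Simulator

Populations are generated at the tally level — multinomial genotype counts,
binomial affected counts per class — which is exactly equivalent to
per-individual sampling and keeps 10⁶–10⁷-individual runs at constant
memory; a per-individual stream is available on request.  A single seeded
`numpy.random.Generator` drives each run; seeds are mandatory and recorded
in outputs.

The default study condition is the Turkish calibration: `q = 0.05`,
prevalence 0.001, `f_het = 19/9101 ≈ 2.1×10⁻³` and `f_non = 30/90848 ≈
3.3×10⁻⁴` (the maximum-likelihood values implied by the closed-population
reconstruction), with `f_hom ≈ 0.2015` solved so the net prevalence is
exactly 0.001.  The implied two-mutation penetrance of ~0.2 is itself a
finding of the reconstruction: at the reported prevalence, far fewer
two-mutation carriers are diagnosed than exist.

Families draw a parental mating from HWE conditioned on the pair being able
to produce a two-mutation child (weights `q⁴ : 2·q²·2pq : (2pq)²` for
mm×mm, mm×mN, mN×mN), then children by Mendelian segregation and phenotypes
by penetrance.  Ascertainment is **single**, through a fixed proband slot:
a draw is accepted when the first child is an affected two-mutation proband
and at least one later sibling is affected.  With single ascertainment the
siblings remain an iid draw, so conditional closed forms (e.g. the affected
-sib heterozygous fraction `(P_het·f_het)/(P_het·f_het + P_mm·f_hom)` for
`f_non = 0`) hold exactly; ascertaining instead on "any affected mm child"
would over-count families whose only affected pair is proband+heterozygote.
Sibship sizes default to uniform on {2, 3, 4} (family-structure detail is
not published; this brackets typical sibships in the study populations).
Rejection sampling aborts with a diagnostic if a family is not accepted
within 10⁶ draws.

What the simulator deliberately does **not** model: mutation-specific
effects (genotypes are abstracted to carrier classes), variable expressivity
and age of onset, shared family environment, and any non-*MEFV* genetic
architecture.  Passing tests therefore show the statistical machinery is
correct under the stated model, not that the model captures every feature
of real FMF cohorts.

## Known inconsistencies in the published numbers

These are reported, flagged, and never forced:

* The published Sephardic recessive-prevalence cell (0.005) is inconsistent
  with the published allele frequency `q = 0.09` (`q² = 0.0081`); the
  package reports 0.008.
* The E148Q-inclusive allele frequencies were never published; the packaged
  values (Turkish 0.1, Sephardic 0.14) are back-derived from the published
  recessive cells and flagged.  No Sephardic `q` reproduces both published
  E148Q cells under half-up display (0.14 gives 0.02 but a carrier-causal
  bound of 0.26 → 0.3, not the printed 0.2).
* The Turkish expected counts 3.86/35.14 imply `R = 0.11` (two-decimal
  rounding of 0.10526) while the ratio itself is printed as 0.1; both
  variants are reported.
* The published relative-risk endpoints use inconsistent rounding: 6.3
  (Turkish) is the unrounded ratio, while 8.1 (Sephardic) is only
  reachable from display-rounded risks.  The package uses the unrounded
  ratio uniformly; the shipped back-derived Sephardic scenario (fractions
  0.6075/0.2425/0.15 at prevalence 0.004, chosen to give integer
  compartments 243/97/60 and the published risk 5.8×10⁻³) computes RR 8.04
  → 8.0.
* The published 92% two-mutation fraction among affected siblings recomputes
  to 63/69 = 91.3%; both are reported.
* The family table is a reconstruction: only its totals were published
  (63 families; 69 affected siblings, 63 mm / 6 mN with 3 diagnoses not
  retained; 16 unaffected mN siblings), and the packaged per-family layout
  is any arrangement consistent with them.  All summary statistics depend
  only on the totals.

## Numerical and design choices

* Verdicts comparing observed prevalence with the model band use unrounded
  values, so display rounding can never flip a qualitative conclusion.
* `1 − p²` is computed as `q·(2 − q)` to avoid cancellation at tiny `q`.
* Degenerate inputs fail loudly: `q = 1` (no non-carriers) raises an
  undefined-ratio error, all-zero penetrances and zero-column 2×2 tables
  are rejected, populations too small to contain one patient are refused.
* Patient-fraction partitions must sum to 1 within 10⁻⁹.
* Test problem sizes: parameter recovery uses 20 populations of 10⁶;
  null calibration 200 populations of 10⁶; Hardy-Weinberg calibration
  1,000 populations of 10⁵; Fisher-vs-enumeration equivalence sweeps every
  2×2 table with row sums ≤ 30; chi-square p-values are cross-checked
  against 10⁵ Monte-Carlo null simulations per study table.  These sizes
  give sampling errors comfortably below the asserted tolerances while
  keeping the suite quick on one CPU.

## Limitations

The risk reconstruction is a point estimate with no sampling uncertainty —
uncertainty statements should come from the simulator (seeded replicate
runs), not from the reconstruction.  The heterozygote-excess test inherits
the conservatism described above.  All conclusions are conditional on the
published allele frequencies and prevalences, which carry their own
(unmodelled) estimation error.
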