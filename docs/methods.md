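# Methods

`drivecage` models a single-locus CRISPR homing suppression drive in a
discrete-generation insect cage population and estimates the fitness cost
of drive/wild-type females from DsRed phenotype trajectories. This note
documents the model, its assumptions, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## The allele and transmission model

Three allele classes segregate at the target locus: wild-type `W`, the
drive construct `D` (scored by its DsRed body marker), and nonfunctional
resistance `R` (an end-joining repair product that the drive can no longer
cut and that also disrupts the target gene). Six unordered genotypes
follow. The target gene is a haplosufficient female-fertility gene, which
fixes the phenotypic rules:

- **Germline conversion.** Only drive/wild-type (`D/W`) germlines are
  active. The wild-type allele is converted to drive with probability `c`
  (homing) or to resistance with probability `r`, so gametes are drawn as
  P(D) = (1+c)/2, P(R) = r/2, P(W) = (1−c−r)/2. Rates are sex-specific:
  default `c_f = 0.076`, `c_m = 0.146`, with `r = c/2` in each sex (the
  resistance rate is tied to conversion because both arise from the same
  germline cuts). All other genotypes transmit each carried allele with
  probability 1/2; in particular `D/R` and `D/D` germlines carry no
  wild-type target and transmit without conversion, and `R` is terminal
  (no further editing of resistance alleles).
- **Female sterility.** Females with no wild-type allele (`D/D`, `D/R`,
  `R/R`) are sterile. Heterozygotes are fertile (haplosufficiency), and
  `W/R` females have full fitness.
- **Fecundity cost.** `D/W` females produce offspring at relative rate
  `f` (`f_het`, wild-type = 1); the fitness cost is `1 − f`. This is the
  single free parameter of the inference. Males carry no costs and are
  never sterile.
- **Maternal carryover.** Cas9 deposited in the egg by a drive-carrying
  mother may convert each zygotic `W` allele to `R` with probability
  `embryo_cut_rate`. The default is 0 (germline cut rates are low enough
  that embryo resistance is negligible), but the machinery is implemented
  and tested so the assumption can be relaxed.

The locus is treated as autosomal with independent 50/50 offspring sex
assignment.

## Cage generation cycle

A cage is a closed population at fixed census `N` (default 120, the
seeding size: 15 + 15 drive-heterozygous males and females plus 45 + 45
wild-type, i.e. 25% carriers). One generation:

1. every fertile female picks one male uniformly at random, with
   replacement (males may mate multiply; mate choice is the female's);
2. each mated pair contributes offspring in proportion to the mother's
   fecundity weight;
3. the next generation of exactly `N` individuals is drawn multinomially
   from the fecundity-weighted mixture of pair offspring distributions,
   then split into sexes binomially.

A multinomial draw over the pair mixture is used instead of per-female
Poisson litters: identical in expectation, cheaper, and aligned with the
frequency-based likelihood. If no fertile female or no male remains the
cage goes extinct (an empty population propagates as zeros rather than
raising mid-run).

The deterministic infinite-population limit of the same cycle
(`expected_phenotype_trajectory`) iterates genotype frequencies through
fecundity-weighted random mating. One subtlety worth stating: even with
`c = r = 0` and `f = 1` the carrier frequency declines slowly, because
homozygous-female sterility is a structural rule, not part of `f`. The
recursion — not a flat neutral line — is therefore the reference curve for
all "no drive activity" checks.

## Likelihood and fitting

The observable per generation is the DsRed-positive count `k_t` of
`n_t` phenotyped flies. The likelihood at candidate fitness `f`:

1. Generation 0 genotypes are known exactly: all carriers are `D/W`
   (founders inherit the drive paternally and embryo cutting is off).
2. The state advances one generation with the deterministic recursion,
   giving a predicted carrier frequency `p_t`.
3. The observation contributes the binomial kernel
   `k_t log p_t + (n_t − k_t) log(1 − p_t)`; combinatorial constants are
   dropped consistently, which shifts nothing that depends on `f`.
4. The genotype state is then reconditioned on the observed phenotype
   split: frequencies within the carrier class are rescaled by
   (observed/predicted carrier fraction) and likewise for non-carriers.
   This keeps the model state anchored to the measured trajectory instead
   of compounding drift across twelve generations.
5. Replicate cages are independent; their log-likelihoods add.

`CageFitnessModel.fit()` scans `f` on a grid (default step 0.005 over
[0, 1.5] — the upper bound deliberately exceeds 1 so a spurious benefit is
detectable rather than clipped), refines the optimum with a bounded scalar
search to 1e−4, and reports a 95% likelihood-ratio interval (drop of
χ²₁/2 = 1.92 log-units, endpoints bracketed on the grid and solved by
root-finding). A profile whose finite range is below 1e−6 log-units is
flagged unidentifiable (e.g. a trajectory with no carriers) and the CI
widens to the search bounds. All drive-performance rates stay fixed during
the fit; only `f` is estimated, because the cage data cannot separate
conversion, resistance, and fecundity effects at these sample sizes.

At the experimental census (120) the estimator shows a small upward bias
of roughly 2–3 percentage points on the cost scale (mean estimate ≈ 0.49–
0.50 for a true cost of 0.47 over replicate experiments); it shrinks below
a point at census 10⁴. This is the usual finite-population mismatch
between a deterministic-recursion likelihood and drifting data, and it is
well inside the spread of single-experiment estimates (SD ≈ 0.10 at
census 120).

## Synthetic data

The generators emulate the three experimental designs:

- **Crosses** — per-vial offspring totals are Poisson (mean 100 by
  default; real vial sizes are not fixed) and DsRed-positive counts are
  Binomial(n, (1+c)/2) with the drive parent's sex rate.
- **Cages** — full genotype-resolved simulation as above, with truth
  columns carried through the file format.
- **Fecundity** — per-female daily egg counts are negative binomial
  around group means (wild-type 24.46, heterozygote 23.57, homozygote
  5.40, homozygote-on-octopamine 26.76 eggs/female/day) with dispersion
  `k = 5`; only group means are specified by the underlying measurements,
  so the noise model and its dispersion are this package's choice of a
  realistic overdispersed count distribution. Octopamine feeding is
  modelled as restoring the homozygote mean only; normal females keep
  their baseline means.

What the generators do **not** emulate: overlapping generations,
egg-to-adult viability selection, density dependence, male mating-success
costs, functional (in-frame) resistance alleles, multiplexed-gRNA allele
classes, vial-to-vial heterogeneity in conversion (sequence polymorphism
enters only as a pass-through label), and partial egg-laying by
drive-homozygous females (the inference model assumes full sterility even
though real homozygotes lay a few eggs). Passing tests therefore certify
internal consistency of model, simulator and estimator under these
idealisations — not that real cage data meet them.

## Numerical and design notes

- Genotype frequency vectors are length-6 numpy arrays in a fixed
  canonical order; gamete tables and the 6×6×6 pair-offspring tensor are
  precomputed per parameter set, and profile scans reuse them (only the
  fecundity weights depend on `f`).
- Gamete distributions must sum to 1 within 1e−12; conditioned states
  renormalise to 1 within 1e−12.
- The Fisher exact test against Mendelian inheritance compares the
  observed split to an expected half/half split of the same total, odd
  totals resolved by rounding the expected positive count half up. The
  test construction (not just the test name) is a package choice and its
  p-values are reported, never used as fit inputs.
- t-tests on fecundity use the female as the unit of analysis (daily
  counts averaged per female first), Student's equal-variance by default
  with Welch as an option.
- The vial-averaged and count-pooled inheritance rates are both reported;
  they differ whenever vial sizes differ, and conversion rates derive from
  the pooled rate via `c = 2p − 1` (clamped at 0 with a flag when
  p < 0.5). Optional per-vial weights support weighted pooling, but no
  default weighting scheme is assumed.
- Problem sizes in the test suite and the acceptance script (replicate
  counts of 100 for simulate-then-fit experiments, 200 synthetic datasets
  for cross summaries, 30 females per fecundity group) were chosen to keep
  Monte-Carlo standard errors a few times smaller than the effects being
  checked.

## Known limitations

- The likelihood conditions on observed phenotype counts each generation;
  an unconditioned forward expectation is a plausible alternative and
  would weight late generations differently. Conditioning was chosen
  because it tracks the measured trajectory and keeps per-transition
  binomial errors approximately independent.
- The LR-based confidence interval relies on the χ²₁ asymptotics of a
  one-parameter profile; at census 120 with three cages its coverage is
  approximate.
- Drift enters the data but not the likelihood's state propagation
  (beyond the conditioning step), which is the source of the small
  finite-census bias described above.
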