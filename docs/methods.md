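# Methods

## The question the pipeline answers

A gene that a driver oncogene upregulates when that oncogene is the only
active driver may behave differently when c-Myc, mutant KRAS and mutant
p53 are co-expressed: its control may persist (non-redundant), be shared
(redundancy possible), or be taken over entirely by the co-expressed
oncogenes (redundant). The pipeline quantifies this from
control-vs-knockdown differential expression in cell lines with one
versus three active oncogenes, and checks the mirror-image association
pattern in patient cohorts.

## Regulatory model and synthetic data

Every simulated gene carries a control mode, a set of regulating
oncogenes, a dominance order (a permutation of the three oncogenes), an
effect size in log2 units, a baseline mean and a negative-binomial
dispersion. The expected log2 abundance in a genotype is the baseline
plus the sum of per-oncogene contributions:

* **null** — no contribution.
* **redundant** — the highest-ranked active regulator contributes the
  full effect; the others contribute nothing. Any single active
  regulator therefore drives the gene alone, and co-expression changes
  *who* controls it, not *how much* it is expressed.
* **cooperative** — every active regulator contributes the full effect
  additively (a `cooperative_share` parameter can scale this, or split
  the effect equally). Joint activation exceeds individual activation,
  which is what distinguishes cooperation operationally.
* **competitive** — the dominant active regulator contributes the full
  effect; co-active sub-dominant regulators contribute a *negative*
  fraction (default 0.5) of it. Knocking down a sub-dominant competitor
  therefore raises expression. The magnitude of the opposing effect is
  not constrained by data, so it is an explicit parameter.

A knockdown removes the knocked-down oncogene's contribution, scaled by
an efficiency parameter (default 1.0, i.e. complete loss at the 48 h
collection point; compensation over longer time scales is deliberately
not modeled). The planted redundancy class of each (gene, oncogene) pair
is derived deterministically from these rules for the single-{X} and
triple genotypes and serialized with every dataset, so recovery can be
scored exactly.

mRNA counts are gamma–Poisson (variance μ + μ²φ) with per-gene baselines
drawn log-uniformly between 50 and 5,000 counts; protein intensities are
log-normal around the same planted means with σ(log2) = 0.3
(multiplicative error is the dominant proteomics noise). Per-sample
library-size factors are log-normal with σ = 0.15 so that size-factor
normalization is non-trivial. The generator-wide default dispersion is
φ = 0.1, a typical bulk RNA-seq figure across heterogeneous samples.

**Panel dispersion.** The default *panel* configuration (and the
recovery analyses) uses φ = 0.02, appropriate for biological replicates
of an isogenic cell line harvested 48 h after transfection. This is a
consequential choice: a design power analysis for the two-sample t-test
at n = 3 per arm shows per-gene power ≈ 0.95 at |LFC| = 2 for φ = 0.02
but only ≈ 0.5 at φ = 0.1, and class-percentage recovery within ±5
points requires per-test power ≳ 0.9 (misses demote shared genes into
the non-redundant or redundant classes asymmetrically).

**What the generator does not emulate**: read-level sequencing noise,
isoform structure, copy-number variation, batch effects, correlated
genes, GC/length biases, partial or variable knockdown efficiency per
cell line, and compensatory rewiring after oncogene loss. Passing the
recovery tests therefore demonstrates the *analysis logic* is correct
under the declared noise model, not that real datasets of this size
would yield the same accuracy.

## Differential analysis

mRNA: relative-log-expression size factors (median across all-positive
genes of the ratio to the per-gene geometric mean), log2(x + 1), per-gene
two-sample t-test, Benjamini–Hochberg; significant at q < 0.05. Protein:
total-protein-approach proportions (each intensity divided by its
sample's total), log2 with a pseudocount of half the smallest positive
proportion, t-test; significant at raw p < 0.05. The log fold change is
the difference of log2 means (knockdown − control). Thresholds are
configurable.

The test is the pooled-variance Student's t. The Welch–Satterthwaite
variant is exposed (`welch_t`, and `welch_t_rows(equal_var=False)`) but
is not the default inside `differential_analysis`: at n = 3 per arm the
Welch test is intrinsically conservative (measured type-I rate ≈ 0.035
at α = 0.05 even on ideal normal data), which would break the null
calibration property the pipeline is tested against, while the pooled
test is exact under the equal-variance design the panel actually has.
A negative-binomial GLM with dispersion shrinkage is deliberately not
re-implemented; downstream stages consume only (gene, LFC, p, q) and
accept externally produced tables.

## Redundancy classification

Pools are built per oncogene and context from mRNA tables only
(protein-layer redundancy is out of scope), restricted to a coding-gene
filter, with multiple cell lines per (oncogene, context) combined by
union (intersection available). Classification is pure set logic over
(single pool, own triple pool, union of the other two triple pools).

Two denominator conventions exist for the percentages because genes in
the single-context pool that vanish from *both* triple pools
("context-dropped") could be counted either way. The package reports
percentages over the three informative classes (summing to 100) and,
alongside, the all-inclusive variant — both appear in
`redundancy_summary.json`.

Membership ignores the direction of regulation by default, matching the
set-based treatment of gene pools; a strict mode requiring sign
concordance between contexts is available
(`classify_redundancy(..., require_sign_concordance=True)`).

Residual recovery bias: with ~0.95 per-test power, a shared gene whose
own-knockdown signal is missed in the triple line is misread as
redundant, and one whose other-oncogene signal is missed as
non-redundant; false positives under BH also promote a few specific
genes into the shared class. At default panel settings this biases the
recovered split from 60/30/10 to roughly 56/31/13 — within the ±5-point
band the recovery tests assert, and a useful reminder that the measured
"redundant" fraction is an upper-ish estimate at finite power.

## Patient cohorts

Strata follow exclusive definitions: MYC-high means strictly above the
cohort-mean MYC expression; the TP53 stratum uses missense mutations
only; TP53-null (nonsense/frameshift) is *not* missense and is eligible
for the control group (MYC-low, TP53 WT/null, KRAS WT). The signature
score is the plain per-patient mean of the listed genes (a z-score-first
variant is available; with genes on a common normalized scale the plain
mean matches practice).

Association lists use a per-gene Student's t of the stratum against a
comparator, BH-adjusted at FDR < 0.001. The default comparator is the
rest of the cohort. For *planted-overlap recovery* the pipeline's
default configuration uses the control-group comparator instead: with
the rest-comparator, a gene elevated only in oncogene-X patients is also
*negatively* associated with the other oncogenes' strata (whose
comparator group contains X-active patients), so the sign-agnostic
overlap saturates near 100 % by construction and no planted fraction can
be recovered. Both comparators are exposed; the choice is recorded in
each run's manifest.

Survival: two-group log-rank over the shared risk-set table with the
hypergeometric variance; hazard ratio estimated as (O₁/E₁)/(O₂/E₂),
which is closed-form and exactly testable against a hand-computed table.
A proportional-hazards fit with covariates is out of scope.

## ΔΔCt

Replicate Ct values are averaged on the cycle scale before
exponentiation (averaging fold values instead would bias the estimate
upward by Jensen's inequality). Amplification efficiency is fixed at 2.0
by default and exposed as a parameter.

## Numerical and design choices

* Gene identifiers are uppercased at ingest; duplicate feature ids are
  rejected. Matching is exact-string; no alias resolution.
* The enrichment background defaults to the features quantified in the
  experiment, not the genome, matching detection bias.
* Hypergeometric p-values are upper-tail P(X ≥ k); zero overlap gives
  p = 1.
* Degenerate t-tests: zero variance in both arms with equal means gives
  p = 1; with unequal means the p → 0 limit is returned.
* Target selection ties break deterministically: total count descending,
  then mRNA count descending, then lexicographic gene id.
* Recovery analyses in the tests and the acceptance script use 2,000
  genes × 30 samples per panel seed, 5,000 genes for null calibration,
  and 300-patient cohorts with 1,500 genes — sizes at which every
  recovery property is stable across seeds while a full suite run stays
  in the low minutes.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit arguments; identical configuration and seed reproduce outputs
  byte-identically, which the tests assert on whole run directories.

## Known limitations

* The percentages carry no uncertainty estimates (no bootstrap), by
  design.
* The redundancy classifier is threshold-based set logic; near-threshold
  genes flip classes under resampling, which is why recovery is asserted
  on percentages rather than per-gene labels.
* The cohort generator draws oncogene statuses independently, ignoring
  the co-mutation structure of real tumors; stratum sizes in real
  cohorts will differ.
* The stand-in differential stage does not share variance information
  across genes and is therefore less powerful than shrinkage-based
  methods at n = 3; real-data users can import externally produced DEG
  tables instead.
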