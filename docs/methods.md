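# Methods

This note documents what `crossblup` simulates and fits, the defaults and
why, the numerical choices, and what the test suite does and does not
establish.

## Population simulator

**Lines and founders.** Three parental lines share ancestral allele
frequencies drawn uniformly on (0.1, 0.9) per marker. Each line's
frequencies are Balding–Nichols draws,
Beta(p(1−F)/F, (1−p)(1−F)/F), with divergence F playing the role of a
fixation index: the expected pairwise Hudson-type Fst between two lines with
divergence F is ≈ F. The default F = 0.15 expresses "genetically distant but
same species"; no published within-line frequency spectra exist to calibrate
it further, so it is a package choice. Founder haplotypes are independent
Bernoulli draws at the line frequencies (linkage equilibrium in founders;
LD arises downstream only through co-segregation in the pedigree).

**Genome and meiosis.** Default 10 autosomes of 1 Morgan with markers evenly
spaced; crossover counts are Poisson per chromosome with mean equal to the
map length (no interference), positions uniform. Sex chromosomes are never
simulated — the cleaning rules would remove them anyway. Gamete 0 of every
animal is the paternal gamete, which makes the crossbreds' sire-line gamete
identifiable by construction and gives the exact invariant that 50% of a
crossbred's alleles carry line-A origin labels.

**Mating design.** F1 dams are B×C crosses of founder pools; purebred
offspring come from (both + purebred-only) sires × purebred dams, crossbred
offspring from (both + crossbred-only) sires × F1 dams. Full-sib family
sizes are geometric on {1..11} (p = 0.60 purebred, 0.64 crossbred): the
published family-size distribution of the motivating broiler study is
near-geometric (observed proportions 0.604/0.232/0.098 for sizes 1/2/3 vs
geometric(0.60) 0.600/0.240/0.096). Every eligible sire receives at least
one family; a repeated (sire, dam) draw extends the existing family, so a
full-sib family is exactly one (sire, dam) pair.

**Traits.** A trait carries separate purebred and crossbred definitions:
QTL (a random subset of markers, observed-QTL regime) receive effect pairs
from a zero-mean bivariate normal with correlation r_pc, then each effect
vector is rescaled so that the realised variance of true breeding values
equals the target heritability *exactly* in its base group (purebred
offspring for the purebred trait, crossbred offspring for the crossbred
one), with total phenotypic variance 1. Rescaling by a scalar preserves the
effect correlation. The same crossbred effects apply to B- and C-origin
alleles: the model is additive, line differences arise through allele
frequencies only. Defaults are the two body-weight settings of the
motivating study, (h²_PB, h²_CB, r_pc) = (0.09, 0.18, 0.80) and
(0.22, 0.23, 0.96), the second with 4% record dropout emulating mortality
between the two weighings.

**Phenotypes.** value = fixed class effect (batch×pen×sex×age; one N(0,
0.5²) draw per observed level) + own-trait true breeding value + maternal
permanent-environment effect per dam (default variance 0.05) + residual
(variance 1 − h² − σ²ₘ for the animal's group). Ages jitter ±1 day around
the nominal day so the age factor is non-degenerate. Pens within a batch are
allocated predominantly to one genetic group with a 5% mixing probability,
reproducing the "most pens ≥90% one group" housing pattern.

**What the generator does not emulate**: ancestral LD and realistic
haplotype block structure, selection over generations, genotyping error,
genotype-by-environment interaction (purebreds and crossbreds share one
environment by design), dominance/epistasis (so r_pc < 1 is imposed through
effect correlation, not emergent). Passing tests therefore show the
*pipeline arithmetic and estimators* behave as designed under the stated
statistical structure, not that real data would yield the same scenario
rankings.

## Quality control

Filter order is fixed: location → call rate (markers, then animals) →
Mendelian consistency → MAF, followed by within-group per-marker mode
imputation. Choices the cleaning rules leave open:

* outlier mean/sd are computed once on the unfiltered group (no iteration),
  with the sample (n−1) sd; groups of <2 records pass through with a
  warning;
* call-rate boundary: a marker/animal at exactly 90% is kept ("lower than"
  is the removal condition);
* Mendelian: inconsistency = opposing homozygotes; markers with >1%
  inconsistent evaluable pairs removed; on surviving markers both members of
  an inconsistent pair are masked; animals with >1% inconsistencies across
  markers are flagged;
* MAF < 0.005 in the genotype matrix *or* among the crossbreds' sire-origin
  (BOA) alleles removes the marker. The BOA-file MAF is computed on
  sire-origin alleles only, because that is the allele set entering the
  partial matrix;
* imputation is deterministic (mode, ties toward the lower dosage). Each
  filter is idempotent; the pipeline including imputation is not strictly
  so, because imputed genotypes ignore the pedigree and can create new
  opposing-homozygote pairs — at simulation missingness levels this affects
  a handful of boundary markers at most.

## Relationship matrices

All four constructions are single cross-products W W′ and hence positive
semidefinite. The centring frequency and the Σ2p(1−p) denominator of a
block always use the same frequency vector. The sire-line frequency pools
the purebred sires' two alleles with each crossbred's one sire-origin
allele, following the partial-matrix definition; whether to pool sires only
or all purebred animals is exposed through which genotypes are passed to
`compute_allele_frequencies`. In the displayed form of the BOA matrix the
purebred block and the cross block are centred with the same sire-line
frequency, which is one defensible reading of the construction and the one
that keeps the whole matrix a cross-product. Unassigned-origin codes (9)
enter partial matrices as the mean (centred 0) and are excluded from the
frequency pooling; the simulator never emits them. Frequencies are computed
on each fold's analysis set (reference + candidates), which is deterministic
per fold and replicate.

## Mixed models

EM-REML uses the P-matrix form of the expectation-maximisation update,
σ²ₖ ← σ²ₖ + σ⁴ₖ/qₖ (y′PCₖPy − tr(PCₖ)), which keeps components positive and
the restricted likelihood monotonically non-decreasing; convergence is a
likelihood change < tol (default 1e−8, capped at 500 iterations;
non-convergence warns and returns the best iterate flagged). EM is robust
but slow near flat optima — estimates stabilise long before the likelihood
criterion is met, and tests cross-check the fixed point against a direct
Nelder–Mead maximisation of the same restricted likelihood. REML is run on
the phenotyped animals only (candidates integrate out of the restricted
likelihood); prediction then solves Henderson's equations over the full GRM
index, so unphenotyped candidates receive GEBV through their genomic
covariances. G is regularised by +1e−6 on the diagonal before inversion.
The one-factor fixed design (combined batch|pen|sex|age class) is full rank
by construction; a pivoted-QR guard handles any degenerate input. A maternal
variance of exactly 0 drops the term rather than producing an infinite
variance ratio.

Dense linear algebra bounds practical problem sizes at a few thousand
records per fit; that covers the package's simulation scales. Variance
components for prediction are estimated once per trait × scenario on the
first replicate's full reference data and reused across replicates and folds
(configurable override); re-estimating per fold changes third-decimal
validation correlations at these scales. The crossbred heritability used in
reliability weights defaults to animal-model REML on all crossbred records
(`h2_policy="animal"`), with `"sire"` (4σ²ₛ/(σ²ₛ+σ²ₘ+σ²ₑ)) or a fixed number
as alternatives.

Corrected phenotypes come from one sire-model fit per trait on *all*
crossbred records, never per replicate, so validation records are identical
across scenarios and replicates.

## Scenario engine

Each replicate draws a family-matched crossbred subset (per family size s,
as many crossbred full-sib families as there are purebred ones, all of them
when fewer exist) and one near-even random partition of the sires with
crossbred offspring into five cross-validation groups. Offspring follow
their sire's group, which enforces, by construction, that validation units
have no offspring and no paternal half-sibs in the reference set; the
engine asserts it anyway. The same subset and partition serve all scenarios
and traits of the replicate, so scenario contrasts are paired. The subset is
sampled once per replicate from the first trait's records; a later trait's
analysis intersects it with that trait's records (mortality removes a few
animals rather than re-sampling the subset). Purebred offspring of sires
without crossbred offspring are part of every purebred reference set.
Replicate r uses seed base_seed + r, so any replicate is reproducible in
isolation. Ties in the win-fraction statistic count 0.5.

Two structural properties of the design that the suite verifies
empirically: (i) with individual-record validation, the full-G crossbred
reference out-correlates the sire-line BOA reference even though its sire
GEBV are no better — the dam alleles predict the dam genetic component left
in the corrected records; (ii) even at r_pc = 1 with identical lines and
equal, family-matched reference sizes, a purebred reference beats a
crossbred BOA reference on offspring-average validation, because the
sire-line alleles of a crossbred record carry only half the genetic
variance while the rest of the record acts as noise.

## Test-harness problem sizes

The suite exercises the pipeline at desk scale: simulated studies of ~30–40
sires, 900–1200 markers, ~1000–1300 crossbred records; 20 seeds for the
heritability-recovery check; 30 seeds for the realised-r_pc check; 30
replicates for the scenario-contrast check; ≥500 replicate pairs for the
overlap arithmetic on the published family table. At these sizes the
complete suite runs on one CPU in well under half an hour. Larger runs
(e.g. the full 161-sire, 50k-marker configuration) are supported by the same
code paths through the CLI but take correspondingly longer.

## Known limitations

* No single-step (pedigree-blended) matrices, no dominance or epistatic
  relationship matrices, no multi-trait REML.
* Phasing/BOA assignment is not implemented: the simulator provides exact
  origin labels, and real-data mode expects BOA codes as input.
* EM-REML's convergence criterion is conservative; very flat likelihoods
  (small σ²ₘ with few dams per sire) end with a non-convergence warning
  although the estimates have stabilised.
* The dam-line partial matrix centres the purebred block with dam-line
  frequencies to preserve the cross-product form; other centrings are
  conceivable and would change sire-block relationships by a constant-ish
  shift absorbed in prediction.
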