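# Methods

## The estimation problem

Long-term forest censuses classify each tagged stem into an ordered ladder
of size classes — here the canonical 12-class ladder: new seedling
(age < 1 yr), aged seedling (height < 30 cm), sapling (30 cm–2 m),
juvenile (≥ 2 m, DBH < 5 cm), then DBH classes D10 … D80 in 10-cm bins
(D80 open-ended).  The estimands are, per species *k* and class *i*, the
annual probabilities of stasis *S*, progression *G* (one class up) and
retrogression *R* (one class down, allowed only for the flexible sapling
and juvenile stages).  Derived quantities are annual survivorship
*S + G + R*, mortality 1 − (*S + G + R*), and the growth index
*G*/(*S + G + R*) — the probability that a survivor advances a class in a
year, the stage-classified surrogate for a growth rate.

Two structural zeros follow from the ladder's semantics: a surviving new
seedling necessarily leaves class 1 (*S*₁ = *R*₁ = 0), and a stem in its
species' maximum class cannot advance (*G* = 0 there).  Per species the
identifiable inventory is therefore *S* at classes 2–12, *G* at 1–11 and
*R* at 3–4: 24 elements, 408 over a 17-species community.

## Mixed observation intervals

Surveys mix 1-, 2- and 4-year intervals (annual seedling censuses;
quadrat surveys of saplings/juveniles in 1987, '89, '90, '92, '94, '96,
2000, 2004; whole-plot surveys of DBH classes in 1987, '89, '91, '93,
'97, 2001, 2005).  Multi-year tallies are linked to the annual rates by
composing one-step moves, under the modelling restriction that a stem
never nets more than one class per observation interval:

    S_{i,2} = S² + G·R₊ (+ R·G₋, dropped)
    G_{i,2} = S·G + G·S₊
    R_{i,2} = R·S₋ + S·R

with 4-year rates obtained by applying the same composition to the 2-year
rates.  The down-then-up term *R·G₋* of the stasis composition is dropped
deliberately (such paths are vanishingly rare at these rates); the exact
two-step enumeration differs from the simplified stasis by exactly
*R·G₋*, an identity the test suite asserts to machine precision.
Out-of-ladder neighbours contribute structural zeros.

## Likelihood and hierarchy

Each tally cell (species × class × interval length) holds the counts
*N*(all) starting the interval and *N*(ST), *N*(PR), *N*(RT) of survivors
by outcome.  Rather than modelling (S, G, R) directly, the likelihood
factorizes into three nested binomials on an equivalent conditional
parameterization — survival *P*(SV) = S+G+R; stay-or-advance given
survival *P*(ST or PR | SV) = (S+G)/(S+G+R); stay given stay-or-advance
*P*(ST | ST or PR) = S/(S+G):

    N(ST)+N(PR)+N(RT) ~ Bin(P(SV), N(all))
    N(ST)+N(PR)       ~ Bin(P(ST or PR | SV), N(ST)+N(PR)+N(RT))
    N(ST)             ~ Bin(P(ST | ST or PR), N(ST)+N(PR))

with the interval-linked rates substituted for 2- and 4-year cells.  Each
conditional probability is a free value in [0, 1], so sampling on the
logit scale keeps every posterior draw a valid rate triple by
construction.  Degenerate denominators use the harmless conventions
*P*(ST or PR | SV) := 1 when nothing survives and *P*(ST | ST or PR) := 1
when no survivor stays-or-advances (zero-probability branches).

Species are exchangeable within a class: for each class × probability
type, logit *p* per species is Normal(μ, σ²) with hyperpriors
μ ~ Normal(0, 1000) and 1/σ² ~ Gamma(shape 100, rate 100).  The Gamma
hyperprior concentrates the precision near 1 (sd ≈ 0.1), i.e. roughly
unit logit-scale scatter between species; data-free species–class cells
shrink to the class hyperdistribution, which is what makes single-digit
sample sizes usable.  Although hyperparameters are per class, the 2- and
4-year linking couples neighbouring classes' parameters, so one joint
posterior over all classes is sampled.

## Sampler

Adaptive random-walk Metropolis on every species-level logit, proposing a
cell's 17 species in one vectorized pass (their likelihoods are
conditionally independent), plus Gibbs-exact conjugate updates for each
cell's μ (normal) and precision (gamma; the full conditional is conjugate,
so no Metropolis step is needed).  Each cell also gets a joint translation
move — μ and all its species logits shifted together — because the
species-level prior is invariant under that shift, it recenters the whole
hierarchy in one step and removes the slow joint drift that data-poor
cells (top DBH classes) otherwise show.  Proposal scales adapt during
burn-in only (Robbins–Monro toward 44% acceptance for single-site moves,
30% for translations), so the retained chain is a fixed-kernel Markov
chain.  A proposal's likelihood delta touches only tallies within two
classes of the updated class (one for 2-year cells, zero for 1-year),
which the compiled kernel exploits.

Defaults reproduce the reference analysis: 3 chains × 300,000 steps,
200,000 burn-in, thinning 20 (15,000 retained draws); initial values −11
for the logits, −1 for μ, 1 for the precisions; logits clamped at ±30
before exponentiation so the near-zero initial probability cannot
overflow.  Draws are reproducible given the seed; chains differ only by
derived seeds.  Convergence is summarized by the classical Gelman–Rubin
potential-scale-reduction factor per parameter (zero within-chain
variance is flagged, never divided by); an arviz cross-check is part of
the test suite.  Posterior summaries are means over all retained draws;
derived quantities (mortality, growth index) are computed per draw and
then averaged — the order matters because the growth index is a ratio —
with 95% equal-tailed intervals as auxiliary output.

Species' maximum classes are enforced structurally: the stay-probability
at a species' maximum class carries no parameter (it is 1, so *G* = 0),
while classes above the maximum still receive prior-shrunk draws, since a
fit-everything-then-exclude convention keeps the parameter layout uniform
across species.

## Comparative stage

Per class, survivorship and growth are logit-transformed (values clamped
to [10⁻⁶, 1−10⁻⁶]; hierarchical shrinkage makes exact 0/1 essentially
impossible, but synthetic edge cases must not produce infinities) and
tested for association across species twice: ordinary Pearson *r* with a
two-sided *t*-test on *n* − 2 df, and Pearson *r* on Felsenstein's
standardized independent contrasts with (*n* − 1) − 2 df — contrasts are
treated as ordinary points for the test, not forced through the origin;
back-computing *t* from published (r, n) pairs of this analysis design
reproduces the printed p-values under exactly this convention, which the
suite pins as a regression test.  A through-origin variant is available
but non-default.  Species enter a class's test only with pooled sample
size ≥ 5 there; growth is excluded outright at the entry class and at a
species' maximum class, where it is structurally 1 and 0.  Normality of
the transformed traits is checked with Shapiro–Wilk (the conventional
choice at these sample sizes).

Phylogenetic signal per class is Pagel's λ: the multiplier on the
off-diagonal Brownian-motion tip covariance, estimated by maximum
likelihood with the ancestral mean and rate profiled analytically and λ
optimized by golden-section search on [0, 1] (tolerance 10⁻⁴, endpoints
checked), with a 1-df likelihood-ratio test against λ = 0.  Trees are
consumed as Newick input (construction is out of scope); polytomies are
rejected for PIC by default with an explicit opt-in for arbitrary
zero-length resolution, and zero-length terminal branches get ε = 10⁻⁸
added before contrast standardization.

## Synthetic data

The census generator plants known rates and replays the survey design: 17
pseudo-species with the tabulated species maxima and order-of-magnitude
sample sizes of the reference community, standing counts derived from the
tabulated totals divided by each class group's observation-pair count,
seedling recruitment keeping the annual cohort roughly stationary
(recruits are Poisson per year, tagged at their entry class's next
survey; sapling and large-stem entry classes get recruitment replacing
their annual outflow).  Planted species rates scatter on the logit scale
(sd 1, matching the hyperprior's precision scale) around U-shaped
mortality templates: high seedling mortality, minimum near D40–D50, a
slight uptick above D60.

Two modes: *mechanistic* steps each stem annually through a multinomial
over (S, G, R, death) and records it at its survey years only, holding
net within-interval displacement to one class (the one-step regime the
tally reduction requires); *model-exact* draws each multi-year outcome
directly from the linked interval law, so the fitted model is exactly
correctly specified — parameter-recovery checks use this mode.  The two
laws coincide wherever no two-step path can leave the one-class band
(e.g. below a maximum class with no retrogression), which is tested.
Each stem keeps its recruitment class-group's schedule for life; real
stems crossing group boundaries changed schedules mid-life, which can
produce intervals the model has no likelihood for — a deliberate
simplification.  What passing recovery tests on these censuses shows is
that the estimator is correct under its own assumptions at realistic
sample sizes; they cannot detect field phenomena the generator omits
(year effects, spatial structure, multi-class jumps by shrubs,
observation error in class assignment).

The trait generator draws pairs of traits from a bivariate Brownian
motion on the λ-transformed tree with a requested evolutionary
correlation (Cholesky of the λ-scaled tip covariance crossed with the
2×2 trait covariance), so contrast-based correlation recovery and λ
recovery can be tested against planted truth.

## Problem sizes and numerical choices

Validation runs scale the reference chain settings down tenfold (30,000
steps, 20,000 burn-in) and use the full 17-species census scale; at those
settings pooled 90% credible-interval coverage of planted rates is
~85–91% per replicate and R̂ stays within ~1.01 of unity.  The conjugate
single-cell check fixes the hypervariance at 1000, making the species
prior effectively flat on the logit scale, and compares against the
Beta(1,1)-binomial mean to ±0.02 (covering the prior mismatch and Monte
Carlo error).  Contrast correctness is checked against an explicit
generalized-least-squares whitening of the Brownian covariance (U C Uᵀ = I
to 10⁻¹⁰) rather than against another traversal of the same algorithm.
Tallies reaching the sampler are pre-validated against the structure
(stasis at class 1, progression at a maximum class, retrogression outside
sapling/juvenile are rejected), so the compiled likelihood never
evaluates log 0.

## Known limitations

- No year effects, individual effects or spatial covariates, mirroring
  the target analysis; rates are assumed constant over the study window.
- Transitions of two or more classes per interval have no likelihood;
  data containing them are rejected rather than reinterpreted.
- The λ-likelihood profile is over a single trait; no joint λ across
  classes, no alternative signal statistics.
- The exclusion arithmetic that a published per-species inventory applied
  above species maxima is ambiguous in its source; this package keeps the
  uniform 24-per-species layout and reports classes up to each species'
  maximum.
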