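# Methods

`gexpand` implements a comparative-phylogenomic analysis of bacterial genome
size across human body sites: do lineages that transitioned into the gut
evolve larger genomes than their closest relatives elsewhere?  This note
documents the models, the statistics, the synthetic generator used to test
them, and the numerical and design choices a maintainer should know about.

## The comparative design

Treating every genome as an independent data point would confound habitat
effects with shared ancestry.  The unit of analysis is instead a
**phylogenetically independent comparison**: a pair of sister clades within
one genus (or species), one containing only gut isolates and the other only
non-gut isolates.

Extraction operates on a rooted tree whose tips are joined (bijectively,
checked) to metadata.  In a single post-order pass each node learns whether
its subtree is pure gut, pure non-gut, or mixed.  An internal node *anchors*
a comparison iff every one of its children is pure for one side and both
sides occur among them; for multifurcations the pure-gut children are pooled
against the pure-non-gut children.  When a taxonomic constraint is active,
all tips under the anchor must share one genus (congeneric level) or one
species (conspecific level).  Two consequences follow from the rule itself:

- **Tip-disjointness.** An anchor's subtree is mixed, so none of its
  ancestors can anchor; its children are single-sided, so none of its
  descendants can.  Comparisons never share tips, which is what makes the
  sign test's independence assumption structural rather than aspirational.
  (It is still asserted at run time on every extraction.)
- **Determinism.** No random resolution of polytomies is needed during
  extraction; results are ordered by the anchor's pre-order index.

**Polarisation** infers which habitat is the derived state from the
anchor's immediate sister clades only, requiring unanimity: if every sister
tip is non-gut, the gut clade is nested inside non-gut diversity and gut
residency is the derived state (`gut_derived`); the mirror case gives
`nongut_derived`; mixed sisters or a root anchor leave the comparison
`unpolarized` and excluded from polarity-conditioned tests.  This is a
deliberately conservative parsimony criterion; less restrictive nesting
definitions would polarise more comparisons at the cost of ambiguity.

MAG (metagenome-assembled genome) comparisons are intraspecific: after
filtering to completeness strictly above 90% (and optionally contamination
strictly below a ceiling), every species-level bin observed in the gut and
at least one other body site contributes one comparison.  No within-species
tree is available, so independence is assumed across bins.

## Divergence statistics

For each comparison the clade genome size is the arithmetic mean over
member tips, computed both raw and **completeness-corrected**
(`size × 100 / completeness`), which rescales an assembly to its estimated
true genome length.  Divergence is reported as a percent difference
(relative to the non-gut clade) and a log fold difference (natural log;
base 2 configurable).

The primary test is the **one-sided exact binomial sign test** on the
direction of divergence: p = Σᵢ₌ₖⁿ C(n,i)·2⁻ⁿ, evaluated in exact rational
arithmetic before conversion to float (no normal approximation at any n).
Exact ties in clade means are dropped from n and logged; they have measure
zero on real data.  Confidence intervals on the mean percent difference use
a two-sided 95% t interval by default, with a seeded percentile bootstrap
(10,000 resamples) as the alternative.  Habitat-stratified tests assign a
comparison to a stratum only when all its non-gut tips share that habitat,
otherwise to `mixed`.

The **pattern probability** (1 − q)^m answers a specific question: given
that a fraction q of comparisons diverge one way, what is the chance that m
independent comparisons (here, the pathogen-surveillance set) all fall the
other way?

**Phylogenetic ANOVA** is simulation-based: the observed one-way F of a tip
trait by group is referred to the F distribution of Brownian-motion traits
simulated on the same tree, with rate σ̂² set to the mean squared
standardized contrast of the observed trait and
p = (1 + #{F_sim ≥ F_obs}) / (1 + n_sim).  Because F is scale-invariant,
σ̂² does not affect the null law and the p-value is uniform on its discrete
grid under the null (verified by a KS check in the acceptance suite).
Polytomies are resolved with zero-length branches in tip-label order for
contrast computation only.

Two printed values in the source survey do not match the standard exact
test recomputed from their own counts: 16-of-19 is reported as 4.0e-4 where
the exact one-sided binomial gives ≈2.2e-3, and the 254-vs-118 annotation
sign test as 5.72e-5 where the binomial on those counts gives ≈1e-12 (their
pairing unit is likely not the individual annotation).  The package
implements the standard test and surfaces the counts; it does not
reverse-engineer those two numbers.

## Independent contrasts and regressions

`pic` implements Felsenstein pruning: at a node joining subtrees with
nodal values x₁, x₂ and adjusted branch lengths v₁, v₂, the standardized
contrast is (x₁ − x₂)/√(v₁ + v₂); the nodal value is the
variance-weighted mean and the node's branch is lengthened by
v₁v₂/(v₁ + v₂).  Sign convention: first minus second child in tip-label
order.  A node whose two adjusted lengths are both zero is uninformative
and is an error.  Contrast regression runs through the origin (contrasts
have zero expectation under BM), with uncentered R² and a t test on the
slope at n − 1 df.

The independent oracle is **BM generalized least squares** on the tip
values with covariance C_ij = shared root-to-MRCA path length.  The GLS
model includes an intercept — the phylogenetic mean — which is exactly the
quantity the contrasts eliminate; with it, the GLS slope is algebraically
identical to the through-origin PIC slope (a two-tip counterexample shows
the intercept-free variant is *not*).  The acceptance suite verifies the
identity to 1e-8 on 1,000 random trees.

Tip-level abundance regressions fit mean log10 relative abundance
(per-species mean over hosts; zeros dropped by default, half-minimum
imputation available) on genome size in Mb by polynomial OLS (degree 2 by
default, significance always reported for the linear coefficient).  The
within-genus variant centers both variables on genus means — genera with a
single species drop out — and pools the residuals, isolating divergence
among congeners from between-genus trends.

## Enrichment statistics

Enrichment scores are consumed, never computed, here.  The direction test
is the same exact sign test applied to nonzero scores (positive =
gut-enriched).  Category overrepresentation (e.g. CRISPR-associated gene
families among gut-enriched vs unenriched families) uses the two-sided
Fisher exact test under the minimum-likelihood convention (sum of all
same-margin tables no more probable than the observed one), cross-checked
against full fixed-margin enumeration.  Multiple testing uses
Benjamini–Hochberg.  Note that BH re-application is not a no-op: adjusted
values can only move further up, which the property tests assert instead of
idempotence.

## The synthetic cohort generator

The generator produces complete study inputs with known ground truth:

1. **Tree** — pure-birth (Yule) process, birth rate 1.0/unit time,
   conditioned on n tips and extended by one extra Exp(n·λ) interval so the
   tree is exactly ultrametric.
2. **Habitat history** — a continuous-time Markov chain over
   {gut, oral, urogenital, skin, airways} along every branch (uniform
   off-diagonal rate 0.12/unit time by default, root state oral), with the
   full per-branch state path retained.
3. **Genome size** — "trend-BM": log size gains Brownian noise of variance
   σ²·dt (σ² = 0.02) plus a deterministic drift of `gut_trend_delta` per
   unit time spent in the gut state (default 0.1; an alternative
   `shift_at_transition` mode applies a point shift on each entry into the
   gut instead).  Expansion is thus modelled as in-situ evolution while
   resident in the gut, not as a jump at colonisation.
4. **Observation** — completeness ~ Uniform(90, 100)%, assembly size =
   true size × completeness/100 (rounded), so the completeness correction
   inverts the observation model to ±1 bp.
5. **Taxonomy** — genera and species are the clades obtained by cutting
   the ultrametric tree at fixed ages (1.2 and 0.4 time units before the
   present).  This is a modelling convenience, not a claim about
   taxonomy.
6. **Companion tables** — per-habitat abundance follows mean log10
   abundance = intercept + slope·size(Mb) + noise (defaults: slope +1/Mb in
   the gut, −1/Mb elsewhere; per-host abundances are rescaled to sum ≤ 1,
   a common per-host factor that provably leaves the generative slope
   untouched); MAG tables resample species bins across habitats with a
   small gut log-size shift (0.014); enrichment scores are signed
   exponentials with a configurable gut bias and CRISPR flag rates.

All stages draw from named substreams of one master seed (seed folded with
a CRC32 of the stage name into a `SeedSequence`), so cohorts are
bit-reproducible and any single stage can be replayed without replaying the
others.

**Scale of the default cohort.**  Defaults were fixed by a design-time
operating-characteristics calculation, not by data fitting: n = 2,048 tips
matches the order of the real isolate surveys (~2,200 genomes) and yields
roughly 120 independent comparisons per cohort.  That size matters because
the exact sign test is conservative under discreteness; with ~120
comparisons its realised size is ≈0.043 at nominal α = 0.05, close enough
to nominal for the null-calibration checks to be meaningful.  The default
trend δ = 0.1 produces mean expansions of ~4%, the magnitude observed in
real gut lineages.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: horizontal gene transfer and
recombination, non-Brownian size evolution (jumps, bounded walks),
habitat-dependent diversification or sampling bias, correlated
completeness errors, within-species population structure in MAG bins, and
compositional coupling between species abundances beyond the sum
constraint.  The pipeline's statistical behaviour under those violations is
untested by design.

## Problem sizes in the validation suite

The statistical suite uses 500 replicate cohorts for null calibration
(pooled direction fraction, per-cohort test size, and a 500-replicate KS
uniformity check of the phylogenetic-ANOVA p with 199 simulations each), 60
cohorts per point on the δ ∈ {0, 0.1, 0.25, 0.5} grid for effect-size and
power monotonicity, 100 replicates per habitat at 200 species for
abundance slope-sign recovery, 1,000 random trees (≤12 tips) for the
PIC/GLS identity, exhaustive enumeration for the sign test (n ≤ 15) and
Fisher test, and 400 random trees (≤10 tips) against a brute-force
extraction oracle written on an entirely separate tree library.

## Known limitations

- Polarisation uses only the immediate sister; deeper outgroup evidence is
  ignored, so some genuinely polarisable comparisons are labelled
  unpolarized.
- Clade size is an unweighted tip mean; heavily sampled subspecies can
  dominate a clade mean.
- The MAG path has no within-bin phylogeny, so "independence" there is an
  assumption inherited from the bin definitions.
- Branch lengths are taken as given and unit-agnostic; all rates in the
  generator are per unit of whatever the input tree measures.
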