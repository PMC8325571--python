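# gexpand

Comparative phylogenomics of bacterial genome-size divergence between the
human gut and other body sites.

Bacteria of the human microbiome span more than an order of magnitude in
genome size, and gut residents are, on average, the largest.  Did big
genomes merely colonise the gut, or does life in the gut drive genomes to
grow?  `gexpand` implements the comparative test: it finds every pair of
reciprocally monophyletic sister clades within a genus (or species) where
one clade was isolated from the gut and the other from another body site.
Each such pair is one phylogenetically independent observation of
habitat-associated divergence, immune to pseudoreplication from shared
ancestry.  The package is aimed at microbial comparative genomicists who
have a phylogeny plus per-genome body-site metadata (and optionally MAG,
abundance, or functional-enrichment tables) and want the full statistical
pipeline behind this design.

## What it computes

Given a rooted Newick tree joined to tip metadata (genus, species, body
site, assembly size, CheckM-style completeness, pathogen-surveillance
flag), `gexpand`:

- extracts all tip-disjoint gut vs non-gut comparisons (congeneric,
  conspecific, or MAG species-bin level) and polarises each by outgroup
  context (is gut the derived state?);
- summarises per-comparison divergence as percent and log-fold differences
  of clade-mean genome size, raw and completeness-corrected
  (size × 100/completeness);
- tests direction with the one-sided exact binomial sign test,
  p = Σᵢ₌ₖⁿ C(n,i)·2⁻ⁿ, in exact rational arithmetic, with t or bootstrap
  confidence intervals, per-habitat strata, polarity-conditioned and
  pathogen-excluded variants, the all-minority pattern probability
  (1 − q)^m, and a simulation-based phylogenetic ANOVA;
- regresses abundance on genome size at the tip level (polynomial OLS per
  habitat, genus-centered within genera) and via Felsenstein's
  phylogenetically independent contrasts (through-origin regression,
  verified against a BM-GLS oracle);
- applies the matching enrichment statistics to annotation score tables
  (direction sign tests, two-sided Fisher exact for category
  overrepresentation such as CRISPR genes, Benjamini–Hochberg correction);
- and generates fully synthetic study cohorts (Yule tree, CTMC body-site
  history, trend-BM genome sizes, observation model, abundance/MAG/
  enrichment tables) with known ground truth, so the entire pipeline is
  testable without any external downloads.

See `docs/methods.md` for the models, assumptions, and design choices.

## Worked example

Simulate a 300-genome cohort and run the full analysis:

```sh
gexpand simulate --seed 11 --n-tips 300 --out demo
gexpand run --tree demo/tree.nwk --metadata demo/tips.tsv \
    --abundance-table demo/abundance.tsv --mags demo/mags.tsv \
    --scores demo/enrichment.tsv --seed 11 --out demo/out
```

`demo/out/report.md` then contains (abridged):

```
## Congeneric comparisons
- comparisons: 23
- gut larger (raw sizes): 15/23, one-sided sign-test p = 0.105
- gut larger (completeness-corrected): 16/23, p = 0.04657
- mean percent difference: 3.78% (95% CI -2.72 to 10.3)

## Polarized: gut_derived
- comparisons: 12
- gut larger (raw sizes): 10/12, one-sided sign-test p = 0.01929
- mean percent difference: 6.36% (95% CI 0.0772 to 12.6)

## Abundance–size regressions (degree 2, p on linear term)
- gut: linear coefficient 1.953, R^2 = 0.758, p = 1.68e-07, n = 50
- oral: linear coefficient -0.151, R^2 = 0.62, p = 0.838, n = 47
```

Reading this: the cohort yielded 23 independent congeneric comparisons; in
16 of 23 the completeness-corrected gut clade mean was larger (exact sign
test p = 0.047), with gut genomes on average 3.78% larger.  Restricting to
the 12 comparisons where gut residency is the derived state sharpens the
signal (10/12, p = 0.019, +6.4%) — the generative model behind this cohort
drifts log genome size upward by 0.1 per unit time spent in the gut, and
the pipeline recovers both the direction and the single-digit-percent
magnitude.  The abundance regressions recover the generative positive
size–abundance slope in the gut and the negative slope elsewhere.

Individual stages are available as `gexpand extract`, `test`, `pic`,
`abundance`, `enrich`, and `mag-compare`; every subcommand that touches
randomness takes `--seed`, and identical seeds give byte-identical outputs.

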