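# Methods

## The estimation model

mtDNA is maternally inherited without recombination, so a deep-rooted
maternal lineage is a tree of transmissions along which germline mutations
accumulate. The pipeline observes, for each lineage, the whole-mtGenome
profiles (differences from the 16,569-bp circular rCRS reference) of the
sequenced members, and counts as the denominator the union of
mother-to-child edges on the paths from every sequenced member back to the
founding mother. Using the edge *union* rather than a sum of per-individual
path lengths counts a shared ancestor's transmission exactly once; an
unsequenced intermediate mother still contributes her edges because a
mutation on them is observable in her sequenced descendants.

Events are called within a lineage only:

1. a variant carried homoplasmically by *every* sampled member is the
   lineage's ancestral haplotype, not an event — even if absent from other
   lineages;
2. any other difference is a candidate event;
3. candidates at masked sites are dropped (below);
4. heteroplasmic candidates (two-base IUPAC codes) need a minor-allele
   fraction at or above the detection threshold, default 0.20 — comparison
   is `>=`, so a mixture at exactly 20 % is kept;
5. a surviving variant seen in several relatives is one event with several
   carriers (single-origin parsimony): recurrence within a lineage is far
   less likely than identity by descent at these rates;
6. carriers must be a proper subset of members — a "candidate" in everyone
   (e.g. a shared heteroplasmy) is treated as ancestral.

The rate is `x / (n·L)` per site per generation and `x·10⁶ / (n·L·g)` per
site per Myr. The estimator is conditionally unbiased for the *detectable*
rate: mutations censored by the MAF threshold, or falling on edges no
sequenced descendant witnesses, are invisible by design, which is one
documented reason pedigree rates and phylogenetic rates differ.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| generation time `g` | 26.9 | years | genealogy-derived maternal interval; 25 y for cross-study standardization |
| MAF threshold | 0.20 | fraction | detection limit for point heteroplasmy; configurable |
| site counts `L` | preset | sites | see below |
| CI trials | `n·L` | site-transmissions | alternative `n` (per-transmission) available |

### Site-count presets

Two presets ship because the published per-region arithmetic is internally
inconsistent with the printed interval bounds. `paper_table2`
(default: mtGenome 16596, HVI 359, HVII 314, HVI+HVII 673, control 1149,
coding 15447) contains the unique integers that reproduce the published
per-region point estimates to three decimals, and makes the worked example
bit-reproducible. `strict_rcrs` (16569, 360, 315, 675, 1122, 15447) uses
the inclusive interval lengths on the rCRS circle and is the recommended
setting for new data. Coordinates are 1-based inclusive throughout; the
control region (16024–576) wraps the origin, handled by interval wrap and
never by negative positions.

### Exclusion mask

Indel/length-variant hotspots (309, 455, 463, 573, 960, 5899, 8276, 8285,
16193), the unreliable 16180–16183 stretch around the 16189 poly-C, and the
HVII 302–316 and HVI 16183–16194 homopolymer tracts are ignored in all
comparisons: length determination in these tracts is platform-unreliable,
so variants there are dropped rather than called. Indels and length
heteroplasmy are representable in input files but always removed by the
default mask.

## Confidence intervals

Clopper–Pearson is computed from beta-distribution quantiles
(`low = 0` at `x = 0`, `high = 1` at `x = n`); Wilson is the closed-form
score interval. Both are computed on the proportion over `n·L`
site-transmission trials and scaled by `10⁶/g`. The Clopper–Pearson
interval is conservative by construction and is never narrower than Wilson
here. Published interval bounds from web calculators of unrecorded version
may differ from either closed form by a few thousandths (and, for
sparse-count regions, by up to a few hundredths); point estimates are exact.
Reported tables round half-up to three decimals; full precision is kept
internally.

## Association tests

Heteroplasmy carriage versus sex or haplogroup is tested on r×2 tables with
a first-principles Pearson chi-square (no continuity correction unless
requested) and a two-sided Fisher exact test that enumerates all tables
with the observed margins and sums multivariate-hypergeometric
probabilities no greater than the observed table's (point-probability
rule, ties compared with a 10⁻⁷ relative tolerance). Enumeration is
refused above ~2×10⁶ candidate tables with a pointer to the chi-square
test. These operations exist for users holding the covariate data; the
bundled fixture does not include per-sample sex/haplogroup assignments, so
no published test statistic is asserted.

## The bundled fixture

`data/table1_lineages.tsv` encodes the 45-lineage study summary: published
lineage ids, the nine mutation labels with carrier counts, and the three
censored below-threshold mixtures (MAF 0.12/0.15/0.15). The printed
per-row meioses/individual values are typographically ambiguous in the
available source, so rows distribute meioses and individuals to reproduce
the authoritative totals (345/225) exactly; every prevalence figure and the
per-region event partition follow from the mutation assignments alone.
Expansion builds, per lineage, either a caterpillar (unsequenced founder
and chain, sequenced leaves) or a fully sequenced chain, both with an edge
union equal to the recorded meioses, and gives every member a two-variant
ancestral haplotype (A73G, A263G) so ancestral inference is genuinely
exercised. MAFs of detected heteroplasmies are synthetic placeholders
(0.35); the source prints MAFs only for the censored calls.
`data/table3_published_rates.tsv` carries the cross-study comparison rows;
two rows whose printed standardized values cannot be reproduced from the
data given are retained for completeness but not asserted.

## The simulator

`simulate_pedigree` grows each lineage as a branching process: every female
has Poisson(2) children, half female, over a configurable number of
generations; individuals in the last four generations are sequenced with a
configurable probability. Note the female line is then critical
(expected ~2 transmissions per lineage-generation), matching how such
studies accumulate meioses linearly rather than exponentially.
`simulate_transmissions` drops Poisson(μ·L) mutations on every edge at
uniformly drawn unmasked sites (without replacement within a lineage — a
negligible deviation from the independent-sites model at realistic μ·L·T,
about which the simulator warns when it stops being negligible). Each
mutation is heteroplasmic with probability 7/9 (the observed event mix)
with MAF ~ Uniform(0.05, 0.95), presenting in the carrier only; homoplasmic
mutations are inherited by all matrilineal descendants. A truth log records
every mutation with a `detected` flag computed from the generative model
(threshold survival plus carriage by a non-empty proper subset of the
lineage's sequenced members), and the test-suite checks the pipeline
recovers exactly the flagged events on every replicate.

What the simulator does *not* emulate: sequencing error and homopolymer
artefacts, NUMT contamination, multi-generation heteroplasmy drift
(a `maf_transition` hook is provided for custom drift models), recurrent
mutation at a site, and selection against coding mutations. Passing
recovery tests therefore demonstrate the *counting and interval machinery*
is calibrated under the stated generative model, not that real data are
free of those artefacts.

## Monte-Carlo calibration

The study-scale calibration uses 45 lineages × 5 generations, all
individuals sequenced (expected ≈360 transmissions, matching the study's
345), μ = 1.57×10⁻⁶, L = 16596, 2000 replicates — sizes chosen so the
whole experiment runs in about a minute and a half on one CPU while the
Monte-Carlo error on the relative bias is under 1 %. Against the
analytically detectable rate μ·(1 − p_het·P(MAF < 0.2)), the count
estimator's relative bias is within Monte-Carlo error of zero and both
intervals' empirical coverage falls in [0.93, 0.97]. Exact summation of
binomial tail masses shows the Clopper–Pearson interval's true coverage at
these conditions is 0.9698 — conservative, and close enough to the band's
edge that its empirical coverage sits near 0.97 by construction rather than
by chance.

## Numerical and design notes

- Rounding for reports is half-up at three decimals (`decimal` module),
  matching how such tables are conventionally printed.
- Only the six two-base IUPAC codes are accepted for heteroplasmy; the
  code must contain the reference base. Three/four-base codes are rejected
  (biallelic point heteroplasmy only).
- Heteroplasmic input calls lacking a MAF raise by default
  (`missing_maf="strict"`); a lenient mode keeps them with a warning.
- Pedigree validation rejects duplicate ids, dangling parent references,
  male mothers and matrilineal cycles; missing parents code founders.
  Sex-unknown individuals may transmit maternally when recorded as a
  mother.
- A sequenced founder is a lineage member contributing zero edges.
- Orthogonal-confirmation status is carried as a boolean input flag, never
  computed (chromatogram interpretation is out of scope).
- Standardization recomputes from raw counts when a study provides them;
  otherwise it converts the reported value (per-generation values are
  divided by the target generation time; per-year values are
  generation-free; per-Myr values are rescaled by the ratio of generation
  times).
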