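# Methods

This note documents the models, conventions and design choices behind
`oysterpanel`, in the order data flows through the package.

## Synthetic breeding design (`simdata`)

The generator emulates a hatchery strain founded from differentiated wild
populations and bred for two generations.

**Founder divergence.** Each site draws an ancestral alt-allele frequency
`p ~ Uniform(0.05, 0.95)`; each population's frequency comes from the
Balding–Nichols distribution `Beta(p(1−F)/F, (1−p)(1−F)/F)`, so the
between-population variance is `F·p(1−p)`. Any exchangeable divergence
model would serve; Balding–Nichols is the standard single-parameter choice
and its moments are directly testable. `fst = 0` is the exact
divergence-free limit (all populations keep the ancestral frequency).

**Site placement.** Site positions are distinct uniform draws over the
concatenated genome (so uniform within chromosomes, ≥1 bp apart, counts
proportional to chromosome length). No minimum spacing is enforced beyond
distinctness: clustered sites are realistic and exercise the
neighbor-count logic in probe selection. Allele pairs are drawn with
transition-heavy type proportions matching a typical bivalve manifest
(A/G and C/T 28% each; A/T 16%; G/T and A/C 11%; C/G 6%).

**Pedigree.** F1 crosses pair founders from two *different* populations;
F2 crosses pair F1 individuals from two different F1 families. Parents may
appear in several crosses, as in a real hatchery. Requests that cannot
satisfy the distinctness constraints (one founder population; fewer than
two F1 families) raise errors.

**Transmission and rendering.** Founders draw two alleles independently
from their population's frequencies (Hardy–Weinberg within populations).
At designated null loci a third, assay-invisible allele `n` takes
frequency `null_allele_freq`, the visible alleles sharing the remainder
proportionally. Offspring receive one uniformly chosen allele per parent;
sites segregate independently — there is no recombination map, so
simulated LD reflects family structure only, never physical linkage, and
LD checks are property-based (perfect duplicates, independence baselines)
rather than curve-matching. Observed dosages render `X/n` as the `X/X`
homozygote and `n/n` as a missing call: a true null gives no probe signal,
so forcing a homozygote would be wrong, and this rendering still produces
both signals the analysis relies on (heterozygote deficit and
homozygous-opposite-child trio errors). Genotyping error then replaces an
observed dosage with one of the other two uniformly at rate `e` —
symmetric replacement, not allele dropout, so that dropout-like signal
comes only from the null channel and causes stay separable. Extra missing
calls are added at `missing_rate`. The true null-carrier table is returned
alongside the matrix for oracle tests.

**Defaults.** The defaults encode the study design the package targets:
11 founder populations, 42 founders each (~464), moderate differentiation
`fst = 0.1`, 39 F1 and 82 F2 crosses. `offspring_per_cross = 14` matches
the genotyped-F1-per-cross scale of such programs (a single knob covers
both generations). `n_sites = 1000` and the 1/100-scaled ten-chromosome
layout in `default_layout()` keep simulated datasets desk-sized while
preserving the uneven chromosome-length distribution the allocation step
must handle; tests and the acceptance script use smaller explicit configs
(2–10 chromosomes, 60–800 sites, 50–300 individuals) chosen so every
stochastic property is comfortably resolved at that size. Artefact
defaults: 10% null loci at frequency 0.2, `e = 0.005`, 5% missingness —
inside the ranges array panels actually show. All randomness flows from
`seed` through per-operation substreams, so identical configs give
byte-identical output files regardless of call order.

## Discovery filters (`sitefilter`)

A site is retained iff biallelic (two distinct single-base alleles),
`maf > min_maf` strictly (default 0.01), called in ≥ `min_called_fraction`
of individuals (default 0.5, inclusive), and — when a total-depth vector
is available — `depth < max_total_depth` strictly (default cap 8,700).
Allele frequencies come from called genotypes; with no depth information
the depth criterion passes, since depth caps belong to the read level this
package does not model. Filtering is idempotent and monotone in each
threshold (both property-tested).

## Probe selection (`arraydesign`)

The stringency grid is the Cartesian product of MAF floors, flank sizes
and neighbor caps; defaults give the 18-set grid, enumerated most
stringent first. Conventions chosen where wording is genuinely ambiguous:

- **Neighbor counting** uses `|Δpos| ≤ flank_bp` on the same chromosome,
  boundary inclusive, focal site excluded, *summed over both sides* and
  compared to the cap once — the stricter of the two readings of a
  per-window cap. Neighbors are counted against the *full* discovered SNP
  list, not just co-candidates: any real polymorphism disrupts a probe.
- **Ranking** sorts by membership count desc, then MAF desc, then
  (chromosome, position) for determinism, and assigns priority numbers
  1..N. Ranking on membership before MAF is what lets a clean MAF-0.06
  site outrank a crowded MAF-0.45 one.
- **Allocation** apportions the requested total over chromosomes with
  largest-remainder (Hamilton) quotas on chromosome length — the simplest
  apportionment whose rounding error is provably < 1 per chromosome, so
  realized density correlates with length at r ≥ 0.99. Quota slots a
  chromosome cannot fill are redistributed by global priority; the output
  size always equals the request.
- **Flanks** are forward-strand, uppercased, 1-based inclusive; probes
  whose flanks run off a chromosome end or contain an N are excluded and
  reported with a reason rather than silently padded. Vendor scoring
  (p-convert-style) is consumed as an optional acceptance mask, never
  computed.

## Validation statistics (`popstats`)

- QC removes individuals below the call-rate floor first, then SNPs
  (recomputed on retained individuals); both default to 0.9, inclusive.
- `He = 2p(1−p)` with no small-sample correction; `Fis = (He−Ho)/He`,
  reported as missing when `He = 0`.
- The HWE test is the exact conditional test: condition on observed allele
  counts, enumerate all compatible heterozygote counts with their
  `2^h · multinomial` weights (log-gamma arithmetic), and sum the
  probabilities of configurations no more likely than the observed one —
  the common two-sided convention, without mid-p. It is verified against
  an exact integer-arithmetic enumeration for every configuration up to
  n = 30. Bonferroni screening divides α (default 0.05) by the number of
  *polymorphic* sites tested; cohort summaries report polymorphism as a
  share of called SNPs and HWE as a share of polymorphic SNPs, the panel
  report convention.
- LD is the squared Pearson correlation of unphased dosages over
  individuals called at both sites (the standard for genotype data; no
  haplotype phase is assumed). Pairs with fewer than 10 shared
  individuals, or no variance at either site, are skipped, not
  zero-filled. Default bins: 100 bp to 20 kb, then 1 kb to 500 kb. The
  curve reports the first bin midpoint where the mean r² falls to half its
  maximum and where it falls below 0.1.
- Conversion summaries classify probes by unordered allele pair into six
  types (transitions A/G, C/T), with rates to two decimals as printed in
  manifests.

## Mendelian-error analysis (`mendel`)

The eight trio error codes and their precedence: both-homozygous-parent
codes (5, 8) first, then single-homozygous-parent codes (3, 4, 6, 7), then
heterozygous-child codes (1, 2). Precedence is required because the
single-parent wildcard patterns overlap the both-parent patterns; with it,
classification is exhaustive and exclusive over all dosage combinations,
verified against a gamete-enumeration oracle. A missing parent genotype
matches only the wildcard — never a homozygote pattern — so duos
(one genotyped parent) can still yield codes 3/4/6/7; this is the
conservative no-imputation choice.

Rates follow the panel-report definitions: an individual's rate divides
its error count by its called-SNP count; a SNP's rate divides by the
constant number of trio-assigned offspring (a per-site called-trio
denominator is available behind `per_site_denominator=True`). Retention
tables count SNPs with rate ≤ cutoff, which makes the zero cutoff mean
"zero errors". The outlier fence is Q3 + 1.5·IQR with linear-interpolation
quantiles (the common default; flagging requires strict excess, so an
all-zero panel flags nothing). The F<sub>IS</sub>~MIE correlation is
reported overall and within strata below/above a rate split (default
0.01; the boundary goes to the upper stratum — with discrete error counts
the boundary is a measure-zero case). The null-allele diagnostic is the
summed proportion of errors in codes {3, 4, 6, 7}; under the simulator's
null-only condition it is provably exactly 1, because a child observed as
a heterozygote cannot carry a null and parents observed homozygous for the
same allele can only transmit that allele or a null.

Kinship reconstruction is deliberately out of scope: the pedigree is an
input (tracked crosses in practice, ground truth in simulation).

## What passing tests do and do not show

The simulator produces Hardy–Weinberg founders, Mendelian transmission,
and exactly three artefact channels. Real panels add things it omits —
linkage, copy-number variation, batch effects, clustering-algorithm
miscalls, pedigree errors — so passing the property suite shows the
*analysis* is correct under the stated model, not that a real panel will
hit any particular rate. Conversely the ratio reproductions
(polymorphism/HWE percentages, conversion rates, retention percentages)
are arithmetic on published report counts and validate the summary
operations independently of any simulation.

## Known limitations

- No recombination map: simulated LD decay cannot be compared to physical
  decay curves.
- Null alleles segregate independently per locus; no shared CNV structure.
- The per-SNP rate's constant denominator slightly deflates rates at
  low-call-rate SNPs (the flag above switches to the exact denominator).
- The exact HWE test enumerates per site; for panels of millions of sites
  a chi-square prescreen would be faster (not needed at package scale).
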