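# Methods

This note documents the models behind each module, the simulated study
conditions, the numerical choices that matter, and what the passing tests do
— and do not — demonstrate about real data.

## Genotype and coordinate conventions

All statistics operate on unphased diploid dosages in {0, 1, 2, missing}.
Internally every interval is 0-based half-open; VCF and GFF3 (1-based
inclusive) convert at the file boundary, BED is native.  The pairwise
genotype distance used by dxy and RNDmin is the expected allele mismatch
between one random allele from each individual,

    d(a, b) = a/2 + b/2 − a·b/2 ,

so a heterozygote–heterozygote pair scores ½.  RNDmin was defined on
haplotypes in its source literature; with unphased diploids we use this
per-individual genotype distance instead (a documented deviation — no
phasing stage exists in this pipeline).  Per-bp quantities are normalized by
the full window length, matching the windowed-π convention of VCFtools-style
pipelines; pairs with missing data are renormalized by the fraction of
window sites they could be compared at.

## Wright–Fisher forward simulator

Discrete non-overlapping generations of N diploids.  Each offspring draws
two parents (selfing allowed) with weights 1, 1+s, 1+2s from the dosage at
the selected site; each gamete is a recombinant with Poisson(L·r) crossovers
at uniform positions; mutation is infinite-sites at Poisson(2N·L·μ) new
sites per population per generation (position collisions resampled).  A
burn-in of 10·N generations precedes the first event so the root population
is near mutation–drift equilibrium (expected heterozygosity reaches
1 − e⁻⁵ ≈ 99% of θ).  Population splits copy the parent pool and let
ordinary reproduction draw the child's first generation — founding the child
by resampling individuals would add one generation of drift to the child
branch only, which measurably biases Patterson's D.  An admixture pulse at
generation t replaces each destination parent draw by a source parent with
probability f, for that generation only.  A sweep introduces a single copy
at onset; under `condition_on_fixation` the whole post-onset phase restarts
from a snapshot (fresh derived RNG stream per attempt) until the allele
fixes before sampling.  Restarts therefore also re-randomize the other
populations' post-onset drift, which is immaterial because only the focal
population is scanned.

Sampling takes the configured number of diploids per population without
replacement.  The VCF reference allele is the outgroup-sample consensus (the
ancestral-state estimate all polarized statistics use); sites where the
outgroup sample is polymorphic are emitted with an `OGP` flag.  Sites fixed
or lost across all populations are pruned (every 8 generations; the interval
is output-invariant).  Same seed ⇒ bit-identical output.  The gamete
assembly is a numba kernel that copies haplotype segments between crossover
breakpoints and splices the generation's new mutation columns in the same
pass; positions are kept sorted throughout.

### Study conditions (scenario defaults)

These were fixed from pilot runs of the generator itself (diversity levels,
informative-site counts, sweep footprint widths) before the recovery
measurements were frozen, and are deliberately "scaled down": small N with
mutation and recombination rates raised so that a single short
pseudo-chromosome behaves like a genome sample.

| scenario | populations | L | μ (/bp/gen) | r (/bp/gen) | events |
|---|---|---|---|---|---|
| quartet | P1,P2,P3,OUT, N=100 each; samples 8/8/8/4 | 500 kb | 4e−7 | 1e−6 | splits 400/150/60 gen; optional P3→P2 pulse (f, t=20) |
| pair | A,B,OUT, N=100; samples 8/8/6 | 400 kb | 4e−7 | 1e−6 | splits 1200/600; optional B→A pulse (f=0.2, t=30) |
| sweep | FOC N=500 (40 sampled), OUT N=100 (6) | 1 Mb | 5e−8 | 1e−6 | outgroup split 1500; sweep s=0.1 at centre, onset 200, conditioned |
| neutral | single population, N=200, 20 sampled | 200 kb | 1e−8 | 1e−8 | none |

Rationale for the key values: quartet split times are 0.3/0.75/2.0 × 2N
generations so incomplete lineage sorting leaves ≥ ~45 informative
ABBA–BABA sites per run; 4N·r = 4·10⁻⁴/bp makes LD tracts ~2.5 kb so a
500 kb chromosome holds many quasi-independent gene trees (the regime a
block jackknife needs).  The sweep scenario's r makes the expected sweep
footprint s/(r·ln 2N) ≈ 15–50 kb, comparable to the 50 kb localization
tolerance used in the tests.

What the generator does **not** emulate: genotyping error and missing data,
variable mutation/recombination rates along the chromosome, background
selection, realistic demography (growth, bottlenecks), gene conversion, or
multi-chromosome genomes.  Passing recovery tests therefore show the
estimators behave correctly on clean data of realistic information content,
not that they are robust to real-data artifacts.

## Patterson's D, fd and the jackknife

Derived alleles are polarized as the minor allele of the pooled outgroup
sample; sites with outgroup frequency exactly ½, an all-missing outgroup, or
any all-missing population are excluded.  D = Σ(C_ABBA−C_BABA) /
Σ(C_ABBA+C_BABA) over frequency-weighted pattern counts.  Significance comes
from a delete-one block jackknife with two choices that differ from the
genome-scale convention, both adopted after direct calibration measurements
on neutral simulations:

- **Blocks are contiguous equal-span genomic intervals** (default 20,
  allotted to chromosomes by extent), not equal informative-site counts.
  With ~70 informative sites, equal-count blocks hold ~3.5 sites — narrower
  than one LD tract — so deleting a block removes only part of a correlated
  cluster and the variance is underestimated.  Equal-count blocking remains
  available (`block_by="sites"`) and is the right choice when informative
  sites number in the tens of thousands.
- **The p-value uses a t reference with B−1 degrees of freedom**, since the
  jackknife SE is itself estimated from B blocks.

Measured neutral test size at α = 0.05 went from 16% (equal-count + normal)
to 8% (equal-span + t) over 100 replicates.  The residual mild
anticonservatism is genome-wide drift correlation from the small simulated
populations (all tracts share one realized pedigree), which no positional
blocking can remove and which shrinks with N in real data.

fd windows hold 50 informative sites each (never spanning chromosomes; a
final partial window is flagged), with the dynamic donor p_D = max(p₂, p₃)
substituted for both P2 and P3 in the denominator sums; fd is undefined
where the window D ≤ 0.  The genome admixture fraction is the pooled-sums fd
(× 100), reported 0 when pooled D ≤ 0; both pooled and windowed forms are
exposed because published per-genome percentages do not state which was
used.

## CLR scan

The background spectrum φ(j) is the genome-wide SFS hypergeometrically
projected to a common size n, conditioned on polymorphism.  The sweep model
follows the classic independent-escape construction: each of n lineages
escapes with pe = 1 − exp(−α·d); non-escapees coalesce into the single swept
haplotype; the pre-sweep sample of size k+1 draws its derived count by
projection of φ; the post-sweep count renormalizes over polymorphic
outcomes.  Numerical choices:

- φ*(j; pe) is tabulated on 256 geometric pe bins (1e−8..1); a site's
  contribution is log(w·φ*) where w is the site's projection weight vector,
  which reduces to a table lookup for complete data and marginalizes
  partial-call sites correctly.  pe bins where the polymorphism mass falls
  below 1e−12 (pe → 0) contribute the neutral term.
- The α grid (default 40 log-spaced points, 1e−8..1e−2/bp) is always
  augmented with the **α → ∞ limit**, where every lineage escapes and the
  sweep model equals the background.  This nests neutrality exactly and
  keeps Λ ≥ 0; without it, a SNP lying a few bp from a grid position cannot
  "escape" at any finite α in the grid and single-handedly drives Λ to −70.
- Ties in α (common once pe saturates the bins) resolve to the largest α,
  i.e. the narrowest maximizing window.
- The analysis default **projects the SFS to n = 20** even though 40
  diploids are sampled.  At full n = 80 the independent-escape model assigns
  astronomically small probabilities to intermediate derived counts at small
  pe, but real sweep flanks contain exactly such counts (escape happens as
  clades, not independent lineages); projection marginalizes each site over
  subsamples and rescues these classes.  Localization on simulated sweeps
  went from 0/6 to ~half of replicates within 50 kb after projection.
- The maximizing window is x ± ln(1/ε)/α̂ (ε = 0.01), clipped to the
  chromosome — the documented surrogate for the dynamic window of the
  reference implementation, whose exact rule is unpublished.

## ω scan and the intersection procedure

ω uses composite (genotype) r², flanks of up to 30 SNPs within 50 kb per
side, at least 3 per side, maximized over both flank extents with cumulative
sums; undefined r² pairs are skipped with pair-count renormalization and the
between-flank mean is floored at 1e−6 (flagged).  Both scans share the grid
(default 1 kb spacing).  A CLR point is retained iff its Λ reaches the
genome-wide top-1% threshold (ties count as above) and its maximizing window
contains a top-1% ω position; retained windows merge (touching included)
into selection regions; within each retained window the maximal contiguous
run of above-threshold Λ grid points containing the focal position, padded
by half the grid spacing, is the target region.  The whole procedure is
deterministic.

## Gene-level analyses

Similarity-hit filters are strict inequalities (e < 1e−4, identity > 60).
Reciprocal best hits break ties by bitscore, then e-value, then
lexicographic subject id.  The overlap χ² is Pearson's with 1 df and no
continuity correction.  Fixed differences require every called sample
homozygous, opposite alleles between groups, ≥1 call per group, within gene
± 1 kb.  GO enrichment is a one-sided Fisher exact per term with
Benjamini–Yekutieli adjustment (valid under arbitrary dependence); the
gene→term map is a user-supplied table.

## Problem sizes

The test suite runs 200 neutral quartets (D calibration), 50 pulse quartets
(fd recovery), 20 conditioned sweeps + 20 neutral genomes (scan recovery and
specificity), 20 paired RNDmin replicates and 100 small neutral runs (π
calibration); the acceptance script repeats the same measurements at
reduced replicate counts (60/30/8/8/10).

## Limitations

- **Sweep localization.**  At this sweep strength (4Ns = 200) the CLR
  argmax lands within 50 kb of the true site in only about half of
  replicates (9/20 in the frozen cohort).  Two causes, both structural: the
  diversity trough's centroid itself wanders by roughly the early-phase
  recombination scale 1/(r·T) because a handful of early escape clades
  dominate the flank pattern; and the composite likelihood treats linked
  sites as independent, so singleton clusters elsewhere on the chromosome
  can outscore the true peak.  The region-level procedure absorbs most of
  this: the merged intersect-and-merge regions contain the true site in
  15/20 replicates.
- **Neutral region coverage.**  The pe-bound window rule gives windows of
  width 2·ln(100)/α̂; at desk-scale SNP density α̂ at retained neutral
  points is often 1e−5..1e−4, i.e. windows of 50–500 kb, and merged regions
  cover ~40% of a sweep-free 1 Mb chromosome instead of a few percent.
  Narrowing the windows would shrink this at the direct cost of the
  region-recovery rate above; with genome-scale SNP densities α̂ is sharp
  and both behave.
- The D test retains ~3 points of anticonservatism from shared-pedigree
  correlation (see above).
- fd on a single 500 kb realization has a replicate SD near its own mean
  (ancestry drifts hard in N=100 recipients); only replicate averages are
  meaningful.
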