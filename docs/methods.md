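# Methods

This note documents the statistical machinery, its defaults, and the design
choices made where the published workflow left the details open.

## Genotype representation and ploidy

A call is the *set* of distinct repeat counts at one locus (1–5 alleles);
fragment sizes in bp are converted by `round((size − offset) / motif)`, with
a warning when the value sits more than 0.34 repeat units off the motif grid
(real fragment calls drift by ±1 bp; rejection would discard usable data).
Missingness is per locus, never per isolate. Ploidy classes come from the
maximum distinct-allele count over called loci: ≤2 → 2n, 3 → 3n, ≥4 → 4n/5n;
the number of loci with ≥3 alleles is recorded alongside. Clone collapse
treats genotypes as identical only when every locus matches, including
missing status — a conservative rule that never merges isolates on partial
evidence.

## Bruvo distance

Allele distance `1 − 2^(−|x−y|)` weights stepwise mutations geometrically.
For equal-size allele sets the genotype distance is the minimum mean allele
distance over perfect matchings, found exactly by linear-sum assignment
(identical to exhaustive enumeration, cheaper at 4–5 alleles). For unequal
sizes the *addition* model pads the smaller set with its own alleles and the
*loss* model with alleles of the larger set; each enumerates all distinct
padded multisets (combinations with replacement), scores them as equal-size
comparisons, and averages. The default model averages addition and loss —
the usual choice when the direction of the ploidy change is unknown; an
*infinity* fallback (phantom alleles at distance 1) is available. Distances
are computed on repeat counts. Pairwise matrix entries average over loci
called in both isolates; a pair with no shared locus is an error rather than
a silent guess (impute first). Nearest-neighbour imputation copies the
missing allele set from the closest isolate (Bruvo distance over mutually
called loci) that is called at that locus, ties broken by dataset order;
it is intended for analyses that need a complete matrix (MDS), not as a
default preprocessing step.

## Trees, MDS, cluster number, node reliability

Neighbour joining follows the Q-criterion; a negative branch-length
estimate is clamped to zero and the deficit moved to the sister branch, so
leaf-to-leaf path lengths are preserved and additive matrices are
reproduced exactly. UPGMA uses average-linkage agglomeration (SciPy) and is
ultrametric by construction. Classical MDS double-centres the squared
distances and eigendecomposes; negative eigenvalues (non-Euclidean input,
routine for Bruvo matrices) are dropped with a warning.

Cluster number selection runs K-means for k = 1..kmax (best of 10 restarts)
on the MDS coordinates retaining 95% of positive-eigenvalue variance, and
picks the smallest k whose relative WSS drop `(WSS(k) − WSS(k+1))/WSS(1)`
falls below τ = 0.05. A WSS-drop rule alone can never return k = 1 —
K-means removes a substantial WSS fraction from *any* point cloud — so a
Gaussian-reference guard runs first: the observed log-WSS decay is compared
with K-means on surrogate draws from a single Gaussian matched for mean and
covariance, and k = 1 is returned when no k beats that reference by more
than two standard errors. This mirrors the gap-statistic logic at minimal
cost.

Node reliability is a reconstruction of the partition idea: for each clade
of 2..N−1 leaves, the observed mean pairwise distance is compared with R =
1000 random leaf subsets of the same size; reliability is the fraction of
subsets strictly looser than the clade, and nodes above 0.90 are flagged.
Null distributions are shared across clades of equal size. Under a topology
independent of the distances the score is uniform, so ~10% of nodes exceed
0.90 by chance — the tests verify exactly that calibration.

## Core-diploid extraction

The polyploid class is every isolate with ≥3 distinct alleles at ≥1 locus.
Each observed (locus, allele) is tested in a 2×2 carrier × class table with
Pearson χ² (1 df, no continuity correction, α = 0.01; expected counts < 5
log a warning rather than switching tests). An allele is excluded only when
the association is significant **and** its carrier rate is higher among
polyploids — the exclusion targets alleles specific to the polyploid
lineages; a two-sided rule would equally strip diploid-specific alleles and
destroy the core dataset. After removal, emptied calls and calls still
holding >2 alleles become missing. Even under a true null the χ² excludes
~1% of shared alleles (type-I errors), and clonal replication inflates that
rate by pseudo-replication; the tests bound false exclusions accordingly
instead of expecting zero.

## AMOVA, Mantel, FST

AMOVA is single-factor and distance-based: `SS_total = (1/N) Σ_{i<j} d²`,
within-group sums weighted by group size, variance components from the
standard one-level moments with `n0 = (N − Σn_g²/N)/(G−1)`; negative
among-group components are truncated to zero for the percentage. The
p-value permutes group labels (default 10⁴ permutations, add-one rule).
Groups of size 1 are dropped with a warning. Factors (country, substrate,
ploidy) are tested independently, plus geography restricted to non-wine
isolates.

The Mantel statistic is the Pearson correlation over upper-triangle entries
with simultaneous row/column permutations of the second matrix, one-sided
(greater), add-one p. Geographic distances are great circles (radius
6371 km) between country centroids from a small editable table; isolates
from the same country are at distance 0, and per-isolate coordinates
override the centroid when present.

FST is Weir & Cockerham's (1984) θ computed per allele and locus from
sample sizes, allele frequencies and observed heterozygote frequencies,
summed as a ratio of averages; single-allele calls count as homozygotes,
calls with >2 alleles are ignored, negative estimates truncate to 0, and a
pair with no shared polymorphism is NaN with a warning. Validation uses
fixed differences (θ = 1), an arbitrarily split panmictic sample (θ ≈ 0)
and Balding–Nichols frequencies with known F = 0.25.

## Ancestry

Core genotypes are encoded as allele-dosage rows: per called locus the
block holds 1.0 for a single-allele call or 0.5/0.5 for two alleles, so
blocks sum to one; missing blocks are masked. The model `X ≈ QG` constrains
Q rows and per-locus G blocks to the simplex and is fitted by EM-style
multiplicative updates, which decrease the training cross-entropy
monotonically (verified to 1e-10 per step). A random 5% of called blocks is
held out per fit; model choice minimises the mean held-out cross-entropy
over repeated fits (default 10; the reference workflow used 100) and takes
the smallest K within one standard error of the minimum. Held-out scoring
mixes the fitted block probabilities with 1e-3 of the uniform distribution,
capping the penalty for alleles a component never saw in training; without
this, single rare alleles dominate the criterion. No sparsity penalty is
applied. Label switching is resolved in the tests by Hungarian matching of
components before computing accuracies.

With 12 microsatellite loci at a few hundred isolates, the entropy
criterion typically resolves the 2–3 strongest ancestries of the synthetic
complex rather than all five pools; resolving finer structure needs either
more loci or the full-size collection. The K-recovery tests therefore use
strongly separated pools, where the criterion is exact.

## Growth phenotyping

Per curve: maximal OD is the maximum reading; growth requires a rise of
δ = 0.2 OD units (the published criterion is verbal, "growth absence");
lag is the linearly interpolated time to 5% of the maximal OD increase;
maximal rate is the largest `Δlog₂(OD)/Δt` over consecutive readings
(divisions/h), skipping non-positive readings. A strain is Sensitive when
some non-zero dose abolishes growth in all replicates, or when
Kruskal–Wallis across doses (α = 0.05) is significant for rate or maximal
OD *and* some dose mean sits at least 10% below the dose-0 mean. The 10%
floor exists because rank tests at triplicate depth flag sub-noise dips;
the published tolerant exemplar (rates 0.07/0.09/0.08/0.07) shows such dips
must not force an S call. Lag prolongation alone never makes a strain
Sensitive. A separate effect-size flag marks monotone ≥50% rate declines,
kept apart from the test-based call because Kruskal–Wallis at n = 3 per
group has limited power.

## Synthetic generator

Allele frequencies are hierarchical: a species-wide Dirichlet base per
locus, lineage-level frequencies drawn as `Dirichlet(c_lineage · base)` and
pool-level as `Dirichlet(c_pool · lineage)` — Balding–Nichols-style drift
with fixation index ≈ 1/(1+c) per level (defaults c = 3 at both levels,
giving pairwise FST in the 0.2–0.4 range the complex shows). All pools
share allele support, which is what lets differentiation survive the
core-allele exclusion. Triploids are allotriploid: a diploid core from
their pool plus one haploid draw per locus from a donor pool on a disjoint
repeat range (26–40 vs 5–25), so triploid-specific alleles are known by
construction; autotriploidy is not modelled. Clone-class sizes follow a
geometric law matched to each group's isolates-per-genotype ratio and
adjusted to the exact group size; clonal copies mutate each allele ±1
repeat at rate 0.01 and lose loci at rate 0.02. The default six-group
census (sizes, genotype counts, ploidy, substrates, country spreads)
follows the published collection's group table; a `scale` factor shrinks
every group proportionally (minimum 4 isolates) for tests and the
acceptance run, which uses scale 0.25 (~370 isolates) and a 39-strain
growth panel.

Growth curves use the three-phase model — flat at the inoculation OD
through the lag, exponential at a constant divisions/h rate, clipped at the
plateau — because it realises exactly the lag/rate/plateau parametrisation
the extractor estimates, making generator truth well defined; it does not
emulate the smooth lag-to-exponential transition or death phases of real
curves. Tolerant archetypes keep rate and plateau across doses and only
lengthen the lag; sensitive archetypes scale rate/plateau down with dose
and fail entirely at 0.6 mg/L. Gaussian OD noise (σ = 0.03) is added and
readings clipped at 0.01.

What passing tests show — and what they do not: the generator reproduces
the *statistical shape* of a clonal mixed-ploidy complex (hierarchical
differentiation, allotriploid allele structure, dose-response phenotypes),
so green tests demonstrate that the estimators recover known structure of
that shape at realistic sizes. They do not certify behaviour on real
electropherogram-derived data, which adds allele-binning artefacts,
null alleles, and linkage the generator does not model.

## Numerical conventions

Permutation p-values always use the add-one rule. All stochastic routines
take explicit seeds and are reproducible bit-for-bit. Negative variance
components, θ estimates, and NJ branch lengths truncate to zero at the
reporting boundary only. Allele sets larger than 5 are rejected (guards the
factorial matching). Ties in nearest-neighbour imputation and K* selection
resolve to the earliest candidate (dataset order; smallest K).
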