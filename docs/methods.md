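# Methods

This note documents the models, conventions and numerical choices behind
`mitolineage`, and what the synthetic data do and do not establish.

## Data model and coordinates

All statistics operate on a rectangular alignment over {A, C, G, T, N, −}
with 1-based, inclusive column coordinates; the circular mitochondrial
genome is treated as its linearised alignment. Ambiguity codes other than
N are rejected rather than coerced — population mitogenome consensus
sequences are normally unambiguous, and silent coercion hides fixture
bugs. Partition entries carry a class (protein / rRNA / tRNA / dloop /
other), and protein entries a reading-frame column and strand. Entries of
the same class may not overlap, but cross-class overlap is legal because
the historical D-loop genotyping amplicon overlaps tRNA-Pro; a column
covered by two classes counts toward both densities, and the
whole-genome/per-class conservation identity S(whole) = Σ S(class) is
only asserted where classes tile the genome disjointly.

## Diversity statistics

Haplotypes are identity classes of sequences; N matches anything (grouping
is greedy first-fit against class representatives, which equals plain
string identity on fully called data). A column is segregating when two
or more nucleotides are observed after excluding N/−. Classification
follows the minor-state count over genomes: singleton iff exactly one
genome carries a non-major state, shared otherwise; the haplotype-level
minor count is reported alongside because "found in single genomes" and
"shared between two or more haplotypes" can in principle diverge (they
coincide on all data considered here).

π is the mean uncorrected p-distance over unordered pairs — only the
p model satisfies the identity (mean pairwise differences) = π × L. K2P
distances, d = −½ ln[(1 − 2P − Q)√(1 − 2Q)], are used for AMOVA and tree
building; pairs where the logarithm's argument is non-positive raise a
saturated-pair error rather than returning infinity. Comparisons are
pairwise-complete: a column with N/− in either member is dropped for that
pair only.

## AMOVA

The two-level analysis follows the squared-distance formulation:
SS_total = (1/N)Σ_{i<j} d²; within-group SS analogously per group; level
SS by subtraction; df = (G−1, P−G, N−P). Variance components are solved
from the expected mean squares with the unequal-size coefficients

    n'   = (N − Σ_g Σ_{p∈g} n_p²/n_g) / (P − G)
    n''  = (Σ_g Σ_{p∈g} n_p²/n_g − Σ_p n_p²/N) / (G − 1)
    n''' = (N − Σ_g n_g²/N) / (G − 1)

and Φ_RT = σ²a/σ²T, Φ_PR = σ²b/(σ²b + σ²c), Φ_PT = (σ²a + σ²b)/σ²T.
Negative components are reported as estimated and flagged; a second
column floors them at zero (the convention of the spreadsheet tools
practitioners use), so both readings are always available. With a single
region σ²a is undefined: Φ_RT is NaN and Φ_PT reduces to the one-level
statistic. Permutation nulls are statistic-specific — individuals among
populations (Φ_PT), individuals among populations within regions (Φ_PR),
whole populations among regions (Φ_RT) — and p = (1 + k)/(1 + n_perm),
which cannot report p = 0 at finite n_perm. Default n_perm is 10,000 and
a seed is mandatory wherever permutations run.

## Trees and homoplasy

Neighbor-joining is implemented in-package so its determinism is pinned:
Q-criterion ties break on the lowest index pair, and negative branch
lengths are floored at zero with the deficit moved to the sibling so the
pair's length sum is preserved. Tests cross-check the topology against an
independent NJ implementation on additive matrices. Monophyly and
Robinson–Foulds comparisons use the unrooted bipartition convention.

Per-site step counts use an exact unit-cost Sankoff dynamic program
(rather than the two-pass set heuristic) because NJ produces unrooted
trees whose arbitrary rooting can be multifurcating; the DP is exact on
any tree shape and is verified against exhaustive labeling enumeration on
small trees. Indices: CI = m/s with m = #states − 1; HI = 1 − CI;
RI = (g − s)/(g − m) with g the star-tree step count computed on *genome*
counts (pass tip weights when the tree's tips are haplotype
representatives); parsimony-uninformative sites (g = m) take RI := 1,
RC := CI and are flagged. The indices are tree-conditional by design: any
user newick (e.g. an externally estimated ML tree) can replace the NJ
surrogate, and step counts for topology-sensitive sites will differ
between trees.

## Codon analysis

Translation uses the vertebrate mitochondrial code (NCBI table 2).
Minus-strand loci are handled by reverse-complementing the codon read
leftward from the frame column; coordinates stay on the aligned strand.
Each protein-partition segregating site is mapped to its codon and every
observed minor codon is classified against the major one; codons
containing N/− are skipped and premature stops are flagged, never
dropped. Branch attribution reconstructs per-site ancestral states by
backtracking the Sankoff DP deterministically (root takes the
alphabetically first optimal state; children keep the parent state when
optimal); sites where a genuine tie was suppressed by that rule are
flagged ambiguous and tallied separately.

The regional replacement-excess test defines a change as unique to a
region when all carriers of its minor codon are in that region; the
per-region statistic is the proportion of its unique changes that are
amino-acid replacements, compared against a null built by permuting
sample → region labels (p = (1 + k)/(1 + n_perm) per region). The source
survey did not name its test or the exact denominator behind its printed
percentages, so this package reports counts, proportions and the grand
mean rather than asserting any printed p-value.

## Waiting-time clock

Given per-species neutral rates r_i (substitutions per third-codon site
per year) and L usable sites, waiting times are t_i = 1/(r_i L) exactly,
so every fitted summary scales as 1/L across site counts — the core of
the gene-versus-genome precision argument. The lognormal is fitted by
maximum likelihood on log times (μ = mean, σ = sd with denominator n),
not by curve-fitting a histogram; the point estimate is the mode
exp(μ − σ²) and the 95% interval the fitted quantiles exp(μ ± 1.96σ).
`lognormal_from_ci` inverts the quantile formulas to recover (μ, σ) from
a reported interval, which reproduces the reported gene-scale mode to
0.1% and, rescaled by 379/3,796, the genome-scale mode — the package's
internal-consistency check of the published figures. A reported ~16.7 ky
date for lineages 1.8 synonymous substitutions from their ancestor does
not equal 1.8 × the 8.4 ky genome-scale mode (≈15.2 ky); the computation
behind the published figure is unstated, so `tmrca` returns the direct
product and this note records the discrepancy.

## Synthetic data

The generator emulates the survey's design: 40 samples in 6 populations
nested in 3 subspecies; 16,290 columns partitioned 2,528 rRNA / 1,515
tRNA / 11,397 protein (three codon-complete blocks) / 299 D-loop / 551
other; per-class rates calibrated so expected change counts match the
survey's densities (≈66 changes genome-wide, D-loop ≈9× the protein
rate); κ = 4 transition:transversion kernel, matching the K2P assumption
downstream; and four hotspot columns (protein, tRNA, two D-loop) whose
weights target two expected changes each, making recurrent mutation
likely where the survey observed it. Trees are ultrametric with depths in
expected-substitution units (within-population 0.2, population splits
0.45, subspecies splits 1.0, successive joins staggered 10% to stay
binary); node times are deterministic given the design, so total tree
length — and hence rate calibration — does not depend on the topology
seed. Mutations fall as per-branch per-column Poisson draws and are
logged exhaustively in the truth record.

The deterministic `fisher_fixture` is a synthetic stand-in for the
deposited survey alignment (sequences are not shipped): it reproduces the
haplotype-sharing structure of the 40 samples (15 classes), the exact
per-partition site counts and the 47/19 singleton/shared split, with
singletons on the six frequency-1 genomes. Protein-partition sites are
planted at most one per codon on a GCA backbone, cycling codon positions
3, 3, 1, so the synonymous/replacement mix is known by construction.

What passing tests show — counting statistics, AMOVA algebra, parsimony
indices, codon classification and the clock arithmetic are correct on
data with the survey's structure, and the D-loop-versus-genome conflict
emerges from planted hotspots. What they do not show: the fixture does
not reproduce pairwise distances or tree shape of the real data (its π is
set by the planted site counts, not the survey's 0.00088), the simulator
has no indels, no recombination or migration beyond the fixed hierarchy,
and no within-population rate heterogeneity beyond the hotspot columns.

## Problem sizes

Stochastic test batches use 10–20 replicates at full survey scale
(40 × 16,290) for calibration checks and smaller designs (≤12 samples,
≤2 kb) for null-distribution checks; permutation counts in tests are
49–999, with 10,000 the library default. These sizes make the suite a
few minutes long while keeping Monte-Carlo assertions comfortably inside
their tolerance bands.
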