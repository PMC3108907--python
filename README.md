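# mitolineage

Whole-mitogenome matrilineage analysis for population-scale surveys of
low-diversity species.

Conservation genetics has long leaned on short mitochondrial fragments —
above all the hypervariable displacement-loop (D-loop) amplicon — to define
maternal lineages. In species with very low mitogenomic divergence (the
North American fisher, *Martes pennanti*, is the motivating case: 40 complete
genomes, 66 segregating sites over 16,290 aligned bp), the D-loop's high
mutation rate cuts both ways: it concentrates variable sites into a few
hundred bases, but recurrent (homoplasious) mutation at those sites can
erase or fabricate haplotype identities, so the amplicon contradicts the
genealogy recorded by the rest of the genome. `mitolineage` packages the
statistics needed to quantify that contradiction and to exploit
whole-genome data properly:

- **Partitioned diversity** — haplotype collapsing, segregating sites S with
  shared/singleton classification, per-partition densities S/L
  (protein / rRNA / tRNA / D-loop / other), nucleotide diversity
  π = mean pairwise p-distance, and Kimura 2-parameter distances
  d = −½ ln[(1 − 2P − Q)√(1 − 2Q)] with the transition/transversion split
  (P, Q) retained per pair.
- **Hierarchical AMOVA** — Excoffier-style variance partitioning of squared
  distances across subspecies ⊃ populations ⊃ individuals with
  unequal-sample-size coefficients; Φ_RT, Φ_PR, Φ_PT (the mitochondrial
  F_ST analogue) with permutation p-values p = (1 + k)/(1 + n), and a
  population-pair Φ_PT matrix.
- **Genealogy and homoplasy** — deterministic neighbor-joining surrogate
  trees, monophyly queries, Robinson–Foulds conflict between partition
  trees, and per-site parsimony indices CI = m/s, HI = 1 − CI,
  RI = (g − s)/(g − m), RC = CI·RI, where s is the tree-conditional minimum
  change count, m = (#states − 1) and g the star-tree step count.
- **Codon analysis** — translation under the vertebrate mitochondrial code
  (ATA = Met, TGA = Trp, AGA/AGG = Stop), synonymous vs replacement
  classification of protein-partition polymorphisms, branch attribution of
  changes by parsimony, and a permutation test for a regional excess of
  region-unique amino-acid replacements.
- **Waiting-time divergence dating** — rescale per-species third-codon
  substitution rates r_i to waiting times t_i = 1/(r_i·L) for L usable
  sites, fit a lognormal to ln t by maximum likelihood, and report the mode
  exp(μ − σ²) with the fitted 2.5%/97.5% quantiles; divergence dates are
  k × mode for k synonymous substitutions.
- **Synthetic mitogenomes** — a generator that plants mutations along a
  known hierarchy tree (Poisson per branch per column, K2P substitution
  kernel, hotspot columns with elevated recurrence) and returns the full
  truth record, so every estimator above can be validated end to end
  without any sequence downloads.

## Worked example

```python
from mitolineage import collapse_haplotypes, segregating_sites, partition_density
from mitolineage.datasets import fisher_fixture

aln, parts, table = fisher_fixture()   # 40 genomes x 16,290 bp, deterministic
haps = collapse_haplotypes(aln)
report = segregating_sites(aln, haps)
print(haps.n_haplotypes, report.n_segregating, report.n_shared, report.n_singleton)
print(partition_density(aln, parts, report).to_string(index=False))
```

prints

```
15 66 19 47
  class  S     L  density
protein 42 11397  0.00369
   rRNA  9  2528  0.00356
   tRNA  2  1515  0.00132
  dloop 10   299  0.03344
  other  3   551  0.00544
```

i.e. the 40 genomes collapse to 15 haplotypes defined by 66 segregating
sites (19 shared by two or more haplotypes, 47 confined to single genomes),
and the D-loop carries ~33 SNPs/kb against ~3.7/kb in the proteome — a
nine-fold density excess packed into 299 bp. The `examples/` directory has
one short script per capability (diversity, AMOVA, homoplasy, codon
changes, clock), each printing the numbers it computes and what they mean.

The same analyses run from the shell:

```bash
mitolineage simulate --seed 11 --out run/sim
mitolineage diversity --fasta run/sim/alignment.fasta \
    --partitions run/sim/partitions.tsv --out run/div
mitolineage amova --fasta run/sim/alignment.fasta \
    --samples run/sim/samples.tsv --seed 11 --out run/amova
```

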