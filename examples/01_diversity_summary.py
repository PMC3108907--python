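"""Partitioned diversity of a 40-genome mitogenome alignment.

Builds the deterministic survey-shaped alignment (40 fisher-like
genomes, 16,290 bp), collapses haplotypes, counts segregating sites and
tabulates per-partition SNP densities.  The densities show the classic
D-loop excess: ~33 variable sites per kb versus ~3.7/kb in the
protein-coding fraction, a ~9x rate difference in a region only 299 bp
long.
"""

from mitolineage import (
    collapse_haplotypes,
    mean_pairwise_stats,
    pairwise_distances,
    partition_density,
    segregating_sites,
)
from mitolineage.datasets import fisher_fixture

aln, parts, table = fisher_fixture()
haps = collapse_haplotypes(aln)
report = segregating_sites(aln, haps)

print(f"{aln.n_samples} genomes x {aln.length} bp")
print(f"haplotypes: {haps.n_haplotypes}")
print(
    f"segregating sites: {report.n_segregating} "
    f"({report.n_shared} shared, {report.n_singleton} singleton)"
)
print("\nper-partition SNP density (S sites over L bp):")
print(partition_density(aln, parts, report).to_string(index=False))

pi, diffs = mean_pairwise_stats(pairwise_distances(aln, "p"), aln.length)
print(f"\nnucleotide diversity pi = {pi:.5f}")
print(f"mean pairwise differences = {diffs:.1f} per genome pair")
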