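"""The fisher (Martes pennanti) mitogenome study design, as reusable inputs.

This module encodes the published sampling design of the range-wide
fisher whole-mitogenome survey (GenBank haplotypes GU121228-GU121237 and
HQ705176-HQ705180): 40 samples in 6 geographic populations nested in 3
subspecies, a 16,290 bp aligned genome partitioned into 11,397 bp of
protein-coding genes, 2,528 bp of rRNA, 1,515 bp of tRNA and the 299 bp
D-loop genotyping amplicon, and the observed variation profile of 66
segregating sites (47 singletons, 19 shared) distributed 42/9/2/10 over
protein/rRNA/tRNA/D-loop with the remainder in other non-coding sites.

Sequences are NOT shipped: :func:`fisher_fixture` builds a synthetic
alignment that reproduces the survey's haplotype-sharing structure and
per-partition site counts exactly, which is all the downstream counting
statistics depend on.  :func:`study_config` supplies the matching
simulation conditions for stochastic replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import Alignment, Partition, PartitionMap, SampleTable
from .simulate import (
    PopulationSpec,
    SimulationConfig,
    TruthRecord,
    evolve_alignment,
    make_fixture,
    simulate_tree,
    total_tree_length,
)

__all__ = [
    "GENOME_LENGTH",
    "fisher_sample_table",
    "study_partitions",
    "study_site_counts",
    "fisher_fixture",
    "study_config",
    "simulate_study",
]

GENOME_LENGTH = 16_290

# (sample, haplotype accession, subspecies, population) for the 40 genomes
_TABLE1 = [
    ("MP1", "GU121228", "pacifica", "S_California"),
    ("MP2", "GU121228", "pacifica", "S_California"),
    ("MP3", "GU121228", "pacifica", "S_California"),
    ("MP4", "GU121229", "pacifica", "N_California"),
    ("MP5", "GU121229", "pacifica", "N_California"),
    ("MP6", "GU121229", "pacifica", "N_California"),
    ("MP7", "GU121230", "pacifica", "N_California"),
    ("MP9", "GU121231", "columbiana", "Idaho_Montana"),
    ("MP10", "GU121231", "columbiana", "Idaho_Montana"),
    ("MP11", "GU121232", "columbiana", "British_Columbia"),
    ("MP12", "GU121232", "columbiana", "Idaho_Montana"),
    ("MP13", "GU121232", "columbiana", "Idaho_Montana"),
    ("MP14", "GU121233", "columbiana", "Idaho_Montana"),
    ("MP15", "GU121233", "columbiana", "Idaho_Montana"),
    ("MP16", "GU121233", "columbiana", "Idaho_Montana"),
    ("MP17", "GU121234", "pennanti", "GreatLakes_MN"),
    ("MP18", "GU121235", "pennanti", "GreatLakes_MN"),
    ("MP19", "GU121236", "pennanti", "GreatLakes_WI"),
    ("MP20", "GU121236", "pennanti", "GreatLakes_WI"),
    ("MP21", "GU121228", "pacifica", "S_California"),
    ("MP22", "GU121228", "pacifica", "S_California"),
    ("MP23", "GU121228", "pacifica", "S_California"),
    ("MP24", "GU121228", "pacifica", "S_California"),
    ("MP25", "GU121230", "pacifica", "N_California"),
    ("MP26", "GU121231", "columbiana", "British_Columbia"),
    ("MP27", "GU121231", "columbiana", "British_Columbia"),
    ("MP28", "GU121237", "columbiana", "British_Columbia"),
    ("MP29", "GU121232", "columbiana", "British_Columbia"),
    ("MP30", "GU121232", "columbiana", "British_Columbia"),
    ("MP31", "GU121232", "columbiana", "British_Columbia"),
    ("MP32", "GU121232", "columbiana", "Idaho_Montana"),
    ("MP34", "GU121235", "pennanti", "GreatLakes_WI"),
    ("MP35", "GU121235", "pennanti", "GreatLakes_WI"),
    ("MP36", "GU121236", "pennanti", "GreatLakes_WI"),
    ("MP37", "HQ705177", "columbiana", "British_Columbia"),
    ("MP38", "HQ705178", "columbiana", "British_Columbia"),
    ("MP39", "HQ705179", "columbiana", "British_Columbia"),
    ("MP40", "HQ705176", "columbiana", "British_Columbia"),
    ("MP41", "HQ705180", "columbiana", "Idaho_Montana"),
    ("MP42", "HQ705180", "columbiana", "Idaho_Montana"),
]


def fisher_sample_table(include_accession: bool = False) -> SampleTable:
    """The 40-sample / 6-population / 3-subspecies sampling design."""
    df = pd.DataFrame(
        _TABLE1, columns=["sample", "accession", "subspecies", "population"]
    )
    if not include_accession:
        df = df.drop(columns="accession")
    return SampleTable(df)


def fisher_haplotype_classes() -> dict[str, list[str]]:
    """Haplotype accession -> member samples (15 classes over 40 genomes)."""
    classes: dict[str, list[str]] = {}
    for sample, acc, _, _ in _TABLE1:
        classes.setdefault(acc, []).append(sample)
    return classes


def study_partitions(length: int = GENOME_LENGTH) -> PartitionMap:
    """Partition layout with the survey's class lengths.

    Loci are merged into blocks per class (the counting statistics only
    see classes): 2,528 bp rRNA, 1,515 bp tRNA, 11,397 bp protein in
    three codon-complete blocks, the 299 bp D-loop amplicon, and 551 bp
    of other non-coding sequence.
    """
    entries = [
        Partition("12S_16S_rRNA", "rRNA", 1, 2528),
        Partition("tRNA_block", "tRNA", 2529, 4043),
        Partition("CDS_block1", "protein", 4044, 9440, frame=4044),
        Partition("CDS_block2", "protein", 9441, 13640, frame=9441),
        Partition("CDS_block3", "protein", 13641, 15440, frame=13641),
        Partition("Dloop_amplicon", "dloop", 15441, 15739),
        Partition("NC_other", "other", 15740, 16290),
    ]
    return PartitionMap(entries, length)


def study_site_counts() -> dict[str, tuple[int, int]]:
    """Per-class (singleton, shared) segregating-site counts of the survey.

    Class totals are 42 protein / 9 rRNA / 2 tRNA / 10 D-loop; the
    published total of 66 segregating sites leaves 3 in other non-coding
    positions.  The 47/19 singleton/shared split is allocated across
    classes (the survey reports only the totals).
    """
    return {
        "protein": (31, 11),
        "rRNA": (7, 2),
        "tRNA": (1, 1),
        "dloop": (6, 4),
        "other": (2, 1),
    }


def fisher_fixture() -> tuple[Alignment, PartitionMap, SampleTable]:
    """Synthetic 40-genome alignment mirroring the survey's variation.

    Deterministic stand-in for the deposited sequences (which are not
    shipped): samples sharing a haplotype accession receive identical
    sequences, per-partition segregating-site counts are exact
    (42/9/2/10 + 3 other), singletons sit on the six frequency-1 genomes
    and shared sites mark the nine multi-genome haplotype classes, so
    haplotype collapse yields 15 classes and the shared/singleton split
    is 19/47 exactly.
    """
    parts = study_partitions()
    table = fisher_sample_table()
    samples = [row[0] for row in _TABLE1]
    index = {s: i for i, s in enumerate(samples)}
    classes = fisher_haplotype_classes()
    singles = [index[m[0]] for m in classes.values() if len(m) == 1]
    multis = [tuple(index[s] for s in m) for m in classes.values() if len(m) > 1]
    aln = make_fixture(
        n_samples=len(samples),
        parts=parts,
        counts=study_site_counts(),
        sample_names=samples,
        singleton_carriers=singles,
        shared_carriers=multis,
    )
    return aln, parts, table


def study_populations() -> list[PopulationSpec]:
    sizes = (
        fisher_sample_table()
        .rows.groupby(["subspecies", "population"])
        .size()
        .reset_index(name="n")
    )
    return [
        PopulationSpec(row["population"], row["subspecies"], int(row["n"]))
        for _, row in sizes.iterrows()
    ]


#: expected segregating-site density per class under the study conditions
STUDY_DENSITIES = {
    "protein": 42 / 11_397,
    "rRNA": 9 / 2_528,
    "tRNA": 2 / 1_515,
    "dloop": 10 / 299,
    "other": 3 / 551,
}

#: hotspot columns planted by default: one protein first-codon-position
#: site, one tRNA site and two D-loop sites, echoing where recurrent
#: mutation was observed in the survey
STUDY_HOTSPOT_COLUMNS = {
    "protein": 9465,
    "tRNA": 3900,
    "dloop": 15545,
    "dloop2": 15600,
}


def study_config(
    tree_length: float | None = None,
    hotspot_changes: float = 2.0,
) -> SimulationConfig:
    """Simulation conditions emulating the survey.

    Per-class mutation rates are calibrated so that, over a tree of
    total length ``tree_length``, the expected number of changes per
    class matches the survey's segregating-site densities (so roughly 66
    segregating sites genome-wide, with the D-loop rate ~9x the protein
    rate).  Hotspot weights are set so each hotspot column expects
    ``hotspot_changes`` changes, making recurrent mutation likely there.
    When ``tree_length`` is None the rates are left as raw densities
    (callers that build the tree first should pass the measured length;
    :func:`simulate_study` does this).
    """
    T = tree_length if tree_length else 1.0
    rates = {c: d / T for c, d in STUDY_DENSITIES.items()}
    cls_of = {"protein": "protein", "tRNA": "tRNA", "dloop": "dloop", "dloop2": "dloop"}
    hotspots = {
        col: hotspot_changes / STUDY_DENSITIES[cls_of[key]]
        for key, col in STUDY_HOTSPOT_COLUMNS.items()
    }
    return SimulationConfig(
        populations=study_populations(),
        partitions=study_partitions(),
        class_rates=rates,
        hotspots=hotspots,
        kappa=4.0,
        depth_within=0.2,
        depth_population=0.45,
        depth_root=1.0,
    )


def simulate_study(
    seed: int, hotspot_changes: float = 2.0
) -> tuple[Alignment, TruthRecord, SimulationConfig, SampleTable]:
    """One stochastic replicate of the survey-shaped simulation.

    Builds the hierarchy tree, calibrates per-class rates against the
    realised total tree length, evolves the alignment, and returns the
    matching sample table for the synthetic samples.
    """
    ss = np.random.SeedSequence(seed)
    tree_seed, evolve_seed = (int(s) % 2**31 for s in ss.generate_state(2))
    cfg = study_config(hotspot_changes=hotspot_changes)
    tree = simulate_tree(cfg, tree_seed)
    cfg = study_config(
        tree_length=total_tree_length(tree), hotspot_changes=hotspot_changes
    )
    aln, truth = evolve_alignment(tree, cfg, evolve_seed)
    rows = []
    for pop in cfg.populations:
        for i in range(pop.n_samples):
            rows.append(
                {
                    "sample": f"{pop.name}_{i + 1:02d}",
                    "subspecies": pop.subspecies,
                    "population": pop.name,
                }
            )
    return aln, truth, cfg, SampleTable(pd.DataFrame(rows))
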