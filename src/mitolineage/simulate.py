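"""Synthetic mitogenome alignments with known (planted) mutation histories.

The generator emulates the structure of a range-wide mitogenome survey:
samples nested in populations nested in subspecies, a partitioned
circular genome treated as a linear alignment, per-class mutation rates
with a strong D-loop excess, and explicit hotspot columns whose elevated
rates produce recurrent (homoplasious) mutation.  Every run returns a
:class:`TruthRecord` carrying the generating tree and the full per-branch
mutation log, so downstream estimators can be tested for recovery.

Trees are ultrametric with depths in expected-substitution units per
unit rate; mutations fall as a Poisson process per branch per column
with intensity (class rate x hotspot weight x branch length), and each
event draws its target state from a two-class kernel with transition
probability kappa / (kappa + 2) — the process whose pairwise distances
the K2P correction inverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io import Alignment, PartitionMap

__all__ = [
    "PopulationSpec",
    "SimulationConfig",
    "TruthRecord",
    "simulate_tree",
    "evolve_alignment",
    "make_fixture",
    "total_tree_length",
]

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    subspecies: str
    n_samples: int


@dataclass
class SimulationConfig:
    populations: list[PopulationSpec]
    partitions: PartitionMap
    class_rates: dict[str, float]  # substitutions/site per unit branch length
    hotspots: dict[int, float] = field(default_factory=dict)  # column -> weight
    kappa: float = 4.0  # transition:transversion ratio of the kernel
    depth_within: float = 0.2  # tip -> population MRCA
    depth_population: float = 0.45  # population splits within subspecies
    depth_root: float = 1.0  # subspecies splits

    def __post_init__(self) -> None:
        if any(p.n_samples < 1 for p in self.populations):
            raise ValueError("every population needs >= 1 sample")
        if any(r < 0 for r in self.class_rates.values()):
            raise ValueError("rates must be >= 0")
        L = self.partitions.alignment_length
        for col in self.hotspots:
            if not 1 <= col <= L:
                raise ValueError(f"hotspot column {col} outside genome 1..{L}")
        if not 0 < self.depth_within <= self.depth_population <= self.depth_root:
            raise ValueError("depths must satisfy 0 < within <= population <= root")

    @property
    def genome_length(self) -> int:
        return self.partitions.alignment_length

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{p.name}_{i + 1:02d}" for p in self.populations for i in range(p.n_samples)
        ]

    def rate_vector(self) -> np.ndarray:
        """Per-column intensity: class rate times hotspot weight."""
        L = self.genome_length
        rates = np.full(L, self.class_rates.get("other", 0.0))
        for entry in self.partitions.entries:
            rates[entry.start - 1 : entry.end] = self.class_rates.get(entry.cls, 0.0)
        for col, w in self.hotspots.items():
            rates[col - 1] *= w
        return rates


@dataclass
class TruthRecord:
    tree: dendropy.Tree
    # (branch label, 1-based column, from state, to state), in placement order
    mutations: list[tuple[str, int, str, str]]
    change_counts: np.ndarray  # per-column planted change multiplicity
    haplotype_of: dict[str, str]
    seed: int

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)


def _coalesce(
    lineages: list[dendropy.Node],
    times: list[float],
    ages: dict[dendropy.Node, float],
    rng: np.random.Generator,
) -> dendropy.Node:
    """Merge lineages pairwise at the given (sorted) event times."""
    lineages = list(lineages)
    for t in times:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = dendropy.Node()
        ages[parent] = t
        for k in (j, i):  # pop higher index first
            child = lineages.pop(k)
            child.edge.length = t - ages[child]
            parent.add_child(child)
        lineages.append(parent)
    assert len(lineages) == 1
    return lineages[0]


def simulate_tree(config: SimulationConfig, seed: int) -> dendropy.Tree:
    """Rooted binary ultrametric tree realising the sampling hierarchy.

    Within-population coalescences happen at evenly spaced times up to
    ``depth_within`` (topology randomised by ``seed``; node times, and
    hence the total tree length, are a deterministic function of the
    design).  Population lineages then join within their subspecies at
    ``depth_population`` and subspecies lineages at ``depth_root``, each
    series of joins staggered by 10% steps so the tree stays binary.
    """
    rng = np.random.default_rng(seed)
    ages: dict[dendropy.Node, float] = {}
    taxa = dendropy.TaxonNamespace()
    by_subspecies: dict[str, list[dendropy.Node]] = {}
    for pop in config.populations:
        tips = []
        for i in range(pop.n_samples):
            taxon = taxa.new_taxon(f"{pop.name}_{i + 1:02d}")
            node = dendropy.Node(taxon=taxon)
            ages[node] = 0.0
            tips.append(node)
        n = len(tips)
        if n == 1:
            root = tips[0]
        else:
            times = [config.depth_within * j / (n - 1) for j in range(1, n)]
            root = _coalesce(tips, times, ages, rng)
        by_subspecies.setdefault(pop.subspecies, []).append(root)

    subspecies_roots = []
    for ssp in sorted(by_subspecies):
        pops = by_subspecies[ssp]
        k = len(pops)
        if k == 1:
            subspecies_roots.append(pops[0])
        else:
            times = [config.depth_population * (1 + 0.1 * j) for j in range(k - 1)]
            subspecies_roots.append(_coalesce(pops, times, ages, rng))
    if len(subspecies_roots) == 1:
        root = subspecies_roots[0]
    else:
        k = len(subspecies_roots)
        times = [config.depth_root * (1 + 0.1 * j) for j in range(k - 1)]
        root = _coalesce(subspecies_roots, times, ages, rng)

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    if root.edge.length is None:
        root.edge.length = 0.0
    return tree


def total_tree_length(tree: dendropy.Tree) -> float:
    return sum(
        node.edge.length or 0.0
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    )


def _branch_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return "|".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


def evolve_alignment(
    tree: dendropy.Tree, config: SimulationConfig, seed: int
) -> tuple[Alignment, TruthRecord]:
    """Drop mutations along the tree and return the tip alignment + truth.

    The root sequence is uniform random over {A,C,G,T}; each branch draws
    per-column Poisson mutation counts at intensity rate x length, and
    each event replaces the current state via the kappa kernel.  Hotspot
    columns accumulate recurrent changes naturally.
    """
    rng = np.random.default_rng(seed)
    L = config.genome_length
    rates = config.rate_vector()
    root_seq = rng.choice(_BASES, size=L)
    mutations: list[tuple[str, int, str, str]] = []
    change_counts = np.zeros(L, dtype=int)
    seqs: dict[dendropy.Node, np.ndarray] = {tree.seed_node: root_seq}
    tv_prob = 1.0 / (config.kappa + 2.0)

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        seq = seqs[node.parent_node].copy()
        lam = rates * (node.edge.length or 0.0)
        counts = rng.poisson(lam)
        label = _branch_label(node)
        for col in np.flatnonzero(counts):
            for _ in range(counts[col]):
                old = seq[col]
                u = rng.random()
                if u < 2 * tv_prob:
                    new = _TRANSVERSIONS[old][0 if u < tv_prob else 1]
                else:
                    new = _TRANSITION[old]
                seq[col] = new
                mutations.append((label, int(col) + 1, old, new))
                change_counts[col] += 1
        seqs[node] = seq

    names = config.sample_names
    tip_seq = {
        leaf.taxon.label: "".join(seqs[leaf]) for leaf in tree.leaf_node_iter()
    }
    aln = Alignment(names, [tip_seq[n] for n in names])

    from .diversity import collapse_haplotypes

    haps = collapse_haplotypes(aln)
    truth = TruthRecord(
        tree=tree,
        mutations=mutations,
        change_counts=change_counts,
        haplotype_of=dict(haps.assignment),
        seed=seed,
    )
    return aln, truth


# ---------------------------------------------------------------------------
# Deterministic fixtures


def _transition(base: str) -> str:
    return _TRANSITION[base]


def _base_sequence(parts: PartitionMap) -> list[str]:
    """Monomorphic backbone: GCA codons in protein loci, A elsewhere.

    GCA (Ala) makes the three codon positions exercise replacement
    (Ala>Thr), replacement (Ala>Val) and synonymous (Ala>Ala) changes
    under the transition used for fixture minor states.
    """
    seq = ["A"] * parts.alignment_length
    for e in parts.protein_entries():
        pattern = "GCA"
        for col in range(e.frame, e.end + 1):
            seq[col - 1] = pattern[(col - e.frame) % 3]
    return seq


def make_fixture(
    n_samples: int,
    parts: PartitionMap,
    counts: dict[str, tuple[int, int]],
    sample_names: list[str] | None = None,
    singleton_carriers: list[int] | None = None,
    shared_carriers: list[tuple[int, ...]] | None = None,
) -> Alignment:
    """Construct, without randomness, an alignment with exact site counts.

    ``counts`` maps a partition class to (n_singleton, n_shared): the
    number of variable columns planted inside that class's spans whose
    minor state occurs in exactly one genome, respectively in >= 2
    genomes.  Minor states are the transition partner of the backbone
    state.  Carrier patterns cycle: singletons over ``singleton_carriers``
    (default: all samples in order), shared sites over
    ``shared_carriers`` (default: adjacent pairs).

    Raises ``ValueError`` for infeasible requests (more sites than
    columns in a class, shared carrier groups smaller than 2, ...).
    """
    if sample_names is None:
        sample_names = [f"S{i + 1:02d}" for i in range(n_samples)]
    if len(sample_names) != n_samples:
        raise ValueError("sample_names length must equal n_samples")
    if singleton_carriers is None:
        singleton_carriers = list(range(n_samples))
    if shared_carriers is None:
        if n_samples < 2:
            shared_carriers = []
        else:
            shared_carriers = [
                (i, (i + 1) % n_samples) for i in range(n_samples)
            ]
    for group in shared_carriers:
        if len(set(group)) < 2:
            raise ValueError("shared carrier groups need >= 2 distinct samples")

    base = _base_sequence(parts)
    matrix = [list(base) for _ in range(n_samples)]

    # available columns per class, in span order; protein classes offer at
    # most one column per codon (cycling codon positions 3, 3, 1) so planted
    # sites never share a codon and the syn/rep mix is known by construction
    columns_of: dict[str, list[int]] = {}
    offsets = (2, 2, 0)
    for e in parts.entries:
        if e.cls == "protein" and e.strand == "+":
            n_codons = (e.end - e.frame + 1) // 3
            cols = [
                e.frame + 3 * j + offsets[j % 3] for j in range(n_codons)
            ]
            columns_of.setdefault(e.cls, []).extend(cols)
        else:
            columns_of.setdefault(e.cls, []).extend(e.columns())

    si = 0  # global cycling indices so every carrier pattern gets used
    sh = 0
    for cls, (n_single, n_shared) in counts.items():
        cols = columns_of.get(cls, [])
        if n_single + n_shared > len(cols):
            raise ValueError(
                f"class {cls!r}: requested {n_single + n_shared} sites in "
                f"{len(cols)} columns"
            )
        if n_shared > 0 and not shared_carriers:
            raise ValueError("shared sites requested but no carrier groups possible")
        used = iter(cols)
        for _ in range(n_single):
            col = next(used)
            carrier = singleton_carriers[si % len(singleton_carriers)]
            si += 1
            matrix[carrier][col - 1] = _transition(base[col - 1])
        for _ in range(n_shared):
            col = next(used)
            group = shared_carriers[sh % len(shared_carriers)]
            sh += 1
            for carrier in group:
                matrix[carrier][col - 1] = _transition(base[col - 1])

    return Alignment(sample_names, ["".join(row) for row in matrix])
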