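"""Haplotype collapsing, segregating sites, partition densities, distances.

Summary statistics of within-species mitogenome variation: samples are
collapsed into haplotypes by sequence identity, polymorphic columns are
listed and classified as shared vs singleton, per-partition SNP densities
(S/L) are tabulated, and pairwise distance matrices are computed under
the uncorrected p model or the Kimura 2-parameter (K2P) correction

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the proportions of transitional and transversional
differences over pairwise-complete columns.  Nucleotide diversity pi is
the mean p-distance over unordered sample pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Alignment, PartitionMap, PARTITION_CLASSES

__all__ = [
    "HaplotypeTable",
    "SiteRecord",
    "SiteReport",
    "DistanceMatrix",
    "SaturatedPairError",
    "collapse_haplotypes",
    "segregating_sites",
    "partition_density",
    "pairwise_distances",
    "mean_pairwise_stats",
]

BASES = ("A", "C", "G", "T")
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


class SaturatedPairError(ValueError):
    """K2P undefined for a pair (log argument <= 0)."""


@dataclass
class HaplotypeTable:
    """Partition of samples into sequence-identity classes.

    ``assignment`` maps each sample to a haplotype ID ``H1..Hk`` numbered
    by first occurrence; ``representative`` gives the index (in alignment
    order) of the first sample carrying each haplotype.
    """

    assignment: dict[str, str]
    representative: dict[str, int]
    frequencies: dict[str, int]

    @property
    def n_haplotypes(self) -> int:
        return len(self.representative)

    def members(self, hap: str) -> list[str]:
        return [s for s, h in self.assignment.items() if h == hap]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": list(self.assignment),
                "haplotype": [self.assignment[s] for s in self.assignment],
            }
        )


@dataclass
class SiteRecord:
    position: int  # 1-based alignment column
    states: str  # observed nucleotides, e.g. "A/G", major state first
    minor_genomes: int  # genomes carrying a non-major state
    minor_haplotypes: int  # haplotypes carrying a non-major state
    classification: str  # "singleton" | "shared"


@dataclass
class SiteReport:
    sites: list[SiteRecord]

    @property
    def positions(self) -> list[int]:
        return [s.position for s in self.sites]

    @property
    def n_segregating(self) -> int:
        return len(self.sites)

    @property
    def n_singleton(self) -> int:
        return sum(1 for s in self.sites if s.classification == "singleton")

    @property
    def n_shared(self) -> int:
        return sum(1 for s in self.sites if s.classification == "shared")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [s.position for s in self.sites],
                "states": [s.states for s in self.sites],
                "minor_genomes": [s.minor_genomes for s in self.sites],
                "minor_haplotypes": [s.minor_haplotypes for s in self.sites],
                "class": [s.classification for s in self.sites],
            }
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with the transition/transversion split kept."""

    labels: list[str]
    d: np.ndarray
    model: str  # "p" | "k2p"
    P: np.ndarray  # transition proportion per pair
    Q: np.ndarray  # transversion proportion per pair

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])

    def submatrix(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(k) for k in keep]
        return DistanceMatrix(
            list(keep),
            self.d[np.ix_(idx, idx)].copy(),
            self.model,
            self.P[np.ix_(idx, idx)].copy(),
            self.Q[np.ix_(idx, idx)].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def collapse_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Group samples whose sequences are identical over non-N columns.

    Two samples share a haplotype iff their sequences agree at every
    column where neither carries N (gaps must match exactly).  With
    fully-called sequences this is plain string identity.
    """
    n = aln.n_samples
    groups: list[list[int]] = []
    # N-tolerant identity is not transitive in pathological cases; greedy
    # first-fit against the group representative keeps the result
    # deterministic and matches plain identity on N-free data.
    for i in range(n):
        placed = False
        for g in groups:
            rep = g[0]
            a, b = aln.sequences[rep], aln.sequences[i]
            if all(x == y or x == "N" or y == "N" for x, y in zip(a, b)):
                g.append(i)
                placed = True
                break
        if not placed:
            groups.append([i])
    assignment: dict[str, str] = {}
    representative: dict[str, int] = {}
    frequencies: dict[str, int] = {}
    for k, g in enumerate(groups, start=1):
        hid = f"H{k}"
        representative[hid] = g[0]
        frequencies[hid] = len(g)
        for i in g:
            assignment[aln.samples[i]] = hid
    return HaplotypeTable(assignment, representative, frequencies)


def segregating_sites(aln: Alignment, haps: HaplotypeTable | None = None) -> SiteReport:
    """List polymorphic columns and classify each as shared or singleton.

    A column is segregating when >= 2 distinct nucleotides are observed
    (N and - are excluded from state counts).  A site is a singleton when
    exactly one genome carries a non-major state, shared when two or more
    do.  The haplotype-level minor count is reported alongside because
    sharing "between two or more haplotypes" and "in more than one
    genome" can in principle diverge.
    """
    if haps is None:
        haps = collapse_haplotypes(aln)
    mat = aln.matrix
    records: list[SiteRecord] = []
    hap_of = np.array([haps.assignment[s] for s in aln.samples])
    for col in range(aln.length):
        states = mat[:, col]
        called = np.isin(states, BASES)
        if not called.any():
            continue
        vals, counts = np.unique(states[called], return_counts=True)
        if len(vals) < 2:
            continue
        order = np.argsort(-counts, kind="stable")
        vals, counts = vals[order], counts[order]
        minor_genomes = int(counts[1:].sum())
        minor_mask = called & (states != vals[0])
        minor_haps = len(set(hap_of[minor_mask]))
        records.append(
            SiteRecord(
                position=col + 1,
                states="/".join(vals),
                minor_genomes=minor_genomes,
                minor_haplotypes=minor_haps,
                classification="singleton" if minor_genomes == 1 else "shared",
            )
        )
    return SiteReport(records)


def partition_density(
    aln: Alignment, parts: PartitionMap, report: SiteReport | None = None
) -> pd.DataFrame:
    """Per-class segregating-site counts S, class lengths L and density S/L.

    A segregating column inside a class span counts toward that class; a
    column covered by spans of several classes (the D-loop amplicon
    overlapping tRNA) counts toward each.  Columns outside every span are
    assigned to class "other" with the residual length, never dropped.
    """
    if report is None:
        report = segregating_sites(aln)
    covered = np.zeros(aln.length, dtype=bool)
    for e in parts.entries:
        covered[e.start - 1 : e.end] = True
    rows = []
    for cls in PARTITION_CLASSES:
        length = parts.class_length(cls)
        in_class = np.zeros(aln.length, dtype=bool)
        for e in parts.entries:
            if e.cls == cls:
                in_class[e.start - 1 : e.end] = True
        s = sum(1 for p in report.positions if in_class[p - 1])
        if cls == "other":
            # residual columns not covered by any entry fold into "other"
            residual = int((~covered).sum())
            length += residual
            s += sum(1 for p in report.positions if not covered[p - 1])
        if length == 0:
            continue
        rows.append(
            {
                "class": cls,
                "S": s,
                "L": length,
                "density": round(s / length, 5),
            }
        )
    return pd.DataFrame(rows)


def _pair_counts(row_a: np.ndarray, row_b: np.ndarray) -> tuple[int, int, int]:
    """(compared columns, transitions, transversions) for one pair."""
    called = np.isin(row_a, BASES) & np.isin(row_b, BASES)
    a, b = row_a[called], row_b[called]
    diff = a != b
    n_cmp = int(called.sum())
    if n_cmp == 0:
        return 0, 0, 0
    purine_a = np.isin(a, ("A", "G"))
    purine_b = np.isin(b, ("A", "G"))
    ts = int((diff & (purine_a == purine_b)).sum())
    tv = int((diff & (purine_a != purine_b)).sum())
    return n_cmp, ts, tv


def k2p_from_proportions(P: float, Q: float) -> float:
    """Kimura 2-parameter distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedPairError(f"K2P undefined for P={P}, Q={Q}")
    return -0.5 * np.log(w1 * np.sqrt(w2))


def pairwise_distances(aln: Alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distance matrix under the p or K2P model.

    Columns with N or - in either member of a pair are excluded for that
    pair (pairwise-complete).  K2P raises :class:`SaturatedPairError`
    when the correction's log argument is non-positive.
    """
    model = model.lower()
    if model not in ("p", "k2p"):
        raise ValueError("model must be 'p' or 'k2p'")
    n = aln.n_samples
    mat = aln.matrix
    d = np.zeros((n, n))
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            n_cmp, ts, tv = _pair_counts(mat[i], mat[j])
            if n_cmp == 0:
                raise ValueError(
                    f"no comparable columns between {aln.samples[i]} and {aln.samples[j]}"
                )
            p_ts, p_tv = ts / n_cmp, tv / n_cmp
            P[i, j] = P[j, i] = p_ts
            Q[i, j] = Q[j, i] = p_tv
            if model == "p":
                val = (ts + tv) / n_cmp
            else:
                try:
                    val = k2p_from_proportions(p_ts, p_tv)
                except SaturatedPairError as err:
                    raise SaturatedPairError(
                        f"pair ({aln.samples[i]}, {aln.samples[j]}): {err}"
                    ) from None
            d[i, j] = d[j, i] = val
    return DistanceMatrix(list(aln.samples), d, model, P, Q)


def mean_pairwise_stats(dm: DistanceMatrix, length: int) -> tuple[float, float]:
    """Nucleotide diversity pi and the mean pairwise difference count.

    pi is the mean of the p-distances over unordered sample pairs; the
    difference count is pi times the aligned length.
    """
    if dm.model != "p":
        raise ValueError("pi is defined on the uncorrected p-distance matrix")
    if dm.n < 2:
        raise ValueError("need >= 2 samples")
    iu = np.triu_indices(dm.n, k=1)
    pi = float(dm.d[iu].mean())
    return pi, pi * length
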