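"""Readers, writers and validated containers for the pipeline's file formats.

The pipeline works on a rectangular multiple alignment of complete
mitochondrial genomes, a partition table mapping aligned columns to loci
(protein-coding with reading frame, rRNA, tRNA, D-loop amplicon, other
non-coding), a two-level sample table (subspecies > population), and
newick trees.  Coordinates are 1-based and inclusive on the aligned
matrix; the circular genome is treated as the linearised alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
import dendropy

__all__ = [
    "Alignment",
    "Partition",
    "PartitionMap",
    "SampleTable",
    "AlignmentError",
    "FormatError",
    "PARTITION_CLASSES",
    "read_fasta",
    "write_fasta",
    "read_partition_table",
    "write_partition_table",
    "read_sample_table",
    "write_sample_table",
    "read_newick",
    "write_newick",
]

VALID_CHARS = frozenset("ACGTN-")
PARTITION_CLASSES = ("protein", "rRNA", "tRNA", "dloop", "other")


class FormatError(ValueError):
    """Malformed input file (duplicate IDs, bad columns, empty file...)."""


class AlignmentError(ValueError):
    """Alignment-level invariant violated (ragged rows, bad characters...)."""


@dataclass
class Alignment:
    """A rectangular nucleotide alignment over {A, C, G, T, N, -}.

    Sequences are stored uppercase; ``matrix`` exposes the alignment as an
    (n_samples, length) array of single characters for column arithmetic.
    """

    samples: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.samples:
            raise FormatError("alignment has no records")
        if len(self.samples) != len(set(self.samples)):
            raise FormatError("duplicate sample IDs in alignment")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged sequence lengths: {sorted(lengths)}")
        (self.length,) = lengths
        if self.length == 0:
            raise AlignmentError("zero-length alignment")
        bad = set("".join(self.sequences)) - VALID_CHARS
        if bad:
            raise AlignmentError(
                f"invalid characters {sorted(bad)}; only A,C,G,T,N,- are accepted"
            )
        self._matrix: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def matrix(self) -> np.ndarray:
        if self._matrix is None:
            self._matrix = np.array(
                [list(s) for s in self.sequences], dtype="U1"
            )
        return self._matrix

    def column(self, pos: int) -> np.ndarray:
        """States at 1-based column ``pos`` in sample order."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"column {pos} outside 1..{self.length}")
        return self.matrix[:, pos - 1]

    def subset_columns(self, positions: Sequence[int]) -> "Alignment":
        """New alignment keeping the given 1-based columns, in the given order."""
        idx = [p - 1 for p in positions]
        sub = self.matrix[:, idx]
        return Alignment(list(self.samples), ["".join(row) for row in sub])

    def index_of(self, sample: str) -> int:
        return self.samples.index(sample)


@dataclass(frozen=True)
class Partition:
    locus: str
    cls: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    frame: int | None = None  # 1-based column of first codon position
    strand: str = "+"

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1

    def columns(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class PartitionMap:
    """Locus annotation of the aligned columns.

    Entries of the same class may not overlap; overlap across classes is
    allowed (the D-loop genotyping amplicon overlaps tRNA-Pro in real
    mitogenomes).  Protein entries must be codon-complete after honouring
    the frame offset.
    """

    entries: list[Partition]
    alignment_length: int

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.cls not in PARTITION_CLASSES:
                raise FormatError(f"unknown partition class {e.cls!r}")
            if not 1 <= e.start <= e.end <= self.alignment_length:
                raise FormatError(
                    f"{e.locus}: span {e.start}-{e.end} outside 1..{self.alignment_length}"
                )
            if e.strand not in ("+", "-"):
                raise FormatError(f"{e.locus}: strand must be + or -")
            if e.cls == "protein":
                if e.frame is None or not e.start <= e.frame <= e.end:
                    raise FormatError(f"{e.locus}: protein entry needs in-span frame")
                # frame marks the first codon position; codons run rightward on
                # the plus strand, leftward on the minus strand
                span = (e.end - e.frame + 1) if e.strand == "+" else (e.frame - e.start + 1)
                if span % 3 != 0:
                    raise FormatError(
                        f"{e.locus}: protein span not codon-complete from frame {e.frame}"
                    )
        by_class: dict[str, list[Partition]] = {}
        for e in self.entries:
            by_class.setdefault(e.cls, []).append(e)
        for cls, group in by_class.items():
            group = sorted(group, key=lambda e: e.start)
            for a, b in zip(group, group[1:]):
                if b.start <= a.end:
                    raise FormatError(
                        f"overlapping {cls} entries: {a.locus} and {b.locus}"
                    )

    def class_length(self, cls: str) -> int:
        return sum(e.span_length for e in self.entries if e.cls == cls)

    def class_lengths(self) -> dict[str, int]:
        return {c: self.class_length(c) for c in PARTITION_CLASSES}

    def classes_at(self, pos: int) -> list[str]:
        """All classes annotating 1-based column ``pos`` (may be several)."""
        return [e.cls for e in self.entries if e.start <= pos <= e.end]

    def locus_at(self, pos: int) -> Partition | None:
        """First entry covering ``pos``, preferring coding over non-coding."""
        hits = [e for e in self.entries if e.start <= pos <= e.end]
        if not hits:
            return None
        order = {c: i for i, c in enumerate(PARTITION_CLASSES)}
        return min(hits, key=lambda e: order[e.cls])

    def protein_entries(self) -> list[Partition]:
        return [e for e in self.entries if e.cls == "protein"]


@dataclass
class SampleTable:
    """Two-level grouping of samples: subspecies (region) > population."""

    rows: pd.DataFrame  # columns: sample, subspecies, population

    def __post_init__(self) -> None:
        need = {"sample", "subspecies", "population"}
        if not need <= set(self.rows.columns):
            raise FormatError(f"sample table needs columns {sorted(need)}")
        if self.rows["sample"].duplicated().any():
            raise FormatError("duplicate sample IDs in sample table")
        nesting = self.rows.groupby("population")["subspecies"].nunique()
        bad = nesting[nesting > 1]
        if len(bad):
            raise FormatError(
                f"populations under multiple subspecies: {list(bad.index)}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.rows["sample"])

    @property
    def subspecies(self) -> list[str]:
        return sorted(self.rows["subspecies"].unique())

    @property
    def populations(self) -> list[str]:
        return sorted(self.rows["population"].unique())

    def population_of(self, sample: str) -> str:
        return self.rows.set_index("sample").loc[sample, "population"]

    def subspecies_of_population(self, population: str) -> str:
        sub = self.rows.loc[self.rows["population"] == population, "subspecies"]
        return sub.iloc[0]

    def members(self, population: str) -> list[str]:
        return list(self.rows.loc[self.rows["population"] == population, "sample"])

    def validate_against(self, aln: Alignment) -> None:
        missing = set(aln.samples) - set(self.samples)
        if missing:
            raise FormatError(f"alignment samples absent from table: {sorted(missing)}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA into an :class:`Alignment` (order preserved)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        raise FormatError(f"duplicate record IDs in {path}")
    return Alignment(ids, [str(r.seq) for r in records])


def write_fasta(aln: Alignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(aln.samples, aln.sequences):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Partition / sample tables (tab-delimited with header)


def read_partition_table(path: str | Path, aln: Alignment) -> PartitionMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"locus", "class", "start", "end"}
    if not need <= set(df.columns):
        raise FormatError(f"partition table needs columns {sorted(need)}")
    entries = []
    for _, row in df.iterrows():
        frame = row.get("frame")
        frame = int(frame) if frame not in (None, "", "NA") and not pd.isna(frame) else None
        strand = row.get("strand", "+")
        strand = "+" if pd.isna(strand) or strand == "" else str(strand)
        entries.append(
            Partition(
                locus=row["locus"],
                cls=row["class"],
                start=int(row["start"]),
                end=int(row["end"]),
                frame=frame,
                strand=strand,
            )
        )
    return PartitionMap(entries, aln.length)


def write_partition_table(parts: PartitionMap, path: str | Path) -> None:
    rows = [
        {
            "locus": e.locus,
            "class": e.cls,
            "start": e.start,
            "end": e.end,
            "frame": "" if e.frame is None else e.frame,
            "strand": e.strand,
        }
        for e in parts.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_table(path: str | Path, aln: Alignment | None = None) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    table = SampleTable(df)
    if aln is not None:
        table.validate_against(aln)
    return table


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick trees (dendropy)


def _check_tips(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate tip labels in newick tree")
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as err:  # dendropy raises schema-specific parse errors
        raise FormatError(f"cannot parse newick {path}: duplicate tips or malformed ({err})") from err
    return _check_tips(tree)


def parse_newick(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as err:
        raise FormatError(f"cannot parse newick: duplicate tips or malformed ({err})") from err
    return _check_tips(tree)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)
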