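"""Codon-level analysis under the vertebrate mitochondrial genetic code.

Protein partitions are translated with the vertebrate mitochondrial code
(ATA=Met, TGA=Trp, AGA/AGG=Stop; NCBI translation table 2).  Segregating
sites inside protein loci are mapped to their codons and every observed
state pair is classified as synonymous or replacement; changes can be
attributed to tree branches via deterministic minimum-change ancestral
reconstruction, and a label-permutation test asks whether one geographic
region carries an excess of region-unique amino-acid replacements.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .diversity import SiteReport, segregating_sites
from .homoplasy import sankoff_assign
from .io import Alignment, PartitionMap, Partition, SampleTable

__all__ = [
    "CodonChange",
    "BranchChange",
    "ReplacementExcessResult",
    "translate_mito",
    "classify_substitutions",
    "branch_changes",
    "replacement_excess_test",
]

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Stop",
}


def translate_mito(codon: str) -> str:
    """One-letter amino acid (or ``*``) for a codon, vertebrate mito code."""
    codon = codon.upper()
    if len(codon) != 3 or any(c not in "ACGT" for c in codon):
        raise ValueError(f"cannot translate ambiguous codon {codon!r}")
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table[codon]


@dataclass
class CodonChange:
    position: int  # 1-based alignment column of the changed site
    locus: str
    codon_index: int  # 1-based codon number within the locus
    codon_position: int  # 1, 2 or 3
    from_codon: str
    to_codon: str
    from_aa: str
    to_aa: str
    classification: str  # "synonymous" | "replacement"
    minor_carriers: tuple[str, ...] = ()  # samples carrying the minor codon
    premature_stop: bool = False

    @property
    def aa_change(self) -> str:
        return f"{AA3[self.from_aa]} > {AA3[self.to_aa]}"


def _codon_at(
    aln_row: np.ndarray, part: Partition, pos: int
) -> tuple[str, int, int]:
    """(codon string, 1-based codon index, codon position) for column pos.

    Reverse-strand loci are handled by reverse-complementing the codon;
    coordinates stay on the aligned (plus) strand.
    """
    if part.strand == "+":
        offset = pos - part.frame
        if offset < 0:
            raise ValueError(f"column {pos} upstream of frame start {part.frame}")
        codon_index = offset // 3
        codon_pos = offset % 3
        start = part.frame + 3 * codon_index
        codon = "".join(aln_row[start - 1 : start + 2])
        return codon, codon_index + 1, codon_pos + 1
    # minus strand: first codon position at the frame column reading leftward
    offset = part.frame - pos
    if offset < 0:
        raise ValueError(f"column {pos} downstream of frame start {part.frame}")
    codon_index = offset // 3
    codon_pos = offset % 3
    start = part.frame - 3 * codon_index  # plus-strand column of codon position 1
    plus = "".join(aln_row[start - 3 : start])  # columns start-2..start
    codon = str(Seq(plus).reverse_complement())
    return codon, codon_index + 1, codon_pos + 1


def classify_substitutions(
    aln: Alignment,
    parts: PartitionMap,
    report: SiteReport | None = None,
) -> list[CodonChange]:
    """Classify each protein-locus segregating site as synonymous/replacement.

    For every segregating site inside a protein partition, the observed
    codons across samples are enumerated and each (major, minor) codon
    pair classified.  Codons containing N or - are skipped.  A change
    creating a premature stop is flagged, not dropped.
    """
    if report is None:
        report = segregating_sites(aln)
    changes: list[CodonChange] = []
    for rec in report.sites:
        for part in parts.protein_entries():
            if not part.start <= rec.position <= part.end:
                continue
            codons: dict[str, list[str]] = {}
            meta = None
            for idx, sample in enumerate(aln.samples):
                try:
                    codon, ci, cp = _codon_at(aln.matrix[idx], part, rec.position)
                except ValueError:
                    continue
                if any(c not in "ACGT" for c in codon):
                    continue
                codons.setdefault(codon, []).append(sample)
                meta = (ci, cp)
            if meta is None or len(codons) < 2:
                continue
            ci, cp = meta
            major = max(codons, key=lambda c: (len(codons[c]), c))
            for minor in sorted(codons):
                if minor == major:
                    continue
                aa_from = translate_mito(major)
                aa_to = translate_mito(minor)
                changes.append(
                    CodonChange(
                        position=rec.position,
                        locus=part.locus,
                        codon_index=ci,
                        codon_position=cp,
                        from_codon=major,
                        to_codon=minor,
                        from_aa=aa_from,
                        to_aa=aa_to,
                        classification=(
                            "synonymous" if aa_from == aa_to else "replacement"
                        ),
                        minor_carriers=tuple(codons[minor]),
                        premature_stop=(aa_to == "*" and aa_from != "*"),
                    )
                )
    return changes


@dataclass
class BranchChange:
    branch: str  # label of the child node the edge leads to
    position: int
    locus: str
    from_state: str
    to_state: str
    classification: str  # synonymous | replacement | noncoding
    ambiguous: bool  # minimum-change assignment had unresolved ties


def _branch_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    tips = sorted(lf.taxon.label for lf in node.leaf_iter())
    return "|".join(tips)


def branch_changes(
    tree: dendropy.Tree,
    aln: Alignment,
    parts: PartitionMap,
    report: SiteReport | None = None,
) -> pd.DataFrame:
    """Attribute inferred changes to branches and tally syn/rep per branch.

    Each segregating site gets deterministic minimum-change ancestral
    states (unit-cost parsimony, ties broken toward the parent state then
    alphabetically); every edge whose endpoints differ carries one
    change, classified through the parent/child codons for protein
    sites.  Sites whose assignment hit a tie are flagged ``ambiguous``
    and reported in a separate tally column.
    """
    if report is None:
        report = segregating_sites(aln)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = tips - set(aln.samples)
    if missing:
        raise ValueError(f"tree tips not in alignment: {sorted(missing)}")
    # per-site ancestral assignments, computed once per segregating column
    site_assign: dict[int, dict] = {}
    site_ambig: dict[int, bool] = {}
    for rec in report.sites:
        col = aln.column(rec.position)
        states = {s: col[aln.index_of(s)] for s in tips}
        assignment, ambiguous = sankoff_assign(tree, states)
        site_assign[rec.position] = assignment
        site_ambig[rec.position] = ambiguous

    def node_state(node: dendropy.Node, pos: int) -> str:
        if pos in site_assign:
            return site_assign[pos][node]
        # monomorphic column: take any tip's state
        first = next(iter(tips))
        return aln.column(pos)[aln.index_of(first)]

    records: list[BranchChange] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        label = _branch_label(node)
        for pos, assignment in site_assign.items():
            parent_state = assignment[node.parent_node]
            child_state = assignment[node]
            if parent_state == child_state:
                continue
            part = next(
                (e for e in parts.protein_entries() if e.start <= pos <= e.end),
                None,
            )
            if part is None:
                cls = "noncoding"
            else:
                # rebuild parent/child codons from the per-site assignments
                if part.strand == "+":
                    offset = pos - part.frame
                    start = part.frame + 3 * (offset // 3)
                    cols = [start, start + 1, start + 2]
                else:
                    offset = part.frame - pos
                    start = part.frame - 3 * (offset // 3)
                    cols = [start - 2, start - 1, start]
                parent_codon = "".join(node_state(node.parent_node, c) for c in cols)
                child_codon = "".join(node_state(node, c) for c in cols)
                if part.strand == "-":
                    parent_codon = str(Seq(parent_codon).reverse_complement())
                    child_codon = str(Seq(child_codon).reverse_complement())
                cls = (
                    "synonymous"
                    if translate_mito(parent_codon) == translate_mito(child_codon)
                    else "replacement"
                )
            records.append(
                BranchChange(
                    branch=label,
                    position=pos,
                    locus=(parts.locus_at(pos).locus if parts.locus_at(pos) else "other"),
                    from_state=parent_state,
                    to_state=child_state,
                    classification=cls,
                    ambiguous=site_ambig[pos],
                )
            )
    if not records:
        return pd.DataFrame(
            columns=["branch", "synonymous", "replacement", "noncoding", "ambiguous"]
        )
    df = pd.DataFrame([r.__dict__ for r in records])
    tally = (
        df.pivot_table(
            index="branch",
            columns="classification",
            values="position",
            aggfunc="count",
            fill_value=0,
        )
        .reindex(columns=["synonymous", "replacement", "noncoding"], fill_value=0)
        .reset_index()
    )
    ambig = df.groupby("branch")["ambiguous"].sum().rename("ambiguous").reset_index()
    out = tally.merge(ambig, on="branch")
    out.attrs["changes"] = records
    return out


@dataclass
class ReplacementExcessResult:
    per_region: pd.DataFrame  # region, unique_replacements, unique_changes, proportion, p
    grand_mean: float
    n_perm: int
    seed: int | None


def _unique_props(
    carrier_sets: list[tuple[frozenset[str], str]],
    region_of: dict[str, str],
    regions: list[str],
) -> dict[str, tuple[int, int]]:
    """Per region: (# region-unique replacements, # region-unique changes)."""
    counts = {r: [0, 0] for r in regions}
    for carriers, cls in carrier_sets:
        carrier_regions = {region_of[s] for s in carriers}
        if len(carrier_regions) != 1:
            continue
        (r,) = carrier_regions
        counts[r][1] += 1
        if cls == "replacement":
            counts[r][0] += 1
    return {r: (c[0], c[1]) for r, c in counts.items()}


def replacement_excess_test(
    changes: list[CodonChange],
    groups: SampleTable,
    n_perm: int = 10_000,
    seed: int | None = None,
    level: str = "subspecies",
) -> ReplacementExcessResult:
    """Test each region for an excess of region-unique amino-acid replacements.

    A change is unique to a region when every carrier of its minor codon
    belongs to that region.  The per-region statistic is the proportion
    of its unique changes that are replacements; the null distribution
    comes from permuting the sample -> region labels, and for each region
    p = (1 + #{perm proportion >= observed}) / (1 + n_perm).  Regions
    with no unique changes are excluded with a NaN proportion.
    """
    if level not in ("subspecies", "population"):
        raise ValueError("level must be 'subspecies' or 'population'")
    if not changes:
        raise ValueError("no codon changes supplied")
    col = level
    region_of = dict(zip(groups.rows["sample"], groups.rows[col]))
    regions = sorted(set(region_of.values()))
    if len(regions) < 2:
        raise ValueError("need >= 2 regions")
    carrier_sets = [
        (frozenset(c.minor_carriers), c.classification)
        for c in changes
        if c.minor_carriers
    ]
    observed = _unique_props(carrier_sets, region_of, regions)
    obs_prop = {
        r: (u / t if t > 0 else float("nan")) for r, (u, t) in observed.items()
    }
    valid = [r for r in regions if observed[r][1] > 0]
    grand_mean = float(np.mean([obs_prop[r] for r in valid])) if valid else float("nan")

    rng = np.random.default_rng(seed)
    samples = list(region_of)
    labels = [region_of[s] for s in samples]
    exceed = {r: 0 for r in regions}
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        perm_of = dict(zip(samples, perm))
        pc = _unique_props(carrier_sets, perm_of, regions)
        for r in regions:
            u, t = pc[r]
            prop = u / t if t > 0 else -np.inf  # no unique changes: cannot exceed
            if r in valid and prop >= obs_prop[r] - 1e-12:
                exceed[r] += 1
    rows = []
    for r in regions:
        u, t = observed[r]
        rows.append(
            {
                "region": r,
                "unique_replacements": u,
                "unique_changes": t,
                "proportion": obs_prop[r],
                "p": (1 + exceed[r]) / (1 + n_perm) if r in valid else float("nan"),
            }
        )
    return ReplacementExcessResult(
        per_region=pd.DataFrame(rows),
        grand_mean=grand_mean,
        n_perm=n_perm,
        seed=seed,
    )
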