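"""Cognate HK-RR pair matching from gene order, and pair-wise merging.

Histidine kinase / response regulator pairs are overwhelmingly
co-operonic, so genomic adjacency identifies cognate partners: an HK and
an RR are matched iff they sit at consecutive gene-order positions on the
same contig and neither has a competing adjacent candidate.  Runs of
HK/RR genes where cognate assignment is ambiguous ("clusters") are
removed wholesale — both the ambiguous gene and every gene it is adjacent
to — and genes with no adjacent opposite-role partner are dropped as
orphans.  Matched pairs are then merged into one concatenated record per
pair (HK first) for joint phylogenetic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import Alignment
from .errors import InvalidInputError, MissingSequenceError

ROLES = ("HK", "RR")


@dataclass(frozen=True)
class GeneRecord:
    """One gene in a genome's gene-order table."""

    genome: str
    contig: str
    ordinal: int
    strand: str
    role: str
    gene_id: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise InvalidInputError(
                f"gene {self.gene_id!r}: role must be HK or RR, got {self.role!r}"
            )
        if self.strand not in ("+", "-"):
            raise InvalidInputError(
                f"gene {self.gene_id!r}: strand must be '+' or '-'"
            )


@dataclass(frozen=True)
class MatchedPair:
    hk_gene_id: str
    rr_gene_id: str
    genome: str
    merged_id: str


@dataclass(frozen=True)
class DroppedGene:
    gene_id: str
    reason: str  # "cluster" | "orphan"


def match_cognate_pairs(
    records: list[GeneRecord],
) -> tuple[list[MatchedPair], list[DroppedGene]]:
    """Pair adjacent HK-RR genes; drop clusters and orphans.

    A gene with two or more adjacent opposite-role candidates is ambiguous:
    it and all its candidates are dropped with reason ``"cluster"``.  Genes
    with no adjacent opposite-role candidate are dropped as ``"orphan"``.
    The result is order-independent and covers every input gene exactly
    once (pairs + dropped).
    """
    seen_pos: dict[tuple[str, str, int], str] = {}
    for rec in records:
        key = (rec.genome, rec.contig, rec.ordinal)
        if key in seen_pos:
            raise InvalidInputError(
                f"duplicate gene-order position {key}: "
                f"{seen_pos[key]!r} and {rec.gene_id!r}"
            )
        seen_pos[key] = rec.gene_id
    by_pos = {
        (rec.genome, rec.contig, rec.ordinal): rec for rec in records
    }
    neighbors: dict[str, list[GeneRecord]] = {rec.gene_id: [] for rec in records}
    for rec in records:
        for delta in (-1, 1):
            other = by_pos.get((rec.genome, rec.contig, rec.ordinal + delta))
            if other is not None and other.role != rec.role:
                neighbors[rec.gene_id].append(other)

    clustered: set[str] = set()
    for rec in records:
        if len(neighbors[rec.gene_id]) >= 2:
            clustered.add(rec.gene_id)
            clustered.update(o.gene_id for o in neighbors[rec.gene_id])

    pairs: list[MatchedPair] = []
    dropped: list[DroppedGene] = []
    paired: set[str] = set()
    for rec in sorted(records, key=lambda r: (r.genome, r.contig, r.ordinal)):
        gid = rec.gene_id
        if gid in clustered:
            dropped.append(DroppedGene(gid, "cluster"))
            continue
        cands = [o for o in neighbors[gid] if o.gene_id not in clustered]
        if not cands:
            dropped.append(DroppedGene(gid, "orphan"))
            continue
        if gid in paired:
            continue
        (other,) = cands  # unique: >=2 would have been a cluster
        hk, rr = (rec, other) if rec.role == "HK" else (other, rec)
        pairs.append(
            MatchedPair(
                hk_gene_id=hk.gene_id,
                rr_gene_id=rr.gene_id,
                genome=rec.genome,
                merged_id=f"{hk.gene_id}__{rr.gene_id}",
            )
        )
        paired.update((hk.gene_id, rr.gene_id))
    return pairs, dropped


#: provenance entry: (source alignment "HK"|"RR", 1-based source column)
ProvenanceMap = list[tuple[str, int]]


def merge_pair_alignments(
    hk_alignment: Alignment,
    rr_alignment: Alignment,
    pairs: list[MatchedPair],
) -> tuple[Alignment, ProvenanceMap]:
    """Concatenate each pair's HK and RR rows (HK first).

    Returns the merged alignment (ids are the pairs' ``merged_id``) and a
    column-provenance map: merged column ``j`` (1-based) came from
    ``provenance[j-1] = (source, source_column)``.
    """
    records = []
    for pair in pairs:
        if pair.hk_gene_id not in hk_alignment:
            raise MissingSequenceError(
                f"HK alignment lacks sequence {pair.hk_gene_id!r}"
            )
        if pair.rr_gene_id not in rr_alignment:
            raise MissingSequenceError(
                f"RR alignment lacks sequence {pair.rr_gene_id!r}"
            )
        records.append(
            (
                pair.merged_id,
                hk_alignment.sequence(pair.hk_gene_id)
                + rr_alignment.sequence(pair.rr_gene_id),
            )
        )
    provenance: ProvenanceMap = [
        ("HK", c) for c in range(1, hk_alignment.n_columns + 1)
    ] + [("RR", c) for c in range(1, rr_alignment.n_columns + 1)]
    return Alignment(records), provenance


def split_merged_alignment(
    merged: Alignment, provenance: ProvenanceMap
) -> tuple[Alignment, Alignment]:
    """Inverse of :func:`merge_pair_alignments` (ids stay the merged ids)."""
    hk_cols = [i + 1 for i, (src, _) in enumerate(provenance) if src == "HK"]
    rr_cols = [i + 1 for i, (src, _) in enumerate(provenance) if src == "RR"]
    return merged.take_columns(hk_cols), merged.take_columns(rr_cols)
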