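"""Readers and writers for the standard formats shared by all stages.

Conventions stated in every output: sequence coordinates are 1-based,
times are seconds, concentrations are uM.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import Alignment
from .ancestors import AncestorSequence, SitePosteriorMatrix
from .errors import FormatError, InvalidInputError
from .kinetics import TimeCourse
from .pairing import DroppedGene, GeneRecord, MatchedPair

GENE_TABLE_COLUMNS = ["genome", "contig", "ordinal", "strand", "role", "gene_id"]
TIMECOURSE_COLUMNS = ["pair", "time_s", "intensity"]


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: "str | os.PathLike", aligned: bool = True):
    """Read a FASTA file.

    With ``aligned=True`` (default) the records become an
    :class:`Alignment` and unequal lengths are a format error; with
    ``aligned=False`` the raw ``(id, sequence)`` list is returned.
    Duplicate ids are always rejected.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate record ids")
    if not aligned:
        return records
    lengths = {len(seq) for _, seq in records}
    if len(lengths) > 1:
        raise FormatError(
            f"{path}: records have unequal lengths {sorted(lengths)}"
        )
    try:
        return Alignment(records)
    except InvalidInputError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_fasta(alignment: Alignment, path: "str | os.PathLike") -> None:
    """Write FASTA with 60-column line wrapping."""
    records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in alignment
    ]
    SeqIO.write(records, str(path), "fasta")


# -- time courses -----------------------------------------------------------

def read_timecourse_csv(path: "str | os.PathLike") -> list[TimeCourse]:
    """Read ``pair,time_s,intensity`` rows into per-pair time courses.

    Rows are grouped by pair label and sorted by time; a pair without a
    t=0 row is a format error (normalization would be undefined).
    """
    table = pd.read_csv(path)
    missing = [c for c in TIMECOURSE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for pair, grp in table.groupby("pair", sort=True):
        grp = grp.sort_values("time_s")
        times = grp["time_s"].to_numpy(dtype=float)
        if len(times) == 0 or times[0] != 0.0:
            raise FormatError(f"{path}: pair {pair!r} has no t=0 row")
        try:
            out.append(
                TimeCourse(
                    pair=str(pair),
                    times=times,
                    intensity=grp["intensity"].to_numpy(dtype=float),
                )
            )
        except InvalidInputError as exc:
            raise FormatError(f"{path}: {exc}") from None
    return out


def write_timecourse_csv(
    timecourses: Iterable[TimeCourse], path: "str | os.PathLike"
) -> None:
    rows = [
        {"pair": tc.pair, "time_s": t, "intensity": y}
        for tc in timecourses
        for t, y in zip(tc.times, tc.intensity)
    ]
    pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS).to_csv(path, index=False)


# -- gene tables ------------------------------------------------------------

def read_gene_table(path: "str | os.PathLike") -> list[GeneRecord]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    try:
        return [
            GeneRecord(
                genome=row.genome,
                contig=row.contig,
                ordinal=int(row.ordinal),
                strand=row.strand,
                role=row.role,
                gene_id=row.gene_id,
            )
            for row in table.itertuples()
        ]
    except (InvalidInputError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_gene_table(
    records: Iterable[GeneRecord], path: "str | os.PathLike"
) -> None:
    pd.DataFrame(
        [
            {
                "genome": r.genome,
                "contig": r.contig,
                "ordinal": r.ordinal,
                "strand": r.strand,
                "role": r.role,
                "gene_id": r.gene_id,
            }
            for r in records
        ],
        columns=GENE_TABLE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# -- pairing outputs --------------------------------------------------------

def write_pairs_table(
    pairs: Iterable[MatchedPair],
    dropped: Iterable[DroppedGene],
    pairs_path: "str | os.PathLike",
    dropped_path: "str | os.PathLike",
) -> None:
    pd.DataFrame(
        [
            {
                "merged_id": p.merged_id,
                "hk_gene_id": p.hk_gene_id,
                "rr_gene_id": p.rr_gene_id,
                "genome": p.genome,
            }
            for p in pairs
        ],
        columns=["merged_id", "hk_gene_id", "rr_gene_id", "genome"],
    ).to_csv(pairs_path, sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": d.gene_id, "reason": d.reason} for d in dropped],
        columns=["gene_id", "reason"],
    ).to_csv(dropped_path, sep="\t", index=False)


# -- reconstruction outputs -------------------------------------------------

def write_posteriors_tsv(
    posteriors: Iterable[SitePosteriorMatrix], path: "str | os.PathLike"
) -> None:
    """One row per (node, site), 1-based sites, 20 probability columns."""
    frames = []
    for post in posteriors:
        frame = pd.DataFrame(
            post.probabilities, columns=list(post.alphabet)
        )
        frame.insert(0, "site", np.arange(1, post.n_sites + 1))
        frame.insert(0, "node", post.node_id)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_ancestor_confidence_tsv(
    ancestors: Iterable[AncestorSequence], path: "str | os.PathLike"
) -> None:
    rows = []
    for anc in ancestors:
        for site, (residue, pp) in enumerate(
            zip(anc.map_sequence, anc.site_max_pp), start=1
        ):
            rows.append(
                {
                    "node": anc.node_id,
                    "site": site,
                    "map_residue": residue,
                    "max_pp": pp,
                    "tied": site in anc.tied_sites,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_ancestral_truth_tsv(
    truth: dict[str, str], path: "str | os.PathLike"
) -> None:
    pd.DataFrame(
        sorted(truth.items()), columns=["node_id", "sequence"]
    ).to_csv(path, sep="\t", index=False)


def read_ancestral_truth_tsv(path: "str | os.PathLike") -> dict[str, str]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("node_id", "sequence"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return dict(zip(table["node_id"], table["sequence"]))
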