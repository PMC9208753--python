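"""Clade residue-frequency profiles and paralog-specific position calling.

After a duplication, positions that determine partner specificity show a
characteristic signature: one residue (or chemical class, e.g. the acidic
pair D/E) nearly fixed in one paralog clade and nearly absent from the
other.  This module computes per-position residue frequencies over leaf
subsets, calls such clade-diagnostic positions, trims alignments by
occupancy and conservation, maps reference residue numbering to alignment
columns, and applies bookkeeping substitutions (e.g. ``R27Q``) to
ancestor sequences.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, GAP, UNKNOWN, Alignment
from .errors import InvalidArgumentError, WildTypeMismatchError

#: default residue classes for class-level frequency calls
DEFAULT_RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "acidic": frozenset({"D", "E"}),
    "basic": frozenset({"K", "R"}),
}


@dataclass
class FrequencyTable:
    """Per-position residue frequencies among non-gap characters.

    ``frequencies`` is indexed by 1-based alignment position with one
    column per amino acid; rows sum to 1 (positions with no non-gap
    characters are all-zero with ``n_sequences`` 0).
    """

    frequencies: pd.DataFrame
    n_sequences: pd.Series
    subset_size: int

    @property
    def positions(self) -> list[int]:
        return list(self.frequencies.index)

    def frequency(self, position: int, residues: "str | set[str]") -> float:
        """Frequency of a residue (or summed class of residues)."""
        if isinstance(residues, str):
            residues = {residues}
        row = self.frequencies.loc[position]
        return float(sum(row[r] for r in residues))


def position_frequencies(
    alignment: Alignment,
    subset: Sequence[str],
    positions: Sequence[int] | None = None,
) -> FrequencyTable:
    """Residue frequencies over ``subset`` at the given columns (default all).

    Gaps and ``X`` are excluded from both numerator and denominator;
    ``n_sequences`` reports the per-position non-gap count.
    """
    subset = list(subset)
    if not subset:
        raise InvalidArgumentError("subset must contain at least one id")
    if positions is None:
        positions = range(1, alignment.n_columns + 1)
    positions = [int(p) for p in positions]
    for p in positions:
        if not 1 <= p <= alignment.n_columns:
            raise InvalidArgumentError(
                f"position {p} out of range 1..{alignment.n_columns}"
            )
    rows = [alignment.sequence(rid) for rid in subset]
    data = np.zeros((len(positions), len(AMINO_ACIDS)))
    counts = np.zeros(len(positions), dtype=int)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for i, p in enumerate(positions):
        for seq in rows:
            ch = seq[p - 1]
            if ch in (GAP, UNKNOWN):
                continue
            data[i, aa_index[ch]] += 1
            counts[i] += 1
        if counts[i]:
            data[i] /= counts[i]
    return FrequencyTable(
        frequencies=pd.DataFrame(
            data, index=pd.Index(positions, name="position"), columns=list(AMINO_ACIDS)
        ),
        n_sequences=pd.Series(counts, index=positions, name="n_sequences"),
        subset_size=len(subset),
    )


@dataclass
class PositionCall:
    """Verdict on whether one position distinguishes the two clades."""

    position: int
    clade1_top: str
    clade1_top_freq: float
    clade2_top: str
    clade2_top_freq: float
    is_specific: bool
    feature: str | None = None      # residue or class name that triggered
    direction: int | None = None    # clade (1 or 2) where the feature is high
    f_high: float = 0.9
    f_low: float = 0.1
    boundary: bool = False          # a frequency sits exactly on a threshold


def paralog_specific_positions(
    freq1: FrequencyTable,
    freq2: FrequencyTable,
    f_high: float = 0.9,
    f_low: float = 0.1,
    residue_classes: Mapping[str, frozenset[str]] | None = None,
) -> list[PositionCall]:
    """Call positions where a residue or class separates the two clades.

    A position is paralog-specific when some single residue, or one of the
    declared residue classes, has frequency >= ``f_high`` in one clade and
    <= ``f_low`` in the other (in either direction).  Returns one call per
    position; filter on ``is_specific`` for the diagnostic subset.
    """
    if list(freq1.positions) != list(freq2.positions):
        raise InvalidArgumentError(
            "frequency tables cover different position sets"
        )
    if residue_classes is None:
        residue_classes = DEFAULT_RESIDUE_CLASSES
    features: list[tuple[str, set[str]]] = [(aa, {aa}) for aa in AMINO_ACIDS]
    features += [(name, set(members)) for name, members in residue_classes.items()]

    calls = []
    for pos in freq1.positions:
        row1 = freq1.frequencies.loc[pos]
        row2 = freq2.frequencies.loc[pos]
        top1 = row1.idxmax() if row1.max() > 0 else "-"
        top2 = row2.idxmax() if row2.max() > 0 else "-"
        call = PositionCall(
            position=int(pos),
            clade1_top=top1,
            clade1_top_freq=float(row1.max()),
            clade2_top=top2,
            clade2_top_freq=float(row2.max()),
            is_specific=False,
            f_high=f_high,
            f_low=f_low,
        )
        for name, members in features:
            p1 = freq1.frequency(pos, members)
            p2 = freq2.frequency(pos, members)
            hit1 = p1 >= f_high and p2 <= f_low
            hit2 = p2 >= f_high and p1 <= f_low
            if hit1 or hit2:
                call.is_specific = True
                call.feature = name
                call.direction = 1 if hit1 else 2
                call.boundary = (
                    p1 in (f_high, f_low) or p2 in (f_high, f_low)
                )
                break
        calls.append(call)
    return calls


def trim_alignment(
    alignment: Alignment,
    min_occupancy: float = 0.5,
    min_conservation: float = 0.25,
) -> tuple[Alignment, list[int]]:
    """Drop low-occupancy, then low-conservation columns.

    A column is removed when its non-gap fraction is strictly below
    ``min_occupancy``, or when its most frequent non-gap residue accounts
    for strictly less than ``min_conservation`` of the non-gap characters.
    Returns the trimmed alignment and the surviving original columns
    (1-based); trimming a trimmed alignment removes nothing further.
    Removing every column is a warning, not an error: the result is a
    zero-column alignment.
    """
    for name, val in (
        ("min_occupancy", min_occupancy),
        ("min_conservation", min_conservation),
    ):
        if not 0.0 < val <= 1.0:
            raise InvalidArgumentError(f"{name} must be in (0, 1], got {val}")
    n = alignment.n_sequences
    kept: list[int] = []
    for col in range(1, alignment.n_columns + 1):
        column = alignment.column(col)
        residues = [ch for ch in column if ch not in (GAP, UNKNOWN)]
        if len(residues) / n < min_occupancy:
            continue
        if not residues:
            continue
        top = max(residues.count(aa) for aa in set(residues))
        if top / len(residues) < min_conservation:
            continue
        kept.append(col)
    if not kept:
        warnings.warn("all columns were removed by trimming", stacklevel=2)
    return alignment.take_columns(kept), kept


def plot_frequency_logo(
    tables: "Mapping[str, FrequencyTable]",
    positions: Sequence[int],
    path: "str | None" = None,
):
    """Stacked-frequency (logo-style) plot for chosen positions.

    One panel per named subset (e.g. the two paralog clades); bar height
    is residue frequency.  Requires matplotlib; returns the figure, and
    writes PNG/SVG when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, len(tables), figsize=(2.2 * len(positions) * len(tables) / 2 + 2, 3),
        squeeze=False,
    )
    for ax, (name, table) in zip(axes[0], tables.items()):
        xs = np.arange(len(positions))
        for i, pos in enumerate(positions):
            bottom = 0.0
            row = table.frequencies.loc[pos].sort_values(ascending=False)
            for residue, freq in row.items():
                if freq <= 0:
                    continue
                ax.bar(i, freq, bottom=bottom, width=0.7)
                if freq > 0.08:
                    ax.text(i, bottom + freq / 2, residue,
                            ha="center", va="center", fontsize=9)
                bottom += freq
        ax.set_xticks(xs, [str(p) for p in positions])
        ax.set_ylim(0, 1.02)
        ax.set_title(f"{name} (n={table.subset_size})")
        ax.set_xlabel("position")
        ax.set_ylabel("frequency")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig


@dataclass
class CoordinateMap:
    """Bidirectional map between ungapped reference positions and columns."""

    reference_id: str
    ref_to_column: dict[int, int] = field(default_factory=dict)
    column_to_ref: dict[int, int] = field(default_factory=dict)

    def column(self, reference_position: int) -> int:
        try:
            return self.ref_to_column[reference_position]
        except KeyError:
            raise InvalidArgumentError(
                f"reference position {reference_position} beyond the ungapped "
                f"length of {self.reference_id!r}"
            ) from None

    def reference_position(self, column: int) -> int:
        try:
            return self.column_to_ref[column]
        except KeyError:
            raise InvalidArgumentError(
                f"column {column} is a gap in reference {self.reference_id!r}"
            ) from None


def map_reference_position(
    alignment: Alignment,
    reference_id: str,
    reference_positions: Sequence[int] | None = None,
) -> CoordinateMap:
    """Map 1-based ungapped positions of a reference row to alignment columns."""
    seq = alignment.sequence(reference_id)
    ref_to_col: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(seq, start=1):
        if ch == GAP:
            continue
        pos += 1
        ref_to_col[pos] = col
    if reference_positions is not None:
        for p in reference_positions:
            if p not in ref_to_col:
                raise InvalidArgumentError(
                    f"reference position {p} beyond ungapped length {pos} "
                    f"of {reference_id!r}"
                )
        ref_to_col = {p: ref_to_col[p] for p in reference_positions}
    return CoordinateMap(
        reference_id=reference_id,
        ref_to_column=ref_to_col,
        column_to_ref={c: p for p, c in ref_to_col.items()},
    )


_MUTATION_RE = re.compile(r"^([A-Y])(\d+)([A-Y])$")


@dataclass
class AppliedSubstitution:
    mutation: str
    reference_position: int
    column: int
    from_residue: str
    to_residue: str


def apply_substitutions(
    sequence: str,
    mutations: Sequence[str],
    coordinate_map: CoordinateMap | None = None,
) -> tuple[str, list[AppliedSubstitution]]:
    """Apply mutations like ``"R27Q"`` left to right, verifying wild types.

    Positions are reference numbering translated through ``coordinate_map``
    (or direct 1-based columns when no map is given).  A mismatch between
    the stated wild-type residue and the sequence raises, guarding against
    numbering drift.
    """
    seq = list(sequence)
    applied: list[AppliedSubstitution] = []
    for mutation in mutations:
        m = _MUTATION_RE.match(mutation)
        if not m:
            raise InvalidArgumentError(
                f"cannot parse mutation {mutation!r} (expected e.g. 'R27Q')"
            )
        wild, pos, new = m.group(1), int(m.group(2)), m.group(3)
        col = coordinate_map.column(pos) if coordinate_map else pos
        if not 1 <= col <= len(seq):
            raise InvalidArgumentError(
                f"mutation {mutation!r}: column {col} outside sequence "
                f"length {len(seq)}"
            )
        found = seq[col - 1]
        if found != wild:
            raise WildTypeMismatchError(
                f"mutation {mutation!r}: expected {wild} at position {pos} "
                f"(column {col}) but found {found}"
            )
        seq[col - 1] = new
        applied.append(
            AppliedSubstitution(
                mutation=mutation,
                reference_position=pos,
                column=col,
                from_residue=wild,
                to_residue=new,
            )
        )
    return "".join(seq), applied
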