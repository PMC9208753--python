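"""Amino-acid alignment container.

Sequences use the 20 standard one-letter amino-acid codes plus ``-`` (gap)
and ``X`` (unknown residue).  Both ``-`` and ``X`` are treated as missing
data by every downstream computation; neither is ever a 21st state.
Column indices are 1-based throughout the package.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import InvalidArgumentError, InvalidInputError

#: Amino acids in the fixed order used by all matrices and frequency vectors
#: (the conventional order of published rate-matrix files).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
UNKNOWN = "X"
_ALPHABET = set(AMINO_ACIDS) | {GAP, UNKNOWN}
#: residue -> index in AMINO_ACIDS; gap/unknown map to -1 (missing data).
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
AA_INDEX[GAP] = -1
AA_INDEX[UNKNOWN] = -1


class Alignment:
    """An ordered collection of equal-length amino-acid sequences.

    Parameters
    ----------
    records:
        Iterable of ``(id, sequence)`` pairs.  Ids must be unique and
        sequences must share one length and stay within the alphabet.
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        recs = [(str(i), str(s).upper()) for i, s in records]
        if not recs:
            raise InvalidInputError("alignment must contain at least one record")
        ids = [r[0] for r in recs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"duplicate sequence ids: {dup}")
        length = len(recs[0][1])
        for rid, seq in recs:
            if len(seq) != length:
                raise InvalidInputError(
                    f"sequence {rid!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - _ALPHABET
            if bad:
                raise InvalidInputError(
                    f"sequence {rid!r} contains characters outside the "
                    f"amino-acid alphabet: {sorted(bad)}"
                )
        self._ids = ids
        self._seqs = [r[1] for r in recs]
        self._index = {rid: k for k, rid in enumerate(ids)}

    # -- basic container protocol -------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    @property
    def n_sequences(self) -> int:
        return len(self._ids)

    @property
    def n_columns(self) -> int:
        return len(self._seqs[0])

    def __len__(self) -> int:
        return len(self._ids)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self._ids, self._seqs))

    def __contains__(self, rid: str) -> bool:
        return rid in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self._ids == other._ids and self._seqs == other._seqs

    def sequence(self, rid: str) -> str:
        try:
            return self._seqs[self._index[rid]]
        except KeyError:
            raise KeyError(f"no sequence with id {rid!r}") from None

    def column(self, col: int) -> str:
        """Return alignment column ``col`` (1-based) as a string."""
        if not 1 <= col <= self.n_columns:
            raise InvalidArgumentError(
                f"column {col} out of range 1..{self.n_columns}"
            )
        return "".join(s[col - 1] for s in self._seqs)

    def subset(self, ids: Sequence[str]) -> "Alignment":
        """Row subset in the given order."""
        return Alignment((rid, self.sequence(rid)) for rid in ids)

    def slice_columns(self, start: int, end: int) -> "Alignment":
        """Columns ``start``..``end`` inclusive, 1-based."""
        if not (1 <= start <= end <= self.n_columns):
            raise InvalidArgumentError(
                f"invalid column range {start}..{end} for width {self.n_columns}"
            )
        return Alignment(
            (rid, seq[start - 1 : end]) for rid, seq in zip(self._ids, self._seqs)
        )

    def take_columns(self, columns: Sequence[int]) -> "Alignment":
        """Arbitrary column subset (1-based, in the given order)."""
        for c in columns:
            if not 1 <= c <= self.n_columns:
                raise InvalidArgumentError(f"column {c} out of range")
        return Alignment(
            (rid, "".join(seq[c - 1] for c in columns))
            for rid, seq in zip(self._ids, self._seqs)
        )

    def encoded(self, ids: Sequence[str] | None = None) -> np.ndarray:
        """Integer-coded matrix (rows follow ``ids``), missing data as -1."""
        rows = ids if ids is not None else self._ids
        out = np.empty((len(rows), self.n_columns), dtype=np.int8)
        for k, rid in enumerate(rows):
            seq = self.sequence(rid)
            out[k] = [AA_INDEX[ch] for ch in seq]
        return out

    def __repr__(self) -> str:
        return (
            f"Alignment({self.n_sequences} sequences x "
            f"{self.n_columns} columns)"
        )
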