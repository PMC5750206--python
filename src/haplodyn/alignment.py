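"""Pairwise alignment primitives shared across the pipeline.

All identity / divergence / score computations in the package route through
:func:`align_stats`, which wraps edlib's global (Needleman–Wunsch) alignment
and summarises the extended CIGAR into match / mismatch / gap column counts.

Conventions
-----------
* ``identity``   = matches / total alignment columns (gap columns included) —
  the quantity used for anchor-pair filtering.
* ``p_distance`` = mismatches / (matches + mismatches) — gap columns excluded,
  the observed divergence used for LTR dating.
* ``score``      = match +1, mismatch -1, gap column -2 (linear gap cost) —
  the internal score scale used for solo-LTR candidate filtering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XID])")

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2


@dataclass(frozen=True)
class AlignmentStats:
    """Column counts of one global pairwise alignment."""

    matches: int
    mismatches: int
    gap_columns: int

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gap_columns

    @property
    def identity(self) -> float:
        """Identical columns over all alignment columns (gaps count against)."""
        if self.columns == 0:
            return 0.0
        return self.matches / self.columns

    @property
    def p_distance(self) -> float:
        """Mismatched fraction of aligned (non-gap) columns."""
        aligned = self.matches + self.mismatches
        if aligned == 0:
            return 0.0
        return self.mismatches / aligned

    @property
    def score(self) -> int:
        return (
            MATCH_SCORE * self.matches
            + MISMATCH_SCORE * self.mismatches
            + GAP_SCORE * self.gap_columns
        )


def _as_str(seq: str | bytes) -> str:
    if isinstance(seq, (bytes, bytearray)):
        return seq.decode("ascii")
    return seq


def align_stats(a: str | bytes, b: str | bytes, mode: str = "NW") -> AlignmentStats:
    """Globally align two sequences and tally alignment columns.

    Parameters
    ----------
    a, b:
        Nucleotide sequences (``str`` or ASCII ``bytes``).
    mode:
        edlib mode: ``"NW"`` global (default), ``"HW"`` infix (a within b).

    Raises
    ------
    ValueError
        If either sequence is empty.
    """
    a, b = _as_str(a), _as_str(b)
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    res = edlib.align(a, b, mode=mode, task="path")
    matches = mismatches = gaps = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        if op == "=":
            matches += n
        elif op == "X":
            mismatches += n
        else:  # I or D
            gaps += n
    return AlignmentStats(matches, mismatches, gaps)


def identity(a: str | bytes, b: str | bytes) -> float:
    """Global alignment identity of two sequences (gap columns penalised)."""
    return align_stats(a, b).identity


def kmer_positions(seq: str | bytes, k: int) -> dict[bytes, list[int]]:
    """Map every k-mer of ``seq`` to its (0-based) start positions."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    seq = bytes(seq)
    out: dict[bytes, list[int]] = {}
    for i in range(len(seq) - k + 1):
        out.setdefault(seq[i : i + k], []).append(i)
    return out


def unique_kmer_positions(seq: str | bytes, k: int) -> dict[bytes, int]:
    """Map each k-mer occurring exactly once in ``seq`` to its start position."""
    out: dict[bytes, int] = {}
    dup: set[bytes] = set()
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    seq = bytes(seq)
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in out:
            del out[km]
            dup.add(km)
        else:
            out[km] = i
    return out
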