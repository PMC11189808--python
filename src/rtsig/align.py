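"""Global pairwise alignment of amplicon reads and minimal SAM I/O.

Needleman-Wunsch with linear gap penalties (match +1, mismatch -1, gap -2 by
default).  Two end-gap policies are provided:

* strict global — both sequences fully aligned end to end;
* semi-global (free reference end gaps) — the read must be consumed in full
  but may cover only a contiguous stretch of the reference.  This is the
  production policy for amplicon reads, because RT-arrested molecules yield
  truncated reads covering a reference suffix and must not be charged a giant
  leading deletion.

Among co-optimal traces, deletions are left-aligned (placed at the smallest
reference coordinate), matching standard variant-normalisation convention, so
an RT jump is attributed to a deterministic position.  Traceback ties break
M over D over I.

The DP kernel is JIT-compiled with numba; at ~200 nt amplicons this sustains
tens of thousands of reads per second, enough to align depth-10,000 cohorts
in seconds.  SAM reading/writing goes through pysam.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from numba import njit

__all__ = [
    "Scoring",
    "AlignedRead",
    "AlignmentError",
    "SamFormatError",
    "global_align",
    "align_reads",
    "write_sam",
    "read_sam",
    "cigar_to_string",
    "parse_cigar_string",
]


class AlignmentError(ValueError):
    """Invalid alignment input (empty sequence, bad alphabet)."""


class SamFormatError(ValueError):
    """A SAM record could not be parsed or is internally inconsistent."""


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap: int = -2


# CIGAR op encoding shared with the numba kernel.
_OP_M, _OP_D, _OP_I, _OP_S = 0, 1, 2, 3
_OP_CHARS = "MDIS"
_READ_OPS = {"M", "I", "S"}
_REF_OPS = {"M", "D"}

# ASCII byte -> nucleotide code; codes >= 4 (N and anything else) never match.
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
    _CODE_LUT[_b + 32] = _i  # tolerate lowercase


def _encode(seq: str) -> np.ndarray:
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class AlignedRead:
    """A read aligned to a single reference, 1-based ``ref_start``.

    ``cigar`` is an ordered list of ``(length, op)`` with op in {M, D, I, S}:
    M aligns read to reference (match or mismatch), D consumes reference only,
    I consumes read only, S soft-clips read bases.  Invariants: M+I+S ops sum
    to the read length, no two adjacent ops share a kind.
    """

    read_id: str
    ref_start: int
    cigar: list[tuple[int, str]]
    seq: str
    mapped: bool = True
    score: int | None = None

    def __post_init__(self) -> None:
        if not self.mapped:
            return
        read_len = sum(n for n, op in self.cigar if op in _READ_OPS)
        if read_len != len(self.seq):
            raise ValueError(
                f"{self.read_id}: CIGAR consumes {read_len} read bases, "
                f"sequence has {len(self.seq)}"
            )
        for (_, a), (_, b) in zip(self.cigar, self.cigar[1:]):
            if a == b:
                raise ValueError(f"{self.read_id}: adjacent CIGAR ops {a!r}")
        if self.ref_start < 1:
            raise ValueError(f"{self.read_id}: ref_start must be >= 1")

    @property
    def ref_span(self) -> int:
        """Number of reference bases consumed (M + D)."""
        return sum(n for n, op in self.cigar if op in _REF_OPS)

    @property
    def ref_end(self) -> int:
        """Last reference position covered (1-based, inclusive)."""
        return self.ref_start + self.ref_span - 1

    @property
    def cigar_string(self) -> str:
        return cigar_to_string(self.cigar)


def cigar_to_string(cigar: Sequence[tuple[int, str]]) -> str:
    return "".join(f"{n}{op}" for n, op in cigar)


def parse_cigar_string(s: str) -> list[tuple[int, str]]:
    out: list[tuple[int, str]] = []
    num = ""
    for ch in s:
        if ch.isdigit():
            num += ch
        elif ch in "MDIS" and num:
            out.append((int(num), ch))
            num = ""
        else:
            raise SamFormatError(f"malformed CIGAR {s!r}")
    if num:
        raise SamFormatError(f"malformed CIGAR {s!r}")
    return out


@njit(cache=True)
def _nw_kernel(read, ref, match, mismatch, gap, free_ref_ends):  # pragma: no cover
    m = read.shape[0]
    n = ref.shape[0]
    score = np.empty((m + 1, n + 1), dtype=np.int32)
    score[0, 0] = 0
    for j in range(1, n + 1):
        score[0, j] = 0 if free_ref_ends else j * gap
    for i in range(1, m + 1):
        score[i, 0] = i * gap
    for i in range(1, m + 1):
        ri = read[i - 1]
        for j in range(1, n + 1):
            sub = match if (ri == ref[j - 1] and ri < 4) else mismatch
            best = score[i - 1, j - 1] + sub
            d = score[i, j - 1] + gap
            if d > best:
                best = d
            ins = score[i - 1, j] + gap
            if ins > best:
                best = ins
            score[i, j] = best

    # End column: global pins at n; free-end mode takes the leftmost maximum
    # of the last row (ties broken to the smallest reference coordinate).
    j_end = n
    if free_ref_ends:
        best_end = score[m, 0]
        j_end = 0
        for j in range(1, n + 1):
            if score[m, j] > best_end:
                best_end = score[m, j]
                j_end = j

    # Traceback, tie order M > D > I; this left-aligns gaps among co-optimal
    # traces because preferring the diagonal defers gap placement to the
    # smallest coordinates.
    ops = np.empty(m + n, dtype=np.uint8)
    k = m + n
    i = m
    j = j_end
    while i > 0 or j > 0:
        if free_ref_ends and i == 0:
            break  # reference prefix [1..j] left uncovered at no cost
        took_m = False
        if i > 0 and j > 0:
            ri = read[i - 1]
            sub = match if (ri == ref[j - 1] and ri < 4) else mismatch
            if score[i, j] == score[i - 1, j - 1] + sub:
                k -= 1
                ops[k] = 0  # M
                i -= 1
                j -= 1
                took_m = True
        if took_m:
            continue
        if j > 0 and score[i, j] == score[i, j - 1] + gap:
            k -= 1
            ops[k] = 1  # D
            j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            k -= 1
            ops[k] = 2  # I
            i -= 1
        else:  # unreachable for a consistent matrix
            break
    ref_start = j + 1  # in free-end mode the untraced prefix [1..j] is unaligned
    final = score[m, j_end]
    return final, ops[k:], ref_start


def _compress_ops(ops: np.ndarray) -> list[tuple[int, str]]:
    cigar: list[tuple[int, str]] = []
    for code in ops:
        ch = _OP_CHARS[code]
        if cigar and cigar[-1][1] == ch:
            cigar[-1] = (cigar[-1][0] + 1, ch)
        else:
            cigar.append((1, ch))
    return cigar


def global_align(
    read: str,
    ref: str,
    scoring: Scoring = Scoring(),
    *,
    free_ref_end_gaps: bool = False,
    read_id: str = "read",
) -> AlignedRead:
    """Align ``read`` against ``ref`` and return the optimal trace.

    With ``free_ref_end_gaps=False`` this is strict Needleman-Wunsch global
    alignment (``ref_start`` is always 1).  With ``free_ref_end_gaps=True``
    leading/trailing reference bases may be left uncovered at no cost, which
    is how truncated (RT-arrested) reads are aligned to the reference suffix
    they actually cover.
    """
    if not read or not ref:
        raise AlignmentError("empty sequence")
    score, ops, ref_start = _nw_kernel(
        _encode(read), _encode(ref),
        np.int32(scoring.match), np.int32(scoring.mismatch),
        np.int32(scoring.gap), free_ref_end_gaps,
    )
    if not free_ref_end_gaps:
        ref_start = 1
    return AlignedRead(
        read_id=read_id,
        ref_start=int(ref_start),
        cigar=_compress_ops(ops),
        seq=read,
        score=int(score),
    )


def align_reads(
    reads: Iterable[tuple[str, str]],
    ref: str,
    scoring: Scoring = Scoring(),
    *,
    free_ref_end_gaps: bool = True,
) -> Iterator[AlignedRead]:
    """Align ``(read_id, sequence)`` pairs against one reference.

    Defaults to free reference end gaps — the right policy for amplicon
    pipelines where arrest-truncated reads cover only a suffix.
    """
    for read_id, seq in reads:
        yield global_align(
            seq, ref, scoring,
            free_ref_end_gaps=free_ref_end_gaps, read_id=read_id,
        )


# --- SAM subset via pysam ---------------------------------------------------

_PYSAM_OP = {"M": 0, "I": 1, "D": 2, "S": 4}
_PYSAM_OP_INV = {0: "M", 1: "I", 2: "D", 4: "S"}


def write_sam(
    reads: Iterable[AlignedRead],
    ref: str,
    path: str | os.PathLike,
    *,
    ref_name: str = "amplicon",
) -> None:
    """Write reads as plain-text SAM with an @HD/@SQ header."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref_name, "LN": len(ref)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.read_id
            seg.query_sequence = r.seq
            seg.flag = 0 if r.mapped else 4
            seg.reference_id = 0 if r.mapped else -1
            seg.reference_start = r.ref_start - 1
            seg.mapping_quality = 255
            seg.cigartuples = [(_PYSAM_OP[op], n) for n, op in r.cigar]
            out.write(seg)


def read_sam(path: str | os.PathLike) -> list[AlignedRead]:
    """Read a SAM file back into :class:`AlignedRead` records.

    Unsorted input is accepted (the pileup stage does its own indexing) and
    unknown optional tags are ignored.  Malformed records raise
    :class:`SamFormatError` naming the offending record.
    """
    import pysam

    out: list[AlignedRead] = []
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for i, seg in enumerate(fh, start=1):
                if seg.is_unmapped:
                    out.append(AlignedRead(
                        read_id=seg.query_name or f"record{i}",
                        ref_start=1,
                        cigar=[],
                        seq=seg.query_sequence or "",
                        mapped=False,
                    ))
                    continue
                try:
                    cigar = [
                        (n, _PYSAM_OP_INV[op]) for op, n in (seg.cigartuples or [])
                    ]
                    out.append(AlignedRead(
                        read_id=seg.query_name,
                        ref_start=seg.reference_start + 1,
                        cigar=cigar,
                        seq=seg.query_sequence or "",
                    ))
                except (KeyError, ValueError) as exc:
                    raise SamFormatError(
                        f"{path}: record {i} ({seg.query_name!r}): {exc}"
                    ) from exc
    except OSError as exc:
        raise SamFormatError(f"{path}: {exc}") from exc
    return out
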