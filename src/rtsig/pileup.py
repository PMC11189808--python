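"""Per-site pileup counting and RT-signature statistics.

The readout of the assay is a single-site summary: the fraction of base calls
at the modified position that mismatch the reference (decomposed by observed
base), and the jump rate — the fraction of site-spanning reads whose
alignment carries a deletion at the position, attributed to RT skipping the
methylated base.  The two rates deliberately use different denominators:
mismatch rates are fractions of base calls, the jump rate is a fraction of
spanning reads (base calls + deletions).  RT-arrest truncations are counted
(``term_count``) but no arrest-rate statistic is produced.

SNP-carrier genotyping works on the same pileup machinery: the alternate
allele fraction at the variant position is thresholded into
carrier / non-carrier / indeterminate.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable

from .align import AlignedRead
from .refmodel import SnpRule

__all__ = [
    "SitePileup",
    "SiteSignature",
    "SnpStatus",
    "LowCoverageError",
    "pileup_site",
    "signature_from_pileup",
    "detect_snp_carrier",
    "DEFAULT_MIN_DEPTH",
    "DEFAULT_VAF_THRESHOLD",
]

logger = logging.getLogger(__name__)

# Below ~100 spanning reads, binomial noise swamps sub-percent signatures.
DEFAULT_MIN_DEPTH = 100
DEFAULT_VAF_THRESHOLD = 0.8

_BASES = ("A", "C", "G", "T")


class LowCoverageError(ValueError):
    """Too few spanning reads to quantify the site."""

    def __init__(self, msg: str, depth: int):
        super().__init__(msg)
        self.depth = depth


@dataclass
class SitePileup:
    """Counts of what aligned reads do at one reference position.

    Each read contributes at most one of: a base call (an M op covers the
    position), a deletion (a D op covers it), or nothing.  Reads that do not
    span the position but whose alignment abuts it (truncated right at the
    site, as RT arrest produces) are tallied in ``term_count``.
    """

    pos: int
    ref_base: str
    base_counts: dict[str, int] = field(
        default_factory=lambda: dict.fromkeys(_BASES, 0)
    )
    del_count: int = 0
    term_count: int = 0

    @property
    def base_total(self) -> int:
        return sum(self.base_counts.values())

    @property
    def span_count(self) -> int:
        """Reads spanning the position: base calls + deletions."""
        return self.base_total + self.del_count


@dataclass(frozen=True)
class SiteSignature:
    """The per-sample readout: mismatch split by base, jump rate, depth."""

    mismatch_rate: float
    mismatch_by_base: dict[str, float]
    jump_rate: float
    depth: int

    def __post_init__(self) -> None:
        if abs(self.mismatch_rate - sum(self.mismatch_by_base.values())) > 1e-12:
            raise ValueError("mismatch_rate must equal the sum of its decomposition")
        rates = [self.mismatch_rate, self.jump_rate, *self.mismatch_by_base.values()]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("rates must lie in [0, 1]")

    def metric(self, name: str) -> float:
        """Look up a statistic by column name (mismatch_rate, jump_rate, mm_X)."""
        if name in ("mismatch_rate", "jump_rate"):
            return getattr(self, name)
        if name.startswith("mm_") and name[3:] in self.mismatch_by_base:
            return self.mismatch_by_base[name[3:]]
        raise KeyError(f"unknown metric {name!r}")


class SnpStatus(str, enum.Enum):
    CARRIER = "carrier"
    NON_CARRIER = "non_carrier"
    INDETERMINATE = "indeterminate"


def pileup_site(
    reads: Iterable[AlignedRead], pos: int, ref: str
) -> SitePileup:
    """Pile up one position (1-based, in the alignment reference frame).

    Soft-clipped bases and N calls never contribute to ``base_counts``;
    insertions consume read bases without touching reference coordinates.
    """
    if not 1 <= pos <= len(ref):
        raise ValueError(f"position {pos} outside reference (length {len(ref)})")
    p = SitePileup(pos=pos, ref_base=ref[pos - 1])
    for read in reads:
        if not read.mapped:
            continue
        rpos = read.ref_start  # next reference position to consume
        qpos = 0               # next read index to consume
        spanned = False
        for length, op in read.cigar:
            if op == "M":
                if rpos <= pos < rpos + length:
                    base = read.seq[qpos + (pos - rpos)]
                    if base in p.base_counts:
                        p.base_counts[base] += 1
                    spanned = True
                    break
                rpos += length
                qpos += length
            elif op == "D":
                if rpos <= pos < rpos + length:
                    p.del_count += 1
                    spanned = True
                    break
                rpos += length
            else:  # I, S consume read only
                qpos += length
        if not spanned:
            # alignment abuts the site: starts just after it (RT ran 3'->5'
            # and terminated there) or ends just before it
            if read.ref_start == pos + 1 or rpos == pos:
                p.term_count += 1
    return p


def signature_from_pileup(
    p: SitePileup, min_depth: int = DEFAULT_MIN_DEPTH
) -> SiteSignature:
    """Convert raw counts into rates.

    mismatch_rate = non-reference base calls / all base calls;
    jump_rate = deletions / spanning reads.  A pileup whose spanning depth is
    below ``min_depth`` raises :class:`LowCoverageError` carrying the depth.
    """
    if p.span_count < min_depth:
        raise LowCoverageError(
            f"depth {p.span_count} at position {p.pos} below min_depth {min_depth}",
            depth=p.span_count,
        )
    bt = p.base_total
    by_base = {
        b: (p.base_counts[b] / bt if bt else 0.0)
        for b in _BASES if b != p.ref_base
    }
    return SiteSignature(
        mismatch_rate=sum(by_base.values()),
        mismatch_by_base=by_base,
        jump_rate=p.del_count / p.span_count,
        depth=p.span_count,
    )


def detect_snp_carrier(
    reads: Iterable[AlignedRead],
    ref: str,
    snp: SnpRule,
    *,
    snp_pos: int | None = None,
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> SnpStatus:
    """Genotype a sample at a variant position from its pileup.

    ``snp_pos`` is the variant's 1-based position in the alignment reference
    frame (defaults to ``snp.genome_pos``, appropriate when reads are aligned
    in genome coordinates).  Carrier if the alternate-allele fraction is
    >= ``vaf_threshold``, non-carrier if <= 1 - ``vaf_threshold``; anything in
    between — heteroplasmy, contamination — is indeterminate and should be
    excluded.  Low depth also yields indeterminate (with a warning) rather
    than a hard error, since genotyping feeds sample exclusion.
    """
    if not 0.5 < vaf_threshold <= 1.0:
        raise ValueError("vaf_threshold must lie in (0.5, 1]")
    pos = snp.genome_pos if snp_pos is None else snp_pos
    p = pileup_site(reads, pos, ref)
    if p.base_total < min_depth:
        logger.warning(
            "SNP site %d: depth %d below min_depth %d -> indeterminate",
            pos, p.base_total, min_depth,
        )
        return SnpStatus.INDETERMINATE
    vaf = p.base_counts.get(snp.alt_allele, 0) / p.base_total
    if vaf >= vaf_threshold:
        return SnpStatus.CARRIER
    if vaf <= 1.0 - vaf_threshold:
        return SnpStatus.NON_CARRIER
    logger.warning(
        "SNP site %d: ambiguous alt fraction %.3f -> indeterminate", pos, vaf
    )
    return SnpStatus.INDETERMINATE
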