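"""Coordinate frame and reverse-transcription complement logic.

Mitochondrial genes are single-exon, so the transcript <-> genome mapping is
pure offset arithmetic. All coordinates in this package are 1-based inclusive,
matching how positions are conventionally printed for the human mitochondrial
genome (rCRS): the N1-methyladenosine in the ND5 message sits at transcript
position 1374, i.e. mtDNA position 13710, the wobble (third) position of an
alanine codon GCA.

The reference sequence is always stored and reported mRNA-sense.  Reverse
transcription reads the template 3'->5', incorporating cDNA bases; an
incorporated base b shows up in the sense-frame pileup as the Watson-Crick
complement of b.  That is why misincorporation of A and C opposite m1A is
observed as sense-strand T and G mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CoordinateError",
    "FrameError",
    "GeneAnnotation",
    "TargetSite",
    "SnpRule",
    "ND5",
    "ND5_M1A_SITE",
    "G13708A",
    "map_transcript_to_genome",
    "map_genome_to_transcript",
    "codon_of",
    "incorporation_to_sense_mismatch",
    "complement",
]

NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

STRAND_FORWARD = "sense_equals_genome_forward"
STRAND_REVERSE = "sense_equals_genome_reverse"


class CoordinateError(ValueError):
    """A position falls outside the gene (or reference) bounds."""


class FrameError(ValueError):
    """A transcript position lies outside the CDS reading frame."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A single-exon gene anchored on the genome, 1-based inclusive.

    Parameters
    ----------
    gene_name : str
        Display name, e.g. ``"MT-ND5"``.
    genome_start, genome_end : int
        First and last genomic base of the transcript (inclusive).
    strand : str
        ``"sense_equals_genome_forward"`` if transcript position 1 is
        ``genome_start`` (heavy-strand mitochondrial genes), or
        ``"sense_equals_genome_reverse"`` if it is ``genome_end``.
    cds_offset : int
        Transcript position of the first CDS base (1 when the transcript
        starts at the start codon, as for mitochondrial ORFs).
    """

    gene_name: str
    genome_start: int
    genome_end: int
    strand: str = STRAND_FORWARD
    cds_offset: int = 1

    def __post_init__(self) -> None:
        if self.genome_start > self.genome_end:
            raise ValueError(
                f"genome_start {self.genome_start} > genome_end {self.genome_end}"
            )
        if self.strand not in (STRAND_FORWARD, STRAND_REVERSE):
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.cds_offset < 1:
            raise ValueError(f"cds_offset must be >= 1, got {self.cds_offset}")

    @property
    def length(self) -> int:
        return self.genome_end - self.genome_start + 1

    @classmethod
    def from_config(cls, cfg: dict) -> "GeneAnnotation":
        """Build from a minimal config block (YAML/JSON dict).

        Expected keys: ``name``, ``start``, ``end`` (1-based inclusive),
        optional ``strand`` (default forward) and ``cds_offset`` (default 1).
        """
        return cls(
            gene_name=str(cfg["name"]),
            genome_start=int(cfg["start"]),
            genome_end=int(cfg["end"]),
            strand=cfg.get("strand", STRAND_FORWARD),
            cds_offset=int(cfg.get("cds_offset", 1)),
        )

    @classmethod
    def from_bed_interval(
        cls, name: str, chrom_start: int, chrom_end: int, strand: str = "+",
        cds_offset: int = 1,
    ) -> "GeneAnnotation":
        """Convert a BED interval (0-based, half-open) to 1-based inclusive."""
        return cls(
            gene_name=name,
            genome_start=chrom_start + 1,
            genome_end=chrom_end,
            strand=STRAND_FORWARD if strand == "+" else STRAND_REVERSE,
            cds_offset=cds_offset,
        )


def map_transcript_to_genome(t: int, ann: GeneAnnotation) -> int:
    """Map a 1-based transcript position to its genomic coordinate."""
    if not 1 <= t <= ann.length:
        raise CoordinateError(
            f"transcript position {t} outside {ann.gene_name} (length {ann.length})"
        )
    if ann.strand == STRAND_FORWARD:
        return ann.genome_start + t - 1
    return ann.genome_end - t + 1


def map_genome_to_transcript(g: int, ann: GeneAnnotation) -> int:
    """Inverse of :func:`map_transcript_to_genome`."""
    if not ann.genome_start <= g <= ann.genome_end:
        raise CoordinateError(
            f"genome position {g} outside {ann.gene_name} "
            f"[{ann.genome_start}, {ann.genome_end}]"
        )
    if ann.strand == STRAND_FORWARD:
        return g - ann.genome_start + 1
    return ann.genome_end - g + 1


def codon_of(t: int, ann: GeneAnnotation, sense_seq: str) -> tuple[int, int, str]:
    """Codon index, position-in-codon and codon string for transcript pos ``t``.

    ``codon_pos == 3`` identifies the wobble position.  ``sense_seq`` is the
    mRNA-sense transcript sequence (or any sequence long enough to cover the
    codon, indexed in transcript coordinates).
    """
    if t < ann.cds_offset:
        raise FrameError(
            f"transcript position {t} precedes CDS start {ann.cds_offset}"
        )
    if t > ann.length:
        raise CoordinateError(
            f"transcript position {t} outside {ann.gene_name} (length {ann.length})"
        )
    off = t - ann.cds_offset
    codon_index = off // 3 + 1
    codon_pos = off % 3 + 1
    codon_start = t - (codon_pos - 1)  # transcript pos of codon base 1
    if len(sense_seq) < codon_start + 2:
        raise FrameError(
            f"sense sequence (length {len(sense_seq)}) too short for codon at "
            f"transcript positions {codon_start}..{codon_start + 2}"
        )
    codon_sense = sense_seq[codon_start - 1 : codon_start + 2]
    return codon_index, codon_pos, codon_sense


def complement(base: str) -> str:
    """Watson-Crick complement of a single nucleotide."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"not a nucleotide: {base!r}") from None


def incorporation_to_sense_mismatch(incorporated_base: str) -> str:
    """Sense-strand base observed when RT incorporates ``incorporated_base``.

    An incorporated cDNA base reads back, after second-strand synthesis and
    sequencing, as its complement on the mRNA-sense frame: incorporation of A
    opposite m1A is seen as a sense T mismatch, incorporation of C as a sense
    G.  Correct incorporation (T opposite A) reads back as the reference A.
    The map is an involution.
    """
    return complement(incorporated_base)


@dataclass(frozen=True)
class TargetSite:
    """A modified position tied to both coordinate frames and its codon."""

    transcript_pos: int
    genome_pos: int
    ref_base_sense: str
    codon_index: int
    codon_pos: int
    codon_sense: str

    def __post_init__(self) -> None:
        if self.ref_base_sense not in NUCLEOTIDES:
            raise ValueError(f"ref_base_sense must be A/C/G/T, got {self.ref_base_sense!r}")
        if self.codon_pos not in (1, 2, 3):
            raise ValueError(f"codon_pos must be 1..3, got {self.codon_pos}")
        if self.codon_sense[self.codon_pos - 1] != self.ref_base_sense:
            raise ValueError(
                f"codon {self.codon_sense!r} position {self.codon_pos} "
                f"disagrees with ref base {self.ref_base_sense!r}"
            )

    @classmethod
    def from_annotation(
        cls, t: int, ann: GeneAnnotation, sense_seq: str
    ) -> "TargetSite":
        idx, pos, codon = codon_of(t, ann, sense_seq)
        return cls(
            transcript_pos=t,
            genome_pos=map_transcript_to_genome(t, ann),
            ref_base_sense=sense_seq[t - 1],
            codon_index=idx,
            codon_pos=pos,
            codon_sense=codon,
        )


@dataclass(frozen=True)
class SnpRule:
    """A genomic variant with a known effect on the modification."""

    genome_pos: int
    ref_allele: str
    alt_allele: str
    effect: str = "abolishes_methylation"

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for a in (self.ref_allele, self.alt_allele):
            if a not in NUCLEOTIDES:
                raise ValueError(f"allele must be A/C/G/T, got {a!r}")


# Packaged defaults: MT-ND5 on the heavy strand of the rCRS.  Only the start
# coordinate matters for the transcript<->genome arithmetic; it is implied by
# the printed pair (transcript 1374 == mtDNA 13710).  Override via
# GeneAnnotation.from_config for other references.
ND5 = GeneAnnotation(
    gene_name="MT-ND5", genome_start=12337, genome_end=14148,
    strand=STRAND_FORWARD, cds_offset=1,
)

# The m1A site: wobble position of codon GCA (transcript 1372-1374).
ND5_M1A_SITE = TargetSite(
    transcript_pos=1374,
    genome_pos=13710,
    ref_base_sense="A",
    codon_index=458,
    codon_pos=3,
    codon_sense="GCA",
)

# Eurasian J-haplogroup variant two bases upstream of the m1A genomic
# position; carriers show no methylation signal at the target site.
G13708A = SnpRule(genome_pos=13708, ref_allele="G", alt_allele="A")
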