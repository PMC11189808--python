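"""End-to-end glue: reads -> alignment -> pileup -> signature table -> stats.

Thin orchestration over the library modules; everything here is also
reachable piecemeal.  The per-sample signature table uses the documented
columns: sample_id, depth, mismatch_rate, mm_T, mm_G, mm_C, jump_rate,
snp_status.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import simulate as sim
from .align import AlignedRead, Scoring, align_reads
from .pileup import (
    DEFAULT_MIN_DEPTH,
    DEFAULT_VAF_THRESHOLD,
    SiteSignature,
    SnpStatus,
    detect_snp_carrier,
    pileup_site,
    signature_from_pileup,
)
from .simulate import Amplicon, CohortConfig, SignatureParams
from .stats import ComparisonResult, SampleRecord, compare_groups

__all__ = [
    "quantify_reads",
    "quantify_sample",
    "quantify_cohort_dir",
    "records_from_tables",
    "run_cohort",
]

SIGNATURE_COLUMNS = [
    "sample_id", "depth", "mismatch_rate", "mm_T", "mm_G", "mm_C",
    "jump_rate", "snp_status",
]


def quantify_reads(
    aligned: Sequence[AlignedRead],
    amplicon: Amplicon,
    *,
    min_depth: int = DEFAULT_MIN_DEPTH,
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
) -> tuple[SiteSignature, SnpStatus]:
    """Signature at the modified site + SNP genotype, from aligned reads."""
    pile = pileup_site(aligned, amplicon.site_local, amplicon.seq)
    signature = signature_from_pileup(pile, min_depth=min_depth)
    snp_status = detect_snp_carrier(
        aligned, amplicon.seq, amplicon.snp,
        snp_pos=amplicon.snp_local,
        vaf_threshold=vaf_threshold, min_depth=min_depth,
    )
    return signature, snp_status


def quantify_sample(
    reads: Iterable[tuple[str, str]],
    amplicon: Amplicon,
    *,
    scoring: Scoring = Scoring(),
    min_depth: int = DEFAULT_MIN_DEPTH,
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
) -> tuple[SiteSignature, SnpStatus]:
    """Align raw reads (free reference end gaps) and quantify the sample."""
    aligned = list(align_reads(reads, amplicon.seq, scoring))
    return quantify_reads(
        aligned, amplicon, min_depth=min_depth, vaf_threshold=vaf_threshold
    )


def _signature_row(sample_id: str, signature: SiteSignature, snp_status: SnpStatus) -> dict:
    return {
        "sample_id": sample_id,
        "depth": signature.depth,
        "mismatch_rate": signature.mismatch_rate,
        "mm_T": signature.mismatch_by_base.get("T", 0.0),
        "mm_G": signature.mismatch_by_base.get("G", 0.0),
        "mm_C": signature.mismatch_by_base.get("C", 0.0),
        "jump_rate": signature.jump_rate,
        "snp_status": snp_status.value,
    }


def quantify_cohort_dir(
    cohort_dir: str | os.PathLike,
    amplicon: Amplicon,
    *,
    min_depth: int = DEFAULT_MIN_DEPTH,
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
) -> pd.DataFrame:
    """Quantify every ``<sample_id>.fastq`` named in the cohort metadata."""
    cohort_dir = Path(cohort_dir)
    metadata = pd.read_csv(cohort_dir / "metadata.tsv", sep="\t")
    rows = []
    for sample_id in metadata["sample_id"]:
        reads = sim.read_fastq(cohort_dir / f"{sample_id}.fastq")
        signature, snp_status = quantify_sample(
            reads, amplicon, min_depth=min_depth, vaf_threshold=vaf_threshold
        )
        rows.append(_signature_row(sample_id, signature, snp_status))
    return pd.DataFrame(rows, columns=SIGNATURE_COLUMNS)


def records_from_tables(
    signatures: pd.DataFrame, metadata: pd.DataFrame
) -> list[SampleRecord]:
    """Join the signature and metadata tables into stats-ready records."""
    merged = signatures.merge(metadata, on="sample_id", validate="one_to_one")
    records = []
    for row in merged.itertuples(index=False):
        by_base = {"T": row.mm_T, "G": row.mm_G, "C": row.mm_C}
        records.append(SampleRecord(
            sample_id=row.sample_id,
            group=row.group,
            braak=None if pd.isna(row.braak) else int(row.braak),
            snp_status=SnpStatus(row.snp_status),
            signature=SiteSignature(
                mismatch_rate=sum(by_base.values()),
                mismatch_by_base=by_base,
                jump_rate=row.jump_rate,
                depth=int(row.depth),
            ),
        ))
    return records


def run_cohort(
    config: CohortConfig,
    outdir: str | os.PathLike,
    params: SignatureParams = sim.DEFAULT_PARAMS,
    *,
    metric: str = "mismatch_rate",
    stratify: bool = False,
    min_depth: int = DEFAULT_MIN_DEPTH,
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
) -> tuple[pd.DataFrame, ComparisonResult]:
    """Simulate, align, quantify and compare a full synthetic cohort.

    Writes the cohort under ``outdir`` (FASTQ + tables + signatures.tsv) and
    returns the signature table and the comparison result.
    """
    outdir = Path(outdir)
    amplicon, metadata, _truth = sim.simulate_cohort(config, outdir, params)
    signatures = quantify_cohort_dir(
        outdir, amplicon, min_depth=min_depth, vaf_threshold=vaf_threshold
    )
    signatures.to_csv(outdir / "signatures.tsv", sep="\t", index=False)
    records = records_from_tables(signatures, metadata)
    result = compare_groups(records, metric, stratify=stratify)
    return signatures, result
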