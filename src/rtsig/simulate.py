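"""Synthetic amplicon-sequencing generator for RT-signature experiments.

Emulates the wet-lab readout the pipeline quantifies: targeted RT-PCR of a
short mRNA-sense amplicon containing a methylated adenosine, followed by
sequencing.  Each molecule is independently methylated with per-sample
stoichiometry theta; reverse transcription over a methylated site then draws
one of four outcomes:

* read-through  — correct incorporation (T opposite A), reads back reference;
* misincorporation of A, C or G — observed on the sense frame as the
  complement (T, G or C mismatch);
* jump          — RT skips the base, a single-base deletion in the read;
* arrest        — RT terminates; because cDNA synthesis runs 3'->5' along the
  mRNA, the read covers only positions downstream (3') of the site and never
  calls a base at it.

Unmethylated molecules read through cleanly.  Uniform substitution sequencing
error (no indel errors) is applied to every emitted base.  Samples carrying
the methylation-abolishing SNP get theta forced to 0 and the alternate allele
substituted into every template molecule.

A cohort generator assembles control/case samples with Braak stages and
SNP-carrier flags, writes per-sample FASTQ (Phred+33, constant quality) plus
metadata and truth tables, and is byte-reproducible under a master seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .refmodel import (
    G13708A,
    ND5_M1A_SITE,
    SnpRule,
    TargetSite,
    complement,
)
from .pileup import SitePileup

__all__ = [
    "SignatureParams",
    "SampleSpec",
    "TruthRecord",
    "Amplicon",
    "CohortConfig",
    "DEFAULT_PARAMS",
    "make_reference",
    "simulate_molecule",
    "simulate_sample",
    "simulate_cohort",
    "site_base_distribution",
    "expected_signature",
    "simulate_signature_counts",
]

_EVENTS = ("readthrough", "mis_A", "mis_C", "mis_G", "jump", "arrest")
_BASES = "ACGT"
_BASE_CODES = {b: i for i, b in enumerate(_BASES)}
PHRED_QUALITY_CHAR = "I"  # Q40, carried but never used by the pipeline


@dataclass(frozen=True)
class SignatureParams:
    """RT outcome model at a modified adenosine plus sequencing error.

    ``theta`` is the default methylation stoichiometry (fraction of molecules
    carrying the mark); per-sample specs override it.  Conditional on a
    molecule being modified, the RT outcome is read-through with
    ``p_readthrough``, misincorporation of cDNA base b with ``p_mis[b]``
    (b in {A, C, G}; T is the correct incorporation opposite A), a single-base
    jump with ``p_jump`` or arrest with ``p_arrest``; these must sum to 1.
    ``seq_error`` is the per-base uniform substitution error rate.
    """

    theta: float = 0.0
    p_readthrough: float = 0.80
    p_mis: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.10, "C": 0.06, "G": 0.01}
    )
    p_jump: float = 0.02
    p_arrest: float = 0.01
    seq_error: float = 0.001

    def __post_init__(self) -> None:
        probs = [self.theta, self.p_readthrough, self.p_jump, self.p_arrest,
                 *self.p_mis.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not set(self.p_mis) <= {"A", "C", "G"}:
            raise ValueError(
                "p_mis keys must be within {A, C, G}; T is correct incorporation"
            )
        total = self.p_readthrough + sum(self.p_mis.values()) + self.p_jump + self.p_arrest
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"conditional event probabilities sum to {total}, not 1")
        if not 0.0 <= self.seq_error <= 0.1:
            raise ValueError("seq_error must lie in [0, 0.1]")

    @property
    def p_mis_total(self) -> float:
        return sum(self.p_mis.values())

    def with_(self, **kw) -> "SignatureParams":
        d = asdict(self)
        d.update(kw)
        return SignatureParams(**d)


DEFAULT_PARAMS = SignatureParams()


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    group: str  # "control" | "case"
    braak: int
    snp_carrier: bool
    theta: float
    n_molecules: int
    seed: int

    def __post_init__(self) -> None:
        if self.group not in ("control", "case"):
            raise ValueError(f"group must be control/case, got {self.group!r}")
        if not 0 <= self.braak <= 6:
            raise ValueError(f"braak stage must be 0..6, got {self.braak}")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")

    @property
    def effective_theta(self) -> float:
        """Stoichiometry actually applied: the SNP abolishes methylation."""
        return 0.0 if self.snp_carrier else self.theta


@dataclass
class TruthRecord:
    """Programmed parameters and realized per-molecule event counts."""

    sample_id: str
    theta: float
    snp_carrier: bool
    n_molecules: int
    counts: dict[str, int]  # keys: unmodified + _EVENTS

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_molecules:
            raise ValueError("realized event counts do not sum to n_molecules")


@dataclass(frozen=True)
class Amplicon:
    """A sense-strand amplicon anchored on the genome (1-based inclusive)."""

    seq: str
    genome_start: int
    site: TargetSite
    snp: SnpRule

    @property
    def site_local(self) -> int:
        """1-based position of the modified site within the amplicon."""
        return self.site.genome_pos - self.genome_start + 1

    @property
    def snp_local(self) -> int:
        return self.snp.genome_pos - self.genome_start + 1

    def local_pos(self, genome_pos: int) -> int:
        p = genome_pos - self.genome_start + 1
        if not 1 <= p <= len(self.seq):
            raise ValueError(f"genome position {genome_pos} outside amplicon")
        return p


def make_reference(
    length: int = 200,
    site: TargetSite = ND5_M1A_SITE,
    snp: SnpRule = G13708A,
    seed: int = 0,
) -> Amplicon:
    """Generate a random sense-strand amplicon around the target site.

    The modified adenosine is placed mid-amplicon with its codon context
    (``...GCA``) forced, which simultaneously pins the SNP reference allele G
    two bases upstream.  The sequence contains no homopolymer of length >= 3,
    so a single-base RT jump left-aligns to an unambiguous coordinate.
    """
    if length < 60:
        raise ValueError("amplicon length must be >= 60")
    site_local = length // 2
    if site_local < 21 or length - site_local < 20:
        raise ValueError("site must have >= 20 nt flanks")
    offset = site.genome_pos - snp.genome_pos
    if offset < 1 or site_local - offset < 1:
        raise ValueError("SNP position out of amplicon range")

    rng = np.random.default_rng(seed)
    forced = {  # 0-based index -> base (codon GCA ending at the site)
        site_local - 3: site.codon_sense[0],
        site_local - 2: site.codon_sense[1],
        site_local - 1: site.codon_sense[2],
    }
    if forced.get(site_local - 1 - offset, snp.ref_allele) != snp.ref_allele:
        raise ValueError("SNP reference allele conflicts with codon context")
    forced[site_local - 1 - offset] = snp.ref_allele

    seq: list[str] = []
    for i in range(length):
        if i in forced:
            seq.append(forced[i])
            continue
        choices = list(_BASES)
        # no homopolymer of length 3: forbid extending a run of two
        if i >= 2 and seq[i - 1] == seq[i - 2]:
            choices.remove(seq[i - 1])
        # don't let the base before a forced base create a forced triple
        nxt = forced.get(i + 1)
        if nxt is not None and i >= 1 and seq[i - 1] == nxt and nxt in choices:
            choices.remove(nxt)
        seq.append(choices[rng.integers(len(choices))])
    return Amplicon(
        seq="".join(seq),
        genome_start=site.genome_pos - site_local + 1,
        site=site,
        snp=snp,
    )


def _apply_seq_errors(codes: np.ndarray, seq_error: float, rng) -> None:
    """Uniform substitution to one of the 3 alternative bases, in place."""
    if seq_error <= 0.0:
        return
    hits = np.flatnonzero(rng.random(codes.shape[0]) < seq_error)
    if hits.size:
        # shift by 1..3 mod 4 picks an alternative base uniformly
        codes[hits] = (codes[hits] + rng.integers(1, 4, size=hits.size)) % 4


def simulate_molecule(
    template: str,
    site_local: int,
    params: SignatureParams,
    is_modified: bool,
    rng: np.random.Generator,
    *,
    force_event: str | None = None,
) -> tuple[str, int, str]:
    """Simulate one sequenced molecule; returns ``(read, ref_start, event)``.

    ``template`` is the sense-strand molecule sequence (possibly carrying a
    sample-level SNP allele); ``site_local`` its 1-based modified position.
    ``force_event`` overrides the stochastic RT outcome (testing hook); it is
    ignored for unmodified molecules.
    """
    codes = np.array([_BASE_CODES[b] for b in template], dtype=np.int64)
    s = site_local - 1
    ref_start = 1
    if not is_modified:
        event = "unmodified"
    else:
        if force_event is not None:
            event = force_event
        else:
            p = [params.p_readthrough,
                 params.p_mis.get("A", 0.0),
                 params.p_mis.get("C", 0.0),
                 params.p_mis.get("G", 0.0),
                 params.p_jump, params.p_arrest]
            event = _EVENTS[rng.choice(len(_EVENTS), p=p)]
        if event.startswith("mis_"):
            codes[s] = _BASE_CODES[complement(event[-1])]
        elif event == "jump":
            codes = np.delete(codes, s)
        elif event == "arrest":
            # cDNA synthesis runs 3'->5' on the mRNA and stops at the site:
            # the read covers only positions downstream (3') of it.
            codes = codes[s + 1:]
            ref_start = site_local + 1
        elif event != "readthrough":
            raise ValueError(f"unknown RT event {event!r}")
    _apply_seq_errors(codes, params.seq_error, rng)
    read = "".join(_BASES[c] for c in codes)
    return read, ref_start, event


def simulate_sample(
    spec: SampleSpec,
    amplicon: Amplicon,
    params: SignatureParams,
    fastq_path: str | os.PathLike | None = None,
) -> tuple[list[tuple[str, str]], TruthRecord]:
    """Simulate all molecules of one sample.

    Returns the reads as ``(read_id, sequence)`` pairs and the truth record;
    optionally writes them as Phred+33 FASTQ with constant quality.
    """
    rng = np.random.default_rng(spec.seed)
    template = amplicon.seq
    if spec.snp_carrier:
        i = amplicon.snp_local - 1
        template = template[:i] + amplicon.snp.alt_allele + template[i + 1:]
    theta = spec.effective_theta

    modified = rng.random(spec.n_molecules) < theta
    reads: list[tuple[str, str]] = []
    counts = dict.fromkeys(("unmodified",) + _EVENTS, 0)
    for i in range(spec.n_molecules):
        read, _ref_start, event = simulate_molecule(
            template, amplicon.site_local, params, bool(modified[i]), rng
        )
        counts[event] += 1
        reads.append((f"{spec.sample_id}_{i:06d}", read))
    truth = TruthRecord(
        sample_id=spec.sample_id,
        theta=spec.theta,
        snp_carrier=spec.snp_carrier,
        n_molecules=spec.n_molecules,
        counts=counts,
    )
    if fastq_path is not None:
        write_fastq(reads, fastq_path)
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{PHRED_QUALITY_CHAR * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTQ back as ``(read_id, sequence)`` pairs (quality discarded)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        return [(title.split()[0], seq) for title, seq, _q in FastqGeneralIterator(fh)]


@dataclass(frozen=True)
class CohortConfig:
    """Study design of a synthetic cohort.

    Defaults mirror the target study: 12 controls vs 13 cases with 2
    SNP-carrier cases; Braak stages drawn to match the reported group means
    (controls ~2.5, cases ~4.7).  Stoichiometries are free parameters of the
    generator (no printed values exist); the default effect size is
    theta 0.05 -> 0.15 with between-sample SD 0.02.
    """

    n_control: int = 12
    n_case: int = 13
    n_snp_carriers_case: int = 2
    theta_control: float = 0.05
    theta_case: float = 0.15
    theta_sd: float = 0.02
    n_molecules: int = 10_000
    amplicon_length: int = 200
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_case < 1:
            raise ValueError("need >= 1 sample per group")
        if self.n_snp_carriers_case > self.n_case:
            raise ValueError("more SNP carriers than case samples")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        return cls(**{k: d[k] for k in d})


_CONTROL_BRAAK = (1, 2, 3, 4)                  # uniform: mean 2.5, SD ~1.1
_CASE_BRAAK = ((4, 5, 6), (0.4, 0.5, 0.1))     # mean 4.7, SD ~0.64


def _derive_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def build_sample_specs(config: CohortConfig) -> list[SampleSpec]:
    """Deterministically expand a cohort config into per-sample specs."""
    meta_rng = np.random.default_rng(_derive_seed(config.master_seed, 0))
    specs: list[SampleSpec] = []
    idx = 1
    for group, n, theta0 in (
        ("control", config.n_control, config.theta_control),
        ("case", config.n_case, config.theta_case),
    ):
        for k in range(n):
            if group == "control":
                braak = int(meta_rng.choice(_CONTROL_BRAAK))
            else:
                braak = int(meta_rng.choice(_CASE_BRAAK[0], p=_CASE_BRAAK[1]))
            theta = float(np.clip(
                meta_rng.normal(theta0, config.theta_sd), 0.0, 1.0
            ))
            # carriers are the first samples of the case group (deterministic)
            carrier = group == "case" and k < config.n_snp_carriers_case
            specs.append(SampleSpec(
                sample_id=f"{'ctl' if group == 'control' else 'ad'}{k + 1:02d}",
                group=group,
                braak=braak,
                snp_carrier=carrier,
                theta=theta,
                n_molecules=config.n_molecules,
                seed=_derive_seed(config.master_seed, idx),
            ))
            idx += 1
    _check_unique_ids(specs)
    return specs


def _check_unique_ids(specs: list[SampleSpec]) -> None:
    seen: set[str] = set()
    for s in specs:
        if s.sample_id in seen:
            raise ValueError(f"duplicate sample_id {s.sample_id!r} in cohort")
        seen.add(s.sample_id)


def simulate_cohort(
    config: CohortConfig,
    outdir: str | os.PathLike,
    params: SignatureParams = DEFAULT_PARAMS,
    *,
    specs: list[SampleSpec] | None = None,
) -> tuple[Amplicon, pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort into ``outdir``.

    Writes one FASTQ per sample, ``reference.fa``, ``metadata.tsv``
    (sample_id, group, braak, snp_carrier) and ``truth.tsv``.  Returns the
    amplicon and both tables.  Byte-identical for identical
    ``(config, params)``.  ``specs`` overrides the config-derived sample
    specs (must have unique sample ids).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    amplicon = make_reference(
        length=config.amplicon_length, seed=_derive_seed(config.master_seed, 10_000)
    )
    with open(outdir / "reference.fa", "w") as fh:
        fh.write(f">amplicon genome_start={amplicon.genome_start}\n{amplicon.seq}\n")

    if specs is None:
        specs = build_sample_specs(config)
    else:
        _check_unique_ids(specs)
    meta_rows, truth_rows = [], []
    for spec in specs:
        _reads, truth = simulate_sample(
            spec, amplicon, params, fastq_path=outdir / f"{spec.sample_id}.fastq"
        )
        meta_rows.append({
            "sample_id": spec.sample_id,
            "group": spec.group,
            "braak": spec.braak,
            "snp_carrier": spec.snp_carrier,
        })
        truth_rows.append({
            "sample_id": spec.sample_id,
            "theta": spec.theta,
            "snp_carrier": spec.snp_carrier,
            "n_molecules": spec.n_molecules,
            **{f"n_{k}": v for k, v in truth.counts.items()},
        })
    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return amplicon, metadata, truth


# --- Closed-form site distribution and count-level shortcut ------------------

def site_base_distribution(
    theta: float, params: SignatureParams
) -> dict[str, float]:
    """Exact per-molecule outcome distribution at the modified site.

    Returns probabilities for observed sense-frame bases A/C/G/T (after the
    sequencing-error channel), ``del`` (RT jump) and ``term`` (RT arrest:
    the read does not span the site).  Sums to 1.
    """
    # pre-error emitted base probabilities on the sense frame
    pre = {
        "A": (1.0 - theta) + theta * params.p_readthrough,
        "T": theta * params.p_mis.get("A", 0.0),
        "G": theta * params.p_mis.get("C", 0.0),
        "C": theta * params.p_mis.get("G", 0.0),
    }
    eps = params.seq_error
    obs = {}
    for b in _BASES:
        obs[b] = sum(
            pre[b0] * ((1.0 - eps) if b0 == b else eps / 3.0) for b0 in _BASES
        )
    obs["del"] = theta * params.p_jump
    obs["term"] = theta * params.p_arrest
    return obs


def expected_signature(
    theta: float, params: SignatureParams
) -> dict[str, float]:
    """Closed-form expected signature statistics under the RT-event model.

    ``mismatch_rate`` is the expected non-reference fraction among base calls
    at the site; ``mm_T``/``mm_G``/``mm_C`` its per-base decomposition;
    ``jump_rate`` the expected deletion fraction among spanning reads.
    """
    d = site_base_distribution(theta, params)
    base_total = sum(d[b] for b in _BASES)
    span_total = base_total + d["del"]
    return {
        "mismatch_rate": (base_total - d["A"]) / base_total,
        "mm_T": d["T"] / base_total,
        "mm_G": d["G"] / base_total,
        "mm_C": d["C"] / base_total,
        "jump_rate": d["del"] / span_total,
    }


def simulate_signature_counts(
    theta: float,
    params: SignatureParams,
    n_molecules: int,
    rng: np.random.Generator,
    *,
    ref_base: str = "A",
    pos: int = 1,
) -> SitePileup:
    """Draw site-outcome counts directly at depth ``n_molecules``.

    Samples the per-molecule multinomial from
    :func:`site_base_distribution` — distributionally identical to running
    reads through alignment and pileup when alignment is exact.  Used for
    large calibration studies where emitting reads would be wasteful.
    """
    d = site_base_distribution(theta, params)
    cats = ["A", "C", "G", "T", "del", "term"]
    counts = rng.multinomial(n_molecules, [d[c] for c in cats])
    return SitePileup(
        pos=pos,
        ref_base=ref_base,
        base_counts={b: int(c) for b, c in zip(cats[:4], counts[:4])},
        del_count=int(counts[4]),
        term_count=int(counts[5]),
    )
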