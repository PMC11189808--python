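"""Cohort statistics: Grubbs outlier exclusion, unpaired t-tests and
Braak-stage stratified group comparison.

The comparison pipeline is fixed and logged: (1) drop SNP carriers (the
variant abolishes methylation, so carriers measure nothing), (2) optionally
stratify by Braak stage — controls at stages 0-3 versus cases at stages 5-6,
(3) remove extreme outliers per group with Grubbs' test (at most one removal
per group by default), (4) two-sided unpaired t-test.  "Unpaired t-test" is
interpreted as Student's pooled-variance test; Welch is available behind a
flag.  No multiple-testing correction is applied across metrics.

Grubbs' test: G = max |x_i - mean| / sd (sample SD), compared against the
two-sided critical value  G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2))
where t is the upper alpha/(2n) quantile of Student's t with n-2 df.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .pileup import SiteSignature, SnpStatus

__all__ = [
    "StatsError",
    "EmptyStratumError",
    "SampleRecord",
    "ComparisonResult",
    "grubbs_statistic",
    "grubbs_critical",
    "remove_outliers",
    "unpaired_t",
    "stratify_braak",
    "compare_groups",
]

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    """Statistical procedure not applicable to the given data."""


class EmptyStratumError(StatsError):
    """A stratification left one group empty."""


@dataclass(frozen=True)
class SampleRecord:
    """One sample entering the statistics stage."""

    sample_id: str
    group: str  # "control" | "case"
    braak: int | None
    snp_status: SnpStatus | str
    signature: SiteSignature

    def metric(self, name: str) -> float:
        return self.signature.metric(name)


@dataclass
class ComparisonResult:
    metric: str
    n_control: int
    n_case: int
    mean_control: float
    mean_case: float
    sem_control: float
    sem_case: float
    t: float
    df: float
    p: float
    excluded_snp: list[str]
    excluded_indeterminate: list[str]
    excluded_outliers: list[str]
    excluded_missing_braak: list[str]
    stratification: str

    def to_dict(self) -> dict:
        return asdict(self)


def grubbs_statistic(x: Sequence[float]) -> tuple[float, int]:
    """Maximum studentized deviation from the mean and its index.

    Ties break to the first (lowest-index) extreme point.
    """
    arr = np.asarray(x, dtype=float)
    n = arr.size
    if n < 3:
        raise StatsError(f"Grubbs' test needs n >= 3, got n = {n}")
    sd = arr.std(ddof=1)
    if sd == 0.0:
        raise StatsError("Grubbs' test undefined for zero variance")
    dev = np.abs(arr - arr.mean())
    idx = int(np.argmax(dev))  # argmax returns the first maximum
    return float(dev[idx] / sd), idx


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value."""
    if n < 3:
        raise StatsError(f"Grubbs' test needs n >= 3, got n = {n}")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def remove_outliers(
    x: Sequence[float], alpha: float = 0.05, max_removals: int = 1
) -> tuple[np.ndarray, list[int]]:
    """Iterative Grubbs removal; returns kept values and removed indices.

    Indices refer to the original input.  At most ``max_removals`` points are
    removed (default 1 — only genuinely extreme outliers go); input is
    returned unchanged if nothing exceeds the critical value or the procedure
    is not applicable (n < 3, zero variance).
    """
    arr = np.asarray(x, dtype=float)
    orig_idx = np.arange(arr.size)
    removed: list[int] = []
    for _ in range(max_removals):
        if arr.size < 3:
            break
        try:
            g, i = grubbs_statistic(arr)
        except StatsError:
            break
        if g <= grubbs_critical(arr.size, alpha):
            break
        removed.append(int(orig_idx[i]))
        arr = np.delete(arr, i)
        orig_idx = np.delete(orig_idx, i)
    return arr, removed


def unpaired_t(
    x: Sequence[float], y: Sequence[float], variant: str = "student"
) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; returns ``(t, df, p)``.

    ``variant="student"`` pools variances (df = n1+n2-2);
    ``variant="welch"`` uses the Satterthwaite df.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"variant must be student/welch, got {variant!r}")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise StatsError("each group needs n >= 2")
    if xa.std(ddof=1) == 0.0 and ya.std(ddof=1) == 0.0:
        if xa.mean() == ya.mean():
            # identical constant groups: no evidence of difference
            df = (xa.size + ya.size - 2) if variant == "student" else float("nan")
            return 0.0, float(df), 1.0
        raise StatsError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(xa, ya, equal_var=(variant == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def stratify_braak(
    records: Iterable[SampleRecord],
    control_range: tuple[int, int] = (0, 3),
    case_range: tuple[int, int] = (5, 6),
) -> list[SampleRecord]:
    """Keep controls with Braak stage 0-3 and cases with stage 5-6.

    Records with missing Braak stage are dropped with a warning.  An empty
    stratum raises :class:`EmptyStratumError` naming the stratum.
    """
    kept: list[SampleRecord] = []
    for r in records:
        if r.braak is None:
            logger.warning("sample %s: missing Braak stage, dropped", r.sample_id)
            continue
        lo, hi = control_range if r.group == "control" else case_range
        if lo <= r.braak <= hi:
            kept.append(r)
    for grp, rng in (("control", control_range), ("case", case_range)):
        if not any(r.group == grp for r in kept):
            raise EmptyStratumError(
                f"no {grp} samples with Braak stage in {rng[0]}-{rng[1]}"
            )
    return kept


def compare_groups(
    records: Iterable[SampleRecord],
    metric: str = "mismatch_rate",
    *,
    stratify: bool = False,
    alpha: float = 0.05,
    variant: str = "student",
    max_removals: int = 1,
) -> ComparisonResult:
    """Full group comparison with the fixed exclusion pipeline.

    Order: SNP-carrier / indeterminate exclusion, optional Braak
    stratification, per-group Grubbs removal at level ``alpha``, unpaired
    t-test (two-sided p reported; compare against your own significance
    level).  The result records every exclusion.  Output is invariant to
    input record order (records are sorted by sample_id internally).
    """
    recs = sorted(records, key=lambda r: r.sample_id)

    def status(r: SampleRecord) -> str:
        return r.snp_status.value if isinstance(r.snp_status, SnpStatus) else str(r.snp_status)

    excluded_snp = [r.sample_id for r in recs if status(r) == "carrier"]
    excluded_ind = [r.sample_id for r in recs if status(r) == "indeterminate"]
    recs = [r for r in recs if status(r) == "non_carrier"]
    for sid in excluded_snp:
        logger.info("sample %s excluded: methylation-abolishing SNP carrier", sid)

    excluded_missing: list[str] = []
    strat_label = "none"
    if stratify:
        with_braak = [r for r in recs if r.braak is not None]
        excluded_missing = [r.sample_id for r in recs if r.braak is None]
        recs = stratify_braak(with_braak)
        strat_label = "control Braak 0-3 vs case Braak 5-6"

    groups: dict[str, list[SampleRecord]] = {"control": [], "case": []}
    for r in recs:
        groups[r.group].append(r)

    kept_vals: dict[str, np.ndarray] = {}
    excluded_outliers: list[str] = []
    for grp, grp_recs in groups.items():
        vals = [r.metric(metric) for r in grp_recs]
        kept, removed = remove_outliers(vals, alpha, max_removals)
        kept_vals[grp] = kept
        for i in removed:
            excluded_outliers.append(grp_recs[i].sample_id)
            logger.info(
                "sample %s excluded: Grubbs outlier (%s = %.4g)",
                grp_recs[i].sample_id, metric, vals[i],
            )

    xc, xa = kept_vals["control"], kept_vals["case"]
    if xc.size < 2 or xa.size < 2:
        raise StatsError(
            f"fewer than 2 usable samples per group after exclusions "
            f"(control {xc.size}, case {xa.size})"
        )
    t, df, p = unpaired_t(xc, xa, variant=variant)
    return ComparisonResult(
        metric=metric,
        n_control=int(xc.size),
        n_case=int(xa.size),
        mean_control=float(xc.mean()),
        mean_case=float(xa.mean()),
        sem_control=float(xc.std(ddof=1) / math.sqrt(xc.size)),
        sem_case=float(xa.std(ddof=1) / math.sqrt(xa.size)),
        t=t,
        df=df,
        p=p,
        excluded_snp=excluded_snp,
        excluded_indeterminate=excluded_ind,
        excluded_outliers=excluded_outliers,
        excluded_missing_braak=excluded_missing,
        stratification=strat_label,
    )
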