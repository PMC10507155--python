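"""The signed product statistic: a one-tailed joint test of ancestry and association.

For a variant in an admixed cohort, let ``Z_A`` be the Z score of the
locus-specific-ancestry effect on the phenotype (admixture mapping) and
``Z_G|A`` the Z score of the genotype effect conditional on locus-specific
ancestry (structured association).  Let ``f0`` and ``f2`` be the
effect-allele frequencies in the two homozygous-ancestry strata (coded 0
and 2).  The joint test statistic is

    T = sign(f2 - f0) * Z_A * Z_G|A.

An ancestry effect can only be causally explained by an association effect
whose direction matches the ancestral allele-frequency differential, so
only positive products are evidence for joint ancestry AND association:
the test is one tailed, an intersection-union construction.  Under the
null T follows the product-normal distribution (both Z scores are
conditionally independent standard normals, and the frequency sign is
independent of both), so p = P_prodnorm(X > T).

This module works on per-variant summary statistics; computing the Z
scores and stratum frequencies from individual-level data lives in
:mod:`ujat.assoc`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from . import prodnorm

__all__ = [
    "SummaryRecord",
    "JointResult",
    "joint_statistic",
    "joint_pvalue",
    "run_joint_scan",
    "directional_consistency_filter",
]

GENOME_WIDE_ALPHA = 5e-8
_LN10 = math.log(10.0)


@dataclass
class SummaryRecord:
    """Per-variant summary-statistic inputs to the joint test.

    ``f0``/``f2`` are effect-allele frequencies in the homozygous strata of
    locus-specific ancestry coded 0 and 2.  Either may be ``None`` (or NaN)
    when a stratum is empty; the scan then flags the record degenerate
    instead of guessing the frequency sign, which carries the direction
    information the one-tailed test depends on.
    """

    variant_id: str
    z_ancestry: float
    z_assoc: float
    f0: Optional[float] = None
    f2: Optional[float] = None
    chrom: str = ""
    pos: int = 0
    effect_allele: str = ""
    other_allele: str = ""
    extras: Optional[dict] = None


@dataclass
class JointResult:
    """Outcome of the joint test for one variant.

    ``consistent`` marks a positive statistic: the association effect's
    direction and the ancestral frequency differential can causally explain
    the ancestry effect.  ``degenerate`` marks records with no usable
    frequency differential or a zero/missing Z score; these carry p = 0.5
    (tied frequencies or a zero Z) or NaN (missing inputs), never evidence.
    """

    variant_id: str
    statistic: float
    p_joint: float
    log10_p_joint: float
    consistent: bool
    degenerate: bool
    significant: bool = False


def _check_freq(f: float, name: str) -> float:
    f = float(f)
    if not math.isfinite(f) or not (0.0 <= f <= 1.0):
        raise ValueError(f"{name} must be a frequency in [0, 1], got {f!r}")
    return f


def joint_statistic(z_ancestry: float, z_assoc: float, f0: float, f2: float) -> float:
    """T = sign(f2 - f0) * z_ancestry * z_assoc.

    The sign of an exact frequency tie is defined as 0: equal stratum
    frequencies carry no directional information, so the statistic is 0
    and the p value 0.5 regardless of the Z scores.
    """
    z_ancestry = float(z_ancestry)
    z_assoc = float(z_assoc)
    if not (math.isfinite(z_ancestry) and math.isfinite(z_assoc)):
        raise ValueError("Z scores must be finite")
    f0 = _check_freq(f0, "f0")
    f2 = _check_freq(f2, "f2")
    sign = math.copysign(1.0, f2 - f0) if f2 != f0 else 0.0
    return sign * z_ancestry * z_assoc


def joint_pvalue(statistic: float) -> float:
    """One-tailed p value of the signed product under the product-normal null."""
    statistic = float(statistic)
    if not math.isfinite(statistic):
        raise ValueError(f"statistic must be finite, got {statistic!r}")
    return prodnorm.sf(statistic)


def _missing(value: Optional[float]) -> bool:
    return value is None or not math.isfinite(float(value))


def _evaluate(record: SummaryRecord, alpha: float) -> JointResult:
    if _missing(record.f0) or _missing(record.f2) or \
            _missing(record.z_ancestry) or _missing(record.z_assoc):
        return JointResult(
            variant_id=record.variant_id,
            statistic=math.nan,
            p_joint=math.nan,
            log10_p_joint=math.nan,
            consistent=False,
            degenerate=True,
        )
    stat = joint_statistic(record.z_ancestry, record.z_assoc, record.f0, record.f2)
    p = prodnorm.sf(stat)
    log10p = prodnorm.log_sf(stat) / _LN10
    return JointResult(
        variant_id=record.variant_id,
        statistic=stat,
        p_joint=p,
        log10_p_joint=log10p,
        consistent=stat > 0.0,
        degenerate=(stat == 0.0),
        significant=p < alpha,
    )


def run_joint_scan(
    records: Sequence[SummaryRecord],
    alpha: float = GENOME_WIDE_ALPHA,
) -> List[JointResult]:
    """Apply the joint test to every record, preserving input order.

    Records with missing frequencies or non-finite Z scores are flagged
    degenerate rather than dropped, so output aligns 1:1 with input.
    """
    if len(records) == 0:
        raise ValueError("no summary records supplied")
    alpha = float(alpha)
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    return [_evaluate(r, alpha) for r in records]


def directional_consistency_filter(results: Sequence[JointResult]) -> List[JointResult]:
    """Keep only variants whose statistic is positive (fine-mapping filter).

    A positive signed product means the ancestry that carries more of the
    effect allele is the ancestry associated with the trait shift — the
    only configuration in which the variant can explain the admixture peak.
    """
    return [r for r in results if r.consistent]


def scan_statistics(
    z_ancestry: np.ndarray,
    z_assoc: np.ndarray,
    f0: np.ndarray,
    f2: np.ndarray,
) -> np.ndarray:
    """Vectorized signed product over aligned arrays (NaN passes through)."""
    z_ancestry = np.asarray(z_ancestry, dtype=float)
    z_assoc = np.asarray(z_assoc, dtype=float)
    diff = np.asarray(f2, dtype=float) - np.asarray(f0, dtype=float)
    return np.sign(diff) * z_ancestry * z_assoc
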