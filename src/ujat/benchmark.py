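"""Analytic benchmarking of the joint test against the standard GWAS test.

The joint ancestry-and-association statistic is the product of two Z
scores, so at a fixed joint significance level ``alpha_joint`` the
conditional-association evidence required for discovery depends on how
strong the admixture-mapping (ancestry) signal already is:

    z_required = Q_prod(alpha_joint) / z_ancestry,

where ``Q_prod`` is the one-tailed product-normal quantile.  Because
association Z scores scale with the square root of the sample size at a
fixed effect size, the power gain translates into an equivalent
sample-size fold

    fold = (z_single / z_required)^2,

with ``z_single`` the standard-normal Z at the conventional two-sided
genome-wide level.  All computations here are deterministic, carried out
with unrounded intermediates on the Z scale; nothing is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List

from scipy.stats import norm

from . import prodnorm

__all__ = [
    "BenchmarkPoint",
    "z_from_p_two_sided",
    "p_two_sided_from_z",
    "required_assoc_z",
    "sample_size_fold",
    "breakeven_ancestry_p",
    "benchmark_curve",
]

GENOME_WIDE_ALPHA = 5e-8


def _check_p(p: float, name: str = "p") -> float:
    p = float(p)
    if not (0.0 < p < 1.0) or not math.isfinite(p):
        raise ValueError(f"{name} must lie strictly in (0, 1), got {p!r}")
    return p


def _check_alpha(alpha: float, name: str) -> float:
    alpha = float(alpha)
    if not (0.0 < alpha < 0.5):
        raise ValueError(f"{name} must lie in (0, 0.5), got {alpha!r}")
    return alpha


def z_from_p_two_sided(p: float) -> float:
    """Two-sided p value -> nonnegative standard-normal Z, |Phi^-1(p/2)|."""
    p = _check_p(p)
    return float(norm.isf(p / 2.0))


def p_two_sided_from_z(z: float) -> float:
    """Nonnegative Z -> two-sided p value, 2(1 - Phi(z))."""
    z = float(z)
    if not math.isfinite(z) or z < 0.0:
        raise ValueError(f"z must be finite and nonnegative, got {z!r}")
    return float(2.0 * norm.sf(z))


def required_assoc_z(p_ancestry: float, alpha_joint: float = GENOME_WIDE_ALPHA) -> float:
    """Conditional-association Z needed for joint significance.

    Given an ancestry signal with two-sided p value ``p_ancestry``, the
    joint statistic reaches its critical value once
    z_assoc = quantile(alpha_joint) / z_ancestry.
    """
    p_ancestry = _check_p(p_ancestry, "p_ancestry")
    alpha_joint = _check_alpha(alpha_joint, "alpha_joint")
    z_anc = z_from_p_two_sided(p_ancestry)
    if z_anc <= 0.0:
        raise ValueError(
            "p_ancestry is too close to 1: the ancestry Z is zero and no "
            "finite association evidence can reach joint significance"
        )
    return prodnorm.quantile(alpha_joint) / z_anc


def sample_size_fold(
    p_ancestry: float,
    alpha_joint: float = GENOME_WIDE_ALPHA,
    alpha_assoc: float = GENOME_WIDE_ALPHA,
) -> float:
    """Equivalent sample-size multiple of the standard association test.

    Values above 1 mean the joint test detects association with the power a
    standard test would need a fold-larger cohort to match; below 1 the
    ancestry signal is too weak and the joint test loses power.
    """
    z_single = z_from_p_two_sided(_check_alpha(alpha_assoc, "alpha_assoc"))
    z_req = required_assoc_z(p_ancestry, alpha_joint)
    return (z_single / z_req) ** 2


def breakeven_ancestry_p(
    alpha_joint: float = GENOME_WIDE_ALPHA,
    alpha_assoc: float = GENOME_WIDE_ALPHA,
) -> float:
    """Ancestry p value at which the joint and standard tests tie.

    At this ancestry evidence the association Z required by the joint test
    equals the standard genome-wide Z, so the sample-size fold is exactly 1.
    """
    alpha_joint = _check_alpha(alpha_joint, "alpha_joint")
    alpha_assoc = _check_alpha(alpha_assoc, "alpha_assoc")
    z_anc = prodnorm.quantile(alpha_joint) / z_from_p_two_sided(alpha_assoc)
    return p_two_sided_from_z(z_anc)


@dataclass(frozen=True)
class BenchmarkPoint:
    """One point of the power-translation curve (ancestry p -> fold)."""

    p_ancestry: float
    z_ancestry: float
    z_assoc_required: float
    p_assoc_required: float
    fold: float
    alpha_joint: float = GENOME_WIDE_ALPHA
    alpha_assoc: float = GENOME_WIDE_ALPHA


def benchmark_point(
    p_ancestry: float,
    alpha_joint: float = GENOME_WIDE_ALPHA,
    alpha_assoc: float = GENOME_WIDE_ALPHA,
) -> BenchmarkPoint:
    """Evaluate the full benchmarking chain at one ancestry p value."""
    z_anc = z_from_p_two_sided(_check_p(p_ancestry, "p_ancestry"))
    z_req = required_assoc_z(p_ancestry, alpha_joint)
    return BenchmarkPoint(
        p_ancestry=p_ancestry,
        z_ancestry=z_anc,
        z_assoc_required=z_req,
        p_assoc_required=p_two_sided_from_z(z_req),
        fold=(z_from_p_two_sided(alpha_assoc) / z_req) ** 2,
        alpha_joint=alpha_joint,
        alpha_assoc=alpha_assoc,
    )


def benchmark_curve(
    p_ancestry_grid: Iterable[float],
    alpha_joint: float = GENOME_WIDE_ALPHA,
    alpha_assoc: float = GENOME_WIDE_ALPHA,
) -> List[BenchmarkPoint]:
    """Evaluate :func:`benchmark_point` over a grid of ancestry p values."""
    return [benchmark_point(p, alpha_joint, alpha_assoc) for p in p_ancestry_grid]
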