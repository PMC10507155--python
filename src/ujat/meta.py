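"""Inverse-variance fixed-effect meta-analysis with heterogeneity statistics.

Pools per-stratum (or per-study) effect estimates with weights 1/SE^2 — the
"standard error scheme" familiar from METAL — and reports Cochran's Q, its
chi-square heterogeneity p value, and the I^2 inconsistency percentage,
together with a METAL-style per-stratum direction string.

In the joint ancestry-and-association workflow the strata are the three
locus-specific-ancestry classes of an admixed cohort (and, in cross-study
analyses, additional non-admixed cohorts); the pooled Z is the
ancestry-conditional association Z score fed into the joint test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

from scipy.stats import chi2, norm

__all__ = [
    "StratumEstimate",
    "MetaResult",
    "inverse_variance_meta",
    "cochran_q",
    "i_squared",
    "het_pvalue",
    "direction_string",
]


@dataclass(frozen=True)
class StratumEstimate:
    """Effect estimate from one ancestry stratum or study.

    ``beta`` is on the analysis scale of the trait (for serum lipids,
    typically the natural-log scale); ``se`` must be positive for the
    stratum to be usable.  A missing estimate may be encoded with
    ``beta=nan`` or a nonpositive/NaN ``se``; such strata are excluded
    from pooling and shown as '?' in the direction string.
    """

    label: str
    beta: float
    se: float
    n: Optional[int] = None

    @property
    def usable(self) -> bool:
        return (
            math.isfinite(self.beta)
            and math.isfinite(self.se)
            and self.se > 0.0
        )


@dataclass(frozen=True)
class MetaResult:
    """Pooled fixed-effect estimate plus heterogeneity diagnostics."""

    beta: float
    se: float
    z: float
    p: float
    direction: str
    q: float
    df: int
    het_p: float
    i2: float


def _usable(estimates: Sequence[StratumEstimate]) -> list:
    used = [e for e in estimates if e.usable]
    if len(used) < 2:
        raise ValueError(
            f"meta-analysis needs at least 2 usable strata, got {len(used)} "
            f"of {len(estimates)}"
        )
    return used


def direction_string(estimates: Sequence[StratumEstimate]) -> str:
    """Per-stratum sign summary: '+', '-' or '?' in input order."""
    if not estimates:
        raise ValueError("no estimates given")
    chars = []
    for e in estimates:
        if not e.usable:
            chars.append("?")
        elif e.beta > 0:
            chars.append("+")
        elif e.beta < 0:
            chars.append("-")
        else:
            chars.append("0")
    return "".join(chars)


def cochran_q(estimates: Sequence[StratumEstimate]) -> Tuple[float, int]:
    """Cochran's heterogeneity Q and its degrees of freedom (k - 1)."""
    used = _usable(estimates)
    w = [1.0 / e.se**2 for e in used]
    beta = sum(wi * e.beta for wi, e in zip(w, used)) / sum(w)
    q = sum(wi * (e.beta - beta) ** 2 for wi, e in zip(w, used))
    return q, len(used) - 1


def i_squared(q: float, df: int) -> float:
    """I^2 inconsistency percentage: 100 * max(0, (Q - df) / Q).

    Zero whenever Q <= df (no excess heterogeneity beyond chance).
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if q < 0:
        raise ValueError(f"q must be nonnegative, got {q}")
    if q <= df:
        return 0.0
    return 100.0 * (q - df) / q


def het_pvalue(q: float, df: int) -> float:
    """Upper-tail chi-square probability of Q on df degrees of freedom."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if q < 0:
        raise ValueError(f"q must be nonnegative, got {q}")
    return float(chi2.sf(q, df))


def inverse_variance_meta(estimates: Sequence[StratumEstimate]) -> MetaResult:
    """Pool estimates with weights 1/SE^2 (fixed-effect model).

    Unusable strata (missing beta, nonpositive or missing SE) are excluded
    from pooling and from Q/df, but still occupy a '?' slot in the
    direction string so its length always matches the input.
    """
    used = _usable(estimates)
    w = [1.0 / e.se**2 for e in used]
    sw = sum(w)
    beta = sum(wi * e.beta for wi, e in zip(w, used)) / sw
    se = 1.0 / math.sqrt(sw)
    z = beta / se
    q = sum(wi * (e.beta - beta) ** 2 for wi, e in zip(w, used))
    df = len(used) - 1
    return MetaResult(
        beta=beta,
        se=se,
        z=z,
        p=float(2.0 * norm.sf(abs(z))),
        direction=direction_string(estimates),
        q=q,
        df=df,
        het_p=het_pvalue(q, df),
        i2=i_squared(q, df),
    )
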