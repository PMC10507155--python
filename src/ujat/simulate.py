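"""Validity and power experiments, and a synthetic admixed-cohort generator.

Three layers of simulation support the joint ancestry-and-association test:

* ``simulate_type1`` — the calibration experiment: a million (by default)
  null replicates of three independent standard-normal variates, combined
  as sign(first) x second x third, checked against the product-normal
  one-tailed critical value.  The first variate stands in for the
  frequency-differential sign, independent of both Z scores under the null.
* ``simulate_power`` — the power surface: the association Z is drawn from
  Normal(mu, 1) while the realized ancestry Z is held fixed on a grid
  (0..4); effects are independent and share direction by construction, so
  the statistic is ``z_ancestry * Z_assoc``.
* ``simulate_admixed_cohort`` — a two-way admixed cohort with known truth:
  individual ancestry proportions from a Beta distribution, per-locus
  ancestry counts Binomial(2, theta), allele copies drawn with
  ancestry-specific effect-allele frequencies, and an additive quantitative
  phenotype with age and sex covariates.  Defaults mimic an
  African-American cohort at an LPL-like variant: mean 80% ancestry from
  the population coded 2, effect-allele frequency 0.429 on that background
  versus 0.689 on the other, and an ancestry effect acting purely through
  the genotype.

Ancestry counts are drawn independently across loci — there is no
ancestry-tract linkage along the chromosome — which is exactly what the
single-locus joint test consumes; see the methods note for what this does
not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import prodnorm
from .assoc import CohortData

__all__ = [
    "SimulationConfig",
    "CohortConfig",
    "simulate_type1",
    "null_statistics",
    "simulate_power",
    "simulate_admixed_cohort",
]


@dataclass
class SimulationConfig:
    """Settings for the statistical-replicate experiments."""

    n_reps: int = 1_000_000
    alpha: float = 0.05
    seed: Optional[int] = None
    mu_assoc: float = 0.0
    z_ancestry_fixed: float = 0.0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


def null_statistics(n_reps: int, seed=None) -> np.ndarray:
    """Null draws of the signed product: sign(W) * Z1 * Z2, all iid N(0,1)."""
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(seed)
    w, z1, z2 = rng.standard_normal((3, n_reps))
    return np.sign(w) * z1 * z2


def simulate_type1(config: SimulationConfig) -> float:
    """Empirical type I error rate of the one-tailed product test.

    Fraction of null replicates whose statistic exceeds the product-normal
    upper quantile at ``config.alpha``; reproducible given ``config.seed``.
    """
    stats = null_statistics(config.n_reps, config.seed)
    crit = prodnorm.quantile(config.alpha)
    return float(np.mean(stats > crit))


def simulate_power(
    mu_grid: Sequence[float],
    z_ancestry_values: Sequence[float],
    n_reps: int = 10_000,
    alpha: float = 5e-8,
    seed=None,
) -> pd.DataFrame:
    """Monte-Carlo power of the joint test over (mu, Z_A) combinations.

    For each cell the association Z is drawn Normal(mu, 1) and multiplied
    by the fixed realized ancestry Z; the frequency sign is consistent
    (positive) by construction.  Returns a DataFrame indexed by mu with one
    column per ancestry Z.  Power is identically zero whenever Z_A = 0:
    the product can only be nonzero if both Z scores are nonzero.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if not (0.0 < alpha < 0.5):
        raise ValueError(f"alpha must lie in (0, 0.5), got {alpha}")
    rng = np.random.default_rng(seed)
    crit = prodnorm.quantile(alpha)
    table = {}
    for za in z_ancestry_values:
        powers = []
        for mu in mu_grid:
            z_assoc = rng.normal(loc=mu, scale=1.0, size=n_reps)
            powers.append(float(np.mean(za * z_assoc > crit)))
        table[float(za)] = powers
    out = pd.DataFrame(table, index=pd.Index([float(m) for m in mu_grid], name="mu"))
    out.columns.name = "z_ancestry"
    return out


@dataclass
class CohortConfig:
    """Generating parameters of a synthetic two-way admixed cohort.

    The two parental populations are labeled by their homozygous ancestry
    stratum code: ``freq_anc2`` is the effect-allele frequency on the
    background coded 2 and ``freq_anc0`` on the background coded 0.
    Defaults follow the LPL-like configuration: Beta(8, 2) individual
    proportions of ancestry-2 (mean 0.8), frequencies 0.429 vs 0.689, a
    positive per-allele genotype effect on the log-scale phenotype and no
    direct ancestry effect beyond the genotype (``beta_ancestry = 0``), so
    the marginal ancestry effect is fully mediated.
    """

    n_individuals: int = 5_000
    n_loci: int = 1
    admixture_alpha: float = 8.0
    admixture_beta: float = 2.0
    freq_anc0: float = 0.689
    freq_anc2: float = 0.429
    beta_ancestry: float = 0.0
    beta_genotype: float = 0.1
    beta_age: float = 0.002
    beta_sex: float = 0.1
    noise_sd: float = 0.8
    causal_index: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError(f"n_individuals must be >= 1, got {self.n_individuals}")
        if self.n_loci < 1:
            raise ValueError(f"n_loci must be >= 1, got {self.n_loci}")
        for name in ("admixture_alpha", "admixture_beta", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("freq_anc0", "freq_anc2"):
            f = getattr(self, name)
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {f}")
        if not (0 <= self.causal_index < self.n_loci):
            raise ValueError(
                f"causal_index must lie in [0, {self.n_loci}), got {self.causal_index}"
            )


def simulate_admixed_cohort(config: CohortConfig) -> CohortData:
    """Generate a cohort with known ancestry and genotype effects.

    Per individual i and locus j:
    theta_i ~ Beta(a, b); ancestry count a_ij ~ Binomial(2, theta_i);
    each of the a_ij ancestry-2 allele copies carries the effect allele
    with probability ``freq_anc2`` and each of the 2 - a_ij ancestry-0
    copies with probability ``freq_anc0``.  The phenotype is additive in
    the causal locus's ancestry count and dosage plus age, sex and
    Gaussian noise.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_loci

    theta = rng.beta(config.admixture_alpha, config.admixture_beta, size=n)
    ancestry = rng.binomial(2, theta[:, None], size=(n, m))
    dosage = (
        rng.binomial(ancestry, config.freq_anc2)
        + rng.binomial(2 - ancestry, config.freq_anc0)
    ).astype(float)

    age = rng.normal(50.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    j = config.causal_index
    phenotype = (
        config.beta_ancestry * ancestry[:, j]
        + config.beta_genotype * dosage[:, j]
        + config.beta_age * age
        + config.beta_sex * sex
        + rng.normal(0.0, config.noise_sd, size=n)
    )

    ids = pd.Index([f"ind{i:06d}" for i in range(n)], name="id")
    variants = [f"var{j:04d}" for j in range(m)]
    individuals = pd.DataFrame(
        {"age": age, "sex": sex, "phenotype": phenotype, "admixture": theta},
        index=ids,
    )
    return CohortData(
        individuals=individuals,
        dosage=pd.DataFrame(dosage, index=ids, columns=variants),
        ancestry=pd.DataFrame(ancestry, index=ids, columns=variants),
    )
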