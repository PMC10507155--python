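"""Regression machinery: from individual-level data to the two Z scores.

Produces the inputs the joint test consumes, for a two-way admixed cohort
with known (or simulated) locus-specific ancestry:

* admixture mapping — ordinary least squares of the phenotype on the
  locus-specific ancestry count (0/1/2 copies from one parental
  population), adjusted for fixed covariates, giving ``Z_A``;
* structured association — the genotype-dosage effect estimated separately
  within each ancestry stratum (homozygous-0, heterozygous, homozygous-2),
  robust to the unknown mode of inheritance; the per-stratum estimates are
  pooled by :mod:`ujat.meta` into ``Z_G|A``;
* iterative conditional association — the same stratified regressions with
  the dosages of already-selected variants added as covariates;
* stratum effect-allele frequencies ``f0``/``f2`` (mean dosage / 2 within
  each homozygous stratum), which fix the sign of the joint statistic;
* a weighted allelic-dosage genetic score for out-of-sample prediction.

All models are fixed-effect OLS: the synthetic cohorts this package
generates are unrelated by construction, so no genetic-relatedness random
effect is fitted.  The regression entry points accept a covariate list, so
a richer variance structure can be emulated upstream by pre-adjusting the
phenotype if needed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .joint_test import SummaryRecord
from .meta import StratumEstimate, inverse_variance_meta

__all__ = [
    "CohortData",
    "ScoreWeights",
    "STRATUM_LABELS",
    "admixture_mapping_scan",
    "stratified_association",
    "conditional_association",
    "stratum_allele_freqs",
    "genetic_score",
    "joint_inputs",
]

#: locus-specific ancestry stratum code -> human-readable label
STRATUM_LABELS = {0: "homozygous-0", 1: "heterozygous", 2: "homozygous-2"}

DEFAULT_COVARIATES = ("age", "sex")
MIN_STRATUM_SIZE = 30


@dataclass
class CohortData:
    """Individual-level data for a two-way admixed cohort.

    ``individuals`` is indexed by sample id with at least ``phenotype``,
    ``age`` and ``sex`` columns (``study`` optional, categorical).
    ``dosage`` (effect-allele dosage in [0, 2]) and ``ancestry``
    (locus-specific ancestry count in {0, 1, 2}) share that index and have
    one column per variant; the ancestry track of a variant is the column
    of the same name.
    """

    individuals: pd.DataFrame
    dosage: pd.DataFrame
    ancestry: pd.DataFrame
    effect_alleles: Optional[pd.Series] = None  # variant -> effect allele

    def __post_init__(self) -> None:
        for name in ("phenotype", "age", "sex"):
            if name not in self.individuals.columns:
                raise ValueError(f"individuals table lacks column {name!r}")
        if not self.individuals.index.equals(self.dosage.index):
            raise ValueError("dosage index does not match individuals index")
        if not self.individuals.index.equals(self.ancestry.index):
            raise ValueError("ancestry index does not match individuals index")
        if not np.isfinite(self.individuals["phenotype"]).all():
            raise ValueError("phenotype contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.individuals)

    def variants(self) -> List[str]:
        return list(self.dosage.columns)


@dataclass
class ScoreWeights:
    """Weights of a genetic score: intercept, covariates, per-variant betas.

    ``variant_weights`` maps variant id to ``(effect_allele, beta)``; the
    dosage of a variant whose cohort effect allele is the stated *other*
    allele is flipped to ``2 - dosage`` before weighting.
    """

    intercept: float = 0.0
    beta_age: float = 0.0
    beta_sex: float = 0.0
    variant_weights: Dict[str, Tuple[str, float]] = field(default_factory=dict)


def _covariate_matrix(cohort: CohortData, covariates: Sequence[str]) -> pd.DataFrame:
    cols = []
    for name in covariates:
        if name == "study":
            dummies = pd.get_dummies(
                cohort.individuals["study"], prefix="study", drop_first=True
            ).astype(float)
            cols.append(dummies)
        else:
            cols.append(cohort.individuals[name].astype(float))
    if not cols:
        return pd.DataFrame(index=cohort.individuals.index)
    return pd.concat(cols, axis=1)


def _fit_ols(y: np.ndarray, X: pd.DataFrame, term: str):
    """OLS with an explicit rank check; returns the fitted results."""
    arr = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (columns: {list(X.columns)})"
        )
    model = sm.OLS(np.asarray(y, dtype=float), arr)
    res = model.fit()
    idx = list(X.columns).index(term)
    return res.params[idx], res.bse[idx], res


def admixture_mapping_scan(
    cohort: CohortData,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    loci: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Regress phenotype on locus-specific ancestry at each locus.

    Returns a DataFrame indexed by locus with columns ``beta``, ``se``,
    ``z``, ``p``, ``n`` and ``estimable``.  Loci with a single ancestry
    value present are flagged ``estimable = False`` rather than dropped.
    """
    from scipy.stats import norm

    loci = list(loci) if loci is not None else list(cohort.ancestry.columns)
    covs = _covariate_matrix(cohort, covariates)
    y = cohort.individuals["phenotype"].to_numpy()
    rows = []
    for locus in loci:
        anc = cohort.ancestry[locus].astype(float)
        if anc.nunique() < 2:
            rows.append((locus, np.nan, np.nan, np.nan, np.nan, cohort.n, False))
            continue
        X = pd.concat(
            [pd.Series(1.0, index=anc.index, name="const"), anc.rename("ancestry"), covs],
            axis=1,
        )
        beta, se, _ = _fit_ols(y, X, "ancestry")
        z = beta / se
        rows.append((locus, beta, se, z, float(2 * norm.sf(abs(z))), cohort.n, True))
    return pd.DataFrame(
        rows, columns=["locus", "beta", "se", "z", "p", "n", "estimable"]
    ).set_index("locus")


def stratified_association(
    cohort: CohortData,
    variant: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    conditioning: Sequence[str] = (),
    min_stratum_size: int = MIN_STRATUM_SIZE,
) -> List[StratumEstimate]:
    """Genotype association within each locus-specific-ancestry stratum.

    Each stratum gets its own OLS of phenotype on dosage plus covariates
    (and conditioning dosages, if any).  Strata smaller than
    ``min_stratum_size`` or with no genotype variance are omitted with a
    warning; if every stratum is unusable an error is raised.
    """
    if variant not in cohort.dosage.columns:
        raise KeyError(f"variant {variant!r} not present in cohort dosages")
    anc = cohort.ancestry[variant]
    covs = _covariate_matrix(cohort, covariates)
    cond = cohort.dosage[list(conditioning)] if conditioning else None
    estimates: List[StratumEstimate] = []
    for code, label in STRATUM_LABELS.items():
        mask = (anc == code).to_numpy()
        n_k = int(mask.sum())
        if n_k < min_stratum_size:
            warnings.warn(
                f"stratum {label} omitted for {variant}: n={n_k} < {min_stratum_size}"
            )
            continue
        dos = cohort.dosage.loc[mask, variant].astype(float)
        if dos.nunique() < 2:
            warnings.warn(
                f"stratum {label} omitted for {variant}: no genotype variance"
            )
            continue
        parts = [
            pd.Series(1.0, index=dos.index, name="const"),
            dos.rename("dosage"),
            covs.loc[mask],
        ]
        if cond is not None:
            parts.append(cond.loc[mask].astype(float))
        X = pd.concat(parts, axis=1)
        y = cohort.individuals.loc[mask, "phenotype"].to_numpy()
        beta, se, _ = _fit_ols(y, X, "dosage")
        estimates.append(StratumEstimate(label=label, beta=beta, se=se, n=n_k))
    if not estimates:
        raise ValueError(f"no usable ancestry stratum for variant {variant!r}")
    return estimates


def conditional_association(
    cohort: CohortData,
    variant: str,
    conditioning: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    min_stratum_size: int = MIN_STRATUM_SIZE,
) -> List[StratumEstimate]:
    """Stratified association conditioning on previously selected variants.

    The conditioning variants' dosages enter every stratum's regression as
    covariates — the covariate-adjustment realization of iterative
    conditional analysis.
    """
    conditioning = list(conditioning)
    if variant in conditioning:
        raise ValueError(f"test variant {variant!r} is in the conditioning set")
    missing = [v for v in conditioning if v not in cohort.dosage.columns]
    if missing:
        raise KeyError(f"conditioning variants absent from cohort: {missing}")
    return stratified_association(
        cohort,
        variant,
        covariates=covariates,
        conditioning=conditioning,
        min_stratum_size=min_stratum_size,
    )


def stratum_allele_freqs(cohort: CohortData, variant: str) -> Tuple[float, float]:
    """Effect-allele frequencies (f0, f2) in the homozygous-ancestry strata.

    Each is the mean dosage / 2 among individuals with ancestry count 0
    (respectively 2) at the variant's locus; an empty stratum yields NaN,
    which downstream marks the joint-test record degenerate.
    """
    if variant not in cohort.dosage.columns:
        raise KeyError(f"variant {variant!r} not present in cohort dosages")
    anc = cohort.ancestry[variant]
    freqs = []
    for code in (0, 2):
        mask = anc == code
        if mask.sum() == 0:
            freqs.append(math.nan)
        else:
            freqs.append(float(cohort.dosage.loc[mask, variant].mean() / 2.0))
    return freqs[0], freqs[1]


def genetic_score(cohort: CohortData, weights: ScoreWeights) -> pd.Series:
    """Weighted allelic-dosage score per individual.

    score = intercept + beta_age * age + beta_sex * sex
            + sum_j beta_j * dosage_j (allele-aligned).
    """
    score = (
        weights.intercept
        + weights.beta_age * cohort.individuals["age"].astype(float)
        + weights.beta_sex * cohort.individuals["sex"].astype(float)
    )
    for variant, (allele, beta) in weights.variant_weights.items():
        if variant not in cohort.dosage.columns:
            raise KeyError(f"variant {variant!r} required by the score is "
                           "missing from the cohort")
        dos = cohort.dosage[variant].astype(float)
        if cohort.effect_alleles is not None and allele:
            cohort_allele = cohort.effect_alleles.get(variant)
            if cohort_allele is not None and allele != cohort_allele:
                dos = 2.0 - dos  # weight refers to the opposite allele
        score = score + beta * dos
    return score.rename("score")


def joint_inputs(
    cohort: CohortData,
    variant: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    conditioning: Sequence[str] = (),
    min_stratum_size: int = MIN_STRATUM_SIZE,
) -> SummaryRecord:
    """Assemble the joint test's summary record for one variant.

    Runs the admixture-mapping regression at the variant's locus for
    ``Z_A``, the stratified association pooled by inverse-variance meta for
    ``Z_G|A``, and the homozygous-stratum allele frequencies for the sign.
    """
    scan = admixture_mapping_scan(cohort, covariates, loci=[variant])
    z_anc = float(scan.loc[variant, "z"])
    strata = stratified_association(
        cohort, variant, covariates=covariates, conditioning=conditioning,
        min_stratum_size=min_stratum_size,
    )
    pooled = inverse_variance_meta(strata) if len(strata) >= 2 else None
    if pooled is not None:
        z_assoc = pooled.z
    else:
        only = strata[0]
        z_assoc = only.beta / only.se
    f0, f2 = stratum_allele_freqs(cohort, variant)
    return SummaryRecord(
        variant_id=variant,
        z_ancestry=z_anc,
        z_assoc=z_assoc,
        f0=f0,
        f2=f2,
    )
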