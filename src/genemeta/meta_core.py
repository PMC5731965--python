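"""Effect estimation, pooling, heterogeneity and power for 2x2 meta-analysis.

Per-study effects are log odds ratios with Woolf standard errors.
Fixed-effect pooling uses the Mantel-Haenszel estimator with the
Robins-Breslow-Greenland (RBG) variance; inverse-variance (IV) fixed
pooling is provided as a cross-check and as the anchor for Cochran's Q.
Random-effects pooling uses the DerSimonian-Laird (DL) moment estimator
of the between-study variance tau^2.

Method selection follows the common I^2 rule: random effects when
I^2 exceeds a threshold (default 50%), Mantel-Haenszel fixed otherwise;
a tie at the threshold goes to fixed, the less-parameterised default.

All computation is on the natural-log scale; odds ratios are
exponentiated only for reporting.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genetic_models import (
    GeneticModel,
    TwoByTwo,
    apply_continuity_correction,
    derive_two_by_two,
)
from .study_io import StudyRecord, ValidationError

__all__ = [
    "PoolingMethod",
    "EffectEstimate",
    "Heterogeneity",
    "PooledResult",
    "study_effect",
    "pool_mh",
    "pool_iv",
    "pool_dl",
    "heterogeneity",
    "select_method",
    "z_test",
    "power_hedges_pigott",
    "pool_studies",
]

#: 95% Wald intervals use the conventional 1.96 normal quantile.
Z95 = 1.96
I2_THRESHOLD_DEFAULT = 50.0


class PoolingMethod(enum.Enum):
    MH_FIXED = "MH fixed"
    IV_FIXED = "IV fixed"
    DL_RANDOM = "DL random"


@dataclass(frozen=True)
class EffectEstimate:
    """A log odds ratio with its standard error and 95% Wald CI."""

    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_log_or(cls, log_or: float, se: float) -> "EffectEstimate":
        if se <= 0:
            raise ValidationError(f"standard error must be positive, got {se}")
        return cls(
            log_or=log_or,
            se=se,
            or_=math.exp(log_or),
            ci_low=math.exp(log_or - Z95 * se),
            ci_high=math.exp(log_or + Z95 * se),
        )


@dataclass(frozen=True)
class Heterogeneity:
    """Cochran's Q, I^2 and the DL between-study variance."""

    q: float
    df: int
    p_q: float
    i2: float     # percentage in [0, 100]
    tau2: float   # >= 0


@dataclass(frozen=True)
class PooledResult:
    """A pooled odds ratio with its Z-test and heterogeneity summary."""

    method: PoolingMethod
    k: int
    pooled: EffectEstimate
    z: float
    p: float
    het: Heterogeneity
    model: GeneticModel | None = None

    def with_model(self, model: GeneticModel) -> "PooledResult":
        return PooledResult(self.method, self.k, self.pooled, self.z, self.p,
                            self.het, model)


def study_effect(t: TwoByTwo) -> EffectEstimate:
    """Log OR and Woolf SE for one table: y = ln(ad/bc), se = sqrt(sum 1/cell).

    Zero cells must be handled beforehand via
    :func:`~genemeta.genetic_models.apply_continuity_correction`.
    """
    if t.has_zero_cell():
        raise ValidationError(
            "table has a zero cell; apply_continuity_correction before study_effect"
        )
    y = math.log(t.a * t.d / (t.b * t.c))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return EffectEstimate.from_log_or(y, se)


def _effects_for_q(tables: Sequence[TwoByTwo]) -> list[EffectEstimate]:
    return [study_effect(apply_continuity_correction(t)) for t in tables]


def heterogeneity(effects: Sequence[EffectEstimate],
                  pooled_y: float | None = None) -> Heterogeneity:
    """Cochran's Q around the IV-fixed pooled log OR, with I^2 and DL tau^2.

    ``pooled_y`` overrides the anchor point; by default the
    inverse-variance fixed pooled estimate of ``effects`` is used, the
    conventional pairing even when the reported pooled OR is MH.
    """
    k = len(effects)
    if k == 0:
        raise ValidationError("heterogeneity requires at least one effect")
    if k == 1:
        return Heterogeneity(q=0.0, df=0, p_q=1.0, i2=0.0, tau2=0.0)
    y = np.array([e.log_or for e in effects])
    w = np.array([1 / e.se**2 for e in effects])
    if pooled_y is None:
        pooled_y = float((w * y).sum() / w.sum())
    q = float((w * (y - pooled_y) ** 2).sum())
    df = k - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q == 0 else max(0.0, (q - df) / q) * 100.0
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return Heterogeneity(q=q, df=df, p_q=p_q, i2=i2, tau2=tau2)


def z_test(pooled: EffectEstimate) -> tuple[float, float]:
    """Wald Z test of the pooled log OR against zero; two-sided p."""
    z = pooled.log_or / pooled.se
    p = 2 * float(stats.norm.sf(abs(z)))
    return z, p


def pool_mh(tables: Sequence[TwoByTwo]) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled OR with the RBG variance.

    The MH sums use the *uncorrected* counts (the estimator tolerates
    zero cells); the attached heterogeneity uses per-study
    inverse-variance effects on continuity-corrected tables.
    """
    k = len(tables)
    if k == 0:
        raise ValidationError("pool_mh requires at least one table")
    a = np.array([t.a for t in tables])
    b = np.array([t.b for t in tables])
    c = np.array([t.c for t in tables])
    d = np.array([t.d for t in tables])
    n = a + b + c + d
    R_i = a * d / n
    S_i = b * c / n
    R, S = R_i.sum(), S_i.sum()
    if R == 0 or S == 0:
        raise ValidationError("MH pooled OR degenerate: all a*d = 0 or all b*c = 0")
    log_or = math.log(R / S)
    # Robins-Breslow-Greenland variance of ln(OR_MH)
    P_i = (a + d) / n
    Q_i = (b + c) / n
    var = (
        (P_i * R_i).sum() / (2 * R**2)
        + (P_i * S_i + Q_i * R_i).sum() / (2 * R * S)
        + (Q_i * S_i).sum() / (2 * S**2)
    )
    pooled = EffectEstimate.from_log_or(log_or, math.sqrt(var))
    z, p = z_test(pooled)
    het = heterogeneity(_effects_for_q(tables))
    return PooledResult(PoolingMethod.MH_FIXED, k, pooled, z, p, het)


def pool_iv(effects: Sequence[EffectEstimate]) -> PooledResult:
    """Inverse-variance fixed-effect pooling: w_i = 1/se_i^2."""
    if not effects:
        raise ValidationError("pool_iv requires at least one effect")
    y = np.array([e.log_or for e in effects])
    w = np.array([1 / e.se**2 for e in effects])
    pooled_y = float((w * y).sum() / w.sum())
    se = float(1 / math.sqrt(w.sum()))
    pooled = EffectEstimate.from_log_or(pooled_y, se)
    z, p = z_test(pooled)
    het = heterogeneity(effects, pooled_y=pooled_y)
    return PooledResult(PoolingMethod.IV_FIXED, len(effects), pooled, z, p, het)


def pool_dl(effects: Sequence[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pooling: w*_i = 1/(se_i^2 + tau^2).

    Reduces exactly to :func:`pool_iv` when the estimated tau^2 is zero.
    """
    if not effects:
        raise ValidationError("pool_dl requires at least one effect")
    het = heterogeneity(effects)
    y = np.array([e.log_or for e in effects])
    w = np.array([1 / (e.se**2 + het.tau2) for e in effects])
    pooled_y = float((w * y).sum() / w.sum())
    se = float(1 / math.sqrt(w.sum()))
    pooled = EffectEstimate.from_log_or(pooled_y, se)
    z, p = z_test(pooled)
    return PooledResult(PoolingMethod.DL_RANDOM, len(effects), pooled, z, p, het)


def select_method(het: Heterogeneity,
                  i2_threshold: float = I2_THRESHOLD_DEFAULT) -> PoolingMethod:
    """Random effects iff I^2 strictly exceeds the threshold (default 50%)."""
    return PoolingMethod.DL_RANDOM if het.i2 > i2_threshold else PoolingMethod.MH_FIXED


def power_hedges_pigott(true_log_or: float, se: float, alpha: float = 0.05) -> float:
    """Power of the pooled Z test to detect ``true_log_or`` at level alpha.

    With noncentrality lambda = true_log_or / se and z* the upper
    alpha/2 normal quantile: power = 1 - Phi(z* - lambda) + Phi(-z* - lambda).
    """
    if se <= 0:
        raise ValidationError("se must be positive")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    lam = true_log_or / se
    zcrit = float(stats.norm.ppf(1 - alpha / 2))
    return float(stats.norm.sf(zcrit - lam) + stats.norm.cdf(-zcrit - lam))


def pool_studies(
    studies: Sequence[StudyRecord],
    model: GeneticModel,
    i2_threshold: float = I2_THRESHOLD_DEFAULT,
) -> PooledResult:
    """Full pooling of a set of studies under one genetic model.

    Derives the 2x2 tables, measures heterogeneity, selects the method
    by the I^2 rule and pools (MH fixed or DL random accordingly).
    """
    if not studies:
        raise ValidationError("pool_studies requires at least one study")
    tables = [derive_two_by_two(s.cases, s.controls, model) for s in studies]
    effects = _effects_for_q(tables)
    het = heterogeneity(effects)
    method = select_method(het, i2_threshold)
    if method is PoolingMethod.DL_RANDOM:
        result = pool_dl(effects)
    else:
        result = pool_mh(tables)
    return result.with_model(model)
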