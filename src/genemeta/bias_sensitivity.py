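"""Publication-bias diagnostics and leave-one-out sensitivity analysis.

Egger's test regresses the standard normal deviate y_i/se_i on the
precision 1/se_i by ordinary least squares and tests the intercept
(t, k-2 df); this is algebraically identical to the classic weighted
regression of y on se with weights 1/se^2.  Begg's test is Kendall's
rank correlation between the variance-standardised deviates and the
study variances, with the normal approximation for the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_models import GeneticModel
from .meta_core import (
    EffectEstimate,
    PooledResult,
    pool_iv,
    pool_studies,
)
from .study_io import StudyCollection, ValidationError

__all__ = [
    "BiasResult",
    "LeaveOneOutResult",
    "FunnelData",
    "egger_test",
    "begg_test",
    "leave_one_out",
    "funnel_data",
]

#: Variance differences se_i^2 - se_pooled^2 below this floor are
#: clamped (and flagged) in Begg's standardisation.
_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class BiasResult:
    """Publication-bias test outcomes (Egger and/or Begg fields)."""

    k: int
    egger_intercept: float | None = None
    egger_se: float | None = None
    egger_t: float | None = None
    egger_p: float | None = None
    egger_degenerate: bool = False
    begg_tau: float | None = None
    begg_z: float | None = None
    begg_p: float | None = None
    begg_clamped: bool = False


@dataclass(frozen=True)
class LeaveOneOutResult:
    omitted_study_id: str
    pooled: PooledResult


@dataclass(frozen=True)
class FunnelData:
    """Funnel-plot data: study points plus pseudo-95%-CI envelope."""

    points: pd.DataFrame   # columns: log_or, se (sorted by se)
    limits: pd.DataFrame   # columns: se, low, high (grid from 0 to max se)
    pooled_log_or: float

    def write_tsv(self, path) -> None:
        self.points.to_csv(path, sep="\t", index=False)


def _check_k(effects, minimum: int, what: str) -> None:
    if len(effects) < minimum:
        raise ValidationError(f"{what} requires at least {minimum} studies, got {len(effects)}")


def egger_test(effects: list[EffectEstimate]) -> BiasResult:
    """Egger's weighted-regression asymmetry test (k >= 3).

    A degenerate fit (constant standard normal deviate, zero residual
    variance) is returned flagged rather than raising.
    """
    _check_k(effects, 3, "Egger's test")
    k = len(effects)
    y = np.array([e.log_or for e in effects])
    se = np.array([e.se for e in effects])
    snd = y / se
    prec = 1 / se
    res = stats.linregress(prec, snd)
    if not np.isfinite(res.intercept_stderr) or res.intercept_stderr == 0:
        return BiasResult(k=k, egger_intercept=float(res.intercept),
                          egger_se=0.0, egger_degenerate=True)
    t = res.intercept / res.intercept_stderr
    p = 2 * float(stats.t.sf(abs(t), df=k - 2))
    return BiasResult(k=k, egger_intercept=float(res.intercept),
                      egger_se=float(res.intercept_stderr),
                      egger_t=float(t), egger_p=p)


def begg_test(effects: list[EffectEstimate],
              continuity_correction: bool = False) -> BiasResult:
    """Begg's rank-correlation asymmetry test (k >= 3).

    Deviates are standardised against the IV-fixed pooled estimate:
    v_i = (y_i - y_pooled) / sqrt(se_i^2 - se_pooled^2).  Kendall's tau
    is computed by explicit pair counting with tie correction on the
    normal statistic's denominator; ``continuity_correction`` applies
    the |S|-1 correction some software reports.
    """
    _check_k(effects, 3, "Begg's test")
    k = len(effects)
    y = np.array([e.log_or for e in effects])
    var = np.array([e.se**2 for e in effects])
    iv = pool_iv(effects)
    var_pooled = iv.pooled.se**2
    diff = var - var_pooled
    clamped = bool((diff <= _VAR_FLOOR).any())
    diff = np.maximum(diff, _VAR_FLOOR)
    v = (y - iv.pooled.log_or) / np.sqrt(diff)

    concordant = discordant = 0
    tied = 0
    for i in range(k):
        for j in range(i + 1, k):
            s = np.sign(v[i] - v[j]) * np.sign(var[i] - var[j])
            if s > 0:
                concordant += 1
            elif s < 0:
                discordant += 1
            else:
                tied += 1
    s_stat = concordant - discordant
    n_pairs = k * (k - 1) / 2
    denom_pairs = n_pairs - tied
    tau = s_stat / denom_pairs if denom_pairs > 0 else 0.0
    sd = np.sqrt(k * (k - 1) * (2 * k + 5) / 18)
    if continuity_correction and s_stat != 0:
        z = (abs(s_stat) - 1) / sd * np.sign(s_stat)
    else:
        z = s_stat / sd
    p = 2 * float(stats.norm.sf(abs(z)))
    return BiasResult(k=k, begg_tau=float(tau), begg_z=float(z), begg_p=p,
                      begg_clamped=clamped)


def leave_one_out(
    collection: StudyCollection,
    model: GeneticModel,
    i2_threshold: float = 50.0,
) -> list[LeaveOneOutResult]:
    """Re-pool after omitting each study in turn (method re-selected).

    Returns one result per study, in collection order.
    """
    if len(collection) < 2:
        raise ValidationError("leave-one-out requires at least 2 studies")
    results = []
    for sid in collection.study_ids():
        remaining = collection.drop(sid)
        pooled = pool_studies(remaining.studies, model, i2_threshold)
        results.append(LeaveOneOutResult(omitted_study_id=sid, pooled=pooled))
    return results


def funnel_data(effects: list[EffectEstimate], grid_points: int = 50) -> FunnelData:
    """Study points and pseudo-confidence envelope for a funnel plot.

    The envelope is pooled_y +/- 1.96*se on an se grid from 0 (where it
    has zero width) to the largest observed se.  A single study is its
    own centre.
    """
    if not effects:
        raise ValidationError("funnel_data requires at least one effect")
    if len(effects) == 1:
        pooled_y = effects[0].log_or
    else:
        pooled_y = pool_iv(effects).pooled.log_or
    pts = pd.DataFrame({
        "log_or": [e.log_or for e in effects],
        "se": [e.se for e in effects],
    }).sort_values("se", kind="stable").reset_index(drop=True)
    se_grid = np.linspace(0.0, pts["se"].max(), grid_points)
    limits = pd.DataFrame({
        "se": se_grid,
        "low": pooled_y - 1.96 * se_grid,
        "high": pooled_y + 1.96 * se_grid,
    })
    return FunnelData(points=pts, limits=limits, pooled_log_or=float(pooled_y))
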