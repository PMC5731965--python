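"""Hardy-Weinberg equilibrium tests on genotype counts.

Two tests on a single arm (conventionally the controls of a
case-control study, where HWE deviation flags genotyping or sampling
problems):

* :func:`hwe_chi2` -- Pearson goodness-of-fit chi-square on the three
  genotype classes against expected proportions ((1-q)^2, 2q(1-q), q^2)
  at the estimated allele frequency q, 1 degree of freedom, no
  continuity correction.
* :func:`hwe_exact` -- the exact conditional test: given the observed
  allele counts, the heterozygote count follows a known one-parameter
  distribution, and the p-value sums the probabilities of all
  configurations no more probable than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .study_io import GenotypeCounts, ValidationError

__all__ = ["HweResult", "hwe_chi2", "hwe_exact"]

ALPHA = 0.05


@dataclass(frozen=True)
class HweResult:
    """Outcome of an HWE test on one arm."""

    chi2: float
    df: int
    p: float
    exact_p: float | None = None
    in_hwe: bool = True
    monomorphic: bool = False


def _pearson(g: GenotypeCounts) -> tuple[float, float, bool]:
    n = g.total()
    if n == 0:
        raise ValidationError("HWE test requires a non-empty arm")
    q = g.a_alleles / (2 * n)
    if q in (0.0, 1.0):
        return 0.0, 1.0, True
    expected = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2])
    observed = np.array([g.gg, g.ga, g.aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p, False


def hwe_chi2(g: GenotypeCounts) -> HweResult:
    """Pearson chi-square HWE test (1 df, no continuity correction).

    A monomorphic arm (allele frequency 0 or 1) is flagged, not an
    error: chi2 = 0, p = 1.
    """
    chi2, p, mono = _pearson(g)
    return HweResult(chi2=chi2, df=1, p=p, in_hwe=p >= ALPHA, monomorphic=mono)


def _log_het_prob(n_het: int, n: int, n_a: int) -> float:
    """Log probability of ``n_het`` heterozygotes given n subjects and
    n_a minor alleles, under the exact conditional HWE distribution."""
    n_hom_a = (n_a - n_het) // 2
    n_hom_g = n - n_het - n_hom_a
    return (
        gammaln(n + 1) - gammaln(n_hom_g + 1) - gammaln(n_het + 1) - gammaln(n_hom_a + 1)
        + n_het * np.log(2.0)
        + gammaln(n_a + 1) + gammaln(2 * n - n_a + 1) - gammaln(2 * n + 1)
    )


def hwe_exact(g: GenotypeCounts) -> HweResult:
    """Exact conditional HWE test.

    Enumerates every heterozygote count with the parity of the observed
    minor-allele count and sums the probabilities of all configurations
    whose conditional probability does not exceed the observed one.
    The Pearson statistic is reported alongside; ``p`` and ``exact_p``
    both carry the exact p-value and ``in_hwe`` is judged from it.
    """
    chi2, _, mono = _pearson(g)
    if mono:
        return HweResult(chi2=0.0, df=1, p=1.0, exact_p=1.0, in_hwe=True, monomorphic=True)
    n = g.total()
    n_a = g.a_alleles
    # heterozygote count shares the parity of the minor-allele count
    # and cannot exceed min(n_a, 2n - n_a)
    max_het = min(n_a, 2 * n - n_a)
    hets = np.arange(n_a % 2, max_het + 1, 2)
    logp = np.array([_log_het_prob(int(h), n, n_a) for h in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == g.ga][0]
    exact_p = float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))
    return HweResult(chi2=chi2, df=1, p=exact_p, exact_p=exact_p,
                     in_hwe=exact_p >= ALPHA, monomorphic=False)
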