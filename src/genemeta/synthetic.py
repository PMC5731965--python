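"""Synthetic case-control genotype collections with known truth.

Generates study collections with the statistical structure the
meta-analysis assumes, so every stage of the pipeline can be exercised
against known parameters:

* control genotype frequencies at a specified minor-allele frequency,
  under Hardy-Weinberg equilibrium or perturbed from it via an
  inbreeding-like coefficient F (P(GG) = (1-q)^2 + Fq(1-q),
  P(GA) = 2q(1-q)(1-F), P(AA) = q^2 + Fq(1-q));
* case genotype probabilities proportional to the control
  probabilities times the genotype odds ratios exp(log or_het + u_i)
  and exp(log or_hom + u_i), renormalised — u_i ~ Normal(0, tau2) is a
  shared per-study shift.  The dominant-model log OR inherits the
  shift exactly (between-study variance tau2, the structure the
  DerSimonian-Laird model assumes); the allele-model log OR inherits
  it partially, through the carrier frequency;
* optional small-study publication bias by selection-on-significance
  thinning: candidate studies with a sub-significant dominant-model Z
  score are discarded with a probability that grows with both the
  shortfall and ``bias_strength``, and sampling continues until k
  studies are retained.

All randomness flows from the single integer seed through one
``numpy.random.Generator``; the same params reproduce the same
collection exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genetic_models import GeneticModel, apply_continuity_correction, derive_two_by_two
from .meta_core import study_effect
from .study_io import (
    CollapsedStudyRecord,
    GenotypeCounts,
    StudyCollection,
    StudyRecord,
    ValidationError,
)

__all__ = ["SimulationParams", "SimulatedCollection", "simulate_collection", "simulate_collapsed"]

_Z_SIG = 1.959964  # significance cut used by the bias-thinning mechanism


@dataclass(frozen=True)
class SimulationParams:
    """Generative settings for a synthetic study collection.

    Defaults mirror a typical East-Asian candidate-gene meta-analysis:
    12 studies of ~500 subjects per arm at a control minor-allele
    frequency of 0.25, no genotype effect, no between-study
    heterogeneity, controls in HWE, no publication bias.
    """

    k: int = 12
    n_cases: int | Sequence[int] = 500
    n_controls: int | Sequence[int] = 500
    maf: float = 0.25
    or_het: float = 1.0
    or_hom: float = 1.0
    tau2: float = 0.0
    hwe_disequilibrium: float = 0.0
    bias_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if not 0 < self.maf <= 0.5:
            raise ValidationError("maf must be in (0, 0.5]")
        if self.or_het <= 0 or self.or_hom <= 0:
            raise ValidationError("genotype odds ratios must be positive")
        if self.tau2 < 0:
            raise ValidationError("tau2 must be >= 0")
        if self.bias_strength < 0:
            raise ValidationError("bias_strength must be >= 0")
        for name in ("n_cases", "n_controls"):
            sizes = self._sizes(name)
            if len(sizes) != self.k:
                raise ValidationError(f"{name}: need a scalar or a length-k sequence")
            if min(sizes) < 1:
                raise ValidationError(f"{name}: all sizes must be >= 1")

    def _sizes(self, name: str) -> list[int]:
        v = getattr(self, name)
        if isinstance(v, (int, np.integer)):
            return [int(v)] * self.k
        return [int(x) for x in v]

    @property
    def case_sizes(self) -> list[int]:
        return self._sizes("n_cases")

    @property
    def control_sizes(self) -> list[int]:
        return self._sizes("n_controls")


@dataclass(frozen=True)
class SimulatedCollection:
    """A simulated collection together with its generating truth."""

    collection: StudyCollection
    params: SimulationParams
    study_log_or_het: tuple[float, ...]   # realised per-study GA log ORs
    study_log_or_hom: tuple[float, ...]   # realised per-study AA log ORs


def _control_probs(params: SimulationParams) -> np.ndarray:
    q = params.maf
    f = params.hwe_disequilibrium
    probs = np.array([
        (1 - q) ** 2 + f * q * (1 - q),
        2 * q * (1 - q) * (1 - f),
        q**2 + f * q * (1 - q),
    ])
    if (probs <= 0).any() or (probs >= 1).any():
        raise ValidationError(
            f"hwe_disequilibrium={f} with maf={q} gives genotype "
            f"probabilities outside (0, 1): {probs.round(4).tolist()}"
        )
    return probs


def _draw_study(rng: np.random.Generator, params: SimulationParams,
                n_case: int, n_control: int) -> tuple[GenotypeCounts, GenotypeCounts, float, float]:
    u = rng.normal(0.0, math.sqrt(params.tau2)) if params.tau2 > 0 else 0.0
    log_het = math.log(params.or_het) + u
    log_hom = math.log(params.or_hom) + u
    p_ctrl = _control_probs(params)
    w = p_ctrl * np.array([1.0, math.exp(log_het), math.exp(log_hom)])
    p_case = w / w.sum()
    ctrl = rng.multinomial(n_control, p_ctrl)
    case = rng.multinomial(n_case, p_case)
    return (GenotypeCounts(*map(int, case)), GenotypeCounts(*map(int, ctrl)),
            log_het, log_hom)


def _passes_selection(rng: np.random.Generator, params: SimulationParams,
                      cases: GenotypeCounts, controls: GenotypeCounts) -> bool:
    """Selection-on-significance thinning for the bias mechanism."""
    if params.bias_strength == 0:
        return True
    try:
        t = apply_continuity_correction(
            derive_two_by_two(cases, controls, GeneticModel.DOMINANT))
        eff = study_effect(t)
    except ValidationError:
        return True
    z = eff.log_or / eff.se
    if z >= _Z_SIG:
        return True
    keep_prob = math.exp(-params.bias_strength * (_Z_SIG - z))
    return bool(rng.random() < keep_prob)


def simulate_collection(params: SimulationParams) -> SimulatedCollection:
    """Draw a study collection under ``params`` (deterministic in seed)."""
    rng = np.random.default_rng(params.seed)
    case_sizes = params.case_sizes
    control_sizes = params.control_sizes
    studies: list[StudyRecord] = []
    log_hets: list[float] = []
    log_homs: list[float] = []
    max_attempts = 10_000 * params.k
    attempts = 0
    while len(studies) < params.k:
        attempts += 1
        if attempts > max_attempts:
            raise ValidationError(
                "bias thinning rejected too many candidate studies; "
                "lower bias_strength or raise study sizes"
            )
        i = len(studies)
        cases, controls, lh, lhom = _draw_study(
            rng, params, case_sizes[i], control_sizes[i])
        if cases.total() == 0 or controls.total() == 0:
            continue
        if not _passes_selection(rng, params, cases, controls):
            continue
        studies.append(StudyRecord(
            study_id=f"sim{i + 1:03d}",
            first_author=f"Sim{i + 1:03d}",
            year=2000 + i,
            country="Simland",
            control_source="PB",
            cases=cases,
            controls=controls,
        ))
        log_hets.append(lh)
        log_homs.append(lhom)
    return SimulatedCollection(
        collection=StudyCollection(studies, label=f"simulated(seed={params.seed})"),
        params=params,
        study_log_or_het=tuple(log_hets),
        study_log_or_hom=tuple(log_homs),
    )


def simulate_collapsed(params: SimulationParams,
                       stratum_label: str) -> list[CollapsedStudyRecord]:
    """Simulate a collection and collapse it to dominant-model records.

    Collapsing is exactly the dominant contrast: exposed = GA + AA,
    reference = GG, in both arms.
    """
    sim = simulate_collection(params)
    records = []
    for s in sim.collection:
        records.append(CollapsedStudyRecord(
            study_id=s.study_id,
            stratum_label=stratum_label,
            case_exposed=s.cases.ga + s.cases.aa,
            case_ref=s.cases.gg,
            control_exposed=s.controls.ga + s.controls.aa,
            control_ref=s.controls.gg,
        ))
    return records
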