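"""Bonferroni and Benjamini-Hochberg adjustment over analysis families.

A *family* here is the set of p-values adjusted together — in the
standard reporting layout, the five genetic-model tests within one
population category (overall or a subgroup), so m = 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genetic_models import GeneticModel
from .study_io import ValidationError

__all__ = ["PvalueFamily", "AdjustedPvalues", "bonferroni", "bh_fdr", "adjust", "build_families"]


@dataclass(frozen=True)
class PvalueFamily:
    """Raw p-values jointly adjusted, aligned to analysis labels."""

    labels: tuple[str, ...]
    p_raw: tuple[float, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.p_raw):
            raise ValidationError("labels and p_raw must have equal length")
        if len(self.p_raw) == 0:
            raise ValidationError("a p-value family must be non-empty")
        for p in self.p_raw:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"p-value outside [0, 1]: {p}")

    @property
    def m(self) -> int:
        return len(self.p_raw)


@dataclass(frozen=True)
class AdjustedPvalues:
    labels: tuple[str, ...]
    p_raw: tuple[float, ...]
    p_bonferroni: tuple[float, ...]
    p_fdr: tuple[float, ...]


def bonferroni(family: PvalueFamily) -> list[float]:
    """Each p multiplied by the family size m, capped at 1."""
    return [min(1.0, family.m * p) for p in family.p_raw]


def bh_fdr(family: PvalueFamily) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in label order.

    adjusted_(i) = min over j >= i of m * p_(j) / j on the ascending
    ranking, capped at 1 and mapped back to the original order.
    """
    p = np.asarray(family.p_raw, dtype=float)
    m = family.m
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out.tolist()


def adjust(family: PvalueFamily) -> AdjustedPvalues:
    """Both adjustments at once, aligned to the family's labels."""
    return AdjustedPvalues(
        labels=family.labels,
        p_raw=family.p_raw,
        p_bonferroni=tuple(bonferroni(family)),
        p_fdr=tuple(bh_fdr(family)),
    )


def build_families(
    pvalues: Mapping[tuple[str, str], float],
    models: Sequence[GeneticModel] = tuple(GeneticModel),
) -> list[PvalueFamily]:
    """One family per category from a ``(category, model value) -> p`` map.

    Each category must carry a p-value for every requested model;
    a missing (category, model) pair raises naming the gap.
    """
    if not pvalues:
        raise ValidationError("empty result set: no p-values to adjust")
    categories: list[str] = []
    for cat, _ in pvalues:
        if cat not in categories:
            categories.append(cat)
    families = []
    for cat in categories:
        ps = []
        for model in models:
            key = (cat, model.value)
            if key not in pvalues:
                raise ValidationError(
                    f"category {cat!r} is missing a p-value for model {model.value!r}"
                )
            ps.append(pvalues[key])
        families.append(PvalueFamily(
            labels=tuple(m.value for m in models), p_raw=tuple(ps), name=cat,
        ))
    return families
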