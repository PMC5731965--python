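"""Genetic-model contrasts: genotype counts to 2x2 exposed/unexposed tables.

Five standard contrasts for a biallelic G>A variant:

=============  ===========================  =========================
model          exposed                      unexposed
=============  ===========================  =========================
ALLELE         A alleles (ga + 2*aa)        G alleles (2*gg + ga)
DOMINANT       GA + AA subjects             GG subjects
RECESSIVE      AA subjects                  GA + GG subjects
HOM            AA subjects                  GG subjects (GA excluded)
HET            GA subjects                  GG subjects (AA excluded)
=============  ===========================  =========================

HOM and HET are the two co-dominant contrasts; subjects carrying the
excluded genotype are absent from their tables entirely.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .study_io import GenotypeCounts, ValidationError

__all__ = ["GeneticModel", "TwoByTwo", "derive_two_by_two", "apply_continuity_correction"]


class GeneticModel(enum.Enum):
    ALLELE = "allele"        # A vs G
    DOMINANT = "dominant"    # GA+AA vs GG
    RECESSIVE = "recessive"  # AA vs GA+GG
    HOM = "hom"              # AA vs GG (co-dominant homozygote)
    HET = "het"              # GA vs GG (co-dominant heterozygote)

    @property
    def label(self) -> str:
        return _LABELS[self]

    def contrast(self, g: GenotypeCounts) -> tuple[int, int]:
        """(exposed, unexposed) counts for one arm under this model."""
        if self is GeneticModel.ALLELE:
            return g.a_alleles, g.g_alleles
        if self is GeneticModel.DOMINANT:
            return g.ga + g.aa, g.gg
        if self is GeneticModel.RECESSIVE:
            return g.aa, g.ga + g.gg
        if self is GeneticModel.HOM:
            return g.aa, g.gg
        if self is GeneticModel.HET:
            return g.ga, g.gg
        raise ValueError(f"unknown genetic model: {self!r}")


_LABELS = {
    GeneticModel.ALLELE: "A vs G",
    GeneticModel.DOMINANT: "GA+AA vs GG",
    GeneticModel.RECESSIVE: "AA vs GA+GG",
    GeneticModel.HOM: "AA vs GG",
    GeneticModel.HET: "GA vs GG",
}


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table: exposed/unexposed x case/control.

    Cell layout follows the conventional a/b/c/d notation: ``a`` exposed
    cases, ``b`` unexposed cases, ``c`` exposed controls, ``d``
    unexposed controls.  Cells are floats so a 0.5 continuity
    correction can be represented.
    """

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False
    correction: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError(f"2x2 cells must be non-negative: {self.cells()}")
        if self.n == 0:
            raise ValidationError("2x2 table is empty (n = 0)")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def has_zero_cell(self) -> bool:
        return min(self.cells()) == 0


def derive_two_by_two(
    cases: GenotypeCounts, controls: GenotypeCounts, model: GeneticModel
) -> TwoByTwo:
    """Build the 2x2 table for ``model`` from per-arm genotype counts.

    No continuity correction is applied at this stage; see
    :func:`apply_continuity_correction`.  Raises
    :class:`~genemeta.study_io.ValidationError` if either arm is empty
    or the contrast is empty in an arm (both compared classes zero).
    """
    if not isinstance(model, GeneticModel):
        raise ValidationError(f"model must be a GeneticModel member, got {model!r}")
    if cases.total() == 0 or controls.total() == 0:
        raise ValidationError("both study arms must be non-empty")
    a, b = model.contrast(cases)
    c, d = model.contrast(controls)
    if a + b == 0 or c + d == 0:
        raise ValidationError(
            f"empty contrast for model {model.value!r}: an arm has no subjects "
            "in either compared class"
        )
    return TwoByTwo(float(a), float(b), float(c), float(d))


def apply_continuity_correction(t: TwoByTwo) -> TwoByTwo:
    """Add 0.5 to every cell if any cell is zero; otherwise return ``t``.

    The correction is applied to the affected table only and is meant
    for per-study (inverse-variance) effect estimates; Mantel-Haenszel
    sums should use the uncorrected counts, which tolerate zero cells.
    """
    if not t.has_zero_cell():
        return t
    return TwoByTwo(t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5,
                    corrected=True, correction=0.5)
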