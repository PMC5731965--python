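"""End-to-end analysis: overall and subgroup pooling, reporting tables.

``run_analysis`` orchestrates, for each requested genetic model and
each population category (overall plus subgroups defined by study
metadata): 2x2 derivation, per-study effects, heterogeneity, method
selection by the I^2 rule, pooling, the Z test, Begg/Egger bias tests
(where at least three studies are available) and per-category
multiplicity adjustment over the model family.

``run_collapsed_analysis`` applies the same machinery to
dominant-model-only collapsed counts grouped into labelled strata
(sex / smoking / drinking status), the form in which stratified counts
are usually published.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .bias_sensitivity import begg_test, egger_test
from .genetic_models import GeneticModel, apply_continuity_correction, derive_two_by_two
from .hwe import hwe_chi2
from .meta_core import (
    PooledResult,
    PoolingMethod,
    heterogeneity,
    pool_dl,
    pool_mh,
    select_method,
    study_effect,
)
from .multiplicity import PvalueFamily, adjust
from .study_io import CollapsedStudyRecord, StudyCollection, ValidationError

__all__ = ["AnalysisConfig", "ResultTable", "run_analysis", "run_collapsed_analysis",
           "characteristics_summary", "CharacteristicsSummary"]

ALL_MODELS = tuple(GeneticModel)

#: metadata attribute behind each supported grouping name
_GROUP_ATTRS = {"country": "country", "control_source": "control_source",
                "source": "control_source"}

_COLUMNS = ["model", "category", "k", "or", "ci_low", "ci_high", "p",
            "p_bonferroni", "p_fdr", "i2", "p_het", "tau2", "method",
            "begg_p", "egger_p"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable settings of a full analysis run.

    ``group_by`` names zero or more study metadata fields
    ("country", "control_source") whose values define subgroup
    categories in addition to the overall pooling.
    """

    models: tuple[GeneticModel, ...] = ALL_MODELS
    group_by: tuple[str, ...] = ()
    i2_threshold: float = 50.0
    alpha: float = 0.05
    ci_level: float = 0.95
    seed: int = 0
    output_format: str = "tsv"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must be in (0, 1)")
        if not 0 <= self.i2_threshold <= 100:
            raise ValidationError("i2_threshold must be in [0, 100]")
        for g in self.group_by:
            if g not in _GROUP_ATTRS:
                raise ValidationError(
                    f"unknown group_by field {g!r}; choose from {sorted(set(_GROUP_ATTRS))}"
                )


def _fmt(x, decimals: int) -> str:
    return "NA" if x is None or (isinstance(x, float) and pd.isna(x)) else f"{x:.{decimals}f}"


@dataclass
class ResultTable:
    """Report rows keyed by (category, model), with export helpers."""

    df: pd.DataFrame
    label: str = ""

    def row(self, category: str, model: GeneticModel | str) -> pd.Series:
        mv = model.value if isinstance(model, GeneticModel) else model
        hit = self.df[(self.df["category"] == category) & (self.df["model"] == mv)]
        if hit.empty:
            raise KeyError((category, mv))
        return hit.iloc[0]

    def to_tsv(self) -> str:
        """Report at conventional printed precision: ORs and CI bounds
        to 3 decimals, p-values to 3 decimals, I^2 to 1 decimal."""
        lines = ["\t".join(_COLUMNS)]
        for _, r in self.df.iterrows():
            lines.append("\t".join([
                r["model"], r["category"], str(int(r["k"])),
                _fmt(r["or"], 3), _fmt(r["ci_low"], 3), _fmt(r["ci_high"], 3),
                _fmt(r["p"], 3), _fmt(r["p_bonferroni"], 3), _fmt(r["p_fdr"], 3),
                _fmt(r["i2"], 1), _fmt(r["p_het"], 3), _fmt(r["tau2"], 4),
                r["method"], _fmt(r["begg_p"], 3), _fmt(r["egger_p"], 3),
            ]))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        records = json.loads(self.df.to_json(orient="records"))
        return json.dumps({"label": self.label, "rows": records}, indent=1)

    def write(self, path, fmt: str = "tsv") -> None:
        text = self.to_tsv() if fmt == "tsv" else self.to_json()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


def _pool_tables(tables, i2_threshold: float) -> PooledResult:
    effects = [study_effect(apply_continuity_correction(t)) for t in tables]
    het = heterogeneity(effects)
    method = select_method(het, i2_threshold)
    if method is PoolingMethod.DL_RANDOM:
        return pool_dl(effects)
    return pool_mh(tables)


def _bias_ps(tables) -> tuple[float | None, float | None]:
    if len(tables) < 3:
        return None, None
    effects = [study_effect(apply_continuity_correction(t)) for t in tables]
    egger = egger_test(effects)
    begg = begg_test(effects)
    return begg.begg_p, (None if egger.egger_degenerate else egger.egger_p)


def _categories(collection: StudyCollection,
                config: AnalysisConfig) -> list[tuple[str, StudyCollection]]:
    cats: list[tuple[str, StudyCollection]] = [("Overall", collection)]
    for g in config.group_by:
        attr = _GROUP_ATTRS[g]
        for value, sub in collection.group_by(attr).items():
            if len(sub) == 0:
                warnings.warn(f"subgroup {value!r} is empty; omitted")
                continue
            cats.append((value, sub))
    return cats


def run_analysis(collection: StudyCollection, config: AnalysisConfig | None = None) -> ResultTable:
    """Full meta-analysis of a study collection.

    Returns one row per (requested model, category).  Bonferroni and
    BH-FDR columns are filled per category over the family of all five
    genetic models; a run restricted to a subset of models reports raw
    p-values only (adjusted columns NA).  Begg and Egger p-values are
    attached wherever the category has at least three studies.
    """
    config = config or AnalysisConfig()
    if len(collection) == 0:
        raise ValidationError("cannot analyse an empty study collection")
    cats = _categories(collection, config)
    rows: list[dict] = []
    raw_p: dict[tuple[str, str], float] = {}
    for model in config.models:
        for cat_name, sub in cats:
            tables = [derive_two_by_two(s.cases, s.controls, model) for s in sub]
            pooled = _pool_tables(tables, config.i2_threshold)
            begg_p, egger_p = _bias_ps(tables)
            raw_p[(cat_name, model.value)] = pooled.p
            rows.append({
                "model": model.value, "category": cat_name, "k": pooled.k,
                "or": pooled.pooled.or_, "ci_low": pooled.pooled.ci_low,
                "ci_high": pooled.pooled.ci_high, "p": pooled.p,
                "p_bonferroni": None, "p_fdr": None,
                "i2": pooled.het.i2, "p_het": pooled.het.p_q,
                "tau2": pooled.het.tau2, "method": pooled.method.value,
                "begg_p": begg_p, "egger_p": egger_p,
            })
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if set(config.models) == set(ALL_MODELS) and not df.empty:
        for cat_name, _ in cats:
            fam = PvalueFamily(
                labels=tuple(m.value for m in config.models),
                p_raw=tuple(raw_p[(cat_name, m.value)] for m in config.models),
                name=cat_name,
            )
            adj = adjust(fam)
            for label, pb, pf in zip(adj.labels, adj.p_bonferroni, adj.p_fdr):
                mask = (df["category"] == cat_name) & (df["model"] == label)
                df.loc[mask, "p_bonferroni"] = pb
                df.loc[mask, "p_fdr"] = pf
    return ResultTable(df=df, label=collection.label)


def run_collapsed_analysis(records: Sequence[CollapsedStudyRecord],
                           config: AnalysisConfig | None = None) -> ResultTable:
    """Dominant-model meta-analysis of collapsed counts, per stratum.

    Each distinct ``stratum_label`` (in order of first appearance)
    becomes one category; the 2x2 tables come directly from the
    collapsed counts.  Adjusted-p columns are NA (strata are separate
    questions, not a model family).
    """
    config = config or AnalysisConfig()
    if not records:
        raise ValidationError("no collapsed records to analyse")
    strata: dict[str, list[CollapsedStudyRecord]] = {}
    for r in records:
        strata.setdefault(r.stratum_label, []).append(r)
    from .genetic_models import TwoByTwo

    rows = []
    for label, recs in strata.items():
        tables = [TwoByTwo(float(r.case_exposed), float(r.case_ref),
                           float(r.control_exposed), float(r.control_ref))
                  for r in recs]
        pooled = _pool_tables(tables, config.i2_threshold)
        begg_p, egger_p = _bias_ps(tables)
        rows.append({
            "model": GeneticModel.DOMINANT.value, "category": label, "k": pooled.k,
            "or": pooled.pooled.or_, "ci_low": pooled.pooled.ci_low,
            "ci_high": pooled.pooled.ci_high, "p": pooled.p,
            "p_bonferroni": None, "p_fdr": None,
            "i2": pooled.het.i2, "p_het": pooled.het.p_q,
            "tau2": pooled.het.tau2, "method": pooled.method.value,
            "begg_p": begg_p, "egger_p": egger_p,
        })
    return ResultTable(df=pd.DataFrame(rows, columns=_COLUMNS), label="collapsed")


@dataclass(frozen=True)
class CharacteristicsSummary:
    n_studies: int
    total_cases: int
    total_controls: int
    by_country: dict[str, int]
    by_source: dict[str, int]
    hwe_p: dict[str, float]       # control-arm HWE p per study
    hwe_in: dict[str, bool]


def characteristics_summary(collection: StudyCollection) -> CharacteristicsSummary:
    """Study-characteristics roll-up; the HWE column is computed from
    the control genotype counts, never read from metadata."""
    by_country: dict[str, int] = {}
    by_source: dict[str, int] = {}
    hwe_p: dict[str, float] = {}
    hwe_in: dict[str, bool] = {}
    for s in collection:
        by_country[s.country] = by_country.get(s.country, 0) + 1
        by_source[s.control_source] = by_source.get(s.control_source, 0) + 1
        res = hwe_chi2(s.controls)
        hwe_p[s.study_id] = res.p
        hwe_in[s.study_id] = res.in_hwe
    return CharacteristicsSummary(
        n_studies=len(collection),
        total_cases=collection.total_cases(),
        total_controls=collection.total_controls(),
        by_country=by_country,
        by_source=by_source,
        hwe_p=hwe_p,
        hwe_in=hwe_in,
    )
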