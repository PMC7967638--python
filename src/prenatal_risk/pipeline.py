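"""End-to-end orchestration of the risk-score analysis.

Stages, in order: recode -> small-cell merge -> crude exact fits for every
variable -> factor selection -> multiple exact fit -> weight derivation ->
per-record scores -> score distribution -> classification table -> AUC ->
cut-off.  Each stage writes one CSV/JSON artifact and the run ends with a
manifest that fully determines reproducibility (input source, seed,
versions, selected factors, formula, cutoff, file paths).

Two input modes exist because the published evidence has two shapes: a
per-category count table reproduces every crude fit exactly (count-only
mode), while score derivation and ROC evaluation need individual records
(full mode, from a cohort CSV or the synthetic generator).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from . import __version__
from . import cohort as _cohort
from .exact import ExactParameterInference, GroupedDesign, fit_exact_logit
from .roc import auc, classification_table, select_cutoff
from .score import (
    ScoreFormula,
    WeightRule,
    compute_score,
    derive_weights,
    score_distribution,
    select_factors,
)
from .simulate import GeneratorConfig, generate_cohort

__all__ = [
    "PipelineError",
    "RunManifest",
    "design_from_frame",
    "crude_fits_from_tables",
    "inference_frame",
    "run_full_analysis",
]

_NA = _cohort.NOT_ANSWERED
_NI = _cohort.NOT_INVESTIGATED


class PipelineError(RuntimeError):
    """A stage failed; carries the stage label."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunManifest:
    input_source: dict
    version: str
    mode: Literal["records", "counts"]
    selected_factors: list[str]
    score_formula: dict | None
    cutoff: int | None
    outputs: dict[str, str]
    dropped_parameters: list[str] = dataclasses.field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def design_from_frame(
    recoded: pd.DataFrame,
    variables: Sequence[str],
    merge_threshold: int = 5,
) -> GroupedDesign:
    """Grouped design over several variables' dummies from a recoded frame.

    Applies the small-cell rule first (a variable's ``not_answered``
    category with fewer than ``merge_threshold`` respondents folds into
    its reference), then groups records by joint dummy pattern.
    """
    dummies: list[tuple[str, str]] = []
    columns: dict[str, pd.Series] = {}
    for var in variables:
        order = list(_cohort.RECODED_CATEGORIES[var])
        if _NI not in order:
            order.append(_NI)
        col = recoded[var]
        ref = order[0]
        na_count = int((col == _NA).sum())
        if 0 < na_count < merge_threshold:
            col = col.replace({_NA: ref})
        columns[var] = col
        present = [c for c in order[1:] if (col == c).any()]
        dummies.extend((var, c) for c in present)
    if not dummies:
        raise ValueError("no non-reference categories among the given variables")
    frame = pd.DataFrame({f"{v}={c}": (columns[v] == c).astype(int) for v, c in dummies})
    frame["_y"] = recoded["outcome_rccrc"].astype(int)
    names = [f"{v}={c}" for v, c in dummies]
    grouped = frame.groupby(names, sort=True)["_y"].agg(["size", "sum"]).reset_index()
    patterns = [
        (tuple(int(row[n]) for n in names), int(row["size"]), int(row["sum"]))
        for _, row in grouped.iterrows()
    ]
    return GroupedDesign.from_rows(patterns, names)


def crude_fits_from_tables(
    tables: Mapping[str, _cohort.CategoryCountTable],
    merge_threshold: int = 5,
    level: float = 0.95,
    p_method: str = "probability",
) -> dict[str, list[ExactParameterInference]]:
    """One crude exact fit per variable from per-category count tables."""
    out: dict[str, list[ExactParameterInference]] = {}
    for var, table in tables.items():
        merged = _cohort.merge_small_not_answered(table, threshold=merge_threshold)
        design = GroupedDesign.one_variable(var, merged.rows)
        out[var] = fit_exact_logit(design, level=level, p_method=p_method)
    return out


def inference_frame(
    fits: Mapping[str, Sequence[ExactParameterInference]]
    | Sequence[ExactParameterInference],
) -> pd.DataFrame:
    """Inference results as a flat table (OR, CI, kind, p per parameter)."""
    if isinstance(fits, Mapping):
        items = [f for fs in fits.values() for f in fs]
    else:
        items = list(fits)
    return pd.DataFrame(
        {
            "parameter": [f.parameter_name for f in items],
            "estimate_kind": [f.estimate_kind for f in items],
            "odds_ratio": [f.odds_ratio for f in items],
            "ci_lower": [f.ci_lower for f in items],
            "ci_upper": [f.ci_upper for f in items],
            "p_value": [f.p_value for f in items],
            "t_observed": [f.t_observed for f in items],
        }
    )


def _write(path: Path, text: str) -> None:
    path.write_text(text)


def run_full_analysis(
    outdir: str | Path,
    cohort_csv: str | Path | None = None,
    municipality_config: str | Path | None = None,
    counts_csv: str | Path | None = None,
    generator_config: GeneratorConfig | None = None,
    use_fixture_counts: bool = False,
    level: float = 0.95,
    p_method: str = "probability",
    weight_rule: WeightRule = WeightRule(),
    cutoff_criterion: Literal["youden", "accuracy"] = "youden",
    merge_threshold: int = 5,
) -> RunManifest:
    """Run the whole analysis, writing one artifact per stage plus a manifest.

    Exactly one input source must be given: a cohort CSV, a generator
    config (full record mode), a count-table CSV, or the packaged
    published counts (count-only mode; crude fits only).  On a stage
    failure the partial manifest is kept with a ``.partial`` suffix and a
    stage-labeled :class:`PipelineError` is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sources = [cohort_csv, generator_config, counts_csv,
               use_fixture_counts or None]
    if sum(s is not None for s in sources) != 1:
        raise ValueError("give exactly one input source")

    mode: Literal["records", "counts"] = (
        "counts" if (counts_csv or use_fixture_counts) else "records"
    )
    outputs: dict[str, str] = {}
    manifest = RunManifest(
        input_source={}, version=__version__, mode=mode,
        selected_factors=[], score_formula=None, cutoff=None, outputs=outputs,
    )
    stage = "input"
    try:
        if mode == "counts":
            if use_fixture_counts:
                tables = _cohort.load_published_counts()
                manifest.input_source = {"kind": "packaged_counts"}
            else:
                frame = pd.read_csv(counts_csv)
                tables = {
                    str(var): _cohort.CategoryCountTable(
                        str(var),
                        tuple(
                            (str(r.category), int(r.n_total), int(r.n_events))
                            for r in grp.itertuples()
                        ),
                    )
                    for var, grp in frame.groupby("variable", sort=False)
                }
                manifest.input_source = {"kind": "counts_csv", "path": str(counts_csv)}
            recoded = None
        else:
            if generator_config is not None:
                cohort = generate_cohort(generator_config)
                manifest.input_source = {
                    "kind": "generator",
                    "seed": generator_config.seed,
                    "n": generator_config.n,
                    "target_prevalence": generator_config.target_prevalence,
                }
                path = outdir / "cohort.csv"
                _cohort.write_cohort_csv(cohort, path)
                outputs["cohort"] = path.name
            else:
                muni = (
                    _cohort.load_municipality_config(municipality_config)
                    if municipality_config
                    else None
                )
                cohort = _cohort.load_cohort_csv(cohort_csv, muni)
                manifest.input_source = {"kind": "cohort_csv", "path": str(cohort_csv)}
            stage = "recode"
            recoded = _cohort.recode_frame(cohort)
            stage = "tabulate"
            tables = {}
            for var in _cohort.VARIABLES:
                order = list(_cohort.RECODED_CATEGORIES[var])
                if _NI not in order:
                    order.append(_NI)
                tables[var] = _cohort.build_count_table(
                    recoded, _cohort.CodedVariable(var, tuple(order))
                )

        stage = "merge"
        merged = {
            v: _cohort.merge_small_not_answered(t, threshold=merge_threshold)
            for v, t in tables.items()
        }
        counts_frame = pd.concat([t.to_frame() for t in merged.values()])
        path = outdir / "count_tables.csv"
        counts_frame.to_csv(path, index=False)
        outputs["count_tables"] = path.name

        stage = "crude_fits"
        total_events = next(iter(merged.values())).n_events
        if total_events == 0:
            raise ValueError("cohort has zero events; exact inference is impossible")
        crude = crude_fits_from_tables(
            merged, merge_threshold=merge_threshold, level=level, p_method=p_method
        )
        path = outdir / "crude_fits.csv"
        inference_frame(crude).to_csv(path, index=False)
        outputs["crude_fits"] = path.name

        stage = "select_factors"
        selected = select_factors(crude)
        manifest.selected_factors = selected
        if mode == "counts":
            path = outdir / "manifest.json"
            _write(path, manifest.to_json())
            outputs["manifest"] = path.name
            return manifest
        if not selected:
            raise ValueError("no factor reached significance; score undefined")

        stage = "multiple_fit"
        assert recoded is not None
        design = design_from_frame(recoded, selected, merge_threshold=merge_threshold)
        adjusted = fit_exact_logit(design, level=level, p_method=p_method)
        path = outdir / "adjusted_fits.csv"
        inference_frame(adjusted).to_csv(path, index=False)
        outputs["adjusted_fits"] = path.name

        stage = "derive_weights"
        informative = [f for f in adjusted if f.informative]
        dropped = [f.parameter_name for f in adjusted if not f.informative]
        if dropped:
            # e.g. perfectly collinear "not investigated" dummies whose
            # conditional support collapses to a point
            manifest.dropped_parameters = dropped
            logging.getLogger(__name__).warning(
                "non-informative parameters excluded from the score: %s", dropped
            )
        if not informative:
            raise ValueError("no informative parameter in the multiple fit")
        formula = derive_weights(informative, rule=weight_rule)
        manifest.score_formula = json.loads(formula.to_json())
        path = outdir / "score_formula.json"
        _write(path, formula.to_json())
        outputs["score_formula"] = path.name

        stage = "score"
        merged_recoded = _apply_merge(recoded, formula, merge_threshold)
        scores = [
            compute_score(row, formula)
            for row in merged_recoded[list(formula.variables)].to_dict("records")
        ]
        scored = pd.DataFrame(
            {
                "household_id": cohort["household_id"],
                "score": scores,
                "outcome_rccrc": recoded["outcome_rccrc"].astype(int),
            }
        )
        path = outdir / "scores.csv"
        scored.to_csv(path, index=False)
        outputs["scores"] = path.name

        stage = "score_distribution"
        dist = score_distribution(scores)
        path = outdir / "score_distribution.csv"
        pd.DataFrame(
            [(s, c, p) for s, (c, p) in dist.items()],
            columns=["score", "count", "percent"],
        ).to_csv(path, index=False)
        outputs["score_distribution"] = path.name

        stage = "classification"
        labels = recoded["outcome_rccrc"].astype(int).tolist()
        table = classification_table(scores, labels)
        path = outdir / "classification.csv"
        pd.DataFrame([r.display() for r in table]).to_csv(path, index=False)
        outputs["classification"] = path.name

        stage = "roc"
        roc = auc(scores, labels, level=level)
        path = outdir / "roc.json"
        _write(
            path,
            json.dumps(
                {
                    "auc": roc.auc,
                    "auc_ci": list(roc.auc_ci),
                    "n_pos": roc.n_pos,
                    "n_neg": roc.n_neg,
                },
                indent=2,
            ),
        )
        outputs["roc"] = path.name

        stage = "cutoff"
        manifest.cutoff = select_cutoff(table, criterion=cutoff_criterion)

        path = outdir / "manifest.json"
        _write(path, manifest.to_json())
        outputs["manifest"] = path.name
        return manifest
    except Exception as exc:
        _write(outdir / "manifest.partial.json", manifest.to_json())
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc


def _apply_merge(
    recoded: pd.DataFrame, formula: ScoreFormula, merge_threshold: int
) -> pd.DataFrame:
    """Re-apply the small-cell merge so record categories match the formula."""
    out = recoded.copy()
    for var in formula.variables:
        ref = _cohort.RECODED_CATEGORIES[var][0]
        na_count = int((out[var] == _NA).sum())
        if 0 < na_count < merge_threshold:
            out[var] = out[var].replace({_NA: ref})
    return out
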