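"""End-to-end orchestration of the CNV analysis stages.

Stages: simulate (synthetic cohort) -> callcn (ddCt copy calling) ->
assoc (case-control association) -> emld (haplotype EM + LD) -> expr
(copy-dosage expression trends).  A run is fully determined by its config
and seed; the JSON run report isolates its timestamp so reports from
identical runs compare equal once that field is dropped.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field

from . import __version__, defaults, io
from .association import (
    copy_category_table,
    dichotomize,
    fisher_exact_2x2,
    fisher_exact_2xK,
    logistic_adjust,
    onset_analysis,
)
from .expression import dosage_trend
from .haplotypes import EmConfig, em_haplotype_frequencies, ld_r2
from .qpcr import call_cohort
from .synthetic import (
    REFERENCE_AMPLICON,
    TARGET_AMPLICON,
    SimulationConfig,
    simulate_case_control,
    simulate_ct_data,
    simulate_expression,
    simulate_population,
)

logger = logging.getLogger("nsfcnv")
if not logger.handlers:  # stage-tagged lines to stderr
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

ALL_STAGES = ("simulate", "callcn", "assoc", "emld", "expr")


class PipelineConfig(BaseModel):
    """Run settings; file paths may point at externally produced tables."""

    seed: int = 0
    n_individuals: int = 1792
    low_set: list[int] = Field(default=[2, 3])
    ambiguity_tolerance: float = 0.3
    efficiency: float = defaults.DEFAULT_EFFICIENCY
    em_tolerance: float = 1e-5
    em_max_iterations: int = 200
    stages: list[str] = Field(default=list(ALL_STAGES))
    genotype_tsv: Optional[str] = None
    ct_tsv: Optional[str] = None
    calibrator_tsv: Optional[str] = None
    expression_tsv: Optional[str] = None

    def model_post_init(self, __context) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


class RunReport(BaseModel):
    version: str
    config: PipelineConfig
    generated_at: Optional[str] = None  # excluded from determinism checks
    warnings: list[str] = Field(default_factory=list)
    stages: dict[str, dict] = Field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_inputs(paths: dict[str, str | Path]) -> list[str]:
    """Schema checks on input tables; violations are returned, not raised."""
    import pandas as pd

    violations: list[str] = []
    for kind, path in paths.items():
        path = Path(path)
        if not path.exists():
            violations.append(f"{kind}: file not found: {path}")
            continue
        df = pd.read_csv(path, sep="\t")
        if df["sample_id"].duplicated().any() and kind in ("genotype", "calibrator"):
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].unique()
            violations.append(f"{kind}: duplicated sample_id {list(map(str, dups))[:5]}")
        if kind == "genotype":
            for col in ("sample_id", "total_copies"):
                if col not in df.columns:
                    violations.append(f"{kind}: missing column {col!r}")
            if "total_copies" in df.columns:
                bad = df.loc[~df["total_copies"].isin([2, 3, 4, 5, 6]), "total_copies"]
                if len(bad):
                    violations.append(f"{kind}: total_copies outside [2,6]: {sorted(set(bad))}")
            if "status" in df.columns:
                bad_status = set(df["status"].dropna()) - {"case", "control"}
                if bad_status:
                    violations.append(f"{kind}: unknown status values {sorted(bad_status)}")
        elif kind == "ct":
            for col in ("sample_id", "amplicon", "replicate", "ct"):
                if col not in df.columns:
                    violations.append(f"{kind}: missing column {col!r}")
            if "ct" in df.columns and (df["ct"] <= 0).any():
                violations.append(f"{kind}: non-positive Ct values present")
        elif kind == "expression":
            for col in ("sample_id", "transcript", "rel_expr"):
                if col not in df.columns:
                    violations.append(f"{kind}: missing column {col!r}")
    return violations


def _assoc_block(subjects, low_set, seed) -> dict:
    table = dichotomize(subjects, low_set)
    res = fisher_exact_2x2(table, sidedness="two")
    cat = copy_category_table(subjects)
    rng = np.random.default_rng([seed, 97])
    exact_k = fisher_exact_2xK(cat, rng=rng)
    block = {
        "table_low_high": table.counts.tolist(),
        "case_low_pct": float(table.row_percentages()[0, 0]),
        "control_low_pct": float(table.row_percentages()[1, 0]),
        "p_two_tailed": float(res.p_value),
        "or_sample": float(res.or_sample),
        "or_cmle": float(res.or_cmle),
        "ci_95": [res.ci_low, res.ci_high],
        "table_by_copies": cat.counts.tolist(),
        "p_five_categories": exact_k.p_value,
        "p_five_categories_method": exact_k.method,
    }
    try:
        block["age_adjusted"] = logistic_adjust(subjects, low_set, ("age",))
    except (ValueError, RuntimeError) as exc:
        block["age_adjusted"] = {"error": str(exc)}
    try:
        onset = onset_analysis(subjects, low_set)
        block["onset"] = {
            "mann_whitney_p": onset["mann_whitney_p"],
            "median_onset_low": onset["median_onset_low"],
            "median_onset_high": onset["median_onset_high"],
            "early_late_table": onset["early_late_table"].counts.tolist(),
            "one_tailed_p": float(onset["one_tailed_fisher"].p_value),
            "or_sample": float(onset["one_tailed_fisher"].or_sample),
        }
    except ValueError as exc:
        block["onset"] = {"error": str(exc)}
    return block


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute the enabled stages, passing tables between them.

    A stage failure aborts the run with :class:`StageError` naming the
    stage; the report accumulated so far is attached to the exception as
    ``partial_report``.
    """
    report = RunReport(version=__version__, config=config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    low_set = frozenset(config.low_set)
    sim_cfg = SimulationConfig(n_individuals=config.n_individuals, seed=config.seed,
                               efficiency=config.efficiency)
    individuals = subjects = measurements = panel = expr_samples = None

    for stage in config.stages:
        logger.info("stage %s: start", stage)
        try:
            if stage == "simulate":
                individuals = simulate_population(sim_cfg)
                subjects = simulate_case_control(individuals, sim_cfg)
                measurements, panel = simulate_ct_data(individuals, sim_cfg)
                expr_samples = simulate_expression(individuals, sim_cfg)
                n_cases = sum(s.status == "case" for s in subjects)
                report.stages["simulate"] = {
                    "n_individuals": len(individuals),
                    "n_cases": n_cases,
                    "n_controls": len(subjects) - n_cases,
                    "copy_totals": {
                        str(k): sum(i.total_copies == k for i in individuals)
                        for k in range(2, 7)
                    },
                }
                if out is not None:
                    io.write_genotype_tsv(out / "genotypes.tsv", individuals, subjects,
                                          loci=defaults.LOCI)
                    io.write_ct_tsv(out / "ct.tsv", measurements)
                    io.write_calibrator_tsv(out / "calibrators.tsv", panel)
                    io.write_expression_tsv(out / "expression.tsv", expr_samples)
            elif stage == "callcn":
                if measurements is None:
                    if config.ct_tsv is None:
                        raise FileNotFoundError("no Ct data: enable simulate or set ct_tsv")
                    measurements = io.read_ct_tsv(config.ct_tsv)
                    panel = io.read_calibrator_tsv(config.calibrator_tsv)
                calls = call_cohort(
                    measurements, panel, [TARGET_AMPLICON], REFERENCE_AMPLICON,
                    config.efficiency, config.ambiguity_tolerance,
                )
                n_ambiguous = int(calls["call"].isna().sum())
                report.stages["callcn"] = {
                    "n_samples": int(calls["sample_id"].nunique()),
                    "n_ambiguous": n_ambiguous,
                    "call_counts": {
                        str(int(k)): int(v)
                        for k, v in calls["call"].dropna().value_counts().sort_index().items()
                    },
                }
                if out is not None:
                    calls.to_csv(out / "copy_calls.tsv", sep="\t", index=False)
            elif stage == "assoc":
                if subjects is None:
                    if config.genotype_tsv is None:
                        raise FileNotFoundError("no subjects: enable simulate or set genotype_tsv")
                    subjects = io.read_subject_tsv(config.genotype_tsv)
                report.stages["assoc"] = _assoc_block(subjects, low_set, config.seed)
            elif stage == "emld":
                if individuals is None:
                    if config.genotype_tsv is None:
                        raise FileNotFoundError("no genotypes: enable simulate or set genotype_tsv")
                    individuals, _ = io.read_genotype_tsv(config.genotype_tsv)
                em = em_haplotype_frequencies(
                    individuals,
                    EmConfig(tolerance=config.em_tolerance,
                             max_iterations=config.em_max_iterations),
                )
                risk = defaults.RISK_HAPLOALLELE
                ld = ld_r2(em, lambda a: a == risk, lambda c: c == 1)
                report.stages["emld"] = {
                    "iterations": em.iteration_count,
                    "converged": em.converged,
                    "log_likelihood": em.log_likelihood_trace[-1],
                    "frequencies": {
                        f"{''.join(h.alleles)}|{h.copies}": f for h, f in em.items()
                    },
                    "r2_risk_vs_one_copy": ld.r_squared,
                }
                if out is not None:
                    io.write_haplotype_table_tsv(out / "haplotype_frequencies.tsv", em)
            elif stage == "expr":
                if expr_samples is None:
                    if config.expression_tsv is None:
                        raise FileNotFoundError("no expression data: enable simulate or set expression_tsv")
                    expr_samples = io.read_expression_tsv(config.expression_tsv)
                import pandas as pd

                df = expr_samples if isinstance(expr_samples, pd.DataFrame) else None
                if df is None:
                    from .expression import _to_frame

                    df = _to_frame(expr_samples)
                block = {}
                for transcript in sorted(df["transcript"].unique()):
                    trend = dosage_trend(df, transcript_id=transcript, low_set=low_set)
                    block[transcript] = {
                        k: v for k, v in asdict(trend).items() if k != "transcript_id"
                    }
                report.stages["expr"] = block
            else:  # pragma: no cover - guarded by PipelineConfig validation
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            err = StageError(stage, exc)
            err.partial_report = report  # type: ignore[attr-defined]
            logger.error("stage %s: failed (%s)", stage, exc)
            raise err from exc
        logger.info("stage %s: done", stage)

    report.generated_at = datetime.now(timezone.utc).isoformat()
    if out is not None:
        (out / "report.json").write_text(report.model_dump_json(indent=2))
    return report


def report_schema() -> dict:
    """JSON schema of the run report (also shipped as report_schema.json)."""
    return RunReport.model_json_schema()


def write_report_schema(path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_schema(), indent=2))
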