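"""Ranked rule reports and end-to-end pipeline orchestration.

Two report styles mirror how high-risk combination analyses are usually
presented: a prevalence table (rules ranked by carrier count within
each antecedent order) and an impact table (ranked by adjusted odds
ratio, falling back to confidence when no adjusted estimates are
attached). Every column is labeled explicitly — coverage and confidence
are separate columns, and the two lift variants are never conflated
under a bare "%".

Display rounding (coverage/confidence one decimal, lifts and odds
ratios two) is applied only at write time; a full-precision JSON file
is always emitted alongside any rounded CSV/markdown report. Report
files carry a run-metadata header (config hash, seed, package version)
and deliberately no timestamps, so identical runs produce identical
bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import json

import pandas as pd
import yaml

from . import __version__
from .code_mapping import IndicatorMatrix, build_indicators, load_mapping, map_records
from .effect_estimation import EffectEstimate, estimate_adjusted_or
from .redundancy_filter import annotate_improvements, apply_improvement_filter
from .rule_mining import (
    MiningConfig,
    Rule,
    mine_rules,
    write_rules_jsonl,
)
from .synthetic_cohort import (
    build_default_mapping,
    cohort_to_records,
    config_from_yaml,
    default_config,
    generate_cohort,
)

logger = logging.getLogger("ihtminer")

_RANK_KEYS = ("antecedent_count", "confidence", "aor")

#: Display decimals per column family, applied only at write time.
DISPLAY_DECIMALS = {
    "coverage_pct": 1,
    "confidence_pct": 1,
    "improvement_pp": 1,
    "lift_outcome": 2,
    "lift_cooccurrence": 2,
    "odds_ratio": 2,
    "or_ci_low": 2,
    "or_ci_high": 2,
    "adjusted_or": 2,
    "aor_ci_low": 2,
    "aor_ci_high": 2,
}


class ReportError(ValueError):
    """Raised for invalid report specifications."""


class PipelineError(RuntimeError):
    """Stage-labeled pipeline failure."""


def baseline_mortality_pct(n_patients: int, n_deaths: int) -> float:
    """Cohort mortality as a percentage (e.g. 1041/8893 -> 11.7...)."""
    if n_patients <= 0:
        raise ReportError("n_patients must be positive")
    return 100.0 * n_deaths / n_patients


@dataclass(frozen=True)
class ReportSpec:
    rank_by: str = "confidence"
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.rank_by not in _RANK_KEYS:
            raise ReportError(f"unknown ranking key {self.rank_by!r}; allowed: {_RANK_KEYS}")
        if self.top_k < 1:
            raise ReportError("top_k must be >= 1")


def rules_to_frame(
    rules: Sequence[Rule],
    estimates: Mapping[tuple[str, ...], EffectEstimate] | None = None,
) -> pd.DataFrame:
    """Full-precision tabular view of rules (plus effect estimates if given)."""
    estimates = estimates or {}
    rows = []
    for rule in rules:
        est = estimates.get(rule.antecedent)
        rows.append(
            {
                "order": rule.order,
                "antecedent": " & ".join(rule.antecedent),
                "n_antecedent": rule.n_antecedent,
                "n_deaths": rule.n_both,
                "coverage_pct": 100.0 * rule.coverage,
                "confidence_pct": 100.0 * rule.confidence,
                "lift_outcome": rule.lift_outcome,
                "lift_cooccurrence": rule.lift_cooccurrence,
                "improvement_pp": rule.improvement,
                "odds_ratio": est.or_unadjusted.value if est else None,
                "or_ci_low": est.or_unadjusted.ci_low if est else None,
                "or_ci_high": est.or_unadjusted.ci_high if est else None,
                "adjusted_or": est.aor if est else None,
                "aor_ci_low": est.aor_ci[0] if est else None,
                "aor_ci_high": est.aor_ci[1] if est else None,
            }
        )
    return pd.DataFrame(rows)


_KEY_COLUMN = {
    "antecedent_count": "n_antecedent",
    "confidence": "confidence_pct",
    "aor": "adjusted_or",
}


def rank_rules(
    rules: Sequence[Rule],
    spec: ReportSpec = ReportSpec(),
    estimates: Mapping[tuple[str, ...], EffectEstimate] | None = None,
) -> pd.DataFrame:
    """Top-k report rows per antecedent order, sorted by the ranking key.

    Within each order rules are sorted descending on the key with ties
    broken lexicographically by antecedent; rules lacking the key (e.g.
    no attached aOR when ranking by aOR) are a configuration error.
    """
    frame = rules_to_frame(rules, estimates)
    if frame.empty:
        return frame
    key = _KEY_COLUMN[spec.rank_by]
    if frame[key].isna().any():
        raise ReportError(
            f"ranking key {spec.rank_by!r} missing on "
            f"{int(frame[key].isna().sum())} rule(s)"
        )
    frame = frame.sort_values(
        ["order", key, "antecedent"], ascending=[True, False, True], kind="stable"
    )
    return frame.groupby("order", group_keys=False).head(spec.top_k).reset_index(drop=True)


def _metadata_lines(metadata: Mapping[str, object]) -> list[str]:
    meta = {"package_version": __version__, **metadata}
    return [f"# {k} = {v}" for k, v in meta.items()]


def write_report(
    rows: pd.DataFrame,
    path: str | Path,
    format: str = "csv",
    metadata: Mapping[str, object] | None = None,
) -> list[Path]:
    """Write a report with display rounding; full precision goes alongside.

    Returns the written paths (the requested file plus the
    ``*.full.json`` companion carrying unrounded values).
    """
    if format not in ("csv", "json", "markdown"):
        raise ReportError(f"unknown report format {format!r}")
    path = Path(path)
    metadata = metadata or {}
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        full = path.with_suffix(path.suffix + ".full.json") if format != "json" else None

        display = rows.copy()
        for col, nd in DISPLAY_DECIMALS.items():
            if col in display.columns:
                display[col] = pd.to_numeric(display[col], errors="coerce").round(nd)

        if format == "csv":
            with open(path, "w", encoding="utf-8") as fh:
                for line in _metadata_lines(metadata):
                    fh.write(line + "\n")
                display.to_csv(fh, index=False)
        elif format == "markdown":
            with open(path, "w", encoding="utf-8") as fh:
                for line in _metadata_lines(metadata):
                    fh.write(line + "\n")
                fh.write("\n")
                fh.write(display.to_markdown(index=False))
                fh.write("\n")
        else:
            payload = {
                "metadata": {"package_version": __version__, **metadata},
                "rows": rows.to_dict(orient="records"),
            }
            path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

        written = [path]
        if full is not None:
            payload = {
                "metadata": {"package_version": __version__, **metadata},
                "rows": rows.to_dict(orient="records"),
            }
            full.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
            written.append(full)
        return written
    except OSError as err:
        raise ReportError(f"cannot write report to {path}: {err}") from err


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    matrix: IndicatorMatrix
    rules: list[Rule]
    retained: list[Rule]
    estimates: dict[tuple[str, ...], EffectEstimate]
    artifacts: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    """Decorator-ish helper: re-raise stage failures with a stage label."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: str | Path | Mapping) -> PipelineResult:
    """Execute simulate -> map -> mine -> filter -> estimate -> report.

    ``config`` is a YAML path or a parsed mapping; see the packaged demo
    configuration for the schema. Deterministic given seed and config.
    """
    if not isinstance(config, Mapping):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    out_dir = Path(cfg.get("output_dir", "ihtminer_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    # Plain-text run log next to the artifacts. No timestamps: identical
    # runs must produce identical bytes.
    log_handler = logging.FileHandler(out_dir / "pipeline.log", mode="w", encoding="utf-8")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log_handler.setLevel(logging.INFO)
    logger.addHandler(log_handler)
    prior_level = logger.level
    if logger.level > logging.INFO or logger.level == logging.NOTSET:
        logger.setLevel(logging.INFO)
    try:
        return _run_pipeline_stages(cfg, seed, out_dir)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
        logger.setLevel(prior_level)


def _run_pipeline_stages(cfg: dict, seed: int, out_dir: Path) -> "PipelineResult":
    logger.info("pipeline start: seed=%d output_dir=%s resolved_config=%s",
                seed, out_dir, json.dumps(cfg, sort_keys=True, default=str))

    artifacts: dict[str, Path] = {}
    config_hash = "external-input"

    if cfg.get("indicators"):
        # mine-only mode: a prebuilt indicator matrix CSV is provided
        with _stage("load"):
            matrix = IndicatorMatrix.read_csv(cfg["indicators"])
            logger.info("load: indicator matrix %d patients x %d items", matrix.N, len(matrix.item_names))
    elif cfg.get("records"):
        # map mode: long-format records + demographics + mapping table
        with _stage("map"):
            if not cfg.get("mapping"):
                raise PipelineError("[map] mapping path is required when records are supplied")
            if not cfg.get("demographics"):
                raise PipelineError("[map] demographics path is required when records are supplied")
            mapping = load_mapping(cfg["mapping"])
            records = pd.read_csv(cfg["records"], dtype=str)
            demographics = pd.read_csv(cfg["demographics"])
            item_sets, map_report = map_records(records, mapping)
            matrix = build_indicators(item_sets, demographics)
            logger.info(
                "map: %d records -> %d mapped, %d unmapped; matrix %d x %d",
                map_report.n_records, map_report.n_mapped, map_report.n_unmapped,
                matrix.N, len(matrix.item_names),
            )
    else:
        with _stage("simulate"):
            sim = dict(cfg.get("simulate") or {})
            n_patients = int(sim.get("n_patients", 8893))
            cohort_cfg_path = sim.get("cohort_config")
            if cohort_cfg_path:
                sim_config = config_from_yaml(cohort_cfg_path, n_patients=n_patients, seed=seed)
            else:
                sim_config = default_config(n_patients=n_patients, seed=seed)
            config_hash = sim_config.config_hash()
            cohort = generate_cohort(sim_config)
            logger.info("simulate: n=%d death_rate=%.4f", cohort.n, cohort.death_rate)
        with _stage("map"):
            mapping = (
                load_mapping(cfg["mapping"]) if cfg.get("mapping")
                else build_default_mapping(sim_config.item_catalog)
            )
            records, demographics = cohort_to_records(cohort, mapping)
            item_sets, map_report = map_records(records, mapping)
            matrix = build_indicators(item_sets, demographics)
            logger.info(
                "map: %d records -> matrix %d x %d",
                map_report.n_records, matrix.N, len(matrix.item_names),
            )
            records.to_csv(out_dir / "records.csv", index=False)
            demographics.to_csv(out_dir / "demographics.csv", index=False)
            mapping.to_csv(out_dir / "mapping.csv")
            artifacts["records"] = out_dir / "records.csv"
            artifacts["demographics"] = out_dir / "demographics.csv"
            artifacts["mapping"] = out_dir / "mapping.csv"

    run_meta = {"config_hash": config_hash, "seed": seed}

    with _stage("mine"):
        mine_cfg = dict(cfg.get("mine") or {})
        mining = MiningConfig(
            min_antecedent_count=int(mine_cfg.get("min_count", 25)),
            max_order=int(mine_cfg.get("max_order", 4)),
        )
        rules = mine_rules(matrix, mining)
        logger.info("mine: %d rules at floor %d, order <= %d",
                    len(rules), mining.min_antecedent_count, mining.max_order)

    with _stage("filter"):
        filt_cfg = dict(cfg.get("filter") or {})
        min_improvement = float(filt_cfg.get("min_improvement", 10.0))
        rules = annotate_improvements(rules, matrix.baseline_mortality)
        retained = apply_improvement_filter(
            rules, min_improvement, baseline=matrix.baseline_mortality
        )
        logger.info("filter: retained %d of %d rules", len(retained), len(rules))
        write_rules_jsonl(
            rules, out_dir / "rules.jsonl",
            meta={"N": matrix.N, "D": matrix.D, **run_meta},
        )
        write_rules_jsonl(
            retained, out_dir / "rules_retained.jsonl",
            meta={"N": matrix.N, "D": matrix.D, **run_meta},
        )
        artifacts["rules"] = out_dir / "rules.jsonl"
        artifacts["rules_retained"] = out_dir / "rules_retained.jsonl"

    with _stage("estimate"):
        est_cfg = dict(cfg.get("estimate") or {})
        top_k = int(est_cfg.get("top_k_per_order", 10))
        shortlist = rank_rules(retained, ReportSpec(rank_by="confidence", top_k=top_k))
        estimates: dict[tuple[str, ...], EffectEstimate] = {}
        wanted = set(shortlist["antecedent"]) if not shortlist.empty else set()
        for rule in retained:
            if " & ".join(rule.antecedent) in wanted:
                estimates[rule.antecedent] = estimate_adjusted_or(matrix, rule.antecedent)
        logger.info("estimate: adjusted ORs for %d rules", len(estimates))

    with _stage("report"):
        rep_cfg = dict(cfg.get("report") or {})
        formats = list(rep_cfg.get("formats", ["csv", "json"]))
        top_k = int(rep_cfg.get("top_k", 10))
        estimated = [r for r in retained if r.antecedent in estimates]
        prevalence = rank_rules(
            retained, ReportSpec(rank_by="antecedent_count", top_k=top_k)
        )
        impact = rank_rules(
            estimated, ReportSpec(rank_by="aor", top_k=top_k), estimates
        )
        ext = {"csv": ".csv", "json": ".json", "markdown": ".md"}
        for name, frame in (("report_prevalence", prevalence), ("report_impact", impact)):
            for fmt in formats:
                written = write_report(
                    frame, out_dir / f"{name}{ext[fmt]}", format=fmt, metadata=run_meta
                )
                artifacts[f"{name}{ext[fmt]}"] = written[0]
        logger.info(
            "report: prevalence %d rows, impact %d rows -> %s",
            len(prevalence), len(impact), out_dir,
        )

    return PipelineResult(
        matrix=matrix, rules=rules, retained=retained,
        estimates=estimates, artifacts=artifacts,
    )
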