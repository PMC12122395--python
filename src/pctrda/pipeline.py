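"""End-to-end pipeline orchestration with reproducible configuration.

Stages: generate (optional) -> prep -> classify -> rda grid -> roc ->
comparison tables. Every stage reads/writes delimited text under one output
directory, logs its row counts and timing, and contributes to a manifest
JSON carrying a fingerprint of the configuration, so a run is reproducible
and auditable from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort_prep, cohort_stats, course_classifier, rda, roc_decision
from .synthetic_cohort import GeneratorConfig, PolicyModel, generate_cohort

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "validate_schema",
    "load_config",
    "TIME_COLUMNS",
]

log = logging.getLogger("pctrda")

ISO = "%Y-%m-%dT%H:%M:%S"
TIME_COLUMNS = {
    "encounters": ["admit_time", "discharge_time", "pct_time"],
    "administrations": ["admin_time"],
    "eligible_cohort": ["admit_time", "discharge_time", "pct_time", "first_abx_time"],
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Either ``generator`` is set (synthetic run), or ``inputs`` maps the
    table names ``encounters`` / ``administrations`` / ``prescriptions`` to
    CSV paths, or both are ``None`` and stages re-run from the CSVs already
    in ``outdir``. ``seed`` is mandatory whenever the generator is used.
    """

    outdir: Path
    seed: int | None = None
    generator: GeneratorConfig | None = None
    inputs: Mapping[str, Path] | None = None
    cutpoints: Sequence[float] = rda.DEFAULT_CUTPOINTS
    bandwidths: Sequence[float] = rda.DEFAULT_BANDWIDTHS
    strata: Sequence[str] = rda.DEFAULT_STRATA
    alpha: float = 0.05
    bh_adjust: bool = False
    plot: bool = True

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.generator is not None and self.seed is None:
            raise PipelineError("config: seed is mandatory for generator runs")

    def fingerprint(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return str(o)

        fields = dataclasses.asdict(self)
        fields.pop("outdir")  # identifies the analysis, not where it lands
        payload = json.dumps(fields, default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path, seed: int | None = None, outdir=None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file; ``seed``/``outdir``
    arguments override the file's values."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    gen = None
    if "generator" in raw:
        g = dict(raw["generator"])
        if seed is not None:
            g["seed"] = seed
        if "policy" in g:
            pol = g["policy"]
            if isinstance(pol, Mapping) and "kind" not in pol:
                g["policy"] = {k: PolicyModel(**v) for k, v in pol.items()}
            else:
                g["policy"] = PolicyModel(**pol)
        if "pct_mixture" in g:
            g["pct_mixture"] = [tuple(c) for c in g["pct_mixture"]]
        gen = GeneratorConfig(**g)
    inputs = (
        {k: Path(v) for k, v in raw["inputs"].items()} if "inputs" in raw else None
    )
    return RunConfig(
        outdir=Path(outdir or raw.get("outdir", "pctrda_out")),
        seed=seed if seed is not None else raw.get("seed", gen.seed if gen else None),
        generator=gen,
        inputs=inputs,
        cutpoints=tuple(raw.get("cutpoints", rda.DEFAULT_CUTPOINTS)),
        bandwidths=tuple(raw.get("bandwidths", rda.DEFAULT_BANDWIDTHS)),
        strata=tuple(raw.get("strata", rda.DEFAULT_STRATA)),
        alpha=float(raw.get("alpha", 0.05)),
        bh_adjust=bool(raw.get("bh_adjust", False)),
        plot=bool(raw.get("plot", True)),
    )


# ---------------------------------------------------------------------------
# schema validation

SCHEMAS = {
    "encounters": {
        "encounter_id": "any",
        "patient_id": "any",
        "age": "number",
        "loc": "any",
        "admit_time": "datetime",
        "discharge_time": "datetime",
        "pct_value": "number",
        "pct_time": "datetime",
        "ed_discharge": "bool",
        "obstetrics": "bool",
    },
    "administrations": {
        "encounter_id": "any",
        "is_antibiotic": "bool",
        "admin_time": "datetime",
    },
    "prescriptions": {
        "encounter_id": "any",
        "is_antibiotic": "bool",
        "days_supplied": "number",
        "continues_inpatient_regimen": "bool",
    },
}


@dataclass
class SchemaReport:
    path: str
    missing_columns: list[str] = field(default_factory=list)
    violations: list[tuple[int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.missing_columns and not self.violations


def validate_schema(path, expected: Mapping[str, str] | str) -> SchemaReport:
    """Check a CSV against an expected schema plus invariant spot checks.

    ``expected`` is a schema mapping (column -> kind) or the name of a
    built-in schema. Spot checks: non-negative PCT and days supplied,
    admission strictly before discharge, parseable timestamps. Violations
    are reported with their (0-based) row indices.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if isinstance(expected, str):
        expected = SCHEMAS[expected]
    df = pd.read_csv(path)
    report = SchemaReport(path=str(path))
    report.missing_columns = [c for c in expected if c not in df.columns]
    if report.missing_columns:
        return report
    for col, kind in expected.items():
        if kind == "number":
            vals = pd.to_numeric(df[col], errors="coerce")
            for i in df.index[vals.isna() & df[col].notna()]:
                report.violations.append((int(i), f"{col}: not numeric"))
        elif kind == "datetime":
            vals = pd.to_datetime(df[col], errors="coerce")
            for i in df.index[vals.isna()]:
                report.violations.append((int(i), f"{col}: unparseable timestamp"))
    if "pct_value" in df.columns:
        bad = pd.to_numeric(df["pct_value"], errors="coerce") < 0
        for i in df.index[bad]:
            report.violations.append((int(i), "pct_value: negative"))
    if "days_supplied" in df.columns:
        bad = pd.to_numeric(df["days_supplied"], errors="coerce") < 0
        for i in df.index[bad]:
            report.violations.append((int(i), "days_supplied: negative"))
    if {"admit_time", "discharge_time"} <= set(df.columns):
        a = pd.to_datetime(df["admit_time"], errors="coerce")
        d = pd.to_datetime(df["discharge_time"], errors="coerce")
        bad = a.notna() & d.notna() & (a >= d)
        for i in df.index[bad]:
            report.violations.append((int(i), "admit_time not before discharge_time"))
    report.violations.sort()
    return report


# ---------------------------------------------------------------------------
# stages


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.path = outdir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"config_fingerprint": config.fingerprint(), "files": {}}
        self.data["config_fingerprint"] = config.fingerprint()

    def record(self, name: str, path: Path, rows: int | None = None) -> None:
        self.data["files"][name] = {
            "path": str(path.relative_to(self.outdir)),
            "rows": rows,
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _write_csv(df: pd.DataFrame, path: Path, table: str | None = None) -> None:
    df = df.copy()
    for col in TIME_COLUMNS.get(table or "", []):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col]).dt.strftime(ISO)
    df.to_csv(path, index=False)


def _read_csv(path: Path, table: str | None = None) -> pd.DataFrame:
    if not Path(path).exists():
        raise PipelineError(f"missing input file: {path}")
    kwargs = {}
    cols = TIME_COLUMNS.get(table or "", [])
    df = pd.read_csv(path)
    for col in cols:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], errors="coerce")
    return df


def _stage(name):
    def deco(fn):
        def wrapped(cfg: RunConfig, manifest: _Manifest, *a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(cfg, manifest, *a, **kw)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 — annotate with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
            return out

        wrapped.__name__ = fn.__name__
        return wrapped

    return deco


@_stage("generate")
def stage_generate(cfg: RunConfig, manifest: _Manifest):
    tables = generate_cohort(cfg.generator)
    for name, df in tables._asdict().items():
        path = cfg.outdir / f"{name}.csv"
        _write_csv(df, path, name)
        manifest.record(name, path, len(df))
        log.info("stage=generate table=%s rows=%d", name, len(df))
    return tables


@_stage("prep")
def stage_prep(cfg: RunConfig, manifest: _Manifest):
    if cfg.generator is not None or cfg.inputs is None:
        enc = _read_csv(cfg.outdir / "encounters.csv", "encounters")
        adm = _read_csv(cfg.outdir / "administrations.csv", "administrations")
    else:
        enc = _read_csv(cfg.inputs["encounters"], "encounters")
        adm = _read_csv(cfg.inputs["administrations"], "administrations")
    cohort = cohort_prep.apply_exclusions(enc, adm)
    path = cfg.outdir / "eligible_cohort.csv"
    _write_csv(cohort.frame, path, "eligible_cohort")
    manifest.record("eligible_cohort", path, len(cohort.frame))
    audit_path = cfg.outdir / "exclusions_audit.json"
    audit_path.write_text(cohort.audit_json())
    manifest.record("exclusions_audit", audit_path)
    log.info(
        "stage=prep raw=%d eligible=%d excluded=%s",
        cohort.n_raw, len(cohort.frame), cohort.audit_dict,
    )
    return cohort


@_stage("classify")
def stage_classify(cfg: RunConfig, manifest: _Manifest):
    eligible = _read_csv(cfg.outdir / "eligible_cohort.csv", "eligible_cohort")
    if cfg.generator is not None or cfg.inputs is None:
        adm = _read_csv(cfg.outdir / "administrations.csv", "administrations")
        rx = _read_csv(cfg.outdir / "prescriptions.csv")
    else:
        adm = _read_csv(cfg.inputs["administrations"], "administrations")
        rx = _read_csv(cfg.inputs["prescriptions"])
    decisions = course_classifier.classify_cohort(eligible, adm, rx)
    path = cfg.outdir / "decisions.csv"
    _write_csv(decisions, path)
    manifest.record("decisions", path, len(decisions))
    n_full = int(decisions["outcome_full"].sum())
    log.info(
        "stage=classify n=%d full=%d (%.1f%%)",
        len(decisions), n_full, 100 * n_full / max(len(decisions), 1),
    )
    return decisions


def _analysis_frame(cfg: RunConfig) -> pd.DataFrame:
    eligible = _read_csv(cfg.outdir / "eligible_cohort.csv", "eligible_cohort")
    decisions = _read_csv(cfg.outdir / "decisions.csv")
    merged = eligible.merge(decisions, on="encounter_id", how="inner")
    merged["outcome_full"] = merged["outcome_full"].astype(bool)
    return merged


@_stage("rda")
def stage_rda(cfg: RunConfig, manifest: _Manifest):
    cohort = _analysis_frame(cfg)
    grid = rda.sensitivity_grid(
        cohort,
        cutpoints=cfg.cutpoints,
        bandwidths=cfg.bandwidths,
        strata=cfg.strata,
        alpha=cfg.alpha,
        bh_adjust=cfg.bh_adjust,
    )
    path = cfg.outdir / "rda_results.csv"
    grid.to_csv(path, index=False)
    manifest.record("rda_results", path, len(grid))
    txt = cfg.outdir / "rda_table.txt"
    txt.write_text(rda.render_table(grid) + "\n")
    manifest.record("rda_table", txt)
    log.info("stage=rda cells=%d degenerate=%d", len(grid),
             int((grid["flags"].str.contains("degenerate")).sum()))
    return grid


@_stage("roc")
def stage_roc(cfg: RunConfig, manifest: _Manifest):
    cohort = _analysis_frame(cfg)
    curves, skipped = roc_decision.stratified_roc(cohort)
    summary = {"skipped_strata": skipped, "curves": [c.summary() for c in curves]}
    for curve in curves:
        path = cfg.outdir / f"roc_points_{curve.stratum}.csv"
        curve.points_frame().to_csv(path, index=False)
        manifest.record(f"roc_points_{curve.stratum}", path, len(curve.fpr))
        log.info("stage=roc stratum=%s auc=%.3f n=%d",
                 curve.stratum, curve.auc, curve.n_pos + curve.n_neg)
    spath = cfg.outdir / "roc_summary.json"
    spath.write_text(json.dumps(summary, indent=2))
    manifest.record("roc_summary", spath)
    if cfg.plot:
        ppath = cfg.outdir / "roc_curves.png"
        roc_decision.plot_curves(curves, ppath)
        manifest.record("roc_plot", ppath)
    return curves


@_stage("tables")
def stage_tables(cfg: RunConfig, manifest: _Manifest):
    cohort = _analysis_frame(cfg)
    cohort["los_days"] = (
        cohort["discharge_time"] - cohort["admit_time"]
    ).dt.total_seconds() / 86400.0
    cont = [c for c in ("age", "los_days", "pct_value") if c in cohort.columns]
    cat = [c for c in ("sex", "race", "loc", "disposition") if c in cohort.columns]

    outputs = []
    t1 = cohort_stats.build_comparison_table(cohort, "outcome_full", cont, cat)
    outputs.append(("comparison_full_vs_not", t1))
    # near-cut-point exchangeability tables, one per primary cut-point
    for c in cfg.cutpoints:
        h = rda.PRIMARY_BANDWIDTHS.get(c, 0.05)
        (lo, _), (_, hi) = rda.bandwidth_window(c, h)
        sub = cohort[(cohort["pct_value"] >= lo) & (cohort["pct_value"] < hi)].copy()
        sub["side"] = np.where(sub["pct_value"] >= c, "above", "below")
        if sub["side"].nunique() == 2:
            t = cohort_stats.build_comparison_table(sub, "side", cont, cat)
            outputs.append((f"comparison_window_{c:g}", t))
        else:
            log.warning("stage=tables window at %g has a single side; skipped", c)
    for name, table in outputs:
        path = cfg.outdir / f"{name}.csv"
        table.frame.to_csv(path, index=False)
        manifest.record(name, path, len(table.frame))
        (cfg.outdir / f"{name}.txt").write_text(table.render() + "\n")
        manifest.record(f"{name}_txt", cfg.outdir / f"{name}.txt")
    return outputs


STAGES = {
    "generate": stage_generate,
    "prep": stage_prep,
    "classify": stage_classify,
    "rda": stage_rda,
    "roc": stage_roc,
    "tables": stage_tables,
}


def run_pipeline(cfg: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the requested stages (default: all applicable) and return the
    manifest dictionary."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(cfg.outdir, cfg)
    if stages is None:
        stages = (["generate"] if cfg.generator is not None else []) + [
            "prep", "classify", "rda", "roc", "tables",
        ]
    for name in stages:
        if name == "generate" and cfg.generator is None:
            raise PipelineError("stage 'generate' requires a generator config")
        STAGES[name](cfg, manifest)
    return manifest.data
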