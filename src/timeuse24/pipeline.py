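"""End-to-end workflow: simulate -> process -> compose -> regress -> report.

Each stage reads and writes CSV artifacts inside a run directory and
records itself in ``manifest.json`` together with the seed, a hash of
the configuration and content hashes of its outputs.  A stage whose
outputs already exist under the same configuration hash is skipped, so
re-running a pipeline only redoes what changed (epoch simulation is the
slow stage).  Identical configuration + seed reproduces byte-identical
CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accelerometry import AccelConfig, process_cohort
from .coda import (close_composition, compositional_mean,
                   proportional_impute_nonwear, replace_zeros)
from .cohort import CohortSpec, default_outcome_specs, generate_cohort, write_cohort
from .feasibility import FeasibilityCounts, feasibility_metrics
from .power import PowerQuery, required_sample_size
from .regression import (all_reallocation_curves, fit_all_rotations,
                         leading_effects_table, model_diagnostics,
                         plot_reallocation_curves)

log = logging.getLogger("timeuse24.pipeline")

DOMAIN_COLUMNS = ["sleep_min", "sedentary_min", "lpa_min", "mvpa_min"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""

    outdir: str = "timeuse24_run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)       # CohortSpec overrides
    accel: dict = field(default_factory=dict)        # AccelConfig overrides
    outcomes: tuple[str, ...] = ("pcs12", "mcs12")
    covariates: tuple[str, ...] = ()                 # () = unadjusted models
    zero_method: str = "em"
    realloc_grid: tuple[float, float, float] = (-60.0, 60.0, 5.0)
    n_referred: int = 36
    power_queries: tuple[dict, ...] = (
        {"f2": 0.3, "alpha": 0.05, "power": 0.80,
         "n_predictors": 8, "dropout_rate": 0.14},
        {"f2": 0.2, "alpha": 0.05, "power": 0.80,
         "n_predictors": 8, "dropout_rate": 0.14},
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("outcomes", "covariates", "realloc_grid", "power_queries"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["power_queries"] = list(d["power_queries"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(seed=self.seed, **self.cohort)

    def accel_config(self) -> AccelConfig:
        accel = dict(self.accel)
        for key in ("cutpoints",):
            if key in accel and isinstance(accel[key], list):
                accel[key] = tuple(accel[key])
        return AccelConfig(**accel)

    def realloc_deltas(self) -> np.ndarray:
        lo, hi, step = self.realloc_grid
        return np.arange(lo, hi + step / 2.0, step)


# ---------------------------------------------------------------------------
# manifest helpers

def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_manifest(outdir: Path) -> dict:
    path = outdir / "manifest.json"
    if path.exists():
        return json.loads(path.read_text())
    return {}


def _save_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))


def _stage_current(manifest: dict, stage: str, cfg_hash: str,
                   outdir: Path) -> bool:
    entry = manifest.get("stages", {}).get(stage)
    if not entry or entry.get("config_hash") != cfg_hash:
        return False
    return all((outdir / p).exists() for p in entry.get("outputs", []))


def _record_stage(manifest: dict, stage: str, cfg_hash: str, outdir: Path,
                  outputs: list[str], elapsed: float) -> None:
    manifest.setdefault("stages", {})[stage] = {
        "config_hash": cfg_hash,
        "outputs": outputs,
        "output_hashes": {p: _file_hash(outdir / p) for p in outputs
                          if (outdir / p).exists()},
        "elapsed_s": round(elapsed, 2),
    }


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: PipelineConfig, force: bool = False) -> dict:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(outdir)
    h = cfg.config_hash()
    if not force and _stage_current(manifest, "simulate", h, outdir):
        log.info("simulate: up to date, skipping")
        return manifest
    t0 = time.perf_counter()
    tables = generate_cohort(cfg.cohort_spec(), default_outcome_specs())
    write_cohort(tables, outdir / "simulated")
    outputs = [f"simulated/{n}.csv" for n in
               ("epochs", "diary", "metadata", "truth_participants",
                "truth_days", "truth_outcome_params")]
    manifest.update(seed=cfg.seed, config_hash=h, config=cfg.to_dict(),
                    package_version=__version__)
    _record_stage(manifest, "simulate", h, outdir, outputs,
                  time.perf_counter() - t0)
    _save_manifest(outdir, manifest)
    log.info("simulate: %d participants x %d days",
             cfg.cohort_spec().n_participants, cfg.cohort_spec().n_days)
    return manifest


def stage_process(cfg: PipelineConfig, force: bool = False) -> dict:
    outdir = Path(cfg.outdir)
    manifest = _load_manifest(outdir)
    h = cfg.config_hash()
    if not force and _stage_current(manifest, "process", h, outdir):
        log.info("process: up to date, skipping")
        return manifest
    t0 = time.perf_counter()
    epochs = pd.read_csv(outdir / "simulated" / "epochs.csv")
    diary = pd.read_csv(outdir / "simulated" / "diary.csv",
                        keep_default_na=False)
    daily, participants = process_cohort(epochs, diary, cfg.accel_config())
    daily.to_csv(outdir / "daily_summaries.csv", index=False)
    participants.to_csv(outdir / "participant_time_use.csv", index=False)

    table2 = summarize_time_use_means(participants, cfg.zero_method)
    table2.to_csv(outdir / "table2_means.csv", index=False)
    _plot_daily_bars(daily, outdir / "daily_timeuse_bars.png")
    outputs = ["daily_summaries.csv", "participant_time_use.csv",
               "table2_means.csv", "daily_timeuse_bars.png"]
    _record_stage(manifest, "process", h, outdir, outputs,
                  time.perf_counter() - t0)
    _save_manifest(outdir, manifest)
    log.info("process: %d days, %d included participants",
             len(daily), len(participants))
    return manifest


def summarize_time_use_means(participants: pd.DataFrame,
                             zero_method: str = "em") -> pd.DataFrame:
    """Three flavours of cohort-mean daily minutes.

    Arithmetic means of the weighted participant values (with non-wear
    as a fifth part), arithmetic means after proportionally imputing
    each participant's non-wear into the behaviours, and the
    compositional (geometric) mean of the imputed compositions after
    zero replacement.  Each column's behaviours (plus non-wear where
    carried) sum to 1440.
    """
    if participants.empty:
        return pd.DataFrame(columns=["domain", "arithmetic_with_nonwear",
                                     "arithmetic_imputed", "compositional"])
    parts = participants[DOMAIN_COLUMNS].to_numpy(float)
    nonwear = participants["nonwear_min"].to_numpy(float)
    arith = parts.mean(axis=0)
    imputed = proportional_impute_nonwear(parts, nonwear)
    arith_imp = imputed.mean(axis=0)
    if (imputed[:, 3] == 0).any():
        positive = replace_zeros(imputed, part="mvpa", method=zero_method)
    else:
        positive = imputed
    comp_mean = compositional_mean(close_composition(positive))
    rows = []
    for i, name in enumerate(["sleep", "sedentary", "lpa", "mvpa"]):
        rows.append({"domain": name,
                     "arithmetic_with_nonwear": round(arith[i], 2),
                     "arithmetic_imputed": round(arith_imp[i], 2),
                     "compositional": round(comp_mean[i], 2)})
    rows.append({"domain": "nonwear",
                 "arithmetic_with_nonwear": round(float(nonwear.mean()), 2),
                 "arithmetic_imputed": np.nan, "compositional": np.nan})
    return pd.DataFrame(rows)


def _plot_daily_bars(daily: pd.DataFrame, path: Path) -> None:
    """Stacked per-day time-use bars — the visual-inspection surrogate."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if daily.empty:
        return
    pids = sorted(daily["participant_id"].unique())[:12]
    sub = daily[daily["participant_id"].isin(pids)]
    fig, ax = plt.subplots(figsize=(10, 4))
    x = np.arange(len(sub))
    bottom = np.zeros(len(sub))
    for col, color in zip(DOMAIN_COLUMNS + ["nonwear_min"],
                          ["#4c72b0", "#dd8452", "#55a868", "#c44e52", "#8c8c8c"]):
        vals = sub[col].to_numpy(float)
        ax.bar(x, vals, bottom=bottom, width=0.9, label=col.replace("_min", ""),
               color=color)
        bottom += vals
    ax.set(xlabel="participant-day", ylabel="minutes",
           title="Daily time use (first 12 participants)")
    ax.legend(ncol=5, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _encode_covariates(metadata: pd.DataFrame,
                       names: tuple[str, ...]) -> pd.DataFrame | None:
    if not names:
        return None
    cols = {}
    for name in names:
        col = metadata[name]
        if col.dtype == object:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True,
                                     dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
        else:
            cols[name] = col.to_numpy(float)
    return pd.DataFrame(cols)


def stage_analyze(cfg: PipelineConfig, force: bool = False) -> dict:
    outdir = Path(cfg.outdir)
    manifest = _load_manifest(outdir)
    h = cfg.config_hash()
    if not force and _stage_current(manifest, "analyze", h, outdir):
        log.info("analyze: up to date, skipping")
        return manifest
    t0 = time.perf_counter()
    participants = pd.read_csv(outdir / "participant_time_use.csv")
    metadata = pd.read_csv(outdir / "simulated" / "metadata.csv")
    outputs: list[str] = []
    n_covariate_cols = 0
    if not participants.empty:
        cov_probe = _encode_covariates(
            participants.merge(metadata, on="participant_id"), cfg.covariates)
        n_covariate_cols = 0 if cov_probe is None else cov_probe.shape[1]
    # intercept + 3 ilr coordinates + covariates, plus one residual df
    min_n = 5 + n_covariate_cols
    if len(participants) < min_n:
        log.warning("analyze: %d included participants, fewer than the %d "
                    "needed to fit the model; writing empty outputs",
                    len(participants), min_n)
        pd.DataFrame(columns=["outcome", "domain", "beta", "se", "p_value"]) \
            .to_csv(outdir / "table4_effects.csv", index=False)
        outputs.append("table4_effects.csv")
    else:
        merged = participants.merge(metadata, on="participant_id", how="inner")
        parts = merged[DOMAIN_COLUMNS].to_numpy(float)
        imputed = proportional_impute_nonwear(
            parts, merged["nonwear_min"].to_numpy(float))
        comps = replace_zeros(imputed, part="mvpa", method=cfg.zero_method) \
            if (imputed[:, 3] == 0).any() else imputed
        comps = close_composition(comps)
        reference = compositional_mean(comps)
        covariates = _encode_covariates(merged, cfg.covariates)
        effect_tables, diag = [], {}
        for outcome in cfg.outcomes:
            y = merged[outcome].to_numpy(float)
            results = fit_all_rotations(comps, y, covariates, outcome)
            effect_tables.append(leading_effects_table(results))
            curves = all_reallocation_curves(results[0], reference,
                                             cfg.realloc_deltas())
            curve_rows = []
            for domain, curve in curves.items():
                tab = curve.table.copy()
                tab.insert(0, "domain", domain)
                curve_rows.append(tab)
            curve_df = pd.concat(curve_rows, ignore_index=True)
            curve_df.insert(0, "outcome", outcome)
            curve_path = f"reallocation_{outcome}.csv"
            curve_df.to_csv(outdir / curve_path, index=False)
            png_path = f"reallocation_{outcome}.png"
            plot_reallocation_curves(curves, outdir / png_path, outcome)
            diag[outcome] = model_diagnostics(results[0], outdir,
                                              prefix=f"{outcome}")
            outputs += [curve_path, png_path, f"{outcome}_diagnostics.png"]
        table4 = pd.concat(effect_tables, ignore_index=True)
        table4.to_csv(outdir / "table4_effects.csv", index=False)
        (outdir / "diagnostics.json").write_text(
            json.dumps(diag, indent=2, default=str))
        outputs += ["table4_effects.csv", "diagnostics.json"]
    _record_stage(manifest, "analyze", h, outdir, outputs,
                  time.perf_counter() - t0)
    _save_manifest(outdir, manifest)
    return manifest


def stage_power(cfg: PipelineConfig, force: bool = False) -> dict:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(outdir)
    h = cfg.config_hash()
    if not force and _stage_current(manifest, "power", h, outdir):
        log.info("power: up to date, skipping")
        return manifest
    t0 = time.perf_counter()
    rows = []
    for q in cfg.power_queries:
        query = PowerQuery(**q)
        n_analyzed, n_recruited = required_sample_size(query)
        rows.append({**q, "n_analyzed": n_analyzed, "n_recruited": n_recruited})
    pd.DataFrame(rows).to_csv(outdir / "power_report.csv", index=False)
    _record_stage(manifest, "power", h, outdir, ["power_report.csv"],
                  time.perf_counter() - t0)
    _save_manifest(outdir, manifest)
    return manifest


def stage_feasibility(cfg: PipelineConfig, force: bool = False) -> dict:
    outdir = Path(cfg.outdir)
    manifest = _load_manifest(outdir)
    h = cfg.config_hash()
    if not force and _stage_current(manifest, "feasibility", h, outdir):
        log.info("feasibility: up to date, skipping")
        return manifest
    t0 = time.perf_counter()
    participants = pd.read_csv(outdir / "participant_time_use.csv")
    n_enrolled = cfg.cohort_spec().n_participants
    n_completed = len(participants)
    counts = FeasibilityCounts(
        n_referred=max(cfg.n_referred, n_enrolled),
        n_enrolled=n_enrolled,
        n_completed=n_completed,
        n_cards_provided=n_enrolled,
        n_cards_returned=n_enrolled,
        n_monitors_dispensed=n_enrolled,
        n_monitors_returned=n_enrolled,
        n_monitors_extracted=n_enrolled,
        nonwear_min_per_day=participants["nonwear_min"].tolist()
        if not participants.empty else [],
    )
    metrics = feasibility_metrics(counts)
    rows = [{"metric": k, "value": (v if not isinstance(v, dict)
                                    else v["formatted"])}
            for k, v in metrics.items()]
    pd.DataFrame(rows).to_csv(outdir / "table3_feasibility.csv", index=False)
    _record_stage(manifest, "feasibility", h, outdir,
                  ["table3_feasibility.csv"], time.perf_counter() - t0)
    _save_manifest(outdir, manifest)
    return manifest


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> dict:
    """Run every stage in order; returns the final manifest."""
    stage_simulate(cfg, force)
    stage_process(cfg, force)
    stage_analyze(cfg, force)
    stage_power(cfg, force)
    stage_feasibility(cfg, force)
    return make_report(cfg)


# ---------------------------------------------------------------------------
# report

def _markdown_table(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    out = ["| " + " | ".join(cols) + " |",
           "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        out.append("| " + " | ".join("" if pd.isna(v) else str(v)
                                     for v in row) + " |")
    return "\n".join(out)


def _embed_csv(path: Path, lines: list[str], warnings: list[str]) -> None:
    if not path.exists():
        warnings.append(f"missing artifact: {path.name}")
        return
    df = pd.read_csv(path)
    if df.empty:
        warnings.append(f"empty artifact: {path.name}")
        return
    lines.append(_markdown_table(df))
    lines.append("")


def make_report(cfg: PipelineConfig) -> dict:
    """Assemble a Markdown report from the manifest's artifacts.

    The report is regenerable from the manifest alone; missing artifacts
    are listed as warnings and the report is still produced.
    """
    outdir = Path(cfg.outdir)
    manifest = _load_manifest(outdir)
    warnings: list[str] = []
    lines = ["# 24-h time-use analysis report", "",
             f"Seed: {manifest.get('seed', cfg.seed)}  ",
             f"Config hash: {manifest.get('config_hash', cfg.config_hash())}  ",
             f"Package version: {manifest.get('package_version', __version__)}",
             ""]
    lines.append("## Cohort time-use means (min/day)")
    lines.append("")
    _embed_csv(outdir / "table2_means.csv", lines, warnings)
    lines.append("## Time use vs outcomes (leading ilr effects)")
    lines.append("")
    _embed_csv(outdir / "table4_effects.csv", lines, warnings)
    lines.append("## One-for-remaining reallocation curves")
    lines.append("")
    for outcome in cfg.outcomes:
        png = outdir / f"reallocation_{outcome}.png"
        if png.exists():
            lines.append(f"![{outcome} reallocations]({png.name})")
        else:
            warnings.append(f"missing artifact: {png.name}")
    lines.append("")
    lines.append("## Feasibility metrics")
    lines.append("")
    _embed_csv(outdir / "table3_feasibility.csv", lines, warnings)
    lines.append("## Power / required sample size")
    lines.append("")
    _embed_csv(outdir / "power_report.csv", lines, warnings)
    if warnings:
        lines.append("## Warnings")
        lines.append("")
        lines += [f"- {w}" for w in warnings]
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))
    manifest.setdefault("stages", {})["report"] = {
        "config_hash": cfg.config_hash(), "outputs": ["report.md"],
        "warnings": warnings}
    _save_manifest(outdir, manifest)
    return manifest
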