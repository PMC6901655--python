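"""Orchestration: simulate -> fit-nh3 -> fdg-regional -> work -> stats.

Each stage reads and writes only the declared file interfaces under the run
directory, so stages can be re-run independently on persisted intermediates.
A run is fully determined by its configuration and seed; the report carries
the seed and a hash of the canonical configuration for provenance.

The run can emulate the availability pattern of a real cohort (a few
patients missing an FDG scan, an ammonia scan, or the follow-up
echocardiogram); statistics then carry per-metric Ns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from dyssync import __version__ as _pkg_version
from dyssync import cohort_stats, fdg_regional, myocardial_work, nh3_kinetics
from dyssync import synthetic_cohort as sc

log = logging.getLogger("dyssync")

STAGES = ("simulate", "fit-nh3", "fdg-regional", "work", "stats")


@dataclass(frozen=True)
class MissingnessConfig:
    """Per-modality counts of patients excluded at random, as in real cohorts."""

    emulate: bool = True
    n_missing_fdg: int = 3
    n_missing_nh3: int = 1
    n_missing_post_echo: int = 2


@dataclass(frozen=True)
class RunConfig:
    cohort: sc.CohortConfig = field(default_factory=sc.CohortConfig)
    outdir: str = "run"
    stages: tuple[str, ...] = STAGES
    report_format: str = "json"  # json | markdown
    missing: MissingnessConfig = field(default_factory=MissingnessConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise ValueError("stages must follow the canonical order")
        if self.report_format not in ("json", "markdown"):
            raise ValueError("report_format must be 'json' or 'markdown'")


def config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    cohort = sc.generate_cohort(config.cohort)
    sc.write_cohort(cohort, outdir / "cohort")
    log.info("simulate: wrote %d patients", len(cohort.patients))


def stage_fit_nh3(outdir: Path) -> None:
    cohort_dir = outdir / "cohort"
    manifest = sc.read_manifest(cohort_dir / "manifest.json")
    aif_t, wb, mf = nh3_kinetics.read_aif_csv(cohort_dir / "aif.csv")
    mbf_dir = outdir / "mbf"
    mbf_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for entry in manifest["patients"]:
        pid = entry["id"]
        tacs = nh3_kinetics.read_tacs_csv(cohort_dir / f"{pid}_tacs.csv")
        fits = nh3_kinetics.fit_patient(tacs, aif_t, wb, mf)
        nh3_kinetics.write_fit_json(fits, mbf_dir / f"{pid}.json")
        row = {"id": pid}
        for wall, fr in fits.items():
            row[f"mbf_{wall}"] = fr.mbf
        row["mbf_slr"] = nh3_kinetics.mbf_slr(
            fits["septal"].mbf, fits["lateral"].mbf
        )
        rows.append(row)
        log.debug("fit-nh3: %s done", pid)
    pd.DataFrame(rows).to_csv(outdir / "mbf.csv", index=False)
    log.info("fit-nh3: fitted %d patients", len(rows))


def stage_fdg(outdir: Path) -> None:
    cohort_dir = outdir / "cohort"
    manifest = sc.read_manifest(cohort_dir / "manifest.json")
    rows = []
    for entry in manifest["patients"]:
        pid = entry["id"]
        pmap = fdg_regional.read_polar_map_csv(cohort_dir / f"{pid}_polarmap.csv")
        res = fdg_regional.analyze_polar_map(pmap)
        rows.append(
            {
                "id": pid,
                "suv_septal": res["septal"],
                "suv_lateral": res["lateral"],
                "suv_anterior": res["anterior"],
                "suv_inferior": res["inferior"],
                "fdg_slr": res["fdg_slr"],
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "fdg.csv", index=False)
    log.info("fdg-regional: %d maps", len(rows))


def stage_work(outdir: Path) -> None:
    cohort_dir = outdir / "cohort"
    manifest = sc.read_manifest(cohort_dir / "manifest.json")
    rows = []
    for entry in manifest["patients"]:
        pid = entry["id"]
        traces = myocardial_work.read_traces(
            cohort_dir / f"{pid}_traces.csv", cohort_dir / f"{pid}_traces.json"
        )
        res = myocardial_work.analyze_traces(traces)
        rows.append(
            {
                "id": pid,
                "work_septal": res.regional["septal"],
                "work_lateral": res.regional["lateral"],
                "work_anterior": res.regional.get("anterior", np.nan),
                "work_inferior": res.regional.get("inferior", np.nan),
                "wasted_septal": res.wasted_septal,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "work.csv", index=False)
    log.info("work: %d patients", len(rows))


def _apply_missingness(
    metrics: pd.DataFrame, missing: MissingnessConfig, seed: int
) -> pd.DataFrame:
    if not missing.emulate:
        return metrics
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD15]))
    metrics = metrics.copy()
    n = len(metrics)
    plans = (
        (missing.n_missing_fdg, ["suv_septal", "suv_lateral", "suv_anterior",
                                 "suv_inferior", "fdg_slr"]),
        (missing.n_missing_nh3, ["mbf_septal", "mbf_lateral", "mbf_anterior",
                                 "mbf_inferior", "mbf_slr"]),
        (missing.n_missing_post_echo, ["delta_esv"]),
    )
    for k, cols in plans:
        k = min(k, n)
        idx = rng.choice(n, size=k, replace=False)
        for c in cols:
            if c in metrics.columns:
                metrics.loc[metrics.index[idx], c] = np.nan
    return metrics


def stage_stats(config: RunConfig, outdir: Path) -> dict:
    manifest = sc.read_manifest(outdir / "cohort" / "manifest.json")
    base = pd.DataFrame(
        [
            {
                "id": e["id"],
                "group": "dys" if e["dyssynchrony"] else "nondys",
                "delta_esv": cohort_stats.delta_esv(e["esv_pre"], e["esv_post"]),
                "reader_a": e["reader_labels"][0],
                "reader_b": e["reader_labels"][1],
            }
            for e in manifest["patients"]
        ]
    )
    for stem in ("mbf", "fdg", "work"):
        path = outdir / f"{stem}.csv"
        if path.exists():
            base = base.merge(pd.read_csv(path), on="id", how="left")
    metrics = _apply_missingness(base, config.missing, config.cohort.seed)
    metrics.to_csv(outdir / "metrics.csv", index=False)

    report = cohort_stats.cohort_report(metrics)
    report["provenance"] = {
        "seed": config.cohort.seed,
        "config_hash": config_hash(config),
        "package_version": _pkg_version,
        "stages": list(config.stages),
        "n_dys": int((base["group"] == "dys").sum()),
        "n_nondys": int((base["group"] == "nondys").sum()),
    }
    cohort_stats.write_report_json(report, outdir / "report.json")
    if config.report_format == "markdown":
        (outdir / "report.md").write_text(cohort_stats.report_markdown(report))
    log.info("stats: report written")
    return report


# ---------------------------------------------------------------------------
# run / replicate


def run(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the report (or a
    partial-status dict when the stats stage is not requested)."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": {"seed": config.cohort.seed,
                                   "config_hash": config_hash(config),
                                   "stages": list(config.stages)}}
    for stage in config.stages:
        if stage == "simulate":
            stage_simulate(config, outdir)
        elif stage == "fit-nh3":
            stage_fit_nh3(outdir)
        elif stage == "fdg-regional":
            stage_fdg(outdir)
        elif stage == "work":
            stage_work(outdir)
        elif stage == "stats":
            report = stage_stats(config, outdir)
    return report


def headline_metrics(report: dict) -> dict[str, float]:
    """Flatten a run report into scalar headline metrics."""
    out: dict[str, float] = {}
    for grp, entry in report.get("groups", {}).items():
        for metric, s in entry.items():
            if isinstance(s, dict) and "mean" in s:
                out[f"{grp}.{metric}.mean"] = s["mean"]
                out[f"{grp}.{metric}.sd"] = s["sd"]
    for name, cr in report.get("correlations", {}).items():
        out[f"corr.{name}.r"] = cr["r"]
    agreement = report.get("reader_agreement", {})
    if "kappa" in agreement:
        out["kappa"] = agreement["kappa"]
    return out


def replicate(config: RunConfig, n_replicates: int) -> dict:
    """Run `n_replicates` full pipelines with seeds seed+0..seed+n-1 and
    aggregate the mean and SD of every headline metric across replicates."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base_out = Path(config.outdir)
    per_rep: list[dict[str, float]] = []
    for i in range(n_replicates):
        rep_cfg = dataclasses.replace(
            config,
            cohort=dataclasses.replace(config.cohort, seed=config.cohort.seed + i),
            outdir=str(base_out / f"rep_{i:02d}"),
        )
        per_rep.append(headline_metrics(run(rep_cfg)))
    keys = sorted(set().union(*per_rep))
    agg = {}
    for k in keys:
        vals = np.array([r[k] for r in per_rep if k in r], dtype=float)
        agg[k] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "n_replicates": int(len(vals)),
        }
    result = {
        "n_replicates": n_replicates,
        "base_seed": config.cohort.seed,
        "metrics": agg,
    }
    cohort_stats.write_report_json(result, base_out / "replicate_report.json")
    return result
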