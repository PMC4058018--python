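"""End-to-end orchestration: count slides, enumerate per mL, report stats.

These functions sit behind the command-line interface; each writes its
outputs (CSV/JSON plus a provenance block with config hash and seed) under
the configured output directory and returns the in-memory results.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .enumeration import SampleRecord, per_ml
from .imaging import CountResult, count_slide
from .io import read_slide
from .cohort import (
    cox_log_count,
    load_cohort,
    logrank,
    mann_whitney_exact,
    summarize_cohort,
)

log = logging.getLogger("cmcount")

MANIFEST_COLUMNS = [
    "sample_id", "fraction", "total_cells", "cells_per_slide", "blood_volume_ml",
]


def _write_provenance(out_dir: Path, config: RunConfig) -> None:
    (out_dir / "provenance.json").write_text(
        json.dumps(
            {
                "package": "cmcount",
                "version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.seed,
            },
            indent=1,
        )
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample manifest not found: {path}")
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    return df


def run_count(config: RunConfig) -> tuple[CountResult, pd.DataFrame]:
    """Count a slide and extrapolate per-mL concentrations for its samples.

    Writes per-object CSV, the four-class tally CSV (with Poisson CV%),
    the per-sample nCMC/mL CSV and a provenance block.
    """
    if config.slide_dir is None:
        raise ValueError("config has no slide_dir")
    manifest = read_manifest(config.manifest) if config.manifest else None

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    slide = read_slide(config.slide_dir)
    log.info("counting slide %s (%d FOVs)", config.slide_dir, slide.n_fov)
    result = count_slide(slide, config.imaging, out_dir=out_dir / "overlays")
    sc = result.slide_count
    log.info(
        "thresholds used: t_red=%.1f t_green=%.1f (%s mode)",
        result.thresholds.t_red, result.thresholds.t_green, result.thresholds.mode,
    )

    result.cells.to_csv(out_dir / "objects.csv", index=False)
    tally = pd.DataFrame(
        [
            {
                "n_cmc_slide": sc.n_cmc_slide,
                "n_leuko_slide": sc.n_leuko_slide,
                "n_dual": sc.n_dual,
                "n_null": sc.n_null,
                "n_debris": sc.n_debris,
                "n_border": sc.n_border,
                "cv_percent": sc.cv_percent,
                "t_red": result.thresholds.t_red,
                "t_green": result.thresholds.t_green,
                "threshold_mode": result.thresholds.mode,
            }
        ]
    )
    tally.to_csv(out_dir / "tally.csv", index=False)

    per_sample = pd.DataFrame()
    if manifest is not None:
        rows = []
        for rec in manifest.itertuples(index=False):
            sample = SampleRecord(
                sample_id=str(rec.sample_id),
                fraction=str(rec.fraction),
                total_cells_in_fraction=float(rec.total_cells),
                cells_per_slide=float(rec.cells_per_slide),
                blood_volume_ml=float(rec.blood_volume_ml),
            )
            conc = per_ml(sc.n_cmc_slide, sample)
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "fraction": sample.fraction,
                    "n_cmc_slide": sc.n_cmc_slide,
                    "cv_percent": sc.cv_percent,
                    "n_cmc_ml": round(conc),
                }
            )
        per_sample = pd.DataFrame(rows)
        per_sample.to_csv(out_dir / "per_ml.csv", index=False)

    _write_provenance(out_dir, config)
    return result, per_sample


def run_cohort(
    config: RunConfig,
    patients: str | Path | None = None,
    healthy=None,
    dichotomy_cmc_ml: float = 100.0,
) -> dict:
    """Cohort statistics report: summary, Mann-Whitney, Cox (both log bases),
    and log-rank on the count dichotomy.  Uses the packaged melanoma cohort
    when no patient CSV is given."""
    if patients is None:
        df = load_cohort()
    else:
        patients = Path(patients)
        if not patients.exists():
            raise FileNotFoundError(f"patient table not found: {patients}")
        df = pd.read_csv(patients)
        required = {"survival_months", "alive_at_analysis", "n_cmc_ml"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"patient table {patients} lacks columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError(f"patient table {patients} is empty")
        df["alive_at_analysis"] = df["alive_at_analysis"].astype(bool)

    report: dict = {"summary": summarize_cohort(df)}

    if healthy is not None:
        u, p = mann_whitney_exact(df["n_cmc_ml"], healthy)
        report["mann_whitney_vs_healthy"] = {"U": u, "p": p}

    for base in ("ln", "log10"):
        fit = cox_log_count(df, base=base)
        report[f"cox_{base}"] = {
            "beta": fit.beta,
            "hazard_ratio": fit.hazard_ratio,
            "ci95": list(fit.ci95),
            "p": fit.p,
            "n_events": fit.n_events,
        }

    events = ~df["alive_at_analysis"].to_numpy()
    group_high = df["n_cmc_ml"].to_numpy() > dichotomy_cmc_ml
    if events.any() and 0 < group_high.sum() < len(df):
        chi2, p = logrank(df["survival_months"], events, group_high)
        report["logrank_dichotomized"] = {
            "cut_cmc_ml": dichotomy_cmc_ml, "chi2": chi2, "p": p,
        }

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "cohort_report.json").write_text(json.dumps(report, indent=1))
    lines = [f"cohort of {report['summary']['n']} patients"]
    s = report["summary"]
    lines.append(
        f"median {s['median_cmc_ml']:.0f} CMC/mL "
        f"(range {s['min_cmc_ml']:.0f}-{s['max_cmc_ml']:.0f})"
    )
    c = report["cox_ln"]
    lines.append(
        f"Cox (ln counts): HR {c['hazard_ratio']:.2f} "
        f"CI ({c['ci95'][0]:.2f}, {c['ci95'][1]:.2f}) p={c['p']:.2f}"
    )
    (out_dir / "cohort_report.txt").write_text("\n".join(lines) + "\n")
    _write_provenance(out_dir, config)
    return report


def run_demo(out_dir: str | Path, seed: int = 0) -> dict:
    """Small end-to-end demonstration on a synthetic slide.

    Generates a 10-FOV slide with known composition, counts it, extrapolates
    to CMC/mL, and returns the key numbers (also printed by the CLI).
    """
    from .synthetic import SceneSpec, make_slide
    from .io import write_slide
    from .enumeration import SampleRecord

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = SceneSpec(n_cmc=25, n_leuko=400, n_dual=5, n_debris=20, seed=seed)
    slide, truth = make_slide(spec, n_fov=10)
    slide_dir = write_slide(slide, out_dir / "slide")
    truth.to_csv(out_dir / "slide" / "ground_truth.csv", index=False)

    config = RunConfig(slide_dir=str(slide_dir), out_dir=str(out_dir), seed=seed)
    result = count_slide(read_slide(slide_dir), config.imaging,
                         out_dir=out_dir / "overlays")
    sc = result.slide_count
    sample = SampleRecord(sample_id="demo", fraction="Eluate",
                          total_cells_in_fraction=2_500_000,
                          cells_per_slide=50_000, blood_volume_ml=10.0)
    demo = {
        "true_cmc": int((truth["true_class"] == "cmc").sum()),
        "counted_cmc": sc.n_cmc_slide,
        "counted_leuko": sc.n_leuko_slide,
        "counted_dual": sc.n_dual,
        "counted_debris": sc.n_debris,
        "cv_percent": sc.cv_percent,
        "cmc_per_ml": round(per_ml(sc.n_cmc_slide, sample)),
        "t_red": result.thresholds.t_red,
        "t_green": result.thresholds.t_green,
    }
    (out_dir / "demo.json").write_text(json.dumps(demo, indent=1))
    _write_provenance(out_dir, config)
    return demo
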