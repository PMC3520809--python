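"""Pipeline orchestration: generate -> indices -> function -> histology -> stats.

Stages communicate through plain CSV/JSON files in a dataset directory, so
each stage can be re-run and audited independently:

``run_generate``
    writes the synthetic dataset (tables, IBS traces, phantom references,
    histology fields, truth) plus a run manifest.
``run_analyze``
    computes UTC indices from the traces, echo function from the M-mode
    table, collagen percentages from the histology fields, then runs the
    statistical chain and writes ``summary_table.csv``, ``betas.csv``,
    ``correlations.csv``, ``roc.csv``, ``report.json`` and plots.

Datasets written with ``write_assets=False`` carry the exam-level values but
no raw fixtures; the analysis then consumes the tabulated values directly
(the fast path used for multi-seed statistical studies).

All randomness flows from a single seed through named substreams; numeric
outputs are deterministic given the dataset and options. Logs go to stderr
and are never interleaved with numeric outputs.
"""

from __future__ import annotations

import json
import logging
import re
import time
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, generate_cohort, write_cohort
from .config import GeneratorConfig
from .echo import MModeMeasurement, echo_function
from .errors import InputError
from .histology import batch_threshold, quantify_heart
from .stats import (
    ROCResult,
    betas_by_animal,
    categorical_test,
    derive_threshold,
    kruskal_wallis,
    roc_analysis,
    spearman,
    summarize_groups,
)
from .utc import IBSTrace, compute_indices

log = logging.getLogger("cardiotox_utc")

#: Variables entering the statistical chain, with the direction in which
#: they move with disease (+1: increases, -1: decreases).
MARKER_ORIENTATION = {"cc_ibs": +1, "mcv": -1, "lvef_pct": -1, "sf_pct": -1}


# ---------------------------------------------------------------------------
# generate


def run_generate(
    config: GeneratorConfig | str | Path | None,
    seed: int,
    out_dir: str | Path,
    write_assets: bool = True,
) -> Path:
    """Generate a dataset directory from a config (path or object) and seed."""
    if config is None:
        config = GeneratorConfig()
    elif not isinstance(config, GeneratorConfig):
        config = GeneratorConfig.from_json(config)
    t0 = time.time()
    cohort = generate_cohort(config, seed=seed)
    out = write_cohort(cohort, out_dir, write_assets=write_assets)
    manifest = {
        "stage": "generate",
        "version": __version__,
        "seed": seed,
        "config_hash": config.content_hash(),
        "write_assets": write_assets,
        "n_animals": len(cohort.animals),
        "group_sizes": cohort.group_sizes(),
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("generate: %d animals -> %s (%.2fs)", len(cohort.animals), out, manifest["elapsed_s"])
    return out


# ---------------------------------------------------------------------------
# per-stage readers/computations


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"{stage} stage input missing: {path}")
    return path


def utc_stage(data_dir: Path, config: GeneratorConfig, linear_power: bool = False) -> pd.DataFrame:
    """CC-IBS and MCV per exam, from trace files if present, else from records."""
    traces = data_dir / "traces"
    if traces.exists():
        rows = []
        for tpath in sorted(traces.glob("*.csv")):
            m = re.match(r"(\d+)_([\d.]+)\.csv$", tpath.name)
            if not m:
                continue
            animal_id, dose = int(m.group(1)), float(m.group(2))
            ppath = _require(data_dir / "phantom" / tpath.name, "utc (phantom reference)")
            tissue = IBSTrace.from_csv(
                tpath, depth_cm=config.depth_cm, heart_rate_bpm=config.heart_rate_bpm
            )
            phantom = IBSTrace.from_csv(
                ppath,
                depth_cm=config.depth_cm,
                heart_rate_bpm=config.heart_rate_bpm,
                source="phantom",
            )
            idx = compute_indices(tissue, phantom, linear_power=linear_power)
            rows.append(
                {
                    "animal_id": animal_id,
                    "dose_mg_per_kg": dose,
                    "cc_ibs": idx.cc_ibs,
                    "mcv": idx.mcv,
                    "n_cycles_used": idx.n_cycles_used,
                }
            )
        return pd.DataFrame(rows).sort_values(["dose_mg_per_kg", "animal_id"], ignore_index=True)
    records = pd.read_csv(_require(data_dir / "records.csv", "utc"))
    log.info("utc: no trace fixtures, using tabulated exam values")
    out = records[["animal_id", "dose_mg_per_kg", "cc_ibs", "mcv"]].copy()
    out["n_cycles_used"] = 3
    return out


def echo_stage(data_dir: Path) -> pd.DataFrame:
    """Teichholz LVEF and SF per exam from the per-cycle M-mode table."""
    mmode = pd.read_csv(_require(data_dir / "mmode.csv", "echo function"))
    rows = []
    for (animal_id, dose), grp in mmode.groupby(["animal_id", "dose_mg_per_kg"], sort=True):
        cycles = [
            MModeMeasurement(
                lvedd_cm=r.lvedd_cm,
                lvesd_cm=r.lvesd_cm,
                ivs_cm=r.ivs_cm,
                pw_cm=r.pw_cm,
                heart_rate_bpm=r.hr_bpm,
                cycle_index=int(r.cycle),
            )
            for r in grp.itertuples()
        ]
        res = echo_function(cycles)
        rows.append(
            {
                "animal_id": int(animal_id),
                "dose_mg_per_kg": float(dose),
                "lvef_pct": res.lvef_pct,
                "sf_pct": res.sf_pct,
                "edv_ml": res.edv_ml,
                "esv_ml": res.esv_ml,
            }
        )
    return pd.DataFrame(rows).sort_values(["dose_mg_per_kg", "animal_id"], ignore_index=True)


def histology_stage(data_dir: Path, threshold: Optional[float] = None) -> pd.DataFrame:
    """Heart-level collagen percentages.

    Segments the stained field images when present; datasets without image
    fixtures fall back to the tabulated terminal collagen values. Returns an
    empty frame when the dataset has no histology at all.
    """
    hearts_path = data_dir / "hearts.csv"
    hearts = pd.read_csv(hearts_path) if hearts_path.exists() else pd.DataFrame()
    hist_dir = data_dir / "histology"
    if hist_dir.exists():
        import imageio.v3 as iio

        rows = []
        by_animal: Dict[int, list] = {}
        for p in sorted(hist_dir.glob("*_field*.png")):
            if p.stem.endswith("_mask"):
                continue
            m = re.match(r"(\d+)_field(\d+)$", p.stem)
            if not m:
                continue
            by_animal.setdefault(int(m.group(1)), []).append(
                (int(m.group(2)), iio.imread(p).astype(float) / 255.0)
            )
        dose_map = (
            dict(zip(hearts["animal_id"], hearts["dose_mg_per_kg"]))
            if not hearts.empty
            else {}
        )
        if threshold is None and by_animal:
            threshold = batch_threshold(
                [img for fields in by_animal.values() for _, img in fields]
            )
            log.info("histology: staining-batch threshold %.4f", threshold)
        for animal_id, fields in sorted(by_animal.items()):
            fields.sort()
            res = quantify_heart([img for _, img in fields], threshold=threshold)
            for (field_id, _), pct in zip(fields, res.per_field_pct):
                rows.append(
                    {
                        "animal_id": animal_id,
                        "dose_at_sacrifice": dose_map.get(animal_id, np.nan),
                        "field_id": field_id,
                        "field_pct": pct,
                        "heart_pct": res.heart_pct,
                    }
                )
        return pd.DataFrame(rows)
    if not hearts.empty:
        log.info("histology: no field images, using tabulated terminal collagen")
        return pd.DataFrame(
            {
                "animal_id": hearts["animal_id"],
                "dose_at_sacrifice": hearts["dose_mg_per_kg"],
                "field_id": 0,
                "field_pct": hearts["true_collagen_pct"],
                "heart_pct": hearts["true_collagen_pct"],
            }
        )
    return pd.DataFrame()


# ---------------------------------------------------------------------------
# in-memory fast path (no file round-trip)


def records_from_cohort(cohort: Cohort) -> pd.DataFrame:
    """Long-format exam records straight from a cohort's drawn values.

    LVEF is derived from the drawn diameters through the Teichholz formula,
    exactly as the echo stage would; CC-IBS/MCV use the exam-level values
    (the quantities the trace fixtures are built to carry).
    """
    from .echo import ejection_fraction

    ex = cohort.exams
    frames = [
        ex[["animal_id", "dose_mg_per_kg"]].assign(variable=var, value=ex[var])
        for var in ("cc_ibs", "mcv", "sf_pct")
    ]
    lvef = [ejection_fraction(r.lvedd_cm, r.lvesd_cm) for r in ex.itertuples()]
    frames.append(
        ex[["animal_id", "dose_mg_per_kg"]].assign(variable="lvef_pct", value=lvef)
    )
    return pd.concat(frames, ignore_index=True)


def collagen_from_cohort(cohort: Cohort) -> pd.DataFrame:
    """Heart-level collagen table from a cohort's terminal truth values."""
    return pd.DataFrame(
        {
            "animal_id": cohort.hearts["animal_id"],
            "dose_at_sacrifice": cohort.hearts["dose_mg_per_kg"],
            "heart_pct": cohort.hearts["true_collagen_pct"],
        }
    )


# ---------------------------------------------------------------------------
# statistical chain on assembled tables


def _last_observed(records: pd.DataFrame, variable: str) -> pd.Series:
    """Each animal's value of ``variable`` at its last examined dose."""
    sub = records[records["variable"] == variable].sort_values("dose_mg_per_kg")
    return sub.groupby("animal_id")["value"].last()


def analyze_records(
    records: pd.DataFrame,
    collagen: pd.DataFrame,
    score: str = "last",
    ci: str = "delong",
    threshold_k: float = 2.0,
    seed: int = 0,
) -> Dict:
    """Run the statistical chain on long-format exam records plus collagen.

    ``records`` columns: animal_id, dose_mg_per_kg, variable, value.
    ``collagen`` columns: animal_id, dose_at_sacrifice, heart_pct (one row
    per heart; field-level rows are collapsed).

    Returns a JSON-ready dict with the summary table, per-animal betas,
    Kruskal-Wallis group tests, the control-derived collagen threshold,
    slope-collagen Spearman correlations, ROC accuracy per marker and a
    mortality (attrition) contingency test.
    """
    summary = summarize_groups(records)
    betas = betas_by_animal(records)

    report: Dict = {
        "options": {"score": score, "ci": ci, "threshold_k": threshold_k},
        "kruskal_wallis": {},
    }
    for var, grp in records.groupby("variable"):
        groups = [
            g["value"].to_numpy()
            for _, g in grp.groupby("dose_mg_per_kg")
            if len(g) > 0
        ]
        if len(groups) >= 2:
            h, p = kruskal_wallis(groups)
            report["kruskal_wallis"][var] = {"H": h, "p": p}

    # attrition: exited-after vs continued-past each exam dose
    exit_dose = records.groupby("animal_id")["dose_mg_per_kg"].max()
    doses = sorted(records["dose_mg_per_kg"].unique())
    if len(doses) > 1:
        table = []
        for d in doses[:-1]:
            examined = records.loc[records["dose_mg_per_kg"] == d, "animal_id"].unique()
            exited = int(sum(exit_dose[a] == d for a in examined))
            table.append([exited, len(examined) - exited])
        table = np.array(table).T
        if (table.sum(axis=0) > 0).all() and table.sum() > 0:
            method, p = categorical_test(table)
            report["mortality"] = {"method": method, "p": p}

    correlations: Dict = {}
    roc: Dict = {}
    if collagen.empty or collagen["heart_pct"].size < 2:
        log.warning("no histology available: ROC and correlation analyses skipped")
        report["threshold"] = None
    else:
        hearts = collagen.drop_duplicates("animal_id")[
            ["animal_id", "dose_at_sacrifice", "heart_pct"]
        ]
        base_dose = min(doses) if doses else 0.0
        controls = hearts.loc[hearts["dose_at_sacrifice"] == base_dose, "heart_pct"]
        if controls.size < 2:
            log.warning("fewer than 2 control hearts: threshold and ROC skipped")
            report["threshold"] = None
        else:
            spec = derive_threshold(controls.to_numpy(), k=threshold_k)
            report["threshold"] = asdict(spec)
            labels = (hearts["heart_pct"] > spec.threshold).to_numpy()

            for var in MARKER_ORIENTATION:
                bsub = betas[betas["variable"] == var].set_index("animal_id")["slope"]
                joined = hearts.join(bsub, on="animal_id").dropna(subset=["slope"])
                if len(joined) >= 3:
                    try:
                        rho, p = spearman(joined["slope"], joined["heart_pct"])
                        correlations[var] = {"rho": rho, "p": p, "n": int(len(joined))}
                    except InputError:
                        pass

            for var, orient in MARKER_ORIENTATION.items():
                if score == "beta":
                    svals = betas[betas["variable"] == var].set_index("animal_id")["slope"]
                else:
                    svals = _last_observed(records, var)
                joined = hearts.join(svals.rename("score"), on="animal_id").dropna(
                    subset=["score"]
                )
                lab = (joined["heart_pct"] > spec.threshold).to_numpy()
                if lab.all() or not lab.any() or len(joined) < 4:
                    log.warning("roc: single-class labels for %s, skipped", var)
                    continue
                oriented = orient * joined["score"].to_numpy()
                res = roc_analysis(oriented, lab, ci=ci, seed=seed)
                roc[var] = asdict(res)
                roc[var]["orientation"] = orient
                # map the operating cutoff back to the marker's own scale
                roc[var]["cutoff"] = orient * res.cutoff
                roc[var]["call"] = ">=" if orient > 0 else "<="

    report["spearman_vs_collagen"] = correlations
    report["roc"] = roc
    report["n_hearts"] = int(collagen.drop_duplicates("animal_id").shape[0]) if not collagen.empty else 0
    return {"summary": summary, "betas": betas, "report": report}


# ---------------------------------------------------------------------------
# analyze entry point


def run_analyze(
    data_dir: str | Path,
    out_dir: str | Path,
    score: str = "last",
    ci: str = "delong",
    threshold_k: float = 2.0,
    linear_power: bool = False,
    make_plots: bool = True,
    seed: int = 0,
) -> Dict:
    """Analyze a dataset directory and write all stage outputs and the report."""
    data_dir = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    config = GeneratorConfig.from_json(_require(data_dir / "config.json", "analyze"))

    utc = utc_stage(data_dir, config, linear_power=linear_power)
    utc.to_csv(out / "utc_indices.csv", index=False, float_format="%.10g")
    echo = echo_stage(data_dir)
    echo.to_csv(out / "echo_function.csv", index=False, float_format="%.10g")
    collagen = histology_stage(data_dir)
    collagen.to_csv(out / "collagen.csv", index=False, float_format="%.10g")

    frames = []
    for var in ("cc_ibs", "mcv"):
        frames.append(
            utc[["animal_id", "dose_mg_per_kg"]].assign(variable=var, value=utc[var])
        )
    for var in ("lvef_pct", "sf_pct"):
        frames.append(
            echo[["animal_id", "dose_mg_per_kg"]].assign(variable=var, value=echo[var])
        )
    records = pd.concat(frames, ignore_index=True)

    result = analyze_records(
        records,
        collagen if collagen.empty else collagen.drop_duplicates("animal_id"),
        score=score,
        ci=ci,
        threshold_k=threshold_k,
        seed=seed,
    )
    result["summary"].to_csv(out / "summary_table.csv", index=False, float_format="%.10g")
    result["betas"].to_csv(out / "betas.csv", index=False, float_format="%.10g")
    corr_rows = [
        {"variable": v, **d} for v, d in result["report"]["spearman_vs_collagen"].items()
    ]
    pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False, float_format="%.10g")
    roc_rows = [{"variable": v, **d} for v, d in result["report"]["roc"].items()]
    pd.DataFrame(roc_rows).to_csv(out / "roc.csv", index=False, float_format="%.10g")
    (out / "report.json").write_text(
        json.dumps(result["report"], indent=1, sort_keys=True, default=float)
    )

    if make_plots:
        from . import plots

        plot_dir = out / "plots"
        plots.dose_trends(result["summary"], plot_dir / "dose_trends.png")
        if not collagen.empty:
            plots.beta_collagen_scatter(
                result["betas"],
                collagen.drop_duplicates("animal_id"),
                plot_dir / "beta_vs_collagen.png",
            )
        if result["report"]["roc"]:
            plots.roc_curves(records, collagen, result["report"], plot_dir / "roc.png")
    log.info("analyze: %s -> %s (%.2fs)", data_dir, out, time.time() - t0)
    return result["report"]
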