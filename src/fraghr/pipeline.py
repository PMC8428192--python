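"""End-to-end orchestration: beat annotations → NN series → metrics → models.

``run_subject`` composes extraction and the metric modules for one
recording; ``run_study`` batches subjects, merges the per-subject metrics
with a covariate table and fits the requested regression models.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort as cm
from .hrf import compute_fragmentation
from .hrv import compute_hrv
from .nn_io import (
    eligible_subject,
    extract_sleep_nn,
    read_beat_annotations,
    read_sleep_epochs,
)

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_DATA = 3

METRIC_COLUMNS = (
    "pip", "pnnss", "pnnls", "avnn", "rmssd", "sdnn", "hf",
)


@dataclass
class PipelineConfig:
    """Configuration shared by the pipeline entry points."""

    sampling_frequency: float = 256.0
    n: int = 1
    hf_band: tuple[float, float] = (0.15, 0.40)
    dialect: str = "csv"
    model_ids: tuple[int, ...] = (1, 2, 3, 4, 5)
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_subject(
    beats_path: str | Path,
    epochs_path: str | Path,
    config: PipelineConfig | None = None,
    subject_id: str | None = None,
) -> dict:
    """Process one subject's recording into a metrics row.

    Ineligible subjects (under 2 h combined REM + non-REM sleep) get a row
    with the exclusion reason and no metrics.
    """
    config = config or PipelineConfig()
    subject_id = subject_id or Path(beats_path).stem
    row: dict = {"subject_id": subject_id, "eligible": False, "exclusion_reason": ""}
    beats = read_beat_annotations(
        beats_path, config.sampling_frequency, dialect=config.dialect
    )
    epochs = read_sleep_epochs(epochs_path)
    ok, minutes = eligible_subject(epochs)
    row["sleep_minutes"] = minutes
    if not ok:
        row["exclusion_reason"] = "sleep<2h"
        return row
    nn = extract_sleep_nn(beats, epochs)
    frag = compute_fragmentation(nn, n=config.n)
    hrv = compute_hrv(nn, band=config.hf_band)
    row.update(
        eligible=True,
        n_nn_intervals=len(nn),
        n_runs=int(nn.run_id.max()) + 1,
        pip=frag.pip_pct,
        pnnss=frag.pnnss_pct,
        pnnls=frag.pnnls_pct,
        avnn=hrv.avnn_ms,
        sdnn=hrv.sdnn_ms,
        rmssd=hrv.rmssd_ms,
        hf=hrv.hf_ms2,
        ln_rmssd=hrv.ln_rmssd,
        ln_sdnn=hrv.ln_sdnn,
        ln_hf=hrv.ln_hf,
        n_windows_qualified=hrv.n_windows_qualified,
    )
    return row


def run_study(
    subjects: list[tuple[str | Path, str | Path]],
    covariates: pd.DataFrame | str | Path,
    outcome: str,
    exposure: str = "pnnss",
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Batch subjects, merge with covariates, fit the requested models.

    ``subjects`` is a list of (beats_path, epochs_path); ``covariates`` a
    table (or CSV path) keyed by ``subject_id`` carrying the outcome and
    adjustment variables.  Returns a dict with the per-subject metrics
    table, the tidy model report and the fitted results.
    """
    config = config or PipelineConfig()
    rows = []
    for beats_path, epochs_path in subjects:
        try:
            rows.append(run_subject(beats_path, epochs_path, config))
        except (ValueError, OSError) as exc:
            logger.error("subject %s failed: %s", beats_path, exc)
            rows.append(
                {
                    "subject_id": Path(beats_path).stem,
                    "eligible": False,
                    "exclusion_reason": f"error: {exc}",
                }
            )
    metrics = pd.DataFrame(rows)
    if not metrics["eligible"].any():
        raise ValueError("no subject produced usable metrics")
    if isinstance(covariates, (str, Path)):
        covariates = pd.read_csv(covariates)
    merged = metrics[metrics["eligible"]].merge(
        covariates, on="subject_id", how="inner"
    )
    merged, transforms = cm.transform_variables(merged)
    std_vars = [
        c
        for c in (exposure, "age", "systolic_bp", "total_cholesterol", "hdl",
                  "pack_years", "physical_activity", "nt_probnp", "avnn")
        if c in merged.columns and c != outcome
    ]
    merged, scaling = cm.standardize(merged, std_vars)
    tidy_rows = []
    fits = {}
    for mid in config.model_ids:
        covs = tuple(
            c for c in cm.MODEL_COVARIATES[mid] if c in merged.columns and c != exposure
        )
        spec = cm.ModelSpec(mid, outcome, exposure, covariates=covs)
        fit = cm.fit_model(merged, spec)
        fits[mid] = fit
        for _, r in fit.terms.iterrows():
            tidy_rows.append(
                {
                    "model_id": mid,
                    "outcome": outcome,
                    "term": r["term"],
                    "estimate": r["estimate"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "p": r["p"],
                }
            )
    tidy = pd.DataFrame(tidy_rows)
    result = {
        "metrics": metrics,
        "tidy": tidy,
        "fits": fits,
        "transforms": transforms,
        "scaling": scaling,
        "config_hash": config.config_hash(),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = f"# config_hash={config.config_hash()}\n"
        for name, df in (("metrics.csv", metrics), ("model_report.csv", tidy)):
            path = out_dir / name
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)
    return result
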