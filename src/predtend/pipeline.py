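"""End-to-end orchestration of the analysis stages.

Stages communicate through bridge CSVs in the output directory:

* ``tendency.csv``  — per subject: prediction/updating tendency and the
  frequency-decoding-accuracy control (the decoding stage's product);
* ``encoding.csv``  — per subject x voxel x condition: cortical tracking r
  (the TRF stage's product);
* ``stats_summary.csv`` + ``clusters.json`` — per-voxel posterior summaries
  and neighbour-filtered cluster reports (the statistics stage's product).

Every stage re-derives the synthetic cohort deterministically from
(config, seed), so no stage depends on the HDF5 dumps of ``simulate``.
The resolved configuration is written next to the outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .decoding import estimate_tendency
from .simulate import simulate_cohort
from .stats import fit_cohort_stats
from .trf import crossval_encoding, transfer_encoding

logger = logging.getLogger(__name__)

TENDENCY_CSV = "tendency.csv"
ENCODING_CSV = "encoding.csv"
STATS_CSV = "stats_summary.csv"
CLUSTERS_JSON = "clusters.json"


def _prepare_out(config: RunConfig, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "resolved_config.json")
    return out


def _require(out: Path, filename: str, producer: str) -> Path:
    path = out / filename
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path}; run the '{producer}' stage first to produce {filename}"
        )
    return path


def stage_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Write the cohort ground truth (and per-subject HDF5 sessions)."""
    from .io import save_subject_h5

    out = _prepare_out(config, out_dir)
    cohort = simulate_cohort(config.cohort_config(), seed=config.seed)
    rows = []
    h5_dir = out / "subjects"
    h5_dir.mkdir(exist_ok=True)
    for i in range(cohort.n_subjects):
        sub = cohort.subject(i)
        gt = sub.ground_truth
        save_subject_h5(h5_dir / f"{gt.subject_id}.h5", sub)
        rows.append({"subject_id": gt.subject_id, "g_pred": gt.g_pred,
                     "subject_intercept": gt.subject_intercept})
        logger.info("simulated %s (g_pred=%.3f)", gt.subject_id, gt.g_pred)
    pd.DataFrame(rows).to_csv(out / "ground_truth.csv", index=False)
    return out


def stage_tendency(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Decode every subject's tone runs and write tendency.csv."""
    out = _prepare_out(config, out_dir)
    cohort = simulate_cohort(config.cohort_config(), seed=config.seed)
    dec = config.decoding
    rows = []
    for i in range(cohort.n_subjects):
        sub = cohort.subject(i, include=("tone",))
        res = estimate_tendency(
            sub.tone_runs,
            analysis_window_s=(dec.window_lo_s, dec.window_hi_s),
            dval_scale=dec.dval_scale,
            centering=dec.centering,
        )
        rows.append(
            {
                "subject_id": sub.ground_truth.subject_id,
                "prediction_tendency": res.prediction_tendency,
                "updating_tendency": res.updating_tendency,
                "decoding_accuracy": res.decoding_accuracy,
                "g_pred_true": sub.ground_truth.g_pred,
            }
        )
        logger.info(
            "tendency %s: %.4f (n_train=%d)",
            sub.ground_truth.subject_id,
            res.prediction_tendency,
            res.n_trials["ordered_forward_train"],
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / TENDENCY_CSV, index=False)
    return df


def stage_encode(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """TRF encoding per subject/voxel/condition; writes encoding.csv."""
    out = _prepare_out(config, out_dir)
    cohort = simulate_cohort(config.cohort_config(), seed=config.seed)
    trf_cfg = config.trf
    rows = []
    for i in range(cohort.n_subjects):
        sub = cohort.subject(i, include=("speech",))
        sid = sub.ground_truth.subject_id
        clear = sub.speech_trials[0]
        fs = clear.sample_rate_hz
        score0, kernel = crossval_encoding(
            clear.envelope,
            clear.brain,
            fs,
            k=trf_cfg.k_folds,
            lags_s=(trf_cfg.lag_lo_s, trf_cfg.lag_hi_s),
            validation_fraction=trf_cfg.validation_fraction,
            step_fraction=trf_cfg.step_fraction,
            patience=trf_cfg.patience,
        )
        scores = {0: score0}
        for nd in (1, 2):
            sess = sub.speech_trials[nd]
            scores[nd] = transfer_encoding(
                kernel, sess.envelope, sess.brain, fs, condition=f"{nd}-dist"
            )
        for nd, sc in scores.items():
            for vox, r in enumerate(sc.r):
                rows.append(
                    {"subject_id": sid, "voxel_id": vox, "n_distractors": nd, "tracking": r}
                )
        logger.info("encoded %s: mean r(0-dist)=%.3f", sid, np.nanmean(score0.r))
    df = pd.DataFrame(rows)
    df.to_csv(out / ENCODING_CSV, index=False)
    return df


def stage_stats(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Per-voxel multilevel regression on the bridge CSVs."""
    out = _prepare_out(config, out_dir)
    enc = pd.read_csv(_require(out, ENCODING_CSV, "encode"))
    ten = pd.read_csv(_require(out, TENDENCY_CSV, "tendency"))
    table = enc.merge(
        ten[["subject_id", "prediction_tendency"]], on="subject_id", validate="many_to_one"
    )
    grid = config.cohort_config().grid
    st = config.stats
    summary, clusters = fit_cohort_stats(
        table,
        grid.adjacency(),
        formula=st.formula,
        draws=st.draws,
        warmup=st.warmup,
        n_chains=st.n_chains,
        seed=config.seed,
        hdi_prob=st.hdi_prob,
        min_neighbors=st.min_neighbors,
    )
    summary.to_csv(out / STATS_CSV, index=False)
    report = {
        term: {
            "n_significant_filtered": int(res.filtered_mask.sum()),
            "clusters": res.clusters,
        }
        for term, res in clusters.items()
    }
    (out / CLUSTERS_JSON).write_text(json.dumps(report, indent=2))
    return summary


STAGES = {
    "simulate": stage_simulate,
    "tendency": stage_tendency,
    "encode": stage_encode,
    "stats": stage_stats,
}


def run_pipeline(config: RunConfig, out_dir: str | Path, stage: str = "all"):
    """Run one stage or the whole pipeline (tendency -> encode -> stats)."""
    if stage == "all":
        stage_tendency(config, out_dir)
        stage_encode(config, out_dir)
        return stage_stats(config, out_dir)
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(STAGES)} or 'all'")
    return STAGES[stage](config, out_dir)
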