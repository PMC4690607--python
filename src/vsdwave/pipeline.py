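"""End-to-end pipeline: simulate -> track -> normalize -> features -> classify.

Runs the full analysis chain on synthetic recordings and returns the trained
(reduced) model together with the evaluation report.  Used by the CLI
``pipeline`` command and by integration tests; each stage is also available
on its own through the individual modules.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import beats, evaluate, forest, motion, preprocess, synthdata

logger = logging.getLogger(__name__)


def features_from_recording(
    rec: motion.LineScanRecording,
    label: str,
    recording_id: str,
    smoothing_window: int = 50,
) -> pd.DataFrame:
    """Extract the per-beat feature table from one raw kymograph."""
    centers = motion.detect_membranes(rec)
    entries = []
    for m, c in enumerate(centers):
        trace = motion.track_membrane(rec, c, membrane_id=f"m{m + 1}")
        _, norm = preprocess.correct_photobleach(trace)
        smoothed = preprocess.smooth(norm, smoothing_window)
        metrics, rate, qc = beats.extract_features(smoothed)
        logger.info(
            "%s %s: %d beats (%.1f bpm), %d rejected",
            recording_id, trace.membrane_id, len(metrics), rate, qc["n_rejected"],
        )
        entries.append((metrics, label, recording_id, trace.membrane_id))
    return beats.build_feature_table(entries)


def run_pipeline(
    config: synthdata.SynthConfig | None = None,
    seed: int | None = None,
    n_trees: int = 50,
    smoothing_window: int = 50,
    reduce: bool = True,
) -> dict:
    """Simulate recordings for every condition and run the full analysis.

    Returns a dict with the feature table, split tables, the (reduced)
    model, the reduction report and the evaluation report.
    """
    config = config or synthdata.default_config()
    seed = config.seed if seed is None else seed

    entries = []
    for cond in config.conditions:
        for r in range(config.n_recordings):
            rec_seed = (seed + 104729 * (len(entries) + 1)) % 2**31
            rec, _ = synthdata.simulate_recording(config, cond.label, seed=rec_seed)
            rec_id = f"{cond.label}-r{r + 1}"
            table = features_from_recording(
                rec, cond.label, rec_id, smoothing_window=smoothing_window
            )
            entries.append(table)
    table = pd.concat(entries, ignore_index=True)

    train, valid = forest.stratified_split(table, forest.SplitSpec(seed=seed))
    if reduce:
        report, model = forest.reduce_model(train, valid, n_trees=n_trees, seed=seed)
    else:
        model = forest.train_forest(train, n_trees=n_trees, seed=seed)
        report = None
    preds = forest.predict(model, valid)
    eval_report = evaluate.evaluation_report(
        preds, valid["label"], valid["recording_id"]
    )
    return {
        "feature_table": table,
        "train": train,
        "valid": valid,
        "model": model,
        "reduction_report": report,
        "evaluation": eval_report,
    }
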