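"""Whole-database evaluation on locally available MIT-BIH arrhythmia records.

The MIT-BIH arrhythmia database is not redistributed here; download it from
PhysioNet (https://physionet.org/content/mitdb/1.0.0/) and point --data-dir
at the directory holding the .hea/.dat/.atr files. The script trains the
detector on the annotated records, runs sliding-window detection on each,
and prints location-matched metrics plus pooled and per-record HRV.

    python scripts/evaluate_mitdb.py --data-dir /path/to/mitdb [--records 100 101 ...]
"""

from __future__ import annotations

import argparse
import json
import sys
from pathlib import Path

from ecgpeaks import (
    aggregate_hrv,
    classification_metrics,
    match_detections,
    read_wfdb,
    run_detection,
    train_model,
)
from ecgpeaks.evaluation import ConfusionCounts
from ecgpeaks.pipeline import PipelineConfig


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    parser.add_argument("--records", nargs="*", help="Record names; default: every .hea in data-dir.")
    parser.add_argument("--channel", type=int, default=0)
    parser.add_argument("--config", type=Path, help="YAML pipeline config.")
    parser.add_argument("--hrv-mode", choices=["pooled", "per-record"], default="pooled")
    parser.add_argument("--out", type=Path, help="Optional JSON report path.")
    args = parser.parse_args()

    names = args.records or sorted(p.stem for p in args.data_dir.glob("*.hea"))
    if not names:
        print(
            f"no WFDB records found in {args.data_dir} — expected MIT-BIH arrhythmia "
            "database files (100.hea/.dat/.atr, ...) from PhysioNet",
            file=sys.stderr,
        )
        return 2

    config = PipelineConfig.from_yaml(args.config) if args.config else PipelineConfig()
    records = [read_wfdb(args.data_dir / name, channel=args.channel) for name in names]
    records = [r for r in records if r.annotations]
    if not records:
        print("records found but none carry beat annotations", file=sys.stderr)
        return 2

    model = train_model(records, config)
    tp = fp = fn = 0
    detected_locs = []
    annotated_locs = []
    for rec in records:
        locs = run_detection(rec, model, sliding=True)
        detected_locs.append(locs)
        annotated_locs.append(rec.annotation_indices())
        c = match_detections(locs, rec.annotation_indices(), fs=rec.fs, tolerance_s=config.match_tolerance_s)
        tp, fp, fn = tp + c.tp, fp + c.fp, fn + c.fn

    counts = ConfusionCounts(tp=tp, fp=fp, tn=0, fn=fn)
    fs = records[0].fs
    hrv_det = aggregate_hrv(detected_locs, fs, mode=args.hrv_mode)
    hrv_ann = aggregate_hrv(annotated_locs, fs, mode=args.hrv_mode)
    report = {
        "records": names,
        "counts": {"TP": tp, "FP": fp, "FN": fn},
        "metrics_pct": classification_metrics(counts).rounded(),
        "hrv_detected_s": vars(hrv_det),
        "hrv_annotated_s": vars(hrv_ann),
        "hrv_mode": args.hrv_mode,
        "selected_features": model.selected_features,
    }
    text = json.dumps(report, indent=2)
    print(text)
    if args.out:
        args.out.write_text(text + "\n")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
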