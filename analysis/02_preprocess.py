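#!/usr/bin/env python
"""Trial- and subject-level filtering of the battery trial table.

Fixed pipeline order: RT trimming (floor 200 ms, slow cutoff mean + 3 sd
per subject x trial-type cell) -> retention criterion (a subject leaves a
task when more than half of a cell's correct trials were trimmed) -> 40%
error-rate cutoff per trial-type cell.  Writes the cleaned table and a
trimming/retention summary, and prints the multiverse sweep of error-rate
cutoffs for context.
"""

import argparse
from pathlib import Path

import pandas as pd

from taskrel import preprocess, read_trial_table, write_trial_table
from taskrel.preprocessing import error_rate_sweep


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-file", type=Path, default=Path("scratch/trials.csv"))
    ap.add_argument("--floor-ms", type=float, default=200.0)
    ap.add_argument("--sd-mult", type=float, default=3.0)
    ap.add_argument("--error-cutoff", type=float, default=0.40)
    ap.add_argument("--out-dir", type=Path, default=Path("."))
    args = ap.parse_args()

    ds = read_trial_table(args.in_file)
    clean, reports = preprocess(ds, floor_ms=args.floor_ms, sd_mult=args.sd_mult,
                                error_cutoff=args.error_cutoff)

    results = args.out_dir / "results"
    scratch = args.out_dir / "scratch"
    results.mkdir(exist_ok=True)
    write_trial_table(clean, scratch / "trials_preprocessed.csv")

    trim = reports["trim"].per_task
    removed = pd.concat([reports["retention"].removed, reports["error_rate"].removed],
                        ignore_index=True)
    trim.to_csv(results / "02_trim_summary.csv", index=False)
    removed.to_csv(results / "02_removed_subjects.csv", index=False)

    print("fraction of correct RT trials trimmed, per task:")
    for _, row in trim.iterrows():
        print(f"  {row['task']:<10} {row['fraction_removed']:.3%}")
    by_reason = removed.groupby(["task", "reason"]).size() if len(removed) else {}
    print(f"subjects removed: {len(removed)} task-level exclusions")
    if len(removed):
        print(by_reason.to_string())
    print("error-cutoff multiverse (subjects removed per task):")
    sweep = error_rate_sweep(ds)
    print(sweep.pivot(index="task", columns="cutoff", values="n_removed").to_string())
    print(f"kept {len(clean)} of {len(ds)} trials")


if __name__ == "__main__":
    main()
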