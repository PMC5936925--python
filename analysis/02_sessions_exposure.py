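#!/usr/bin/env python
"""Detect pressure sessions and summarize exposure per site and time of day.

Reads the study written by 01_simulate_study.py, applies the session rule
(>= 5 pressure scans, interruptions <= 10 min) and the exposure definition
(pressure scans / total scans per follow and diel category), and writes
sessions.csv, exposure.csv and the site-by-time summary exposure_summary.csv
under results/.
"""

import argparse
from pathlib import Path

from behavchain.datamodel import SunTimesTable, read_scans
from behavchain.exposure import (
    detect_sessions,
    exposure_table,
    sessions_table,
    summarize_site,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    sun = SunTimesTable.from_csv(args.study / "suntimes.csv")
    follows, rejects = read_scans(args.study / "scans.csv", sun)
    sessions = [s for f in follows for s in detect_sessions(f)]
    expo = exposure_table(follows)
    summary = summarize_site(sessions, expo)

    args.out.mkdir(parents=True, exist_ok=True)
    sessions_table(sessions).to_csv(args.out / "sessions.csv", index=False)
    expo.to_csv(args.out / "exposure.csv", index=False)
    summary.to_csv(args.out / "exposure_summary.csv", index=False)

    print(f"{len(sessions)} pressure sessions from {len(follows)} follows")
    for _, row in summary.iterrows():
        print(
            f"  {row['site']:>13s} {row['time_category']:>9s}: "
            f"exposure {row['exposure_mean']:.2f} ({row['exposure_sd']:.2f}), "
            f"duration {row['duration_mean_min']:.0f} min"
            if row["n_sessions"]
            else f"  {row['site']:>13s} {row['time_category']:>9s}: "
                 f"exposure {row['exposure_mean']:.2f}, no sessions"
        )


if __name__ == "__main__":
    main()
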