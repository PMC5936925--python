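#!/usr/bin/env python
"""Log-linear model selection: which factors shape behavioural transitions?

For each behavioural indicator, fits the hierarchical family of log-linear
models to the transition contingency tables — pooled across sites (factors
time, location, chain) and within each site (time, season where it varies,
chain) — scores them by AIC = G2 - 2 df and reports the supported set
(delta AIC <= 2).  Writes model_selection_pooled.csv and
model_selection_<site>.csv under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from behavchain.chains import build_table
from behavchain.loglinear import enumerate_models, fit_model, selection_report

ROOT = Path(__file__).resolve().parents[1]


def run_family(trans: pd.DataFrame, factors_cond: list[str]) -> pd.DataFrame:
    frames = []
    for ind, grp in trans.groupby("indicator"):
        tab = build_table(grp, ["preceding", "succeeding"] + factors_cond)
        fits = [fit_model(tab, s) for s in enumerate_models(factors_cond)]
        rep = selection_report(fits)
        rep.insert(0, "indicator", ind)
        frames.append(rep)
    return pd.concat(frames, ignore_index=True)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    trans = pd.read_csv(args.out / "transitions.csv")

    pooled = run_family(trans, ["chain", "time_category", "site"])
    pooled.to_csv(args.out / "model_selection_pooled.csv", index=False)
    print("pooled (time x location x chain):")
    for ind, grp in pooled.groupby("indicator"):
        sup = grp[grp["supported"]]
        best = sup.iloc[0]
        print(f"  {ind:>10s}: best {best['model']!r} (AIC {best['aic']:.2f}), "
              f"{len(sup)} supported")

    for site, site_grp in trans.groupby("site"):
        factors = ["chain", "time_category"] + (
            ["season"] if site_grp["season"].nunique() > 1 else []
        )
        rep = run_family(site_grp, factors)
        rep.to_csv(args.out / f"model_selection_{site}.csv", index=False)
        print(f"{site}:")
        for ind, grp in rep.groupby("indicator"):
            best = grp[grp["supported"]].iloc[0]
            print(f"  {ind:>10s}: best {best['model']!r} (AIC {best['aic']:.2f})")


if __name__ == "__main__":
    main()
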