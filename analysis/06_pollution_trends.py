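#!/usr/bin/env python
"""Seasonal structure and site differences of the simulated pollutant
series: per-site means with Bonferroni-corrected pairwise t-tests for BC,
plus the winter/summer anti-phase of NO2 and O3.

Writes results/pollution_site_means.tsv.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from phylloplane import one_way_anova, pairwise_t_tests, significance_letters

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "campaign"
OUT = ROOT / "results"
SITES = ["HGa", "HGb", "HKa", "HKb", "DM", "DW"]


def main() -> None:
    path = DATA / "pollution_daily.tsv"
    if not path.exists():
        raise SystemExit("run analysis/02_simulate_campaign.py first")
    OUT.mkdir(exist_ok=True)
    series = pd.read_csv(path, sep="\t", parse_dates=["date"])

    means = (
        series.pivot_table(index="site", columns="pollutant", values="value", aggfunc="mean")
        .loc[SITES]
        .round(1)
    )

    bc = series[series["pollutant"] == "BC"]
    f, p = one_way_anova(bc["value"], bc["site"])
    res = pairwise_t_tests(bc["value"], bc["site"], correction="bonferroni")
    letters = significance_letters(res, SITES)
    means["bc_different_from"] = [letters[s] for s in SITES]
    means.to_csv(OUT / "pollution_site_means.tsv", sep="\t")
    print(means.to_string())
    print(f"\nBC site ANOVA: F = {f:.1f}, p = {p:.1e}")

    one = series[series["site"] == "HGa"].copy()
    one["month"] = one["date"].dt.month
    winter = one["month"].isin([12, 1, 2])
    summer = one["month"].isin([6, 7, 8])
    for pol in ("NO2", "O3"):
        w = one[(one["pollutant"] == pol) & winter]["value"].mean()
        s = one[(one["pollutant"] == pol) & summer]["value"].mean()
        peak = "winter" if w > s else "summer"
        print(f"{pol}: winter mean {w:.1f}, summer mean {s:.1f} -> peaks in {peak}")


if __name__ == "__main__":
    main()
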