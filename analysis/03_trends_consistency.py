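#!/usr/bin/env python
"""Fit per-member trends in the annual dry-season diagnostics, label the
cross-member consistency at each grid point, and summarize the percent area
with lengthening dry seasons under each definition.

Reads results/seasons/annual_seasons.csv (run 02 first); writes trend and
consistency tables to results/trends/.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from dryseason import io, trends

IN = Path("results/seasons")
OUT = Path("results/trends")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    seasons = pd.read_csv(IN / "annual_seasons.csv")

    rows = []
    keys = ["lat", "lon", "member", "definition", "season_index"]
    for key, grp in seasons.groupby(keys, sort=True):
        grp = grp.sort_values("year")
        for diag in ("dsl", "dsa", "dse", "wd"):
            tr = trends.trend(grp[diag].values.astype(float))
            rows.append(dict(zip(keys, key)) | {
                "diagnostic": diag, "slope_per_decade": tr.slope_per_decade,
                "p_ols": tr.p_ols, "p_mk": tr.p_mk, "n": tr.n})
    trend_df = pd.DataFrame(rows)
    io.write_point_csv(trend_df, OUT / "trends.csv")

    cons_rows = []
    for key, grp in trend_df.groupby(["lat", "lon", "definition", "season_index",
                                      "diagnostic"], sort=True):
        label = trends.consistency_classify(
            [(np.sign(s), p < trends.ALPHA)
             for s, p in zip(grp["slope_per_decade"], grp["p_ols"])])
        cons_rows.append(dict(zip(("lat", "lon", "definition", "season_index",
                                   "diagnostic"), key)) | {"category": label.category})
    cons = pd.DataFrame(cons_rows)
    io.write_point_csv(cons, OUT / "consistency.csv")

    print("regional DSL trend (d/decade, area-weighted over members/points):")
    for d, grp in trend_df[trend_df["diagnostic"] == "dsl"].groupby("definition"):
        mean_slope = trends.area_weighted_mean(grp["slope_per_decade"], grp["lat"])
        print(f"  {d:10s} {mean_slope:+.2f}")

    print("\npercent area by consistency label (DSL):")
    dsl = cons[cons["diagnostic"] == "dsl"]
    for d, grp in dsl.groupby("definition"):
        pct = trends.percent_area_by_category(grp["category"].values,
                                              grp["lat"].values)
        longer = sum(v for k, v in pct.items() if k.endswith("increase"))
        print(f"  {d:10s} lengthening {longer:5.1f}%  ({ {k: round(v, 1) for k, v in pct.items()} })")


if __name__ == "__main__":
    main()
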