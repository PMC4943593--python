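"""Regional century projection with wetland-area scenarios.

Simulates every cell of a synthetic 14-cell region over 2001-2100 for the
three RCP scenarios, and writes the decadal anomaly tables, per-city
percent changes, and fixed-area vs restoration emission totals (with
CO2-equivalent conversion) to results/projection/.
"""

from pathlib import Path

import pandas as pd

from wetlandch4.cli_io import RunConfig, run_projection

OUT = Path("results/projection")
SEED = 1

totals = []
for name in ("rcp26", "rcp45", "rcp85"):
    cfg = RunConfig(scenario=name, years=(2001, 2100), seed=SEED, n_cells=14)
    res = run_projection(cfg, OUT / name)
    row = res["totals"].iloc[0].to_dict()
    row["scenario"] = name
    totals.append(row)
    print(f"\n=== {name} ===")
    print(res["anomalies"].round(2).to_string(index=False))
    print(res["subregion_pct"].round(1).to_string())

table = pd.DataFrame(totals).set_index("scenario")
table.to_csv(OUT / "totals.csv")
print("\n", table.round(4).to_string())
print("\nRestoration totals are exactly 1.25x the fixed-area totals; the "
      "CO2-equivalent column applies the 100-year GWP of 25.")
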