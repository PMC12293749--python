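"""Doubling times per animal from the growth curves, and fractional
enrichment / concentrations from the NMR peak table.

Reads results/phantom/, writes results/growth_sirm/ including a group table
consumed by the statistics driver.
"""

import json
import os

import pandas as pd

from pdxmri.pipeline import run_pipeline

PH = os.path.join("results", "phantom")
OUT = os.path.join("results", "growth_sirm")

summary = run_pipeline({
    "stages": ["doubling_time", "fe"],
    "output_dir": OUT,
    "doubling_time": {"input": os.path.join(PH, "growth.csv")},
    "fe": {"input": os.path.join(PH, "peak_table.csv")},
    "animal_id": "phantom", "site": "SRC",
})

# attach the line label back onto each animal's doubling time -> group table
growth = pd.read_csv(os.path.join(PH, "growth.csv"))
line_of = growth.drop_duplicates("animal_id").set_index("animal_id")["pdx_line"]
td = summary[summary.parameter == "td"].copy()
td["pdx_line"] = td["id"].map(line_of)
td.to_csv(os.path.join(OUT, "group_table_td.csv"), index=False)

for line, sub in td.groupby("pdx_line"):
    print(f"{line}: Td = {sub['value'].mean():.2f} +/- "
          f"{sub['value'].std(ddof=1) / len(sub) ** 0.5:.2f} days (n={len(sub)})")

fe_truth = json.load(open(os.path.join(PH, "peak_table_truth.json")))
for _, row in summary[summary.parameter.str.startswith("fe_")].iterrows():
    met = row["parameter"][3:]
    print(f"FE {met}: {row['value']:.3f} vs truth {fe_truth[met]:.3f}")
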