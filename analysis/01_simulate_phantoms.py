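"""Generate the full set of digital-phantom acquisitions with known truth.

Writes, under results/phantom/: multi-b DWI and saturation-recovery stacks,
a DCE series with its baseline-T1 map, hyperpolarized pyruvate/lactate/urea
dynamics with tumor/vessel/background ROIs, weekly growth curves for three
tumor lines at three implantation-site growth rates, and an NMR peak table
— each with a JSON truth sidecar where applicable.
"""

import os
import sys

import numpy as np
import pandas as pd

from pdxmri.datamodel import ROIMask
from pdxmri.io import write_mask
from pdxmri.phantom import checkerboard_truth, simulate_growth
from pdxmri.pipeline import run_pipeline

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = os.path.join("results", "phantom")
os.makedirs(OUT, exist_ok=True)

# --- static mapping modalities -------------------------------------------
run_pipeline({"stage": "simulate", "modality": "dwi", "seed": SEED, "snr": 20,
              "adc_truth": checkerboard_truth((8, 8, 1)), "output_dir": OUT})
run_pipeline({"stage": "simulate", "modality": "satrec", "seed": SEED, "snr": 50,
              "t1_truth": checkerboard_truth((8, 8, 1), low=1.2, high=2.0),
              "output_dir": OUT})
roi = np.zeros((8, 8, 1), dtype=bool)
roi[2:6, 2:6, :] = True
write_mask(ROIMask(mask=roi, label="tumor"), os.path.join(OUT, "tumor_roi.nii.gz"))

# --- DCE (tumor-typical kinetics; study-scale Ktrans is exercised in tests)
run_pipeline({"stage": "simulate", "modality": "dce", "seed": SEED, "snr": 40,
              "ktrans": 0.25, "ve": 0.30, "vp": 0.05, "t10": 1.8, "output_dir": OUT})

# --- hyperpolarized 13C ---------------------------------------------------
run_pipeline({"stage": "simulate", "modality": "hp", "seed": SEED, "snr": 20,
              "kpl": 0.08, "output_dir": OUT})
tumor = np.zeros((8, 8, 1), dtype=bool); tumor[2:5, 2:5, :] = True
vessel = np.zeros((8, 8, 1), dtype=bool); vessel[6, 6, :] = True
background = ~(tumor | vessel)
write_mask(ROIMask(mask=tumor, label="tumor"), os.path.join(OUT, "hp_tumor_roi.nii.gz"))
write_mask(ROIMask(mask=vessel, label="vessel"), os.path.join(OUT, "hp_vessel_roi.nii.gz"))
write_mask(ROIMask(mask=background, label="bg"), os.path.join(OUT, "hp_background_roi.nii.gz"))

# --- growth: 3 lines x 4 animals at the reported doubling-time scale ------
rows = []
line_td = {"LuCaP93": 5.0, "LTL610": 8.0, "LTL352": 11.0}  # SRC-site ordering
for li, (line, td) in enumerate(line_td.items()):
    for animal in range(4):
        series = simulate_growth(td_days=td, noise_sigma=0.1, n_weeks=4,
                                 seed=SEED + 100 * li + animal)
        for day, vol in zip(series.times_days, series.volumes_mm3):
            rows.append({"animal_id": f"{line}_{animal}", "pdx_line": line,
                         "day": day, "volume_mm3": vol})
pd.DataFrame(rows).to_csv(os.path.join(OUT, "growth.csv"), index=False)

# --- SIRM peak table ------------------------------------------------------
run_pipeline({"stage": "simulate", "modality": "peak_table", "seed": SEED,
              "noise_cv": 0.05, "output_dir": OUT})

print(f"phantom inputs written to {OUT} (seed {SEED})")
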