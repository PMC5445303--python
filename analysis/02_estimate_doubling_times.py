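"""Estimate doubling times from synthetic kinetic growth curves.

Generates plate-reader-style OD600 curves (5-min sampling, lag +
exponential + saturation, 1% per-point multiplicative noise) for a spread
of true doubling times and recovers each with the max-slope sliding-window
estimator, reporting the per-well estimates and their errors.
"""

import os

import numpy as np
import pandas as pd

from magefit.growth import doubling_times_for_plate
from magefit.io_formats import PlateReaderTable, write_plate_reader
from magefit.mage_sim import simulate_growth_curve

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
os.makedirs(OUT, exist_ok=True)

true_times = {"A1": 25.0, "A2": 28.0, "A3": 32.0, "A4": 36.0, "A5": 40.0}
wells = {
    w: simulate_growth_curve(t, n_points=97, noise_cv=0.01, seed=i)
    for i, (w, t) in enumerate(true_times.items())
}
plate = PlateReaderTable(time_min=np.arange(97) * 5.0, wells=wells)
write_plate_reader(plate, os.path.join(OUT, "plate_od600.csv"))

results = doubling_times_for_plate(plate)
rows = []
for w, res in results.items():
    rows.append(
        {
            "well": w,
            "true_t_double_min": true_times[w],
            "estimated_t_double_min": round(res.t_double, 2),
            "error_pct": round(100 * (res.t_double / true_times[w] - 1), 2),
            "window_start_index": res.window_start_index,
        }
    )
df = pd.DataFrame(rows)
df.to_csv(os.path.join(OUT, "doubling_times.tsv"), sep="\t", index=False)
print(df.to_string(index=False))
print(f"mean |error| {df['error_pct'].abs().mean():.2f}% at 1% per-point noise")
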