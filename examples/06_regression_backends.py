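"""The four regression back-ends on CARS-selected wavelengths.

Fits PLSR (7 components), MLR, random forest (100 trees, seed 42) and a
ReLU network (4 hidden layers, 1000 iterations) on a synthetic table and
reports calibration and prediction metrics per model.
"""

import warnings

import numpy as np

from leafwater import RegressorSpec, SimConfig, cars, fit, simulate_sample_table, split
from leafwater.prep import snv
from leafwater.regress import evaluate_arrays

warnings.filterwarnings("ignore")

table = simulate_sample_table(400, SimConfig(), seed=5)
cal, pred = split(table, 0.3, seed=5)
Xc, Xp = snv(cal.reflectance), snv(pred.reflectance)

sel = cars(Xc, cal.water_content, seed=5, grid=cal.grid)
idx = sel.selected_band_indices
print(f"CARS kept {sel.n_selected}/{Xc.shape[1]} bands")

print("model   R2_cal  RMSE    R2_P    RMSEP")
for kind in ("PLSR", "MLR", "RF", "ANN"):
    spec = RegressorSpec(kind=kind, ann_seed=5, mlr_min_norm=True)
    model = fit(spec, Xc[:, idx], cal.water_content)
    r2c, rmsec = evaluate_arrays(cal.water_content, model.predict(Xc[:, idx]))
    r2p, rmsep = evaluate_arrays(pred.water_content, model.predict(Xp[:, idx]))
    print(f"{kind:6s} {r2c:.4f}  {rmsec:.4f}  {r2p:.4f}  {rmsep:.4f}")
# R2_P close to R2_cal indicates the selected bands generalise; RF tends to
# fit the calibration set hardest.
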