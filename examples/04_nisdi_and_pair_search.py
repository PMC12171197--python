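"""NISDI and the exhaustive two-band index searches.

NISDI = 1.3e3 * D(1559 nm) - 1.9 * R(1439 nm) combines the spectral slope
on the recovery flank of the 1440 nm water trough with the trough depth
itself.  The DVI/RVI/NDVI searches scan every ordered band pair for the
strongest Pearson correlation with water content.
"""

from leafwater import SimConfig, simulate_sample_table, split
from leafwater.vindex import fit_index_model, nisdi_table, pearson, search_pairs

table = simulate_sample_table(400, SimConfig(), seed=2)
cal, pred = split(table, 0.3, seed=2)

ni = nisdi_table(cal)
r = pearson(ni, cal.water_content)
print(f"NISDI vs wc: r = {r.r:.3f}, p = {r.p:.3g} (n = {r.n})")

model, metrics = fit_index_model(
    ni, cal.water_content, nisdi_table(pred), pred.water_content, n_wavelengths=3
)
print(f"NISDI linear model: wc = {model.slope:.4f} * NISDI + {model.intercept:.4f}")
print(f"  calibration R2 = {metrics.r2_cal:.4f}, RMSE = {metrics.rmse_cal:.4f}")
print(f"  prediction  R2 = {metrics.r2_pred:.4f}, RMSEP = {metrics.rmsep:.4f}")

for family in ("DVI", "RVI", "NDVI"):
    res = search_pairs(cal, family)
    wl_i, wl_j = res.best_wavelengths_nm(cal.grid)
    print(f"{family}: best pair ({wl_i:.0f}, {wl_j:.0f}) nm, |r| = {res.best_abs_r:.4f}")
# A strong negative NISDI slope means wetter leaves have deeper troughs and
# flatter recovery flanks; the pair searches typically anchor one band near
# the 1440 nm feature.
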