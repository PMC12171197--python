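"""Gravimetric water content and a simulated 4-step drying series.

A leaf group is weighed and imaged four times while drying; water content
at each step is (G_n - G_0) / G_n with G_0 the oven-dry mass.
"""

from leafwater import SimConfig, simulate_drying_series, water_content

print(f"fresh 2.0 g, dry 1.0 g -> wc = {water_content(2.0, 1.0):.2f}")

record, spectra = simulate_drying_series(
    "tree36-upper", initial_wc=0.75, dry_mass_g=1.0, config=SimConfig(), seed=4
)
band_1440 = SimConfig().grid.nearest(1440.0)
print("step  mass/g   wc      R(1440nm)")
for k in range(4):
    print(
        f"  G{k + 1}  {record.masses_g[k]:6.3f}  {record.water_contents[k]:.4f}"
        f"   {spectra[k, band_1440]:.4f}"
    )
# As the leaf dries the 1440 nm water-absorption trough fills in, so
# reflectance there rises while water content falls.
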