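"""The complete study in one call: report tables and the chosen model.

Runs every stage under a single seed and prints the model-comparison
table, the ranked winner and the cross-species transfer results.
"""

import tempfile
import warnings

from leafwater import PipelineConfig, run

warnings.filterwarnings("ignore")

with tempfile.TemporaryDirectory() as tmp:
    report = run(PipelineConfig(out_dir=tmp, seed=1))

print(f"preprocessing carried forward: {report.chosen_prep}")
print("selected bands:", {r["method"]: r["n_selected"] for r in report.selection})
print("\nmodel                na_bands  R2_P    RMSEP")
for row in report.model_rows:
    print(f"{row['model_id']:18s} {row['n_wavelengths']:5d}   {row['r2_pred']:.4f}  {row['rmsep']:.4f}")
chosen = report.chosen_model
print(f"\nchosen (parsimony rule): {chosen['model_id']} "
      f"({chosen['n_wavelengths']} wavelengths, R2_P = {chosen['r2_pred']:.4f})")
for row in report.cross_species:
    print(f"cross-species {row['species']:8s} {row['group']:14s} "
          f"r = {row['r']:.3f}, R2_P = {row['r2_pred']:.3f}, RMSEP = {row['rmsep']:.3f}")
# The winner is the most parsimonious model within 0.025 R2_P of the best;
# transfer to a matched species stays strong while the shifted 'lettuce'
# generator degrades it, as cross-growth-form transfer does on real leaves.
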