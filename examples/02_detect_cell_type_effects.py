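"""Detect cell-type-specific differential methylation with the interaction model.

Regresses each CpG's bulk values on cell fractions and phenotype-by-fraction
interactions (no intercept); the interaction coefficient gamma_k estimates
the within-cell-type case-control shift, tested with a two-sided t test and
BH-adjusted within each cell type.
"""

import numpy as np

from ctsdm import detect_dataset, preset_design, simulate_dataset, synthesize_reference

design = preset_design("450k", snr=11.0, n=100, scale=0.2)
panel = synthesize_reference(design.p, list(design.cell_types), seed=1)
ds = simulate_dataset(design, panel, seed=1)

res = detect_dataset(ds)  # uses the true fractions
calls = res.adjusted_p <= 0.05

print(f"residual df = {res.df} (n - 2K)")
for j, ct in enumerate(ds.cell_types):
    truth = ds.truth.truth[:, j]
    tp = int(np.sum(calls[:, j] & truth))
    fp = int(np.sum(calls[:, j] & ~truth))
    print(f"{ct:>11}: {calls[:, j].sum():4d} calls at BH<=0.05 "
          f"({tp} true, {fp} false; {int(truth.sum())} planted)")

# at planted CpGs the coefficient estimates the planted shift s_c
planted = ds.truth.truth
ratio = res.estimates[planted] / np.broadcast_to(
    ds.truth.effect_size[:, None], planted.shape)[planted]
print(f"mean gamma_hat / s_c over planted CpGs: {ratio.mean():.3f} "
      f"(1.0 = unbiased recovery of the planted effect)")
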