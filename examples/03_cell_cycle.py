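"""Classify S-phase cells from replication-dependent histone content.

Histone scores in a total-RNA experiment are bimodal: non-S cells sit in a
low mode, S-phase cells (replicating chromatin) in a high mode.  This
example fits the two-component Weibull mixture to simulated scores, derives
a data-driven threshold from the equal-posterior crossing, and compares it
with the fixed raw-count rule (score > 35).
"""

import numpy as np
import pandas as pd

from sctotal import cell_cycle as cc

rng = np.random.default_rng(0)
n = 3000
s_truth = rng.random(n) < 0.65  # two thirds of embryonic cells are cycling
scores = np.where(s_truth, rng.poisson(80.0, n), rng.poisson(8.0, n)).astype(float)

fit = cc.fit_weibull_mixture(scores, seed=0)
print("two-component Weibull fit (ascending scale):")
print(f"  weights: {fit.weights.round(3)}")
print(f"  shapes:  {fit.shapes.round(2)}")
print(f"  scales:  {fit.scales.round(2)}  <- low/high histone modes")
print(f"  converged: {fit.converged} after {fit.n_iter} iterations")

suggested = cc.suggest_threshold(fit)
print(f"equal-posterior crossing: {suggested:.1f} (fixed rule uses 35)")

for name, thr in [("fixed 35", 35.0), ("suggested", suggested)]:
    calls = cc.call_s_phase(pd.Series(scores), thr)
    acc = (calls.to_numpy() == s_truth).mean()
    frac = calls.mean()
    print(f"  {name:>10}: S-phase fraction {frac:.1%}, agreement with truth {acc:.1%}")
# both thresholds sit in the valley between the modes, so the raw-count rule
# and the mixture-derived rule classify essentially the same cells
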