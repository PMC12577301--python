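"""Predict FOG-Q severity from regional uptake with classical regressors.

Runs 10-fold cross-validated FOG-Q regression over the 29 PD subjects of the
default cohort, feeding each regressor the per-subject mean uptake of the
planted regions. Reported per-model numbers are MSE/MAE/RMSE as
mean +/- sample SD across the ten folds; lower is better, and the MSE of a
mean-only predictor would be roughly the FOG-Q variance of the cohort.
"""

import numpy as np

from fogpet import build_baselines, default_cohort_config, generate_cohort, run_cv
from fogpet.cv import select_task
from fogpet.pipeline import preprocess_volumes

cfg = default_cohort_config(seed=1)
records, volumes, truth = generate_cohort(cfg)
processed = preprocess_volumes(volumes, fwhm_mm=10.0, target=1.0)
idx, y = select_task(records, "fogq_regress")
vols = [processed[i] for i in idx]
ids = [records[i].id for i in idx]
print(f"FOG-Q over {len(y)} PD subjects: mean {np.mean(y):.2f}, var {np.var(y):.2f}")

for kind in ("poly_reg", "tree_reg", "forest_reg"):
    rep = run_cv(vols, np.asarray(y),
                 lambda fs, _k=kind: build_baselines(_k, region_masks=truth.effect_masks),
                 task_kind="regress", k=10, seed=0, subject_ids=ids,
                 task_name="fogq_regress", model_name=kind)
    parts = []
    for metric in ("mse", "mae", "rmse"):
        mean, sd = rep.aggregate[metric]
        parts.append(f"{metric.upper()} {mean:6.2f} +/- {sd:5.2f}")
    print(f"{kind:11s} " + "  ".join(parts))
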