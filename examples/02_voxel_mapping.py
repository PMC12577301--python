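"""Voxel-wise group mapping: PD-FOG vs PD-NFOG with cluster-extent filtering.

Simulates the default cohort, applies global-mean normalization and 10-mm
smoothing, computes the pooled-variance two-sample t map between the two PD
groups, Gaussianizes it to Z, and reports the clusters surviving a one-sided
voxel threshold of p < 0.001 with a 25-voxel extent, separately for
increases and decreases. The peak table lists world-space peak coordinates
(mm) and peak Z per cluster; compare the recovered locations against the
planted sphere centers printed at the end.
"""

import pandas as pd

from fogpet import (default_cohort_config, generate_cohort, peak_table,
                    preprocess_volumes, threshold_and_cluster, two_sample_t_map)

cfg = default_cohort_config(seed=1)
records, volumes, truth = generate_cohort(cfg)
processed = preprocess_volumes(volumes, fwhm_mm=10.0, target=1.0)

fog = [v for r, v in zip(records, processed) if r.group == "PD-FOG"]
nfog = [v for r, v in zip(records, processed) if r.group == "PD-NFOG"]
stat = two_sample_t_map(fog, nfog, volumes[0].mask)
print(f"two-sample t map: df={stat.df}, {int(stat.mask.sum())} in-mask voxels")

tables = []
for direction in ("A_gt_B", "A_lt_B"):
    cs = threshold_and_cluster(stat, p_voxel=0.001, extent_k=25, connectivity=26,
                               direction=direction)
    tables.append(peak_table(cs))
print(pd.concat(tables, ignore_index=True).round(2).to_string(index=False))

print("\nplanted FOG-specific effects (voxel centers, fraction):")
for spec in truth.effect_specs:
    if spec.group == "PD-FOG":
        print(f"  {spec.region_center}  {spec.effect_fraction:+.2f}")
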