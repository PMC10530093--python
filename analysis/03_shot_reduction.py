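#!/usr/bin/env python
"""Reduce a synthetic single-shot run and audit the pipeline.

Simulates one time point (a 30/50/20 unstructured/duplex/triplex
mixture): 2,000 sample and 2,000 buffer shots with 15% pulse-energy
jitter, Poisson counting on a dominant water background, and 5% of
frames contaminated by ice-diffraction spikes.  Reduces to an averaged,
pulse-normalized, outlier-filtered, buffer-subtracted profile and
reports how well selection and recovery worked against ground truth.
"""

import json
from pathlib import Path

import numpy as np

from rnawaxs.reduction import reduce_timepoint, select_shots
from rnawaxs.synthetic import NoiseConfig, make_basis_set, \
    simulate_timepoint_stack

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

SEED = 11
FRACTIONS = {"unstructured": 0.3, "duplex": 0.5, "triplex": 0.2}

basis, _ = make_basis_set(seed=0)
noise = NoiseConfig(ice_rate=0.05)
sample, buffer, truth = simulate_timepoint_stack(
    FRACTIONS, basis, n_frames=2000, noise=noise, seed=SEED)

# selection audit against truth labels
norm = sample.profiles / sample.pulse_energy[:, None]
keep, log = select_shots(norm, spike_k=6.0, drift_m=5.0)
flags = sample.truth["contaminated"]
sens = float((~keep)[flags].mean())
fpr = float((~keep)[~flags].mean())

red = reduce_timepoint(sample, buffer)
ok = np.abs(red.profile.I - truth.generating_profile.I) \
    <= 3.0 * red.profile.sigma
red.profile.write_dat(OUT / "reduced_mixture.dat")

report = {
    "seed": SEED,
    "n_frames_per_role": 2000,
    "ice_rate": noise.ice_rate,
    "n_kept": red.n_kept,
    "n_rejected": red.n_rejected,
    "spike_sensitivity": sens,
    "false_positive_rate": fpr,
    "bins_within_3sem": float(ok.mean()),
    "median_sem": float(np.median(red.profile.sigma)),
}
(OUT / "reduction_report.json").write_text(json.dumps(report, indent=2))
print(json.dumps(report, indent=2))
print(f"\nIce-spike filter caught {sens:.1%} of contaminated frames at "
      f"{fpr:.2%} false positives; {ok.mean():.1%} of bins recover the "
      "generating mixture within 3 SEM.")
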