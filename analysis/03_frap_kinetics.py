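#!/usr/bin/env python
"""FRAP residence-time extraction and iFRAP aggregation.

Simulates noisy recovery traces, applies photobleaching correction and
1/0 normalization, fits the biexponential recovery, and reports the
slower time constant (the chromatin residence time). Also aggregates
normalized iFRAP decays into a mean +/- SD curve. Writes
results/frap_fits.csv and results/ifrap_mean_sd.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from vermicelli.kinetics import (
    aggregate_traces,
    correct_photobleaching,
    fit_double_exponential,
    normalize_frap,
    normalize_ifrap,
)
from vermicelli.simulate import FrapSimParams, simulate_frap_trace, \
    simulate_ifrap_trace

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1, n_cells: int = 14) -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for k in range(n_cells):
        p = FrapSimParams(noise_sd=0.02, acquisition_bleach_rate=0.002,
                          n_post=300, seed=seed + k)
        trace = correct_photobleaching(simulate_frap_trace(p))
        norm = normalize_frap(trace)
        t = np.arange(p.n_post) * p.dt
        fit = fit_double_exponential(t, norm[p.n_pre:])
        rows.append({"cell": k, "A": fit.A, "tauA_s": fit.tauA,
                     "B": fit.B, "tauB_s": fit.tauB,
                     "residence_time_s": fit.residence_time,
                     "converged": fit.converged})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "frap_fits.csv", index=False)
    print(f"residence time over {n_cells} cells: median "
          f"{df['residence_time_s'].median():.1f} s (truth 30 s)")

    norms, times = [], None
    for k in range(n_cells):
        tr = simulate_ifrap_trace(FrapSimParams(
            mode="ifrap", noise_sd=0.02, n_post=200, seed=seed + 100 + k))
        norms.append(normalize_ifrap(tr))
        times = tr.times
    mean, sd = aggregate_traces(norms)
    pd.DataFrame({"time_s": times, "mean": mean, "sd": sd}).to_csv(
        RESULTS / "ifrap_mean_sd.csv", index=False)
    print(f"iFRAP aggregate over {n_cells} traces: final mean "
          f"{mean[-1]:.2f} (slow unbleached-region decay)")


if __name__ == "__main__":
    main()
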