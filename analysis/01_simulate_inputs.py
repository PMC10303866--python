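#!/usr/bin/env python
"""Generate one synthetic dataset of every kind the pipeline consumes.

Writes a control and a cohesin-overloaded (OE-like) contact map, a
fibrous nucleus image with its planted beads, FRAP/iFRAP traces, and a
territory voxel cloud summary under results/inputs/. These files are
regenerated deterministically from the seed; downstream scripts reuse
the same generators directly.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from vermicelli.config import AnalysisConfig
from vermicelli.pipeline import run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main(seed: int = 1) -> None:
    for preset in ("control", "oe"):
        cfg = AnalysisConfig({"global": {"seed": seed},
                              "simulate_hic": {"n_bins": 400,
                                               "bin_size": 100_000,
                                               "tad_size": 10,
                                               "block_size": 40}})
        out = run_pipeline(cfg, "simulate-hic", out_dir=OUT / preset,
                           preset=preset)
        print(f"{preset} contact map -> {out['matrix']}")

    cfg = AnalysisConfig({"global": {"seed": seed}})
    out = run_pipeline(cfg, "simulate-image", out_dir=OUT / "image")
    beads = pd.read_csv(OUT / "image" / "truth_beads.csv")
    print(f"nucleus image with {len(beads)} planted beads -> {out['image']}")

    out = run_pipeline(cfg, "simulate-frap", out_dir=OUT / "frap")
    print(f"FRAP/iFRAP traces -> {out['frap']}, {out['ifrap']}")


if __name__ == "__main__":
    main()
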