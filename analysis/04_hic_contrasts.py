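#!/usr/bin/env python
"""Genome-architecture contrasts between the paired condition presets.

Simulates the control and cohesin-overloaded contact-map presets with
paired seeds and recomputes every contrast: P(s) short/long-range
change, compartment mixing ratio, saddle corner enrichment, TAD-corner
differential contacts, TAD score, and TAD count/length stability.
Writes results/hic_contrasts.json and results/ps_curves.csv.
"""

import json
from pathlib import Path

import pandas as pd

from vermicelli import hic
from vermicelli.pipeline import compare_presets
from vermicelli.simulate import control_preset, oe_preset, \
    simulate_contact_map

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    out = compare_presets(seed=seed)
    (RESULTS / "hic_contrasts.json").write_text(
        json.dumps(out, indent=2, sort_keys=True, default=float) + "\n")

    kw = dict(n_bins=400, bin_size=100_000, depth=2e6, tad_size=10,
              block_size=40)
    rows = []
    for name, params in (("control", control_preset(seed=seed, **kw)),
                         ("oe", oe_preset(seed=seed + 10_000, **kw))):
        m, _ = simulate_contact_map(params)
        curve = hic.contact_probability(hic.ice_balance(
            m, min_coverage_mad=0))
        for c_bp, p, n in zip(curve.centers_bp, curve.probabilities,
                              curve.pair_counts):
            rows.append({"condition": name, "distance_bp": c_bp,
                         "probability": p, "n_pairs": n})
    pd.DataFrame(rows).to_csv(RESULTS / "ps_curves.csv", index=False)

    print(f"mixing ratio AB/(AA+BB): control "
          f"{out['mixing_ratio_control']:.3f} -> OE "
          f"{out['mixing_ratio_oe']:.3f} (compartments mix more)")
    print(f"saddle corner enrichment: control "
          f"{out['saddle_corner_control']:.2f} -> OE "
          f"{out['saddle_corner_oe']:.2f} (weaker segregation)")
    print(f"TAD score: control {out['tad_score_control']:.2f} -> OE "
          f"{out['tad_score_oe']:.2f} (more inter-TAD mixing); TAD count "
          f"{out['n_tads_control']} -> {out['n_tads_oe']}")
    print(f"all {8} contrast directions reproduced: "
          f"{out['all_directions_reproduced']}")


if __name__ == "__main__":
    main()
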