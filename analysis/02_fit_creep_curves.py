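#!/usr/bin/env python
"""Fit the biphasic model to every simulated creep curve.

Recovers equilibrium contact modulus and hydraulic permeability per region
by nonlinear least squares, applies the r^2 >= 0.70 and a/h <= 0.55
validity gates, and reports how many permeability records the gates drop —
these concentrate in thin, degenerate advanced-OA regions, where the
contact radius approaches the cartilage thickness.
"""

from pathlib import Path

import pandas as pd

from cartmap import PipelineConfig
from cartmap.pipeline import fit_stage
from cartmap import io as cio

OUT = Path("results/cohort")


def main() -> None:
    cfg = PipelineConfig(out_dir=OUT, seed=42)
    fit_stage(cfg)
    records = cio.read_fits_jsonl(OUT / "fits.jsonl")
    frame = pd.DataFrame({
        "group": [r.group for r in records],
        "thin_layer": [r.fit.thin_layer_flag for r in records],
        "valid_k": [r.fit.permeability_valid for r in records],
        "r2": [r.fit.r_squared for r in records],
    })
    print(f"fitted {len(records)} curves; median r^2 = {frame.r2.median():.3f}")
    drops = frame.groupby("group")["valid_k"].agg(lambda v: (~v).sum())
    print("permeability records dropped by the validity gates, per group:")
    print(drops.to_string())
    print("every equilibrium-modulus value is kept (the plateau is always "
          "well fit); only permeability is gated.")


if __name__ == "__main__":
    main()
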