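"""Regenerate the packaged synthetic manufacturer table.

Runs the homogeneous-tissue forward model at the default source
parameters over the clinically used power/duration range and writes the
predicted ablation ellipsoid dimensions to
src/mwablate/data/manufacturer_table_synthetic.csv.

The table is synthetic by construction: it stands in for vendor ex-vivo
specification sheets, which are not public, and is self-consistent with
the package's deposition model (the calibration self-test recovers the
default parameters from it).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mwablate import applicator as app
from mwablate import bioheat as bh
from mwablate.grid import VoxelGrid


def main() -> None:
    tissue = bh.TissueModel()
    blood = bh.BloodModel()
    params = app.SourceParams()
    n, h = 61, 2.0
    half = (n - 1) / 2 * h
    grid = VoxelGrid((n, n, n), (h, h, h), (-half, -half, -half))

    rows = []
    for power in (80.0, 90.0, 100.0):
        for dur_min in range(3, 11):
            length, diam = app.simulate_homogeneous_ablation(
                power, dur_min * 60.0, params, tissue, blood, grid)
            rows.append({
                "power_w": power,
                "duration_min": float(dur_min),
                "length_mm": round(length, 1),
                "diameter_mm": round(diam, 1),
            })
            print(rows[-1])
    frame = pd.DataFrame(rows)
    out = Path(__file__).resolve().parents[1] / "src" / "mwablate" / "data" \
        / "manufacturer_table_synthetic.csv"
    frame.to_csv(out, index=False)
    print(f"wrote {out} ({len(frame)} rows)")


if __name__ == "__main__":
    main()
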