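"""Generate the synthetic study region and summarize what it contains.

Writes the world itself (rasters, occurrence CSV, reserve polygons, truth
tables) under scratch/world/ and a compact per-species summary to
results/world_summary.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study_config import study_config

from sdmshift.pipeline import simulate_world, write_world

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = study_config()
    world = simulate_world(cfg)
    write_world(world, ROOT / "scratch" / "world")

    land = world.current.land_mask
    rows = []
    for sid in sorted(world.occurrences):
        occ = world.occurrences[sid]
        suit = world.truth_suitability[sid]
        rows.append(
            {
                "species": sid,
                "n_records": len(occ.records),
                "n_cells": len(occ.cells),
                "true_prevalence": suit.values[land].mean(),
                "dominant_eta": np.abs(world.truth_eta[sid]).max(),
            }
        )
    df = pd.DataFrame(rows)
    out = ROOT / "results" / "world_summary.csv"
    out.parent.mkdir(exist_ok=True)
    df.to_csv(out, index=False, float_format="%.6g")

    print(f"study region: {world.current.grid.shape} cells, "
          f"{int(land.sum())} on land ({land.mean():.0%})")
    print(f"{len(world.occurrences)} species, "
          f"{sum(len(o.records) for o in world.occurrences.values())} records, "
          f"{len(world.pas)} reserves")
    print(f"mean true prevalence {df['true_prevalence'].mean():.3f}")
    print(f"world written to scratch/world/, summary to {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
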