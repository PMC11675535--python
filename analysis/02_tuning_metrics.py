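#!/usr/bin/env python
"""Compute per cell x speed tuning metrics on the synthetic population.

Writes the feature table (preferred direction, sensitivity index, inverse
CV, AP/PD ratio, peak count, spontaneous rate, most-active flag) and
reports how well the vector-sum preferred direction recovers each
directional cell's generating preferred direction at its center speed.
"""

import argparse
from pathlib import Path

import numpy as np

from lmspeed.metrics import circ_dist
from lmspeed.pipeline import RunConfig, run_pipeline


def main(seed: int = 1, out: Path = Path("results")) -> None:
    result = run_pipeline(RunConfig(seed=seed, out_dir=out,
                                    stages=("simulate", "metrics")))
    features = result.tables["features"]
    truth = result.tables["ground_truth"]

    merged = features.merge(truth, on=["cell_id", "speed"])
    directional = merged[
        (merged["archetype"].isin(["directional", "dir_to_omni"]))
        & (merged["speed"] == 32.0)
    ]
    err = circ_dist(directional["pd"], directional["pd_true"])
    print(f"{len(features)} cell x speed feature rows written")
    print(f"PD recovery at 32 deg/s over {len(directional)} directional cells: "
          f"mean abs circular error {np.mean(err):.1f} deg "
          f"(sampling step is 45 deg)")


if __name__ == "__main__":
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--out", type=Path, default=Path("results"))
    a = p.parse_args()
    main(a.seed, a.out)
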