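#!/usr/bin/env python
"""Simulate a ramp-CPET cohort and write it as breath tables + manifest.

The cohort mirrors the target study design: four sex/age cells, 8-12 min
ramp tests, ~305 breaths per test, post-midpoint AR(1)-correlated
innovations for the gas-exchange metrics and HR, a 1.15 female complexity
multiplier, and a low rate of injected out-of-range artifacts so the
cleaning stage has real work to do.

Writes results/cohort/ (CSV per participant, manifest.csv, truth.json).
"""

import argparse
import json
from pathlib import Path

import numpy as np

from cpet_entropy import CohortSpec, generate_cohort
from cpet_entropy.data_model import write_manifest

parser = argparse.ArgumentParser()
parser.add_argument("--n-per-cell", type=int, default=12,
                    help="participants per sex/age cell (study template: 40-45)")
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--out", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

spec = CohortSpec(
    n_per_group={(s, a): args.n_per_cell for s in ("male", "female") for a in ("younger", "older")},
    artifact_rate=0.005,
    seed=args.seed,
)
cohort = generate_cohort(spec)
manifest = write_manifest(cohort.series, args.out)
(args.out / "truth.json").write_text(
    json.dumps({pid: t.__dict__ for pid, t in cohort.truth.items()}, default=str, indent=1)
)

counts = [len(s) for s in cohort.series]
durations = [s.duration_s / 60 for s in cohort.series]
print(f"wrote {len(cohort.series)} participants to {args.out}")
print(f"breaths/test: mean {np.mean(counts):.1f} (sd {np.std(counts):.1f}), "
      f"range {min(counts)}-{max(counts)}")
print(f"duration: {np.mean(durations):.1f} min (range {min(durations):.1f}-{max(durations):.1f})")
n_art = sum(len(v) for t in cohort.truth.values() for v in t.artifact_positions.values())
print(f"injected out-of-range artifacts: {n_art} (positions recorded in truth.json)")
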