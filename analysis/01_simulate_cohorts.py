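#!/usr/bin/env python
"""Simulate trafficking cohorts for three genotype-like presets.

Generates wild-type, SVBP-KO-like and TTL-KO-like cohorts (axons x tracks,
180 frames at 1 s and 0.175 um/px) with known generative parameters, writes
the raw per-axon track CSVs + ground-truth sidecars under scratch/ (bulky,
regenerable) and a small cohort manifest under results/.
"""

import json
from pathlib import Path

import numpy as np

from axotraffic import io as aio
from axotraffic.synthetic import simulate_tracks, svbp_ko_preset, ttl_ko_preset, wt_preset

SEED = 2024
N_AXONS = {"wt": 60, "svbp_ko": 40, "ttl_ko": 40}
N_TRACKS = 20
KYMO_LENGTH_UM = 111.1

PRESETS = {"wt": wt_preset, "svbp_ko": svbp_ko_preset, "ttl_ko": ttl_ko_preset}


def main() -> None:
    root = Path(__file__).resolve().parents[1]
    scratch = root / "scratch" / "synthetic_tracks"
    results = root / "results"
    results.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    manifest = {"seed": SEED, "n_tracks_per_axon": N_TRACKS,
                "kymo_length_um": KYMO_LENGTH_UM, "groups": {}}
    for group, preset_fn in PRESETS.items():
        out = scratch / group
        out.mkdir(parents=True, exist_ok=True)
        for i in range(N_AXONS[group]):
            seed = int(rng.integers(0, 2**31 - 1))
            tracks, truth = simulate_tracks(preset_fn(n_particles=N_TRACKS, seed=seed))
            axon = f"{group}_axon{i:03d}"
            aio.write_tracks_csv(tracks, out / f"{axon}.csv")
            aio.write_axon_metadata(out / f"{axon}.json", kymo_length_um=KYMO_LENGTH_UM)
            gt = {tid: {"stationary": tt.stationary, "runs": tt.runs,
                        "pauses_s": tt.pauses_s}
                  for tid, tt in truth.tracks.items()}
            (out / f"{axon}.groundtruth.json").write_text(json.dumps(gt))
        manifest["groups"][group] = {"n_axons": N_AXONS[group], "dir": str(out.relative_to(root))}
        print(f"{group}: {N_AXONS[group]} axons x {N_TRACKS} tracks -> {out}")
    (results / "cohort_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"manifest -> {results / 'cohort_manifest.json'}")


if __name__ == "__main__":
    main()
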