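#!/usr/bin/env python
"""Per-cell membrane-potential features from the simulated bundles.

Reads every bundle written by 01_simulate_cohort.py through the normative
CSV/JSON path, extracts the feature vector (spectral upper cutoff, AP
amplitude, peak-to-sustained ratios, input resistance, sustained
hyperpolarization), and writes results/features.csv.
"""

from pathlib import Path

import pandas as pd

from lso_ephys.cohort import extract_features
from lso_ephys.core_io import read_cell_bundle

ROOT = Path(__file__).resolve().parents[1]
BUNDLES = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    if not BUNDLES.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    rows = []
    for bundle in sorted(BUNDLES.iterdir()):
        if not (bundle / "metadata.json").exists():
            continue
        cell = read_cell_bundle(bundle)
        fv = extract_features(cell)
        rows.append(vars(fv))
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "features.csv", index=False)
    print(f"extracted features for {len(table)} cells -> results/features.csv")
    with pd.option_context("display.width", 120):
        print(
            table[["cell_id", "upper_cutoff", "ap_amplitude", "r_in_steady"]]
            .round(1)
            .to_string(index=False)
        )


if __name__ == "__main__":
    main()
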