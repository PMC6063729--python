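#!/usr/bin/env python
"""ILD functions per cell, for the onset and sustained response windows.

Builds rate-vs-ILD curves from the binaural protocols and fits the
decreasing four-parameter logistic.  The expected dissociation: every cell
codes ILD at sound onset, but only non-principal (sustained-firing) cells
carry ILD information beyond the first 10 ms.
"""

from pathlib import Path

import pandas as pd

from lso_ephys import ild as ildm
from lso_ephys.core_io import ValidationError, read_cell_bundle

ROOT = Path(__file__).resolve().parents[1]
BUNDLES = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    if not BUNDLES.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    curve_rows, fit_rows = [], []
    for bundle in sorted(BUNDLES.iterdir()):
        if not (bundle / "metadata.json").exists():
            continue
        cell = read_cell_bundle(bundle)
        protos = cell.protocols_with_prefix("ild_")
        if not protos:
            continue
        for window in ("onset", "sustained"):
            curve = ildm.build_ild_curve(protos, window=window)
            for i, r, nr in zip(curve.ild, curve.rate, curve.normalized_rate):
                curve_rows.append(
                    {
                        "cell_id": cell.cell_id, "window": window,
                        "ild_db": i, "rate_hz": r, "normalized_rate": nr,
                    }
                )
            row = {"cell_id": cell.cell_id, "window": window}
            try:
                fit = ildm.fit_ild_sigmoid(curve)
                row.update(
                    converged=fit.converged,
                    midpoint_db=round(fit.midpoint, 2) if fit.midpoint else None,
                    floor_hz=round(fit.floor, 1),
                    ceiling_hz=round(fit.ceiling, 1),
                    range20_db=round(fit.range_20_80[0], 2),
                    range80_db=round(fit.range_20_80[1], 2),
                    rmse_hz=round(fit.rmse, 2),
                )
            except ValidationError as exc:
                row.update(converged=False, note=str(exc))
            fit_rows.append(row)
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(curve_rows).to_csv(RESULTS / "ild_curves.csv", index=False)
    fits = pd.DataFrame(fit_rows)
    fits.to_csv(RESULTS / "ild_fits.csv", index=False)
    for window in ("onset", "sustained"):
        sub = fits[fits.window == window]
        ok = sub[sub.converged == True]  # noqa: E712
        print(
            f"{window:9s} window: {len(ok)}/{len(sub)} sigmoids converged"
            + (
                f", median midpoint {ok.midpoint_db.median():+.1f} dB ILD"
                if len(ok)
                else ""
            )
        )
    print("curves -> results/ild_curves.csv, fits -> results/ild_fits.csv")


if __name__ == "__main__":
    main()
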