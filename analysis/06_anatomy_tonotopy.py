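#!/usr/bin/env python
"""Anatomical quantification: positions on a centerline and tonotopy.

Places the simulated somata on a synthetic U-shaped LSO centerline at their
generated arc-length fractions, re-measures the normalized lateromedial
position with the projection estimator, and checks the tonotopic gradient
(Spearman rank correlation of BF against position).  Also reruns the
somatic-coverage arithmetic on a constructed single-section example.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lso_ephys import anatomy as anat

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def u_centerline(n=40):
    theta = np.linspace(np.pi, 0.0, n)
    return anat.CenterlineMap(
        np.column_stack([250.0 * np.cos(theta), -180.0 * np.sin(theta)])
    )


def main() -> None:
    truth = pd.read_csv(RESULTS / "ground_truth.csv")
    cl = u_centerline()
    v, seg = cl.vertices, np.diff(u_centerline().vertices, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    rng = np.random.default_rng(2)
    rows = []
    for r in truth.itertuples():
        arc = r.normalized_position * cum[-1]
        i = np.clip(np.searchsorted(cum, arc, "right") - 1, 0, len(seg) - 1)
        p = v[i] + (arc - cum[i]) / seg_len[i] * seg[i]
        # displace the soma off the centerline, as real somata are
        normal = seg[i][::-1] * [-1, 1] / seg_len[i]
        soma = p + normal * rng.uniform(-30.0, 30.0)
        pos = anat.normalized_position(cl, soma)
        rows.append(
            {
                "cell_id": r.cell_id,
                "x_um": round(soma[0], 1),
                "y_um": round(soma[1], 1),
                "normalized_position": round(pos, 4),
                "bf_hz": r.bf_hz,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "anatomy.csv", index=False)

    tono = anat.tonotopy_stat(list(zip(table.normalized_position, table.bf_hz)))
    cov = anat.coverage_percent(
        anat.CoverageMeasurement([100.0], [[40.0, 35.3]])
    )
    print(f"positions for {len(table)} somata -> results/anatomy.csv")
    print(
        f"tonotopy: Spearman rho = {tono.rho:.2f}, p = {tono.p_two_tailed:.2g} "
        f"(n = {tono.n}); BF rises toward the medial pole"
    )
    print(
        f"coverage worked example: {cov.percent:.1f}% of a 100 um perimeter "
        f"(single section, validity flag {cov.valid})"
    )


if __name__ == "__main__":
    main()
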