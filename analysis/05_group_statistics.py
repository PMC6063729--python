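#!/usr/bin/env python
"""Cross-cell statistics: classification, group comparisons, correlation.

Classifies the cohort in (log10 cutoff, AP amplitude) space against the
ground truth, compares the two groups with pooled-variance t tests and
Hedges' g, reproduces the published comparisons from their printed
summaries, and correlates evoked spike rate with sustained contralateral
hyperpolarization.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from lso_ephys import cohort as coh
from lso_ephys.spike_stats import extract_trains, window_rate
from lso_ephys.core_io import read_cell_bundle
from lso_ephys.vm_features import FeatureVector

ROOT = Path(__file__).resolve().parents[1]
BUNDLES = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    features = pd.read_csv(RESULTS / "features.csv")
    truth = pd.read_csv(RESULTS / "ground_truth.csv").set_index("cell_id")
    fvs = [
        FeatureVector(
            cell_id=r.cell_id, upper_cutoff=r.upper_cutoff, ap_amplitude=r.ap_amplitude
        )
        for r in features.itertuples()
    ]
    res = coh.cluster_cells(fvs)
    labels = pd.DataFrame(
        {
            "cell_id": [f.cell_id for f in fvs],
            "assigned": res.labels,
            "confidence": np.round(res.confidence, 3),
        }
    ).set_index("cell_id")
    labels["true"] = truth.true_label
    acc = (labels.assigned == labels.true).mean()
    labels.to_csv(RESULTS / "classification.csv")

    is_p = labels.true.loc[features.cell_id] == "principal"
    fc_p = features.upper_cutoff[is_p.values]
    fc_n = features.upper_cutoff[~is_p.values]
    amp_p = features.ap_amplitude[is_p.values]
    amp_n = features.ap_amplitude[~is_p.values]

    stats_out = {
        "classification_accuracy": round(float(acc), 4),
        "upper_cutoff": {
            "principal_mean_hz": round(fc_p.mean(), 1),
            "principal_sem_hz": round(fc_p.sem(), 1),
            "non_principal_mean_hz": round(fc_n.mean(), 1),
            "non_principal_sem_hz": round(fc_n.sem(), 1),
            "t": round(coh.pooled_t_from_samples(fc_p, fc_n).statistic, 2),
            "hedges_g": round(
                coh.hedges_g(coh.summarize(fc_p), coh.summarize(fc_n)), 2
            ),
        },
        "ap_amplitude": {
            "principal_mean_mv": round(amp_p.mean(), 1),
            "non_principal_mean_mv": round(amp_n.mean(), 1),
            "t": round(coh.pooled_t_from_samples(amp_p, amp_n).statistic, 2),
            "hedges_g": round(
                coh.hedges_g(coh.summarize(amp_p), coh.summarize(amp_n)), 2
            ),
        },
        "published_summaries_reproduced": {
            "cutoff_t10": round(
                coh.pooled_t_from_summaries(
                    coh.GroupSummary(5, 528.7, 66.5), coh.GroupSummary(7, 131.4, 15.5)
                ).statistic,
                3,
            ),
            "cutoff_g": round(
                coh.hedges_g(
                    coh.GroupSummary(5, 528.7, 66.5), coh.GroupSummary(7, 131.4, 15.5)
                ),
                3,
            ),
            "ap_t10": round(
                coh.pooled_t_from_summaries(
                    coh.GroupSummary(5, 28.3, 5.2), coh.GroupSummary(7, 66.3, 4.5)
                ).statistic,
                3,
            ),
            "ap_g": round(
                abs(
                    coh.hedges_g(
                        coh.GroupSummary(5, 28.3, 5.2), coh.GroupSummary(7, 66.3, 4.5)
                    )
                ),
                3,
            ),
        },
    }

    # evoked rate vs sustained contralateral hyperpolarization
    if BUNDLES.exists():
        rates, hyps = [], []
        for r in features.itertuples():
            if pd.isna(r.sustained_hyperpol):
                continue
            cell = read_cell_bundle(BUNDLES / r.cell_id)
            trains = extract_trains(cell.protocols["ipsi_tone"])
            rates.append(window_rate(trains, (0.0, 70.0)))
            hyps.append(r.sustained_hyperpol)
        if len(rates) >= 3:
            pr = coh.pearson_r(rates, hyps)
            stats_out["rate_vs_sustained_hyperpol"] = {
                "r": round(pr.statistic, 2),
                "p": round(pr.p_two_tailed, 3),
                "n": len(rates),
            }

    with open(RESULTS / "group_stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=1)
    print(f"classification accuracy vs ground truth: {acc:.1%}")
    print(
        "upper cutoff: principal "
        f"{stats_out['upper_cutoff']['principal_mean_hz']} +/- "
        f"{stats_out['upper_cutoff']['principal_sem_hz']} Hz vs non-principal "
        f"{stats_out['upper_cutoff']['non_principal_mean_hz']} +/- "
        f"{stats_out['upper_cutoff']['non_principal_sem_hz']} Hz "
        f"(t = {stats_out['upper_cutoff']['t']}, "
        f"g = {stats_out['upper_cutoff']['hedges_g']})"
    )
    print(
        "AP amplitude: principal "
        f"{stats_out['ap_amplitude']['principal_mean_mv']} mV vs "
        f"{stats_out['ap_amplitude']['non_principal_mean_mv']} mV "
        f"(t = {stats_out['ap_amplitude']['t']})"
    )
    pub = stats_out["published_summaries_reproduced"]
    print(
        f"published summaries reproduce t10 = {pub['cutoff_t10']}, "
        f"g = {pub['cutoff_g']} (cutoff) and t10 = {pub['ap_t10']}, "
        f"g = {pub['ap_g']} (AP amplitude)"
    )
    print("-> results/classification.csv, results/group_stats.json")


if __name__ == "__main__":
    main()
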