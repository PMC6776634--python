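#!/usr/bin/env python
"""ON/OFF/ON-OFF/NC composition of mechanically responsive clusters.

Classifies every unit from its white/black flash responses via the Bias
Index (ON > 0.3, OFF < -0.3, else ON-OFF; NC when the flash peak does not
clear basal variability) and compares cell-type composition between the
clusters flagged responsive to the mechanical stimulus and the rest.

Run after 01 and 04:  python analysis/05_rgc_classification.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from retinamech import classify as cl
from retinamech import io as rio
from retinamech import spikes as sp

DATA = Path("scratch/dataset")
OUT = Path("results")
DURATION_S = 250.0
BASAL_IV = (80.0, 200.0)  # after the flash protocol, before the indentation


def main() -> None:
    sts = rio.read_spike_csv(DATA / "spikes.csv", recording_duration_s=DURATION_S)
    sts.events.extend(rio.read_events_csv(DATA / "events.csv"))
    sts = sp.filter_units(sts, min_rate_hz=0.1)

    labeled = cl.classify_units(cl.peak_amplitudes(sts, basal_interval=BASAL_IV))
    labeled.to_csv(OUT / "classification.csv", index=False, float_format="%.6g")
    counts = labeled["label"].value_counts()
    print("cell-type counts:", counts.to_dict())

    labels_df = pd.read_csv(OUT / "cluster_labels.csv")
    summary = json.loads((OUT / "cluster_summary.json").read_text())
    clusters = sp.ClusterAssignment(
        labels_df["unit_id"].tolist(),
        labels_df["cluster"].to_numpy(),
        summary["k_selected"],
        {},
    )
    comp = cl.cluster_composition(
        labeled, clusters, set(summary["responsive_clusters"])
    )
    comp.to_csv(OUT / "composition.csv", index=False, float_format="%.4f")
    print(comp.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    if len(comp) == 2:
        d = comp.set_index("group")
        delta = d.loc["responsive", "frac_ON"] - d.loc["unresponsive", "frac_ON"]
        print(f"ON enrichment in responsive clusters: {100 * delta:+.1f} percentage points")


if __name__ == "__main__":
    main()
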