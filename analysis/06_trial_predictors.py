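#!/usr/bin/env python
"""Which trial features predict a successful mechanical stimulation?

Builds the per-trial feature table (contact area, strain, pressure, depth,
local unit density d5 and local basal rate r5) with a planted
"pressure AND d5" success rule plus 5% label noise, then averages
normalized Gini importances of a decision tree over 1000 stratified
80/20-split refits.

Run:  python analysis/06_trial_predictors.py
"""

import json
from pathlib import Path

import numpy as np

from retinamech import predictors as pred
from retinamech import synth

OUT = Path("results")
SEED = 2026


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = synth.simulate_trial_table(n_trials=200, seed=SEED, label_noise=0.05)
    table.to_csv(OUT / "trial_features.csv", index=False, float_format="%.6g")
    print(
        f"{len(table)} trials, {table['outcome'].mean():.0%} successful "
        "(planted rule: pressure > 100 Pa AND d5 > 7, 5% label noise)"
    )

    imp = pred.feature_importance(table, n_repeats=1000, seed=SEED + 1)
    (OUT / "importance.json").write_text(json.dumps(imp, indent=2, sort_keys=True))
    order = np.argsort(imp["mean_importance"])[::-1]
    print("mean +/- sd Gini importance over 1000 repeats:")
    for i in order:
        print(
            f"  {imp['features'][i]:>18s}  "
            f"{imp['mean_importance'][i]:.3f} +/- {imp['sd_importance'][i]:.3f}"
        )
    top2 = {imp["features"][i] for i in order[:2]}
    print(f"-> top-2 predictors: {sorted(top2)}")


if __name__ == "__main__":
    main()
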