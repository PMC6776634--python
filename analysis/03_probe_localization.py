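#!/usr/bin/env python
"""Locate the indentation probe on the electrode grid.

Far-red light saturates every electrode except those shadowed by the probe;
the largest 4-connected non-saturating component marks the footprint and
its centroid the stimulation site used by the spatial analyses.

Run after 01:  python analysis/03_probe_localization.py
"""

import json
from pathlib import Path

from retinamech import io as rio
from retinamech import localize

DATA = Path("scratch/dataset")
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    frame = rio.read_frame_csv(DATA / "saturation_frame.csv")
    res = localize.localize_probe(frame, min_region=8)
    center = res["center"]
    (OUT / "probe_center.json").write_text(
        json.dumps(
            {"center_row": center[0], "center_col": center[1],
             "shadow_electrodes": int(res["shadow"].sum())}
        )
    )
    print(f"shadow component: {int(res['shadow'].sum())} electrodes")
    print(f"estimated probe center: electrode {center}")


if __name__ == "__main__":
    main()
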