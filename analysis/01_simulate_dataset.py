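#!/usr/bin/env python
"""Generate the demo dataset both measurement streams feed on.

One synthetic retina on the 64x64 MEA (260 background units + four planted
mechanically evoked clusters of 20, flash protocol then a 30 s indentation),
ten dynamic-indentation traces on a 50 um scan grid (5 nm deflection noise),
and a far-red saturation frame with the probe shadow.  Raw data land in
scratch/dataset/ (they are large); downstream scripts read from there.

Run:  python analysis/01_simulate_dataset.py
"""

from pathlib import Path

from retinamech import io as rio
from retinamech import synth

SEED = 2026
DATA = Path("scratch/dataset")

STIM_ONSET_S, STIM_OFFSET_S = 200.0, 230.0
DURATION_S = 250.0


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    (DATA / "traces").mkdir(exist_ok=True)

    tissue = synth.TissueModel.retina_like()
    protocol = synth.IndentationProtocol.map_sweep(depth_um=15.0)
    for i in range(10):
        tr = synth.simulate_indentation_trace(
            protocol, tissue, probe_radius_um=57.0, noise_sd_um=0.005,
            seed=SEED + i, location_xy_um=(50.0 * (i % 5), 50.0 * (i // 5)),
        )
        rio.write_trace_csv(tr, DATA / "traces" / f"trace_{i:03d}.csv")
    print("wrote 10 indentation traces (K' preset 0.7 kPa @ 0.1 Hz -> 1.7 kPa @ 10 Hz)")

    retina = synth.RetinaConfig.four_cluster_preset(
        seed=SEED, n_background=260, cluster_size=20
    )
    flashes = synth.alternating_flash_schedule(10.0, 30)
    stim = synth.StimEvent(onset_s=STIM_ONSET_S, offset_s=STIM_OFFSET_S, depth_um=30.0)
    sts = synth.simulate_spike_trains(retina, [stim], flashes, DURATION_S, seed=SEED + 1)
    rio.write_spike_csv(sts, DATA / "spikes.csv")
    rio.write_events_csv(sts.events, DATA / "events.csv")
    n_spikes = sum(u.spike_times_s.size for u in sts.units)
    print(f"wrote {len(sts.units)} units, {n_spikes} spikes, {len(sts.events)} events")

    frame = synth.simulate_saturation_frame(
        retina.grid_shape, retina.indent_center, 6.0, flip_noise=0.02, seed=SEED + 2
    )
    rio.write_frame_csv(frame, DATA / "saturation_frame.csv")
    print(f"wrote saturation frame; true probe center {retina.indent_center}")


if __name__ == "__main__":
    main()
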