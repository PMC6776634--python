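"""File formats, run configuration and the end-to-end pipeline.

CSV schemas (RFC-4180, UTF-8, '.' decimal):

* spikes:  ``unit_id, electrode_row, electrode_col, spike_time_s`` (one row
  per spike; units without spikes survive only in the HDF5 container)
* events:  ``kind, time_s, depth_um, amplitude_um, frequency_hz``
* trace:   header comments ``# probe_radius_um=..`` / ``# spring_constant_n_per_m=..``
  then ``time_s, piezo_um, deflection_um, load_un, segment``
* frame:   64 x 64 grid of 0/1 (1 = saturating)

The HDF5 layout mirrors the CSVs under groups ``/spikes``, ``/events`` and
``/grid``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import classify, localize, mechanics, predictors, spikes as sp, synth
from .errors import SchemaError

log = logging.getLogger("retinamech")

__all__ = [
    "RunConfig",
    "read_spike_csv",
    "write_spike_csv",
    "read_events_csv",
    "write_events_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_frame_csv",
    "write_frame_csv",
    "write_spike_h5",
    "read_spike_h5",
    "run_full_pipeline",
]

FLOAT_FMT = "%.9g"


# ---------------------------------------------------------------------------
# spike trains


def write_spike_csv(sts: sp.SpikeTrainSet, path: str | Path) -> None:
    rows = []
    for u in sts.units:
        for t in u.spike_times_s:
            rows.append((u.unit_id, u.electrode_row, u.electrode_col, t))
    df = pd.DataFrame(rows, columns=["unit_id", "electrode_row", "electrode_col", "spike_time_s"])
    df.to_csv(path, index=False, float_format="%.9f")  # ns precision keeps ISIs > 0


def read_spike_csv(
    path: str | Path, recording_duration_s: float, grid_shape: tuple[int, int] = (64, 64)
) -> sp.SpikeTrainSet:
    df = pd.read_csv(path)
    required = {"unit_id", "electrode_row", "electrode_col", "spike_time_s"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"spike file missing columns: {sorted(missing)}")
    units = []
    for uid, g in df.groupby("unit_id", sort=True):
        t = g["spike_time_s"].to_numpy(float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise SchemaError(f"unit {uid}: spike times not strictly increasing")
        rows = g["electrode_row"].unique()
        cols = g["electrode_col"].unique()
        if len(rows) != 1 or len(cols) != 1:
            raise SchemaError(f"unit {uid}: inconsistent electrode coordinates")
        units.append(sp.Unit(int(uid), int(rows[0]), int(cols[0]), t))
    return sp.SpikeTrainSet(
        units=units, recording_duration_s=recording_duration_s, grid_shape=grid_shape
    )


def write_events_csv(events: list[sp.Event], path: str | Path) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "kind": e.kind,
                "time_s": e.time_s,
                "depth_um": e.params.get("depth_um", ""),
                "amplitude_um": e.params.get("amplitude_um", ""),
                "frequency_hz": e.params.get("frequency_hz", ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[sp.Event]:
    df = pd.read_csv(path)
    if "kind" not in df.columns or "time_s" not in df.columns:
        raise SchemaError("events file requires 'kind' and 'time_s' columns")
    events = []
    for _, row in df.iterrows():
        params = {
            k: float(row[k])
            for k in ("depth_um", "amplitude_um", "frequency_hz")
            if k in df.columns and pd.notna(row[k])
        }
        events.append(sp.Event(str(row["kind"]), float(row["time_s"]), params))
    return events


def write_spike_h5(sts: sp.SpikeTrainSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("spikes")
        g.create_dataset("unit_id", data=np.array(sts.unit_ids, dtype=np.int64))
        g.create_dataset("electrode", data=sts.positions().astype(np.int64))
        counts = np.array([u.spike_times_s.size for u in sts.units], dtype=np.int64)
        g.create_dataset("spike_counts", data=counts)
        all_t = (
            np.concatenate([u.spike_times_s for u in sts.units])
            if sts.units
            else np.empty(0)
        )
        g.create_dataset("spike_times_s", data=all_t)
        ge = f.create_group("events")
        ge.create_dataset(
            "kind", data=np.array([e.kind for e in sts.events], dtype=h5py.string_dtype())
        )
        ge.create_dataset("time_s", data=np.array([e.time_s for e in sts.events]))
        gg = f.create_group("grid")
        gg.attrs["shape"] = sts.grid_shape
        gg.attrs["pitch_um"] = sts.pitch_um
        f.attrs["recording_duration_s"] = sts.recording_duration_s


def read_spike_h5(path: str | Path) -> sp.SpikeTrainSet:
    with h5py.File(path, "r") as f:
        g = f["spikes"]
        ids = g["unit_id"][:]
        pos = g["electrode"][:]
        counts = g["spike_counts"][:]
        all_t = g["spike_times_s"][:]
        offsets = np.concatenate([[0], np.cumsum(counts)])
        units = [
            sp.Unit(int(ids[i]), int(pos[i, 0]), int(pos[i, 1]), all_t[offsets[i]: offsets[i + 1]])
            for i in range(len(ids))
        ]
        events = [
            sp.Event(k.decode() if isinstance(k, bytes) else str(k), float(t))
            for k, t in zip(f["events"]["kind"][:], f["events"]["time_s"][:])
        ]
        return sp.SpikeTrainSet(
            units=units,
            recording_duration_s=float(f.attrs["recording_duration_s"]),
            events=events,
            grid_shape=tuple(int(v) for v in f["grid"].attrs["shape"]),
            pitch_um=float(f["grid"].attrs["pitch_um"]),
        )


# ---------------------------------------------------------------------------
# indentation traces and saturation frames


def write_trace_csv(trace: mechanics.IndentationTrace, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as f:
        f.write(f"# probe_radius_um={trace.probe_radius_um:.6g}\n")
        f.write(f"# spring_constant_n_per_m={trace.spring_constant_n_per_m:.6g}\n")
        if trace.location_xy_um is not None:
            f.write(
                f"# location_xy_um={trace.location_xy_um[0]:.6g},{trace.location_xy_um[1]:.6g}\n"
            )
        pd.DataFrame(
            {
                "time_s": trace.time_s,
                "piezo_um": trace.piezo_um,
                "deflection_um": trace.deflection_um,
                "load_un": trace.load_un,
                "segment": trace.segment_labels,
            }
        ).to_csv(f, index=False, float_format="%.9g")


def read_trace_csv(path: str | Path) -> mechanics.IndentationTrace:
    header: dict[str, str] = {}
    with open(path, encoding="utf-8") as f:
        pos = f.tell()
        while True:
            line = f.readline()
            if not line.startswith("#"):
                f.seek(pos)
                break
            key, _, val = line[1:].strip().partition("=")
            header[key.strip()] = val.strip()
            pos = f.tell()
        df = pd.read_csv(f)
    if "probe_radius_um" not in header or "spring_constant_n_per_m" not in header:
        raise SchemaError("trace header must carry probe radius and spring constant")
    loc = None
    if "location_xy_um" in header:
        x, y = header["location_xy_um"].split(",")
        loc = (float(x), float(y))
    return mechanics.IndentationTrace(
        time_s=df["time_s"].to_numpy(),
        piezo_um=df["piezo_um"].to_numpy(),
        deflection_um=df["deflection_um"].to_numpy(),
        load_un=df["load_un"].to_numpy(),
        probe_radius_um=float(header["probe_radius_um"]),
        spring_constant_n_per_m=float(header["spring_constant_n_per_m"]),
        segment_labels=df["segment"].to_numpy(dtype=object),
        location_xy_um=loc,
    )


def write_frame_csv(frame: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(frame, dtype=int), fmt="%d", delimiter=",")


def read_frame_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=int, delimiter=",").astype(bool)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; defaults follow the protocol."""

    out_dir: str = "results/run"
    seed: int = 0
    schema_version: int = 1
    # spike pipeline
    window_s: float = 2.0
    step_s: float = 0.01
    k_min: int = 4
    k_max: int = 60
    min_rate_hz: float = 0.1
    basal_s: float = 120.0
    post_offset_margin_s: float = 10.0
    # classification
    bi_threshold: float = 0.3
    # predictors
    d5_radius: float = 5.0
    n_repeats: int = 1000
    # synthetic demo dataset
    n_background: int = 260
    cluster_size: int = 20
    cluster_gain: float = 3.0
    n_flash_repeats: int = 30
    n_trials: int = 200
    probe_radius_um: float = 125.0
    indent_depth_um: float = 30.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# full pipeline


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: RunConfig) -> dict:
    """Simulate the demo dataset and run every stage in order.

    Stages: mechanics map -> probe localization -> spike clustering ->
    ON/OFF classification -> trial predictors.  All artifacts land in
    ``config.out_dir``; the returned report (also written as
    ``report.json``) is byte-identical across reruns with the same config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}
    seed_seq = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seed_seq.spawn(6)]
    report["stage_seeds"] = stage_seeds

    stage = "simulate"
    try:
        log.info("stage %s: building synthetic dataset (seed %d)", stage, stage_seeds[0])
        tissue = synth.TissueModel.retina_like()
        protocol = synth.IndentationProtocol.map_sweep(depth_um=15.0)
        traces = [
            synth.simulate_indentation_trace(
                protocol,
                tissue,
                probe_radius_um=57.0,
                noise_sd_um=0.005,
                seed=stage_seeds[0] + i,
                location_xy_um=(50.0 * (i % 5), 50.0 * (i // 5)),
            )
            for i in range(10)
        ]
        retina = synth.RetinaConfig.four_cluster_preset(
            seed=stage_seeds[1],
            n_background=config.n_background,
            cluster_size=config.cluster_size,
            gain=config.cluster_gain,
        )
        flashes = synth.alternating_flash_schedule(10.0, config.n_flash_repeats)
        stim = synth.StimEvent(onset_s=200.0, offset_s=230.0, depth_um=config.indent_depth_um)
        sts = synth.simulate_spike_trains(
            retina, [stim], flashes, duration_s=250.0, seed=stage_seeds[2]
        )
        frame = synth.simulate_saturation_frame(
            retina.grid_shape, retina.indent_center, 6.0, flip_noise=0.02, seed=stage_seeds[3]
        )
        write_spike_csv(sts, out / "spikes.csv")
        write_events_csv(sts.events, out / "events.csv")
        write_frame_csv(frame, out / "saturation_frame.csv")
        report["stages"][stage] = {
            "n_units": len(sts.units),
            "n_traces": len(traces),
            "planted_clusters": [
                {"kind": pc.kind, "n": len(pc.members)} for pc in retina.planted_clusters
            ],
        }

        stage = "mechanics"
        map_df = mechanics.build_indentation_map(traces, spacing_um=50.0)
        map_df.to_csv(out / "mechanics_map.csv", index=False, float_format=FLOAT_FMT)
        stats = mechanics.frequency_sweep_stats(map_df)
        _json_dump(stats, out / "mechanics_stats.json")
        by_f = map_df.groupby("freq_hz")["k_storage_pa"].mean()
        report["stages"][stage] = {
            "k_storage_pa_by_freq": {f"{f:g}": float(v) for f, v in by_f.items()},
            "kruskal_p_storage": stats["k_storage"]["kruskal_p"],
        }

        stage = "localization"
        loc = localize.localize_probe(frame, min_region=8)
        _json_dump(
            {"center_row": loc["center"][0], "center_col": loc["center"][1]},
            out / "probe_center.json",
        )
        report["stages"][stage] = {
            "center": list(loc["center"]),
            "true_center": list(retina.indent_center),
        }

        stage = "spike_pipeline"
        sts_f = sp.filter_units(sts, config.min_rate_hz)
        sts_f, windows = sp.align_stimulation_window(
            sts_f, [(stim.onset_s, stim.offset_s)], basal_s=config.basal_s
        )
        w = windows[0]
        indent_iv = (
            w["indentation"][0],
            w["indentation"][1] + config.post_offset_margin_s,
        )
        frm_b = sp.compute_firing_rate(sts_f, w["basal"], config.window_s, config.step_s)
        frm_i = sp.compute_firing_rate(sts_f, indent_iv, config.window_s, config.step_s)
        corr_b = sp.correlation_matrix(frm_b)
        corr_i = sp.correlation_matrix(frm_i)
        common = [u for u in corr_i.index if u in set(corr_b.index)]
        corr_b, corr_i = corr_b.loc[common, common], corr_i.loc[common, common]
        clusters = sp.cluster_units(corr_i, (config.k_min, config.k_max))
        _, summary = sp.reorder_basal(corr_b, clusters, corr_i)
        responsive = set(sp.responsive_clusters(frm_b, frm_i, clusters))
        pd.DataFrame(
            {"unit_id": clusters.unit_ids, "cluster": clusters.labels}
        ).to_csv(out / "cluster_labels.csv", index=False)
        report["stages"][stage] = {
            "n_units_kept": len(clusters.unit_ids),
            "k_selected": clusters.k_selected,
            "n_responsive_clusters": len(responsive),
            "corr_summary": summary,
        }

        stage = "classification"
        amps = classify.peak_amplitudes(sts_f, basal_interval=w["basal"])
        labeled = classify.classify_units(amps, config.bi_threshold)
        labeled.to_csv(out / "classification.csv", index=False, float_format=FLOAT_FMT)
        comp = classify.cluster_composition(labeled, clusters, responsive)
        comp.to_csv(out / "composition.csv", index=False, float_format=FLOAT_FMT)
        report["stages"][stage] = {
            "label_counts": labeled["label"].value_counts().to_dict()
        }

        stage = "predictors"
        table = synth.simulate_trial_table(n_trials=config.n_trials, seed=stage_seeds[4])
        table.to_csv(out / "trial_features.csv", index=False, float_format=FLOAT_FMT)
        imp = predictors.feature_importance(
            table, n_repeats=config.n_repeats, seed=stage_seeds[5]
        )
        _json_dump(imp, out / "importance.json")
        order = np.argsort(imp["mean_importance"])[::-1]
        report["stages"][stage] = {
            "top_features": [imp["features"][i] for i in order[:3]]
        }
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        partial = out / "report.partial.json"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _json_dump(report, partial)
        raise type(exc)(f"pipeline failed in stage '{stage}': {exc}") from exc

    report_path = out / "report.json"
    _json_dump(report, report_path)
    report["report_sha256"] = _file_hash(report_path)
    return report
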