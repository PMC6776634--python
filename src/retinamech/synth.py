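"""Synthetic data for both measurement streams.

Two generators with known ground truth drive the whole pipeline:

* indentation traces from a prescribed viscoelastic tissue model (the load
  oscillation amplitude and phase at each drive frequency are the exact
  inverse of the dynamic-stiffness relations used downstream), and
* HD-MEA spike trains as inhomogeneous Poisson processes with basal firing,
  flash-locked transients per functional cell type (ON / OFF / ON-OFF / NC)
  and planted, spatially localized, slow rate modulations around the
  indentation site.

Every stochastic element draws from a generator derived from one explicit
seed; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import InvalidParameterError, ScheduleConflictError
from .mechanics import IndentationTrace, contact_radius
from .spikes import Event, SpikeTrainSet, Unit

FLASH_KERNEL_S = 0.2          # half-cosine flash-response transient
MODULATION_RISE_TAU_S = 1.0   # exponential rise of the mechanically evoked box-car
LATENCY_SLOPE_S_PER_MM = 0.5  # extra latency per mm of distance from the indent site

__all__ = [
    "TissueModel",
    "IndentationProtocol",
    "StimEvent",
    "FlashEvent",
    "PlantedCluster",
    "RetinaConfig",
    "simulate_indentation_trace",
    "simulate_spike_trains",
    "simulate_saturation_frame",
    "simulate_trial_table",
    "alternating_flash_schedule",
    "table1_presets",
]


# ---------------------------------------------------------------------------
# tissue model


@dataclass(frozen=True)
class TissueModel:
    """Frequency-domain apparent moduli K'(f), K"(f) of the sample.

    ``standard_linear_solid`` uses the single-relaxation-time forms
    K'(f) = K_e + dK * x / (1 + x), K"(f) = dK * sqrt(x) / (1 + x) with
    x = (f / f_relax)^2, which is monotone stiffening with frequency.
    """

    k_storage_fn: Callable[[float], float]
    k_loss_fn: Callable[[float], float]
    model_kind: str = "tabulated"

    def k_storage(self, f_hz: float) -> float:
        v = float(self.k_storage_fn(f_hz))
        if v <= 0:
            raise InvalidParameterError(f"K'({f_hz}) = {v} must be positive")
        return v

    def k_loss(self, f_hz: float) -> float:
        v = float(self.k_loss_fn(f_hz))
        if v < 0:
            raise InvalidParameterError(f'K"({f_hz}) = {v} must be non-negative')
        return v

    @classmethod
    def standard_linear_solid(
        cls, k_equilibrium_pa: float, k_delta_pa: float, f_relax_hz: float = 1.0
    ) -> "TissueModel":
        if k_equilibrium_pa <= 0 or k_delta_pa < 0 or f_relax_hz <= 0:
            raise InvalidParameterError("SLS parameters out of range")

        def ks(f: float) -> float:
            x = (f / f_relax_hz) ** 2
            return k_equilibrium_pa + k_delta_pa * x / (1.0 + x)

        def kl(f: float) -> float:
            x = (f / f_relax_hz) ** 2
            return k_delta_pa * np.sqrt(x) / (1.0 + x)

        return cls(ks, kl, model_kind="standard_linear_solid")

    @classmethod
    def from_anchors(
        cls,
        f_low_hz: float,
        k_low_pa: float,
        f_high_hz: float,
        k_high_pa: float,
        f_relax_hz: float = 1.0,
    ) -> "TissueModel":
        """SLS passing through two storage-modulus anchors."""
        x1 = (f_low_hz / f_relax_hz) ** 2 / (1 + (f_low_hz / f_relax_hz) ** 2)
        x2 = (f_high_hz / f_relax_hz) ** 2 / (1 + (f_high_hz / f_relax_hz) ** 2)
        k_delta = (k_high_pa - k_low_pa) / (x2 - x1)
        k_eq = k_low_pa - k_delta * x1
        return cls.standard_linear_solid(k_eq, k_delta, f_relax_hz)

    @classmethod
    def retina_like(cls) -> "TissueModel":
        """Soft-tissue preset: K' rising from 0.7 kPa (0.1 Hz) to 1.7 kPa (10 Hz)."""
        return cls.from_anchors(0.1, 700.0, 10.0, 1700.0, f_relax_hz=1.0)

    @classmethod
    def from_table(
        cls, freqs_hz: Sequence[float], k_storage_pa: Sequence[float], k_loss_pa: Sequence[float]
    ) -> "TissueModel":
        f = np.log10(np.asarray(freqs_hz, float))
        ks = np.asarray(k_storage_pa, float)
        kl = np.asarray(k_loss_pa, float)
        return cls(
            lambda x: float(np.interp(np.log10(x), f, ks)),
            lambda x: float(np.interp(np.log10(x), f, kl)),
            model_kind="tabulated",
        )


# ---------------------------------------------------------------------------
# indentation protocol and trace synthesis


@dataclass(frozen=True)
class IndentationProtocol:
    """Depth-controlled drive: ramp, stress relaxation, frequency sweep."""

    ramp_speed_um_s: float = 2.0
    target_depth_um: float = 15.0
    relaxation_s: float = 10.0
    oscillation_amplitude_um: float = 0.3
    oscillation_frequencies_hz: tuple[float, ...] = (0.1, 1.0, 10.0)
    mode: str = "map_sweep"  # map_sweep | static | small_osc | mild_osc

    def __post_init__(self) -> None:
        if self.target_depth_um <= 0:
            raise InvalidParameterError("target depth must be positive")
        if self.ramp_speed_um_s <= 0:
            raise InvalidParameterError("ramp speed must be positive")
        if self.oscillation_amplitude_um < 0:
            raise InvalidParameterError("oscillation amplitude must be non-negative")
        if self.mode == "static" and self.oscillation_amplitude_um != 0:
            raise InvalidParameterError("static mode forbids oscillation")

    @classmethod
    def map_sweep(cls, depth_um: float = 15.0) -> "IndentationProtocol":
        return cls(target_depth_um=depth_um)

    @classmethod
    def static(cls, depth_um: float) -> "IndentationProtocol":
        return cls(
            target_depth_um=depth_um,
            oscillation_amplitude_um=0.0,
            oscillation_frequencies_hz=(),
            mode="static",
        )

    @classmethod
    def small_osc(cls, depth_um: float) -> "IndentationProtocol":
        return cls(
            target_depth_um=depth_um,
            oscillation_amplitude_um=1.0,
            oscillation_frequencies_hz=(0.1,),
            mode="small_osc",
        )

    @classmethod
    def mild_osc(cls, depth_um: float) -> "IndentationProtocol":
        return cls(
            target_depth_um=depth_um,
            oscillation_amplitude_um=3.0,
            oscillation_frequencies_hz=(0.1,),
            mode="mild_osc",
        )


def _oscillation_periods(f_hz: float, min_periods: int = 3, min_segment_s: float = 12.0) -> int:
    """Integer period count: at least ``min_periods`` and ``min_segment_s``."""
    return int(max(min_periods, np.ceil(min_segment_s * f_hz)))


def simulate_indentation_trace(
    protocol: IndentationProtocol,
    tissue: TissueModel,
    probe_radius_um: float,
    noise_sd_um: float = 0.0,
    seed: int = 0,
    fs_hz: float = 1000.0,
    spring_constant_n_per_m: float = 0.45,
    approach_s: float = 2.0,
    location_xy_um: tuple[float, float] | None = None,
) -> IndentationTrace:
    """Synthesize one depth-controlled trace consistent with ``tissue``.

    During each oscillation segment at frequency f, with contact radius
    ``a = sqrt(R * depth)``, the load oscillation has amplitude
    ``F0 = h0 * 2a * |K*(f)|`` and lags the depth drive by
    ``atan2(K", K')`` — exactly the relations the mechanics stage inverts.
    Gaussian noise of ``noise_sd_um`` is added to the cantilever deflection
    (load follows as spring_constant * deflection).
    """
    if probe_radius_um <= 0:
        raise InvalidParameterError("probe radius must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs_hz
    k_c = spring_constant_n_per_m
    depth = protocol.target_depth_um
    quasi_static_k = tissue.k_storage(1e-3)

    def hertz_load_un(h_um: float, k_pa: float) -> float:
        # F = (4/3) K sqrt(R) h^{3/2}; SI then back to uN
        r_m, h_m = probe_radius_um * 1e-6, max(h_um, 0.0) * 1e-6
        return (4.0 / 3.0) * k_pa * np.sqrt(r_m) * h_m**1.5 * 1e6

    seg_t: list[np.ndarray] = []
    seg_h: list[np.ndarray] = []
    seg_f: list[np.ndarray] = []
    seg_lab: list[np.ndarray] = []
    t_cursor = 0.0

    def push(duration: float, h_fn, f_fn, label: str) -> None:
        nonlocal t_cursor
        n = int(round(duration * fs_hz))
        tt = t_cursor + dt * np.arange(n)
        tl = tt - t_cursor
        seg_t.append(tt)
        seg_h.append(h_fn(tl))
        seg_f.append(f_fn(tl))
        seg_lab.append(np.full(n, label, dtype=object))
        t_cursor += n * dt

    # approach: probe still out of contact, zero load
    push(approach_s, lambda tl: np.full_like(tl, np.nan), lambda tl: np.zeros_like(tl), "approach")
    # ramp at constant speed to target depth
    ramp_s = depth / protocol.ramp_speed_um_s
    push(
        ramp_s,
        lambda tl: protocol.ramp_speed_um_s * tl,
        lambda tl: np.array([hertz_load_un(h, quasi_static_k) for h in protocol.ramp_speed_um_s * tl]),
        "ramp",
    )
    # stress relaxation at constant depth (phenomenological exponential)
    f_hold = hertz_load_un(depth, quasi_static_k)
    push(
        protocol.relaxation_s,
        lambda tl: np.full_like(tl, depth),
        lambda tl: f_hold * (0.9 + 0.1 * np.exp(-tl / 2.0)),
        "relaxation",
    )
    # frequency sweep: integer periods per segment
    h0 = protocol.oscillation_amplitude_um
    a_m = contact_radius(probe_radius_um, depth) * 1e-6
    for f in protocol.oscillation_frequencies_hz:
        kp, kpp = tissue.k_storage(f), tissue.k_loss(f)
        f0_un = h0 * 1e-6 * 2.0 * a_m * np.hypot(kp, kpp) * 1e6
        phi = np.arctan2(kpp, kp)
        n_per = _oscillation_periods(f)
        w = 2 * np.pi * f
        push(
            n_per / f,
            lambda tl, w=w: depth + h0 * np.sin(w * tl),
            lambda tl, w=w, f0=f0_un, phi=phi: f_hold * 0.9 + f0 * np.sin(w * tl + phi),
            f"osc@{f:g}",
        )

    time_s = np.concatenate(seg_t)
    h_true = np.concatenate(seg_h)
    load_clean = np.concatenate(seg_f)
    labels = np.concatenate(seg_lab)

    defl_clean = load_clean / k_c  # um
    # commanded piezo: pre-contact linear approach, then depth + deflection
    contact_dist = protocol.ramp_speed_um_s * approach_s
    piezo = np.where(
        labels == "approach",
        -contact_dist + protocol.ramp_speed_um_s * time_s,
        np.nan_to_num(h_true) + defl_clean,
    )
    deflection = defl_clean + (rng.normal(0.0, noise_sd_um, time_s.size) if noise_sd_um > 0 else 0.0)
    load = k_c * deflection
    return IndentationTrace(
        time_s=time_s,
        piezo_um=piezo,
        deflection_um=deflection,
        load_un=load,
        probe_radius_um=probe_radius_um,
        spring_constant_n_per_m=k_c,
        segment_labels=labels,
        location_xy_um=location_xy_um,
        meta={
            "contact_time_s": approach_s,
            "planted_k_storage_pa": {
                f"{f:g}": tissue.k_storage(f) for f in protocol.oscillation_frequencies_hz
            },
            "planted_k_loss_pa": {
                f"{f:g}": tissue.k_loss(f) for f in protocol.oscillation_frequencies_hz
            },
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# retina / spike-train synthesis


@dataclass(frozen=True)
class StimEvent:
    onset_s: float
    offset_s: float
    depth_um: float = 30.0
    amplitude_um: float = 0.0
    frequency_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise InvalidParameterError("stimulation offset must follow onset")


@dataclass(frozen=True)
class FlashEvent:
    kind: str  # "white" | "black"
    time_s: float
    duration_s: float = 0.5


@dataclass(frozen=True)
class PlantedCluster:
    members: tuple[int, ...]          # unit indices
    kind: str                          # onset_excited | offset_excited | both |
    #                                    onset_suppressed | offset_suppressed |
    #                                    rebound | none
    latency_s: float = 2.0
    duration_s: float = 6.0
    gain: float = 3.0

    def __post_init__(self) -> None:
        if self.latency_s < 0:
            raise InvalidParameterError("latency must be non-negative")
        if self.gain < 0:
            raise InvalidParameterError("gain must be non-negative")


@dataclass
class RetinaConfig:
    """Ground-truth description of one synthetic retina on the MEA."""

    n_units: int
    unit_positions: np.ndarray            # (n, 2) electrode (row, col)
    cell_types: list[str]                 # ON | OFF | ON_OFF | NC per unit
    basal_rates_hz: np.ndarray
    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    indent_center: tuple[int, int] = (32, 32)
    grid_shape: tuple[int, int] = (64, 64)
    pitch_um: float = 42.0
    flash_gain: float = 3.0               # flash peak = gain * basal, added
    latency_slope_s_per_mm: float = LATENCY_SLOPE_S_PER_MM
    refractory_s: float = 0.0

    def __post_init__(self) -> None:
        self.unit_positions = np.asarray(self.unit_positions, dtype=int)
        self.basal_rates_hz = np.asarray(self.basal_rates_hz, dtype=float)
        if np.any(self.basal_rates_hz < 0):
            raise InvalidParameterError("basal rates must be non-negative")
        taken: set[int] = set()
        for pc in self.planted_clusters:
            if taken & set(pc.members):
                raise InvalidParameterError("planted cluster member sets overlap")
            taken |= set(pc.members)

    @classmethod
    def background_only(
        cls, n_units: int = 100, basal_rate_hz: float = 5.0, seed: int = 0
    ) -> "RetinaConfig":
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 64, size=(n_units, 2))
        return cls(
            n_units=n_units,
            unit_positions=pos,
            cell_types=["NC"] * n_units,
            basal_rates_hz=np.full(n_units, basal_rate_hz),
            flash_gain=0.0,
        )

    @classmethod
    def four_cluster_preset(
        cls,
        seed: int = 0,
        n_background: int = 300,
        cluster_size: int = 30,
        basal_rate_hz: float = 5.0,
        gain: float = 3.0,
        indent_center: tuple[int, int] = (32, 28),
        on_enriched: bool = True,
        heterogeneous_rates: bool = True,
    ) -> "RetinaConfig":
        """The study condition: 4 planted response clusters + background.

        Clusters respond at onset, at offset, at both, or at onset with a
        long latency; each is spatially compact at a different range from
        the indentation site (responses out to ~1 mm).  Responsive clusters
        carry ~20 percentage points more ON cells than background when
        ``on_enriched``.
        """
        rng = np.random.default_rng(seed)
        n_total = n_background + 4 * cluster_size
        pos = np.empty((n_total, 2), dtype=int)
        # Temporally disjoint response envelopes: three onset clusters at
        # growing latency (delays grow with distance from the indent site)
        # plus one offset cluster, so planted clusters are mutually
        # near-orthogonal while each stays internally correlated.
        kinds = [
            ("onset_excited", 2.0, 6.0),
            ("onset_excited", 14.0, 6.0),
            ("onset_excited", 26.0, 6.0),
            ("offset_excited", 2.0, 6.0),
        ]
        clusters: list[PlantedCluster] = []
        centers = [(8, 0), (0, 9), (-10, -4), (16, 10)]  # offsets (electrodes)
        i = 0
        for (kind, lat, dur), (dr, dc) in zip(kinds, centers):
            members = tuple(range(i, i + cluster_size))
            cr, cc = indent_center[0] + dr, indent_center[1] + dc
            pos[i : i + cluster_size] = np.clip(
                np.array([cr, cc]) + rng.integers(-3, 4, size=(cluster_size, 2)),
                0,
                63,
            )
            clusters.append(
                PlantedCluster(members=members, kind=kind, latency_s=lat, duration_s=dur, gain=gain)
            )
            i += cluster_size
        pos[i:] = rng.integers(0, 64, size=(n_background, 2))
        type_names = np.array(["ON", "OFF", "ON_OFF", "NC"])
        p_bg = [0.25, 0.35, 0.20, 0.20]          # scotopic: OFF-dominated
        p_resp = [0.45, 0.25, 0.20, 0.10] if on_enriched else p_bg
        types = np.empty(n_total, dtype=object)
        types[: 4 * cluster_size] = rng.choice(type_names, 4 * cluster_size, p=p_resp)
        types[4 * cluster_size :] = rng.choice(type_names, n_background, p=p_bg)
        if heterogeneous_rates:
            rates = rng.gamma(8.0, basal_rate_hz / 8.0, n_total)
        else:
            rates = np.full(n_total, basal_rate_hz)
        return cls(
            n_units=n_total,
            unit_positions=pos,
            cell_types=list(types),
            basal_rates_hz=rates,
            planted_clusters=clusters,
            indent_center=indent_center,
        )

    def distance_mm(self, unit_index: int) -> float:
        dr = self.unit_positions[unit_index, 0] - self.indent_center[0]
        dc = self.unit_positions[unit_index, 1] - self.indent_center[1]
        return float(np.hypot(dr, dc) * self.pitch_um / 1000.0)


def alternating_flash_schedule(
    t_start_s: float, n_repeats: int, period_s: float = 2.0, duration_s: float = 0.5
) -> list[FlashEvent]:
    """White/black full-field flashes alternating every half period."""
    out = []
    for k in range(n_repeats):
        out.append(FlashEvent("white", t_start_s + k * period_s, duration_s))
        out.append(FlashEvent("black", t_start_s + k * period_s + period_s / 2, duration_s))
    return out


def _boxcar_rise(t: np.ndarray, start: float, duration: float, tau: float) -> np.ndarray:
    """Box-car envelope with exponential rise; zero outside [start, start+dur]."""
    inside = (t >= start) & (t < start + duration)
    env = np.zeros_like(t)
    env[inside] = 1.0 - np.exp(-(t[inside] - start) / tau)
    return env


def _cluster_envelope(
    t: np.ndarray, kind: str, stim: StimEvent, latency: float, duration: float
) -> np.ndarray:
    tau = MODULATION_RISE_TAU_S
    if kind == "none":
        return np.zeros_like(t)
    env = np.zeros_like(t)
    if kind in ("onset_excited", "both", "onset_suppressed"):
        env += _boxcar_rise(t, stim.onset_s + latency, duration, tau)
    if kind in ("offset_excited", "both", "offset_suppressed", "rebound"):
        env += _boxcar_rise(t, stim.offset_s + latency, duration, tau)
    return np.clip(env, 0.0, 1.0)


def _flash_envelope(t: np.ndarray, flash_times: np.ndarray) -> np.ndarray:
    """Half-cosine transient of width FLASH_KERNEL_S after each flash onset."""
    if flash_times.size == 0:
        return np.zeros_like(t)
    idx = np.searchsorted(flash_times, t, "right") - 1
    dt = np.where(idx >= 0, t - flash_times[np.clip(idx, 0, None)], np.inf)
    env = np.zeros_like(t)
    m = (dt >= 0) & (dt < FLASH_KERNEL_S)
    env[m] = np.sin(np.pi * dt[m] / FLASH_KERNEL_S)
    return env


def simulate_spike_trains(
    config: RetinaConfig,
    stim_schedule: Sequence[StimEvent],
    flash_schedule: Sequence[FlashEvent],
    duration_s: float,
    seed: int = 0,
) -> SpikeTrainSet:
    """Inhomogeneous-Poisson spike trains with the configured phenomenology.

    Rate of unit i: ``basal_i * m_i(t) + basal_i * flash_gain * f_i(t)`` where
    ``m_i`` is the planted-cluster modulation envelope (excitation scales by
    the cluster gain, suppression scales toward 1/gain) delayed by the
    cluster latency plus ``latency_slope * distance`` from the indent
    center, and ``f_i`` is the flash kernel for the unit's preferred flash
    polarity.  Sampling is by thinning, one RNG substream per unit.
    """
    stims = sorted(stim_schedule, key=lambda s: s.onset_s)
    for a, b in zip(stims, stims[1:]):
        if b.onset_s < a.offset_s:
            raise ScheduleConflictError("overlapping stimulation events")
    last = max(
        [s.offset_s for s in stims]
        + [fl.time_s + fl.duration_s for fl in flash_schedule]
        + [0.0]
    )
    if duration_s < last:
        raise InvalidParameterError("duration does not cover all scheduled events")

    white = np.sort([fl.time_s for fl in flash_schedule if fl.kind == "white"])
    black = np.sort([fl.time_s for fl in flash_schedule if fl.kind == "black"])
    cluster_of: dict[int, PlantedCluster] = {}
    for pc in config.planted_clusters:
        for m in pc.members:
            cluster_of[m] = pc

    streams = np.random.SeedSequence(seed).spawn(config.n_units)
    units: list[Unit] = []
    for i in range(config.n_units):
        rng = np.random.default_rng(streams[i])
        basal = config.basal_rates_hz[i]
        pc = cluster_of.get(i)
        excite_gain = pc.gain if pc and "suppressed" not in pc.kind else 1.0
        rmax = basal * max(excite_gain, 1.0) + basal * config.flash_gain + 1e-9
        if rmax <= 0:
            units.append(Unit(i, *config.unit_positions[i], np.empty(0)))
            continue
        n_cand = rng.poisson(rmax * duration_s)
        t = np.sort(rng.uniform(0.0, duration_s, n_cand))
        rate = np.full(t.shape, basal)
        if pc is not None and pc.kind != "none":
            lat = pc.latency_s + config.latency_slope_s_per_mm * config.distance_mm(i)
            env = np.zeros_like(t)
            for s in stims:
                env += _cluster_envelope(t, pc.kind, s, lat, pc.duration_s)
            env = np.clip(env, 0.0, 1.0)
            if "suppressed" in pc.kind:
                floor = 1.0 / pc.gain if pc.gain > 0 else 0.0
                rate = basal * (1.0 - (1.0 - floor) * env)
            else:
                rate = basal * (1.0 + (pc.gain - 1.0) * env)
        if config.flash_gain > 0:
            ct = config.cell_types[i]
            fenv = np.zeros_like(t)
            if ct in ("ON", "ON_OFF"):
                fenv += _flash_envelope(t, white)
            if ct in ("OFF", "ON_OFF"):
                fenv += _flash_envelope(t, black)
            rate = rate + basal * config.flash_gain * fenv
        keep = rng.uniform(0.0, rmax, t.size) < rate
        spikes = np.unique(t[keep])
        if config.refractory_s > 0 and spikes.size > 1:
            out = [spikes[0]]
            for s in spikes[1:]:
                if s - out[-1] >= config.refractory_s:
                    out.append(s)
            spikes = np.asarray(out)
        units.append(Unit(i, *config.unit_positions[i], spikes))

    events = [
        Event("flash_white" if fl.kind == "white" else "flash_black", fl.time_s)
        for fl in flash_schedule
    ]
    for s in stims:
        events.append(
            Event(
                "indent_on",
                s.onset_s,
                {"depth_um": s.depth_um, "amplitude_um": s.amplitude_um, "frequency_hz": s.frequency_hz},
            )
        )
        events.append(Event("indent_off", s.offset_s))
    return SpikeTrainSet(
        units=units,
        recording_duration_s=duration_s,
        events=sorted(events, key=lambda e: e.time_s),
        grid_shape=config.grid_shape,
        pitch_um=config.pitch_um,
    )


# ---------------------------------------------------------------------------
# probe-shadow saturation frame


def simulate_saturation_frame(
    grid_shape: tuple[int, int],
    probe_center: tuple[int, int],
    probe_outline_radius: float,
    flip_noise: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Boolean saturation frame: True = saturating, False inside the shadow.

    The shadow is the disk of ``probe_outline_radius`` electrodes around
    ``probe_center``; each entry is then flipped independently with
    probability ``flip_noise``.
    """
    rows, cols = grid_shape
    r0, c0 = probe_center
    rad = float(probe_outline_radius)
    if rad < 0 or not (0.0 <= flip_noise <= 1.0):
        raise InvalidParameterError("radius and flip probability out of range")
    if r0 < -rad or r0 > rows - 1 + rad or c0 < -rad or c0 > cols - 1 + rad:
        raise InvalidParameterError("probe disk does not intersect the grid")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    frame = (rr - r0) ** 2 + (cc - c0) ** 2 > rad**2
    if flip_noise > 0:
        rng = np.random.default_rng(seed)
        frame = frame ^ (rng.uniform(size=frame.shape) < flip_noise)
    return frame


# ---------------------------------------------------------------------------
# per-trial feature table with a planted success rule


def table1_presets() -> list[dict]:
    """Stimulation presets mirroring the summary protocol table."""
    return [
        {"retina": "R1", "amplitude_um": 0.0, "depth_um": 30.0, "frequency_hz": 0.0, "max_load_un": 5.0},
        {"retina": "R1", "amplitude_um": 1.0, "depth_um": 30.0, "frequency_hz": 0.1, "max_load_un": 1.5},
        {"retina": "R2", "amplitude_um": 0.0, "depth_um": 20.0, "frequency_hz": 0.0, "max_load_un": 0.3},
        {"retina": "R3", "amplitude_um": 0.0, "depth_um": 60.0, "frequency_hz": 0.0, "max_load_un": 34.0},
    ]


def simulate_trial_table(
    n_trials: int = 200,
    seed: int = 0,
    label_noise: float = 0.05,
    pressure_threshold_pa: float = 100.0,
    d5_threshold: int = 7,
):
    """Synthetic per-trial feature table with outcome = (pressure AND d5) rule.

    Probe radii are drawn from the radii used experimentally (57/73/125 um),
    depths span 10-60 um, and loads scale with depth^1.5 with lognormal
    scatter so pressures span tens to hundreds of Pa.  The planted rule
    ``success = (pressure > pressure_threshold) & (d5 > d5_threshold)`` is
    corrupted by ``label_noise`` random flips.
    """
    import pandas as pd

    from .mechanics import contact_area, trial_pressure_strain

    rng = np.random.default_rng(seed)
    radius = rng.choice([57.0, 73.0, 125.0], n_trials)
    depth = rng.uniform(10.0, 60.0, n_trials)
    load = 0.02 * depth**1.5 * rng.lognormal(0.0, 0.7, n_trials)
    d5 = rng.poisson(8.0, n_trials)
    r5 = np.where(d5 > 0, rng.gamma(4.0, 1.25, n_trials), np.nan)
    rows = []
    for i in range(n_trials):
        pressure, strain = trial_pressure_strain(load[i], radius[i], depth[i])
        rows.append(
            {
                "trial_id": i,
                "contact_area_um2": contact_area(radius[i], depth[i]),
                "strain": strain,
                "pressure_pa": pressure,
                "depth_um": depth[i],
                "d5": int(d5[i]),
                "r5": r5[i],
                "outcome": bool(pressure > pressure_threshold_pa and d5[i] > d5_threshold),
            }
        )
    df = pd.DataFrame(rows)
    flip = rng.uniform(size=n_trials) < label_noise
    df.loc[flip, "outcome"] = ~df.loc[flip, "outcome"]
    return df
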