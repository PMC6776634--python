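"""Dynamic micro-indentation analysis.

Turns depth-controlled oscillatory indentation traces from a ferrule-top
probe into apparent viscoelastic moduli.  The probe is a sphere of radius
``R`` pressed to a mean depth ``h`` (Hertzian contact radius
``a = sqrt(R*h)``, area ``A = pi*a**2``); a small sinusoidal depth
oscillation of amplitude ``h0`` at frequency ``f`` produces a load
oscillation of amplitude ``F0`` lagging by a phase ``phi``.  The apparent
storage and loss moduli (``E/(1-nu^2)`` form, incompressible ``nu = 0.5``)
follow from the dynamic stiffness::

    K' = (F0/h0) * cos(phi) * sqrt(pi) / (2*sqrt(A))
    K" = (F0/h0) * sin(phi) * sqrt(pi) / (2*sqrt(A))

and the loss tangent is ``tan(phi) = K"/K'``.

All trace I/O is in the recorded units (um, uN, N/m); modulus arithmetic is
done in SI internally and returned in Pa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DuplicateLocationError,
    InsufficientDataError,
    InvalidParameterError,
    NoContactError,
)

POISSON_RATIO = 0.5  # incompressible tissue

__all__ = [
    "IndentationTrace",
    "OscillationFit",
    "ViscoModuli",
    "detect_contact_point",
    "indentation_depth",
    "fit_oscillation",
    "contact_radius",
    "contact_area",
    "storage_modulus",
    "loss_modulus",
    "loss_tangent",
    "trial_pressure_strain",
    "analyze_trace",
    "build_indentation_map",
    "frequency_sweep_stats",
]


@dataclass
class IndentationTrace:
    """Synchronized piezo / cantilever-deflection / load time series.

    ``load_un = spring_constant_n_per_m * deflection_um`` holds by
    construction (uN = N/m * um).  ``segment_labels`` assigns each sample to
    one of ``approach``, ``ramp``, ``relaxation`` or ``osc@<f>``.
    """

    time_s: np.ndarray
    piezo_um: np.ndarray
    deflection_um: np.ndarray
    load_un: np.ndarray
    probe_radius_um: float
    spring_constant_n_per_m: float
    segment_labels: np.ndarray
    location_xy_um: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.piezo_um = np.asarray(self.piezo_um, dtype=float)
        self.deflection_um = np.asarray(self.deflection_um, dtype=float)
        self.load_un = np.asarray(self.load_un, dtype=float)
        self.segment_labels = np.asarray(self.segment_labels)
        n = self.time_s.size
        for name in ("piezo_um", "deflection_um", "load_un", "segment_labels"):
            if getattr(self, name).shape[0] != n:
                raise InvalidParameterError(f"{name} length does not match time axis")
        if n >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise InvalidParameterError("time axis must be strictly increasing")
        if self.probe_radius_um <= 0:
            raise InvalidParameterError("probe radius must be positive")
        expected = self.spring_constant_n_per_m * self.deflection_um
        if not np.allclose(self.load_un, expected, rtol=1e-6, atol=1e-9):
            raise InvalidParameterError(
                "load is not spring_constant * deflection within tolerance"
            )

    @property
    def fs_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))

    def segment(self, label: str) -> np.ndarray:
        """Boolean mask of samples carrying ``label``."""
        return self.segment_labels == label

    def oscillation_labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.segment_labels:
            if str(lab).startswith("osc@") and lab not in seen:
                seen.append(str(lab))
        return seen


@dataclass
class OscillationFit:
    """Single-frequency lock-in style amplitude/phase extraction."""

    frequency_hz: float
    f0_un: float          # load oscillation amplitude
    h0_um: float          # indentation oscillation amplitude
    phase_lag_rad: float  # phase(load) - phase(indentation), wrapped to [-pi, pi]
    mean_depth_um: float
    residual_rms_un: float
    physical: bool = True  # phase within [0, pi/2]; flagged, never clipped

    def __post_init__(self) -> None:
        self.physical = 0.0 <= self.phase_lag_rad <= np.pi / 2


@dataclass
class ViscoModuli:
    """Per-location apparent moduli over the swept frequencies."""

    location_xy_um: tuple[float, float]
    frequencies_hz: list[float]
    k_storage_pa: list[float]
    k_loss_pa: list[float]
    tan_phi: list[float]
    contact_radius_um: list[float]
    poisson_ratio: float = POISSON_RATIO


def detect_contact_point(
    trace: IndentationTrace,
    baseline_s: float = 1.0,
    n_sigma: float = 3.0,
    sustain_s: float = 0.05,
) -> tuple[float, float]:
    """Locate tissue contact as the first sustained load excursion.

    The threshold is ``baseline mean + n_sigma * baseline SD`` computed on the
    first ``baseline_s`` seconds of the approach segment; the crossing must
    persist for at least ``sustain_s``.  Returns ``(time_s, piezo_um)`` of the
    first qualifying sample.
    """
    approach = trace.segment("approach")
    if not approach.any():
        raise NoContactError("trace has no approach segment")
    t0 = trace.time_s[approach][0]
    base = approach & (trace.time_s < t0 + baseline_s)
    if base.sum() < 2:
        raise NoContactError("approach segment shorter than the baseline window")
    mu = float(trace.load_un[base].mean())
    sd = float(trace.load_un[base].std())
    thr = mu + n_sigma * sd + 1e-12  # noise-free traces: any positive load
    above = trace.load_un > thr
    n_sustain = max(1, int(round(sustain_s * trace.fs_hz)))
    # first index where `above` holds for n_sustain consecutive samples
    idx = np.flatnonzero(above)
    if idx.size:
        run_ok = np.convolve(above.astype(int), np.ones(n_sustain, int), "valid")
        starts = np.flatnonzero(run_ok == n_sustain)
        if starts.size:
            i = int(starts[0])
            return float(trace.time_s[i]), float(trace.piezo_um[i])
    raise NoContactError("no sustained load crossing found")


def refine_contact_hertz(
    trace: IndentationTrace,
    contact_time_s: float,
    load_fraction: tuple[float, float] = (0.05, 0.5),
) -> float:
    """Hertzian refinement of the contact point on the loading ramp.

    Threshold crossing detects contact late once noise forces a finite
    threshold (the load at crossing already implies ~1 um of depth for soft
    tissue).  For a spherical indenter ``F^(2/3)`` is linear in the probe
    position ``u = piezo - deflection``, so regressing ``F^(2/3)`` on ``u``
    over the early ramp (loads within ``load_fraction`` of the ramp
    maximum) and extrapolating to zero load recovers the contact position.
    Returns the refined contact time (the time at which ``u`` crosses the
    extrapolated contact position).
    """
    ramp = trace.segment("ramp")
    if not ramp.any():
        return contact_time_s
    approach = trace.segment("approach")
    defl_base = float(trace.deflection_um[approach].mean()) if approach.any() else 0.0
    u = trace.piezo_um - (trace.deflection_um - defl_base)
    f_ramp = trace.load_un[ramp]
    f_max = f_ramp.max()
    sel = ramp & (trace.load_un > load_fraction[0] * f_max) & (
        trace.load_un < load_fraction[1] * f_max
    )
    if sel.sum() < 5:
        return contact_time_s
    y = trace.load_un[sel] ** (2.0 / 3.0)
    x = u[sel]
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        return contact_time_s
    u_contact = -intercept / slope
    crossing = np.flatnonzero(u >= u_contact)
    if crossing.size == 0:
        return contact_time_s
    return float(trace.time_s[crossing[0]])


def indentation_depth(trace: IndentationTrace, contact_time_s: float) -> np.ndarray:
    """Depth ``h(t) = (piezo - piezo_contact) - (deflection - baseline)``.

    Negative pre-contact values are left as-is (callers slice by segment).
    """
    i = int(np.searchsorted(trace.time_s, contact_time_s))
    i = min(i, trace.time_s.size - 1)
    approach = trace.segment("approach")
    defl_base = float(trace.deflection_um[approach].mean()) if approach.any() else 0.0
    return (trace.piezo_um - trace.piezo_um[i]) - (trace.deflection_um - defl_base)


def fit_oscillation(
    time_s: np.ndarray,
    depth_um: np.ndarray,
    load_un: np.ndarray,
    frequency_hz: float,
    min_periods: float = 3.0,
) -> OscillationFit:
    """Fit ``c + A sin(2 pi f t) + B cos(2 pi f t)`` to depth and load.

    Linear least squares at the known drive frequency; amplitude
    ``sqrt(A^2+B^2)``, phase ``atan2(B, A)``.  The reported phase lag is
    ``phase(load) - phase(depth)`` wrapped to [-pi, pi].
    """
    time_s = np.asarray(time_s, float)
    depth_um = np.asarray(depth_um, float)
    load_un = np.asarray(load_un, float)
    if frequency_hz <= 0:
        raise InvalidParameterError("frequency must be positive")
    if time_s.size > 1:
        # inclusive span: n samples at spacing dt cover n*dt seconds
        span = time_s[-1] - time_s[0] + float(np.median(np.diff(time_s)))
    else:
        span = 0.0
    if span * frequency_hz < min_periods - 1e-9:
        raise InsufficientDataError(
            f"segment spans {span * frequency_hz:.2f} periods at {frequency_hz} Hz; "
            f"need >= {min_periods}"
        )
    t = time_s - time_s[0]
    w = 2 * np.pi * frequency_hz
    design = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])

    def _fit(y: np.ndarray) -> tuple[float, float, np.ndarray]:
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        a, b, _c = coef
        return float(np.hypot(a, b)), float(np.arctan2(b, a)), design @ coef

    h0, ph_h, _ = _fit(depth_um)
    f0, ph_f, model_f = _fit(load_un)
    lag = float(np.angle(np.exp(1j * (ph_f - ph_h))))  # wrap to [-pi, pi]
    rms = float(np.sqrt(np.mean((load_un - model_f) ** 2)))
    return OscillationFit(
        frequency_hz=frequency_hz,
        f0_un=f0,
        h0_um=h0,
        phase_lag_rad=lag,
        mean_depth_um=float(depth_um.mean()),
        residual_rms_un=rms,
    )


def contact_radius(probe_radius_um: float, depth_um: float) -> float:
    """Hertzian contact radius ``a = sqrt(R*h)`` (um)."""
    if probe_radius_um <= 0:
        raise InvalidParameterError("probe radius must be positive")
    if depth_um < 0:
        raise InvalidParameterError("depth must be non-negative")
    return float(np.sqrt(probe_radius_um * depth_um))


def contact_area(probe_radius_um: float, depth_um: float) -> float:
    """Contact area ``A = pi a^2 = pi R h`` (um^2)."""
    return float(np.pi * contact_radius(probe_radius_um, depth_um) ** 2)


def _dynamic_modulus(fit: OscillationFit, area_um2: float, trig) -> float:
    if area_um2 <= 0:
        raise InvalidParameterError("contact area must be positive")
    if fit.h0_um <= 0:
        raise InvalidParameterError("indentation oscillation amplitude must be positive")
    stiffness_n_per_m = fit.f0_un / fit.h0_um  # uN/um == N/m numerically
    area_m2 = area_um2 * 1e-12
    return float(
        stiffness_n_per_m * trig(fit.phase_lag_rad) * np.sqrt(np.pi) / (2.0 * np.sqrt(area_m2))
    )


def storage_modulus(fit: OscillationFit, area_um2: float) -> float:
    """Apparent storage modulus K' (Pa), in-phase component of the stiffness."""
    return _dynamic_modulus(fit, area_um2, np.cos)


def loss_modulus(fit: OscillationFit, area_um2: float) -> float:
    """Apparent loss modulus K" (Pa), out-of-phase component."""
    return _dynamic_modulus(fit, area_um2, np.sin)


def loss_tangent(k_storage_pa: float, k_loss_pa: float) -> float:
    """Viscous-to-elastic ratio ``K"/K'`` (= tan of the phase lag)."""
    if k_storage_pa <= 0:
        raise InvalidParameterError("storage modulus must be positive")
    return float(k_loss_pa / k_storage_pa)


def trial_pressure_strain(
    max_load_un: float, probe_radius_um: float, depth_um: float
) -> tuple[float, float]:
    """Per-trial mean contact pressure (Pa) and indentation strain.

    ``pressure = F_max / (pi R h)``; ``strain = a/R = sqrt(h/R)``.
    """
    if probe_radius_um <= 0 or depth_um <= 0:
        raise InvalidParameterError("radius and depth must be positive")
    if max_load_un < 0:
        raise InvalidParameterError("load must be non-negative")
    area_um2 = contact_area(probe_radius_um, depth_um)
    pressure_pa = (max_load_un * 1e-6) / (area_um2 * 1e-12)
    strain = float(np.sqrt(depth_um / probe_radius_um))
    return float(pressure_pa), strain


def analyze_trace(trace: IndentationTrace) -> ViscoModuli:
    """Full single-location analysis: contact, per-frequency fit, moduli."""
    t_c, _ = detect_contact_point(trace)
    t_c = refine_contact_hertz(trace, t_c)
    depth = indentation_depth(trace, t_c)
    freqs: list[float] = []
    ks: list[float] = []
    kl: list[float] = []
    tp: list[float] = []
    radii: list[float] = []
    for lab in trace.oscillation_labels():
        f = float(lab.split("@", 1)[1])
        m = trace.segment(lab)
        fit = fit_oscillation(trace.time_s[m], depth[m], trace.load_un[m], f)
        if not fit.physical:
            warnings.warn(
                f"phase lag {fit.phase_lag_rad:.3f} rad at {f} Hz outside [0, pi/2]",
                stacklevel=2,
            )
        a = contact_radius(trace.probe_radius_um, fit.mean_depth_um)
        area = float(np.pi * a**2)
        kp = storage_modulus(fit, area)
        kpp = loss_modulus(fit, area)
        freqs.append(f)
        ks.append(kp)
        kl.append(kpp)
        tp.append(loss_tangent(kp, kpp))
        radii.append(a)
    loc = trace.location_xy_um if trace.location_xy_um is not None else (0.0, 0.0)
    return ViscoModuli(
        location_xy_um=loc,
        frequencies_hz=freqs,
        k_storage_pa=ks,
        k_loss_pa=kl,
        tan_phi=tp,
        contact_radius_um=radii,
    )


def build_indentation_map(
    traces: list[IndentationTrace], spacing_um: float = 50.0
) -> pd.DataFrame:
    """Long-format moduli map: one row per (location, frequency).

    Columns ``x_um, y_um, freq_hz, k_storage_pa, k_loss_pa, tan_phi``.
    Duplicate scan coordinates are an error; off-grid spacing only warns.
    """
    rows = []
    seen: set[tuple[float, float]] = set()
    for tr in traces:
        if tr.location_xy_um is None:
            raise InvalidParameterError("map traces must carry scan coordinates")
        key = (float(tr.location_xy_um[0]), float(tr.location_xy_um[1]))
        if key in seen:
            raise DuplicateLocationError(f"duplicate scan location {key}")
        seen.add(key)
        vm = analyze_trace(tr)
        for f, kp, kpp, t in zip(
            vm.frequencies_hz, vm.k_storage_pa, vm.k_loss_pa, vm.tan_phi
        ):
            rows.append(
                {
                    "x_um": key[0],
                    "y_um": key[1],
                    "freq_hz": f,
                    "k_storage_pa": kp,
                    "k_loss_pa": kpp,
                    "tan_phi": t,
                }
            )
    df = pd.DataFrame(rows)
    if len(seen) > 1 and spacing_um > 0:
        xs = sorted({x for x, _ in seen})
        ys = sorted({y for _, y in seen})
        deltas = np.diff(xs).tolist() + np.diff(ys).tolist()
        deltas = [d for d in deltas if d > 0]
        if deltas and not np.allclose(np.mod(deltas, spacing_um), 0, atol=1e-6):
            warnings.warn(
                f"scan coordinates are not multiples of {spacing_um} um", stacklevel=2
            )
    return df


def frequency_sweep_stats(
    map_df: pd.DataFrame, alphas: tuple[float, float] = (0.01, 0.0005)
) -> dict:
    """Frequency-comparison statistics on a moduli map.

    Shapiro-Wilk normality per frequency, then a Kruskal-Wallis test across
    frequencies, separately for K' and K".  All-identical groups are reported
    as H = 0, p = 1 (the tie-corrected statistic is undefined there).
    """
    freqs = sorted(map_df["freq_hz"].unique())
    if len(freqs) < 2:
        raise InsufficientDataError("need at least two frequencies")
    report: dict = {"frequencies_hz": [float(f) for f in freqs], "alphas": list(alphas)}
    for col, name in (("k_storage_pa", "k_storage"), ("k_loss_pa", "k_loss")):
        groups = [map_df.loc[map_df["freq_hz"] == f, col].to_numpy() for f in freqs]
        if any(len(g) < 3 for g in groups):
            raise InsufficientDataError("need >= 3 locations per frequency")
        shapiro = {}
        for f, g in zip(freqs, groups):
            if np.ptp(g) == 0:
                shapiro[float(f)] = float("nan")
            else:
                shapiro[float(f)] = float(stats.shapiro(g).pvalue)
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*groups)
        report[name] = {
            "shapiro_p": shapiro,
            "kruskal_h": float(h),
            "kruskal_p": float(p),
            "significant": {str(a): bool(p < a) for a in alphas},
        }
    return report
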