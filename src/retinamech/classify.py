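"""ON / OFF / ON-OFF / NC classification from full-field flash responses.

Units are characterized by the Bias Index ``BI = (A_w - A_b)/(A_w + A_b)``
where ``A_w`` and ``A_b`` are the baseline-subtracted peak responses to
white and black flashes.  BI > 0.3 marks ON, BI < -0.3 marks OFF, the rest
are ON-OFF; units whose peak firing rate does not rise above the basal mean
plus one basal SD carry no detectable flash response and are non-classified
(NC).  Basal statistics are taken from the distribution of raw sliding-
window rates over the basal recording — the unit's own firing variability —
so the NC test asks whether the flash peak clears what basal activity alone
produces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, RetinaMechError
from .spikes import ClusterAssignment, SpikeTrainSet, compute_firing_rate

BI_THRESHOLD = 0.3
PSTH_WINDOW_S = 0.1
PSTH_STEP_S = 0.01
RESPONSE_EXTRA_S = 0.5

__all__ = [
    "peak_amplitudes",
    "bias_index",
    "classify_unit",
    "classify_units",
    "cluster_composition",
]


def _trial_averaged_psth(
    spikes: SpikeTrainSet,
    flash_times: np.ndarray,
    span_s: float,
    window_s: float,
    step_s: float,
) -> np.ndarray:
    """(units, bins) PSTH averaged over flash repeats, aligned at flash onset."""
    n_bins = int(np.floor((span_s - window_s) / step_s + 1e-9)) + 1
    centers = window_s / 2 + step_s * np.arange(n_bins)
    out = np.zeros((len(spikes.units), n_bins))
    for i, u in enumerate(spikes.units):
        t = u.spike_times_s
        for t0 in flash_times:
            lo = np.searchsorted(t, t0 + centers - window_s / 2, "left")
            hi = np.searchsorted(t, t0 + centers + window_s / 2, "left")
            out[i] += (hi - lo) / window_s
    return out / max(len(flash_times), 1)


def peak_amplitudes(
    spikes: SpikeTrainSet,
    basal_interval: tuple[float, float],
    flash_duration_s: float = 0.5,
    response_extra_s: float = RESPONSE_EXTRA_S,
    window_s: float = PSTH_WINDOW_S,
    step_s: float = PSTH_STEP_S,
) -> pd.DataFrame:
    """Per-unit flash-response amplitudes and basal statistics.

    ``A_w``/``A_b`` are the trial-averaged-PSTH peaks over the response
    window (flash duration + ``response_extra_s``) minus the basal mean,
    floored at zero.  ``peak_rate_hz`` is the larger raw PSTH peak, used by
    the NC rule.
    """
    whites = np.array([e.time_s for e in spikes.events if e.kind == "flash_white"])
    blacks = np.array([e.time_s for e in spikes.events if e.kind == "flash_black"])
    if whites.size == 0 or blacks.size == 0:
        raise RetinaMechError("flash protocol requires both white and black flashes")
    span = flash_duration_s + response_extra_s
    psth_w = _trial_averaged_psth(spikes, whites, span, window_s, step_s)
    psth_b = _trial_averaged_psth(spikes, blacks, span, window_s, step_s)
    basal = compute_firing_rate(spikes, basal_interval, window_s=window_s, step_s=step_s)
    basal_mean = basal.rates.mean(axis=1)
    basal_sd = basal.rates.std(axis=1)
    a_w = np.maximum(psth_w.max(axis=1) - basal_mean, 0.0)
    a_b = np.maximum(psth_b.max(axis=1) - basal_mean, 0.0)
    peak = np.maximum(psth_w.max(axis=1), psth_b.max(axis=1))
    return pd.DataFrame(
        {
            "unit_id": spikes.unit_ids,
            "a_w_hz": a_w,
            "a_b_hz": a_b,
            "peak_rate_hz": peak,
            "basal_mean_hz": basal_mean,
            "basal_sd_hz": basal_sd,
        }
    )


def bias_index(a_w_hz: float, a_b_hz: float) -> float:
    """``(A_w - A_b)/(A_w + A_b)``; NaN marks the undefined 0/0 case."""
    if a_w_hz < 0 or a_b_hz < 0:
        raise InvalidParameterError("amplitudes must be non-negative")
    total = a_w_hz + a_b_hz
    if total == 0:
        return float("nan")
    return float((a_w_hz - a_b_hz) / total)


def classify_unit(
    a_w_hz: float,
    a_b_hz: float,
    peak_rate_hz: float,
    basal_mean_hz: float,
    basal_sd_hz: float,
    bi_threshold: float = BI_THRESHOLD,
) -> str:
    """Label one unit; the NC (no detectable response) test runs first."""
    if peak_rate_hz < basal_mean_hz + basal_sd_hz:
        return "NC"
    bi = bias_index(a_w_hz, a_b_hz)
    if np.isnan(bi):
        return "NC"
    if bi > bi_threshold:
        return "ON"
    if bi < -bi_threshold:
        return "OFF"
    return "ON_OFF"


def classify_units(amplitudes: pd.DataFrame, bi_threshold: float = BI_THRESHOLD) -> pd.DataFrame:
    """Vector convenience: append ``bias_index`` and ``label`` columns."""
    out = amplitudes.copy()
    out["bias_index"] = [
        bias_index(w, b) for w, b in zip(out["a_w_hz"], out["a_b_hz"])
    ]
    out["label"] = [
        classify_unit(w, b, p, m, s, bi_threshold)
        for w, b, p, m, s in zip(
            out["a_w_hz"], out["a_b_hz"], out["peak_rate_hz"],
            out["basal_mean_hz"], out["basal_sd_hz"],
        )
    ]
    return out


def cluster_composition(
    labels: pd.DataFrame,
    clusters: ClusterAssignment,
    responsive_cluster_ids: set[int],
) -> pd.DataFrame:
    """Cell-type fractions in responsive vs unresponsive cluster groups."""
    import warnings

    label_of = dict(zip(labels["unit_id"], labels["label"]))
    groups: dict[str, list[str]] = {"responsive": [], "unresponsive": []}
    for uid, cl in zip(clusters.unit_ids, clusters.labels):
        if uid not in label_of:
            continue
        key = "responsive" if int(cl) in responsive_cluster_ids else "unresponsive"
        groups[key].append(label_of[uid])
    rows = []
    for key, members in groups.items():
        if not members:
            warnings.warn(f"{key} group is empty", stacklevel=2)
            continue
        n = len(members)
        row = {"group": key, "n_units": n}
        for t in ("ON", "OFF", "ON_OFF", "NC"):
            row[f"frac_{t}"] = members.count(t) / n
        rows.append(row)
    return pd.DataFrame(rows)
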