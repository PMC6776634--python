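"""Sliding-window firing rates, correlation structure and clustering.

The population analysis follows the indentation experiments: per-unit firing
rates are counted in a 2 s window sliding in 10 ms steps, z-scored, and the
Pearson correlation matrix of the standardized rates is computed for a basal
window (the 120 s preceding stimulation onset) and for the indentation
window.  Units are clustered hierarchically on the distance ``1 - |rho|``
(correlated and anti-correlated activity are deliberately treated alike) and
the cluster count is selected by silhouette maximization over k in [4, 60].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .errors import (
    AlignmentError,
    InsufficientDataError,
    InvalidParameterError,
    TriggerConsistencyError,
)

DEFAULT_WINDOW_S = 2.0
DEFAULT_STEP_S = 0.01
DEFAULT_K_RANGE = (4, 60)
BASAL_WINDOW_S = 120.0

__all__ = [
    "Unit",
    "Event",
    "SpikeTrainSet",
    "FiringRateMatrix",
    "ClusterAssignment",
    "filter_units",
    "compute_firing_rate",
    "zscore_rates",
    "correlation_matrix",
    "cluster_units",
    "reorder_basal",
    "within_between_abs_corr",
    "align_stimulation_window",
    "responsive_clusters",
    "cluster_timecourse",
]


@dataclass
class Unit:
    unit_id: int
    electrode_row: int
    electrode_col: int
    spike_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)


@dataclass
class Event:
    kind: str  # indent_on | indent_off | flash_white | flash_black
    time_s: float
    params: dict = field(default_factory=dict)


@dataclass
class SpikeTrainSet:
    """Sorted single units with electrode coordinates and an event schedule."""

    units: list[Unit]
    recording_duration_s: float
    events: list[Event] = field(default_factory=list)
    grid_shape: tuple[int, int] = (64, 64)
    pitch_um: float = 42.0

    def __post_init__(self) -> None:
        for u in self.units:
            t = u.spike_times_s
            if t.size and (t[0] < 0 or t[-1] > self.recording_duration_s):
                raise InvalidParameterError(
                    f"unit {u.unit_id}: spikes outside [0, duration]"
                )
            if t.size >= 2 and not np.all(np.diff(t) > 0):
                raise InvalidParameterError(
                    f"unit {u.unit_id}: spike times not strictly increasing"
                )
            if not (
                0 <= u.electrode_row < self.grid_shape[0]
                and 0 <= u.electrode_col < self.grid_shape[1]
            ):
                raise InvalidParameterError(f"unit {u.unit_id}: electrode off-grid")

    @property
    def unit_ids(self) -> list[int]:
        return [u.unit_id for u in self.units]

    def positions(self) -> np.ndarray:
        """(n_units, 2) array of (row, col) electrode coordinates."""
        return np.array([[u.electrode_row, u.electrode_col] for u in self.units])

    def mean_rates(self, interval: tuple[float, float] | None = None) -> np.ndarray:
        if interval is None:
            t0, t1 = 0.0, self.recording_duration_s
        else:
            t0, t1 = interval
        span = t1 - t0
        return np.array(
            [
                np.count_nonzero((u.spike_times_s >= t0) & (u.spike_times_s < t1)) / span
                for u in self.units
            ]
        )


@dataclass
class FiringRateMatrix:
    unit_ids: list[int]
    bin_centers_s: np.ndarray
    rates: np.ndarray  # (units, bins), Hz when raw
    window_s: float
    step_s: float
    normalized: bool = False
    constant_mask: np.ndarray | None = None  # True where the raw row had zero variance


@dataclass
class ClusterAssignment:
    unit_ids: list[int]
    labels: np.ndarray
    k_selected: int
    silhouette_by_k: dict[int, float]
    linkage_method: str = "average"

    def members(self, label: int) -> list[int]:
        return [u for u, l in zip(self.unit_ids, self.labels) if l == label]


def filter_units(spikes: SpikeTrainSet, min_rate_hz: float = 0.1) -> SpikeTrainSet:
    """Keep units firing at >= ``min_rate_hz`` over the whole recording."""
    if spikes.recording_duration_s <= 0:
        raise InvalidParameterError("recording duration must be positive")
    kept = [
        u
        for u in spikes.units
        if u.spike_times_s.size / spikes.recording_duration_s >= min_rate_hz
    ]
    if not kept:
        warnings.warn("no units survive the rate filter", stacklevel=2)
    return SpikeTrainSet(
        units=kept,
        recording_duration_s=spikes.recording_duration_s,
        events=spikes.events,
        grid_shape=spikes.grid_shape,
        pitch_um=spikes.pitch_um,
    )


def compute_firing_rate(
    spikes: SpikeTrainSet,
    interval: tuple[float, float],
    window_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
) -> FiringRateMatrix:
    """Sliding-window rates on centered bins fully inside ``interval``.

    Bin at center c counts spikes in ``[c - w/2, c + w/2)`` divided by w.
    """
    t0, t1 = interval
    if t1 - t0 < window_s:
        raise InsufficientDataError("interval shorter than the counting window")
    n_bins = int(np.floor((t1 - t0 - window_s) / step_s + 1e-9)) + 1
    centers = t0 + window_s / 2 + step_s * np.arange(n_bins)
    lo = centers - window_s / 2
    hi = centers + window_s / 2
    rates = np.empty((len(spikes.units), n_bins))
    for i, u in enumerate(spikes.units):
        t = u.spike_times_s
        rates[i] = (np.searchsorted(t, hi, "left") - np.searchsorted(t, lo, "left")) / window_s
    return FiringRateMatrix(
        unit_ids=spikes.unit_ids,
        bin_centers_s=centers,
        rates=rates,
        window_s=window_s,
        step_s=step_s,
    )


def zscore_rates(frm: FiringRateMatrix) -> FiringRateMatrix:
    """Per-row z-scoring with the population-SD (divisor n) convention.

    Zero-variance rows are flagged in ``constant_mask`` and left at zero
    rather than producing NaNs; downstream correlation excludes them.
    """
    if frm.rates.shape[1] < 2:
        raise InsufficientDataError("need >= 2 bins to z-score")
    mu = frm.rates.mean(axis=1, keepdims=True)
    sd = frm.rates.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    safe = np.where(sd == 0, 1.0, sd)
    z = (frm.rates - mu) / safe
    z[constant] = 0.0
    return FiringRateMatrix(
        unit_ids=frm.unit_ids,
        bin_centers_s=frm.bin_centers_s,
        rates=z,
        window_s=frm.window_s,
        step_s=frm.step_s,
        normalized=True,
        constant_mask=constant,
    )


def correlation_matrix(frm: FiringRateMatrix) -> pd.DataFrame:
    """Pearson correlations between unit rate rows (constant rows excluded)."""
    z = zscore_rates(frm) if not frm.normalized else frm
    mask = (
        ~z.constant_mask
        if z.constant_mask is not None
        else z.rates.std(axis=1) > 0
    )
    ids = [u for u, keep in zip(z.unit_ids, mask) if keep]
    if len(ids) < 2:
        raise InsufficientDataError("need >= 2 non-constant units")
    rows = z.rates[mask]
    corr = np.corrcoef(rows)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=ids, columns=ids)


def cluster_units(
    corr: pd.DataFrame,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    linkage_method: str = "average",
) -> ClusterAssignment:
    """Agglomerative clustering on distance ``1 - |rho|`` with silhouette k.

    The dendrogram is cut at every k in ``k_range`` and the silhouette score
    (on the precomputed distance) selects k; ties go to the smallest k.
    Degenerate inputs (all-identical signals) fall back to one cluster.
    """
    ids = list(corr.index)
    n = len(ids)
    dist = 1.0 - np.abs(corr.to_numpy())
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    k_min, k_max = k_range
    if n <= k_min:
        warnings.warn(
            f"only {n} units; truncating k range [{k_min}, {k_max}]", stacklevel=2
        )
        k_min = 2
    k_max = min(k_max, n - 1)
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        lab = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        labels_by_k[k] = lab
        sil[k] = float(silhouette_score(dist, lab, metric="precomputed"))
    if not sil:
        warnings.warn(
            "silhouette undefined for every k; single-cluster fallback", stacklevel=2
        )
        return ClusterAssignment(
            unit_ids=ids,
            labels=np.ones(n, dtype=int),
            k_selected=1,
            silhouette_by_k={},
            linkage_method=linkage_method,
        )
    best_k = min(sil, key=lambda k: (-sil[k], k))
    return ClusterAssignment(
        unit_ids=ids,
        labels=labels_by_k[best_k],
        k_selected=best_k,
        silhouette_by_k=sil,
        linkage_method=linkage_method,
    )


def within_between_abs_corr(
    corr: pd.DataFrame, clusters: ClusterAssignment
) -> dict[str, float]:
    """Mean |rho| within clusters (size >= 2 only) and between clusters."""
    if list(corr.index) != clusters.unit_ids:
        order = [u for u in clusters.unit_ids if u in set(corr.index)]
        if len(order) != len(clusters.unit_ids):
            raise AlignmentError("correlation matrix and clustering disagree on units")
        corr = corr.loc[order, order]
    a = np.abs(corr.to_numpy())
    labels = np.asarray(clusters.labels)
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    within_mask = same & off
    between_mask = ~same
    within = float(a[within_mask].mean()) if within_mask.any() else float("nan")
    between = float(a[between_mask].mean()) if between_mask.any() else float("nan")
    return {"within": within, "between": between}


def reorder_basal(
    basal_corr: pd.DataFrame,
    clusters: ClusterAssignment,
    indentation_corr: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Permute the basal matrix cluster-contiguously; summarize both phases."""
    if set(basal_corr.index) != set(clusters.unit_ids):
        raise AlignmentError("basal matrix and clustering cover different units")
    order = [
        u
        for _, u in sorted(
            zip(clusters.labels, clusters.unit_ids), key=lambda p: (p[0], p[1])
        )
    ]
    reordered = basal_corr.loc[order, order]
    summary = {"basal": within_between_abs_corr(basal_corr, clusters)}
    if indentation_corr is not None:
        summary["indentation"] = within_between_abs_corr(indentation_corr, clusters)
    return reordered, summary


def align_stimulation_window(
    spikes: SpikeTrainSet,
    triggers: list[tuple[float, float]],
    basal_s: float = BASAL_WINDOW_S,
) -> tuple[SpikeTrainSet, list[dict]]:
    """Annotate indent_on/indent_off events and derive basal windows.

    Each trigger pair (start, end) yields a basal window of ``basal_s``
    seconds immediately preceding the onset (truncated at t=0 with a
    warning) and the indentation window [start, end).
    """
    windows = []
    events = list(spikes.events)
    for start, end in triggers:
        if end <= start:
            raise TriggerConsistencyError(f"trigger end {end} <= start {start}")
        if start < 0 or end > spikes.recording_duration_s:
            raise TriggerConsistencyError("trigger outside the recording")
        b0 = start - basal_s
        if b0 < 0:
            warnings.warn("basal window truncated at t=0", stacklevel=2)
            b0 = 0.0
        events.append(Event("indent_on", float(start)))
        events.append(Event("indent_off", float(end)))
        windows.append(
            {"basal": (float(b0), float(start)), "indentation": (float(start), float(end))}
        )
    out = SpikeTrainSet(
        units=spikes.units,
        recording_duration_s=spikes.recording_duration_s,
        events=sorted(events, key=lambda e: e.time_s),
        grid_shape=spikes.grid_shape,
        pitch_um=spikes.pitch_um,
    )
    return out, windows


def responsive_clusters(
    frm_basal: FiringRateMatrix,
    frm_indent: FiringRateMatrix,
    clusters: ClusterAssignment,
    min_size: int = 3,
    z_threshold: float = 3.0,
) -> dict[int, float]:
    """Clusters whose mean basal-referenced z-rate swings past threshold.

    Each unit's indentation-window rate is standardized by its own basal
    mean and SD (evoked modulation is judged against the pre-stimulus
    firing regime, not against within-window variance, which the response
    itself inflates).  Returns {cluster label: peak |mean z|} for clusters
    of at least ``min_size`` members exceeding ``z_threshold``.
    """
    if frm_basal.normalized or frm_indent.normalized:
        raise InvalidParameterError("responsive_clusters needs raw (Hz) rate matrices")
    idx_b = {u: i for i, u in enumerate(frm_basal.unit_ids)}
    idx_i = {u: i for i, u in enumerate(frm_indent.unit_ids)}
    out: dict[int, float] = {}
    for label in sorted(set(clusters.labels)):
        members = [u for u in clusters.members(label) if u in idx_b and u in idx_i]
        if len(members) < min_size:
            continue
        zs = []
        for u in members:
            base = frm_basal.rates[idx_b[u]]
            mu, sd = base.mean(), base.std()
            if sd == 0:
                continue
            zs.append((frm_indent.rates[idx_i[u]] - mu) / sd)
        if len(zs) < min_size:
            continue
        peak = float(np.max(np.abs(np.mean(zs, axis=0))))
        if peak >= z_threshold:
            out[int(label)] = peak
    return out


def cluster_timecourse(
    frm: FiringRateMatrix, clusters: ClusterAssignment
) -> dict[int, dict[str, np.ndarray]]:
    """Per-cluster mean +/- SEM of z-scored rates at each bin.

    Single-member clusters get SEM = 0 and ``flagged_single=True``.
    """
    z = frm if frm.normalized else zscore_rates(frm)
    idx = {u: i for i, u in enumerate(z.unit_ids)}
    out: dict[int, dict[str, np.ndarray]] = {}
    for label in sorted(set(clusters.labels)):
        members = [idx[u] for u in clusters.members(label) if u in idx]
        rows = z.rates[members]
        mean = rows.mean(axis=0)
        if len(members) > 1:
            sem = rows.std(axis=0, ddof=1) / np.sqrt(len(members))
            single = False
        else:
            sem = np.zeros_like(mean)
            single = True
        out[int(label)] = {
            "mean": mean,
            "sem": sem,
            "n": len(members),
            "flagged_single": single,
        }
    return out
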