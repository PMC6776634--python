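"""Per-trial predictors of successful mechanical stimulation.

Each indentation trial is summarized by four physical features (contact
area, strain, pressure, depth) and two electrophysiological ones: ``d5``,
the number of units within five electrode distances of the indentation
center, and ``r5``, their mean basal firing rate.  A decision-tree
classifier (Gini criterion) is fit many times under different initial
conditions — repeat-specific stratified 80/20 train splits — and the
normalized Gini importances are averaged to rank the predictors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .errors import (
    AlignmentError,
    DegenerateOutcomeError,
    InsufficientDataError,
    InvalidParameterError,
)
from .mechanics import contact_area, trial_pressure_strain
from .spikes import SpikeTrainSet

FEATURE_COLUMNS = ["contact_area_um2", "strain", "pressure_pa", "depth_um", "d5", "r5"]
D5_RADIUS_ELECTRODES = 5.0

__all__ = ["local_density_rate", "build_feature_table", "feature_importance", "FEATURE_COLUMNS"]


def local_density_rate(
    spikes: SpikeTrainSet,
    center: tuple[int, int],
    basal_interval: tuple[float, float],
    radius_electrodes: float = D5_RADIUS_ELECTRODES,
) -> tuple[int, float]:
    """(d5, r5): unit count and mean basal rate within the local disk.

    Distance is Euclidean in electrode units, inclusive at the radius.
    ``r5`` is NaN when no unit is local.
    """
    r0, c0 = center
    if not (0 <= r0 < spikes.grid_shape[0] and 0 <= c0 < spikes.grid_shape[1]):
        raise InvalidParameterError("center must be on the electrode grid")
    pos = spikes.positions()
    dist = np.hypot(pos[:, 0] - r0, pos[:, 1] - c0)
    local = dist <= radius_electrodes
    d5 = int(local.sum())
    if d5 == 0:
        return 0, float("nan")
    rates = spikes.mean_rates(basal_interval)
    return d5, float(rates[local].mean())


def build_feature_table(
    trials: list[dict],
    spikes_by_trial: dict | SpikeTrainSet,
    centers: dict[int, tuple[int, int]],
    outcomes: dict[int, bool],
    basal_interval: tuple[float, float],
) -> pd.DataFrame:
    """Join mechanics and local-electrophysiology features per trial.

    ``trials`` rows need ``trial_id, depth_um, max_load_un, probe_radius_um``.
    ``spikes_by_trial`` is either one SpikeTrainSet shared by all trials or a
    mapping trial_id -> SpikeTrainSet.  Trials missing any feature are
    dropped with a logged reason.
    """
    import logging

    log = logging.getLogger(__name__)
    seen: set = set()
    rows = []
    for tr in trials:
        tid = tr["trial_id"]
        if tid in seen:
            raise AlignmentError(f"duplicate trial id {tid}")
        seen.add(tid)
        if tid not in centers or tid not in outcomes:
            log.warning("trial %s dropped: missing center or outcome", tid)
            continue
        sts = (
            spikes_by_trial[tid]
            if isinstance(spikes_by_trial, dict)
            else spikes_by_trial
        )
        pressure, strain = trial_pressure_strain(
            tr["max_load_un"], tr["probe_radius_um"], tr["depth_um"]
        )
        d5, r5 = local_density_rate(sts, centers[tid], basal_interval)
        if d5 == 0:
            log.warning("trial %s dropped: no local units (r5 undefined)", tid)
            continue
        rows.append(
            {
                "trial_id": tid,
                "contact_area_um2": contact_area(tr["probe_radius_um"], tr["depth_um"]),
                "strain": strain,
                "pressure_pa": pressure,
                "depth_um": tr["depth_um"],
                "d5": d5,
                "r5": r5,
                "outcome": bool(outcomes[tid]),
            }
        )
    return pd.DataFrame(rows)


def feature_importance(
    table: pd.DataFrame,
    n_repeats: int = 1000,
    seed: int = 0,
    repeat_mode: str = "split",
    test_size: float = 0.2,
    feature_columns: list[str] | None = None,
) -> dict:
    """Mean +/- SD normalized Gini importance over repeated tree fits.

    ``repeat_mode="split"`` refits on a fresh stratified 80/20 train split
    per repeat; ``"seed_only"`` refits on the full table with only the
    tree's internal tie-breaking reseeded.  Per-repeat importances sum to 1
    (sklearn's normalization) whenever the tree makes at least one split.
    """
    cols = feature_columns or [c for c in FEATURE_COLUMNS if c in table.columns]
    if len(table) < 10:
        raise InsufficientDataError("need at least 10 trials")
    y = table["outcome"].astype(bool).to_numpy()
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("outcome has a single class")
    if repeat_mode not in ("split", "seed_only"):
        raise InvalidParameterError(f"unknown repeat_mode {repeat_mode!r}")
    x = table[cols].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    importances = np.empty((n_repeats, len(cols)))
    for rep in range(n_repeats):
        rs = int(rng.integers(0, 2**31 - 1))
        if repeat_mode == "split":
            x_tr, _, y_tr, _ = train_test_split(
                x, y, test_size=test_size, stratify=y, random_state=rs
            )
        else:
            x_tr, y_tr = x, y
        tree = DecisionTreeClassifier(criterion="gini", random_state=rs)
        tree.fit(x_tr, y_tr)
        importances[rep] = tree.feature_importances_
    return {
        "features": cols,
        "mean_importance": importances.mean(axis=0).tolist(),
        "sd_importance": importances.std(axis=0).tolist(),
        "n_repeats": n_repeats,
        "repeat_mode": repeat_mode,
        "per_repeat_sum_ok": bool(
            np.allclose(importances.sum(axis=1), 1.0, atol=1e-9)
        ),
    }
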