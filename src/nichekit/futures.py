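"""Threshold binarization, scenario change accounting, and MESS surfaces."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from nichekit.errors import GeometryError, InputError
from nichekit.grids import EnvStack, GridGeometry
from nichekit.maxent import SuitabilityMap

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD_PERCENTILE = 10.0


@dataclass
class BinaryMap:
    """Thresholded presence/absence grid."""

    mask: np.ndarray
    geometry: GridGeometry
    valid: np.ndarray
    threshold_value: float
    model_id: str
    scenario_id: str = "present"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        self.valid = np.asarray(self.valid, bool)
        if self.mask.shape != self.geometry.shape or self.valid.shape != self.geometry.shape:
            raise InputError("mask shape does not match geometry")
        # suitable cells must be valid in the source map
        self.mask = self.mask & self.valid

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class ChangeMetrics:
    """Pixel bookkeeping between a present and a future binary map.

    Identities: n_present = n_retained + n_lost;
    n_future = n_retained + n_gained.
    """

    n_present: int
    n_future: int
    n_retained: int
    n_lost: int
    n_gained: int
    frac_lost: float
    frac_gained: float


@dataclass
class MESSMap:
    """Multivariate environmental similarity surface.

    Negative values flag cells where at least one variable lies outside
    its training [min, max] (non-analog conditions).
    """

    values: np.ndarray
    most_dissimilar_var: np.ndarray  # object array of variable names ('' on masked cells)
    valid: np.ndarray
    geometry: GridGeometry


def training_threshold(training_presence_scores: np.ndarray, percentile: float = DEFAULT_THRESHOLD_PERCENTILE) -> float:
    """Order-statistic threshold: the (floor(p/100*n)+1)-th smallest score.

    At most floor(p/100*n) training presences fall strictly below it.
    """
    scores = np.sort(np.asarray(training_presence_scores, float))
    n = len(scores)
    if n == 0:
        raise InputError("empty training scores")
    if not (0 <= percentile < 100):
        raise InputError("percentile must be in [0, 100)")
    k = int(np.floor(percentile / 100.0 * n))  # 0-based index of the (k+1)-th smallest
    return float(scores[min(k, n - 1)])


def binarize(
    suitability: SuitabilityMap,
    training_presence_scores: np.ndarray,
    percentile: float = DEFAULT_THRESHOLD_PERCENTILE,
    scenario_id: str = "present",
    threshold_value: float | None = None,
) -> BinaryMap:
    """Binary map: suitability >= training-score threshold on valid cells.

    For future projections pass the present-derived threshold via
    ``threshold_value`` so all scenarios of a class reuse one threshold.
    """
    if threshold_value is None:
        threshold_value = training_threshold(training_presence_scores, percentile)
    layer = suitability.layer
    mask = (layer.values >= threshold_value) & layer.valid_mask
    return BinaryMap(
        mask=mask, geometry=layer.geometry, valid=layer.valid_mask,
        threshold_value=threshold_value, model_id=suitability.model_id,
        scenario_id=scenario_id,
    )


def _check_coreg(a: BinaryMap, b: BinaryMap) -> None:
    if not a.geometry.co_registered(b.geometry):
        raise GeometryError("binary maps are not co-registered")


def change_metrics(present: BinaryMap, future: BinaryMap) -> ChangeMetrics:
    """Loss/gain/retention pixel accounting between two binary maps."""
    _check_coreg(present, future)
    lost = present.mask & ~future.mask
    gained = ~present.mask & future.mask
    retained = present.mask & future.mask
    n_p = present.area
    n_l, n_g, n_r = (int(np.count_nonzero(x)) for x in (lost, gained, retained))
    return ChangeMetrics(
        n_present=n_p, n_future=future.area, n_retained=n_r,
        n_lost=n_l, n_gained=n_g,
        frac_lost=n_l / n_p if n_p else 0.0,
        frac_gained=n_g / n_p if n_p else 0.0,
    )


def gcm_intersection(maps: list[BinaryMap], mode: str = "intersection") -> BinaryMap:
    """Cells supported by all (intersection) or any (union) ensemble members."""
    if not maps:
        raise InputError("need >= 1 binary map")
    if mode not in ("intersection", "union"):
        raise InputError("mode must be 'intersection' or 'union'")
    for m in maps[1:]:
        _check_coreg(maps[0], m)
    acc = maps[0].mask.copy()
    valid = maps[0].valid.copy()
    for m in maps[1:]:
        acc = (acc & m.mask) if mode == "intersection" else (acc | m.mask)
        valid &= m.valid
    return BinaryMap(
        mask=acc, geometry=maps[0].geometry, valid=valid,
        threshold_value=maps[0].threshold_value, model_id=maps[0].model_id,
        scenario_id=f"{mode}({','.join(m.scenario_id for m in maps)})",
    )


def class_overlap_change(
    class_a_present: BinaryMap,
    class_a_future: BinaryMap,
    class_b_present: BinaryMap,
    class_b_future: BinaryMap,
) -> dict[str, float]:
    """Between-class overlap per epoch plus the overlap lost in the future.

    Percent overlap convention is intersection/union * 100. The
    ``n_overlap_lost`` cells are those shared at present but no longer
    shared in the future.
    """
    for m in (class_a_future, class_b_present, class_b_future):
        _check_coreg(class_a_present, m)

    def _pair(a: BinaryMap, b: BinaryMap) -> tuple[int, float]:
        inter = int(np.count_nonzero(a.mask & b.mask))
        union = int(np.count_nonzero(a.mask | b.mask))
        return inter, (100.0 * inter / union if union else 0.0)

    inter_p, pct_p = _pair(class_a_present, class_b_present)
    inter_f, pct_f = _pair(class_a_future, class_b_future)
    present_shared = class_a_present.mask & class_b_present.mask
    future_shared = class_a_future.mask & class_b_future.mask
    lost = present_shared & ~future_shared
    return {
        "n_overlap_present": inter_p,
        "pct_overlap_present": pct_p,
        "n_overlap_future": inter_f,
        "pct_overlap_future": pct_f,
        "n_overlap_lost": int(np.count_nonzero(lost)),
    }


def mess_similarity(training: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Single-variable similarity score of projection values ``p``.

    f = 100 * fraction of training values strictly below p;
    similarity = (p-min)/(max-min)*100      if f = 0
                 2f                          if 0 < f <= 50
                 2(100-f)                    if 50 < f < 100
                 (max-p)/(max-min)*100       if f = 100
    Negative iff p lies outside [min, max]. A constant training variable
    scores 0 where p equals the constant and diverges negatively
    otherwise (flagged upstream).
    """
    t = np.sort(np.asarray(training, float))
    p = np.asarray(p, float)
    n = len(t)
    if n == 0:
        raise InputError("empty training vector")
    tmin, tmax = t[0], t[-1]
    f = 100.0 * np.searchsorted(t, p, side="left") / n
    if tmax == tmin:
        return np.where(p == tmin, 0.0, -100.0 * np.abs(p - tmin))
    span = tmax - tmin
    sim = np.where(
        f == 0, (p - tmin) / span * 100.0,
        np.where(
            f <= 50, 2.0 * f,
            np.where(f < 100, 2.0 * (100.0 - f), (tmax - p) / span * 100.0),
        ),
    )
    return sim


def mess(projection_env: EnvStack, training_env: np.ndarray, var_names: list[str] | None = None) -> MESSMap:
    """MESS surface of a projection stack against a training table.

    ``training_env`` columns follow ``var_names`` (default: stack order).
    """
    if var_names is None:
        var_names = list(projection_env.names)
    missing = [n for n in var_names if n not in projection_env.names]
    if missing:
        raise InputError(f"projection stack missing variables: {missing}")
    T = np.asarray(training_env, float)
    if T.shape[1] != len(var_names):
        raise InputError("training table width does not match variable list")
    for j, name in enumerate(var_names):
        if T[:, j].min() == T[:, j].max():
            log.warning("mess: training variable %r is constant; similarity degenerate", name)
    valid = projection_env.valid_mask
    rows, cols = np.nonzero(valid)
    sims = np.empty((len(rows), len(var_names)))
    for j, name in enumerate(var_names):
        sims[:, j] = mess_similarity(T[:, j], projection_env[name].values[rows, cols])
    min_idx = np.argmin(sims, axis=1)
    values = np.zeros(projection_env.geometry.shape)
    values[rows, cols] = sims[np.arange(len(rows)), min_idx]
    worst = np.full(projection_env.geometry.shape, "", dtype=object)
    worst[rows, cols] = np.asarray(var_names, dtype=object)[min_idx]
    return MESSMap(values=values, most_dissimilar_var=worst, valid=valid,
                   geometry=projection_env.geometry)


def scenario_summary(
    present_bins: dict[str, BinaryMap],
    future_bins: dict[tuple[str, int, str, str], BinaryMap],
) -> pd.DataFrame:
    """Long change-metrics table per class x period x pathway x GCM.

    ``future_bins`` is keyed (class, period, pathway, gcm_id). Each
    (class, period, pathway) group also gets an ``all_gcm_intersection``
    row. Classes with no future maps are listed as absent rows.
    """
    records = []
    groups: dict[tuple[str, int, str], list[BinaryMap]] = {}
    for (cls, period, pathway, gcm), fmap in sorted(future_bins.items()):
        if cls not in present_bins:
            raise InputError(f"no present binary map for class {cls!r}")
        cm = change_metrics(present_bins[cls], fmap)
        records.append({
            "class": cls, "period": period, "pathway": pathway, "gcm": gcm,
            **cm.__dict__,
        })
        groups.setdefault((cls, period, pathway), []).append(fmap)
    for (cls, period, pathway), maps in sorted(groups.items()):
        inter = gcm_intersection(maps, mode="intersection")
        cm = change_metrics(present_bins[cls], inter)
        records.append({
            "class": cls, "period": period, "pathway": pathway,
            "gcm": "all_gcm_intersection", **cm.__dict__,
        })
    for cls in sorted(present_bins):
        if not any(r["class"] == cls for r in records):
            records.append({"class": cls, "period": None, "pathway": "absent", "gcm": "absent",
                            "n_present": present_bins[cls].area, "n_future": None,
                            "n_retained": None, "n_lost": None, "n_gained": None,
                            "frac_lost": None, "frac_gained": None})
    return pd.DataFrame.from_records(records)
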