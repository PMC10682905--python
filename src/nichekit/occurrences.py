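"""Occurrence data model, thinning, extraction, variable selection, splits."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from nichekit.errors import InputError
from nichekit.grids import EnvStack

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

FINE_CLASSES = ("wild", "semiwild", "landrace", "commercial")
#: broad labels derivable from fine labels by union
BROAD_CLASSES = {
    "wild_sl": ("wild", "semiwild"),
    "cultivated": ("landrace", "commercial"),
}
CLASS_LABELS = FINE_CLASSES + tuple(BROAD_CLASSES)


def expand_class(label: str) -> tuple[str, ...]:
    """Fine labels covered by ``label`` (identity for fine labels)."""
    if label in BROAD_CLASSES:
        return BROAD_CLASSES[label]
    if label in FINE_CLASSES:
        return (label,)
    raise InputError(f"unknown class label {label!r}")


@dataclass
class OccurrenceSet:
    """Georeferenced, class-labelled presence records.

    ``env`` (records x variables) and ``env_names`` are populated by
    :func:`extract_env`; ``valid`` flags records that landed on unmasked
    grid cells.
    """

    ids: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    class_label: np.ndarray
    source: np.ndarray
    env: np.ndarray | None = None
    env_names: list[str] = field(default_factory=list)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.class_label = np.asarray(self.class_label, dtype=object)
        self.source = np.asarray(self.source, dtype=object)
        n = len(self.ids)
        for arr, what in ((self.lon, "lon"), (self.lat, "lat"), (self.class_label, "class"), (self.source, "source")):
            if len(arr) != n:
                raise InputError(f"{what} length {len(arr)} != {n} ids")
        if n and len(set(self.ids.tolist())) != n:
            raise InputError("occurrence ids must be unique")
        if n and (np.any(np.abs(self.lon) > 180) or np.any(np.abs(self.lat) > 90)):
            raise InputError("coordinates out of lon/lat range")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "OccurrenceSet":
        """Build from (id, lon, lat, class_label, source) tuples."""
        rows = list(records)
        if not rows:
            return cls.empty()
        ids, lon, lat, cl, src = zip(*rows)
        return cls(np.array(ids, dtype=object), np.array(lon, float), np.array(lat, float),
                   np.array(cl, dtype=object), np.array(src, dtype=object))

    @classmethod
    def empty(cls) -> "OccurrenceSet":
        z = np.array([], dtype=object)
        return cls(z, np.array([], float), np.array([], float), z.copy(), z.copy())

    def subset(self, index: np.ndarray) -> "OccurrenceSet":
        out = OccurrenceSet(
            self.ids[index], self.lon[index], self.lat[index],
            self.class_label[index], self.source[index],
        )
        if self.env is not None:
            out.env = self.env[index]
            out.env_names = list(self.env_names)
        if self.valid is not None:
            out.valid = self.valid[index]
        return out

    def for_class(self, label: str) -> "OccurrenceSet":
        fine = expand_class(label)
        keep = np.isin(self.class_label.astype(str), fine)
        return self.subset(keep)

    def valid_env(self) -> np.ndarray:
        """Environment table restricted to records on valid cells."""
        if self.env is None:
            raise InputError("environment not extracted; call extract_env first")
        if self.valid is None:
            return self.env
        return self.env[self.valid]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "id": self.ids.astype(str),
            "lon": self.lon,
            "lat": self.lat,
            "class": self.class_label.astype(str),
            "source": self.source.astype(str),
        })
        if self.env is not None:
            for j, name in enumerate(self.env_names):
                df[name] = self.env[:, j]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrenceSet":
        df = pd.read_csv(path, dtype={"id": str, "class": str, "source": str})
        required = {"id", "lon", "lat", "class"}
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"{path}: missing columns {sorted(missing)}")
        src = df["source"] if "source" in df.columns else pd.Series([""] * len(df))
        out = cls(
            df["id"].to_numpy(dtype=object), df["lon"].to_numpy(float), df["lat"].to_numpy(float),
            df["class"].to_numpy(dtype=object), src.to_numpy(dtype=object),
        )
        env_cols = [c for c in df.columns if c not in ("id", "lon", "lat", "class", "source")]
        if env_cols:
            out.env = df[env_cols].to_numpy(float)
            out.env_names = env_cols
            out.valid = np.ones(len(out), dtype=bool)
        return out


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (Earth radius 6371 km). Vectorized."""
    lon1, lat1 = np.radians(lon1), np.radians(lat1)
    lon2, lat2 = np.radians(lon2), np.radians(lat2)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def thin(points: OccurrenceSet, min_dist_km: float, seed: int | None = None) -> OccurrenceSet:
    """Greedy spatial thinning to a minimum pairwise great-circle distance.

    Single pass in input order: a record is kept iff its haversine
    distance to every already-kept record is >= ``min_dist_km``. Passing
    ``seed`` shuffles the priority order first (sensitivity checks);
    default is deterministic input order.
    """
    if min_dist_km < 0:
        raise InputError("min_dist_km must be >= 0")
    n = len(points)
    if n == 0 or min_dist_km == 0:
        return points.subset(np.arange(n))
    order = np.arange(n)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(n)
    kept: list[int] = []
    kept_lon = np.empty(n)
    kept_lat = np.empty(n)
    for i in order:
        k = len(kept)
        if k:
            d = haversine_km(points.lon[i], points.lat[i], kept_lon[:k], kept_lat[:k])
            if np.any(d < min_dist_km):
                continue
        kept_lon[k] = points.lon[i]
        kept_lat[k] = points.lat[i]
        kept.append(i)
    keep_idx = np.sort(np.array(kept, dtype=int))
    return points.subset(keep_idx)


def extract_env(points: OccurrenceSet, stack: EnvStack) -> OccurrenceSet:
    """Attach per-record environment vectors from the stack.

    Cell assignment uses the documented half-open rule (x in [left,right),
    y in (top,bottom]). Records off-grid or on masked cells are flagged
    invalid and excluded from downstream statistics; the count is logged.
    """
    out = points.subset(np.arange(len(points)))
    n = len(points)
    env = np.full((n, len(stack)), np.nan)
    row, col, inside = stack.geometry.locate(points.lon, points.lat)
    valid = inside.copy()
    if np.any(inside):
        r, c = row[inside], col[inside]
        on_valid = stack.valid_mask[r, c]
        valid[inside] = on_valid
        env_inside = stack.values_table(r, c)
        env[inside] = env_inside
    env[~valid] = np.nan
    n_dropped = int(n - np.count_nonzero(valid))
    if n_dropped:
        log.warning("extract_env: %d of %d records off-grid or on masked cells; excluded", n_dropped, n)
    out.env = env
    out.env_names = list(stack.names)
    out.valid = valid
    return out


def correlation_filter(
    env_table: pd.DataFrame | np.ndarray,
    threshold: float,
    names: Sequence[str] | None = None,
    keep: Sequence[str] = (),
) -> list[str]:
    """Greedy variable elimination so no retained pair has |Pearson r| > threshold.

    Pairs above threshold are visited in descending |r|; from each the
    member with the larger mean absolute correlation to the remaining
    variables is dropped. Variables in ``keep`` are never dropped
    (expert-knowledge hook). Constant variables are excluded up front
    with a warning (their r is undefined).
    """
    if isinstance(env_table, pd.DataFrame):
        names = list(env_table.columns)
        X = env_table.to_numpy(float)
    else:
        X = np.asarray(env_table, float)
        if names is None:
            names = [f"v{j}" for j in range(X.shape[1])]
        names = list(names)
    if X.shape[0] < 2:
        raise InputError("need >= 2 records to compute correlations")
    sd = X.std(axis=0)
    active = [j for j in range(X.shape[1]) if sd[j] > 0]
    for j in range(X.shape[1]):
        if sd[j] == 0:
            log.warning("correlation_filter: variable %r is constant; excluded", names[j])
    keep_set = set(keep)
    while True:
        if len(active) < 2:
            break
        R = np.corrcoef(X[:, active], rowvar=False)
        np.fill_diagonal(R, 0.0)
        absR = np.abs(R)
        i, j = np.unravel_index(np.argmax(absR), absR.shape)
        if absR[i, j] <= threshold:
            break
        a, b = active[i], active[j]
        mean_a = absR[i].sum() / (len(active) - 1)
        mean_b = absR[j].sum() / (len(active) - 1)
        # drop the member with larger mean |r|; keep-list overrides
        if names[a] in keep_set and names[b] in keep_set:
            log.warning("correlation_filter: kept pair (%s, %s) exceeds threshold per keep-list", names[a], names[b])
            break
        if names[a] in keep_set:
            drop = b
        elif names[b] in keep_set:
            drop = a
        else:
            drop = a if mean_a >= mean_b else b
        active.remove(drop)
    return [names[j] for j in active]


def split_train_test(points: OccurrenceSet, test_fraction: float, seed: int) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Seeded disjoint, exhaustive split; test size = round(n * fraction)."""
    if not (0 <= test_fraction < 1):
        raise InputError("test_fraction must be in [0, 1)")
    n = len(points)
    n_test = int(round(n * test_fraction))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return points.subset(train_idx), points.subset(test_idx)
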