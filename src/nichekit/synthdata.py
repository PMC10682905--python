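"""Seeded synthetic environments, class niches, occurrences, and scenarios.

Everything here is deterministic given its seed; a single master seed
fans out to per-stage child seeds by fixed offsets (see
:data:`SEED_OFFSETS`), recorded in run manifests.

The synthetic true niche is a Gaussian bell in environment space:
``s(e) = exp(-0.5 * sum_v ((e_v - opt_v)/breadth_v)^2)``, a smooth
unimodal suitability with controllable nesting — the recovery target for
the downstream model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon

from nichekit.errors import GeometryError, InputError
from nichekit.grids import EnvStack, GridGeometry, Layer
from nichekit.occurrences import OccurrenceSet

#: fixed child-seed offsets per pipeline stage, fanned out from the master seed
SEED_OFFSETS = {
    "env": 1,
    "occurrences": 2,
    "proxies": 3,
    "scenarios": 4,
    "split": 5,
    "background": 6,
    "replicates": 7,
    "randomization": 8,
    "bootstrap": 9,
}

PERIODS = (2050, 2070, 2090)
PATHWAYS = ("ssp245", "ssp585")
N_GCMS_DEFAULT = 8


def child_seed(master_seed: int, stage: str) -> int:
    if stage not in SEED_OFFSETS:
        raise InputError(f"unknown seed stage {stage!r}")
    return int(master_seed) * 1000 + SEED_OFFSETS[stage]


@dataclass(frozen=True)
class NicheSpec:
    """Gaussian true niche for one occurrence class."""

    class_label: str
    optimum: tuple[float, ...]
    breadth: tuple[float, ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if len(self.optimum) != len(self.breadth):
            raise InputError("optimum and breadth must have equal length")
        if any(b <= 0 for b in self.breadth):
            raise InputError("breadth must be strictly positive")
        if not (0 <= self.weight <= 1):
            raise InputError("weight must be in [0, 1]")

    def suitability(self, env: np.ndarray) -> np.ndarray:
        """True suitability s(e) in (0, 1] for an (n, n_vars) table.

        Uses the first ``len(optimum)`` environment columns.
        """
        env = np.asarray(env, float)
        k = len(self.optimum)
        if env.shape[1] < k:
            raise InputError(f"environment has {env.shape[1]} variables; niche needs {k}")
        z = (env[:, :k] - np.asarray(self.optimum)) / np.asarray(self.breadth)
        return np.exp(-0.5 * np.sum(z * z, axis=1))


@dataclass(frozen=True)
class ScenarioDelta:
    """Additive/multiplicative climate perturbation for one pseudo-GCM run."""

    gcm_id: str
    period: int
    pathway: str
    temp_shift: float
    precip_scale: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.precip_scale <= 0:
            raise InputError("precip_scale must be > 0")
        if self.period not in PERIODS:
            raise InputError(f"period must be one of {PERIODS}")
        if self.pathway not in PATHWAYS:
            raise InputError(f"pathway must be one of {PATHWAYS}")

    @property
    def scenario_id(self) -> str:
        return f"{self.period}_{self.pathway}_{self.gcm_id}"


@dataclass
class ScenarioSuite:
    """Future environment stacks indexed by (period, pathway, gcm_id)."""

    stacks: dict[tuple[int, str, str], EnvStack] = field(default_factory=dict)
    deltas: dict[tuple[int, str, str], ScenarioDelta] = field(default_factory=dict)

    def add(self, delta: ScenarioDelta, stack: EnvStack) -> None:
        key = (delta.period, delta.pathway, delta.gcm_id)
        self.stacks[key] = stack
        self.deltas[key] = delta

    def keys(self):
        return self.stacks.keys()

    def gcms(self, period: int, pathway: str) -> list[str]:
        return [g for (p, sp, g) in self.stacks if p == period and sp == pathway]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], smoothness: float) -> np.ndarray:
    """Unit-variance smoothed Gaussian random field."""
    noise = rng.standard_normal(shape)
    if smoothness > 0:
        noise = ndimage.gaussian_filter(noise, sigma=smoothness, mode="reflect")
    sd = noise.std()
    if sd > 0:
        noise = noise / sd
    return noise


def make_env_layers(
    seed: int,
    geometry: GridGeometry,
    n_vars: int = 9,
    correlation: np.ndarray | None = None,
    smoothness: float = 3.0,
    gradient_strength: float = 1.0,
    names: Sequence[str] | None = None,
) -> EnvStack:
    """Generate correlated bioclim-like layers on a lon/lat grid.

    Each latent field is a deterministic large-scale gradient plus a
    smoothed Gaussian field (latent 0 carries a north-south
    temperature-like gradient, latent 1 an east-west precipitation-like
    gradient); latents are standardized and mixed through the Cholesky
    factor of ``correlation`` so empirical cross-layer correlations
    track the target. Values are in standardized units (mean ~0, sd ~1).
    """
    if n_vars < 1:
        raise InputError("n_vars must be >= 1")
    if correlation is None:
        correlation = np.eye(n_vars)
    correlation = np.asarray(correlation, float)
    if correlation.shape != (n_vars, n_vars):
        raise InputError("correlation must be n_vars x n_vars")
    if not np.allclose(correlation, correlation.T, atol=1e-10):
        raise InputError("correlation must be symmetric")
    if not np.allclose(np.diag(correlation), 1.0, atol=1e-10):
        raise InputError("correlation must have unit diagonal")
    eigvals = np.linalg.eigvalsh(correlation)
    if eigvals.min() < -1e-8:
        raise InputError("correlation matrix is not positive semi-definite")
    # PSD but possibly singular: use eigen square root
    w = np.clip(eigvals, 0.0, None)
    _, vecs = np.linalg.eigh(correlation)
    L = vecs @ np.diag(np.sqrt(w))

    rng = np.random.default_rng(seed)
    shape = geometry.shape
    lat_grad = np.linspace(1.0, -1.0, geometry.n_rows)[:, None] * np.ones((1, geometry.n_cols))
    lon_grad = np.ones((geometry.n_rows, 1)) * np.linspace(-1.0, 1.0, geometry.n_cols)[None, :]
    gradients = [lat_grad, lon_grad]

    latents = np.empty((n_vars,) + shape)
    for k in range(n_vars):
        f = _smooth_field(rng, shape, smoothness)
        if gradient_strength > 0 and k < len(gradients):
            f = f + gradient_strength * gradients[k]
        f = f - f.mean()
        sd = f.std()
        if sd > 0:
            f = f / sd
        latents[k] = f

    mixed = np.tensordot(L, latents, axes=(1, 0))
    if names is None:
        names = [f"bio{k + 1}" for k in range(n_vars)]
    layers = [Layer(name=str(names[k]), geometry=geometry, values=mixed[k]) for k in range(n_vars)]
    return EnvStack(layers)


def true_suitability_layer(stack: EnvStack, niche: NicheSpec) -> Layer:
    """Per-cell true suitability of ``niche`` over the stack (masked cells 0)."""
    rows, cols, table = stack.valid_cell_table()
    s = niche.suitability(table)
    values = np.zeros(stack.geometry.shape)
    values[rows, cols] = s
    return Layer(
        name=f"true_suitability_{niche.class_label}",
        geometry=stack.geometry,
        values=values,
        nodata_mask=~stack.valid_mask,
    )


def sample_occurrences(seed: int, stack: EnvStack, niche: NicheSpec, n: int) -> OccurrenceSet:
    """Draw ``n`` presences with cell probability proportional to true suitability.

    Cells are drawn with replacement; each occurrence is then placed
    uniformly within its cell.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rows, cols, table = stack.valid_cell_table()
    if len(rows) == 0:
        raise InputError("stack has no valid cells")
    s = niche.suitability(table)
    total = s.sum()
    if total <= 0:
        raise InputError("true suitability is zero everywhere on the valid mask")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, p=s / total)
    g = stack.geometry
    jitter_x = rng.random(n)
    jitter_y = rng.random(n)
    lon = g.x_origin + (cols[idx] + jitter_x) * g.cell_size
    lat = g.y_origin - (rows[idx] + jitter_y) * g.cell_size
    label = niche.class_label
    ids = np.array([f"{label}_{i:05d}" for i in range(n)], dtype=object)
    return OccurrenceSet(
        ids, lon, lat,
        np.array([label] * n, dtype=object),
        np.array(["synthetic"] * n, dtype=object),
    )


def make_polygon_proxies(
    seed: int,
    polygons: Sequence[Sequence[tuple[float, float]]],
    n_per_polygon: int,
    class_label: str = "cultivated",
) -> OccurrenceSet:
    """Uniform random proxy points strictly inside each polygon ring.

    Rejection sampling in each ring's bounding box; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    ids, lons, lats, labels, sources = [], [], [], [], []
    for p_idx, ring in enumerate(polygons):
        poly = Polygon(ring)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError(f"polygon {p_idx} is degenerate")
        minx, miny, maxx, maxy = poly.bounds
        count = 0
        attempts = 0
        max_attempts = max(10000, 1000 * n_per_polygon)
        while count < n_per_polygon:
            if attempts > max_attempts:
                raise GeometryError(f"polygon {p_idx}: rejection sampling failed to converge")
            x = minx + rng.random() * (maxx - minx)
            y = miny + rng.random() * (maxy - miny)
            attempts += 1
            if poly.contains(Point(x, y)):
                ids.append(f"proxy_{p_idx}_{count:05d}")
                lons.append(x)
                lats.append(y)
                labels.append(class_label)
                sources.append(f"polygon_{p_idx}")
                count += 1
    if not ids:
        return OccurrenceSet.empty()
    return OccurrenceSet(
        np.array(ids, dtype=object), np.array(lons), np.array(lats),
        np.array(labels, dtype=object), np.array(sources, dtype=object),
    )


def make_future_stack(
    stack: EnvStack,
    delta: ScenarioDelta,
    var_kinds: Mapping[str, str],
    seed: int,
    noise_smoothness: float = 3.0,
) -> EnvStack:
    """Warmed / precipitation-scaled / perturbed copy of a present stack.

    Temperature layers get ``+temp_shift``; precipitation layers get
    ``*precip_scale``; every layer gets smooth noise of sd ``noise_sd``.
    Geometry and masks are unchanged.
    """
    missing = [n for n in stack.names if n not in var_kinds]
    if missing:
        raise InputError(f"var_kinds missing entries for {missing}")
    rng = np.random.default_rng(seed)
    out_layers = []
    for ly in stack.layers:
        kind = var_kinds[ly.name]
        if kind not in ("temperature", "precipitation", "other"):
            raise InputError(f"unknown variable kind {kind!r} for layer {ly.name!r}")
        vals = ly.values.copy()
        if kind == "temperature":
            vals = vals + delta.temp_shift
        elif kind == "precipitation":
            vals = vals * delta.precip_scale
        if delta.noise_sd > 0:
            vals = vals + delta.noise_sd * _smooth_field(rng, ly.geometry.shape, noise_smoothness)
        vals = np.where(ly.nodata_mask, 0.0, vals)
        out_layers.append(Layer(ly.name, ly.geometry, vals, ly.nodata_mask.copy()))
    return EnvStack(out_layers)


#: per-period baseline warming (degrees, in standardized units) and per-pathway multiplier
_PERIOD_WARMING = {2050: 0.5, 2070: 1.0, 2090: 1.5}
_PATHWAY_FACTOR = {"ssp245": 1.0, "ssp585": 2.0}


def make_scenario_deltas(
    seed: int,
    n_gcms: int = N_GCMS_DEFAULT,
    periods: Sequence[int] = PERIODS,
    pathways: Sequence[str] = PATHWAYS,
    gcm_spread: float = 0.15,
    precip_drift: float = 0.05,
    noise_sd: float = 0.05,
) -> list[ScenarioDelta]:
    """Pseudo-GCM deltas: warming grows with period, doubles under ssp585.

    Per-GCM jitter (multiplicative on the warming, additive on the
    precipitation scale) is deterministic per seed and consistent across
    periods for a given GCM, so ensembles behave like distinct models.
    """
    rng = np.random.default_rng(seed)
    warm_jitter = 1.0 + gcm_spread * rng.standard_normal(n_gcms)
    precip_jitter = precip_drift * rng.standard_normal(n_gcms)
    deltas = []
    for period in periods:
        for pathway in pathways:
            base = _PERIOD_WARMING[period] * _PATHWAY_FACTOR[pathway]
            for g in range(n_gcms):
                deltas.append(ScenarioDelta(
                    gcm_id=f"gcm{g + 1:02d}",
                    period=int(period),
                    pathway=str(pathway),
                    temp_shift=base * max(0.1, warm_jitter[g]),
                    precip_scale=max(0.2, 1.0 - 0.1 * base * _PATHWAY_FACTOR[pathway] + precip_jitter[g]),
                    noise_sd=noise_sd,
                ))
    return deltas


def default_var_kinds(names: Sequence[str]) -> dict[str, str]:
    """Heuristic kinds: first half temperature-like, second half precipitation-like."""
    names = list(names)
    half = max(1, len(names) // 2)
    kinds = {}
    for i, n in enumerate(names):
        kinds[n] = "temperature" if i < half else "precipitation"
    return kinds


def make_scenario_suite(
    seed: int,
    stack: EnvStack,
    var_kinds: Mapping[str, str] | None = None,
    n_gcms: int = N_GCMS_DEFAULT,
    periods: Sequence[int] = PERIODS,
    pathways: Sequence[str] = PATHWAYS,
    noise_sd: float = 0.05,
) -> ScenarioSuite:
    """Full future suite: ``n_gcms`` pseudo-GCMs per period x pathway."""
    if var_kinds is None:
        var_kinds = default_var_kinds(stack.names)
    deltas = make_scenario_deltas(seed, n_gcms=n_gcms, periods=periods, pathways=pathways, noise_sd=noise_sd)
    suite = ScenarioSuite()
    for i, delta in enumerate(deltas):
        suite.add(delta, make_future_stack(stack, delta, var_kinds, seed=seed * 100003 + i))
    return suite


def default_niches(n_vars: int = 2) -> dict[str, NicheSpec]:
    """The nested/shifted study design used throughout the tests.

    landrace shares the wild optimum with half the breadth (nested);
    semiwild sits between; commercial is shifted toward the dry /
    high-seasonality corner of environment space.
    """
    def pad(vec: Sequence[float], fill: float) -> tuple[float, ...]:
        out = list(vec) + [fill] * (n_vars - len(vec))
        return tuple(out[:max(n_vars, len(vec))][:n_vars]) if n_vars >= len(vec) else tuple(vec[:n_vars])

    wild_opt, wild_br = (0.0, 0.0), (1.4, 1.4)
    specs = {
        "wild": NicheSpec("wild", pad(wild_opt, 0.0), pad(wild_br, 3.0)),
        "semiwild": NicheSpec("semiwild", pad((0.2, 0.2), 0.0), pad((1.1, 1.1), 3.0)),
        "landrace": NicheSpec("landrace", pad(wild_opt, 0.0), pad((0.7, 0.7), 3.0)),
        "commercial": NicheSpec("commercial", pad((1.6, -1.6), 0.0), pad((0.9, 0.9), 3.0)),
    }
    return specs
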