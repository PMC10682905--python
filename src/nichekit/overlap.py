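"""Niche similarity statistics and their randomization tests.

Schoener's D = 1 - 0.5 * sum|p - q| and Warren's I = 1 - 0.5 *
sum (sqrt p - sqrt q)^2 on cell-normalized suitability surfaces, plus
equivalency (label-shuffling) and background (random-cell replacement)
randomization tests, and the environment-space occupancy-grid variant.
Empirical p-values carry the +1 correction and are never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.stats import spearmanr

from nichekit.errors import GeometryError, InputError
from nichekit.grids import EnvStack
from nichekit.maxent import ENMConfig, MaxentModel, SuitabilityMap, build_features, fit_maxent, predict_logistic
from nichekit.occurrences import OccurrenceSet, extract_env


@dataclass
class OverlapStats:
    schoener_d: float
    warren_i: float
    spearman_rho: float
    n_cells: int


@dataclass
class RandomizationResult:
    observed: OverlapStats
    null_d: np.ndarray
    null_i: np.ndarray
    p_low_d: float    # P(null <= observed)
    p_high_d: float   # P(null >= observed)
    p_low_i: float
    p_high_i: float
    n_reps: int


def _normalize(v: np.ndarray) -> np.ndarray:
    total = v.sum()
    if total <= 0:
        raise InputError("cannot normalize an all-zero suitability surface")
    return v / total


def overlap_vectors(a: np.ndarray, b: np.ndarray) -> OverlapStats:
    """D, I and Spearman rho for two suitability vectors on shared cells."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("score vectors must be 1-D and equally long")
    if len(a) < 2:
        raise InputError("need >= 2 shared cells")
    p = _normalize(a)
    q = _normalize(b)
    d = 1.0 - 0.5 * np.abs(p - q).sum()
    i = 1.0 - 0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum()
    if np.all(a == a[0]) or np.all(b == b[0]):
        rho = 0.0  # rank correlation undefined for a constant surface
    else:
        rho = float(spearmanr(a, b).statistic)
    return OverlapStats(float(d), float(i), rho, len(a))


def overlap_stats(map_a: SuitabilityMap, map_b: SuitabilityMap) -> OverlapStats:
    """Overlap statistics of two co-registered suitability maps."""
    la, lb = map_a.layer, map_b.layer
    if not la.geometry.co_registered(lb.geometry):
        raise GeometryError("suitability maps are not co-registered")
    shared = la.valid_mask & lb.valid_mask
    if np.count_nonzero(shared) < 2:
        raise InputError("fewer than 2 shared valid cells")
    return overlap_vectors(la.values[shared], lb.values[shared])


DEFAULT_RANDOMIZATION_CONFIG = ENMConfig(
    classes=("L", "Q"), reg_multiplier=1.0, max_iter=200, tol=1e-6,
    test_fraction=0.0, min_presences=5,
)


def _fit_class_map(
    env: np.ndarray,
    background_env: np.ndarray,
    stack: EnvStack,
    config: ENMConfig,
    model_id: str,
    surface: str = "raw",
) -> SuitabilityMap:
    """Fit a reduced model and project it over the stack.

    ``surface='raw'`` projects the Gibbs density (the classical input to
    D/I randomization tests, with far more contrast than the logistic
    transform); ``'logistic'`` gives the bounded [0,1] output.
    """
    fs = build_features(
        background_env, classes=config.classes,
        hinge_knots_per_var=config.hinge_knots_per_var,
        var_names=stack.names,
        clamp_env=np.vstack([background_env, env]),
    )
    model = fit_maxent(env, background_env, fs, reg_multiplier=config.reg_multiplier,
                       max_iter=config.max_iter, tol=config.tol,
                       min_presences=config.min_presences)
    if surface == "logistic":
        return predict_logistic(model, stack, clamp=True, model_id=model_id)
    rows, cols = np.nonzero(stack.valid_mask)
    table = np.column_stack([stack[n].values[rows, cols] for n in stack.names])
    scores, _ = model.raw_scores(table, clamp=True)
    values = np.zeros(stack.geometry.shape)
    values[rows, cols] = scores
    from nichekit.grids import Layer
    layer = Layer(f"raw_{model_id}", stack.geometry, values, ~stack.valid_mask)
    return SuitabilityMap(layer=layer, model_id=model_id,
                          clamped_mask=np.zeros(stack.geometry.shape, bool))


def _presence_env(points: OccurrenceSet, stack: EnvStack) -> np.ndarray:
    if points.env is None or points.env_names != stack.names:
        points = extract_env(points, stack)
    return points.valid_env()


def _pvals(null: np.ndarray, observed: float) -> tuple[float, float]:
    n = len(null)
    p_low = (np.count_nonzero(null <= observed) + 1) / (n + 1)
    p_high = (np.count_nonzero(null >= observed) + 1) / (n + 1)
    return float(p_low), float(p_high)


def equivalency_test(
    points_a: OccurrenceSet,
    points_b: OccurrenceSet,
    stack: EnvStack,
    enm_config: ENMConfig = DEFAULT_RANDOMIZATION_CONFIG,
    n_reps: int = 99,
    seed: int = 0,
    n_background: int = 2000,
) -> RandomizationResult:
    """Niche equivalency by pooled label shuffling.

    Null: pool the two presence sets, shuffle class assignments
    preserving sample sizes, refit both models, recompute D/I.
    Equivalency is rejected when the observed statistic falls below the
    null distribution (small ``p_low``).
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    env_a = _presence_env(points_a, stack)
    env_b = _presence_env(points_b, stack)
    from nichekit.maxent import sample_background
    bg = sample_background(stack, n=n_background, seed=int(rng.integers(2**31)))

    map_a = _fit_class_map(env_a, bg, stack, enm_config, "obs_a")
    map_b = _fit_class_map(env_b, bg, stack, enm_config, "obs_b")
    observed = overlap_stats(map_a, map_b)

    pooled = np.vstack([env_a, env_b])
    na = env_a.shape[0]
    null_d = np.empty(n_reps)
    null_i = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(pooled.shape[0])
        pa, pb = pooled[perm[:na]], pooled[perm[na:]]
        ma = _fit_class_map(pa, bg, stack, enm_config, f"null_a_{r}")
        mb = _fit_class_map(pb, bg, stack, enm_config, f"null_b_{r}")
        st = overlap_stats(ma, mb)
        null_d[r] = st.schoener_d
        null_i[r] = st.warren_i
    pld, phd = _pvals(null_d, observed.schoener_d)
    pli, phi = _pvals(null_i, observed.warren_i)
    return RandomizationResult(observed, null_d, null_i, pld, phd, pli, phi, n_reps)


def background_test(
    points_a: OccurrenceSet,
    points_b: OccurrenceSet,
    stack: EnvStack,
    background_region_b: np.ndarray | None = None,
    enm_config: ENMConfig = DEFAULT_RANDOMIZATION_CONFIG,
    n_reps: int = 49,
    seed: int = 0,
    n_background: int = 2000,
) -> RandomizationResult:
    """Background similarity test (asymmetric; run both directions).

    Null: keep class a's model fixed, replace class b's presences with
    random cells drawn from b's background region (boolean cell mask,
    default the stack valid mask), refit b, recompute D/I. ``p_high``
    small means the observed similarity exceeds the null ("more similar
    than random"); ``p_low`` small means less similar than random.

    The test is asymmetric: to probe nesting of a narrow niche inside a
    broad one, fix the narrow class as ``points_a`` and randomize the
    broad class (the narrow reference surface departs strongly from the
    flat null models, so genuine similarity stands out).
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    env_a = _presence_env(points_a, stack)
    env_b = _presence_env(points_b, stack)
    nb = env_b.shape[0]
    if background_region_b is None:
        background_region_b = stack.valid_mask
    region = np.asarray(background_region_b, bool) & stack.valid_mask
    rows, cols = np.nonzero(region)
    if len(rows) < nb:
        raise InputError(f"background region ({len(rows)} cells) smaller than n_b ({nb})")
    region_env = stack.values_table(rows, cols)

    from nichekit.maxent import sample_background
    bg = sample_background(stack, n=n_background, seed=int(rng.integers(2**31)))

    map_a = _fit_class_map(env_a, bg, stack, enm_config, "obs_a")
    map_b = _fit_class_map(env_b, bg, stack, enm_config, "obs_b")
    observed = overlap_stats(map_a, map_b)

    null_d = np.empty(n_reps)
    null_i = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.choice(len(rows), size=nb, replace=False)
        mb = _fit_class_map(region_env[idx], bg, stack, enm_config, f"null_b_{r}")
        st = overlap_stats(map_a, mb)
        null_d[r] = st.schoener_d
        null_i[r] = st.warren_i
    pld, phd = _pvals(null_d, observed.schoener_d)
    pli, phi = _pvals(null_i, observed.warren_i)
    return RandomizationResult(observed, null_d, null_i, pld, phd, pli, phi, n_reps)


def envspace_density_overlap(
    points_a: OccurrenceSet | np.ndarray,
    points_b: OccurrenceSet | np.ndarray,
    background_env: np.ndarray,
    grid_res: int = 100,
    bandwidth: float | None = None,
    stack: EnvStack | None = None,
) -> OverlapStats:
    """Occupancy-grid niche overlap in PC1-PC2 environment space.

    PCA is fit on the background environment; occurrence and background
    densities are Gaussian-kernel-smoothed histograms on a
    ``grid_res x grid_res`` grid over the background PC range; occupancy
    = occurrence density / background density (0 where background
    density is 0), normalized to sum 1; D and I are computed between the
    two occupancy grids. ``bandwidth`` is in PC units (default: 2 grid
    cells).
    """
    from nichekit.envspace import run_pca

    def _env(obj) -> np.ndarray:
        if isinstance(obj, OccurrenceSet):
            if obj.env is None:
                if stack is None:
                    raise InputError("points lack extracted environment and no stack given")
                obj = extract_env(obj, stack)
            return obj.valid_env()
        return np.asarray(obj, float)

    env_a = _env(points_a)
    env_b = _env(points_b)
    if env_a.shape[0] < 5 or env_b.shape[0] < 5:
        raise InputError("need >= 5 points per class")
    bg = np.asarray(background_env, float)
    pca = run_pca(bg)
    if pca.explained_var_fraction[1] <= 1e-12:
        raise InputError("degenerate PCA: second component explains nothing")
    bg_pc = pca.scores[:, :2]
    a_pc = pca.transform(env_a)[:, :2]
    b_pc = pca.transform(env_b)[:, :2]

    lo = bg_pc.min(axis=0)
    hi = bg_pc.max(axis=0)
    span = hi - lo
    lo = lo - 0.05 * span
    hi = hi + 0.05 * span
    edges = [np.linspace(lo[d], hi[d], grid_res + 1) for d in range(2)]
    cell = (hi - lo) / grid_res
    if bandwidth is None:
        bandwidth = 0.05 * float(span.mean())  # fixed in PC units, resolution-stable
    sigma_cells = float(bandwidth / cell.mean())

    def _density(pts: np.ndarray) -> np.ndarray:
        h, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=edges)
        return ndimage.gaussian_filter(h, sigma=sigma_cells, mode="constant")

    dens_bg = _density(bg_pc)

    def _occupancy(pts: np.ndarray) -> np.ndarray:
        dens = _density(pts)
        occ = np.where(dens_bg > 0, dens / np.where(dens_bg > 0, dens_bg, 1.0), 0.0)
        total = occ.sum()
        if total <= 0:
            raise InputError("empty occupancy grid")
        return occ / total

    oa = _occupancy(a_pc).ravel()
    ob = _occupancy(b_pc).ravel()
    d = 1.0 - 0.5 * np.abs(oa - ob).sum()
    i = 1.0 - 0.5 * ((np.sqrt(oa) - np.sqrt(ob)) ** 2).sum()
    rho = float(spearmanr(oa, ob).statistic) if (oa.std() > 0 and ob.std() > 0) else 0.0
    return OverlapStats(float(d), float(i), rho, oa.size)
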