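"""Presence-background maximum-entropy suitability model.

Fits a Gibbs distribution q(z) = exp(lambda . f(z)) / Z over background
cells by maximizing the L1-penalized log-likelihood

    l(lambda) = mean_i lambda . f(x_i) - log Z_lambda - sum_j beta_j |lambda_j|

with proximal gradient ascent (backtracking line search, monotone by
construction). Feature classes: linear, quadratic, product, hinge
(forward/reverse pairs at background quantile knots), all min-max scaled
to [0, 1] on the background. The logistic output uses the fitted
distribution's entropy H: logistic = r e^H / (1 + r e^H) with raw
r(z) = exp(lambda . f(z)) / Z_train.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata

from nichekit.errors import InputError
from nichekit.grids import EnvStack, Layer

log = logging.getLogger(__name__)

FEATURE_CLASSES = ("L", "Q", "H", "P")

#: L1 base-penalty interpolation tables, keyed by feature class:
#: (presence-count grid, beta0 values); linear interpolation, clamped at
#: the ends. Implementation constants of this package.
BETA0_TABLES = {
    "L": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "Q": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "P": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "H": ([0, 1], [0.5, 0.5]),
}

DEFAULT_HINGE_KNOTS = 30
DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-6
MIN_PRESENCES_DEFAULT = 10


@dataclass(frozen=True)
class Feature:
    """One basis function: kind in {L,Q,P,H}, variable index/indices,
    hinge knot and direction (+1 forward, -1 reverse)."""

    kind: str
    vars: tuple[int, ...]
    knot: float = 0.0
    direction: int = 0

    def describe(self, names: Sequence[str]) -> str:
        vs = "*".join(names[v] for v in self.vars)
        if self.kind == "H":
            d = "fwd" if self.direction > 0 else "rev"
            return f"H({vs},{float(self.knot)!r},{d})"
        return f"{self.kind}({vs})"


@dataclass
class FeatureSet:
    """Feature definitions plus the background-derived normalizers."""

    var_names: list[str]
    features: list[Feature]
    var_min: np.ndarray          # per-variable background min (hinge denominators)
    var_max: np.ndarray
    feat_min: np.ndarray         # per-feature raw min over background
    feat_max: np.ndarray
    clamp_min: np.ndarray        # per-variable training range for clamping
    clamp_max: np.ndarray
    classes: tuple[str, ...] = ("L", "Q", "H", "P")

    def __len__(self) -> int:
        return len(self.features)

    def evaluate_raw(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        n = X.shape[0]
        out = np.empty((n, len(self.features)))
        # hinges grouped by (variable, direction) for one broadcast op each
        hinge_groups: dict[tuple[int, int], tuple[list[int], list[float]]] = {}
        for j, ft in enumerate(self.features):
            if ft.kind == "L":
                out[:, j] = X[:, ft.vars[0]]
            elif ft.kind == "Q":
                out[:, j] = X[:, ft.vars[0]] ** 2
            elif ft.kind == "P":
                out[:, j] = X[:, ft.vars[0]] * X[:, ft.vars[1]]
            else:
                cols, knots = hinge_groups.setdefault((ft.vars[0], ft.direction), ([], []))
                cols.append(j)
                knots.append(ft.knot)
        for (v, direction), (cols, knots) in hinge_groups.items():
            k = np.asarray(knots)
            x = X[:, v][:, None]
            if direction > 0:
                vals = np.maximum(0.0, (x - k) / (self.var_max[v] - k))
            else:
                vals = np.maximum(0.0, (k - x) / (k - self.var_min[v]))
            out[:, cols] = vals
        return out

    def evaluate(self, X: np.ndarray, clamp: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Scaled features in [0,1] on training data; returns (F, clamped_rows)."""
        X = np.asarray(X, float)
        clamped = np.zeros(X.shape[0], dtype=bool)
        if clamp:
            Xc = np.clip(X, self.clamp_min, self.clamp_max)
            clamped = np.any(Xc != X, axis=1)
            X = Xc
        F = self.evaluate_raw(X)
        span = self.feat_max - self.feat_min
        span = np.where(span > 0, span, 1.0)
        return (F - self.feat_min) / span, clamped


def build_features(
    background_env: np.ndarray,
    classes: Sequence[str] = ("L", "Q", "H", "P"),
    hinge_knots_per_var: int = DEFAULT_HINGE_KNOTS,
    var_names: Sequence[str] | None = None,
    clamp_env: np.ndarray | None = None,
) -> FeatureSet:
    """Construct the feature basis from background environment values.

    Hinge knots sit at evenly spaced interior quantiles of each
    variable's background values; each knot yields a forward and a
    reverse hinge. Quadratic/hinge features of constant variables are
    dropped with a warning. ``clamp_env`` (default: the background)
    supplies the per-variable training ranges used for clamping.
    """
    X = np.asarray(background_env, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("need a 2-D background table with >= 2 rows")
    bad = [c for c in classes if c not in FEATURE_CLASSES]
    if bad:
        raise InputError(f"unknown feature classes {bad}")
    p = X.shape[1]
    if var_names is None:
        var_names = [f"v{j}" for j in range(p)]
    var_min = X.min(axis=0)
    var_max = X.max(axis=0)
    constant = var_max == var_min

    feats: list[Feature] = []
    if "L" in classes:
        feats.extend(Feature("L", (j,)) for j in range(p))
    if "Q" in classes:
        for j in range(p):
            if constant[j]:
                log.warning("build_features: variable %r constant; Q feature dropped", var_names[j])
                continue
            feats.append(Feature("Q", (j,)))
    if "P" in classes:
        for a in range(p):
            for b in range(a + 1, p):
                feats.append(Feature("P", (a, b)))
    if "H" in classes:
        K = hinge_knots_per_var
        qs = np.arange(1, K + 1) / (K + 1)
        for j in range(p):
            if constant[j]:
                log.warning("build_features: variable %r constant; hinge features dropped", var_names[j])
                continue
            knots = np.quantile(X[:, j], qs)
            for k in knots:
                if var_max[j] - k > 0:
                    feats.append(Feature("H", (j,), knot=float(k), direction=+1))
                if k - var_min[j] > 0:
                    feats.append(Feature("H", (j,), knot=float(k), direction=-1))

    if clamp_env is None:
        clamp_min, clamp_max = var_min.copy(), var_max.copy()
    else:
        clamp_env = np.asarray(clamp_env, float)
        clamp_min = clamp_env.min(axis=0)
        clamp_max = clamp_env.max(axis=0)

    fs = FeatureSet(
        var_names=list(var_names), features=feats,
        var_min=var_min, var_max=var_max,
        feat_min=np.zeros(len(feats)), feat_max=np.ones(len(feats)),
        clamp_min=clamp_min, clamp_max=clamp_max,
        classes=tuple(classes),
    )
    raw = fs.evaluate_raw(X)
    fs.feat_min = raw.min(axis=0)
    fs.feat_max = raw.max(axis=0)
    return fs


@dataclass
class MaxentModel:
    features: FeatureSet
    lambdas: np.ndarray
    reg_multiplier: float
    betas: np.ndarray
    linear_predictor_offset: float   # -log Z over the training partition set
    entropy_H: float
    n_presence: int
    n_background: int
    n_iter: int
    converged: bool
    objective_path: np.ndarray = field(default_factory=lambda: np.array([]))

    def raw_scores(self, env: np.ndarray, clamp: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Raw Gibbs scores r(z) = exp(lambda.f(z)) / Z_train; (scores, clamped)."""
        F, clamped = self.features.evaluate(env, clamp=clamp)
        return np.exp(F @ self.lambdas + self.linear_predictor_offset), clamped

    def logistic_scores(self, env: np.ndarray, clamp: bool = False) -> tuple[np.ndarray, np.ndarray]:
        r, clamped = self.raw_scores(env, clamp=clamp)
        re_h = r * np.exp(self.entropy_H)
        return re_h / (1.0 + re_h), clamped


def _beta_vector(features: FeatureSet, m: int, reg_multiplier: float, feat_sd: np.ndarray) -> np.ndarray:
    betas = np.empty(len(features))
    for j, ft in enumerate(features.features):
        grid, vals = BETA0_TABLES[ft.kind]
        beta0 = float(np.interp(m, grid, vals))
        betas[j] = reg_multiplier * feat_sd[j] / np.sqrt(m) * beta0
    return betas


def fit_maxent(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    features: FeatureSet,
    reg_multiplier: float = 1.0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    min_presences: int = MIN_PRESENCES_DEFAULT,
    include_presences_in_background: bool = True,
) -> MaxentModel:
    """Fit the penalized maxent model by monotone proximal gradient ascent.

    The partition function is evaluated over the background cells plus
    (by default) the presence rows, the standard presence-background
    convention. Per-feature penalties are
    ``beta_j = reg_multiplier * sd_j / sqrt(m) * beta0(class_j)``.
    """
    P = np.asarray(presence_env, float)
    B = np.asarray(background_env, float)
    if P.ndim != 2 or P.shape[0] == 0:
        raise InputError("no presence records")
    if P.shape[0] < min_presences:
        raise InputError(f"need >= {min_presences} presences, got {P.shape[0]}")
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(B))):
        raise InputError("non-finite environment values")

    Fp, _ = features.evaluate(P)
    Fb, _ = features.evaluate(B)
    if include_presences_in_background:
        Fz = np.vstack([Fb, Fp])
    else:
        Fz = Fb
    m = P.shape[0]
    N = Fz.shape[0]
    feat_sd = Fz.std(axis=0)
    betas = _beta_vector(features, m, reg_multiplier, feat_sd)
    f_bar = Fp.mean(axis=0)

    lam = np.zeros(len(features))
    eta = Fz @ lam  # linear predictor over partition set

    def objective(lam_v: np.ndarray, eta_v: np.ndarray) -> float:
        return float(lam_v @ f_bar - logsumexp(eta_v) - betas @ np.abs(lam_v))

    obj = objective(lam, eta)
    path = [obj]
    step = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_z = logsumexp(eta)
        q = np.exp(eta - log_z)
        grad = f_bar - q @ Fz
        # proximal step with backtracking on the true objective (monotone)
        improved = False
        for _ in range(60):
            cand = np.sign(lam + step * grad) * np.maximum(np.abs(lam + step * grad) - step * betas, 0.0)
            eta_c = Fz @ cand
            obj_c = objective(cand, eta_c)
            if obj_c >= obj - 1e-15:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        delta = obj_c - obj
        lam, eta, obj = cand, eta_c, obj_c
        path.append(obj)
        step = min(step * 1.3, 1e6)  # gentle step recovery
        if delta < tol:
            converged = True
            break

    log_z = logsumexp(eta)
    q = np.exp(eta - log_z)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(q > 0, q * np.log(q), 0.0)
    entropy = float(-plogp.sum())
    return MaxentModel(
        features=features,
        lambdas=lam,
        reg_multiplier=reg_multiplier,
        betas=betas,
        linear_predictor_offset=float(-log_z),
        entropy_H=entropy,
        n_presence=m,
        n_background=N,
        n_iter=it,
        converged=converged,
        objective_path=np.array(path),
    )


@dataclass
class SuitabilityMap:
    """Continuous [0,1] logistic suitability over a grid."""

    layer: Layer
    model_id: str
    clamped_mask: np.ndarray


def predict_logistic(model: MaxentModel, stack: EnvStack, clamp: bool = True, model_id: str = "maxent") -> SuitabilityMap:
    """Project the model over a stack's valid cells as logistic output."""
    missing = [n for n in model.features.var_names if n not in stack.names]
    if missing:
        raise InputError(f"stack missing model variables: {missing}")
    rows, cols = np.nonzero(stack.valid_mask)
    table = np.column_stack([stack[n].values[rows, cols] for n in model.features.var_names])
    scores, clamped = model.logistic_scores(table, clamp=clamp)
    values = np.zeros(stack.geometry.shape)
    values[rows, cols] = scores
    cmask = np.zeros(stack.geometry.shape, dtype=bool)
    cmask[rows, cols] = clamped
    layer = Layer(name=f"suitability_{model_id}", geometry=stack.geometry,
                  values=values, nodata_mask=~stack.valid_mask)
    return SuitabilityMap(layer=layer, model_id=model_id, clamped_mask=cmask)


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    pres = np.asarray(presence_scores, float)
    bg = np.asarray(background_scores, float)
    if len(pres) == 0 or len(bg) == 0:
        raise InputError("both score vectors must be non-empty")
    ranks = rankdata(np.concatenate([pres, bg]))
    r_pres = ranks[: len(pres)].sum()
    u = r_pres - len(pres) * (len(pres) + 1) / 2.0
    return float(u / (len(pres) * len(bg)))


@dataclass
class TSSResult:
    tss: float
    sensitivity: float
    specificity: float
    threshold: float
    max_tss: float
    max_tss_threshold: float


def tss(presence_scores: np.ndarray, background_scores: np.ndarray, threshold: float) -> TSSResult:
    """True skill statistic at a threshold, plus the max over thresholds.

    sensitivity = fraction of presences >= threshold; specificity =
    fraction of background < threshold.
    """
    if not (0 <= threshold <= 1):
        raise InputError("threshold must be in [0, 1]")
    pres = np.asarray(presence_scores, float)
    bg = np.asarray(background_scores, float)

    def _tss(t: float) -> tuple[float, float, float]:
        sens = float(np.mean(pres >= t))
        spec = float(np.mean(bg < t))
        return sens + spec - 1.0, sens, spec

    t0, sens, spec = _tss(threshold)
    cand = np.unique(np.concatenate([pres, bg, [0.0, 1.0]]))
    best_t, best = 0.0, -np.inf
    for t in cand:
        v, _, _ = _tss(float(t))
        if v > best:
            best, best_t = v, float(t)
    return TSSResult(t0, sens, spec, threshold, best, best_t)


def permutation_importance(
    model: MaxentModel,
    presence_env: np.ndarray,
    background_env: np.ndarray,
    seed: int = 0,
    n_perm: int = 5,
) -> dict[str, float]:
    """Per-variable importance as percent AUC degradation under permutation.

    Each variable's values are shuffled jointly across the pooled
    presence+background rows; raw importance is
    ``max(0, AUC_orig - mean permuted AUC)``, normalized to sum to 100.
    """
    P = np.asarray(presence_env, float)
    B = np.asarray(background_env, float)
    names = model.features.var_names
    m = P.shape[0]

    def _auc(Pv: np.ndarray, Bv: np.ndarray) -> float:
        sp, _ = model.raw_scores(Pv)
        sb, _ = model.raw_scores(Bv)
        return auc(sp, sb)

    auc_orig = _auc(P, B)
    rng = np.random.default_rng(seed)
    raw_imp = np.zeros(len(names))
    pooled = np.vstack([P, B])
    for v in range(len(names)):
        drops = []
        for _ in range(n_perm):
            shuffled = pooled.copy()
            shuffled[:, v] = rng.permutation(shuffled[:, v])
            drops.append(auc_orig - _auc(shuffled[:m], shuffled[m:]))
        raw_imp[v] = max(0.0, float(np.mean(drops)))
    total = raw_imp.sum()
    if total == 0:
        log.warning("permutation_importance: all importances zero; reporting uniform percentages")
        pct = np.full(len(names), 100.0 / len(names))
    else:
        pct = 100.0 * raw_imp / total
    return dict(zip(names, pct.tolist()))


@dataclass
class EvalReport:
    auc_train: float
    auc_test: float
    tss: TSSResult | None = None
    permutation_importance: dict[str, float] | None = None
    jackknife: dict[str, tuple[float, float]] | None = None


@dataclass
class ENMConfig:
    """Model-fitting configuration surface."""

    classes: tuple[str, ...] = ("L", "Q", "H", "P")
    hinge_knots_per_var: int = DEFAULT_HINGE_KNOTS
    reg_multiplier: float = 1.0
    max_iter: int = DEFAULT_MAX_ITER
    tol: float = DEFAULT_TOL
    test_fraction: float = 0.3
    min_presences: int = MIN_PRESENCES_DEFAULT


def _fit_eval(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    config: ENMConfig,
    seed: int,
    var_names: Sequence[str] | None = None,
) -> tuple[MaxentModel, EvalReport]:
    """One seeded 70/30 split, fit on train, evaluate on both partitions."""
    rng = np.random.default_rng(seed)
    m = presence_env.shape[0]
    n_test = int(round(m * config.test_fraction))
    perm = rng.permutation(m)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    fs = build_features(
        background_env, classes=config.classes,
        hinge_knots_per_var=config.hinge_knots_per_var, var_names=var_names,
        clamp_env=np.vstack([background_env, presence_env]),
    )
    model = fit_maxent(
        presence_env[train_idx], background_env, fs,
        reg_multiplier=config.reg_multiplier, max_iter=config.max_iter,
        tol=config.tol, min_presences=config.min_presences,
    )
    s_bg, _ = model.raw_scores(background_env)
    s_train, _ = model.raw_scores(presence_env[train_idx])
    auc_train = auc(s_train, s_bg)
    if n_test > 0:
        s_test, _ = model.raw_scores(presence_env[test_idx])
        auc_test = auc(s_test, s_bg)
    else:
        auc_test = float("nan")
    return model, EvalReport(auc_train=auc_train, auc_test=auc_test)


def replicate_cv(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    config: ENMConfig,
    n_replicates: int = 10,
    seed: int = 0,
    stack: EnvStack | None = None,
    var_names: Sequence[str] | None = None,
    model_id: str = "maxent",
) -> tuple[list[tuple[MaxentModel, EvalReport]], SuitabilityMap | None, SuitabilityMap | None]:
    """Replicated 70/30 hold-out fits plus per-cell median and SD maps.

    Returns (replicates, median_map, sd_map); maps are None when no
    stack is supplied.
    """
    replicates = []
    maps = []
    for r in range(n_replicates):
        model, report = _fit_eval(presence_env, background_env, config, seed=seed * 10007 + r, var_names=var_names)
        replicates.append((model, report))
        if stack is not None:
            maps.append(predict_logistic(model, stack, clamp=True, model_id=f"{model_id}_rep{r}"))
    median_map = sd_map = None
    if stack is not None:
        arr = np.stack([mp.layer.values for mp in maps])
        med = np.median(arr, axis=0)
        sd = arr.std(axis=0)
        mask = maps[0].layer.nodata_mask
        clamped = np.any(np.stack([mp.clamped_mask for mp in maps]), axis=0)
        median_map = SuitabilityMap(
            Layer(f"suitability_median_{model_id}", stack.geometry, np.where(mask, 0.0, med), mask),
            model_id=f"{model_id}_median", clamped_mask=clamped)
        sd_map = SuitabilityMap(
            Layer(f"suitability_sd_{model_id}", stack.geometry, np.where(mask, 0.0, sd), mask),
            model_id=f"{model_id}_sd", clamped_mask=clamped)
    return replicates, median_map, sd_map


def jackknife_contribution(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    config: ENMConfig,
    var_names: Sequence[str] | None = None,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Per-variable (only_gain, without_gain) as test AUC of refits.

    ``only``: model trained on that variable alone; ``without``: model
    trained on all other variables. Deterministic per seed.
    """
    P = np.asarray(presence_env, float)
    B = np.asarray(background_env, float)
    p = P.shape[1]
    if p < 2:
        raise InputError("jackknife needs >= 2 variables")
    if var_names is None:
        var_names = [f"v{j}" for j in range(p)]
    out = {}
    for v in range(p):
        only_cols = [v]
        without_cols = [j for j in range(p) if j != v]
        _, rep_only = _fit_eval(P[:, only_cols], B[:, only_cols], config, seed=seed,
                                var_names=[var_names[v]])
        _, rep_without = _fit_eval(P[:, without_cols], B[:, without_cols], config, seed=seed,
                                   var_names=[var_names[j] for j in without_cols])
        out[var_names[v]] = (rep_only.auc_test, rep_without.auc_test)
    return out


def sample_background(stack: EnvStack, n: int = 10000, seed: int = 0) -> np.ndarray:
    """Uniform background sample (without replacement) from the valid mask.

    Returns a cells x variables table; n is capped at the valid cell count.
    """
    rows, cols, table = stack.valid_cell_table()
    if len(rows) == 0:
        raise InputError("stack has no valid cells")
    n_take = min(n, len(rows))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n_take, replace=False)
    return table[idx]


# ---------------------------------------------------------------------------
# Model serialization (diffable structured text)
# ---------------------------------------------------------------------------

def write_lambdas(model: MaxentModel, path) -> None:
    """Write the fitted model as a diffable text table (see read_lambdas)."""
    fs = model.features
    names = fs.var_names
    with open(path, "w") as fh:
        fh.write("# nichekit maxent model\n")
        fh.write(f"classes\t{','.join(fs.classes)}\n")
        fh.write(f"entropy_H\t{model.entropy_H!r}\n")
        fh.write(f"offset\t{model.linear_predictor_offset!r}\n")
        fh.write(f"reg_multiplier\t{model.reg_multiplier!r}\n")
        fh.write(f"n_presence\t{model.n_presence}\n")
        fh.write(f"n_background\t{model.n_background}\n")
        fh.write(f"converged\t{model.converged}\n")
        fh.write("variable\tvar_min\tvar_max\tclamp_min\tclamp_max\n")
        for v, name in enumerate(names):
            fh.write(f"{name}\t{float(fs.var_min[v])!r}\t{float(fs.var_max[v])!r}"
                     f"\t{float(fs.clamp_min[v])!r}\t{float(fs.clamp_max[v])!r}\n")
        fh.write("feature\tlambda\tfeat_min\tfeat_max\tbeta\n")
        for j, ft in enumerate(fs.features):
            fh.write(
                f"{ft.describe(names)}\t{float(model.lambdas[j])!r}\t{float(fs.feat_min[j])!r}"
                f"\t{float(fs.feat_max[j])!r}\t{float(model.betas[j])!r}\n"
            )


def _parse_feature(desc: str, names: list[str]) -> Feature:
    kind, _, body = desc.partition("(")
    body = body.rstrip(")")
    if kind == "H":
        var, knot, direction = body.rsplit(",", 2)
        return Feature("H", (names.index(var),), knot=float(knot),
                       direction=+1 if direction == "fwd" else -1)
    if kind == "P":
        a, b = body.split("*")
        return Feature("P", (names.index(a), names.index(b)))
    if kind in ("L", "Q"):
        return Feature(kind, (names.index(body),))
    raise InputError(f"unparseable feature description {desc!r}")


def read_lambdas(path) -> MaxentModel:
    """Reconstruct a model from a write_lambdas file (projection-ready)."""
    header: dict[str, str] = {}
    var_rows: list[list[str]] = []
    feat_rows: list[list[str]] = []
    section = "header"
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "variable":
                section = "vars"
                continue
            if parts[0] == "feature":
                section = "feats"
                continue
            if section == "header":
                header[parts[0]] = parts[1]
            elif section == "vars":
                var_rows.append(parts)
            else:
                feat_rows.append(parts)
    if not var_rows or not feat_rows:
        raise InputError(f"{path}: not a lambdas file")
    names = [r[0] for r in var_rows]
    fs = FeatureSet(
        var_names=names,
        features=[_parse_feature(r[0], names) for r in feat_rows],
        var_min=np.array([float(r[1]) for r in var_rows]),
        var_max=np.array([float(r[2]) for r in var_rows]),
        feat_min=np.array([float(r[2]) for r in feat_rows]),
        feat_max=np.array([float(r[3]) for r in feat_rows]),
        clamp_min=np.array([float(r[3]) for r in var_rows]),
        clamp_max=np.array([float(r[4]) for r in var_rows]),
        classes=tuple(header.get("classes", "L,Q,H,P").split(",")),
    )
    return MaxentModel(
        features=fs,
        lambdas=np.array([float(r[1]) for r in feat_rows]),
        reg_multiplier=float(header["reg_multiplier"]),
        betas=np.array([float(r[4]) for r in feat_rows]),
        linear_predictor_offset=float(header["offset"]),
        entropy_H=float(header["entropy_H"]),
        n_presence=int(header["n_presence"]),
        n_background=int(header["n_background"]),
        n_iter=0,
        converged=header.get("converged") == "True",
    )
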