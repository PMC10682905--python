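"""End-to-end pipeline: synthetic world -> models -> overlap -> futures.

Every stage draws its randomness from child seeds fanned out from one
master seed, so a rerun with the same config reproduces identical
outputs. All tabular outputs are CSV; rasters are ESRI ASCII.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from nichekit import envspace, futures, maxent, overlap, synthdata
from nichekit.errors import InputError, NichekitError
from nichekit.grids import EnvStack, GridGeometry, Layer, crop_to_hull, write_raster
from nichekit.occurrences import (
    OccurrenceSet, correlation_filter, extract_env, thin,
    FINE_CLASSES,
)

log = logging.getLogger(__name__)

DEFAULT_REG_MULTIPLIERS = {
    "wild": 3.0, "semiwild": 3.0, "wild_sl": 3.0, "landrace": 3.0,
    "commercial": 1.0, "cultivated": 1.0,
}


@dataclass
class RunConfig:
    """Pipeline configuration; defaults mirror the study design
    (5-km thinning, 10,000 background, 30% test, 10 replicates, 500
    iterations, LQHP features, 10th-percentile threshold, per-class
    regularization multipliers of 3 for wild-side and 1 for
    commercial-side classes, 3 periods x 2 pathways x 8 GCMs)."""

    master_seed: int = 1
    outdir: str = "runs/default"

    # synthetic world
    grid_rows: int = 100
    grid_cols: int = 100
    x_origin: float = -110.0
    y_origin: float = 30.0
    cell_size: float = 0.05
    n_vars: int = 9
    smoothness: float = 3.0
    env_correlation_rho: float = 0.4
    n_occurrences: dict[str, int] = field(default_factory=lambda: {
        "wild": 300, "semiwild": 120, "landrace": 280, "commercial": 500,
    })
    n_proxy_per_polygon: int = 40

    # occurrence processing
    thin_km: float = 5.0
    crop_buffer_deg: float = 3.0
    corr_threshold: float = 0.8
    keep_variables: tuple[str, ...] = ()

    # model surface
    feature_classes: tuple[str, ...] = ("L", "Q", "H", "P")
    hinge_knots_per_var: int = 30
    n_background: int = 10000
    test_fraction: float = 0.3
    n_replicates: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    reg_multipliers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REG_MULTIPLIERS))
    model_classes: tuple[str, ...] = ("wild", "semiwild", "landrace", "commercial", "wild_sl", "cultivated")
    min_presences: int = 10

    # envelope statistics
    n_boot: int = 1000
    boot_statistic: str = "mean"

    # randomization tests
    run_randomization: bool = False
    randomization_pairs: tuple[tuple[str, str], ...] = (("wild", "landrace"), ("wild", "commercial"))
    n_equivalency_reps: int = 99
    n_background_reps: int = 49

    # futures
    threshold_percentile: float = 10.0
    periods: tuple[int, ...] = synthdata.PERIODS
    pathways: tuple[str, ...] = synthdata.PATHWAYS
    n_gcms: int = 8
    scenario_noise_sd: float = 0.05
    overlap_pairs: tuple[tuple[str, str], ...] = (("wild_sl", "cultivated"), ("landrace", "commercial"), ("wild", "landrace"))

    write_rasters: bool = True

    def geometry(self) -> GridGeometry:
        return GridGeometry(self.grid_rows, self.grid_cols, self.x_origin, self.y_origin, self.cell_size)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True, default=str)


def _ar1_correlation(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_world(config: RunConfig) -> tuple[EnvStack, OccurrenceSet, dict[str, synthdata.NicheSpec]]:
    """Synthetic environment plus class-labelled occurrences (incl. proxies)."""
    geom = config.geometry()
    stack = synthdata.make_env_layers(
        seed=synthdata.child_seed(config.master_seed, "env"),
        geometry=geom, n_vars=config.n_vars,
        correlation=_ar1_correlation(config.n_vars, config.env_correlation_rho),
        smoothness=config.smoothness,
    )
    niches = synthdata.default_niches(config.n_vars)
    occ_seed = synthdata.child_seed(config.master_seed, "occurrences")
    parts = []
    for i, cls in enumerate(FINE_CLASSES):
        n = config.n_occurrences.get(cls, 0)
        if n > 0:
            parts.append(synthdata.sample_occurrences(occ_seed + i, stack, niches[cls], n))
    if config.n_proxy_per_polygon > 0:
        # two rectangular "agricultural census" polygons inside the grid
        g = geom
        w = g.n_cols * g.cell_size
        h = g.n_rows * g.cell_size
        def rect(fx0, fy0, fx1, fy1):
            return [
                (g.x_origin + fx0 * w, g.y_origin - fy0 * h),
                (g.x_origin + fx1 * w, g.y_origin - fy0 * h),
                (g.x_origin + fx1 * w, g.y_origin - fy1 * h),
                (g.x_origin + fx0 * w, g.y_origin - fy1 * h),
            ]
        proxies = synthdata.make_polygon_proxies(
            synthdata.child_seed(config.master_seed, "proxies"),
            [rect(0.55, 0.15, 0.85, 0.45), rect(0.15, 0.55, 0.45, 0.85)],
            config.n_proxy_per_polygon, class_label="commercial",
        )
        parts.append(proxies)
    ids, lon, lat, cl, src = [], [], [], [], []
    for p_idx, p in enumerate(parts):
        for i in range(len(p)):
            ids.append(f"p{p_idx}_{p.ids[i]}")
            lon.append(p.lon[i]); lat.append(p.lat[i])
            cl.append(p.class_label[i]); src.append(p.source[i])
    occ = OccurrenceSet(np.array(ids, dtype=object), np.array(lon), np.array(lat),
                        np.array(cl, dtype=object), np.array(src, dtype=object))
    return stack, occ, niches


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Stages: simulate -> joint thin + crop -> per-class thin + extract ->
    variable filter -> PCA envelopes + bootstrap CIs -> per-class
    replicate maxent fits -> pairwise overlap statistics (optional
    randomization tests) -> future-scenario accounting + MESS -> report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        return _run_pipeline(config, outdir)
    except NichekitError:
        raise
    except Exception as exc:  # pragma: no cover - stage tagging
        raise NichekitError(f"pipeline failed: {exc}") from exc


def _run_pipeline(config: RunConfig, outdir: Path) -> Path:
    (outdir / "config.json").write_text(config.to_json())

    log.info("stage: simulate")
    stack, occ, niches = simulate_world(config)
    occ.to_csv(outdir / "occurrences_raw.csv")

    log.info("stage: crop to joint hull")
    joint_thinned = thin(occ, config.thin_km)
    stack = crop_to_hull(stack, list(zip(joint_thinned.lon, joint_thinned.lat)), config.crop_buffer_deg)

    log.info("stage: per-class thin + extract")
    class_points: dict[str, OccurrenceSet] = {}
    for cls in config.model_classes:
        pts = thin(occ.for_class(cls), config.thin_km)
        pts = extract_env(pts, stack)
        class_points[cls] = pts

    log.info("stage: variable filter")
    joint_env = extract_env(joint_thinned, stack)
    env_df = pd.DataFrame(joint_env.valid_env(), columns=stack.names)
    retained = correlation_filter(env_df, config.corr_threshold, keep=config.keep_variables)
    pd.DataFrame({"variable": retained}).to_csv(outdir / "variables_retained.csv", index=False)
    stack = EnvStack([stack[n] for n in retained])
    for cls, pts in class_points.items():
        class_points[cls] = extract_env(pts.subset(np.arange(len(pts))), stack)

    log.info("stage: PCA envelopes")
    _envelope_stage(config, stack, class_points, outdir)

    log.info("stage: maxent fits")
    models, median_maps, train_scores, backgrounds, eval_rows = _model_stage(config, stack, class_points, outdir)
    pd.DataFrame(eval_rows).to_csv(outdir / "model_evaluation.csv", index=False)

    log.info("stage: overlap statistics")
    _overlap_stage(config, stack, class_points, median_maps, outdir)

    log.info("stage: futures")
    _futures_stage(config, stack, models, median_maps, train_scores, backgrounds, outdir)

    manifest = {
        "master_seed": config.master_seed,
        "child_seeds": {k: synthdata.child_seed(config.master_seed, k) for k in synthdata.SEED_OFFSETS},
        "classes": list(config.model_classes),
        "variables": retained,
        "n_records": {cls: int(np.count_nonzero(p.valid)) for cls, p in class_points.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %s", outdir)
    return outdir


def _envelope_stage(config, stack, class_points, outdir) -> None:
    tables = {cls: p.valid_env() for cls, p in class_points.items() if np.count_nonzero(p.valid) >= len(stack.names) + 1}
    pooled = np.vstack([tables[c] for c in sorted(tables)])
    pca = envspace.run_pca(pooled, names=stack.names)
    pd.DataFrame(pca.loadings, index=stack.names,
                 columns=[f"PC{k+1}" for k in range(pca.loadings.shape[1])]).to_csv(outdir / "pca_loadings.csv")
    pd.DataFrame({"component": [f"PC{k+1}" for k in range(len(pca.explained_var_fraction))],
                  "explained_fraction": pca.explained_var_fraction}).to_csv(outdir / "pca_explained.csv", index=False)

    hulls, scores = {}, {}
    for cls, table in tables.items():
        sc = pca.transform(table)[:, :2]
        scores[cls] = sc
        try:
            hulls[cls] = envspace.convex_hull(sc)
        except NichekitError:
            log.warning("envelope: class %r hull degenerate; skipped", cls)
    rows = []
    for a, b in itertools.combinations(sorted(hulls), 2):
        ho = envspace.hull_overlap(hulls[a], hulls[b], scores[a], scores[b])
        rows.append({"class_a": a, "class_b": b, **ho.__dict__})
    pd.DataFrame(rows).to_csv(outdir / "hull_overlap.csv", index=False)

    boot_seed = synthdata.child_seed(config.master_seed, "bootstrap")
    ci_rows = []
    for v_idx, var in enumerate(stack.names):
        cis = {}
        for cls, table in tables.items():
            cis[cls] = envspace.bootstrap_ci(table[:, v_idx], statistic=config.boot_statistic,
                                             n_boot=config.n_boot, seed=boot_seed + v_idx)
        letters = envspace.ci_letter_groups(cis) if len(cis) >= 2 else {c: "a" for c in cis}
        for cls, ci in cis.items():
            ci_rows.append({"variable": var, "class": cls, "estimate": ci.estimate,
                            "ci_low": ci.ci_low, "ci_high": ci.ci_high, "letters": letters[cls]})
    pd.DataFrame(ci_rows).to_csv(outdir / "variable_cis.csv", index=False)


def _model_stage(config, stack, class_points, outdir):
    bg_seed = synthdata.child_seed(config.master_seed, "background")
    rep_seed = synthdata.child_seed(config.master_seed, "replicates")
    models, median_maps, train_scores, backgrounds = {}, {}, {}, {}
    eval_rows = []
    for c_idx, cls in enumerate(config.model_classes):
        pts = class_points[cls]
        pres = pts.valid_env()
        if pres.shape[0] < config.min_presences:
            log.warning("model: class %r has %d presences (< %d); skipped", cls, pres.shape[0], config.min_presences)
            continue
        bg = maxent.sample_background(stack, n=config.n_background, seed=bg_seed + c_idx)
        enm = maxent.ENMConfig(
            classes=tuple(config.feature_classes),
            hinge_knots_per_var=config.hinge_knots_per_var,
            reg_multiplier=config.reg_multipliers.get(cls, 1.0),
            max_iter=config.max_iter, tol=config.tol,
            test_fraction=config.test_fraction, min_presences=config.min_presences,
        )
        replicates, median_map, sd_map = maxent.replicate_cv(
            pres, bg, enm, n_replicates=config.n_replicates,
            seed=rep_seed + c_idx, stack=stack, var_names=stack.names, model_id=cls,
        )
        models[cls] = [m for m, _ in replicates]
        median_maps[cls] = median_map
        backgrounds[cls] = np.vstack([bg, pres])
        # training scores for thresholding: median-map logistic values at presence cells
        scores = np.median(np.stack([m.logistic_scores(pres, clamp=True)[0] for m in models[cls]]), axis=0)
        train_scores[cls] = scores
        for r, (model, report) in enumerate(replicates):
            eval_rows.append({
                "class": cls, "replicate": r,
                "auc_train": report.auc_train, "auc_test": report.auc_test,
                "converged": model.converged, "n_iter": model.n_iter,
            })
        maxent.write_lambdas(models[cls][0], outdir / f"model_{cls}.lambdas.txt")
        if config.write_rasters:
            write_raster(median_map.layer, outdir / f"suitability_{cls}_median.asc", "ascii")
            write_raster(sd_map.layer, outdir / f"suitability_{cls}_sd.asc", "ascii")
        imp = maxent.permutation_importance(models[cls][0], pres, bg, seed=rep_seed + 500 + c_idx)
        pd.DataFrame(sorted(imp.items()), columns=["variable", "importance_pct"]).to_csv(
            outdir / f"importance_{cls}.csv", index=False)
    return models, median_maps, train_scores, backgrounds, eval_rows


def _overlap_stage(config, stack, class_points, median_maps, outdir) -> None:
    rows = []
    for a, b in itertools.combinations(sorted(median_maps), 2):
        st = overlap.overlap_stats(median_maps[a], median_maps[b])
        rows.append({"class_a": a, "class_b": b, "space": "geographic", **st.__dict__})
    bg_env = maxent.sample_background(stack, n=min(config.n_background, 5000),
                                      seed=synthdata.child_seed(config.master_seed, "background") + 99)
    for a, b in config.randomization_pairs:
        if a in class_points and b in class_points:
            try:
                st = overlap.envspace_density_overlap(class_points[a], class_points[b], bg_env, stack=stack)
                rows.append({"class_a": a, "class_b": b, "space": "environmental", **st.__dict__})
            except NichekitError as exc:
                log.warning("envspace overlap %s-%s failed: %s", a, b, exc)
    pd.DataFrame(rows).to_csv(outdir / "overlap_stats.csv", index=False)

    if not config.run_randomization:
        return
    rand_seed = synthdata.child_seed(config.master_seed, "randomization")
    rand_rows = []
    for i, (a, b) in enumerate(config.randomization_pairs):
        eq = overlap.equivalency_test(class_points[a], class_points[b], stack,
                                      n_reps=config.n_equivalency_reps, seed=rand_seed + i)
        rand_rows.append({"test": "equivalency", "class_a": a, "class_b": b,
                          "observed_d": eq.observed.schoener_d, "observed_i": eq.observed.warren_i,
                          "p_low_d": eq.p_low_d, "p_high_d": eq.p_high_d, "n_reps": eq.n_reps})
        bt = overlap.background_test(class_points[a], class_points[b], stack,
                                     n_reps=config.n_background_reps, seed=rand_seed + 100 + i)
        rand_rows.append({"test": "background", "class_a": a, "class_b": b,
                          "observed_d": bt.observed.schoener_d, "observed_i": bt.observed.warren_i,
                          "p_low_d": bt.p_low_d, "p_high_d": bt.p_high_d, "n_reps": bt.n_reps})
    pd.DataFrame(rand_rows).to_csv(outdir / "randomization_tests.csv", index=False)


def _futures_stage(config, stack, models, median_maps, train_scores, backgrounds, outdir) -> None:
    if not models:
        return
    suite = synthdata.make_scenario_suite(
        synthdata.child_seed(config.master_seed, "scenarios"), stack,
        n_gcms=config.n_gcms, periods=config.periods, pathways=config.pathways,
        noise_sd=config.scenario_noise_sd,
    )
    present_bins = {
        cls: futures.binarize(median_maps[cls], train_scores[cls], config.threshold_percentile)
        for cls in models
    }
    future_bins: dict[tuple[str, int, str, str], futures.BinaryMap] = {}
    mess_rows = []
    for (period, pathway, gcm), fstack in sorted(suite.stacks.items()):
        rows, cols = np.nonzero(fstack.valid_mask)
        for cls in models:
            # replicate models share one FeatureSet (same background/clamp
            # inputs), so the scenario feature matrix is evaluated once
            fs = models[cls][0].features
            table = np.column_stack([fstack[n].values[rows, cols] for n in fs.var_names])
            F, _ = fs.evaluate(table, clamp=True)
            arr = np.empty((len(models[cls]), fstack.geometry.n_rows, fstack.geometry.n_cols))
            for k, m in enumerate(models[cls]):
                r = np.exp(F @ m.lambdas + m.linear_predictor_offset)
                reh = r * np.exp(m.entropy_H)
                vals = np.zeros(fstack.geometry.shape)
                vals[rows, cols] = reh / (1.0 + reh)
                arr[k] = vals
            med = np.median(arr, axis=0)
            smap = maxent.SuitabilityMap(
                Layer(f"fut_{cls}", fstack.geometry, np.where(fstack.valid_mask, med, 0.0), ~fstack.valid_mask),
                model_id=f"{cls}_{period}_{pathway}_{gcm}",
                clamped_mask=np.zeros(fstack.geometry.shape, bool))
            future_bins[(cls, period, pathway, gcm)] = futures.binarize(
                smap, train_scores[cls], config.threshold_percentile,
                scenario_id=f"{period}_{pathway}_{gcm}",
                threshold_value=present_bins[cls].threshold_value,
            )
        first_cls = next(iter(models))
        mm = futures.mess(fstack, backgrounds[first_cls], var_names=stack.names)
        mess_rows.append({"period": period, "pathway": pathway, "gcm": gcm,
                          "min_mess": float(mm.values[mm.valid].min()),
                          "pct_novel": float(100.0 * np.mean(mm.values[mm.valid] < 0))})
    pd.DataFrame(mess_rows).to_csv(outdir / "mess_summary.csv", index=False)
    summary = futures.scenario_summary(present_bins, future_bins)
    summary.to_csv(outdir / "futures_summary.csv", index=False)

    rows = []
    for a, b in config.overlap_pairs:
        if a not in models or b not in models:
            continue
        for period in config.periods:
            for pathway in config.pathways:
                fa = futures.gcm_intersection([future_bins[(a, period, pathway, g)]
                                               for g in suite.gcms(period, pathway)])
                fb = futures.gcm_intersection([future_bins[(b, period, pathway, g)]
                                               for g in suite.gcms(period, pathway)])
                oc = futures.class_overlap_change(present_bins[a], fa, present_bins[b], fb)
                rows.append({"class_a": a, "class_b": b, "period": period, "pathway": pathway, **oc})
    pd.DataFrame(rows).to_csv(outdir / "class_overlap_change.csv", index=False)
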