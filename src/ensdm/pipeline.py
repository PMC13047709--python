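"""End-to-end orchestration: thin → screen → tune → fit/evaluate → ensemble →
project per scenario → classify → change/transition → MESS → report.

Every stage writes its artifacts under the output directory; a manifest JSON
records seeds, the config, and every file written.  Rerunning with the same
config and master seed reproduces all tables bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .ensemble import EnsembleModel, evaluate_ensemble, project, select_members
from .grid import AreaModel, EnvStack, read_stack, write_ascii_grid
from .habitat import (REPORT_UNIT, areas, change, classify, rates,
                      suitable_mask, transition_code)
from .learners import LearnerSpec, tune_maxnet
from .mess import Mess
from .metrics import algorithm_summary, run_protocol
from .occurrences import (PseudoAbsenceSpec, ThinningSpec, assemble,
                          read_occurrences, sample_pseudo_absences, thin,
                          write_occurrences)
from .screening import pearson_matrix, permutation_importance, screen
from .synthetic import default_fixture
from .learners import make_learner

__all__ = ["run_all", "report", "STAGES"]

STAGES = ["simulate", "thin", "screen", "tune", "fit", "ensemble", "project",
          "classify", "change", "mess", "report"]

log = logging.getLogger("ensdm")

# fixed per-stage seed offsets from the master seed
SEED_THIN, SEED_PA, SEED_SPLIT, SEED_IMP, SEED_TUNE, SEED_PROTO = 10, 20, 30, 40, 50, 60


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _write_csv(df: pd.DataFrame, path: Path, manifest: list, index=False) -> None:
    df.to_csv(path, index=index)
    manifest.append(str(path))


def _area_model(cfg: RunConfig) -> AreaModel:
    return AreaModel(mode=cfg.area_mode, constant_cell_area_km2=cfg.cell_area_km2)


def run_all(config: RunConfig, outdir: str | Path, upto: str = "report") -> dict:
    """Run the pipeline through stage ``upto`` (inclusive); returns a results
    dict and writes artifacts + ``manifest.json`` under ``outdir``."""
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; stages: {STAGES}")
    last = STAGES.index(upto)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    res: dict = {"config": config.to_dict()}

    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        _run(config, outdir, last, files, res)
    finally:
        log.removeHandler(fh)
        fh.close()
    files.append(str(outdir / "run.log"))

    cfg_yaml = outdir / "config.yaml"
    config.to_yaml(cfg_yaml)
    files.append(str(cfg_yaml))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.read_bytes()).hexdigest(),
        "stages_run": STAGES[: last + 1],
        "files": sorted(files),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    res["manifest"] = manifest
    return res


def _run(cfg: RunConfig, outdir: Path, last: int, files: list, res: dict) -> None:
    seed = cfg.seed

    # -- inputs / simulate --------------------------------------------------
    if cfg.simulate:
        fx = default_fixture(seed=seed, **cfg.synthetic)
        stack: EnvStack = fx["stack"]
        occ = fx["presences"]
        futures: list[EnvStack] = fx["futures"]
        res["truth_map"] = fx["truth_map"]
        if last >= 0:
            sim_dir = outdir / "inputs"
            sim_dir.mkdir(exist_ok=True)
            write_occurrences(occ, sim_dir / "occurrences.csv")
            files.append(str(sim_dir / "occurrences.csv"))
            write_ascii_grid(sim_dir / "truth.asc", stack.spec, fx["truth_map"])
            files.append(str(sim_dir / "truth.asc"))
    else:
        if not cfg.occurrences or not cfg.stacks:
            raise StageError("simulate", "no synthetic mode and no input paths configured")
        occ = read_occurrences(cfg.occurrences)
        scen = dict(cfg.stacks)
        if "current" not in scen:
            raise StageError("simulate", "stacks config must include a 'current' scenario")
        cur = scen.pop("current")
        stack = read_stack(list(cur.values()), "current", names=list(cur.keys()),
                           crs_tag="geographic")
        futures = [read_stack(list(m.values()), sid, names=list(m.keys()),
                              crs_tag="geographic") for sid, m in scen.items()]
    res["stack"], res["futures"] = stack, futures
    log.info("inputs: %d occurrences, stack %dx%d with %d layers, %d future scenarios",
             len(occ), stack.spec.n_rows, stack.spec.n_cols, len(stack.layers), len(futures))
    if last < STAGES.index("thin"):
        return

    # -- thin ---------------------------------------------------------------
    dist = "euclidean" if stack.spec.crs_tag == "abstract" else cfg.distance_mode
    thinned = thin(occ, ThinningSpec(cfg.radius_km, seed + SEED_THIN, dist))
    log.info("thinning: %d -> %d records (radius %.3f km, %s, seed %d)",
             len(occ), len(thinned), cfg.radius_km, dist, seed + SEED_THIN)
    write_occurrences(thinned, outdir / "occurrences_thinned.csv")
    files.append(str(outdir / "occurrences_thinned.csv"))
    res["thinned"] = thinned
    if last < STAGES.index("screen"):
        return

    # -- screen -------------------------------------------------------------
    pa_spec = PseudoAbsenceSpec(cfg.pa_points, cfg.pa_sets, seed + SEED_PA)
    pa_sets = sample_pseudo_absences(stack, thinned, pa_spec)
    full_ds = assemble(stack, thinned, pa_sets, stack.layer_names,
                       cfg.prevalence, cfg.n_reps, cfg.train_frac, seed + SEED_SPLIT)
    prelim = make_learner(LearnerSpec.of("GBM"), random_state=seed + SEED_IMP)
    ds0 = full_ds[0]
    prelim.fit(ds0.X, ds0.y, sample_weight=ds0.w)
    imp = permutation_importance(prelim, ds0.X, stack.layer_names,
                                 cfg.importance_shuffles, seed + SEED_IMP)
    cors = pearson_matrix(stack)
    scr = screen(imp, cors, cfg.c_min_percent, cfg.r_max)
    if not scr.retained:
        raise StageError("screen", "screening retained no variables")
    log.info("screening: retained %d/%d variables: %s",
             len(scr.retained), len(stack.layer_names), scr.retained)
    _write_csv(scr.log, outdir / "screening.csv", files)
    res["screening"] = scr
    datasets = assemble(stack, thinned, pa_sets, scr.retained,
                        cfg.prevalence, cfg.n_reps, cfg.train_frac, seed + SEED_SPLIT)
    res["datasets"] = datasets
    if last < STAGES.index("tune"):
        return

    # -- tune ---------------------------------------------------------------
    maxnet_params = {"fc": "LQ", "rm": 1.0}
    if cfg.tune and "MAXNET" in cfg.learners:
        ds = datasets[0]
        tuning = tune_maxnet(ds.X, ds.y, ds.w, cfg.rm_grid, cfg.fc_grid,
                             cfg.n_hinge_knots, cfg.n_threshold_knots,
                             seed=seed + SEED_TUNE)
        maxnet_params = {"fc": tuning.chosen_fc, "rm": tuning.chosen_rm}
        log.info("tuning: %d combinations, chosen RM=%s FC=%s",
                 len(tuning.table), tuning.chosen_rm, tuning.chosen_fc)
        _write_csv(tuning.table, outdir / "tuning.csv", files)
        res["tuning"] = tuning
    if last < STAGES.index("fit"):
        return

    # -- fit / evaluate -----------------------------------------------------
    specs = []
    for name in cfg.learners:
        if name == "MAXNET":
            specs.append(LearnerSpec.of("MAXNET", n_hinge_knots=cfg.n_hinge_knots,
                                        n_threshold_knots=cfg.n_threshold_knots,
                                        **maxnet_params))
        elif name == "MAXENT":
            specs.append(LearnerSpec.of("MAXENT", n_hinge_knots=cfg.n_hinge_knots,
                                        n_threshold_knots=cfg.n_threshold_knots))
        else:
            specs.append(LearnerSpec.of(name))
    table, models = run_protocol(datasets, specs, seed=seed + SEED_PROTO)
    n_failed = int((table["status"] == "failed").sum())
    if n_failed:
        for r in table[table["status"] == "failed"].itertuples():
            log.warning("member failed: %s pa_set=%d rep=%d: %s",
                        r.algorithm, r.pa_set, r.rep, getattr(r, "error", ""))
    log.info("protocol: %d members, %d failed", len(table), n_failed)
    _write_csv(table.drop(columns=[c for c in ("error",) if c in table], errors="ignore"),
               outdir / "members.csv", files)
    _write_csv(algorithm_summary(table), outdir / "algorithm_summary.csv", files)
    res["member_table"], res["models"] = table, models
    if last < STAGES.index("ensemble"):
        return

    # -- ensemble -----------------------------------------------------------
    try:
        selected = select_members(table, cfg.auc_min, cfg.tss_min, cfg.gate_level)
    except Exception as exc:
        raise StageError("ensemble", str(exc)) from exc
    em = EnsembleModel.from_selection(selected, models)
    em_auc, em_tss = evaluate_ensemble(em, datasets)
    log.info("ensemble: %d members from %s; mean AUC %.3f, mean TSS %.3f",
             len(em.members), sorted(selected["algorithm"].unique()), em_auc, em_tss)
    res.update(ensemble=em, ensemble_auc=em_auc, ensemble_tss=em_tss,
               selected=selected)
    if last < STAGES.index("project"):
        return

    # -- project ------------------------------------------------------------
    scenarios = [stack] + futures
    suit = {}
    for sc in scenarios:
        P = project(em, sc, res["screening"].retained)
        suit[sc.scenario_id] = P
        p = outdir / f"suitability_{sc.scenario_id}.asc"
        write_ascii_grid(p, sc.spec, P)
        files.append(str(p))
    res["suitability"] = suit
    if last < STAGES.index("classify"):
        return

    # -- classify -----------------------------------------------------------
    am = _area_model(cfg)
    grades, area_tables = {}, {}
    for sid, P in suit.items():
        g = classify(P)
        grades[sid] = g
        p = outdir / f"grades_{sid}.asc"
        write_ascii_grid(p, stack.spec, np.where(g > 0, g, np.nan), fmt="%d")
        files.append(str(p))
        area_tables[sid] = areas(g, stack.spec, am)
    res["grades"], res["area_tables"] = grades, area_tables
    if last < STAGES.index("change"):
        return

    # -- change / transition ------------------------------------------------
    cur_bin = suitable_mask(suit["current"], cfg.change_class_mode)
    change_rows, trans = [], {}
    for sc in futures:
        sid = sc.scenario_id
        fut_bin = suitable_mask(suit[sid], cfg.change_class_mode)
        cat, sums = change(cur_bin, fut_bin, stack.spec, am)
        p = outdir / f"change_{sid}.asc"
        write_ascii_grid(p, stack.spec, np.where(cat >= 0, cat, np.nan), fmt="%d")
        files.append(str(p))
        rt = rates(sums["gain"], sums["loss"], sums["retained"])
        change_rows.append({"scenario": sid, **sums, **rt})
        X, mat = transition_code(grades["current"], grades[sid], stack.spec, am)
        trans[sid] = mat
        p = outdir / f"transition_{sid}.asc"
        write_ascii_grid(p, stack.spec, np.where(X > 0, X, np.nan), fmt="%d")
        files.append(str(p))
        _write_csv(mat, outdir / f"transition_matrix_{sid}.csv", files, index=True)
    change_df = pd.DataFrame(change_rows)
    _write_csv(change_df, outdir / "change_areas.csv", files)
    res["change"], res["transitions"] = change_df, trans
    if last < STAGES.index("mess"):
        return

    # -- MESS / MoD ---------------------------------------------------------
    ds0 = res["datasets"][0]
    mess = Mess().fit(ds0.X, ds0.var_names)
    mess_results = {}
    for sc in futures:
        mr = mess.transform(sc.subset(res["screening"].retained))
        mess_results[sc.scenario_id] = mr
        p = outdir / f"mess_{sc.scenario_id}.asc"
        write_ascii_grid(p, stack.spec, mr.S)
        files.append(str(p))
        p = outdir / f"mod_{sc.scenario_id}.asc"
        write_ascii_grid(p, stack.spec,
                         np.where(mr.mod_index >= 0, mr.mod_index.astype(float), np.nan),
                         fmt="%d")
        files.append(str(p))
        log.info("mess %s: %.1f%% of cells beyond the reference range",
                 sc.scenario_id, 100 * mr.extrapolated_fraction())
    legend = pd.DataFrame({"index": range(len(mess.var_names_)),
                           "variable": mess.var_names_})
    _write_csv(legend, outdir / "mod_legend.csv", files)
    res["mess"] = mess_results
    if last < STAGES.index("report"):
        return

    # -- report -------------------------------------------------------------
    t2, t3 = report(res, cfg)
    _write_csv(t2, outdir / "areas_by_grade.csv", files)
    _write_csv(t3, outdir / "change_rates.csv", files)
    res["table_grades"], res["table_rates"] = t2, t3


def report(res: dict, cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary tables (areas in 10⁴ km², 2 decimals).

    The first table lists per-scenario areas by grade plus the suitable total;
    the second the retained/contraction/expansion accounting with rates
    relative to the previous-period suitable baseline.
    """

    def r2(a):
        return round(a / REPORT_UNIT, 2)

    rows = []
    for sid, df in res["area_tables"].items():
        per = dict(zip(df["grade"], df["area_km2"]))
        rows.append({
            "scenario": sid,
            "unsuitable": r2(per[1]), "low": r2(per[2]),
            "moderate": r2(per[3]), "high": r2(per[4]),
            "total_suitable": r2(per[2] + per[3] + per[4]),
        })
    t2 = pd.DataFrame(rows)

    rows = []
    for rec in res["change"].to_dict("records"):
        rows.append({
            "scenario": rec["scenario"],
            "total_suitable": r2(rec["retained"] + rec["gain"]),
            "retained": r2(rec["retained"]),
            "contraction": r2(rec["loss"]),
            "contraction_rate_pct": round(rec["contraction_rate_pct"], 2),
            "expansion": r2(rec["gain"]),
            "expansion_rate_pct": round(rec["expansion_rate_pct"], 2),
        })
    t3 = pd.DataFrame(rows)
    return t2, t3
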