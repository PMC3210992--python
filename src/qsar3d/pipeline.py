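"""End-to-end orchestration: align -> fields -> PLS -> validation -> contours.

Two entry modes mirror what can actually be computed from the available
inputs:

* ``run_model`` (full mode): takes aligned (or alignable) 3D structures
  plus activities, computes a field block, cross-validates, fits at the
  selected component count, and produces the full report (q2/SEP for
  LOO and group CV, r2/SEE/F, field contributions, bootstrap,
  progressive scrambling, external r2_pred) together with STDEV*COEFF
  contour maps.

* ``table_statistics`` (stats mode): takes only an activity/prediction
  table (such as the built-in reference table) and computes every
  statistic derivable from printed columns alone — training r2/SEE/F at
  a stated component count, external-test r2_pred, activity span and
  train/test counts.

All randomness (group CV, bootstrap, scrambling, synthetic series) flows
from one master seed recorded in the report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import validation as val
from .contours import ContourMap, contour_levels, export_map, stdev_coeff_map
from .dataset import CompoundRecord, dataset_summary
from .fields import FieldBlock, Probe, build_grid, comfa_block, comsia_block, parse_field_selection
from .pls import FieldPLS, PLSFitResults, regression_stats
from .structures import Molecule, align_series

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ValidationReport", "run_model", "table_statistics"]


@dataclass
class RunConfig:
    """Settings of one modelling run."""

    method: str = "comfa"                # "comfa" | "comsia"
    fields: str | Sequence[str] | None = None  # None -> S+E (comfa) / all five (comsia)
    grid_spacing: float = 2.0
    grid_margin: float = 4.0
    alpha: float = 0.3                   # CoMSIA attenuation factor
    min_variation: float | None = None   # None -> 2.0 for comfa, 0.0 for comsia
    max_components: int = 10
    cv_scheme: str = "loo"
    n_groups: int = 10
    bootstrap_runs: int = 10
    scrambling_levels: Sequence[float] = val.DEFAULT_SCRAMBLING_LEVELS
    scrambling_reps: int = 3
    run_scrambling: bool = True
    run_group_cv: bool = True
    seed: int = 0
    structures: str | None = None        # SDF/MOL2 path (full mode)
    activities: str | None = None        # activity CSV path
    align: bool = False                  # superpose on the most active compound
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.method not in ("comfa", "comsia"):
            raise ValueError(f"unknown method {self.method!r}")
        for name in ("grid_spacing", "grid_margin", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fields is None:
            self.fields = "S,E" if self.method == "comfa" else "S,E,H,D,A"
        parse_field_selection(self.fields)
        if self.min_variation is None:
            self.min_variation = 2.0 if self.method == "comfa" else 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _null_report() -> dict[str, Any]:
    return {
        "method": None, "fields": None, "seed": None,
        "n_train": None, "n_test": None,
        "optimal_components": None,
        "q2_loo": None, "sep_loo": None,
        "q2_group": None, "sep_group": None,
        "r2": None, "see": None, "f": None,
        "field_distribution_pct": None,
        "bootstrap_r2_mean": None, "bootstrap_r2_sd": None,
        "bootstrap_see_mean": None, "bootstrap_see_sd": None,
        "scrambling_Q2": None, "scrambling_csdep": None, "scrambling_slope": None,
        "r2_pred": None, "press": None, "sd": None,
        "columns_total": None, "columns_kept": None,
    }


@dataclass
class ValidationReport:
    """Flat, stable-schema report of one modelling run."""

    data: dict[str, Any] = dc_field(default_factory=_null_report)

    def __getattr__(self, name: str) -> Any:
        data = object.__getattribute__(self, "__dict__").get("data")
        if data is not None and name in data:
            return data[name]
        raise AttributeError(name)

    def to_json(self, path: str | Path | None = None) -> str:
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        text = json.dumps(self.data, indent=1, sort_keys=True, default=_default)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        d = self.data
        def fmt(v, spec=".3f"):
            return format(v, spec) if isinstance(v, (int, float)) and v is not None else "-"
        lines = [
            f"Model: {d['method']} ({d['fields']})   seed {d['seed']}",
            "=" * 52,
            f"{'LOO cross q2/SEP':<30}{fmt(d['q2_loo'])}/{fmt(d['sep_loo'])}",
            f"{'Group cross q2/SEP':<30}{fmt(d['q2_group'])}/{fmt(d['sep_group'])}",
            f"{'Non-validated r2/SEE':<30}{fmt(d['r2'])}/{fmt(d['see'])}",
            f"{'F':<30}{fmt(d['f'])}",
            f"{'r2 bootstrap':<30}{fmt(d['bootstrap_r2_mean'])} +/- {fmt(d['bootstrap_r2_sd'])}",
            f"{'S bootstrap':<30}{fmt(d['bootstrap_see_mean'])} +/- {fmt(d['bootstrap_see_sd'])}",
            f"{'Optimal components':<30}{d['optimal_components'] or '-'}",
        ]
        if d["field_distribution_pct"]:
            lines.append("Field distribution %")
            for k, v in d["field_distribution_pct"].items():
                lines.append(f"  {k:<28}{fmt(v, '.1f')}")
        lines.append(f"{'Scrambling Q2/cSDEP/slope':<30}"
                     f"{fmt(d['scrambling_Q2'])}/{fmt(d['scrambling_csdep'])}/{fmt(d['scrambling_slope'])}")
        lines.append(f"{'r2 pred':<30}{fmt(d['r2_pred'])}")
        return "\n".join(lines)


def _compute_block(molecules: Sequence[Molecule], config: RunConfig) -> FieldBlock:
    grid = build_grid(molecules, spacing=config.grid_spacing, margin=config.grid_margin)
    if config.method == "comfa":
        return comfa_block(molecules, grid=grid, probe=Probe())
    return comsia_block(
        molecules, fields=config.fields, grid=grid, probe=Probe(), alpha=config.alpha
    )


def run_model(
    config: RunConfig,
    molecules: Sequence[Molecule] | None = None,
    activities: np.ndarray | None = None,
    roles: Sequence[str] | None = None,
    block: FieldBlock | None = None,
) -> tuple[ValidationReport, dict[str, ContourMap], PLSFitResults]:
    """Execute the full modelling chain and return (report, maps, results).

    Inputs may be given programmatically (``molecules``/``activities``/
    ``roles`` or a precomputed ``block``) or via the config's file paths.
    Training uses the compounds whose role is ``train`` (all compounds
    when no roles are given); ``test`` compounds are predicted with the
    final model for r2_pred.
    """
    t0 = time.time()
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    seed_group, seed_boot, seed_scr = (int(s.generate_state(1)[0] % 2**31) for s in seeds)

    if activities is None:
        if config.activities is None:
            raise ValueError("no activities given (argument or config.activities)")
        from .dataset import load_activity_table

        records = load_activity_table(config.activities)
        activities = np.array([r.exp_pec50 for r in records])
        if roles is None:
            roles = [r.role for r in records]
    activities = np.asarray(activities, float).ravel()

    if block is None:
        if molecules is None:
            if config.structures is None:
                raise ValueError("no structures given (argument or config.structures)")
            from .structures import read_structures

            molecules = read_structures(config.structures)
        if len(molecules) != activities.size:
            raise ValueError(
                f"{len(molecules)} structures vs {activities.size} activities"
            )
        if config.align:
            template = molecules[int(np.argmax(activities))]
            molecules, _ = align_series(molecules, template)
        block = _compute_block(molecules, config)

    roles = list(roles) if roles is not None else ["train"] * activities.size
    roles_arr = np.array(roles)
    train = roles_arr == "train"
    test = roles_arr == "test"
    y_train = activities[train]
    X_train = block.matrix[train]
    slices = block.field_slices()

    report = ValidationReport()
    d = report.data
    d.update(
        method=config.method,
        fields=",".join(parse_field_selection(config.fields)),
        seed=config.seed,
        n_train=int(train.sum()),
        n_test=int(test.sum()),
        columns_total=int(block.matrix.shape[1]),
    )
    timings: dict[str, float] = {}

    model = FieldPLS(
        y_train, X_train, field_slices=slices, min_variation=config.min_variation
    )

    t = time.time()
    cv_loo = model.cross_validate(config.max_components, scheme="loo")
    timings["cv_loo"] = time.time() - t
    n_opt = cv_loo.chosen_components
    d["optimal_components"] = n_opt
    d["q2_loo"] = cv_loo.q2
    d["sep_loo"] = cv_loo.sep

    if config.run_group_cv:
        t = time.time()
        cv_grp = model.cross_validate(
            config.max_components, scheme="groups",
            n_groups=min(config.n_groups, int(train.sum())), seed=seed_group,
        )
        timings["cv_group"] = time.time() - t
        d["q2_group"] = cv_grp.q2_by_components[n_opt - 1]
        d["sep_group"] = cv_grp.sep_by_components[n_opt - 1]

    results = model.fit(n_opt)
    d["columns_kept"] = int(results.state.mask.sum())
    d["r2"] = results.rsquared
    d["see"] = results.see
    d["f"] = results.fvalue
    d["field_distribution_pct"] = {
        k: round(v, 1) for k, v in results.field_contributions.items()
    }

    t = time.time()
    boot = val.bootstrap_validate(
        y_train, X_train, n_opt, runs=config.bootstrap_runs, seed=seed_boot,
        min_variation=config.min_variation, field_slices=slices,
    )
    timings["bootstrap"] = time.time() - t
    d["bootstrap_r2_mean"] = boot.r2_mean
    d["bootstrap_r2_sd"] = boot.r2_sd
    d["bootstrap_see_mean"] = boot.see_mean
    d["bootstrap_see_sd"] = boot.see_sd

    if config.run_scrambling:
        t = time.time()
        scr = val.progressive_scrambling(
            y_train, X_train, n_opt, levels=config.scrambling_levels,
            reps=config.scrambling_reps, seed=seed_scr,
            min_variation=config.min_variation, field_slices=slices,
        )
        timings["scrambling"] = time.time() - t
        d["scrambling_Q2"] = scr.Q2
        d["scrambling_csdep"] = scr.cSDEP
        d["scrambling_slope"] = scr.slope

    if test.any() and test.sum() >= 2:
        pred = results.predict(block.matrix[test])
        pr = val.r2_pred(activities[test], pred, float(y_train.mean()))
        d["r2_pred"] = pr.r2_pred
        d["press"] = pr.press
        d["sd"] = pr.sd

    maps = stdev_coeff_map(results, _subset_block(block, train))
    for cmap in maps.values():
        if np.any(cmap.values != 0):
            contour_levels(cmap)
    for stage, dt in timings.items():
        logger.info("stage %s: %.2fs", stage, dt)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        manifest = {"fields": {}, "seed": config.seed, "method": config.method}
        for name, cmap in maps.items():
            export_map(cmap, out / f"{name}.dx")
            manifest["fields"][name] = {
                "file": f"{name}.dx",
                "favored_level": cmap.favored_level,
                "disfavored_level": cmap.disfavored_level,
            }
        (out / "maps.json").write_text(json.dumps(manifest, indent=1))
    logger.info("run complete in %.1fs", time.time() - t0)
    return report, maps, results


def _subset_block(block: FieldBlock, mask: np.ndarray) -> FieldBlock:
    names = None
    if block.compound_names is not None:
        names = [n for n, m in zip(block.compound_names, mask) if m]
    return FieldBlock(
        block.matrix[mask], list(block.column_meta), block.grid, block.fields, names
    )


def table_statistics(
    records: Sequence[CompoundRecord], n_components: int = 5
) -> dict[str, Any]:
    """Statistics-only mode: everything derivable from a printed table.

    For each prediction column present (CoMFA/CoMSIA): training r2, SEE
    and F at the stated component count, and external-test
    r2_pred = 1 - PRESS/SD against the training-set mean activity.
    """
    summary = dataset_summary(records)
    train = [r for r in records if r.role == "train"]
    test = [r for r in records if r.role == "test"]
    out: dict[str, Any] = {
        "n": summary.n,
        "n_train": summary.n_train,
        "n_test": summary.n_test,
        "pec50_min": summary.min_pec50,
        "pec50_max": summary.max_pec50,
        "pec50_span": summary.span,
        "n_components": n_components,
    }
    train_mean = float(np.mean([r.exp_pec50 for r in train])) if train else None
    for model in ("comfa", "comsia"):
        preds_train = [(r.exp_pec50, getattr(r, f"{model}_pred")) for r in train]
        preds_test = [(r.exp_pec50, getattr(r, f"{model}_pred")) for r in test]
        if any(p is None for _, p in preds_train + preds_test):
            out[model] = None
            continue
        y_tr = np.array([a for a, _ in preds_train])
        p_tr = np.array([p for _, p in preds_train])
        r2, see, f = regression_stats(y_tr, p_tr, n_components)
        entry: dict[str, Any] = {"r2": r2, "see": see, "f": f}
        if len(preds_test) >= 2 and train_mean is not None:
            y_te = np.array([a for a, _ in preds_test])
            p_te = np.array([p for _, p in preds_test])
            pr = val.r2_pred(y_te, p_te, train_mean)
            entry.update(r2_pred=pr.r2_pred, press=pr.press, sd=pr.sd)
        out[model] = entry
    return out
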