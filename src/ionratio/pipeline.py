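"""End-to-end pipeline: preprocess -> align -> annotate -> ratios -> GA -> RF.

A :class:`PipelineConfig` (usually loaded from YAML) names the inputs and
all stage parameters; :func:`run_pipeline` executes the stages in order,
writes every intermediate artifact to the output directory, and records a
manifest with versions, the master seed, and per-stage counts. A stage
failure aborts with the stage name; artifacts written by earlier stages are
retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .alignment import align_peaks, average_replicates, choose_cutoff
from .annotation import annotate, annotated_feature_ids
from .features import build_ratios
from .ga import GAConfig, evaluate_solution, rank_and_select, run_ga
from .preprocessing import PeakParams, preprocess_spectrum
from .rf import RFGrid, rf_full, rf_reduced
from .synthetic import (
    CohortSimConfig,
    cohort_to_spectra,
    make_compound_db,
    simulate_cohort,
    split_learning_validation,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "default_config"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def default_config() -> dict:
    """Full default configuration as a plain dict (YAML-serializable)."""
    return {
        "seed": 0,
        "output_dir": "ionratio_out",
        # inputs: either a simulation block, a spectra directory, or matrices
        "simulate": None,           # dict of CohortSimConfig overrides, or None
        "spectra_dir": None,        # directory of .txt/.mzml spectra
        "learning_matrix": None,    # CSV path (skips preprocess/align)
        "validation_matrix": None,
        "n_learning_per_class": 10,
        "peak_params": {f.name: getattr(PeakParams(), f.name)
                        for f in dataclasses.fields(PeakParams)},
        "alignment": {"cutoff": "auto", "candidate_cutoffs": None},
        "annotation": {"db": None, "tol_ppm": 10.0, "synthetic_db": False},
        "features": {"annotated_only": True, "log_ratios": False},
        "ga": {f.name: getattr(GAConfig(), f.name)
               for f in dataclasses.fields(GAConfig)},
        "rf": {"enabled": True, "n_trees": [250, 500, 1000],
               "mtry_rules": ["sqrt", "tenth", "third"],
               "top_k": [6, 2], "n_cv_repeats": 30},
    }


@dataclasses.dataclass
class PipelineConfig:
    """Thin wrapper over the nested config dict with helpers."""

    data: dict

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls.from_dict(user)

    @classmethod
    def from_dict(cls, user: dict) -> "PipelineConfig":
        cfg = default_config()
        _deep_update(cfg, user)
        return cls(cfg)

    def set_override(self, dotted_key: str, value) -> None:
        """Apply a --set key=value override; keys use dots for nesting."""
        keys = dotted_key.split(".")
        node = self.data
        for k in keys[:-1]:
            if not isinstance(node.get(k), dict):
                node[k] = {}
            node = node[k]
        node[keys[-1]] = yaml.safe_load(str(value))

    def peak_params(self) -> PeakParams:
        d = dict(self.data["peak_params"])
        d["scan_window"] = tuple(d["scan_window"])
        return PeakParams(**d)

    def ga_config(self) -> GAConfig:
        d = dict(self.data["ga"])
        d["subset_size_range"] = tuple(d["subset_size_range"])
        return GAConfig(**d)

    def rf_grid(self) -> RFGrid:
        return RFGrid(
            n_trees=tuple(self.data["rf"]["n_trees"]),
            mtry_rules=tuple(self.data["rf"]["mtry_rules"]),
        )


def _deep_update(base: dict, override: dict) -> None:
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rethrown with stage name
                raise PipelineError(name, exc) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; return the report bundle as a dict."""
    data = cfg.data
    seed = int(data["seed"])
    outdir = Path(data["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "ionratio",
        "version": __version__,
        "seed": seed,
        "config": data,
        "stages": {},
    }
    _write_json(outdir / "manifest.json", manifest)  # early, updated at the end

    learn_m, valid_m, truth = _stage("input")(_load_inputs)(cfg, outdir, seed, manifest)

    # --- annotation ---------------------------------------------------------
    ann_cfg = data["annotation"]
    db = None
    if ann_cfg.get("db"):
        db = io.read_compound_db(ann_cfg["db"])
    elif ann_cfg.get("synthetic_db"):
        db, _ = make_compound_db(learn_m.feature_mz, seed=seed + 7)
        io.write_compound_db(db, outdir / "compound_db.csv")
    elif data["features"]["annotated_only"]:
        raise PipelineError(
            "annotate",
            ValueError("annotation.db: no compound database configured"),
        )
    feature_subset = None
    if db is not None:
        anns = _stage("annotate")(annotate)(learn_m, db, ann_cfg["tol_ppm"])
        io.write_annotations(anns, outdir / "annotations.csv")
        manifest["stages"]["annotate"] = {"n_annotations": len(anns)}
        if data["features"]["annotated_only"]:
            feature_subset = annotated_feature_ids(anns)

    # --- ratio features -----------------------------------------------------
    build = _stage("ratios")(build_ratios)
    ratios_learn = build(learn_m, feature_subset, data["features"]["log_ratios"])
    ratios_valid = build(valid_m, feature_subset, data["features"]["log_ratios"])
    manifest["stages"]["ratios"] = {
        "n_source_features": len(ratios_learn.source_feature_ids),
        "n_ratios": ratios_learn.n_ratios,
    }

    # --- GA selection -------------------------------------------------------
    ga_cfg = cfg.ga_config()
    ga_cfg = dataclasses.replace(ga_cfg, seed=seed + ga_cfg.seed)
    y_learn = np.asarray(ratios_learn.class_labels)
    y_valid = np.asarray(ratios_valid.class_labels)
    finals = _stage("ga")(run_ga)(ratios_learn, y_learn, ga_cfg)
    solution = _stage("rank")(rank_and_select)(
        finals,
        (ratios_learn.ratio_matrix, y_learn),
        (ratios_valid.ratio_matrix, y_valid),
        pairs=ratios_learn.pairs,
        pair_labels=ratios_learn.pair_labels,
        seed=seed + 1,
        n_cv_repeats=ga_cfg.rank_cv_repeats,
        accuracy_floor=ga_cfg.accuracy_floor,
    )
    learn_acc, cv30, val_acc = evaluate_solution(
        solution.ratio_indices,
        (ratios_learn.ratio_matrix, y_learn),
        (ratios_valid.ratio_matrix, y_valid),
        seed=seed + 1,
        n_cv_repeats=ga_cfg.rank_cv_repeats,
    )
    sol = solution.to_dict()
    sol.update(
        learning_accuracy=learn_acc, cv30_accuracy=cv30, validation_accuracy=val_acc
    )
    if truth is not None:
        sol["planted_pairs"] = [[p.numerator, p.denominator] for p in truth]
    _write_json(outdir / "solution.json", sol)
    manifest["stages"]["ga"] = {
        "n_final_solutions": sum(len(r) for r in finals),
        "selected_n_ratios": len(solution.ratio_indices),
    }

    # --- RF benchmark -------------------------------------------------------
    table_rows = [
        {
            "method": "GA + LDA",
            "n_ratios": len(solution.ratio_indices),
            "learning_accuracy": learn_acc,
            "cv2_accuracy": cv30,
            "validation_accuracy": val_acc,
        }
    ]
    if data["rf"]["enabled"]:
        grid = cfg.rf_grid()
        n_rep = int(data["rf"]["n_cv_repeats"])
        full = _stage("rf")(rf_full)(
            ratios_learn, y_learn, grid=grid,
            valid=(ratios_valid, y_valid), n_cv_repeats=n_rep, seed=seed + 2,
        )
        reports = [("RF", full)]
        for k in data["rf"]["top_k"]:
            k = int(k)
            if k <= ratios_learn.n_ratios:
                reports.append(
                    (
                        "RF",
                        rf_reduced(
                            ratios_learn, y_learn, k, full_report=full, grid=grid,
                            valid=(ratios_valid, y_valid), n_cv_repeats=n_rep,
                            seed=seed + 2,
                        ),
                    )
                )
        for name, rep in reports:
            table_rows.append(
                {
                    "method": name,
                    "n_ratios": rep.n_ratios_in_model,
                    "learning_accuracy": rep.learning_accuracy,
                    "cv2_accuracy": rep.cv2_accuracy,
                    "validation_accuracy": rep.validation_accuracy,
                }
            )
        _write_json(outdir / "rf_report.json", [r.to_dict() for _, r in reports])
    _write_table(outdir / "accuracy_table.csv", table_rows)

    manifest["stages"]["done"] = True
    _write_json(outdir / "manifest.json", manifest)
    return {"solution": sol, "table": table_rows, "manifest": manifest}


def _load_inputs(cfg: PipelineConfig, outdir: Path, seed: int, manifest: dict):
    """Produce learning/validation aligned matrices from the configured source."""
    data = cfg.data
    truth = None
    if data.get("learning_matrix") and data.get("validation_matrix"):
        learn_m = io.read_aligned_matrix(data["learning_matrix"])
        valid_m = io.read_aligned_matrix(data["validation_matrix"])
        return learn_m, valid_m, truth

    if data.get("simulate") is not None:
        sim = dict(data["simulate"] or {})
        spectra_mode = sim.pop("render_spectra", False)
        for key in ("mz_range", "base_intensity_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        sim.setdefault("seed", seed)
        cohort_cfg = CohortSimConfig(**sim)
        matrix, truth = simulate_cohort(cohort_cfg, average=not spectra_mode)
        if spectra_mode:
            specs = cohort_to_spectra(matrix, seed=seed + 3)
            # rendered spectra carry signal in every scan (no elution
            # structure), so the summation window is the full scan range
            pp = dataclasses.replace(
                cfg.peak_params(), scan_window=(0, specs[0].n_scans - 1)
            )
            tables = [preprocess_spectrum(s, pp) for s in specs]
            matrix = _align_stage(cfg, tables, matrix.class_labels, manifest)
            matrix = average_replicates(matrix)
        io.write_aligned_matrix(matrix, outdir / "aligned_matrix.csv")
    elif data.get("spectra_dir"):
        paths = sorted(Path(data["spectra_dir"]).iterdir())
        specs = [io.read_spectrum(p) for p in paths if p.suffix.lower() in (".txt", ".mzml")]
        if not specs:
            raise ValueError(f"spectra_dir {data['spectra_dir']!r}: no spectra found")
        tables = [preprocess_spectrum(s, cfg.peak_params()) for s in specs]
        for t in tables:
            io.write_peak_table(t, outdir / f"peaks_{t.sample_id}_{t.replicate_id}.csv")
        matrix = _align_stage(cfg, tables, None, manifest)
        matrix = average_replicates(matrix)
        io.write_aligned_matrix(matrix, outdir / "aligned_matrix.csv")
    else:
        raise ValueError(
            "config must provide learning/validation matrices, a simulate "
            "block, or spectra_dir"
        )
    learn_m, valid_m = split_learning_validation(
        matrix, int(data["n_learning_per_class"]), seed=seed + 11
    )
    io.write_aligned_matrix(learn_m, outdir / "learning_matrix.csv")
    io.write_aligned_matrix(valid_m, outdir / "validation_matrix.csv")
    return learn_m, valid_m, truth


def _align_stage(cfg: PipelineConfig, tables, class_labels_list, manifest: dict):
    data = cfg.data
    cutoff = data["alignment"]["cutoff"]
    cands = data["alignment"]["candidate_cutoffs"]
    if cutoff == "auto":
        cutoff = choose_cutoff(tables, cands)
    label_map = None
    if class_labels_list is not None:
        label_map = {t.sample_id: lab for t, lab in zip(tables, class_labels_list)}
    matrix = align_peaks(tables, cutoff=cutoff, class_labels=label_map)
    manifest["stages"]["align"] = {
        "cutoff": float(cutoff),
        "n_features": matrix.n_features,
        "n_peaks": int(sum(len(t) for t in tables)),
    }
    return matrix


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_table(path: Path, rows: list[dict]) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, index=False)
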