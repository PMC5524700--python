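"""End-to-end protocol: align -> grid -> cap -> select -> fit -> rank ->
external validation -> metrics -> hotspot mapping.

One configuration drives the whole sweep; every output lands in a run
directory together with a manifest that records the configuration digest,
so a rerun with the same configuration reproduces the run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity as activity_mod
from .alignment import align_to_reference, build_cep
from .ensemble import assign_parameters, read_ensemble
from .errors import GridQSARError, StageError
from .grid import GridSpec, cap_energies, compute_ied, load_probes
from .mapping import export_pseudoatoms, neighbor_residues, select_top_ieds
from .pls import (ModelScore, enumerate_splits, predict, predict_external,
                  rank_models, run_all_splits)
from .selection import assemble_matrix, correlation_filter, drop_invariant
from .synth import SyntheticSpec, generate_dataset

__all__ = ["ProtocolConfig", "ProtocolResult", "run_protocol"]


@dataclass
class ProtocolConfig:
    """Configuration of one full protocol run.

    ``mode="synthetic"`` generates the inputs from ``synthetic``;
    ``mode="files"`` reads per-code multi-model PDBs plus parameter and
    activity tables.
    """

    mode: str = "synthetic"
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    # files mode
    structure_paths: dict = field(default_factory=dict)  # code -> path
    structure_format: str = "pdb_multimodel"
    params_paths: dict = field(default_factory=dict)  # code -> path
    activity_path: str | None = None
    ref_code: str | None = None
    fit_roles: tuple = ("enzyme",)
    grid_edge: float = 24.0
    grid_spacing: float = 1.0
    grid_center: tuple | None = None  # None -> reference CEP centroid
    probes_path: str | None = None
    # shared stages
    cap_threshold: float = 30.0
    log_base: float = 10.0
    correlation_thresholds: tuple = (0.5, 0.45, 0.4)
    external_codes: tuple = ("D", "G")
    n_components: int | str = 2
    autoscale: bool = False
    q2_min: float = 0.1
    rmse_max: float = 40.0
    limits: tuple = (52.0, 85.0)
    map_cutoff: float = 0.6
    map_sign: str | None = "negative"
    map_radius: float = 2.0
    rc_quantile: float = 0.99

    def __post_init__(self):
        thr = tuple(self.correlation_thresholds)
        if list(thr) != sorted(thr, reverse=True):
            raise GridQSARError("correlation thresholds must be descending")

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["synthetic"] = dataclasses.asdict(self.synthetic)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class ThresholdResult:
    """Everything derived at one |r| threshold."""

    threshold: float
    report: object
    matrix: object
    models: dict
    scores: list
    ranked: list


@dataclass
class ProtocolResult:
    config: ProtocolConfig
    ensembles: list
    grid: GridSpec
    activity: pd.Series
    by_threshold: dict
    best_threshold: float | None
    best_score: ModelScore | None
    external_predictions: pd.DataFrame | None
    metrics: dict
    residue_report: pd.DataFrame | None
    dataset: object = None  # synthetic mode only

    @property
    def best_model(self):
        if self.best_score is None:
            return None
        return self.by_threshold[self.best_threshold].models[
            self.best_score.split_id]


def _load_inputs(config: ProtocolConfig):
    if config.mode == "synthetic":
        dataset = generate_dataset(config.synthetic)
        return (dataset.ensembles, dataset.grid, [dataset.probe],
                dataset.kcat, dataset.tensors, dataset)
    if config.mode != "files":
        raise GridQSARError(f"unknown mode {config.mode!r}")
    if not config.structure_paths:
        raise StageError("load", "no structure paths configured")
    ensembles = []
    for code, path in config.structure_paths.items():
        ens = read_ensemble(path, format=config.structure_format, code=code)
        params = config.params_paths.get(code) or config.params_paths.get("*")
        if params is None:
            raise StageError("load", f"no parameter table for code {code!r}")
        ensembles.append(assign_parameters(ens, params))
    ref_code = config.ref_code or ensembles[0].code
    by_code = {e.code: e for e in ensembles}
    if ref_code not in by_code:
        raise StageError("align", f"reference code {ref_code!r} not loaded")
    ordered = [by_code[ref_code]] + [e for e in ensembles if e.code != ref_code]
    ceps = []
    for i, ens in enumerate(ordered):
        sel = ens.atom_indices(config.fit_roles)
        cep = build_cep(ens, sel)
        if i > 0:
            cep = align_to_reference(cep, ceps[0], sel,
                                     ceps[0].atom_indices(config.fit_roles))
        ceps.append(cep)
    center = (np.asarray(config.grid_center) if config.grid_center is not None
              else ceps[0].coords[0].mean(axis=0))
    grid = GridSpec.centered(center, config.grid_edge, config.grid_spacing)
    probes = load_probes(config.probes_path)
    if config.activity_path is None:
        table = activity_mod.load_activity_table()
    else:
        table = activity_mod.load_activity_table(config.activity_path)
    kcat = table["kcat"].astype(float)
    tensors = None
    return ceps, grid, probes, kcat, tensors, None


def run_protocol(config: ProtocolConfig, outdir=None) -> ProtocolResult:
    """Execute all stages; optionally persist outputs + manifest to outdir."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_digest": config.digest(), "stages": [], "files": []}

    def _fail(stage, exc):
        raise StageError(stage, str(exc)) from exc

    # --- load / align ---
    try:
        ceps, grid, probes, kcat, tensors, dataset = _load_inputs(config)
    except StageError:
        raise
    except Exception as exc:
        _fail("load", exc)
    manifest["stages"].append({"stage": "align", "codes": [e.code for e in ceps]})

    # --- grid + cap ---
    try:
        if tensors is None:
            tensors = [cap_energies(compute_ied(cep, grid, probes),
                                    config.cap_threshold, config.log_base)
                       for cep in ceps]
    except Exception as exc:
        _fail("grid", exc)
    manifest["stages"].append({"stage": "grid",
                               "n_descriptors": tensors[0].n_descriptors})

    # --- assemble + reduce ---
    try:
        matrix = assemble_matrix(tensors)
        matrix, var_report = drop_invariant(matrix)
    except Exception as exc:
        _fail("assemble", exc)
    codes = list(matrix.codes)
    external = [c for c in config.external_codes if c in codes]
    non_external = [c for c in codes if c not in external]
    kcat = kcat.loc[codes]

    # --- per-threshold selection, split sweep, ranking ---
    by_threshold: dict[float, ThresholdResult] = {}
    plans = enumerate_splits(non_external, test_size=3, external=external)
    for thr in config.correlation_thresholds:
        try:
            sel_matrix, report = correlation_filter(matrix, kcat, thr,
                                                    codes=non_external)
            if report.n_retained == 0:
                by_threshold[thr] = ThresholdResult(thr, report, sel_matrix,
                                                    {}, [], [])
                continue
            models, scores = run_all_splits(sel_matrix, kcat, plans,
                                            n_components=config.n_components,
                                            autoscale=config.autoscale)
            ranked = rank_models(scores, q2_min=config.q2_min,
                                 rmse_max=config.rmse_max)
            by_threshold[thr] = ThresholdResult(thr, report, sel_matrix,
                                                models, scores, ranked)
        except Exception as exc:
            _fail(f"select/fit@{thr}", exc)
    manifest["stages"].append({
        "stage": "fit",
        "n_models_per_threshold": {str(t): len(r.scores)
                                   for t, r in by_threshold.items()},
    })

    # --- best model across thresholds ---
    best_threshold = best_score = None
    for thr, res in by_threshold.items():
        if res.ranked:
            cand = res.ranked[0]
            if (best_score is None
                    or (cand.rmse_test, -cand.q2_test)
                    < (best_score.rmse_test, -best_score.q2_test)):
                best_threshold, best_score = thr, cand

    # --- external validation + metrics over ranked models ---
    external_predictions = None
    metrics: dict = {}
    if best_score is not None and external:
        res = by_threshold[best_threshold]
        rows = []
        for score in res.ranked:
            model = res.models[score.split_id]
            X_ext = res.matrix.rows(external)
            preds = predict_external(model, X_ext)
            score.rmse_external = float(np.sqrt(np.mean(
                (preds - kcat.loc[external].to_numpy()) ** 2)))
            for code, pred in zip(external, preds):
                rows.append({"model": score.split_id, "code": code,
                             "predicted_kcat": float(pred),
                             "experimental_kcat": float(kcat.loc[code])})
        external_predictions = pd.DataFrame(rows)
        for score in res.ranked:
            model = res.models[score.split_id]
            all_pred = predict(model, res.matrix.data)
            per_limit = {}
            for limit, polarity in zip(config.limits,
                                       ("low_is_positive", "high_is_positive")):
                counts = activity_mod.confusion_at_limit(
                    all_pred, kcat.to_numpy(), limit, polarity)
                try:
                    sens = activity_mod.sensitivity(counts)
                except GridQSARError:
                    sens = None
                try:
                    spec_ = activity_mod.specificity(counts)
                except GridQSARError:
                    spec_ = None
                per_limit[str(limit)] = {
                    "tp": counts.tp, "tn": counts.tn, "fp": counts.fp,
                    "fn": counts.fn, "sensitivity": sens,
                    "specificity": spec_,
                }
            metrics[score.split_id] = per_limit
    manifest["stages"].append({"stage": "validate",
                               "n_ranked": 0 if best_score is None
                               else len(by_threshold[best_threshold].ranked)})

    # --- hotspot mapping from univariate r and from the best model rc ---
    residue_report = None
    if best_score is not None:
        try:
            res = by_threshold[best_threshold]
            r_weights = res.report.correlations
            ieds = select_top_ieds(r_weights, grid, cutoff=config.map_cutoff,
                                   sign=config.map_sign)
            if ieds:
                residue_report = neighbor_residues(ieds, ceps[0],
                                                   radius=config.map_radius)
            if out is not None and ieds:
                export_pseudoatoms(ieds, out / "ieds_r.pdb")
            rc = res.models[best_score.split_id].coefficient_series()
            rc_cut = float(np.quantile(np.abs(rc), config.rc_quantile))
            rc_ieds = select_top_ieds(rc, grid, cutoff=rc_cut)
            if out is not None and rc_ieds:
                export_pseudoatoms(rc_ieds, out / "ieds_rc.pdb")
        except Exception as exc:
            _fail("map", exc)
    manifest["stages"].append({"stage": "map",
                               "n_hotspot_residues":
                               0 if residue_report is None
                               else len(residue_report)})

    result = ProtocolResult(
        config=config, ensembles=ceps, grid=grid, activity=kcat,
        by_threshold=by_threshold, best_threshold=best_threshold,
        best_score=best_score, external_predictions=external_predictions,
        metrics=metrics, residue_report=residue_report, dataset=dataset,
    )
    if out is not None:
        _persist(result, manifest, out)
    return result


def _write_csv(df: pd.DataFrame, path: Path, manifest: dict, **kwargs):
    df.to_csv(path, float_format="%.10g", **kwargs)
    manifest["files"].append({
        "path": path.name,
        "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
    })


def _persist(result: ProtocolResult, manifest: dict, out: Path) -> None:
    kcat = result.activity
    _write_csv(kcat.to_frame(), out / "activity.csv", manifest)
    for thr, res in result.by_threshold.items():
        tag = f"{thr:g}"
        with open(out / f"selection_{tag}.json", "w") as fh:
            json.dump(res.report.to_dict(), fh, indent=2)
        if res.scores:
            _write_csv(pd.DataFrame([s.to_dict() for s in res.scores]),
                       out / f"scores_{tag}.csv", manifest, index=False)
        if res.ranked:
            _write_csv(pd.DataFrame([s.to_dict() for s in res.ranked]),
                       out / f"ranked_{tag}.csv", manifest, index=False)
    if result.external_predictions is not None:
        _write_csv(result.external_predictions,
                   out / "external_predictions.csv", manifest, index=False)
    with open(out / "metrics.json", "w") as fh:
        json.dump(result.metrics, fh, indent=2, sort_keys=True)
    if result.residue_report is not None:
        _write_csv(result.residue_report, out / "hotspot_residues.csv",
                   manifest, index=False)
    manifest["best"] = None if result.best_score is None else {
        "threshold": result.best_threshold,
        **result.best_score.to_dict(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
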