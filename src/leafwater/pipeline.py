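"""End-to-end study orchestration.

``run`` executes the full estimation study from one config and one seed:
simulate (or load) a sample table → 70/30 split → preprocessing comparison
→ NISDI + exhaustive band-pair index models → CARS/SPA/UVE wavelength
selection crossed with the four regression back-ends → model ranking →
per-pixel water map on a synthetic cube → cross-species evaluation on
external tables.  The result is a :class:`StudyReport` that serialises to
JSON deterministically.

The ranking rule encodes parsimony: among models whose prediction-set R^2
is within ``delta_r2`` (default 0.025) of the best, choose the one built on
the fewest wavelengths, breaking ties by lower RMSEP.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import prep as prep_mod
from . import regress, vindex, watermap, wavesel
from .grid import WavelengthGrid
from .synth import SampleTable, SimConfig, VeinSpec, simulate_cube, simulate_sample_table

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "StudyReport",
    "FittedModel",
    "run",
    "rank_models",
    "cross_species_eval",
]


@dataclass
class PipelineConfig:
    """Everything ``run`` needs; defaults give a desk-scale synthetic study."""

    sim: SimConfig = field(default_factory=SimConfig)
    n_samples: int = 400  # calibration split must exceed the band count for full-spectrum MLR
    sample_csv: str | None = None  # load instead of simulating when set
    prep_methods: tuple[str, ...] = prep_mod.PREP_NAMES
    index_families: tuple[str, ...] = vindex.FAMILIES
    selectors: tuple[str, ...] = ("CARS", "SPA", "UVE")
    regressors: tuple[str, ...] = ("RF", "PLSR", "MLR", "ANN")
    include_full_spectrum: bool = True
    test_fraction: float = 0.3
    cars_n_mc: int = 50
    spa_max_vars: int = 30
    rank_delta_r2: float = 0.025
    map_cube_size: tuple[int, int] = (48, 48)
    vein_wc_offset: float = 0.1
    cross_species: bool = True
    out_dir: str = "leafwater_out"
    seed: int = 0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, path_or_text) -> "PipelineConfig":
        text = Path(path_or_text).read_text() if Path(str(path_or_text)).exists() else str(path_or_text)
        d = yaml.safe_load(text) or {}
        if "sim" in d and isinstance(d["sim"], dict):
            for key in ("wc_range", "absorption_centers_nm", "absorption_widths_nm", "absorption_depth_per_wc"):
                if key in d["sim"]:
                    d["sim"][key] = tuple(d["sim"][key])
            d["sim"] = SimConfig(**d["sim"])
        for key in ("prep_methods", "index_families", "selectors", "regressors", "map_cube_size"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class FittedModel:
    """A frozen prediction path: feature extraction + fitted regressor."""

    model_id: str
    model: object
    grid: WavelengthGrid
    feature_kind: str  # 'nisdi' | 'pair' | 'bands'
    band_indices: np.ndarray | None = None
    pair: tuple[str, int, int] | None = None
    prep: prep_mod.PrepMethod | None = None
    msc_reference: np.ndarray | None = None
    n_wavelengths: int = 0

    def _regrid(self, X: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
        if np.array_equal(grid.centers_nm, self.grid.centers_nm):
            return X
        lo, hi = self.grid.centers_nm[0], self.grid.centers_nm[-1]
        if grid.centers_nm[0] > lo or grid.centers_nm[-1] < hi:
            raise ValueError("external grid does not cover the model's wavelength span")
        return np.vstack([np.interp(self.grid.centers_nm, grid.centers_nm, row) for row in X])

    def features(self, X: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
        X = self._regrid(np.asarray(X, dtype=float), grid)
        if self.feature_kind == "nisdi":
            return np.asarray(vindex.nisdi(X, self.grid)).reshape(-1, 1)
        if self.feature_kind == "pair":
            family, i, j = self.pair
            return np.asarray(vindex.pair_index(family, X[:, i], X[:, j])).reshape(-1, 1)
        if self.prep is not None:
            X = self.prep.apply(X, self.grid, reference=self.msc_reference)
        return X[:, self.band_indices]

    def predict(self, X: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
        return np.asarray(self.model.predict(self.features(X, grid)), dtype=float).ravel()

    def extractor(self):
        """Per-pixel feature extractor bound to the model's own grid."""
        return lambda spectra: self.features(spectra, self.grid)


@dataclass
class StudyReport:
    seed: int
    n_samples: int
    n_calibration: int
    n_prediction: int
    prep_ranking: list[dict]
    chosen_prep: str
    index_search: list[dict]
    selection: list[dict]
    model_rows: list[dict]
    chosen_model: dict
    water_map: dict
    cross_species: list[dict]

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path_or_text) -> "StudyReport":
        p = Path(str(path_or_text))
        text = p.read_text() if p.exists() else str(path_or_text)
        return cls(**json.loads(text))


def rank_models(rows: list[dict], delta_r2: float = 0.025) -> dict:
    """Pick the winning model row, rewarding parsimony.

    Among rows with ``r2_pred`` within ``delta_r2`` of the maximum, the row
    with the fewest ``n_wavelengths`` wins; ties break by lower ``rmsep``,
    then by original order.
    """
    if not rows:
        raise ValueError("no model rows to rank")
    best_r2 = max(row["r2_pred"] for row in rows)
    window = [row for row in rows if row["r2_pred"] >= best_r2 - delta_r2]
    return min(window, key=lambda row: (row["n_wavelengths"], row["rmsep"]))


def cross_species_eval(
    fitted: FittedModel,
    external: SampleTable,
    subgroups: list[str] | None = None,
) -> list[dict]:
    """Apply a frozen model to an external-species table, without refitting.

    Returns overall and (optionally) per-subgroup rows with the Pearson r/p
    between predictions and measured water content, R_P^2 and RMSEP.
    """
    pred = fitted.predict(external.reflectance, external.grid)
    y = external.water_content

    def metrics(name: str, sel: np.ndarray) -> dict:
        pr = vindex.pearson(pred[sel], y[sel])
        r2, rmsep = regress.evaluate_arrays(y[sel], pred[sel])
        return {
            "group": name,
            "n": int(sel.sum()) if sel.dtype == bool else int(sel.size),
            "r": pr.r,
            "p": pr.p,
            "r2_pred": r2,
            "rmsep": rmsep,
        }

    rows = [metrics("all", np.arange(external.n_samples))]
    if subgroups is not None:
        labels = np.asarray(subgroups)
        for g in sorted(set(labels.tolist())):
            rows.append(metrics(str(g), np.flatnonzero(labels == g)))
    return rows


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


def _stage(name: str, t0: float, seed: int, **info) -> None:
    extra = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s seed=%d elapsed=%.2fs %s", name, seed, time.time() - t0, extra)


def run(config: PipelineConfig) -> StudyReport:
    """Execute the full study; see the module docstring for the stages."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(12) % (2**31)
    seeds = [int(s) for s in seeds]

    # --- data ----------------------------------------------------------
    t0 = time.time()
    if config.sample_csv is not None:
        table = SampleTable.from_csv(config.sample_csv)
    else:
        table = simulate_sample_table(config.n_samples, config.sim, seed=seeds[0])
    cal, pred = regress.split(table, config.test_fraction, seed=seeds[1])
    _stage("data", t0, seeds[0], n=table.n_samples, hash=_hash(table.reflectance))

    # --- preprocessing comparison --------------------------------------
    t0 = time.time()
    methods = [prep_mod.PrepMethod(name) for name in config.prep_methods]
    prep_ranking = prep_mod.compare_preprocessing(cal, methods, seed=seeds[2])
    chosen_prep_name = str(prep_ranking.iloc[0]["method"])
    chosen_prep = prep_mod.PrepMethod(chosen_prep_name)
    msc_ref = cal.reflectance.mean(axis=0)  # frozen calibration-set reference
    X_cal = chosen_prep.apply(cal.reflectance, cal.grid, reference=msc_ref)
    X_pred = chosen_prep.apply(pred.reflectance, pred.grid, reference=msc_ref)
    _stage("prep", t0, seeds[2], chosen=chosen_prep_name)

    model_rows: list[dict] = []
    fitted_models: dict[str, FittedModel] = {}

    # --- index models (on unpreprocessed reflectance) ------------------
    t0 = time.time()
    index_search_rows: list[dict] = []
    ni_cal = vindex.nisdi_table(cal)
    ni_pred = vindex.nisdi_table(pred)
    model, m = vindex.fit_index_model(ni_cal, cal.water_content, ni_pred, pred.water_content, n_wavelengths=3)
    row = {
        "model_id": "NISDI-Linear",
        "features": "NISDI",
        "regressor": "Linear",
        "n_wavelengths": 3,
        **m.as_dict(),
    }
    model_rows.append(row)
    fitted_models["NISDI-Linear"] = FittedModel(
        "NISDI-Linear", model, table.grid, "nisdi", n_wavelengths=3
    )
    pr = vindex.pearson(ni_cal, cal.water_content)
    index_search_rows.append(
        {"family": "NISDI", "abs_r": abs(pr.r), "p": pr.p, "wavelengths_nm": [vindex.NISDI_SLOPE_NM, vindex.NISDI_REFL_NM]}
    )
    for family in config.index_families:
        res = vindex.search_pairs(cal, family)
        wl = res.best_wavelengths_nm(cal.grid)
        index_search_rows.append(
            {"family": family, "abs_r": res.best_abs_r, "p": res.best_p, "wavelengths_nm": list(wl)}
        )
        bi, bj = res.best_pair.band_i, res.best_pair.band_j
        iv_cal = vindex.pair_index(family, cal.reflectance[:, bi], cal.reflectance[:, bj])
        iv_pred = vindex.pair_index(family, pred.reflectance[:, bi], pred.reflectance[:, bj])
        model, m = vindex.fit_index_model(iv_cal, cal.water_content, iv_pred, pred.water_content)
        mid = f"{family}-Linear"
        model_rows.append(
            {"model_id": mid, "features": family, "regressor": "Linear", "n_wavelengths": 2, **m.as_dict()}
        )
        fitted_models[mid] = FittedModel(mid, model, table.grid, "pair", pair=(family, bi, bj), n_wavelengths=2)
    _stage("index-search", t0, seeds[3], families=len(index_search_rows))

    # --- wavelength selection ------------------------------------------
    t0 = time.time()
    selections: dict[str, wavesel.SelectionResult] = {}
    selection_rows: list[dict] = []
    y_cal = cal.water_content
    for name in config.selectors:
        if name == "CARS":
            sel = wavesel.cars(X_cal, y_cal, n_mc=config.cars_n_mc, seed=seeds[4], grid=cal.grid)
        elif name == "SPA":
            sel = wavesel.spa(X_cal, y_cal, max_vars=config.spa_max_vars, seed=seeds[5], grid=cal.grid)
        elif name == "UVE":
            sel = wavesel.uve(X_cal, y_cal, seed=seeds[6], grid=cal.grid)
        else:
            raise ValueError(f"unknown selector '{name}'")
        selections[name] = sel
        selection_rows.append(
            {
                "method": name,
                "n_selected": sel.n_selected,
                "wavelengths_nm": [round(float(w), 2) for w in sel.selected_wavelengths_nm],
                "best_trace_value": sel.best_trace_value,
            }
        )
    _stage("selection", t0, seeds[4], **{m: s.n_selected for m, s in selections.items()})

    # --- regression grid -----------------------------------------------
    t0 = time.time()
    feature_sets: list[tuple[str, np.ndarray]] = [
        (name, selections[name].selected_band_indices) for name in config.selectors
    ]
    if config.include_full_spectrum:
        feature_sets.append(("Full", np.arange(X_cal.shape[1])))
    for fs_name, idx in feature_sets:
        for kind in config.regressors:
            # preprocessed spectral designs can be exactly singular (SNV zeroes
            # every row mean; SG edges lie on one polynomial), so the grid's
            # MLR fits use the minimum-norm solution
            spec = regress.RegressorSpec(kind=kind, ann_seed=seeds[7], mlr_min_norm=True)
            model = regress.fit(spec, X_cal[:, idx], y_cal)
            r2_cal, rmse_cal = regress.evaluate_arrays(y_cal, model.predict(X_cal[:, idx]))
            r2_p, rmsep = regress.evaluate_arrays(pred.water_content, model.predict(X_pred[:, idx]))
            mid = f"{fs_name}-{kind}"
            model_rows.append(
                {
                    "model_id": mid,
                    "features": fs_name,
                    "regressor": kind,
                    "n_wavelengths": int(idx.size),
                    "r2_cal": r2_cal,
                    "rmse_cal": rmse_cal,
                    "r2_pred": r2_p,
                    "rmsep": rmsep,
                }
            )
            fitted_models[mid] = FittedModel(
                mid, model, table.grid, "bands", band_indices=idx,
                prep=chosen_prep, msc_reference=msc_ref, n_wavelengths=int(idx.size),
            )
    _stage("regression-grid", t0, seeds[7], rows=len(model_rows))

    # --- ranking --------------------------------------------------------
    chosen_row = rank_models(model_rows, config.rank_delta_r2)
    chosen = fitted_models[chosen_row["model_id"]]

    # --- water map ------------------------------------------------------
    t0 = time.time()
    h, w = config.map_cube_size
    cube, truth = simulate_cube(h, w, config.sim, VeinSpec(wc_offset=config.vein_wc_offset), seed=seeds[8])
    wmap = watermap.predict_map(cube, chosen.model, chosen.extractor(), model_id=chosen.model_id)
    watermap.render_map(wmap, out_dir / "water_map.png")
    from .synth import _leaf_geometry  # vein geometry matches the generator's

    mask, veins = _leaf_geometry(h, w, VeinSpec(wc_offset=config.vein_wc_offset))
    lamina = mask & ~veins
    map_summary = {
        "model_id": chosen.model_id,
        "masked_mean_pred": wmap.masked_mean(),
        "masked_mean_truth": float(np.nanmean(truth)),
        "vein_mean_pred": float(wmap.values[veins].mean()),
        "lamina_mean_pred": float(wmap.values[lamina].mean()),
        "clipped_pixels": wmap.clipped_pixels,
    }
    _stage("water-map", t0, seeds[8], size=f"{h}x{w}")

    # --- cross-species --------------------------------------------------
    t0 = time.time()
    cross_rows: list[dict] = []
    if config.cross_species:
        sim = config.sim
        # close relative: same spectral model, different wc range and seed
        apple_cfg = dataclasses.replace(sim, wc_range=(0.05, 0.65))
        apple = simulate_sample_table(max(60, config.n_samples // 3), apple_cfg, species="apple", role="external", seed=seeds[9])
        for row in cross_species_eval(chosen, apple):
            cross_rows.append({"species": "apple", **row})
        # different growth form: shifted wc range, stronger scatter, shallower troughs
        lettuce_cfg = dataclasses.replace(
            sim,
            wc_range=(0.55, 0.96),
            absorption_depth_per_wc=tuple(0.75 * d for d in sim.absorption_depth_per_wc),
            scatter_mult_sd=2.5 * sim.scatter_mult_sd,
            scatter_add_sd=2.5 * sim.scatter_add_sd,
        )
        lettuce = simulate_sample_table(max(60, config.n_samples // 3), lettuce_cfg, species="lettuce", role="external", seed=seeds[10])
        half = lettuce.n_samples // 2
        groups = ["with_veins"] * half + ["without_veins"] * (lettuce.n_samples - half)
        for row in cross_species_eval(chosen, lettuce, subgroups=groups):
            cross_rows.append({"species": "lettuce", **row})
    _stage("cross-species", t0, seeds[9], rows=len(cross_rows))

    report = StudyReport(
        seed=config.seed,
        n_samples=table.n_samples,
        n_calibration=cal.n_samples,
        n_prediction=pred.n_samples,
        prep_ranking=prep_ranking.to_dict(orient="records"),
        chosen_prep=chosen_prep_name,
        index_search=index_search_rows,
        selection=selection_rows,
        model_rows=model_rows,
        chosen_model=chosen_row,
        water_map=map_summary,
        cross_species=cross_rows,
    )
    report.to_json(out_dir / "report.json")
    return report
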