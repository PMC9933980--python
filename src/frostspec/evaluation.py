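"""Cross-validation protocol, accuracy metrics, and the model grid.

The protocol mirrors the study design: a k-fold random partition in which
the first k−1 folds take ⌈n/k⌉ samples and the last takes the remainder
(192 samples at k = 5 gives four test folds of 39 against 153 training
samples); the maximal-size folds are the evaluated repeats and results are
averaged over them.

Metrics: R² = 1 − Σ(ŷ−y)²/Σ(y−ȳ)², RMSE = √(Σ(ŷ−y)²/n), and the relative
predictive deviation RPD = 1/√(1−Rp²), equal to SD(y_test)/RMSEP when both
are computed on the same evaluation set.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import regression
from .selection import apply_subset, select_bands
from .simulate import SpectrumMatrix


class EvaluationError(ValueError):
    pass


def derive_seed(base_seed: int, *tokens) -> int:
    """Stable sub-seed from a base seed and context tokens (below 2^31)."""
    text = ":".join(str(t) for t in tokens)
    return (int(base_seed) ^ zlib.crc32(text.encode())) % (2**31 - 1)


@dataclass
class CVPlan:
    n: int
    k: int
    seed: int
    folds: list[np.ndarray]
    evaluated: list[int]  # fold ids serving as test repeats

    def train_indices(self, fold_id: int) -> np.ndarray:
        return np.concatenate([f for j, f in enumerate(self.folds) if j != fold_id])

    def test_indices(self, fold_id: int) -> np.ndarray:
        return self.folds[fold_id]


def make_cv_plan(n: int, k: int = 5, seed: int = 0) -> CVPlan:
    """Random k-fold partition; maximal-size folds are the evaluated repeats."""
    if k < 2:
        raise EvaluationError("need at least two folds")
    if n < k:
        raise EvaluationError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    size = int(np.ceil(n / k))
    folds, start = [], 0
    for j in range(k):
        stop = min(start + size, n) if j < k - 1 else n
        folds.append(np.sort(perm[start:stop]))
        start = stop
    sizes = [f.size for f in folds]
    if min(sizes) == 0:
        raise EvaluationError(f"empty fold in {n}-sample {k}-fold plan")
    max_size = max(sizes)
    evaluated = [j for j, s in enumerate(sizes) if s == max_size]
    return CVPlan(n=n, k=k, seed=seed, folds=folds, evaluated=evaluated)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """(R², RMSE) on one evaluated set; ȳ is the mean of that set."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise EvaluationError("need equal-length vectors of at least two samples")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise EvaluationError("zero variance in the reference values; R² undefined")
    ss_res = float(np.sum((y_pred - y_true) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / y_true.size))
    return r2, rmse


def compute_rpd(rp2: float) -> float:
    """RPD = 1/√(1 − Rp²)."""
    if rp2 >= 1:
        raise EvaluationError("RPD is undefined for Rp² >= 1")
    return float(1.0 / np.sqrt(1.0 - rp2))


@dataclass
class ModelResult:
    """One grid cell, metrics averaged over the evaluated repeats."""

    index: str
    band_method: str
    family: str
    n_bands: float
    Rc2: float
    RMSEC: float
    RMSEV: float
    Rp2: float
    RMSEP: float
    RPD: float
    seed: int


RESULT_COLUMNS = ["index", "band_method", "family", "n_bands", "Rc2", "RMSEC",
                  "RMSEV", "Rp2", "RMSEP", "RPD", "seed"]


class ModelGrid:
    """Grid of (target index × band-selection method × regression family).

    Parameters
    ----------
    spectra : SpectrumMatrix
        Feature matrix (typically preprocessed spectra).
    targets : DataFrame
        One column per target index (physiological components and/or LTRI),
        aligned row-wise with ``spectra``.
    indices, band_methods, families : sequences of names defining the grid.
    selection_mode : "per_fold" refits band selection on each repeat's
        calibration rows (leakage-safe default); "once" selects a single
        subset on all samples.
    selection_configs / model_params : per-method and per-family overrides.
    rmsev_fraction : inner calibration/validation split used for RMSEV.
    """

    def __init__(
        self,
        spectra: SpectrumMatrix,
        targets: pd.DataFrame,
        indices: Sequence[str] | None = None,
        band_methods: Sequence[str] = ("CARS", "SPA", "UVE", "NONE"),
        families: Sequence[str] = regression.FAMILIES,
        cv: CVPlan | None = None,
        selection_mode: str = "per_fold",
        selection_configs: dict | None = None,
        model_params: dict | None = None,
        rmsev_fraction: float = 0.2,
        max_repeats: int | None = None,
        seed: int = 0,
    ):
        if len(targets) != spectra.n_samples:
            raise EvaluationError("targets and spectra have different sample counts")
        if selection_mode not in ("per_fold", "once"):
            raise EvaluationError(f"unknown selection mode {selection_mode!r}")
        self.spectra = spectra
        self.targets = targets
        self.indices = list(indices) if indices is not None else list(targets.columns)
        missing = [c for c in self.indices if c not in targets.columns]
        if missing:
            raise EvaluationError(f"target columns missing from table: {missing}")
        self.band_methods = [m.upper() for m in band_methods]
        self.families = [f.upper() for f in families]
        self.cv = cv or make_cv_plan(spectra.n_samples, 5, seed)
        self.selection_mode = selection_mode
        self.selection_configs = selection_configs or {}
        self.model_params = model_params or {}
        self.rmsev_fraction = rmsev_fraction
        self.max_repeats = max_repeats
        self.seed = seed

    # -- selection cache: one subset per (index, method, fold) -------------
    def _subset_for(self, index: str, method: str, fold: int | None, cache: dict):
        key = (index, method, fold)
        if key not in cache:
            y = self.targets[index].to_numpy(dtype=float)
            if method == "NONE" or self.selection_mode == "once" or fold is None:
                X, rows = self.spectra, None
            else:
                rows = self.cv.train_indices(fold)
                X = self.spectra.copy()
                X.values = self.spectra.values[rows]
                X.sample_ids = [self.spectra.sample_ids[i] for i in rows]
                y = y[rows]
            cache[key] = select_bands(
                X, y, method,
                config=self.selection_configs.get(method),
                seed=derive_seed(self.seed, "select", index, method, fold),
            )
        return cache[key]

    def fit(self) -> "GridResults":
        repeats = self.cv.evaluated
        if self.max_repeats is not None:
            repeats = repeats[: self.max_repeats]
        results: list[ModelResult] = []
        failures: list[dict] = []
        cache: dict = {}
        for index in self.indices:
            y_all = self.targets[index].to_numpy(dtype=float)
            for method in self.band_methods:
                for family in self.families:
                    cell_seed = derive_seed(self.seed, "cell", index, method, family)
                    per_rep = []
                    try:
                        for fold in repeats:
                            fold_key = None if self.selection_mode == "once" else fold
                            subset = self._subset_for(index, method, fold_key, cache)
                            per_rep.append(
                                self._evaluate_cell(index, y_all, subset, family, fold)
                            )
                    except Exception as exc:
                        failures.append({"index": index, "band_method": method,
                                         "family": family, "error": str(exc)})
                        continue
                    arr = np.array(per_rep)  # rows: (n_bands, Rc2, RMSEC, RMSEV, Rp2, RMSEP)
                    mean = arr.mean(axis=0)
                    rp2 = float(mean[4])
                    results.append(ModelResult(
                        index=index, band_method=method, family=family,
                        n_bands=float(mean[0]), Rc2=float(mean[1]),
                        RMSEC=float(mean[2]), RMSEV=float(mean[3]),
                        Rp2=rp2, RMSEP=float(mean[5]),
                        RPD=compute_rpd(rp2) if rp2 < 1 else float("inf"),
                        seed=cell_seed,
                    ))
        return GridResults(self, results, failures)

    def _evaluate_cell(self, index, y_all, subset, family, fold):
        train = self.cv.train_indices(fold)
        test = self.cv.test_indices(fold)
        X_sel = apply_subset(self.spectra, subset)
        Xtr, ytr = X_sel.values[train], y_all[train]
        Xte, yte = X_sel.values[test], y_all[test]
        fold_seed = derive_seed(self.seed, "fit", index, subset.method, family, fold)
        spec = regression.RegressorSpec(
            family, dict(self.model_params.get(family, {})), seed=fold_seed
        )
        # inner 80/20 split of the calibration fold for validation RMSE
        rng = np.random.default_rng(derive_seed(self.seed, "inner", index,
                                                subset.method, family, fold))
        perm = rng.permutation(train.size)
        n_val = max(1, int(round(self.rmsev_fraction * train.size)))
        inner_val, inner_tr = perm[:n_val], perm[n_val:]
        inner_model = regression.fit(spec, Xtr[inner_tr], ytr[inner_tr])
        rmsev = float(np.sqrt(np.mean(
            (inner_model.predict(Xtr[inner_val]) - ytr[inner_val]) ** 2
        )))
        model = regression.fit(spec, Xtr, ytr)
        rc2, rmsec = compute_metrics(ytr, model.predict(Xtr))
        rp2, rmsep = compute_metrics(yte, model.predict(Xte))
        return (subset.n_bands, rc2, rmsec, rmsev, rp2, rmsep)


class GridResults:
    """Model-comparison table plus per-index best models."""

    def __init__(self, grid: ModelGrid, results: list[ModelResult], failures: list[dict]):
        self.grid = grid
        self.results = results
        self.failures = failures

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results], columns=RESULT_COLUMNS)

    def best_models(self) -> pd.DataFrame:
        """Per-index best cell by maximal Rp², ties broken by lower RMSEP."""
        t = self.table
        if t.empty:
            return t
        ordered = t.sort_values(["index", "Rp2", "RMSEP"],
                                ascending=[True, False, True])
        return ordered.groupby("index", sort=False).head(1).reset_index(drop=True)

    def summary(self) -> str:
        t = self.table
        lines = [
            "Model grid: "
            f"{len(self.grid.indices)} indices x {len(self.grid.band_methods)} "
            f"band methods x {len(self.grid.families)} families "
            f"-> {len(self.results)} cells ({len(self.failures)} failed)",
            "",
            "Best model per index (by Rp2, ties by RMSEP):",
        ]
        for _, row in self.best_models().iterrows():
            lines.append(
                f"  {row['index']:>5}: {row['band_method']}-{row['family']}"
                f"  Rp2={row['Rp2']:.3f}  RMSEP={row['RMSEP']:.3f}  RPD={row['RPD']:.3f}"
                f"  bands={row['n_bands']:.0f}"
            )
        if self.failures:
            lines.append("")
            lines.append("Failures:")
            for f in self.failures:
                lines.append(f"  {f['index']}-{f['band_method']}-{f['family']}: {f['error']}")
        return "\n".join(lines)


def run_grid(spectra: SpectrumMatrix, targets: pd.DataFrame, **kwargs) -> GridResults:
    """Functional wrapper: build a :class:`ModelGrid` and fit it."""
    return ModelGrid(spectra, targets, **kwargs).fit()
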