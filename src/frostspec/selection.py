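"""Wavelength selection: successive projections (SPA), competitive adaptive
reweighted sampling (CARS) and uninformative variable elimination (UVE).

All three are implemented from first principles on top of the native PLS:

* SPA grows candidate variable chains by repeatedly adding the column with
  the largest projection onto the orthogonal complement of the chain so far
  (minimum collinearity), and scores every chain length on a held-out split
  by multiple-linear-regression RMSE.
* CARS runs Monte-Carlo PLS fits on random calibration subsets, keeps
  variables by an exponentially decaying retention schedule applied to
  |PLS coefficient| weights (enforced deterministically, then by adaptive
  reweighted sampling), and returns the iteration subset with minimal
  cross-validated RMSE.
* UVE appends artificial noise variables, collects leave-one-out PLS
  coefficient matrices, forms the reliability c_j = mean(b_j)/sd(b_j) per
  variable, and retains real variables whose |c| exceeds the chosen quantile
  of |c| over the noise block.

Each selector is deterministic given its seed and returns a
:class:`BandSubset` carrying full diagnostics for replay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pls import max_components, pls_fit
from .simulate import SpectrumMatrix


class SelectionError(ValueError):
    pass


@dataclass
class SPAConfig:
    min_vars: int = 1
    max_vars: int = 30
    n_starts: int = 20  # number of random starting columns evaluated
    val_fraction: float = 0.3


@dataclass
class CARSConfig:
    mc_runs: int = 300
    cv_folds: int = 10
    max_pls_components: int = 10
    subset_fraction: float = 0.8


@dataclass
class UVEConfig:
    pls_components: int = 5
    n_noise_vars: int | None = None  # default: one per real band
    cutoff: float = 0.99
    noise_scale: float = 1e-10
    #: autoscale columns inside the PLS fits; keeps appended noise columns
    #: statistically exchangeable with uninformative real columns, so the
    #: noise-quantile threshold is calibrated (≈1 − cutoff false retention)
    scale: bool = True
    mode: str = "loo"  # or "mc"
    mc_resamples: int = 700
    mc_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.cutoff <= 1):
            raise SelectionError("cutoff must lie in (0, 1]")


@dataclass
class BandSubset:
    """A selected set of band positions plus the trace that produced it."""

    indices: np.ndarray  # sorted, unique, within [0, B)
    wavelengths: np.ndarray
    method: str  # SPA | CARS | UVE | NONE
    params: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and (
            np.any(np.diff(self.indices) <= 0) or self.indices[0] < 0
        ):
            raise SelectionError("subset indices must be sorted, unique and nonnegative")

    @property
    def n_bands(self) -> int:
        return int(self.indices.size)

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "params": self.params,
                "seed": self.seed,
                "indices": self.indices.tolist(),
                "wavelengths": np.asarray(self.wavelengths, dtype=float).tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "BandSubset":
        obj = json.loads(text)
        return cls(
            indices=np.asarray(obj["indices"], dtype=int),
            wavelengths=np.asarray(obj["wavelengths"], dtype=float),
            method=obj["method"],
            params=obj.get("params", {}),
            seed=obj.get("seed"),
        )


def none_subset(spectra: SpectrumMatrix) -> BandSubset:
    """The full-band (no selection) subset."""
    return BandSubset(
        indices=np.arange(spectra.n_bands),
        wavelengths=spectra.wavelengths.copy(),
        method="NONE",
    )


def apply_subset(spectra: SpectrumMatrix, subset: BandSubset) -> SpectrumMatrix:
    """Restrict a spectrum matrix to the subset's columns (order preserved)."""
    if subset.method == "NONE" and subset.indices.size == spectra.n_bands:
        return spectra.copy()
    if subset.indices.size and subset.indices[-1] >= spectra.n_bands:
        raise SelectionError(
            f"subset index {int(subset.indices[-1])} out of range for "
            f"{spectra.n_bands} bands"
        )
    out = spectra.copy()
    out.values = spectra.values[:, subset.indices]
    out.wavelengths = spectra.wavelengths[subset.indices]
    out.informative_bands = None
    out.provenance = spectra.provenance + [f"subset({subset.method},{subset.n_bands})"]
    return out


# ---------------------------------------------------------------------------
# SPA

def spa_chain(X: np.ndarray, start: int, max_vars: int, tol: float = 1e-12) -> list[int]:
    """Successive-projection chain from a starting column.

    At each step every remaining column is replaced by its residual after
    projection onto the most recently added column's residual (classical SPA
    recursion, equivalent to projecting onto the orthogonal complement of the
    chain's span) and the column of largest residual norm joins the chain.
    """
    R = np.array(X, dtype=float)
    n, B = R.shape
    chain = [int(start)]
    z = R[:, start].copy()
    for _ in range(1, min(max_vars, B)):
        zz = float(z @ z)
        if zz < tol:
            break  # chain span exhausted
        R = R - np.outer(z, (z @ R) / zz)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= np.sqrt(tol):
            break  # remaining columns are rank-deficient w.r.t. the chain
        chain.append(nxt)
        z = R[:, nxt].copy()
    return chain


def _mlr_rmse(Xc: np.ndarray, yc: np.ndarray, Xv: np.ndarray, yv: np.ndarray) -> float:
    A = np.column_stack([np.ones(len(yc)), Xc])
    beta, *_ = np.linalg.lstsq(A, yc, rcond=None)
    pred = np.column_stack([np.ones(len(yv)), Xv]) @ beta
    return float(np.sqrt(np.mean((pred - yv) ** 2)))


def spa_select(
    spectra: SpectrumMatrix,
    y: np.ndarray,
    config: SPAConfig | None = None,
    seed: int = 0,
) -> BandSubset:
    """SPA selection: best chain over random starts × chain lengths by
    held-out multiple-linear-regression RMSE."""
    config = config or SPAConfig()
    X = spectra.values
    y = np.asarray(y, dtype=float).ravel()
    n, B = X.shape
    if y.size != n:
        raise SelectionError("response length does not match the number of spectra")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, cal_idx = perm[:n_val], perm[n_val:]
    if cal_idx.size < 2:
        raise SelectionError("too few samples for an SPA calibration/validation split")
    max_vars = min(config.max_vars, B, cal_idx.size - 1)
    starts = (
        np.arange(B)
        if config.n_starts >= B
        else rng.choice(B, size=config.n_starts, replace=False)
    )
    best = (np.inf, None)
    curve: dict[int, float] = {}
    for start in starts:
        chain = spa_chain(X[cal_idx], int(start), max_vars)
        for k in range(config.min_vars, len(chain) + 1):
            sel = chain[:k]
            rmse = _mlr_rmse(X[np.ix_(cal_idx, sel)], y[cal_idx], X[np.ix_(val_idx, sel)], y[val_idx])
            if k not in curve or rmse < curve[k]:
                curve[k] = rmse
            if rmse < best[0]:
                best = (rmse, sel)
    if best[1] is None:
        raise SelectionError("SPA found no valid chain")
    indices = np.sort(np.asarray(best[1], dtype=int))
    return BandSubset(
        indices=indices,
        wavelengths=spectra.wavelengths[indices],
        method="SPA",
        params={"min_vars": config.min_vars, "max_vars": config.max_vars,
                "n_starts": config.n_starts, "val_fraction": config.val_fraction},
        diagnostics={"rmse_vs_k": dict(sorted(curve.items())), "best_rmse": best[0]},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# CARS

def cars_schedule(n_vars: int, mc_runs: int) -> np.ndarray:
    """Exponentially decreasing retention ratios r_i = a·e^{−k·i}.

    Endpoints fixed so r_1 = 1 (all variables eligible on the first run) and
    r_N = 2/B (two variables survive the final run).
    """
    if mc_runs < 2:
        raise SelectionError("CARS needs at least two Monte Carlo runs")
    k = np.log(n_vars / 2.0) / (mc_runs - 1)
    a = np.exp(k)
    i = np.arange(1, mc_runs + 1)
    return a * np.exp(-k * i)


def _cv_rmse_pls(X: np.ndarray, y: np.ndarray, n_components: int, folds: int,
                 rng: np.random.Generator) -> float:
    n = len(y)
    folds = min(folds, n)
    assign = rng.permutation(n) % folds
    sq = 0.0
    for f in range(folds):
        test = assign == f
        train = ~test
        a = max_components(int(train.sum()), X.shape[1], n_components)
        model = pls_fit(X[train], y[train], a)
        sq += float(np.sum((model.predict(X[test]) - y[test]) ** 2))
    return float(np.sqrt(sq / n))


def cars_select(
    spectra: SpectrumMatrix,
    y: np.ndarray,
    config: CARSConfig | None = None,
    seed: int = 0,
) -> BandSubset:
    """Competitive adaptive reweighted sampling over PLS coefficient weights."""
    config = config or CARSConfig()
    X = spectra.values
    y = np.asarray(y, dtype=float).ravel()
    n, B = X.shape
    if y.size != n:
        raise SelectionError("response length does not match the number of spectra")
    rng = np.random.default_rng(seed)
    ratios = cars_schedule(B, config.mc_runs)
    current = np.arange(B)
    retained_counts, rmse_path, subsets = [], [], []
    for i, r in enumerate(ratios):
        n_cal = max(2, int(round(config.subset_fraction * n)))
        rows = rng.choice(n, size=n_cal, replace=False)
        a = max_components(n_cal, current.size, config.max_pls_components)
        model = pls_fit(X[np.ix_(rows, current)], y[rows], a)
        w = np.abs(model.coef_)
        if w.sum() == 0:
            w = np.ones_like(w)
        w = w / w.sum()
        keep = max(2, int(round(r * B)))
        keep = min(keep, current.size)
        # enforced decay: top-`keep` variables by weight
        top = np.argsort(w)[::-1][:keep]
        # adaptive reweighted sampling within the retained count
        p = w[top] / w[top].sum()
        drawn = np.unique(rng.choice(top, size=keep, replace=True, p=p))
        current = np.sort(current[drawn])
        retained_counts.append(int(current.size))
        rmse = _cv_rmse_pls(
            X[:, current], y,
            max_components(n, current.size, config.max_pls_components),
            config.cv_folds, rng,
        )
        rmse_path.append(rmse)
        subsets.append(current.copy())
        if current.size <= 2:
            break
    best = int(np.argmin(rmse_path))
    indices = subsets[best]
    return BandSubset(
        indices=indices,
        wavelengths=spectra.wavelengths[indices],
        method="CARS",
        params={"mc_runs": config.mc_runs, "cv_folds": config.cv_folds,
                "max_pls_components": config.max_pls_components,
                "subset_fraction": config.subset_fraction},
        diagnostics={"retention_ratios": ratios.tolist(),
                     "retained_counts": retained_counts,
                     "cv_rmse": rmse_path,
                     "best_iteration": best},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# UVE

def uve_reliability(
    X: np.ndarray,
    y: np.ndarray,
    config: UVEConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Reliability c_j = mean(b_j)/sd(b_j) for real and appended noise variables."""
    n, B = X.shape
    n_noise = config.n_noise_vars if config.n_noise_vars is not None else B
    scale = config.noise_scale * float(np.mean(np.abs(X)) or 1.0)
    noise = rng.uniform(0.0, 1.0, size=(n, n_noise)) * scale
    Xaug = np.hstack([X, noise])
    if config.mode == "loo":
        row_sets = [np.delete(np.arange(n), i) for i in range(n)]
    elif config.mode == "mc":
        m = max(2, int(round(config.mc_fraction * n)))
        row_sets = [rng.choice(n, size=m, replace=False) for _ in range(config.mc_resamples)]
    else:
        raise SelectionError(f"unknown UVE mode {config.mode!r}")
    coefs = np.empty((len(row_sets), B + n_noise))
    for r, rows in enumerate(row_sets):
        a = max_components(rows.size, Xaug.shape[1], config.pls_components)
        coefs[r] = pls_fit(Xaug[rows], y[rows], a, scale=config.scale).coef_
    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = mean / sd
    c[(sd == 0) & (mean != 0)] = np.inf  # constant informative coefficient
    c[(sd == 0) & (mean == 0)] = 0.0
    return c[:B], c[B:]


def uve_select(
    spectra: SpectrumMatrix,
    y: np.ndarray,
    config: UVEConfig | None = None,
    seed: int = 0,
) -> BandSubset:
    """Uninformative variable elimination against appended noise variables."""
    config = config or UVEConfig()
    X = spectra.values
    y = np.asarray(y, dtype=float).ravel()
    if y.size != X.shape[0]:
        raise SelectionError("response length does not match the number of spectra")
    rng = np.random.default_rng(seed)
    c_real, c_noise = uve_reliability(X, y, config, rng)
    abs_noise = np.abs(c_noise[np.isfinite(c_noise)])
    if abs_noise.size == 0:
        raise SelectionError("no finite noise reliabilities; cannot set a threshold")
    threshold = float(np.max(abs_noise)) if config.cutoff >= 1.0 else float(
        np.quantile(abs_noise, config.cutoff)
    )
    indices = np.flatnonzero(np.abs(c_real) > threshold)
    return BandSubset(
        indices=indices,
        wavelengths=spectra.wavelengths[indices],
        method="UVE",
        params={"pls_components": config.pls_components,
                "n_noise_vars": config.n_noise_vars,
                "cutoff": config.cutoff, "mode": config.mode},
        diagnostics={"reliability_real": c_real.tolist(),
                     "threshold": threshold,
                     "noise_quantiles": {
                         "q50": float(np.quantile(abs_noise, 0.5)),
                         "q99": float(np.quantile(abs_noise, 0.99)),
                         "max": float(np.max(abs_noise))}},
        seed=seed,
    )


# ---------------------------------------------------------------------------

_METHODS = {"SPA": (spa_select, SPAConfig), "CARS": (cars_select, CARSConfig),
            "UVE": (uve_select, UVEConfig)}


def select_bands(
    spectra: SpectrumMatrix,
    y: np.ndarray,
    method: str,
    config=None,
    seed: int = 0,
) -> BandSubset:
    """Dispatch selection by method name; ``NONE`` returns all bands."""
    method = method.upper()
    if method == "NONE":
        return none_subset(spectra)
    if method not in _METHODS:
        raise SelectionError(f"unknown selection method {method!r}")
    func, default_cls = _METHODS[method]
    return func(spectra, y, config or default_cls(), seed=seed)
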