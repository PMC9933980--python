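"""Low Temperature Response Index (LTRI) construction.

The index is a signed, normalized linear combination of six standardized
physiological variables (SPAD chlorophyll, soluble sugar, malondialdehyde and
the CAT/POD/SOD antioxidant enzyme activities). It is built from a principal
component analysis of the variable correlation matrix:

1. standardize the n × 6 panel to z-scores;
2. eigendecompose the correlation matrix; keep components with eigenvalue
   λ > 1 (Kaiser rule);
3. per retained component j, convert the correlation-scale factor loadings
   LC_ij to linear combination coefficients LCC_ij = LC_ij / √λ_j (the unit
   eigenvector entries);
4. combine components into composite coefficients
   CSC_i = Σ_j LCC_ij · VC_j / CVC_m, weighting by each component's variance
   contribution VC_j and dividing by their cumulative contribution CVC_m;
5. normalize by the sum of absolute values, preserving signs, so the index
   weights satisfy Σ_i |w_i| = 1.

A sample's LTRI is the weighted sum of its z-scores; lower values indicate
greater freezing damage (the chlorophyll and enzyme terms carry the signs
that make healthy controls score high).

`LTRIModel` / `LTRIResults` wrap this chain in a fit/results interface; the
step functions below are the underlying operations and are usable directly,
e.g. to push externally computed loadings through the same chain.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import COMPONENTS


class LTRIError(ValueError):
    pass


@dataclass
class Standardizer:
    """Column means/sds of the fitted panel (sd with n−1 denominator)."""

    means: np.ndarray
    sds: np.ndarray
    columns: tuple[str, ...]

    def transform(self, panel: np.ndarray) -> np.ndarray:
        return (np.asarray(panel, dtype=float) - self.means) / self.sds

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sds + self.means


@dataclass
class PCAResult:
    """Correlation-matrix PCA: eigenvalues, correlation-scale loadings,
    variance contributions (%) and their cumulative sum."""

    eigenvalues: np.ndarray  # descending
    loadings: np.ndarray  # p × m, loading_ij = eigvec_ij * sqrt(λ_j)
    variance_contribution: np.ndarray  # percent, 100 λ / p
    cumulative_contribution: np.ndarray  # percent, nondecreasing to 100


@dataclass
class IndexCoefficients:
    """Coefficient chain outputs: per-component LCC columns, composite CSC,
    and the normalized index weights (Σ|w| = 1, signs preserved)."""

    lcc: np.ndarray  # p × m_retained
    csc: np.ndarray  # p
    weights: np.ndarray  # p
    retained: tuple[int, ...]


def standardize(panel: np.ndarray, columns: Sequence[str] = COMPONENTS) -> tuple[np.ndarray, Standardizer]:
    """Z-score each column; returns the z matrix and the fitted standardizer."""
    X = np.asarray(panel, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise LTRIError("panel must be a 2-D array with at least two rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = np.flatnonzero(sds == 0)
    if constant.size:
        name = columns[constant[0]] if len(columns) > constant[0] else str(constant[0])
        raise LTRIError(f"column {name!r} is constant; cannot standardize")
    scaler = Standardizer(means, sds, tuple(columns))
    return scaler.transform(X), scaler


def pca_correlation(Z: np.ndarray) -> PCAResult:
    """Eigendecomposition of the correlation matrix of a standardized panel.

    Loadings are emitted on the correlation scale (eigenvector · √λ), the
    convention under which LCC = loading/√λ recovers unit eigenvectors.
    Component signs are fixed so each column's largest-|loading| entry is
    positive.
    """
    Z = np.asarray(Z, dtype=float)
    corr = np.corrcoef(Z, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise LTRIError("correlation matrix contains non-finite entries")
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-|entry| loading positive per component
    for j in range(eigvecs.shape[1]):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    loadings = eigvecs * np.sqrt(eigvals)
    p = corr.shape[0]
    vc = 100.0 * eigvals / p
    return PCAResult(
        eigenvalues=eigvals,
        loadings=loadings,
        variance_contribution=vc,
        cumulative_contribution=np.cumsum(vc),
    )


def select_components(pca: PCAResult, rule: str = "eigenvalue_gt_1", k: int | None = None,
                      threshold: float | None = None) -> tuple[int, ...]:
    """Indices of retained components under the given rule (order preserved)."""
    if rule == "eigenvalue_gt_1":
        retained = tuple(int(j) for j in np.flatnonzero(pca.eigenvalues > 1.0))
    elif rule == "top_k":
        if k is None or k < 1:
            raise LTRIError("top_k rule requires k >= 1")
        retained = tuple(range(min(k, pca.eigenvalues.size)))
    elif rule == "cvc_threshold":
        if threshold is None:
            raise LTRIError("cvc_threshold rule requires a threshold")
        m = int(np.searchsorted(pca.cumulative_contribution, threshold) + 1)
        retained = tuple(range(min(m, pca.eigenvalues.size)))
    else:
        raise LTRIError(f"unknown component-selection rule {rule!r}")
    if not retained:
        raise LTRIError("no principal component retained under the selection rule")
    return retained


def linear_combination_coefficients(
    loadings: np.ndarray, eigenvalues: np.ndarray, retained: Sequence[int]
) -> np.ndarray:
    """LCC_ij = loading_ij / √λ_j for retained components (unit eigenvectors)."""
    loadings = np.asarray(loadings, dtype=float)
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    retained = list(retained)
    lam = eigenvalues[retained]
    if np.any(lam <= 0):
        raise LTRIError("retained eigenvalues must be positive")
    return loadings[:, retained] / np.sqrt(lam)


def composite_coefficients(
    lcc: np.ndarray, variance_contribution: np.ndarray, cumulative_m: float
) -> np.ndarray:
    """CSC_i = Σ_j LCC_ij · VC_j / CVC_m over the retained components."""
    if cumulative_m == 0:
        raise LTRIError("cumulative variance contribution is zero")
    vc = np.asarray(variance_contribution, dtype=float)
    return np.asarray(lcc, dtype=float) @ vc / cumulative_m


def normalize_coefficients(csc: np.ndarray) -> np.ndarray:
    """Percentage normalization: divide by Σ|CSC|, preserving signs."""
    csc = np.asarray(csc, dtype=float)
    total = np.abs(csc).sum()
    if total == 0:
        raise LTRIError("all composite coefficients are zero")
    return csc / total


def compute_ltri(Z: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Score standardized samples: LTRI = Σ_i w_i z_i."""
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        bad = np.argwhere(~np.isfinite(Z))[0]
        raise LTRIError(
            f"missing component value at sample {int(bad[0])}, variable "
            f"{COMPONENTS[int(bad[1])] if bad[1] < len(COMPONENTS) else int(bad[1])}"
        )
    return Z @ np.asarray(weights, dtype=float)


def coefficients_from_tables(
    eigenvalues: np.ndarray,
    loadings: np.ndarray,
    variance_contribution: np.ndarray | None = None,
    cumulative_m: float | None = None,
    retained: Sequence[int] | None = None,
) -> IndexCoefficients:
    """Run the LCC → CSC → normalization chain from explicit PCA tables.

    Accepts printed/rounded table values directly: if ``variance_contribution``
    is given it is used as-is (not recomputed from the eigenvalues).
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    loadings = np.asarray(loadings, dtype=float)
    if retained is None:
        retained = tuple(int(j) for j in np.flatnonzero(eigenvalues > 1.0))
        if not retained:
            raise LTRIError("no component has eigenvalue > 1")
    retained = tuple(retained)
    if variance_contribution is None:
        variance_contribution = 100.0 * eigenvalues / loadings.shape[0]
    vc = np.asarray(variance_contribution, dtype=float)[list(retained)]
    if cumulative_m is None:
        cumulative_m = float(vc.sum())
    lcc = linear_combination_coefficients(loadings, eigenvalues, retained)
    csc = composite_coefficients(lcc, vc, cumulative_m)
    weights = normalize_coefficients(csc)
    return IndexCoefficients(lcc=lcc, csc=csc, weights=weights, retained=retained)


def reference_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shipped reference PCA tables (eigenvalues/VC/CVC and factor loadings)
    for the six-variable tea-leaf panel; used by the worked example."""
    root = importlib.resources.files("frostspec") / "data"
    eigen = pd.read_csv(str(root / "pca_eigenvalues.csv"))
    load = pd.read_csv(str(root / "pca_loadings.csv"), index_col=0)
    return eigen, load


def equation_string(coefs: np.ndarray, lhs: str, ndigits: int = 3) -> str:
    """Render a coefficient vector as an equation like ``LTRI=0.081X1+...``."""
    parts = []
    for i, c in enumerate(coefs):
        c = round(float(c), ndigits)
        sign = "-" if c < 0 else ("+" if parts else "")
        parts.append(f"{sign}{abs(c):.{ndigits}f}X{i + 1}")
    return f"{lhs}={''.join(parts)}"


class LTRIModel:
    """Index model over an n × 6 biochemical panel.

    Parameters
    ----------
    panel : DataFrame or array
        Samples × components table; DataFrame columns must include
        SPAD, SS, MDA, CAT, POD, SOD.
    selection_rule : str
        Component-retention rule, default Kaiser (eigenvalue > 1).
    """

    def __init__(self, panel, selection_rule: str = "eigenvalue_gt_1", k: int | None = None):
        if isinstance(panel, pd.DataFrame):
            missing = [c for c in COMPONENTS if c not in panel.columns]
            if missing:
                raise LTRIError(f"panel is missing component columns {missing}")
            self.endog = panel.loc[:, list(COMPONENTS)].to_numpy(dtype=float)
            self.columns = COMPONENTS
        else:
            self.endog = np.asarray(panel, dtype=float)
            self.columns = tuple(f"X{i+1}" for i in range(self.endog.shape[1]))
        self.selection_rule = selection_rule
        self.k = k

    @classmethod
    def from_records(cls, records, **kwargs) -> "LTRIModel":
        from .design import records_to_frame

        return cls(records_to_frame(records), **kwargs)

    def fit(self) -> "LTRIResults":
        Z, scaler = standardize(self.endog, self.columns)
        pca = pca_correlation(Z)
        retained = select_components(pca, self.selection_rule, k=self.k)
        coefs = coefficients_from_tables(
            pca.eigenvalues,
            pca.loadings,
            pca.variance_contribution,
            float(pca.cumulative_contribution[retained[-1]]),
            retained,
        )
        # orientation convention: a positive chlorophyll (SPAD) weight makes
        # lower index values mean greater damage, since chlorophyll falls
        # under stress; the overall component sign is otherwise arbitrary
        if coefs.weights[0] < 0:
            coefs = IndexCoefficients(
                lcc=-coefs.lcc, csc=-coefs.csc, weights=-coefs.weights,
                retained=coefs.retained,
            )
        scores = compute_ltri(Z, coefs.weights)
        return LTRIResults(self, scaler, pca, coefs, scores)


class LTRIResults:
    """Fitted index: PCA diagnostics, coefficient chain, per-sample scores."""

    def __init__(self, model: LTRIModel, scaler: Standardizer, pca: PCAResult,
                 coefficients: IndexCoefficients, scores: np.ndarray):
        self.model = model
        self.standardizer = scaler
        self.pca = pca
        self.coefficients = coefficients
        self.scores = scores

    @property
    def weights(self) -> np.ndarray:
        return self.coefficients.weights

    def score(self, panel) -> np.ndarray:
        """LTRI for new samples, standardized with the fitted panel's scaling."""
        if isinstance(panel, pd.DataFrame):
            panel = panel.loc[:, list(self.model.columns)].to_numpy(dtype=float)
        Z = self.standardizer.transform(panel)
        return compute_ltri(Z, self.weights)

    def coefficient_table(self) -> pd.DataFrame:
        rows = {"CSC": self.coefficients.csc, "LTRI_weight": self.coefficients.weights}
        for col, j in enumerate(self.coefficients.retained):
            rows[f"LCC_Y{j + 1}"] = self.coefficients.lcc[:, col]
        return pd.DataFrame(rows, index=list(self.model.columns))

    def summary(self) -> str:
        pca, coefs = self.pca, self.coefficients
        lines = ["Low Temperature Response Index (correlation-PCA chain)",
                 "=" * 56,
                 f"samples: {self.model.endog.shape[0]}   variables: {len(self.model.columns)}",
                 f"retained components (λ > 1): {[j + 1 for j in coefs.retained]}",
                 "",
                 "component   eigenvalue   VC(%)    CVC(%)"]
        for j, lam in enumerate(pca.eigenvalues):
            lines.append(
                f"  Y{j + 1}          {lam:7.3f}   {pca.variance_contribution[j]:6.3f}  "
                f"{pca.cumulative_contribution[j]:7.3f}"
            )
        lines.append("")
        for col, j in enumerate(coefs.retained):
            lines.append(equation_string(coefs.lcc[:, col], f"Y{j + 1}"))
        lines.append(equation_string(coefs.csc, "Y"))
        lines.append(equation_string(coefs.weights, "LTRI"))
        lines.append("")
        lines.append("Lower LTRI indicates greater low-temperature damage.")
        return "\n".join(lines)
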