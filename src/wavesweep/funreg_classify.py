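"""Penalized functional multinomial regression in the wavelet domain.

Class membership of a genomic region is modelled as a softmax over
linear scores alpha_l + <xi, zeta_l>, where xi is the concatenated
wavelet-coefficient vector of the standardized statistic curves and the
zeta_l are the wavelet-domain regression coefficients, penalized with an
elastic net lambda * (gamma ||zeta||_1 + (1-gamma) ||zeta||_2^2).
Training runs 10-fold stratified cross-validation over the (gamma, j0)
grid with an internal lambda path search per combination, selects the
combination with the highest mean held-out accuracy, and refits on the
full training set.  Standardization is estimated inside each fold to
avoid leakage and frozen into the final model.

The solver is scikit-learn's LogisticRegression; the elastic-net
penalty above maps onto its parameterization exactly via
``l1_ratio = gamma / (2 - gamma)`` and ``C = 1 / ((2 - gamma) n lambda)``
(the factor 2 - gamma absorbs sklearn's 1/2 on the quadratic term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from . import wavelet_core
from .sumstats import (
    MOMENT_NAMES,
    N_STATS,
    STAT_NAMES,
    FeatureCurves,
    StandardizationParams,
    fit_standardization,
    standardize,
)
from .wavelet_core import WaveletBasisSpec

GAMMA_GRID = tuple(round(0.1 * i, 1) for i in range(11))
DEFAULT_SWEEP_THRESHOLD = 0.7
NEUTRAL_LABEL = "neutral"


def build_coefficient_vector(
    fc: FeatureCurves, spec: WaveletBasisSpec
) -> np.ndarray:
    """Concatenated wavelet coefficients xi of a standardized observation.

    Order: the nine statistic curves in their fixed row order, each as a
    length-p segment (fathers then mothers, coarse to fine), followed by
    the flattened 2-D transforms of the four r^2-moment blocks when
    present.
    """
    if not fc.standardized:
        raise ValueError("standardize curves before wavelet transformation")
    parts = [wavelet_core.dwt(fc.curves[s], spec) for s in range(N_STATS)]
    if fc.twod_blocks is not None:
        parts.extend(
            wavelet_core.dwt2(fc.twod_blocks[name], spec)
            for name in MOMENT_NAMES
        )
    return np.concatenate(parts)


def _design_matrix(
    features: list[FeatureCurves],
    sp: StandardizationParams,
    spec: WaveletBasisSpec,
) -> np.ndarray:
    return np.stack(
        [build_coefficient_vector(standardize(fc, sp), spec) for fc in features]
    )


def _sklearn_params(gamma: float, lam: float, n: int) -> dict:
    c = 1.0 / ((2.0 - gamma) * n * lam)
    if gamma == 0.0:
        return dict(l1_ratio=0.0, C=c, solver="lbfgs",
                    max_iter=5000, tol=1e-10)
    return dict(l1_ratio=gamma / (2.0 - gamma), C=c,
                solver="saga", max_iter=2000, tol=1e-5)


def _fit_multinomial(
    X: np.ndarray, y: np.ndarray, gamma: float, lam: float
) -> LogisticRegression:
    clf = LogisticRegression(**_sklearn_params(gamma, lam, len(y)))
    with warnings.catch_warnings():
        # the extremes of the lambda path need not converge fully; the
        # CV winner is refit and path truncation is standard practice
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf

def _symmetric_coefs(
    clf: LogisticRegression, classes: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(alpha, Z) in the symmetric no-reference-class parameterization."""
    if len(classes) == 2:
        # sklearn stores a single contrast for binary problems
        w = clf.coef_[0]
        b = clf.intercept_[0]
        Z = np.stack([-w / 2, w / 2], axis=1)
        alpha = np.array([-b / 2, b / 2])
    else:
        Z = clf.coef_.T.copy()
        alpha = clf.intercept_.copy()
    order = [list(clf.classes_).index(c) for c in classes]
    if len(classes) > 2:
        Z = Z[:, order]
        alpha = alpha[order]
    return alpha, Z


def _lambda_path(
    X: np.ndarray, y: np.ndarray, classes: list[str],
    gamma: float, n_lambda: int,
) -> np.ndarray:
    """Descending log-spaced lambda grid anchored at the glmnet-style
    smallest lambda that zeroes all coefficients (l1 part)."""
    n = len(y)
    Y = np.stack([(y == c).astype(float) for c in classes], axis=1)
    R = Y - Y.mean(axis=0)
    lmax = np.abs(X.T @ R).max() / (n * max(gamma, 0.05))
    lmax = max(lmax, 1e-8)
    return np.logspace(np.log10(lmax), np.log10(lmax) - 3, n_lambda)


@dataclass
class ClassifierModel:
    """Fitted wavelet-domain multinomial classifier."""

    classes: list[str]
    alpha: np.ndarray  # (K,)
    Z: np.ndarray  # (D, K), D = 9p (+ 4 (p/2)^2 with 2-D statistics)
    gamma: float
    lam: float
    basis: WaveletBasisSpec
    standardization: StandardizationParams
    include_2d: bool = False
    cv_report: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        sp = self.standardization
        d = {
            "kind": "classifier",
            "classes": self.classes,
            "alpha": self.alpha,
            "Z": self.Z,
            "gamma": self.gamma,
            "lambda": self.lam,
            "wavelet": {
                "family": self.basis.family,
                "vanishing_moments": self.basis.vanishing_moments,
                "p": self.basis.p,
                "j0": self.basis.j0,
            },
            "standardization": {
                "means": sp.means,
                "sds": sp.sds,
                "block_means": sp.block_means,
                "block_sds": sp.block_sds,
            },
            "include_2d": self.include_2d,
            "stat_names": list(STAT_NAMES),
        }
        if self.cv_report is not None:
            d["cv_report"] = self.cv_report.to_dict(orient="records")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        w = d["wavelet"]
        sp = d["standardization"]
        blocks_m = sp.get("block_means")
        blocks_s = sp.get("block_sds")
        return cls(
            classes=list(d["classes"]),
            alpha=np.asarray(d["alpha"], dtype=float),
            Z=np.asarray(d["Z"], dtype=float),
            gamma=float(d["gamma"]),
            lam=float(d["lambda"]),
            basis=WaveletBasisSpec(
                family=w["family"],
                vanishing_moments=int(w["vanishing_moments"]),
                p=int(w["p"]),
                j0=int(w["j0"]),
            ),
            standardization=StandardizationParams(
                means=np.asarray(sp["means"], dtype=float),
                sds=np.asarray(sp["sds"], dtype=float),
                block_means=None if blocks_m is None else {
                    k: np.asarray(v, dtype=float) for k, v in blocks_m.items()
                },
                block_sds=None if blocks_s is None else {
                    k: np.asarray(v, dtype=float) for k, v in blocks_s.items()
                },
            ),
            include_2d=bool(d.get("include_2d", False)),
            cv_report=(
                pd.DataFrame(d["cv_report"]) if "cv_report" in d else None
            ),
        )


def fit_classifier(
    features: list[FeatureCurves],
    labels: list[str],
    gamma_grid: tuple[float, ...] = GAMMA_GRID,
    level_grid: tuple[int, ...] | None = None,
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 16,
    family: str = wavelet_core.LEAST_ASYMMETRIC,
    vanishing_moments: int = 8,
) -> ClassifierModel:
    """Cross-validated elastic-net multinomial fit over (gamma, j0).

    For every grid combination, ten stratified folds are scored over a
    shared lambda path (standardization refit inside each fold); the
    combination with the highest mean held-out accuracy wins, ties
    preferring smaller j0 (smoother coefficient functions), then larger
    gamma (sparser), then larger lambda.  The winner is refit on the
    full training set.
    """
    if len(features) != len(labels):
        raise ValueError("features and labels length mismatch")
    if not gamma_grid or (level_grid is not None and not level_grid):
        raise ValueError("empty search grid")
    y = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < folds:
        raise ValueError(
            f"every class needs >= {folds} observations for stratified "
            f"{folds}-fold CV; got {counts}"
        )
    if len(set(counts.values())) > 1:
        import logging
        logging.getLogger(__name__).warning(
            "unbalanced classes %s; balanced training data is recommended",
            counts,
        )
    p = features[0].p
    if level_grid is None:
        level_grid = wavelet_core.level_grid(p)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    sp_full = fit_standardization(features)

    records = []
    best = None  # (acc, -j0 pref, gamma pref, lam, j0, gamma)
    for j0 in level_grid:
        spec = WaveletBasisSpec(family=family,
                                vanishing_moments=vanishing_moments,
                                p=p, j0=j0)
        X_full = _design_matrix(features, sp_full, spec)
        fold_designs = []
        for tr, va in splits:
            sp = fit_standardization([features[i] for i in tr])
            X_tr = _design_matrix([features[i] for i in tr], sp, spec)
            X_va = _design_matrix([features[i] for i in va], sp, spec)
            fold_designs.append((X_tr, y[tr], X_va, y[va]))
        for gamma in gamma_grid:
            path = _lambda_path(X_full, y, classes, gamma, n_lambda)
            acc = np.zeros(len(path))
            for X_tr, y_tr, X_va, y_va in fold_designs:
                for k, lam in enumerate(path):
                    clf = _fit_multinomial(X_tr, y_tr, gamma, lam)
                    acc[k] += (clf.predict(X_va) == y_va).mean()
            acc /= len(fold_designs)
            k_best = int(np.argmax(acc))  # path descending: tie -> larger lam
            records.append(
                dict(gamma=gamma, j0=j0, lam=path[k_best],
                     cv_accuracy=acc[k_best])
            )
            key = (acc[k_best], -j0, gamma, path[k_best])
            if best is None or key > best[0]:
                best = (key, gamma, j0, path[k_best])

    _, gamma, j0, lam = best
    spec = WaveletBasisSpec(family=family, vanishing_moments=vanishing_moments,
                            p=p, j0=j0)
    X_full = _design_matrix(features, sp_full, spec)
    clf = _fit_multinomial(X_full, y, gamma, lam)
    alpha, Z = _symmetric_coefs(clf, classes)
    return ClassifierModel(
        classes=classes,
        alpha=alpha,
        Z=Z,
        gamma=gamma,
        lam=lam,
        basis=spec,
        standardization=sp_full,
        include_2d=features[0].twod_blocks is not None,
        cv_report=pd.DataFrame(records),
    )


def _softmax(eta: np.ndarray) -> np.ndarray:
    e = np.exp(eta - eta.max())
    return e / e.sum()


def predict_proba(model: ClassifierModel, fc: FeatureCurves) -> np.ndarray:
    """Class probabilities for one unstandardized observation."""
    xi = build_coefficient_vector(
        standardize(fc, model.standardization), model.basis
    )
    if xi.shape[0] != model.Z.shape[0]:
        raise ValueError(
            f"coefficient vector length {xi.shape[0]} does not match model "
            f"({model.Z.shape[0]})"
        )
    return _softmax(model.alpha + xi @ model.Z)


def call_class(
    probs: np.ndarray,
    classes: list[str],
    sweep_threshold: float = DEFAULT_SWEEP_THRESHOLD,
    neutral_label: str = NEUTRAL_LABEL,
) -> str:
    """Thresholded class call: a non-neutral argmax whose probability is
    <= ``sweep_threshold`` is demoted to neutral; ties break to neutral."""
    probs = np.asarray(probs, dtype=float)
    top = probs.max()
    winners = [classes[i] for i in np.flatnonzero(probs >= top - 1e-12)]
    label = neutral_label if neutral_label in winners else winners[0]
    if label != neutral_label and top <= sweep_threshold:
        return neutral_label
    return label


@dataclass
class CoefficientFunctions:
    """Reconstructed beta(t) curves and wavelet-domain zeta per class/stat."""

    classes: list[str]
    beta: dict[str, dict[str, np.ndarray]]  # class -> stat -> (p,) curve
    zeta: dict[str, dict[str, np.ndarray]]  # class -> stat -> (p,) segment


def coefficient_functions(model: ClassifierModel) -> CoefficientFunctions:
    """Reconstruct the per-class per-statistic coefficient functions."""
    p = model.basis.p
    beta: dict[str, dict[str, np.ndarray]] = {}
    zeta: dict[str, dict[str, np.ndarray]] = {}
    for li, label in enumerate(model.classes):
        beta[label] = {}
        zeta[label] = {}
        for s, stat in enumerate(STAT_NAMES):
            seg = model.Z[s * p : (s + 1) * p, li]
            zeta[label][stat] = seg
            beta[label][stat] = wavelet_core.reconstruct_beta(seg, model.basis)
    return CoefficientFunctions(classes=model.classes, beta=beta, zeta=zeta)


def reliability_curve(
    model: ClassifierModel,
    features: list[FeatureCurves],
    labels: list[str],
    positive_class: str = "sweep",
    window_width: float = 0.05,
    step: float = 0.001,
) -> pd.DataFrame:
    """Calibration table over sliding probability windows.

    950 overlapping windows of the given width at the given step; per
    non-empty window, the mean predicted probability of the positive
    class and the empirical positive fraction.  The final window's upper
    edge is closed so probability 1.0 is counted.
    """
    if not features:
        raise ValueError("empty test set")
    pidx = model.classes.index(positive_class)
    probs = np.array([predict_proba(model, fc)[pidx] for fc in features])
    truth = np.asarray([lab == positive_class for lab in labels], dtype=float)
    rows = []
    n_windows = int(round((1.0 - window_width) / step)) + 1
    for i in range(n_windows):
        lo = i * step
        hi = lo + window_width
        if hi >= 1.0 - 1e-9:
            mask = (probs >= lo) & (probs <= hi + 1e-12)
        else:
            mask = (probs >= lo) & (probs < hi)
        if not mask.any():
            continue
        rows.append(
            dict(
                bin_start=lo,
                mean_predicted=probs[mask].mean(),
                observed_fraction=truth[mask].mean(),
                count=int(mask.sum()),
            )
        )
    return pd.DataFrame(rows)
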