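"""Penalized functional multi-response linear regression.

Selection parameters (selection coefficient s, initial beneficial-allele
frequency f, and onset or donor-split time T) are predicted jointly from
the wavelet-coefficient vector xi of a region's standardized statistic
curves: sigma_l = alpha_l + <xi, zeta_l> + eps.  Responses are
log10-transformed where flagged (s and f always; T by default, matching
their log-uniform priors) and standardized to zero mean and unit SD on
the training set; predictions are mapped back to the natural scale.

The penalty is the same elastic net as the classifier, applied jointly
across responses with a single lambda (grouped L2,1 lasso term via
scikit-learn's MultiTaskElasticNet; exact Ridge at gamma = 0, where the
mapping is simply alpha_ridge = lambda).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import MultiTaskElasticNet, Ridge
from sklearn.model_selection import KFold

from . import wavelet_core
from .funreg_classify import GAMMA_GRID, _design_matrix, build_coefficient_vector
from .sumstats import FeatureCurves, StandardizationParams, fit_standardization, standardize
from .wavelet_core import WaveletBasisSpec

logger = logging.getLogger(__name__)

DEFAULT_LOG_RESPONSES = ("s", "f", "T")


@dataclass
class SelectionParameters:
    """Natural-scale selection parameters for one region.

    ``s``: selection coefficient per generation; ``f``: initial
    beneficial-allele frequency; ``T``: selection onset time in
    generations before present (or the donor-recipient split time for
    the adaptive-introgression predictor).
    """

    s: float | None = None
    f: float | None = None
    T: float | None = None
    extra: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, values: dict[str, float]) -> "SelectionParameters":
        known = {k: values[k] for k in ("s", "f", "T") if k in values}
        extra = {k: v for k, v in values.items() if k not in ("s", "f", "T")}
        return cls(**known, extra=extra)

    def as_dict(self) -> dict[str, float]:
        out = {k: v for k, v in
               (("s", self.s), ("f", self.f), ("T", self.T)) if v is not None}
        out.update(self.extra)
        return out


@dataclass
class PredictorModel:
    """Fitted wavelet-domain multi-response linear predictor."""

    responses: list[str]
    alpha: np.ndarray  # (q,) intercepts on the standardized log scale
    Z: np.ndarray  # (D, q)
    gamma: float
    lam: float
    basis: WaveletBasisSpec
    standardization: StandardizationParams
    log_flags: dict[str, bool]
    y_means: np.ndarray  # (q,) on the (possibly log) scale
    y_sds: np.ndarray
    include_2d: bool = False
    train_xi_norm: float = 0.0  # max ||xi|| seen in training
    cv_report: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        sp = self.standardization
        d = {
            "kind": "predictor",
            "responses": self.responses,
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
            "log_flags": self.log_flags,
            "y_means": self.y_means,
            "y_sds": self.y_sds,
            "include_2d": self.include_2d,
            "train_xi_norm": self.train_xi_norm,
        }
        if self.cv_report is not None:
            d["cv_report"] = self.cv_report.to_dict(orient="records")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PredictorModel":
        w = d["wavelet"]
        sp = d["standardization"]
        blocks_m = sp.get("block_means")
        blocks_s = sp.get("block_sds")
        return cls(
            responses=list(d["responses"]),
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
            log_flags={k: bool(v) for k, v in d["log_flags"].items()},
            y_means=np.asarray(d["y_means"], dtype=float),
            y_sds=np.asarray(d["y_sds"], dtype=float),
            include_2d=bool(d.get("include_2d", False)),
            train_xi_norm=float(d.get("train_xi_norm", 0.0)),
        )


def _transform_responses(
    responses: pd.DataFrame, log_flags: dict[str, bool]
) -> np.ndarray:
    cols = []
    for name in responses.columns:
        vals = responses[name].to_numpy(dtype=float)
        if log_flags.get(name, False):
            if np.any(vals <= 0):
                raise ValueError(
                    f"response {name!r} must be positive for log scaling"
                )
            vals = np.log10(vals)
        cols.append(vals)
    return np.stack(cols, axis=1)


def _fit_linear(
    X: np.ndarray, Y: np.ndarray, gamma: float, lam: float
):
    n = X.shape[0]
    if gamma == 0.0:
        est = Ridge(alpha=lam, solver="cholesky")
    else:
        est = MultiTaskElasticNet(
            alpha=lam * (2.0 - gamma) / (2.0 * n),
            l1_ratio=gamma / (2.0 - gamma),
            max_iter=5000,
            tol=1e-8,
        )
    with warnings.catch_warnings():
        # lambda-path extremes need not converge fully; the winner is refit
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, Y)
    return est


def _lambda_path_linear(
    X: np.ndarray, Y: np.ndarray, gamma: float, n_lambda: int
) -> np.ndarray:
    # KKT zero point of the paper-form objective: lambda*gamma >= 2||X^T R||
    R = Y - Y.mean(axis=0)
    lmax = 2.0 * np.linalg.norm(X.T @ R, axis=1).max() / max(gamma, 0.05)
    lmax = max(lmax, 1e-6)
    return np.logspace(np.log10(lmax), np.log10(lmax) - 4, n_lambda)


def fit_predictor(
    features: list[FeatureCurves],
    responses: pd.DataFrame,
    log_responses: tuple[str, ...] = DEFAULT_LOG_RESPONSES,
    gamma_grid: tuple[float, ...] = GAMMA_GRID,
    level_grid: tuple[int, ...] | None = None,
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 16,
    family: str = wavelet_core.LEAST_ASYMMETRIC,
    vanishing_moments: int = 8,
) -> PredictorModel:
    """Cross-validated joint elastic-net fit of all responses.

    (gamma, j0) are chosen by minimum mean CV squared error summed over
    the standardized log-scale responses, with an internal lambda path
    per combination; the winner is refit on the full training set.
    """
    if len(features) != len(responses):
        raise ValueError("features and responses length mismatch")
    if len(features) < folds:
        raise ValueError(f"need >= {folds} observations for {folds}-fold CV")
    names = list(responses.columns)
    log_flags = {name: name in log_responses for name in names}
    Y_log = _transform_responses(responses, log_flags)
    if not np.isfinite(Y_log).all():
        raise ValueError("responses must be finite")
    p = features[0].p
    if level_grid is None:
        level_grid = wavelet_core.level_grid(p)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(np.zeros(len(features))))
    sp_full = fit_standardization(features)

    def scale_y(Y, means, sds):
        return (Y - means) / sds

    records = []
    best = None
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
            mu = Y_log[tr].mean(axis=0)
            sd = Y_log[tr].std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            fold_designs.append(
                (X_tr, scale_y(Y_log[tr], mu, sd),
                 X_va, scale_y(Y_log[va], mu, sd))
            )
        mu_full = Y_log.mean(axis=0)
        sd_full = Y_log.std(axis=0)
        sd_full = np.where(sd_full == 0, 1.0, sd_full)
        Y_full = scale_y(Y_log, mu_full, sd_full)
        for gamma in gamma_grid:
            path = _lambda_path_linear(X_full, Y_full, gamma, n_lambda)
            mse = np.zeros(len(path))
            for X_tr, Y_tr, X_va, Y_va in fold_designs:
                for k, lam in enumerate(path):
                    est = _fit_linear(X_tr, Y_tr, gamma, lam)
                    pred = est.predict(X_va)
                    mse[k] += float(((pred - Y_va) ** 2).sum(axis=1).mean())
            mse /= len(fold_designs)
            k_best = int(np.argmin(mse))  # path descending: tie -> larger lam
            records.append(
                dict(gamma=gamma, j0=j0, lam=path[k_best], cv_mse=mse[k_best])
            )
            key = (-mse[k_best], -j0, gamma, path[k_best])
            if best is None or key > best[0]:
                best = (key, gamma, j0, path[k_best])

    _, gamma, j0, lam = best
    spec = WaveletBasisSpec(family=family, vanishing_moments=vanishing_moments,
                            p=p, j0=j0)
    X_full = _design_matrix(features, sp_full, spec)
    mu_full = Y_log.mean(axis=0)
    sd_full = Y_log.std(axis=0)
    sd_full = np.where(sd_full == 0, 1.0, sd_full)
    est = _fit_linear(X_full, scale_y(Y_log, mu_full, sd_full), gamma, lam)
    Z = est.coef_.T if est.coef_.ndim == 2 else est.coef_[:, None]
    alpha = np.atleast_1d(est.intercept_)
    return PredictorModel(
        responses=names,
        alpha=alpha.astype(float),
        Z=np.asarray(Z, dtype=float),
        gamma=gamma,
        lam=lam,
        basis=spec,
        standardization=sp_full,
        log_flags=log_flags,
        y_means=mu_full,
        y_sds=sd_full,
        include_2d=features[0].twod_blocks is not None,
        train_xi_norm=float(np.linalg.norm(X_full, axis=1).max()),
        cv_report=pd.DataFrame(records),
    )


def predict_params(
    model: PredictorModel, fc: FeatureCurves
) -> SelectionParameters:
    """Natural-scale parameter predictions for one unstandardized region.

    The affine prediction happens on the standardized log scale and is
    unstandardized and exponentiated per the model's response scaling.
    Inputs far outside the training envelope are not clipped — accuracy
    degrades outside the training range — but a warning is logged when
    the coefficient-vector norm exceeds it.
    """
    xi = build_coefficient_vector(
        standardize(fc, model.standardization), model.basis
    )
    if xi.shape[0] != model.Z.shape[0]:
        raise ValueError("coefficient vector incompatible with model")
    if model.train_xi_norm and np.linalg.norm(xi) > 1.5 * model.train_xi_norm:
        logger.warning(
            "%s: input lies outside the training envelope; predictions "
            "may be unreliable", fc.obs_id,
        )
    z = model.alpha + xi @ model.Z  # standardized log scale
    vals = z * model.y_sds + model.y_means
    out = {}
    for i, name in enumerate(model.responses):
        out[name] = float(10 ** vals[i]) if model.log_flags[name] else float(vals[i])
    return SelectionParameters.from_mapping(out)


def evaluate_predictions(
    pred: pd.DataFrame,
    truth: pd.DataFrame,
    scale: str = "natural",
    log_flags: dict[str, bool] | None = None,
    y_means: np.ndarray | None = None,
    y_sds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-response RMSE and MAE on the requested scale.

    ``scale`` is one of ``natural``, ``unstandardized_log`` (log10 of the
    log-flagged responses) or ``standardized_log`` (additionally z-scored
    with the supplied training moments).  MAE <= RMSE always holds and is
    asserted.
    """
    if len(pred) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    names = list(truth.columns)
    P = pred[names].to_numpy(dtype=float)
    T = truth[names].to_numpy(dtype=float)
    if scale in ("unstandardized_log", "standardized_log"):
        flags = log_flags or {n: True for n in names}
        for i, n in enumerate(names):
            if flags.get(n, False):
                P[:, i] = np.log10(P[:, i])
                T[:, i] = np.log10(T[:, i])
        if scale == "standardized_log":
            if y_means is None or y_sds is None:
                raise ValueError("standardized_log needs y_means and y_sds")
            P = (P - y_means) / y_sds
            T = (T - y_means) / y_sds
    elif scale != "natural":
        raise ValueError(f"unknown scale {scale!r}")
    err = P - T
    rmse = np.sqrt((err**2).mean(axis=0))
    mae = np.abs(err).mean(axis=0)
    assert np.all(mae <= rmse + 1e-12), "MAE must not exceed RMSE"
    return pd.DataFrame({"rmse": rmse, "mae": mae}, index=names)
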