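"""Weighted soft-margin SVM trained by solving the dual quadratic program.

The primal problem minimizes ``0.5 |w|^2 + sum_i C_ii xi_i`` subject to
``y_i (w.x_i + b) >= 1 - xi_i``, where the per-sample cost ``C_ii = C d_i``
scales the misclassification penalty by a sequence weight ``d_i`` (used to
correct taxonomic overrepresentation in the training set). The dual,

    max_a  sum_i a_i - 0.5 sum_ij a_i a_j y_i y_j K(x_i, x_j)
    s.t.   sum_i a_i y_i = 0,   0 <= a_i <= C d_i,

is solved with a deterministic sequential-minimal-optimization (SMO) loop
using maximal-violating-pair working-set selection, the same scheme used by
exact library solvers; the per-sample box bound is the only departure from
the textbook dual. Decision values are ``f(x) = sum_i a_i y_i K(x_i, x) + b``
with class GTA (-1) for ``f < 0`` and virus (+1) otherwise; an exact tie
``f = 0`` is reported as virus and logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from gtascan.features import FeatureSpec, SequenceFeaturizer, _data_path

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


def kernel_eval(kernel: str, xi: np.ndarray, xj: np.ndarray, gamma: float | None = None):
    """Evaluate K(xi, xj) row-wise; 'linear' is the dot product, 'rbf' is Gaussian."""
    xi = np.atleast_2d(np.asarray(xi, float))
    xj = np.atleast_2d(np.asarray(xj, float))
    if xi.shape[1] != xj.shape[1]:
        raise ValueError("kernel arguments must have equal width")
    if kernel == "linear":
        return xi @ xj.T
    if kernel == "rbf":
        g = 1.0 / xi.shape[1] if gamma is None else gamma
        sq = (
            np.sum(xi**2, axis=1)[:, None]
            + np.sum(xj**2, axis=1)[None, :]
            - 2.0 * (xi @ xj.T)
        )
        return np.exp(-g * np.maximum(sq, 0.0))
    raise ValueError(f"unknown kernel {kernel!r}")


def _smo_solve(K: np.ndarray, y: np.ndarray, box: np.ndarray, tol: float, max_iter: int):
    """Maximal-violating-pair SMO on the dual with per-sample box bounds.

    Minimizes 0.5 a'Qa - e'a with Q = yy' * K subject to y'a = 0 and
    0 <= a <= box. Returns (alpha, gradient, n_iter, gap).
    """
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K
    alpha = np.zeros(n)
    G = -np.ones(n)  # gradient of the objective at alpha = 0
    tau = 1e-12
    minus_yG = np.empty(n)
    for it in range(max_iter):
        np.multiply(-y, G, out=minus_yG)
        up = ((y == 1) & (alpha < box - tau)) | ((y == -1) & (alpha > tau))
        low = ((y == -1) & (alpha < box - tau)) | ((y == 1) & (alpha > tau))
        if not up.any() or not low.any():
            return alpha, G, it, 0.0
        i = np.flatnonzero(up)[np.argmax(minus_yG[up])]
        j = np.flatnonzero(low)[np.argmin(minus_yG[low])]
        gap = minus_yG[i] - minus_yG[j]
        if gap <= tol:
            return alpha, G, it, float(gap)

        ai_old, aj_old = alpha[i], alpha[j]
        Ci, Cj = box[i], box[j]
        if y[i] != y[j]:
            quad = max(Q[i, i] + Q[j, j] + 2.0 * Q[i, j], tau)
            delta = (-G[i] - G[j]) / quad
            diff = ai_old - aj_old
            ai, aj = ai_old + delta, aj_old + delta
            if diff > 0:
                if aj < 0:
                    aj, ai = 0.0, diff
            else:
                if ai < 0:
                    ai, aj = 0.0, -diff
            if diff > Ci - Cj:
                if ai > Ci:
                    ai, aj = Ci, Ci - diff
            else:
                if aj > Cj:
                    aj, ai = Cj, Cj + diff
        else:
            quad = max(Q[i, i] + Q[j, j] - 2.0 * Q[i, j], tau)
            delta = (G[i] - G[j]) / quad
            tot = ai_old + aj_old
            ai, aj = ai_old - delta, aj_old + delta
            if tot > Ci:
                if ai > Ci:
                    ai, aj = Ci, tot - Ci
            else:
                if aj < 0:
                    aj, ai = 0.0, tot
            if tot > Cj:
                if aj > Cj:
                    aj, ai = Cj, tot - Cj
            else:
                if ai < 0:
                    ai, aj = 0.0, tot
        dai, daj = ai - ai_old, aj - aj_old
        if dai == 0.0 and daj == 0.0:
            return alpha, G, it, float(gap)
        alpha[i], alpha[j] = ai, aj
        G += Q[:, i] * dai + Q[:, j] * daj
    raise RuntimeError(
        f"QP solver did not converge in {max_iter} iterations (gap {gap:.3g})"
    )


class WeightedSVC:
    """Binary soft-margin SVM with per-sample cost bounds ``C * d_i``.

    scikit-learn estimator protocol: ``fit(X, y, sample_weight=d)``,
    ``decision_function``, ``predict``; fitted attributes carry a trailing
    underscore. Labels must be -1 (GTA) and +1 (virus).

    Parameters
    ----------
    C : float
        Regularization scalar; larger values harden the margin.
    kernel : {"linear", "rbf"}
        Kernel function; linear by default, matching the compositional
        feature setting.
    gamma : float, optional
        RBF width; defaults to 1 / n_features.
    tol : float
        SMO duality-gap stopping tolerance.
    max_iter : int
        Hard iteration cap for the solver.
    """

    def __init__(
        self,
        C: float = 1.0,
        kernel: str = "linear",
        gamma: float | None = None,
        tol: float = 1e-8,
        max_iter: int = 2_000_000,
    ):
        self.C = C
        self.kernel = kernel
        self.gamma = gamma
        self.tol = tol
        self.max_iter = max_iter

    _param_names = ("C", "kernel", "gamma", "tol", "max_iter")

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params) -> "WeightedSVC":
        for key, value in params.items():
            if key not in self._param_names:
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y, sample_weight=None) -> "WeightedSVC":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not (set(np.unique(y)) == {-1.0, 1.0}):
            raise ValueError("training data must contain both classes (-1 and +1)")
        if sample_weight is None:
            sample_weight = np.ones(len(y))
        d = np.asarray(sample_weight, dtype=float)
        if np.any(d <= 0):
            raise ValueError("sample weights must be positive")
        box = self.C * d

        K = kernel_eval(self.kernel, X, X, self.gamma)
        alpha, G, n_iter, gap = _smo_solve(K, y, box, self.tol, self.max_iter)

        # support vectors: alpha above a tolerance relative to its own bound
        sv_tol = 1e-8 * box
        sv = alpha > sv_tol
        margin = sv & (alpha < box - sv_tol)
        # f(x_i) - b = sum_j a_j y_j K_ij relates to the gradient by
        # G_i = y_i * (f(x_i) - b) - 1
        fx_no_b = y * (G + 1.0)
        if margin.any():
            b = float(np.mean(y[margin] - fx_no_b[margin]))
        else:
            # midpoint of the KKT-feasible interval for b
            lo, hi = -np.inf, np.inf
            at_zero = alpha <= sv_tol
            at_cap = alpha >= box - sv_tol
            pos, neg = y > 0, y < 0
            lower = np.concatenate(
                [1.0 - fx_no_b[pos & at_zero], -1.0 - fx_no_b[neg & at_cap]]
            )
            upper = np.concatenate(
                [1.0 - fx_no_b[pos & at_cap], -1.0 - fx_no_b[neg & at_zero]]
            )
            if lower.size:
                lo = float(lower.max())
            if upper.size:
                hi = float(upper.min())
            if np.isinf(lo) and np.isinf(hi):
                b = 0.0
            elif np.isinf(lo):
                b = hi
            elif np.isinf(hi):
                b = lo
            else:
                b = (lo + hi) / 2.0

        self.support_ = np.flatnonzero(sv)
        self.support_vectors_ = X[sv]
        self.support_labels_ = y[sv].astype(int)
        self.alphas_ = alpha[sv]
        self.dual_coef_ = (alpha * y)[sv]
        self.intercept_ = b
        self.n_features_in_ = X.shape[1]
        self.n_iter_ = n_iter
        self.duality_gap_ = gap
        self.kkt_residual_ = float(abs(np.sum(alpha * y)))
        if not (sv & (y > 0)).any() or not (sv & (y < 0)).any():
            logger.warning("degenerate fit: support vectors from one class only")
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "dual_coef_"):
            raise RuntimeError("model is not fitted")

    def decision_function(self, X) -> np.ndarray:
        """f(x) = sum_i alpha_i y_i K(x_i, x) + b for each row of X."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature width {X.shape[1]} != model width {self.n_features_in_}"
            )
        K = kernel_eval(self.kernel, X, self.support_vectors_, self.gamma)
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        """Class labels: -1 (GTA) when f(x) < 0, else +1 (virus)."""
        scores = self.decision_function(X)
        if np.any(scores == 0.0):
            logger.info("decision value exactly 0 for %d queries; labelled virus",
                        int(np.sum(scores == 0.0)))
        return np.where(scores < 0.0, -1, 1)


def label_name(label: int) -> str:
    return "GTA" if label < 0 else "virus"


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def save_model(
    model: WeightedSVC,
    spec: FeatureSpec,
    vocabulary: list[str],
    path: str | Path,
    gene_id: str = "model",
) -> None:
    """Serialize a fitted model plus its frozen feature spec to JSON text.

    Includes checksums of the shipped scale/class tables so a reload can
    verify it reproduces the original feature space bit-for-bit.
    """
    model._check_fitted()
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "gene_id": gene_id,
        "kernel": model.kernel,
        "gamma": model.gamma,
        "C": model.C,
        "intercept": model.intercept_,
        "alphas": model.alphas_.tolist(),
        "support_labels": model.support_labels_.tolist(),
        "support_vectors": model.support_vectors_.tolist(),
        "feature_spec": spec.to_dict(),
        "vocabulary": vocabulary,
        "data_checksums": {
            "aa_scales.tsv": _file_sha256(_data_path("aa_scales.tsv")),
            "physchem_classes.tsv": _file_sha256(_data_path("physchem_classes.tsv")),
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[WeightedSVC, SequenceFeaturizer, str]:
    """Reload a serialized model; returns (svm, fitted featurizer, gene id)."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {payload.get('format_version')}")
    for name, digest in payload["data_checksums"].items():
        if _file_sha256(_data_path(name)) != digest:
            logger.warning("data table %s differs from the one used at training", name)
    model = WeightedSVC(C=payload["C"], kernel=payload["kernel"], gamma=payload["gamma"])
    sv = np.asarray(payload["support_vectors"], dtype=float)
    model.support_vectors_ = sv
    model.support_labels_ = np.asarray(payload["support_labels"], dtype=int)
    model.alphas_ = np.asarray(payload["alphas"], dtype=float)
    model.dual_coef_ = model.alphas_ * model.support_labels_
    model.intercept_ = payload["intercept"]
    model.support_ = np.arange(len(sv))
    model.n_features_in_ = sv.shape[1] if sv.ndim == 2 else 0
    spec = FeatureSpec.from_dict(payload["feature_spec"])
    fz = SequenceFeaturizer(
        kmer_k=spec.kmer_k,
        pseaac_lambda=spec.pseaac_lambda,
        pseaac_omega=spec.pseaac_omega,
        physchem=spec.physchem,
    ).set_vocabulary(payload["vocabulary"])
    return model, fz, payload["gene_id"]
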