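"""Soft-margin SVM on a precomputed kernel, solved in the dual.

The classifier is the standard C-SVM: maximise
``sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j y_i y_j K_ij`` subject to
``sum_i alpha_i y_i = 0`` and ``0 <= alpha_i <= C``.  With a combined
multi-modality kernel this is exactly the multiple-kernel SVM — only the
kernel changes, the optimisation does not.

The solver is sequential minimal optimisation (SMO) with maximal-violating-
pair working-set selection, run to a tight KKT tolerance; any solver
meeting the KKT contract would be interchangeable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kernels import KernelMatrix

__all__ = ["MKSVMModel", "fit_svm", "decision_function", "predict_label"]

KKT_TOL = 1e-8  # stopping tolerance on the maximal KKT violation


@dataclass
class MKSVMModel:
    """Fitted dual solution over a precomputed training kernel.

    ``alpha`` are the dual coefficients (one per training subject), ``b`` the
    bias.  Support vectors have ``alpha_i > eps`` with ``eps = 1e-8 * C``;
    margin support vectors additionally have ``alpha_i < C - eps`` and sit on
    the unit margin.
    """

    alpha: np.ndarray
    b: float
    C: float
    y: np.ndarray
    subject_ids: tuple[str, ...] = ()
    kkt_violation: float = np.nan
    meta: dict = field(default_factory=dict)

    @property
    def sv_epsilon(self) -> float:
        return 1e-8 * self.C

    @property
    def support_(self) -> np.ndarray:
        return np.flatnonzero(self.alpha > self.sv_epsilon)

    @property
    def margin_support_(self) -> np.ndarray:
        eps = self.sv_epsilon
        return np.flatnonzero((self.alpha > eps) & (self.alpha < self.C - eps))

    @property
    def bounded_support_(self) -> np.ndarray:
        return np.flatnonzero(self.alpha >= self.C - self.sv_epsilon)

    def dual_objective(self, K: np.ndarray) -> float:
        """Value of the dual objective at the fitted alpha."""
        a, y = self.alpha, self.y
        return float(a.sum() - 0.5 * (a * y) @ K @ (a * y))

    def to_json(self, path: str | Path | None = None, **extra) -> str:
        payload = {
            "alpha": self.alpha.tolist(),
            "b": self.b,
            "C": self.C,
            "y": self.y.tolist(),
            "subject_ids": list(self.subject_ids),
            "kkt_violation": self.kkt_violation,
            "meta": self.meta,
            **extra,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MKSVMModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(alpha=np.asarray(d["alpha"], float), b=float(d["b"]),
                   C=float(d["C"]), y=np.asarray(d["y"], float),
                   subject_ids=tuple(d.get("subject_ids", ())),
                   kkt_violation=float(d.get("kkt_violation", np.nan)),
                   meta=d.get("meta", {}))


def _smo(Q: np.ndarray, y: np.ndarray, C: float, tol: float,
         max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Minimise 1/2 a'Qa - e'a  s.t. y'a = 0, 0 <= a <= C.

    Maximal-violating-pair SMO: at each step the pair with the largest KKT
    violation gets an exact two-variable update.  Returns (alpha, gradient,
    final violation m - M).
    """
    n = y.size
    alpha = np.zeros(n)
    grad = -np.ones(n)  # Q @ alpha - 1
    yg = np.empty(n)
    ny = -y
    ypos = y > 0
    snap = 1e-12 * C

    for _ in range(max_iter):
        np.multiply(ny, grad, out=yg)  # -y_t * grad_t
        # both sets are non-empty whenever both classes are present
        up = np.where(ypos, alpha < C, alpha > 0)
        low = np.where(ypos, alpha > 0, alpha < C)
        i = int(np.argmax(np.where(up, yg, -np.inf)))
        j = int(np.argmin(np.where(low, yg, np.inf)))
        violation = yg[i] - yg[j]
        if violation <= tol:
            return alpha, grad, float(violation)

        a = Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j]
        a = max(a, 1e-12)
        t = violation / a
        # box limits keeping alpha_i, alpha_j in [0, C]
        t_i = (C - alpha[i]) if y[i] > 0 else alpha[i]
        t_j = alpha[j] if y[j] > 0 else (C - alpha[j])
        t = min(t, t_i, t_j)

        d_i = y[i] * t
        d_j = -y[j] * t
        alpha[i] += d_i
        alpha[j] += d_j
        # snap to the box: round-off can strand alpha within ~1e-16 of a
        # bound, where the same pair gets reselected with zero progress
        for k in (i, j):
            if alpha[k] < snap:
                alpha[k] = 0.0
            elif alpha[k] > C - snap:
                alpha[k] = C
        grad += Q[:, i] * d_i
        grad += Q[:, j] * d_j

    np.multiply(ny, grad, out=yg)
    up = np.where(ypos, alpha < C, alpha > 0)
    low = np.where(ypos, alpha > 0, alpha < C)
    violation = yg[up].max() - yg[low].min()
    return alpha, grad, float(violation)


def fit_svm(K: KernelMatrix | np.ndarray, y, C: float = 1.0,
            tol: float = KKT_TOL, max_iter: int = 200_000,
            check_psd: bool = True) -> MKSVMModel:
    """Solve the SVM dual on a precomputed kernel.

    Parameters
    ----------
    K
        Training kernel (n x n), a :class:`~mkfusion.kernels.KernelMatrix`
        or plain array.  Must be (numerically) PSD.
    y
        Labels in {+1, -1}; both classes must be present.
    C
        Box constraint / regularisation parameter.
    check_psd
        Verify positive semidefiniteness before solving; callers that build
        the kernel as a convex combination of verified PSD kernels may skip
        the (eigendecomposition) cost.

    The bias ``b`` is the mean of ``y_i - sum_j alpha_j y_j K_ij`` over
    margin support vectors; if none exist it falls back to the midpoint of
    the feasible interval defined by the bounded support vectors.
    """
    if isinstance(K, KernelMatrix):
        K.check(psd=check_psd)
        ids = K.subject_ids
        Kv = K.values
    else:
        Kv = np.asarray(K, dtype=float)
        if check_psd:
            w = np.linalg.eigvalsh((Kv + Kv.T) / 2.0)
            if w.min() < -1e-8 * max(np.trace(Kv), 1.0) / Kv.shape[0]:
                raise ValueError(
                    f"kernel is not PSD (min eigenvalue {w.min():.2e}); "
                    "check the kernel computation"
                )
        ids = tuple(f"row{i}" for i in range(Kv.shape[0]))
    y = np.asarray(y, dtype=float).ravel()
    if Kv.shape[0] != y.size:
        raise ValueError(f"kernel is {Kv.shape} but y has {y.size} labels")
    if not np.all(np.isin(y, [-1.0, 1.0])):
        raise ValueError("labels must be +1/-1")
    if (y > 0).all() or (y < 0).all():
        raise ValueError("both classes must be present to fit an SVM")
    if not C > 0:
        raise ValueError(f"C must be positive, got {C}")

    Q = (y[:, None] * y[None, :]) * Kv
    alpha, grad, violation = _smo(Q, y, float(C), tol, max_iter)

    eps = 1e-8 * C
    margin = np.flatnonzero((alpha > eps) & (alpha < C - eps))
    # -y_i grad_i = y_i - sum_j alpha_j y_j K_ij at the solution
    yg = -y * grad
    if margin.size:
        b = float(yg[margin].mean())
    else:
        up = ((y > 0) & (alpha < C - eps)) | ((y < 0) & (alpha > eps))
        low = ((y > 0) & (alpha > eps)) | ((y < 0) & (alpha < C - eps))
        hi = yg[up].max() if up.any() else yg.max()
        lo = yg[low].min() if low.any() else yg.min()
        b = float((hi + lo) / 2.0)

    return MKSVMModel(alpha=alpha, b=b, C=float(C), y=y, subject_ids=ids,
                      kkt_violation=violation)


def decision_function(model: MKSVMModel, K_test: np.ndarray) -> np.ndarray:
    """Raw decision scores ``f(z) = sum_i y_i alpha_i K(z, x_i) + b``.

    ``K_test`` has one row per test point and one column per *training*
    subject, in training order.  The sign is deliberately not applied: raw
    scores are what ROC analysis needs.
    """
    K_test = np.atleast_2d(np.asarray(K_test, dtype=float))
    if K_test.shape[1] != model.alpha.size:
        raise ValueError(
            f"test kernel has {K_test.shape[1]} columns but the model was "
            f"trained on {model.alpha.size} subjects"
        )
    return K_test @ (model.alpha * model.y) + model.b


def predict_label(model: MKSVMModel, K_test: np.ndarray) -> np.ndarray:
    """Class predictions in {+1, -1}; a score of exactly 0 maps to +1."""
    scores = decision_function(model, K_test)
    return np.where(scores >= 0.0, 1.0, -1.0)
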