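"""Weighted non-negative matrix partial co-factorization with KL updates.

The model decomposes each spectrogram segment X(l) (F x T(l)) as

    X(l) ~ U_R diag(D_xR(l)) V_R(l)  +  U_W(l) diag(D_xW(l)) V_W(l)

with a single respiratory dictionary U_R shared across all L segments and,
optionally, a respiratory training spectrogram Y ~ U_R diag(D_yR) H_R.  The
informed inter-segment weighting up-weights wheeze-free segments (label 0,
weight lambda_r0) over wheezing segments (label 1, weight lambda_r1) in the
data-fit terms that shape U_R, so the shared respiratory bases are learned
predominantly from uncontaminated evidence.  A squared-Frobenius penalty on
every dictionary keeps basis vectors from collapsing; after every sweep all
factors are rescaled to unit L2 columns/rows with the removed norms folded
into the gain vectors D, which leaves every reconstruction unchanged.

An optional wheeze-training branch (used by the supervised 2S variant)
co-factorizes a tonal template spectrogram Z with each per-segment wheeze
dictionary: Z ~ U_W(l) diag(D_zW(l)) H_W(l), weighted by ``beta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "SegmentSet",
    "WeightScheme",
    "HyperParams",
    "FactorModel",
    "kl_divergence",
    "reconstruct_segment",
    "reconstruct_training",
    "objective",
    "update_shared_basis",
    "update_wheeze_basis",
    "update_activations",
    "renormalize_model",
    "init_model",
    "fit",
    "IISNMPCF",
]

EPS_DEFAULT = 1e-12


# ---------------------------------------------------------------------------
# containers


@dataclass
class SegmentSet:
    """Ordered spectrogram segments with per-segment wheeze labels.

    ``segments[l]`` is the non-negative F x T(l) magnitude matrix of the l-th
    respiratory stage; ``labels[l]`` is 1 if a wheeze was detected in that
    stage, else 0; ``boundaries[l]`` is the (start, end) half-open frame range
    of the segment in the parent spectrogram.
    """

    segments: list[np.ndarray]
    labels: list[int]
    boundaries: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.segments = [np.asarray(s, dtype=np.float64) for s in self.segments]
        if not self.segments:
            raise ValueError("SegmentSet requires at least one segment")
        if len(self.labels) != len(self.segments):
            raise ValueError("labels length must equal number of segments")
        f = self.segments[0].shape[0]
        for s in self.segments:
            if s.ndim != 2 or s.shape[0] != f:
                raise ValueError("all segments must share the same number of rows F")
            if np.any(s < 0):
                raise ValueError("segments must be non-negative")
        if any(c not in (0, 1) for c in self.labels):
            raise ValueError("labels must be 0 (non-wheezing) or 1 (wheezing)")
        if self.boundaries is None:
            edges = np.cumsum([0] + [s.shape[1] for s in self.segments])
            self.boundaries = list(zip(edges[:-1].tolist(), edges[1:].tolist()))

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_bins(self) -> int:
        return self.segments[0].shape[0]

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.segments, axis=1)


@dataclass(frozen=True)
class WeightScheme:
    """Weighting factors of the co-factorization.

    lambda_r0 weights non-wheezing segments and lambda_r1 wheezing segments in
    the respiratory-basis data terms; lambda_w weights the wheeze-basis data
    term; alpha weights the respiratory-training term.  The informed regime is
    lambda_r0 > lambda_r1 > lambda_w (a warning, not an error, flags
    violations); equal lambdas recover conventional unweighted NMPCF.
    """

    lambda_r0: float = 10.0
    lambda_r1: float = 0.1
    lambda_w: float = 0.01
    alpha: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.lambda_r0, self.lambda_r1, self.lambda_w, self.alpha)
        if any(v < 0 for v in vals):
            raise ValueError("weights must be non-negative")
        if not (self.lambda_r0 >= self.lambda_r1 >= self.lambda_w):
            warnings.warn(
                "recommended weighting is lambda_r0 >= lambda_r1 >= lambda_w",
                stacklevel=2,
            )

    def segment_weight(self, label: int) -> float:
        return self.lambda_r1 if label else self.lambda_r0

    @classmethod
    def equal(cls, value: float = 0.01, alpha: float = 1.0) -> "WeightScheme":
        """Unweighted (conventional NMPCF) scheme: all lambdas equal."""
        return cls(lambda_r0=value, lambda_r1=value, lambda_w=value, alpha=alpha)


@dataclass(frozen=True)
class HyperParams:
    """Rank, iteration and numerical settings of a factorization run."""

    k_r: int = 32
    k_w: int = 64
    max_iter: int = 50
    seed: int = 0
    eps: float = EPS_DEFAULT

    def __post_init__(self) -> None:
        if self.k_r < 1 or self.k_w < 1:
            raise ValueError("component counts must be >= 1")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class FactorModel:
    """All factors of the co-factorization (see module docstring).

    Per-segment quantities are lists indexed by segment.  ``h_r``/``d_yr``
    exist only when a respiratory training matrix participates; ``h_w``/
    ``d_zw`` only when a wheeze-training matrix participates.
    """

    u_r: np.ndarray
    u_w: list[np.ndarray]
    v_r: list[np.ndarray]
    v_w: list[np.ndarray]
    d_xr: list[np.ndarray]
    d_xw: list[np.ndarray]
    h_r: np.ndarray | None = None
    d_yr: np.ndarray | None = None
    h_w: list[np.ndarray] | None = None
    d_zw: list[np.ndarray] | None = None

    @property
    def n_segments(self) -> int:
        return len(self.u_w)

    def copy(self) -> "FactorModel":
        return FactorModel(
            u_r=self.u_r.copy(),
            u_w=[m.copy() for m in self.u_w],
            v_r=[m.copy() for m in self.v_r],
            v_w=[m.copy() for m in self.v_w],
            d_xr=[d.copy() for d in self.d_xr],
            d_xw=[d.copy() for d in self.d_xw],
            h_r=None if self.h_r is None else self.h_r.copy(),
            d_yr=None if self.d_yr is None else self.d_yr.copy(),
            h_w=None if self.h_w is None else [m.copy() for m in self.h_w],
            d_zw=None if self.d_zw is None else [d.copy() for d in self.d_zw],
        )


# ---------------------------------------------------------------------------
# primitives


def kl_divergence(x: np.ndarray, xhat: np.ndarray, eps: float = EPS_DEFAULT) -> float:
    """Generalized Kullback-Leibler divergence sum(x log(x/xhat) - x + xhat).

    Uses the convention 0*log(0) = 0; ``xhat`` is floored at ``eps``.  Zero
    iff x == xhat elementwise.
    """
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape:
        raise ValueError("shape mismatch")
    if np.any(x < 0) or np.any(xhat < 0):
        raise ValueError("KL divergence requires non-negative inputs")
    xhat = np.maximum(xhat, eps)
    pos = x > 0
    out = float(np.sum(xhat) - np.sum(x))
    out += float(np.sum(x[pos] * np.log(x[pos] / xhat[pos])))
    return out


def reconstruct_segment(model: FactorModel, l: int) -> tuple[np.ndarray, np.ndarray]:
    """Respiratory and wheeze reconstructions of segment l (Xhat_R, Xhat_W)."""
    xhat_r = (model.u_r * model.d_xr[l]) @ model.v_r[l]
    xhat_w = (model.u_w[l] * model.d_xw[l]) @ model.v_w[l]
    return xhat_r, xhat_w


def reconstruct_training(model: FactorModel) -> np.ndarray:
    """Training reconstruction Yhat = U_R diag(D_yR) H_R."""
    if model.h_r is None or model.d_yr is None:
        raise ValueError("model has no respiratory-training branch")
    return (model.u_r * model.d_yr) @ model.h_r


def _reconstruct_z(model: FactorModel, l: int) -> np.ndarray:
    return (model.u_w[l] * model.d_zw[l]) @ model.h_w[l]


def objective(
    model: FactorModel,
    segs: SegmentSet,
    y: np.ndarray | None,
    w: WeightScheme,
    z: np.ndarray | None = None,
    beta: float = 0.0,
    eps: float = EPS_DEFAULT,
) -> float:
    """Weighted co-factorization objective.

    sum_l lambda_{C(l)} KL(X(l)|Xhat(l)) + L*||U_R||_F^2 + sum_l ||U_W(l)||_F^2
    + alpha*KL(Y|Yhat) + ||U_R||_F^2 [+ beta*sum_l KL(Z|Zhat(l))].
    """
    if w.alpha > 0 and y is None:
        raise ValueError("alpha > 0 requires a training matrix y")
    L = len(segs)
    total = 0.0
    for l, (x, c) in enumerate(zip(segs.segments, segs.labels)):
        xhat_r, xhat_w = reconstruct_segment(model, l)
        total += w.segment_weight(c) * kl_divergence(x, xhat_r + xhat_w, eps)
        total += float(np.sum(model.u_w[l] ** 2))
    total += (L + 1) * float(np.sum(model.u_r**2))
    if y is not None and w.alpha > 0:
        total += w.alpha * kl_divergence(y, reconstruct_training(model), eps)
    if z is not None and beta > 0:
        for l in range(L):
            total += beta * kl_divergence(z, _reconstruct_z(model, l), eps)
    return total


# ---------------------------------------------------------------------------
# multiplicative updates

def _check_finite(a: np.ndarray, what: str, iteration: int | None = None) -> None:
    if not np.all(np.isfinite(a)):
        where = "" if iteration is None else f" at iteration {iteration}"
        raise FloatingPointError(f"non-finite values in {what}{where}")


def update_shared_basis(
    model: FactorModel,
    segs: SegmentSet,
    y: np.ndarray | None,
    w: WeightScheme,
    eps: float = EPS_DEFAULT,
) -> np.ndarray:
    """One multiplicative update of the shared respiratory dictionary U_R.

    Exact KL multiplicative rule for the terms of the objective touching U_R:
    the weighted segment data fits, the alpha-weighted training fit, and the
    (L+1)*||U_R||_F^2 penalty, whose gradient contributes (2L+2)*U_R to the
    denominator.  Updates the model in place and returns the new U_R.
    """
    L = len(segs)
    num = np.zeros_like(model.u_r)
    den = (2.0 * L + 2.0) * model.u_r.copy()
    for l, (x, c) in enumerate(zip(segs.segments, segs.labels)):
        lam = w.segment_weight(c)
        xhat_r, xhat_w = reconstruct_segment(model, l)
        ratio = x / np.maximum(xhat_r + xhat_w, eps)
        dv = model.d_xr[l][:, None] * model.v_r[l]  # K_R x T(l)
        num += lam * (ratio @ dv.T)
        den += lam * dv.sum(axis=1)[None, :]  # all-ones matrix times (DV)^T
    if y is not None and w.alpha > 0:
        yhat = reconstruct_training(model)
        ratio = y / np.maximum(yhat, eps)
        dh = model.d_yr[:, None] * model.h_r
        num += w.alpha * (ratio @ dh.T)
        den += w.alpha * dh.sum(axis=1)[None, :]
    model.u_r = model.u_r * num / np.maximum(den, eps)
    _check_finite(model.u_r, "U_R")
    return model.u_r


def update_wheeze_basis(
    model: FactorModel,
    segs: SegmentSet,
    w: WeightScheme,
    l: int,
    z: np.ndarray | None = None,
    beta: float = 0.0,
    eps: float = EPS_DEFAULT,
) -> np.ndarray:
    """One multiplicative update of the wheeze dictionary U_W(l).

    The data fit carries weight lambda_w (the wheeze-basis weight, shared by
    all segments); the ||U_W(l)||_F^2 penalty contributes 2*U_W(l) to the
    denominator.  When a wheeze-training branch is active (beta > 0) its data
    term is included symmetrically.
    """
    x = segs.segments[l]
    xhat_r, xhat_w = reconstruct_segment(model, l)
    ratio = x / np.maximum(xhat_r + xhat_w, eps)
    dv = model.d_xw[l][:, None] * model.v_w[l]
    num = w.lambda_w * (ratio @ dv.T)
    den = w.lambda_w * dv.sum(axis=1)[None, :] + 2.0 * model.u_w[l]
    if z is not None and beta > 0:
        zhat = _reconstruct_z(model, l)
        zratio = z / np.maximum(zhat, eps)
        dh = model.d_zw[l][:, None] * model.h_w[l]
        num += beta * (zratio @ dh.T)
        den += beta * dh.sum(axis=1)[None, :]
    model.u_w[l] = model.u_w[l] * num / np.maximum(den, eps)
    _check_finite(model.u_w[l], f"U_W({l})")
    return model.u_w[l]


def update_activations(
    model: FactorModel,
    segs: SegmentSet,
    y: np.ndarray | None,
    z: np.ndarray | None = None,
    beta: float = 0.0,
    eps: float = EPS_DEFAULT,
    alpha: float = 1.0,
) -> FactorModel:
    """Multiplicative updates of all activations V_R(l), V_W(l), H_R (and H_W).

    Plain KL ratios: any positive data weight cancels between numerator and
    denominator, so the rules carry no lambdas.  Updates in place.
    """
    for l, x in enumerate(segs.segments):
        xhat_r, xhat_w = reconstruct_segment(model, l)
        ratio = x / np.maximum(xhat_r + xhat_w, eps)
        ud_r = model.u_r * model.d_xr[l]  # F x K_R
        model.v_r[l] = model.v_r[l] * (ud_r.T @ ratio) / np.maximum(
            ud_r.sum(axis=0)[:, None], eps
        )
        # Xhat changes as V_R does; recompute the ratio for the wheeze update
        xhat_r, xhat_w = reconstruct_segment(model, l)
        ratio = x / np.maximum(xhat_r + xhat_w, eps)
        ud_w = model.u_w[l] * model.d_xw[l]
        model.v_w[l] = model.v_w[l] * (ud_w.T @ ratio) / np.maximum(
            ud_w.sum(axis=0)[:, None], eps
        )
        _check_finite(model.v_r[l], f"V_R({l})")
        _check_finite(model.v_w[l], f"V_W({l})")
    if y is not None and alpha > 0 and model.h_r is not None:
        yhat = reconstruct_training(model)
        ratio = y / np.maximum(yhat, eps)
        ud = model.u_r * model.d_yr
        model.h_r = model.h_r * (ud.T @ ratio) / np.maximum(ud.sum(axis=0)[:, None], eps)
        _check_finite(model.h_r, "H_R")
    if z is not None and beta > 0 and model.h_w is not None:
        for l in range(model.n_segments):
            zhat = _reconstruct_z(model, l)
            ratio = z / np.maximum(zhat, eps)
            ud = model.u_w[l] * model.d_zw[l]
            model.h_w[l] = model.h_w[l] * (ud.T @ ratio) / np.maximum(
                ud.sum(axis=0)[:, None], eps
            )
            _check_finite(model.h_w[l], f"H_W({l})")
    return model


def _norm_cols(u: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum(u**2, axis=0))


def _norm_rows(v: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum(v**2, axis=1))


def _safe_div_cols(u: np.ndarray, norms: np.ndarray) -> np.ndarray:
    nz = norms > 0
    out = u.copy()
    out[:, nz] = out[:, nz] / norms[nz]
    return out


def _safe_div_rows(v: np.ndarray, norms: np.ndarray) -> np.ndarray:
    nz = norms > 0
    out = v.copy()
    out[nz, :] = out[nz, :] / norms[nz][:, None]
    return out


def renormalize_model(model: FactorModel) -> FactorModel:
    """Rescale every basis column and activation row to unit L2 norm.

    The removed norms are folded into the gain vectors D, so every
    reconstruction U diag(D) V is unchanged.  Zero columns/rows are left as
    zero with gain 0 (multiplicative fixed points stay dead).  In place.
    """
    ur_norms = _norm_cols(model.u_r)
    model.u_r = _safe_div_cols(model.u_r, ur_norms)
    for l in range(model.n_segments):
        vr_norms = _norm_rows(model.v_r[l])
        model.v_r[l] = _safe_div_rows(model.v_r[l], vr_norms)
        model.d_xr[l] = model.d_xr[l] * ur_norms * vr_norms

        uw_norms = _norm_cols(model.u_w[l])
        model.u_w[l] = _safe_div_cols(model.u_w[l], uw_norms)
        vw_norms = _norm_rows(model.v_w[l])
        model.v_w[l] = _safe_div_rows(model.v_w[l], vw_norms)
        model.d_xw[l] = model.d_xw[l] * uw_norms * vw_norms

        if model.h_w is not None:
            hw_norms = _norm_rows(model.h_w[l])
            model.h_w[l] = _safe_div_rows(model.h_w[l], hw_norms)
            model.d_zw[l] = model.d_zw[l] * uw_norms * hw_norms
    if model.h_r is not None:
        hr_norms = _norm_rows(model.h_r)
        model.h_r = _safe_div_rows(model.h_r, hr_norms)
        model.d_yr = model.d_yr * ur_norms * hr_norms
    return model


# ---------------------------------------------------------------------------
# fitting


def init_model(
    segs: SegmentSet,
    hp: HyperParams,
    with_training: bool,
    t_y: int = 0,
    with_wheeze_training: bool = False,
    t_z: int = 0,
) -> FactorModel:
    """Random non-negative initialization: uniform(0,1) + eps for all factors.

    Gains start at 1 and are set by the first renormalization.
    """
    rng = np.random.default_rng(hp.seed)
    f = segs.n_bins
    u = lambda *shape: rng.uniform(0.0, 1.0, shape) + hp.eps
    model = FactorModel(
        u_r=u(f, hp.k_r),
        u_w=[u(f, hp.k_w) for _ in segs.segments],
        v_r=[u(hp.k_r, s.shape[1]) for s in segs.segments],
        v_w=[u(hp.k_w, s.shape[1]) for s in segs.segments],
        d_xr=[np.ones(hp.k_r) for _ in segs.segments],
        d_xw=[np.ones(hp.k_w) for _ in segs.segments],
    )
    if with_training:
        model.h_r = u(hp.k_r, t_y)
        model.d_yr = np.ones(hp.k_r)
    if with_wheeze_training:
        model.h_w = [u(hp.k_w, t_z) for _ in segs.segments]
        model.d_zw = [np.ones(hp.k_w) for _ in segs.segments]
    return renormalize_model(model)


def fit(
    segs: SegmentSet,
    y: np.ndarray | None = None,
    hp: HyperParams | None = None,
    w: WeightScheme | None = None,
    z: np.ndarray | None = None,
    beta: float = 0.0,
    early_stop_tol: float | None = None,
) -> tuple[FactorModel, np.ndarray]:
    """Run M full update sweeps and return (model, objective trace).

    A sweep updates U_R, then every U_W(l), then all activations, then
    renormalizes.  The trace has max_iter + 1 entries (initial value first);
    with ``early_stop_tol`` set, iteration stops once the relative objective
    change falls below it and the trace is truncated accordingly.
    """
    hp = hp or HyperParams()
    w = w or WeightScheme()
    if w.alpha > 0 and y is None:
        raise ValueError("alpha > 0 requires a training matrix y")
    if beta > 0 and z is None:
        raise ValueError("beta > 0 requires a wheeze-training matrix z")
    y_used = y if w.alpha > 0 else None
    z_used = z if beta > 0 else None
    model = init_model(
        segs,
        hp,
        with_training=y_used is not None,
        t_y=0 if y_used is None else y_used.shape[1],
        with_wheeze_training=z_used is not None,
        t_z=0 if z_used is None else z_used.shape[1],
    )
    trace = [objective(model, segs, y_used, w, z_used, beta, hp.eps)]
    for it in range(hp.max_iter):
        update_shared_basis(model, segs, y_used, w, hp.eps)
        for l in range(len(segs)):
            update_wheeze_basis(model, segs, w, l, z_used, beta, hp.eps)
        update_activations(model, segs, y_used, z_used, beta, hp.eps, alpha=w.alpha)
        renormalize_model(model)
        val = objective(model, segs, y_used, w, z_used, beta, hp.eps)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite objective at iteration {it}")
        trace.append(val)
        if early_stop_tol is not None and trace[-2] > 0:
            if abs(trace[-2] - trace[-1]) / abs(trace[-2]) < early_stop_tol:
                break
    return model, np.asarray(trace)


class IISNMPCF(BaseEstimator):
    """Informed inter-segment NMPCF estimator (scikit-learn style).

    Parameters mirror the factorization defaults tuned for wheeze separation:
    k_w=64 wheeze and k_r=32 respiratory components, weights
    (lambda_r0, lambda_r1, lambda_w, alpha) = (10, 0.1, 0.01, 1), 50 sweeps.

    Attributes (after ``fit``)
    --------------------------
    model_ : FactorModel
        All fitted factors.
    trace_ : ndarray
        Objective value at initialization and after each sweep.
    n_iter_ : int
        Number of sweeps performed.
    """

    def __init__(
        self,
        k_r: int = 32,
        k_w: int = 64,
        lambda_r0: float = 10.0,
        lambda_r1: float = 0.1,
        lambda_w: float = 0.01,
        alpha: float = 1.0,
        beta: float = 0.0,
        max_iter: int = 50,
        random_state: int = 0,
        eps: float = EPS_DEFAULT,
        early_stop_tol: float | None = None,
    ):
        self.k_r = k_r
        self.k_w = k_w
        self.lambda_r0 = lambda_r0
        self.lambda_r1 = lambda_r1
        self.lambda_w = lambda_w
        self.alpha = alpha
        self.beta = beta
        self.max_iter = max_iter
        self.random_state = random_state
        self.eps = eps
        self.early_stop_tol = early_stop_tol

    def _weights(self) -> WeightScheme:
        return WeightScheme(self.lambda_r0, self.lambda_r1, self.lambda_w, self.alpha)

    def _hyper(self) -> HyperParams:
        return HyperParams(
            k_r=self.k_r,
            k_w=self.k_w,
            max_iter=self.max_iter,
            seed=self.random_state,
            eps=self.eps,
        )

    def fit(
        self,
        X: SegmentSet | list[np.ndarray],
        y: np.ndarray | None = None,
        *,
        labels: list[int] | None = None,
        z: np.ndarray | None = None,
    ) -> "IISNMPCF":
        """Fit the co-factorization.

        X is a SegmentSet, or a list of non-negative matrices combined with
        ``labels``; ``y`` is the respiratory training spectrogram (required
        when alpha > 0); ``z`` the wheeze-training spectrogram (beta > 0).
        """
        if not isinstance(X, SegmentSet):
            X = SegmentSet(segments=list(X), labels=labels or [0] * len(X))
        self.model_, self.trace_ = fit(
            X,
            y=y,
            hp=self._hyper(),
            w=self._weights(),
            z=z,
            beta=self.beta,
            early_stop_tol=self.early_stop_tol,
        )
        self.n_iter_ = len(self.trace_) - 1
        self.segment_set_ = X
        return self

    def transform(self, X=None) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-segment (respiratory, wheeze) magnitude reconstructions."""
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted")
        return [reconstruct_segment(self.model_, l) for l in range(self.model_.n_segments)]

    def fit_transform(self, X, y=None, **kw) -> list[tuple[np.ndarray, np.ndarray]]:
        return self.fit(X, y, **kw).transform()
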