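"""Golden-section-search T1/T2 fit from magnitude configuration modes.

A conventional, training-free baseline in the spirit of
motion-insensitive rapid configuration relaxometry (MIRACLE): the
(T1, T2) pair is found by minimizing the squared Euclidean distance
between the measured normalized magnitude mode vector
``(|F_-1|, |F_0|, |F_1|)`` and the same vector generated by the analytic
on-resonance forward model at the matched number of phase cycles and the
measured B1 scaling.  The 2-D problem is solved by alternating 1-D
golden-section searches over T2 (T1 fixed, starting from the initial T1
estimate of 1000 ms) and T1 (T2 fixed) until both estimates stop
changing.  The implementation is a least-squares inversion of the
identical forward kernel used for simulation, not a reimplementation of
the original mode-ratio update equations.

All searches are vectorized over voxel batches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .datasets import EXTENDED_T1_RANGE, EXTENDED_T2_RANGE
from .signal import ModeFeatures, SequenceParams, phase_cycle_scheme

__all__ = ["GssConfig", "miracle_fit", "MiracleEstimator"]

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0  # 1/golden ratio


@dataclass(frozen=True)
class GssConfig:
    """Golden-section search settings.

    ``t1_init`` is the initial longitudinal estimate in ms; bounds default
    to the extended parameter ranges (the fit has no training-range
    restriction); ``tol`` is the relative convergence tolerance on both
    estimates between outer iterations.
    """

    t1_init: float = 1000.0
    t1_bounds: tuple[float, float] = EXTENDED_T1_RANGE
    t2_bounds: tuple[float, float] = EXTENDED_T2_RANGE
    tol: float = 1e-4
    max_iter: int = 50

    def __post_init__(self) -> None:
        for lo, hi in (self.t1_bounds, self.t2_bounds):
            if not (0 < lo < hi):
                raise ValueError("bounds must be positive and ordered")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def _model_magnitudes(t1, t2, b1, seq: SequenceParams, phi, kernel):
    """Normalized (|F_-1|, |F_0|, |F_1|) of the on-resonance model,
    vectorized over the leading axis."""
    a = np.deg2rad(seq.alpha) * b1[:, None]
    e1 = np.exp(-seq.tr / t1)[:, None]
    e2 = np.exp(-seq.tr / t2)[:, None]
    cos_a = np.cos(a)
    c = e2 * (e1 - 1.0) * (1.0 + cos_a)
    d = (1.0 - e1 * cos_a) - (e1 - cos_a) * e2 * e2
    s = (
        (1.0 - e1)
        * (1.0 - e2 * np.exp(1j * phi))
        * np.sin(a)
        / (c * np.cos(phi) + d)
        * np.exp(-seq.te / t2)[:, None]
    )
    modes = np.abs(s @ kernel) / seq.n_pc
    return modes / np.linalg.norm(modes, axis=1, keepdims=True)


def _objective(t1, t2, b1, target, seq, phi, kernel):
    mags = _model_magnitudes(t1, t2, b1, seq, phi, kernel)
    return np.sum((mags - target) ** 2, axis=1)


def _golden_min(f, lo, hi, n_iter):
    """Vectorized golden-section minimization on per-element brackets."""
    a = np.full_like(lo, lo) if np.isscalar(lo) else lo.copy()
    b = np.full_like(a, hi) if np.isscalar(hi) else hi.copy()
    h = b - a
    x1 = b - _INVPHI * h
    x2 = a + _INVPHI * h
    f1 = f(x1)
    f2 = f(x2)
    for _ in range(n_iter):
        left = f1 < f2
        b = np.where(left, x2, b)
        a = np.where(left, a, x1)
        x1n = np.where(left, b - _INVPHI * (b - a), x2)
        x2n = np.where(left, x1, a + _INVPHI * (b - a))
        fn = f(np.where(left, x1n, x2n))
        f1, f2 = np.where(left, fn, f2), np.where(left, f1, fn)
        x1, x2 = x1n, x2n
    return 0.5 * (a + b)


def miracle_fit(
    features: ModeFeatures | np.ndarray,
    b1: np.ndarray | float,
    seq: SequenceParams,
    cfg: GssConfig | None = None,
    trace: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit (T1, T2) per voxel from normalized magnitude mode features.

    Parameters
    ----------
    features : ModeFeatures or ndarray (n, 3)
        Euclidean-normalized ``(|F_-1|, |F_0|, |F_1|)`` vectors.
    b1 : scalar or ndarray (n,)
        Transmit scaling factors.
    seq : SequenceParams
        Protocol; the model modes are generated at the matched n_pc and
        theta = 0.
    cfg : GssConfig, optional

    Returns
    -------
    t1, t2 : ndarray (n,) in ms (T1 clamped to >= T2)
    converged : bool ndarray (n,)
        False where the alternation hit ``max_iter`` without the relative
        change of both estimates dropping below ``tol``.

    With ``trace=True`` a list of per-outer-iteration objective arrays is
    appended to the return tuple.
    """
    if cfg is None:
        cfg = GssConfig()
    if isinstance(features, ModeFeatures):
        if features.layout != "magnitude":
            raise ValueError("the fit expects the magnitude layout")
        target = np.atleast_2d(features.vector[..., :3])
    else:
        target = np.atleast_2d(np.asarray(features, dtype=float))
    if target.shape[-1] == 4:  # tolerate vectors with B1 appended
        b1 = target[:, 3]
        target = target[:, :3]
    if target.shape[-1] != 3:
        raise ValueError("expected (n, 3) magnitude feature vectors")
    norms = np.linalg.norm(target, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate all-zero feature vector")
    target = target / norms[:, None]

    n = target.shape[0]
    b1 = np.broadcast_to(np.asarray(b1, dtype=float), (n,)).copy()
    phi = phase_cycle_scheme(seq.n_pc)
    kernel = np.exp(-1j * np.outer(phi, [-1.0, 0.0, 1.0]))

    t1 = np.full(n, float(cfg.t1_init))
    t2 = np.full(n, 0.5 * (cfg.t2_bounds[0] + cfg.t2_bounds[1]))
    # inner iteration count for a bracket reduction below tol (relative)
    spans = (
        (cfg.t1_bounds[1] - cfg.t1_bounds[0]) / (cfg.tol * cfg.t1_init),
        (cfg.t2_bounds[1] - cfg.t2_bounds[0]) / (cfg.tol * cfg.t2_bounds[0]),
    )
    n_inner = int(np.ceil(np.log(max(spans)) / -np.log(_INVPHI))) + 1
    converged = np.zeros(n, dtype=bool)
    history = []
    for _ in range(cfg.max_iter):
        t1_old, t2_old = t1, t2
        t2 = _golden_min(
            lambda x: _objective(t1, x, b1, target, seq, phi, kernel),
            np.full(n, cfg.t2_bounds[0]),
            np.full(n, cfg.t2_bounds[1]),
            n_inner,
        )
        t1 = _golden_min(
            lambda x: _objective(x, t2, b1, target, seq, phi, kernel),
            np.maximum(np.full(n, cfg.t1_bounds[0]), t2),  # enforce T1 >= T2
            np.full(n, cfg.t1_bounds[1]),
            n_inner,
        )
        # Powell-style acceleration: a third golden search along the
        # direction of the last outer step.  Plain alternation crawls in
        # near-degenerate diagonal valleys (long-T1/long-T2 voxels where
        # the modes constrain mostly the T1/T2 ratio); searching the
        # combined direction restores fast convergence there.
        d1 = t1 - t1_old
        d2 = t2 - t2_old
        move = np.hypot(d1 / np.maximum(t1, 1e-9), d2 / np.maximum(t2, 1e-9))
        if np.any(move > cfg.tol):
            lam_hi = np.full(n, np.inf)
            for d, lo, hi, x in (
                (d1, cfg.t1_bounds[0], cfg.t1_bounds[1], t1),
                (d2, cfg.t2_bounds[0], cfg.t2_bounds[1], t2),
            ):
                with np.errstate(divide="ignore", invalid="ignore"):
                    room = np.where(d > 0, (hi - x) / d,
                                    np.where(d < 0, (lo - x) / d, np.inf))
                lam_hi = np.minimum(lam_hi, np.maximum(room, 0.0))
            lam_hi = np.where(np.isfinite(lam_hi), lam_hi, 0.0)
            lam = _golden_min(
                lambda L: _objective(
                    np.maximum(t1 + L * d1, t2 + L * d2),
                    t2 + L * d2, b1, target, seq, phi, kernel,
                ),
                np.zeros(n),
                lam_hi,
                n_inner,
            )
            t1 = np.maximum(t1 + lam * d1, t2 + lam * d2)
            t2 = t2 + lam * d2
        rel = np.maximum(
            np.abs(t1 - t1_old) / np.maximum(t1_old, 1e-9),
            np.abs(t2 - t2_old) / np.maximum(t2_old, 1e-9),
        )
        if trace:
            history.append(_objective(t1, t2, b1, target, seq, phi, kernel))
        converged = rel < cfg.tol
        if converged.all():
            break
    t1 = np.maximum(t1, t2)
    if trace:
        return t1, t2, converged, history
    return t1, t2, converged


class MiracleEstimator(BaseEstimator, RegressorMixin):
    """Scikit-learn wrapper around :func:`miracle_fit`.

    The estimator is training-free: :meth:`fit` only validates and stores
    the configuration.  ``predict`` consumes feature vectors
    ``(|F_-1|, |F_0|, |F_1|, B1)`` -- the same input contract as the
    magnitude-layout network estimators -- and returns ``(T1, T2)`` in ms.
    """

    layout = "magnitude"

    def __init__(
        self,
        seq: SequenceParams | None = None,
        t1_init: float = 1000.0,
        t1_bounds: tuple[float, float] = EXTENDED_T1_RANGE,
        t2_bounds: tuple[float, float] = EXTENDED_T2_RANGE,
        tol: float = 1e-4,
        max_iter: int = 50,
    ):
        self.seq = seq
        self.t1_init = t1_init
        self.t1_bounds = t1_bounds
        self.t2_bounds = t2_bounds
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X=None, y=None):
        self.seq_ = self.seq if self.seq is not None else SequenceParams()
        self.cfg_ = GssConfig(
            t1_init=self.t1_init,
            t1_bounds=self.t1_bounds,
            t2_bounds=self.t2_bounds,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        return self

    def predict(self, X):
        if not hasattr(self, "cfg_"):
            self.fit()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != 4:
            raise ValueError("expected (n, 4): |F_-1|, |F_0|, |F_1|, B1")
        t1, t2, self.converged_ = miracle_fit(
            X[:, :3], X[:, 3], self.seq_, self.cfg_
        )
        return np.stack([t1, t2], axis=1)

    def predict_from_signal(self, signals, b1):
        from .signal import features_from_signal

        feats = features_from_signal(np.asarray(signals, dtype=complex),
                                     "magnitude", np.asarray(b1, dtype=float))
        return self.predict(feats)
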