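"""MLP inverse solvers for pc-bSSFP relaxometry (supervised and
physics-informed).

Two estimator variants share one architecture family:

* **SVNN** (supervised): trained with an MSE between predicted and
  ground-truth parameters, each parameter affinely normalized to [0, 1]
  by its output range.
* **PINN** (physics-informed, self-supervised): trained with an MSE
  between the input mode features and the features regenerated from the
  predicted parameters through the analytic signal model -- no ground
  truth enters the loss.

Both exist in a magnitude flavour (inputs ``(|F_-1|, |F_0|, |F_1|, B1)``,
outputs ``(T1, T2)``, two hidden layers of 64 units, 4610 trainable
parameters) and a complex flavour (inputs
``(Re F_-1, Re F_0, Re F_1, Im F_-1, Im F_1, B1)``, outputs
``(T1, T2, theta)``, two hidden layers of 256 units, 68355 trainable
parameters).  Hidden layers use ReLU; the output layer is a sigmoid
mapped affinely to per-parameter (min, max) ranges, so predictions can
never leave the configured range (no extrapolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import _engine
from .datasets import (
    TrainingDataset,
    UNIFORM_T1_RANGE,
    UNIFORM_T2_RANGE,
)
from .signal import (
    SequenceParams,
    features_from_signal,
    n_features,
    noise_sigma,
    theta_to_delta_b0,
)

__all__ = [
    "MlpSpec",
    "TrainConfig",
    "TrainHistory",
    "build_mlp",
    "count_parameters",
    "svnn_loss",
    "pinn_loss",
    "MLPRelaxometer",
]


@dataclass(frozen=True)
class MlpSpec:
    """Architecture description of one estimator flavour."""

    n_in: int
    hidden: tuple[int, int]
    n_out: int

    @classmethod
    def for_layout(cls, layout: str) -> "MlpSpec":
        if layout == "magnitude":
            return cls(n_in=4, hidden=(64, 64), n_out=2)
        if layout == "complex":
            return cls(n_in=6, hidden=(256, 256), n_out=3)
        raise ValueError(f"unknown layout {layout!r}")


@dataclass
class TrainConfig:
    """Optimizer and schedule settings (defaults follow the reference
    protocol: Adam, fixed learning rate 2e-4, batch 128, early stopping
    with patience 25, at most 300 epochs)."""

    learning_rate: float = 2e-4
    batch_size: int = 128
    patience: int = 25
    max_epochs: int = 300
    snr_train: float = np.inf
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("training configuration values must be positive")
        if not (np.isinf(self.snr_train) or self.snr_train > 0):
            raise ValueError("snr_train must be positive or infinite")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class TrainHistory:
    """Per-epoch loss trajectory and the selected checkpoint."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    def __post_init__(self) -> None:
        if self.best_epoch >= 0 and self.best_epoch > self.stopped_epoch:
            raise ValueError("best epoch cannot exceed the stopping epoch")


def _init_params(spec: MlpSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """Dense-layer initialization: uniform(+-1/sqrt(fan_in)) for weights
    and biases (the PyTorch default Linear scheme)."""
    params = []
    sizes = [(spec.n_in, spec.hidden[0]), (spec.hidden[0], spec.hidden[1]),
             (spec.hidden[1], spec.n_out)]
    for fan_in, fan_out in sizes:
        bound = 1.0 / np.sqrt(fan_in)
        params.append(
            rng.uniform(-bound, bound, (fan_in, fan_out)).astype(np.float32)
        )
        params.append(rng.uniform(-bound, bound, fan_out).astype(np.float32))
    return params


def build_mlp(
    spec: MlpSpec,
    ranges: np.ndarray,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Initialize the parameter list [W1, b1, W2, b2, W3, b3].

    ``ranges`` is (n_out, 2) with finite min < max per output.
    """
    ranges = np.asarray(ranges, dtype=float)
    if ranges.shape != (spec.n_out, 2):
        raise ValueError("ranges must be (n_out, 2)")
    if not np.all(np.isfinite(ranges)) or not np.all(ranges[:, 0] < ranges[:, 1]):
        raise ValueError("output ranges must be finite with min < max")
    if rng is None:
        rng = np.random.default_rng()
    return _init_params(spec, rng)


def count_parameters(params: list[np.ndarray]) -> int:
    """Number of trainable parameters."""
    return int(sum(p.size for p in params))


def svnn_loss(pred: np.ndarray, target: np.ndarray, ranges: np.ndarray) -> float:
    """Supervised loss: MSE between predictions and targets, each
    parameter normalized to [0, 1] by its output range, averaged over
    parameters and batch."""
    ranges = np.asarray(ranges, dtype=float)
    lo, hi = ranges[:, 0], ranges[:, 1]
    p01 = (np.asarray(pred, dtype=float) - lo) / (hi - lo)
    t01 = (np.asarray(target, dtype=float) - lo) / (hi - lo)
    return float(np.mean((p01 - t01) ** 2))


def pinn_loss(
    pred: np.ndarray,
    b1: np.ndarray,
    features: np.ndarray,
    seq: SequenceParams,
    layout: str,
    ranges: np.ndarray,
) -> float:
    """Physics-informed loss: regenerate the pc-bSSFP signal from the
    predicted parameters (theta = 0 for the magnitude layout), run the
    identical feature pipeline and return the MSE to the input features
    (B1 entry excluded from the residual)."""
    ranges = np.asarray(ranges, dtype=float)
    lo, hi = ranges[:, 0], ranges[:, 1]
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    s01 = (pred - lo) / (hi - lo)
    feats = np.atleast_2d(np.asarray(features, dtype=float))[:, : n_features(layout)]
    vals = _engine.pinn_loss_values(
        s01, np.broadcast_to(np.asarray(b1, dtype=float), pred.shape[:1]).copy(),
        feats, lo, hi, seq, layout == "complex",
    )
    return float(vals.mean())


class MLPRelaxometer(BaseEstimator, RegressorMixin):
    """Neural-network T1/T2(/off-resonance) estimator for pc-bSSFP modes.

    Parameters
    ----------
    layout : {'magnitude', 'complex'}
        Input feature layout; selects the architecture flavour.
    strategy : {'svnn', 'pinn'}
        Supervised or physics-informed training loss.
    seq : SequenceParams, optional
        Acquisition protocol used for simulation-matched training and for
        the physics-informed loss.  Defaults to TR 4.8 ms / TE 2.4 ms /
        15 deg / 12 phase cycles.
    t1_range, t2_range : (float, float)
        Output ranges in ms; predictions are sigmoid-bounded to these.
        Default to the tissue-range training distribution.
    snr_train : float
        SNR of the per-batch training noise; ``inf`` trains noise-free.
    learning_rate, batch_size, max_epochs, patience, val_fraction :
        Optimizer schedule (see :class:`TrainConfig`).
    random_state : int, optional
        Seed for initialization, data split, shuffling and noise.

    Attributes
    ----------
    params_ : list of ndarray
        Trained weights/biases at the best validation epoch.
    history_ : TrainHistory
        Loss trajectory and checkpoint bookkeeping.
    n_parameters_ : int
        Trainable parameter count (4610 magnitude / 68355 complex).
    ranges_ : ndarray, (n_out, 2)
        Output scaling ranges ((T1), (T2)[, (theta)]).
    """

    _THETA_RANGE = (-np.pi, np.pi)

    def __init__(
        self,
        layout: str = "magnitude",
        strategy: str = "svnn",
        seq: SequenceParams | None = None,
        t1_range: tuple[float, float] = UNIFORM_T1_RANGE,
        t2_range: tuple[float, float] = UNIFORM_T2_RANGE,
        snr_train: float = np.inf,
        learning_rate: float = 2e-4,
        batch_size: int = 128,
        max_epochs: int = 300,
        patience: int = 25,
        val_fraction: float = 0.1,
        random_state: int | None = None,
        fd_eps: float = 1e-3,
        verbose: int = 0,
    ):
        self.layout = layout
        self.strategy = strategy
        self.seq = seq
        self.t1_range = t1_range
        self.t2_range = t2_range
        self.snr_train = snr_train
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.fd_eps = fd_eps
        self.verbose = verbose

    # -- helpers -----------------------------------------------------------
    def _resolved_seq(self) -> SequenceParams:
        return self.seq if self.seq is not None else SequenceParams()

    def _make_ranges(self) -> np.ndarray:
        rows = [self.t1_range, self.t2_range]
        if self.layout == "complex":
            rows.append(self._THETA_RANGE)
        return np.asarray(rows, dtype=float)

    def _check_variant(self) -> MlpSpec:
        if self.strategy not in ("svnn", "pinn"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        return MlpSpec.for_layout(self.layout)

    # -- estimator API -----------------------------------------------------
    def fit(self, S, y=None):
        """Train on clean complex pc-bSSFP signals.

        Parameters
        ----------
        S : TrainingDataset or complex ndarray (n, n_pc)
            Clean signals; noise (if ``snr_train`` is finite) is drawn
            freshly inside every batch.
        y : ndarray (n, 4), columns (T1 ms, T2 ms, theta rad, B1)
            Ground-truth parameters.  Required when ``S`` is an array.
            Only B1 (and the supervised targets) are consumed; the
            physics-informed strategy never sees T1/T2/theta.
        """
        spec = self._check_variant()
        seq = self._resolved_seq()
        if isinstance(S, TrainingDataset):
            if S.mode != self.layout:
                raise ValueError(
                    f"dataset mode {S.mode!r} does not match layout {self.layout!r}"
                )
            signals, y = S.signals, S.targets
            seq = S.seq
        else:
            signals = np.asarray(S)
            if y is None:
                raise ValueError("y is required when S is a signal array")
        y = np.asarray(y, dtype=float)
        if signals.ndim != 2 or signals.shape[-1] != seq.n_pc:
            raise ValueError("signals must be (n, n_pc) matching the protocol")
        if y.shape != (signals.shape[0], 4):
            raise ValueError("targets must be (n, 4): T1, T2, theta, B1")
        if self.layout == "magnitude" and np.any(y[:, 2] != 0.0):
            raise ValueError("magnitude variants require on-resonant (theta=0) data")

        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            patience=self.patience,
            max_epochs=self.max_epochs,
            snr_train=self.snr_train,
            val_fraction=self.val_fraction,
            seed=self.random_state if self.random_state is not None else 0,
        )
        rng = np.random.default_rng(cfg.seed)
        ranges = self._make_ranges()
        params = build_mlp(spec, ranges, rng)
        self._train(params, spec, signals, y, seq, cfg, rng)
        self.seq_ = seq
        self.spec_ = spec
        self.ranges_ = ranges
        self.n_parameters_ = count_parameters(self.params_)
        return self

    def _features(self, signals: np.ndarray, b1: np.ndarray) -> np.ndarray:
        return features_from_signal(
            np.asarray(signals, dtype=complex), self.layout, b1
        ).astype(np.float32)

    def _train(self, params, spec, signals, y, seq, cfg, rng) -> None:
        n = signals.shape[0]
        n_val = max(1, int(round(cfg.val_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if tr_idx.size < cfg.batch_size:
            raise ValueError("not enough training samples for one batch")

        X = self._features(signals, y[:, 3])
        Xtr = np.ascontiguousarray(X[tr_idx])
        Xval = np.ascontiguousarray(X[val_idx])
        lo, hi = self._make_ranges()[:, 0], self._make_ranges()[:, 1]
        cols = [0, 1, 2][: spec.n_out]
        Y01 = ((y[:, cols] - lo) / (hi - lo)).astype(np.float32)
        Ytr = np.ascontiguousarray(Y01[tr_idx])
        Yval = np.ascontiguousarray(Y01[val_idx])

        eta = noise_sigma(cfg.snr_train)
        sig_re = np.ascontiguousarray(signals.real[tr_idx], dtype=np.float64)
        sig_im = np.ascontiguousarray(signals.imag[tr_idx], dtype=np.float64)
        val_re = np.ascontiguousarray(signals.real[val_idx], dtype=np.float64)
        val_im = np.ascontiguousarray(signals.imag[val_idx], dtype=np.float64)
        phi = seq.phases
        cx = self.layout == "complex"
        lo3 = np.zeros(3)
        hi3 = np.zeros(3)
        lo3[: spec.n_out] = lo
        hi3[: spec.n_out] = hi
        ms = [np.zeros(p.size, np.float32) for p in params]
        vs = [np.zeros(p.size, np.float32) for p in params]
        W1, b1_, W2, b2_, W3, b3_ = params
        msT = tuple(ms)
        vsT = tuple(vs)

        history = TrainHistory()
        best_val = np.inf
        best_params = [p.copy() for p in params]
        tstep = 0
        epochs_since_best = 0
        base_seed = int(rng.integers(0, 2**31 - 1))
        for epoch in range(cfg.max_epochs):
            ep_seed = (base_seed + epoch) % (2**31 - 1)
            if self.strategy == "svnn":
                tstep = _engine.svnn_epoch(
                    Xtr, Ytr, sig_re, sig_im, eta, phi, cx,
                    W1, b1_, W2, b2_, W3, b3_, msT, vsT,
                    np.float32(cfg.learning_rate), cfg.batch_size, ep_seed, tstep,
                )
            else:
                tstep = _engine.pinn_epoch(
                    Xtr, sig_re, sig_im, eta, phi, cx, lo3, hi3,
                    float(seq.tr), float(seq.te), float(np.deg2rad(seq.alpha)),
                    W1, b1_, W2, b2_, W3, b3_, msT, vsT,
                    np.float32(cfg.learning_rate), cfg.batch_size, ep_seed, tstep,
                    self.fd_eps,
                )
            val = self._validation_loss(
                params, Xval, Yval, val_re, val_im, eta, seq, rng
            )
            history.val_loss.append(val)
            # training loss tracked on a capped subsample (noise-free view)
            ntr_probe = min(len(Xtr), 5_000)
            history.train_loss.append(
                self._validation_loss(
                    params, Xtr[:ntr_probe], Ytr[:ntr_probe],
                    sig_re[:ntr_probe], sig_im[:ntr_probe], eta, seq, rng,
                )
            )
            if val < best_val:
                best_val = val
                best_params = [p.copy() for p in params]
                history.best_epoch = epoch
                epochs_since_best = 0
            else:
                epochs_since_best += 1
            if self.verbose and (epoch % max(1, self.verbose) == 0):
                print(f"epoch {epoch + 1}: val loss {val:.3e}")
            if epochs_since_best >= cfg.patience:
                break
        history.stopped_epoch = epoch
        self.params_ = best_params
        self.history_ = history

    def _validation_loss(self, params, Xval, Yval, val_re, val_im, eta, seq, rng):
        """Validation under the training conditions: noise-free features
        when training is noise-free, freshly-noised ones otherwise."""
        if eta > 0.0:
            noisy = (
                val_re + rng.normal(0.0, eta, val_re.shape)
                + 1j * (val_im + rng.normal(0.0, eta, val_im.shape))
            )
            feats = features_from_signal(noisy, self.layout, Xval[:, -1].astype(float))
            Xv = feats.astype(np.float32)
        else:
            Xv = Xval
        s = _engine.forward(Xv, params)
        if self.strategy == "svnn":
            return float(np.mean((s - Yval) ** 2))
        nf = n_features(self.layout)
        lo, hi = self._make_ranges()[:, 0], self._make_ranges()[:, 1]
        vals = _engine.pinn_loss_values(
            s.astype(float), Xv[:, nf].astype(float), Xv[:, :nf].astype(float),
            lo, hi, seq, self.layout == "complex",
        )
        return float(vals.mean())

    def predict(self, X):
        """Predict from feature vectors (n, 4) or (n, 6).

        Returns (n, 2) columns (T1 ms, T2 ms) for the magnitude layout or
        (n, 3) with theta (rad) appended for the complex layout.
        """
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.spec_.n_in:
            raise ValueError(
                f"expected {self.spec_.n_in} features for layout "
                f"{self.layout!r}, got {X.shape[1]}"
            )
        s = _engine.forward(np.ascontiguousarray(X), self.params_)
        lo, hi = self.ranges_[:, 0], self.ranges_[:, 1]
        return lo + s.astype(float) * (hi - lo)

    def predict_from_signal(self, signals, b1):
        """Convenience: run the feature pipeline then predict."""
        check_is_fitted(self, "params_")
        feats = self._features(signals, np.asarray(b1, dtype=float))
        return self.predict(feats)

    def predict_delta_b0(self, X):
        """Off-resonance predictions in Hz (complex layout only)."""
        if self.layout != "complex":
            raise ValueError("off-resonance is only predicted by the complex layout")
        pred = self.predict(X)
        return theta_to_delta_b0(pred[:, 2], self.seq_.tr)
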