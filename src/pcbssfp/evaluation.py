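"""Monte-Carlo accuracy/precision validation of relaxometry estimators.

For each test point the clean pc-bSSFP signal is simulated, ``n_mc``
noisy replicates are drawn, the estimator is run per replicate and the
predictions are aggregated into the MC mean (accuracy proxy), MC
standard deviation (precision), relative standard deviation and the
signed relative error in percent.  A global coefficient of determination
per parameter compares MC means with the ground truth across all points.
Every estimator (network-based or golden-section fit) runs through the
same harness via its feature layout and ``predict``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal import (
    SequenceParams,
    TissueParams,
    add_noise,
    features_from_signal,
    simulate_pc_signal,
)

__all__ = ["MCResult", "relative_error", "cod", "monte_carlo", "delta_cod",
           "theta_sweep"]

REFERENCE_SNR_LADDER = (np.inf, 50, 45, 40, 35, 30, 25, 20, 15, 10)


def relative_error(pred_mean, truth):
    """Signed relative error in percent: ``(pred - truth)/truth * 100``."""
    truth = np.asarray(truth, dtype=float)
    if np.any(truth == 0):
        raise ValueError("relative error undefined for zero truth")
    return (np.asarray(pred_mean, dtype=float) - truth) / truth * 100.0


def cod(observed, predicted):
    """Coefficient of determination
    ``1 - sum((y - yhat)^2) / sum((y - ybar)^2)``."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("observed/predicted must be equal-length, size >= 2")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("constant observed vector: CoD undefined")
    return float(1.0 - np.sum((y - yhat) ** 2) / ss_tot)


@dataclass
class MCResult:
    """Per-point Monte-Carlo summaries plus global per-parameter CoD.

    Arrays have shape (n_points, n_params) with parameter order
    (T1, T2).  ``sigma_rel`` is NaN where the MC mean is zero.
    """

    t1_true: np.ndarray
    t2_true: np.ndarray
    mu_mc: np.ndarray
    sigma_mc: np.ndarray
    sigma_rel: np.ndarray
    eps_rel: np.ndarray
    cod: dict = field(default_factory=dict)
    n_mc: int = 0
    snr: float = np.inf
    n_failed: int = 0

    def to_dataframe(self, estimator: str = "") -> pd.DataFrame:
        rows = []
        for j, param in enumerate(("T1", "T2")):
            rows.append(
                pd.DataFrame(
                    {
                        "estimator": estimator,
                        "parameter": param,
                        "T1_true": self.t1_true,
                        "T2_true": self.t2_true,
                        "snr": self.snr,
                        "mu_mc": self.mu_mc[:, j],
                        "sigma_mc": self.sigma_mc[:, j],
                        "sigma_rel": self.sigma_rel[:, j],
                        "eps_rel": self.eps_rel[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _predict_t1t2(estimator, signals, b1):
    feats = features_from_signal(signals, estimator.layout, b1)
    return np.asarray(estimator.predict(feats))[:, :2]


def monte_carlo(
    estimator,
    points: TissueParams,
    seq: SequenceParams,
    snr: float,
    n_mc: int,
    rng: np.random.Generator,
) -> MCResult:
    """MC validation of one estimator on a set of test points.

    The estimator must expose ``layout`` ('magnitude' or 'complex') and
    ``predict`` on feature batches.  Replicates failing inside the
    estimator are excluded and counted in ``n_failed``.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    clean = simulate_pc_signal(points, seq).values
    n_points = clean.shape[0]
    b1 = np.broadcast_to(np.asarray(points.b1, dtype=float), (n_points,))
    preds = np.full((n_mc, n_points, 2), np.nan)
    n_failed = 0
    for r in range(n_mc):
        noisy = add_noise(clean, snr, rng)
        try:
            preds[r] = _predict_t1t2(estimator, noisy, b1)
        except Exception:
            n_failed += 1
    ok = ~np.isnan(preds[:, 0, 0])
    preds = preds[ok]
    mu = preds.mean(axis=0)
    sigma = preds.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_rel = np.where(mu != 0, sigma / mu, np.nan)
    truth = np.stack(
        [np.asarray(points.t1, dtype=float), np.asarray(points.t2, dtype=float)],
        axis=1,
    )
    eps = relative_error(mu, truth)
    cods = {
        "T1": cod(truth[:, 0], mu[:, 0]),
        "T2": cod(truth[:, 1], mu[:, 1]),
    }
    return MCResult(
        t1_true=truth[:, 0],
        t2_true=truth[:, 1],
        mu_mc=mu,
        sigma_mc=sigma,
        sigma_rel=sigma_rel,
        eps_rel=eps,
        cod=cods,
        n_mc=int(preds.shape[0]),
        snr=snr,
        n_failed=n_failed,
    )


def delta_cod(
    estimator_a,
    estimator_b,
    points: TissueParams,
    seq: SequenceParams,
    snr: float,
    n_mc: int,
    rng: np.random.Generator,
) -> dict:
    """CoD difference (a minus b) per parameter under a paired design:
    both estimators see the identical noise replicates."""
    seed = int(rng.integers(0, 2**31 - 1))
    res_a = monte_carlo(estimator_a, points, seq, snr, n_mc,
                        np.random.default_rng(seed))
    res_b = monte_carlo(estimator_b, points, seq, snr, n_mc,
                        np.random.default_rng(seed))
    return {k: res_a.cod[k] - res_b.cod[k] for k in res_a.cod}


def theta_sweep(
    estimator,
    point: TissueParams,
    seq: SequenceParams,
    n_theta: int = 200,
) -> pd.DataFrame:
    """Noise-free relative-error curves across off-resonance.

    Simulates the base point at ``n_theta`` theta values spanning the
    open interval (-pi, pi) and returns per-theta signed relative errors
    for T1 and T2 (percent).
    """
    if n_theta < 3:
        raise ValueError("n_theta must be >= 3")
    # cell-centered grid: spans the open interval, excludes +-pi exactly
    thetas = -np.pi + (2.0 * np.pi) * (np.arange(n_theta) + 0.5) / n_theta
    t1 = float(np.asarray(point.t1))
    t2 = float(np.asarray(point.t2))
    b1 = float(np.asarray(point.b1))
    sweep = TissueParams(
        t1=np.full(n_theta, t1),
        t2=np.full(n_theta, t2),
        b1=np.full(n_theta, b1),
        theta=thetas,
    )
    signals = simulate_pc_signal(sweep, seq).values
    pred = _predict_t1t2(estimator, signals, np.full(n_theta, b1))
    return pd.DataFrame(
        {
            "theta": thetas,
            "eps_rel_t1": relative_error(pred[:, 0], t1),
            "eps_rel_t2": relative_error(pred[:, 1], t2),
        }
    )
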