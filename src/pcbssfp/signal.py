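"""Analytical phase-cycled bSSFP signal model and SSFP configuration modes.

This is the physics kernel shared by the in-silico data generator, the
physics-informed training loss, the golden-section-search reference fit,
and the phantom pipeline.

The steady-state single-isochromat bSSFP signal at RF phase increment
``phi`` is

    S = M0 (1 - E1)(1 - E2 e^{-i psi}) sin(a) / (C cos(psi) + D)
        * e^{-TE/T2} * e^{i theta TE/TR}

with ``psi = theta - phi``, ``E1 = exp(-TR/T1)``, ``E2 = exp(-TR/T2)``,
``C = E2 (E1 - 1)(1 + cos a)``, ``D = (1 - E1 cos a) - (E1 - cos a) E2^2``,
actual flip angle ``a = B1 * alpha_nom`` and ``M0 = 1``.  ``theta`` is the
off-resonance phase accumulated per TR (``delta_B0 = theta / (2 pi TR)``).

SSFP configuration modes are the Fourier coefficients of the signal with
respect to the phase-cycle dimension,

    F_n = (1 / N_pc) sum_j S(phi_j) e^{-i n phi_j},

so that ``F_0`` is the across-cycle mean.  For a finite number of phase
cycles the higher-order modes alias into ``F_{-1}, F_0, F_1``, which makes
the extracted modes sensitive to ``theta`` at small ``N_pc``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NOISE_SCALE",
    "SequenceParams",
    "TissueParams",
    "PcSignal",
    "ModeFeatures",
    "phase_cycle_scheme",
    "bssfp_signal",
    "simulate_pc_signal",
    "remove_average_phase",
    "compute_modes",
    "noise_sigma",
    "add_noise",
    "mode_features",
    "to_features",
    "features_from_signal",
    "n_features",
    "theta_to_delta_b0",
]

# Protocol-level signal-scale constant entering the noise level
# eta = NOISE_SCALE / (sqrt(2) * SNR).  It represents the mean tissue
# signal scale of the F0 configuration for M0 = 1 at the default protocol.
NOISE_SCALE = 0.074

_DEFAULT_ORDERS = (-1, 0, 1)


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition settings of a phase-cycled bSSFP protocol.

    Parameters
    ----------
    tr : float
        Repetition time in ms.
    te : float
        Echo time in ms, ``0 < te <= tr``.
    alpha : float
        Nominal flip angle in degrees (converted to radians internally).
    n_pc : int
        Number of phase cycles, ``>= 2``.
    """

    tr: float = 4.8
    te: float = 2.4
    alpha: float = 15.0
    n_pc: int = 12

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if not 0 < self.te <= self.tr:
            raise ValueError(f"TE must satisfy 0 < TE <= TR, got {self.te}")
        if not 0 < self.alpha < 180:
            raise ValueError(f"flip angle must be in (0, 180) deg, got {self.alpha}")
        if int(self.n_pc) < 2 or self.n_pc != int(self.n_pc):
            raise ValueError(f"n_pc must be an integer >= 2, got {self.n_pc}")

    @property
    def phases(self) -> np.ndarray:
        return phase_cycle_scheme(self.n_pc)


@dataclass(frozen=True)
class TissueParams:
    """One voxel's (or a batch of voxels') ground-truth physical state.

    ``t1``/``t2`` in ms, ``b1`` the transmit scaling factor
    (actual/nominal flip angle) and ``theta`` the off-resonance phase
    accumulation per TR in radians.  Fields may be scalars or arrays of a
    common broadcastable shape.
    """

    t1: np.ndarray | float
    t2: np.ndarray | float
    b1: np.ndarray | float = 1.0
    theta: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        t1 = np.asarray(self.t1, dtype=float)
        t2 = np.asarray(self.t2, dtype=float)
        b1 = np.asarray(self.b1, dtype=float)
        if np.any(t1 <= 0) or np.any(t2 <= 0):
            raise ValueError("T1 and T2 must be positive")
        if np.any(b1 <= 0):
            raise ValueError("B1 scaling must be positive")
        object.__setattr__(self, "t1", t1)
        object.__setattr__(self, "t2", t2)
        object.__setattr__(self, "b1", b1)
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))

    def delta_b0(self, seq: SequenceParams) -> np.ndarray | float:
        """Off-resonance in Hz for reporting, ``theta / (2 pi TR)``."""
        return theta_to_delta_b0(self.theta, seq.tr)


@dataclass
class PcSignal:
    """Complex pc-bSSFP signal along the phase-cycle dimension.

    ``values`` has shape ``(..., n_pc)``; ``phases`` is the phase-cycle
    scheme ``phi(j)`` in radians.
    """

    values: np.ndarray
    phases: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.phases = np.asarray(self.phases, dtype=float)
        if self.values.shape[-1] != self.phases.shape[-1]:
            raise ValueError("values and phases must share the phase-cycle length")

    @property
    def n_pc(self) -> int:
        return self.phases.shape[-1]


@dataclass
class ModeFeatures:
    """Configuration modes arranged as a network/fit input vector.

    ``layout='magnitude'`` uses ``(|F_-1|, |F_0|, |F_1|)``;
    ``layout='complex'`` uses ``(Re F_-1, Re F_0, Re F_1, Im F_-1, Im F_1)``
    (Im F_0 vanishes by construction after average-phase removal).  The
    vector is Euclidean-normalized before B1 is appended.
    """

    modes: np.ndarray
    layout: str
    vector: np.ndarray
    normalized: bool = True
    b1: np.ndarray | float | None = field(default=None)


def theta_to_delta_b0(theta: np.ndarray | float, tr_ms: float) -> np.ndarray | float:
    """Convert phase accumulation per TR (rad) to off-resonance in Hz."""
    return np.asarray(theta) / (2.0 * np.pi * tr_ms * 1e-3)


def phase_cycle_scheme(n_pc: int) -> np.ndarray:
    """RF phase increments ``phi(j) = pi/N_pc * (2j - 1)``, j = 1..N_pc.

    The scheme distributes the increments evenly over (0, 2 pi) and is
    symmetric about pi.
    """
    if int(n_pc) < 2 or n_pc != int(n_pc):
        raise ValueError(f"n_pc must be an integer >= 2, got {n_pc}")
    j = np.arange(1, int(n_pc) + 1)
    return np.pi / int(n_pc) * (2 * j - 1)


def bssfp_signal(
    tissue: TissueParams,
    seq: SequenceParams,
    phi: np.ndarray | float,
) -> np.ndarray | complex:
    """Evaluate the steady-state bSSFP signal at RF phase increment ``phi``.

    All tissue fields and ``phi`` broadcast against each other; the result
    is complex with ``M0 = 1``.
    """
    return _bssfp_signal_arrays(
        tissue.t1, tissue.t2, tissue.b1, tissue.theta, seq, phi
    )


def _bssfp_signal_arrays(t1, t2, b1, theta, seq: SequenceParams, phi):
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("T1 and T2 must be positive")
    a = np.deg2rad(seq.alpha) * np.asarray(b1, dtype=float)
    e1 = np.exp(-seq.tr / t1)
    e2 = np.exp(-seq.tr / t2)
    psi = np.asarray(theta, dtype=float) - np.asarray(phi, dtype=float)
    cos_a = np.cos(a)
    c = e2 * (e1 - 1.0) * (1.0 + cos_a)
    d = (1.0 - e1 * cos_a) - (e1 - cos_a) * e2 * e2
    s = (
        (1.0 - e1)
        * (1.0 - e2 * np.exp(-1j * psi))
        * np.sin(a)
        / (c * np.cos(psi) + d)
    )
    return s * np.exp(-seq.te / t2) * np.exp(1j * np.asarray(theta) * (seq.te / seq.tr))


def simulate_pc_signal(tissue: TissueParams, seq: SequenceParams) -> PcSignal:
    """Simulate the full phase-cycled signal at every ``phi(j)``.

    Tissue fields of shape ``(...)`` yield values of shape ``(..., n_pc)``.
    """
    phi = phase_cycle_scheme(seq.n_pc)
    t1 = np.asarray(tissue.t1)[..., None]
    t2 = np.asarray(tissue.t2)[..., None]
    b1 = np.asarray(tissue.b1)[..., None]
    theta = np.asarray(tissue.theta)[..., None]
    values = _bssfp_signal_arrays(t1, t2, b1, theta, seq, phi)
    return PcSignal(values=values, phases=phi)


def _as_values(s: PcSignal | np.ndarray) -> np.ndarray:
    if isinstance(s, PcSignal):
        return s.values
    return np.asarray(s, dtype=complex)


def remove_average_phase(s: PcSignal | np.ndarray) -> PcSignal | np.ndarray:
    """Remove the constant phase offset across phase cycles.

    Each signal is rotated by the negative phase of its across-cycle
    complex mean (the phase of the F0 configuration).  This removes
    receiver-related constant phase offsets and the global
    ``e^{i theta TE/TR}`` factor, makes Im F0 vanish identically, and is a
    continuous (and idempotent) operation of the signal.  A signal whose
    across-cycle mean is zero is returned unrotated with a warning.
    """
    values = _as_values(s)
    mean = values.mean(axis=-1)
    zero = np.abs(mean) == 0.0
    if np.any(zero):
        warnings.warn(
            "average phase undefined for zero-mean signal; left unrotated",
            RuntimeWarning,
            stacklevel=2,
        )
        mean = np.where(zero, 1.0, mean)
    rotated = values * np.exp(-1j * np.angle(mean))[..., None]
    if isinstance(s, PcSignal):
        return PcSignal(values=rotated, phases=s.phases)
    return rotated


def compute_modes(
    s: PcSignal | np.ndarray,
    orders: tuple[int, ...] = _DEFAULT_ORDERS,
) -> np.ndarray:
    """Extract SSFP configuration modes by DFT along the phase cycles.

    ``F_n = (1/N_pc) sum_j values_j e^{-i n phi_j}``; ``F_0`` equals the
    across-cycle mean.  Orders with ``|n| >= n_pc/2`` are aliased by
    construction.  Returns shape ``(..., len(orders))``.
    """
    values = _as_values(s)
    if isinstance(s, PcSignal):
        phi = s.phases
    else:
        phi = phase_cycle_scheme(values.shape[-1])
    kernel = np.exp(-1j * np.outer(phi, np.asarray(orders, dtype=float)))
    return values @ kernel / values.shape[-1]


def noise_sigma(snr: float, scale: float = NOISE_SCALE) -> float:
    """Per-channel Gaussian noise level ``eta = scale / (sqrt(2) SNR)``.

    ``snr=inf`` gives 0.
    """
    if np.isinf(snr):
        return 0.0
    if snr <= 0:
        raise ValueError(f"SNR must be positive or infinite, got {snr}")
    return scale / (np.sqrt(2.0) * snr)


def add_noise(
    s: PcSignal | np.ndarray,
    snr: float,
    rng: np.random.Generator,
    scale: float = NOISE_SCALE,
) -> PcSignal | np.ndarray:
    """Corrupt real and imaginary parts with i.i.d. Gaussian noise.

    The noise standard deviation per channel is
    ``eta = scale / (sqrt(2) * snr)``; ``snr=inf`` returns the input
    unchanged.
    """
    eta = noise_sigma(snr, scale)
    values = _as_values(s)
    if eta > 0.0:
        noise = rng.normal(0.0, eta, values.shape + (2,))
        values = values + noise[..., 0] + 1j * noise[..., 1]
    if isinstance(s, PcSignal):
        return PcSignal(values=values, phases=s.phases)
    return values


def n_features(layout: str) -> int:
    """Length of the normalized mode-feature vector (B1 excluded)."""
    if layout == "magnitude":
        return 3
    if layout == "complex":
        return 5
    raise ValueError(f"unknown layout {layout!r}")


def mode_features(modes: np.ndarray, layout: str) -> np.ndarray:
    """Arrange modes ``(F_-1, F_0, F_1)`` as a Euclidean-normalized vector.

    Magnitude layout: ``(|F_-1|, |F_0|, |F_1|)``.  Complex layout:
    ``(Re F_-1, Re F_0, Re F_1, Im F_-1, Im F_1)`` -- Im F_0 is omitted
    since it vanishes after average-phase removal.
    """
    modes = np.asarray(modes)
    if modes.shape[-1] != 3:
        raise ValueError("expected the three lowest-order modes (F_-1, F_0, F_1)")
    if layout == "magnitude":
        vec = np.abs(modes)
    elif layout == "complex":
        vec = np.concatenate([modes.real, modes[..., [0, 2]].imag], axis=-1)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    norm = np.linalg.norm(vec, axis=-1, keepdims=True)
    if np.any(norm == 0.0):
        raise ValueError("degenerate all-zero mode vector cannot be normalized")
    return vec / norm


def to_features(
    modes: np.ndarray,
    layout: str,
    b1: np.ndarray | float,
) -> ModeFeatures:
    """Build the network/fit input: normalized mode vector plus B1.

    The mode part is Euclidean-normalized; B1 is appended unnormalized,
    giving vectors of length 4 (magnitude) or 6 (complex).
    """
    vec = mode_features(modes, layout)
    b1_arr = np.broadcast_to(
        np.asarray(b1, dtype=float)[..., None], vec.shape[:-1] + (1,)
    )
    vector = np.concatenate([vec, b1_arr], axis=-1)
    return ModeFeatures(
        modes=np.asarray(modes), layout=layout, vector=vector, normalized=True, b1=b1
    )


def features_from_signal(
    values: np.ndarray,
    layout: str,
    b1: np.ndarray | float,
) -> np.ndarray:
    """Full feature pipeline: average-phase removal, mode extraction,
    layout selection, Euclidean normalization, B1 appended.

    ``values`` has shape ``(..., n_pc)``; returns ``(..., 4)`` or
    ``(..., 6)`` float arrays.  This is the single code path used for
    training data, inference and the physics-informed loss.
    """
    values = np.asarray(values, dtype=complex)
    cleaned = remove_average_phase(values)
    modes = compute_modes(cleaned)
    return to_features(modes, layout, b1).vector
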