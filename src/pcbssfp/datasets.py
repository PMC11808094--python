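"""Training/test parameter sampling and serialized dataset assembly.

Three T1/T2 sampling distributions are supported: a tissue-range uniform
distribution (T1 in [360, 2080] ms, T2 in [20, 120] ms), an extended
uniform distribution (T1 up to 5000 ms, T2 up to 2500 ms) covering fluids,
and a brain-like 2D density over the tissue-range support.  Combinations
with T1 < T2 are rejected for all distributions; B1 is uniform in
[0.7, 1.3]; the off-resonance phase theta is 0 in magnitude mode and
uniform in the open interval (-pi, pi) in complex mode.

The brain-like density is a synthetic stand-in built from two anisotropic
Gaussian clusters (white-matter-like and gray-matter-like tissue); real
subject-derived densities are not part of the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from .signal import SequenceParams, TissueParams, simulate_pc_signal

__all__ = [
    "UNIFORM_T1_RANGE",
    "UNIFORM_T2_RANGE",
    "EXTENDED_T1_RANGE",
    "EXTENDED_T2_RANGE",
    "B1_RANGE",
    "ParameterDistribution",
    "uniform_distribution",
    "uniform_extended_distribution",
    "synthetic_in_vivo_density",
    "sample_parameters",
    "TrainingDataset",
    "build_dataset",
    "save_dataset",
    "load_dataset",
    "build_test_grid",
]

UNIFORM_T1_RANGE = (360.0, 2080.0)
UNIFORM_T2_RANGE = (20.0, 120.0)
EXTENDED_T1_RANGE = (360.0, 5000.0)
EXTENDED_T2_RANGE = (20.0, 2500.0)
B1_RANGE = (0.7, 1.3)

# Synthetic brain-like density stand-in: (T1 ms, T2 ms) cluster centers and
# standard deviations for white-matter-like and gray-matter-like tissue.
_WM_CLUSTER = {"center": (900.0, 60.0), "sigma": (80.0, 8.0), "weight": 0.6}
_GM_CLUSTER = {"center": (1400.0, 75.0), "sigma": (130.0, 10.0), "weight": 0.4}


@dataclass
class ParameterDistribution:
    """A T1/T2 sampling distribution with B1 and theta ranges.

    ``kind`` is one of ``{"uniform", "uniform_extended", "in_vivo_density"}``.
    For the density kind, ``density`` is a 2D histogram over
    ``(t1_edges, t2_edges)`` bins normalized to unit mass with zero mass at
    T1 < T2 bins.
    """

    kind: str
    t1_range: tuple[float, float]
    t2_range: tuple[float, float]
    b1_range: tuple[float, float] = B1_RANGE
    density: np.ndarray | None = None
    t1_edges: np.ndarray | None = None
    t2_edges: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def uniform_distribution() -> ParameterDistribution:
    """Tissue-range uniform distribution."""
    return ParameterDistribution("uniform", UNIFORM_T1_RANGE, UNIFORM_T2_RANGE)


def uniform_extended_distribution() -> ParameterDistribution:
    """Uniform distribution with extended T1/T2 ranges covering fluids."""
    return ParameterDistribution(
        "uniform_extended", EXTENDED_T1_RANGE, EXTENDED_T2_RANGE
    )


def synthetic_in_vivo_density(
    rng: np.random.Generator | None = None,
    n_bins: int = 200,
    clusters: tuple[dict, dict] = (_WM_CLUSTER, _GM_CLUSTER),
) -> ParameterDistribution:
    """Brain-like 2D (T1, T2) density on the tissue-range support.

    A mixture of two anisotropic Gaussian clusters (WM-like and GM-like)
    evaluated on an ``n_bins x n_bins`` grid, truncated to the uniform
    support and to T1 >= T2, and renormalized to unit mass.  ``rng`` is
    accepted for interface symmetry (the density itself is deterministic
    for fixed cluster parameters).
    """
    t1_edges = np.linspace(*UNIFORM_T1_RANGE, n_bins + 1)
    t2_edges = np.linspace(*UNIFORM_T2_RANGE, n_bins + 1)
    t1_mid = 0.5 * (t1_edges[:-1] + t1_edges[1:])
    t2_mid = 0.5 * (t2_edges[:-1] + t2_edges[1:])
    tt1, tt2 = np.meshgrid(t1_mid, t2_mid, indexing="ij")
    density = np.zeros_like(tt1)
    for cl in clusters:
        c1, c2 = cl["center"]
        s1, s2 = cl["sigma"]
        density += cl["weight"] * np.exp(
            -0.5 * (((tt1 - c1) / s1) ** 2 + ((tt2 - c2) / s2) ** 2)
        )
    density[tt1 < tt2] = 0.0
    density /= density.sum()
    return ParameterDistribution(
        "in_vivo_density",
        UNIFORM_T1_RANGE,
        UNIFORM_T2_RANGE,
        density=density,
        t1_edges=t1_edges,
        t2_edges=t2_edges,
        meta={"clusters": [dict(c) for c in clusters]},
    )


def _sample_t1t2(
    dist: ParameterDistribution, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if dist.kind in ("uniform", "uniform_extended"):
        t1 = np.empty(n)
        t2 = np.empty(n)
        todo = np.ones(n, dtype=bool)
        # rejection sampling of the T1 >= T2 constraint
        while todo.any():
            m = int(todo.sum())
            t1[todo] = rng.uniform(*dist.t1_range, m)
            t2[todo] = rng.uniform(*dist.t2_range, m)
            todo &= ~(t1 >= t2)
        return t1, t2
    if dist.kind == "in_vivo_density":
        if dist.density is None:
            raise ValueError("density distribution requires a density map")
        p = dist.density.ravel()
        idx = rng.choice(p.size, size=n, p=p)
        i1, i2 = np.unravel_index(idx, dist.density.shape)
        w1 = np.diff(dist.t1_edges)[i1]
        w2 = np.diff(dist.t2_edges)[i2]
        t1 = dist.t1_edges[i1] + rng.uniform(0, 1, n) * w1
        t2 = dist.t2_edges[i2] + rng.uniform(0, 1, n) * w2
        # in-bin jitter may cross the diagonal in diagonal bins
        swap = t1 < t2
        t1[swap], t2[swap] = t2[swap], t1[swap].copy()
        return t1, t2
    raise ValueError(f"unknown distribution kind {dist.kind!r}")


def sample_parameters(
    dist: ParameterDistribution,
    n: int,
    mode: str,
    rng: np.random.Generator,
) -> TissueParams:
    """Draw ``n`` tissue parameter samples.

    ``mode='magnitude'`` assumes on-resonance (theta = 0); in
    ``mode='complex'`` theta is uniform in the open interval (-pi, pi),
    resampling the (measure-zero but excluded) boundary values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("magnitude", "complex"):
        raise ValueError(f"unknown mode {mode!r}")
    if dist.t1_range[1] < dist.t2_range[0]:
        raise ValueError("empty feasible region: T1 range entirely below T2 range")
    t1, t2 = _sample_t1t2(dist, n, rng)
    b1 = rng.uniform(*dist.b1_range, n)
    if mode == "complex":
        theta = rng.uniform(-np.pi, np.pi, n)
        bad = np.abs(theta) == np.pi
        while bad.any():
            theta[bad] = rng.uniform(-np.pi, np.pi, int(bad.sum()))
            bad = np.abs(theta) == np.pi
    else:
        theta = np.zeros(n)
    return TissueParams(t1=t1, t2=t2, b1=b1, theta=theta)


@dataclass
class TrainingDataset:
    """Clean complex pc-bSSFP training signals with 4-column targets.

    ``signals`` is complex64 of shape ``(n, n_pc)``; ``targets`` is float32
    of shape ``(n, 4)`` with columns (T1 ms, T2 ms, theta rad, B1).  Noise
    is *not* stored; it is drawn freshly per training batch.
    """

    signals: np.ndarray
    targets: np.ndarray
    seq: SequenceParams
    distribution: str
    mode: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.complex64)
        self.targets = np.asarray(self.targets, dtype=np.float32)
        if self.signals.shape[0] != self.targets.shape[0]:
            raise ValueError("signals and targets must have equal sample counts")
        if self.targets.shape[1] != 4:
            raise ValueError("targets must have 4 columns (T1, T2, theta, B1)")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    def payload_bytes(self) -> tuple[int, int]:
        """(signal payload, target payload) in bytes at single precision."""
        return self.signals.nbytes, self.targets.nbytes


def build_dataset(
    dist: ParameterDistribution,
    n: int,
    seq: SequenceParams,
    mode: str,
    rng: np.random.Generator,
    seed: int | None = None,
) -> TrainingDataset:
    """Simulate a clean training dataset of ``n`` samples."""
    tissue = sample_parameters(dist, n, mode, rng)
    signals = simulate_pc_signal(tissue, seq).values
    targets = np.stack([tissue.t1, tissue.t2, tissue.theta, tissue.b1], axis=1)
    return TrainingDataset(
        signals=signals,
        targets=targets,
        seq=seq,
        distribution=dist.kind,
        mode=mode,
        seed=seed,
    )


def save_dataset(ds: TrainingDataset, path) -> None:
    """Serialize to HDF5 with a JSON metadata attribute."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=ds.signals)
        f.create_dataset("targets", data=ds.targets)
        f.attrs["meta"] = json.dumps(
            {
                "seq": asdict(ds.seq),
                "distribution": ds.distribution,
                "mode": ds.mode,
                "seed": ds.seed,
            }
        )


def load_dataset(path) -> TrainingDataset:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        return TrainingDataset(
            signals=f["signals"][()],
            targets=f["targets"][()],
            seq=SequenceParams(**meta["seq"]),
            distribution=meta["distribution"],
            mode=meta["mode"],
            seed=meta["seed"],
        )


def build_test_grid(
    kind: str,
    rng: np.random.Generator | None = None,
    n_steps: int = 200,
    n_in_vivo: int = 40_000,
    dist: ParameterDistribution | None = None,
) -> TissueParams:
    """Evaluation parameter sets: a linear T1/T2 grid or brain-like draws.

    ``linear_grid``: an ``n_steps x n_steps`` inclusive-endpoint grid over
    the tissue-range uniform support, filtered to T1 >= T2, with B1 = 1 and
    theta = 0.  ``in_vivo_test``: ``n_in_vivo`` draws from the brain-like
    density (B1 = 1, theta = 0).
    """
    if kind == "linear_grid":
        t1 = np.linspace(*UNIFORM_T1_RANGE, n_steps)
        t2 = np.linspace(*UNIFORM_T2_RANGE, n_steps)
        tt1, tt2 = np.meshgrid(t1, t2, indexing="ij")
        keep = tt1.ravel() >= tt2.ravel()
        t1v, t2v = tt1.ravel()[keep], tt2.ravel()[keep]
        return TissueParams(
            t1=t1v, t2=t2v, b1=np.ones_like(t1v), theta=np.zeros_like(t1v)
        )
    if kind == "in_vivo_test":
        if rng is None:
            raise ValueError("in_vivo_test requires an rng")
        if dist is None:
            dist = synthetic_in_vivo_density()
        t1, t2 = _sample_t1t2(dist, n_in_vivo, rng)
        return TissueParams(
            t1=t1, t2=t2, b1=np.ones_like(t1), theta=np.zeros_like(t1)
        )
    raise ValueError(f"unknown grid kind {kind!r}")
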