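"""Digital brain-like phantom, volume simulation and whole-volume fitting.

The phantom stands in for in-vivo acquisitions: concentric ellipsoidal
tissue compartments (white-matter-like core, gray-matter-like shell and a
central CSF-like ventricle region) with per-tissue mean T1/T2 plus mild
multiplicative jitter, a smooth polynomial off-resonance (theta) field
emulating static-field inhomogeneity, and a smooth transmit-field (B1)
profile in [0.7, 1.3].  Volumes are exchanged as NIfTI files; parameter
maps inherit the phantom affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .signal import SequenceParams, TissueParams, add_noise, features_from_signal, \
    simulate_pc_signal

__all__ = [
    "TISSUE_LABELS",
    "PhantomVolume",
    "make_phantom",
    "simulate_volume",
    "fit_volume",
    "difference_maps",
    "tissue_summary",
    "save_map",
    "load_map",
    "write_pc_volume",
    "read_pc_volume",
]

TISSUE_LABELS = {"background": 0, "wm": 1, "gm": 2, "csf": 3}

# per-tissue mean (T1 ms, T2 ms); WM-like uses the 3 T white-matter
# reference relaxation values
DEFAULT_TISSUES = {
    "wm": (939.0, 62.0),
    "gm": (1400.0, 80.0),
    "csf": (3500.0, 1800.0),
}


@dataclass
class PhantomVolume:
    """Ground-truth parameter maps of the digital phantom."""

    t1_map: np.ndarray
    t2_map: np.ndarray
    b1_map: np.ndarray
    theta_map: np.ndarray
    label_map: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_size_mm: float = 1.3

    @property
    def shape(self) -> tuple[int, ...]:
        return self.label_map.shape

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.label_map > 0

    def as_tissue_params(self, mask: np.ndarray | None = None) -> TissueParams:
        m = self.tissue_mask if mask is None else mask
        return TissueParams(
            t1=self.t1_map[m],
            t2=self.t2_map[m],
            b1=self.b1_map[m],
            theta=self.theta_map[m],
        )


def _ellipsoid(shape, center, semi):
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, semi):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def make_phantom(
    shape: tuple[int, int, int] = (48, 48, 32),
    rng: np.random.Generator | None = None,
    tissues: dict | None = None,
    jitter: float = 0.02,
    theta_range: tuple[float, float] = (-np.pi, np.pi),
    b1_range: tuple[float, float] = (0.7, 1.3),
    voxel_size_mm: float = 1.3,
) -> PhantomVolume:
    """Build the brain-like phantom.

    ``jitter`` is the relative standard deviation of the voxelwise
    multiplicative T1/T2 variation within a tissue; the theta field is a
    smooth low-order polynomial spanning ``theta_range`` across the
    volume and the B1 field a smooth profile inside ``b1_range``.
    """
    if min(shape) < 16:
        raise ValueError("phantom shape must be at least 16 voxels per axis")
    if rng is None:
        rng = np.random.default_rng()
    if tissues is None:
        tissues = DEFAULT_TISSUES
    center = tuple(s / 2.0 - 0.5 for s in shape)
    semi_outer = tuple(0.45 * s for s in shape)
    semi_inner = tuple(0.32 * s for s in shape)
    semi_csf = tuple(0.10 * s for s in shape)

    label = np.zeros(shape, dtype=np.int16)
    label[_ellipsoid(shape, center, semi_outer)] = TISSUE_LABELS["gm"]
    label[_ellipsoid(shape, center, semi_inner)] = TISSUE_LABELS["wm"]
    label[_ellipsoid(shape, center, semi_csf)] = TISSUE_LABELS["csf"]

    t1 = np.zeros(shape)
    t2 = np.zeros(shape)
    for name, (m1, m2) in tissues.items():
        m = label == TISSUE_LABELS[name]
        n = int(m.sum())
        t1[m] = m1 * (1.0 + jitter * rng.standard_normal(n))
        t2[m] = m2 * (1.0 + jitter * rng.standard_normal(n))
    mask = label > 0
    t1[mask] = np.clip(t1[mask], 1.0, None)
    t2[mask] = np.clip(t2[mask], 1.0, None)
    # keep the physical ordering under jitter
    t1[mask] = np.maximum(t1[mask], t2[mask])

    # smooth fields from normalized coordinates in [-1, 1]
    coords = np.meshgrid(
        *[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij"
    )
    x, y, z = coords
    theta_raw = 0.9 * x + 0.5 * y * y - 0.3 * z + 0.4 * x * y
    theta_raw -= theta_raw.min()
    theta_raw /= theta_raw.max()
    theta = theta_range[0] + theta_raw * (theta_range[1] - theta_range[0])

    b1_raw = 0.6 * (1.0 - 0.5 * (x * x + y * y + 0.5 * z * z)) + 0.2 * y
    b1_raw -= b1_raw.min()
    b1_raw /= b1_raw.max()
    pad = 0.02 * (b1_range[1] - b1_range[0])
    b1 = (b1_range[0] + pad) + b1_raw * (b1_range[1] - b1_range[0] - 2 * pad)

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    return PhantomVolume(
        t1_map=t1,
        t2_map=t2,
        b1_map=b1,
        theta_map=theta,
        label_map=label,
        affine=affine,
        voxel_size_mm=voxel_size_mm,
    )


def simulate_volume(
    ph: PhantomVolume,
    seq: SequenceParams,
    snr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Voxelwise pc-bSSFP simulation: complex (nx, ny, nz, n_pc) volume.

    Background voxels carry zero signal plus (for finite SNR) the same
    additive complex Gaussian noise as tissue.
    """
    vol = np.zeros(ph.shape + (seq.n_pc,), dtype=complex)
    mask = ph.tissue_mask
    tissue = ph.as_tissue_params()
    vol[mask] = simulate_pc_signal(tissue, seq).values
    return add_noise(vol, snr, rng)


def fit_volume(
    estimator,
    vol: np.ndarray,
    b1_map: np.ndarray,
    seq: SequenceParams,
    mask: np.ndarray | None = None,
    background_quantile: float = 0.99,
    background_fraction: float = 0.05,
) -> dict:
    """Apply an estimator voxelwise to a pc-bSSFP volume.

    If no mask is given, background is suppressed by thresholding the
    mean-magnitude (|F0|) image at ``background_fraction`` times its
    ``background_quantile`` quantile.  Returns a dict of maps
    (``t1``, ``t2``[, ``theta``]) plus the ``mask`` used; maps are zero
    outside the mask.
    """
    vol = np.asarray(vol)
    if vol.shape[-1] != seq.n_pc:
        raise ValueError(
            f"volume has {vol.shape[-1]} channels, protocol expects {seq.n_pc}"
        )
    spatial = vol.shape[:-1]
    if np.shape(b1_map) != spatial:
        raise ValueError("b1 map shape must match the volume")
    if mask is None:
        f0_mag = np.abs(vol.mean(axis=-1))
        thr = background_fraction * np.quantile(f0_mag, background_quantile)
        mask = f0_mag > thr
    feats = features_from_signal(vol[mask], estimator.layout,
                                 np.asarray(b1_map)[mask])
    pred = np.asarray(estimator.predict(feats))
    out = {}
    names = ("t1", "t2", "theta")[: pred.shape[1]]
    for j, name in enumerate(names):
        m = np.zeros(spatial)
        m[mask] = pred[:, j]
        out[name] = m
    out["mask"] = mask
    return out


def difference_maps(maps_a: dict, maps_b: dict) -> dict:
    """Voxelwise signed differences (a minus b) on the shared mask."""
    keys = [k for k in maps_a if k != "mask" and k in maps_b]
    if not keys:
        raise ValueError("no common parameter maps to difference")
    mask = maps_a.get("mask")
    out = {}
    for k in keys:
        a, b = np.asarray(maps_a[k]), np.asarray(maps_b[k])
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch for map {k!r}")
        d = a - b
        if mask is not None:
            d = np.where(mask, d, 0.0)
        out[k] = d
    if mask is not None:
        out["mask"] = mask
    return out


def tissue_summary(ph: PhantomVolume, maps: dict) -> pd.DataFrame:
    """Per-tissue mean/std of each fitted map (and of the truth)."""
    rows = []
    for name, lab in TISSUE_LABELS.items():
        if name == "background":
            continue
        m = ph.label_map == lab
        if "mask" in maps:
            m = m & maps["mask"]
        if not m.any():
            continue
        for key in ("t1", "t2"):
            if key not in maps:
                continue
            truth = (ph.t1_map if key == "t1" else ph.t2_map)[m]
            vals = np.asarray(maps[key])[m]
            rows.append(
                {
                    "tissue": name,
                    "parameter": key.upper(),
                    "mean": vals.mean(),
                    "std": vals.std(),
                    "truth_mean": truth.mean(),
                    "n_voxels": int(m.sum()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIfTI I/O

def save_map(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_map(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float32), img.affine


def write_pc_volume(vol: np.ndarray, affine: np.ndarray, path,
                    dialect: str = "complex") -> None:
    """Write a complex pc-bSSFP volume.

    ``dialect='complex'`` stores a single complex64 NIfTI at ``path``;
    ``dialect='magphase'`` stores paired files ``<path>_mag.nii.gz`` and
    ``<path>_phase.nii.gz`` (scanner-export style).
    """
    vol = np.asarray(vol)
    if dialect == "complex":
        nib.save(nib.Nifti1Image(vol.astype(np.complex64), affine), str(path))
    elif dialect == "magphase":
        base = str(path).replace(".nii.gz", "").replace(".nii", "")
        nib.save(
            nib.Nifti1Image(np.abs(vol).astype(np.float32), affine),
            base + "_mag.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(np.angle(vol).astype(np.float32), affine),
            base + "_phase.nii.gz",
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_pc_volume(path, dialect: str = "complex") -> tuple[np.ndarray, np.ndarray]:
    if dialect == "complex":
        img = nib.load(str(path))
        return np.asarray(img.dataobj).astype(np.complex64), img.affine
    if dialect == "magphase":
        base = str(path).replace(".nii.gz", "").replace(".nii", "")
        mag = nib.load(base + "_mag.nii.gz")
        ph = nib.load(base + "_phase.nii.gz")
        vol = np.asarray(mag.get_fdata()) * np.exp(1j * np.asarray(ph.get_fdata()))
        return vol.astype(np.complex64), mag.affine
    raise ValueError(f"unknown dialect {dialect!r}")
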