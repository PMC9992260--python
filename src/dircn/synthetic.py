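"""Synthetic multi-coil k-space generation.

The simulator produces complex-valued ellipse-composite phantoms with a
smooth phase field, smooth per-coil complex sensitivity lobes, and fully
sampled Cartesian k-space per the forward model k_j = F(S_j ∘ x) + ε with
i.i.d. complex Gaussian noise.  Volumes are written as fastMRI-style
multi-coil HDF5 files ("kspace" complex64 [slices, coils, h, w] and
"reconstruction_rss" float32 [slices, h, w]) with contrast labels cycling
through T1/T2/FLAIR.

Phantoms are generated with frequency oversampling along the width, then
quadratically cropped in the image domain and re-transformed, exercising
the same preprocessing path real acquisitions go through.  The stored
ground truth is the RSS of the noiseless cropped coil images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .kspace import coil_expand, crop_quadratic, fft2c, ifft2c, normalize_sensitivities, rss

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "make_phantom",
    "make_coil_maps",
    "simulate_acquisition",
    "random_phantom_spec",
    "make_dataset",
    "SliceDataset",
    "CONTRASTS",
]

CONTRASTS = ("T1", "T2", "FLAIR")


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]      # (cy, cx) in [-1, 1] normalised coords
    axes: tuple[float, float]        # (ay, ax) semi-axes, normalised
    angle: float                     # radians
    amplitude: complex


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int] = (64, 64)
    ellipses: tuple[Ellipse, ...] = ()
    phase_coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (c0, cy, cx)
    n_coils: int = 4
    coil_width: float = 0.8
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if min(self.shape) < 16:
            raise ValueError(f"phantom dims must be >= 16, got {self.shape}")
        if self.n_coils < 1:
            raise ValueError("need at least one coil")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _grid(h: int, w: int):
    ys = np.linspace(-1, 1, h, endpoint=False)
    xs = np.linspace(-1, 1, w, endpoint=False)
    return np.meshgrid(ys, xs, indexing="ij")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Superposed ellipse indicators times a smooth unit-magnitude phase."""
    h, w = spec.shape
    yy, xx = _grid(h, w)
    img = np.zeros((h, w), dtype=np.complex128)
    for e in spec.ellipses:
        ay, ax = e.axes
        if ay <= 0 or ax <= 0:
            raise ValueError(f"degenerate ellipse axes {e.axes}")
        cy, cx = e.center
        ca, sa = np.cos(e.angle), np.sin(e.angle)
        u = (yy - cy) * ca + (xx - cx) * sa
        v = -(yy - cy) * sa + (xx - cx) * ca
        img[(u / ay) ** 2 + (v / ax) ** 2 <= 1.0] += e.amplitude
    c0, cy_, cx_ = spec.phase_coeffs
    img *= np.exp(1j * (c0 + cy_ * yy + cx_ * xx))
    return img


def make_coil_maps(n_coils: int, h: int, w: int, profile_width: float = 0.8,
                   seed: int = 0) -> np.ndarray:
    """Smooth complex coil lobes, normalised to pixelwise unit energy.

    Coil magnitudes are Gaussian bumps centred on points spread around the
    field of view; each coil carries a small linear phase ramp.
    """
    if n_coils < 1:
        raise ValueError("need at least one coil")
    rng = np.random.default_rng(seed)
    yy, xx = _grid(h, w)
    maps = np.empty((n_coils, h, w), dtype=np.complex128)
    angles = 2 * np.pi * (np.arange(n_coils) + rng.uniform(0, 1)) / n_coils
    for i, th in enumerate(angles):
        cy, cx = 0.9 * np.sin(th), 0.9 * np.cos(th)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        mag = np.exp(-d2 / (2.0 * profile_width ** 2))
        ramp = rng.uniform(-1.0, 1.0, size=2)
        maps[i] = mag * np.exp(1j * (ramp[0] * yy + ramp[1] * xx))
    return normalize_sensitivities(maps)


def simulate_acquisition(phantom: np.ndarray, sens: np.ndarray,
                         noise_sigma: float = 0.0, seed: int = 0) -> np.ndarray:
    """Fully sampled noisy multi-coil k-space: F(S_i ∘ x) + ε per coil."""
    if phantom.shape != sens.shape[-2:]:
        raise ValueError(
            f"phantom {phantom.shape} incompatible with coil maps {sens.shape}"
        )
    k = fft2c(coil_expand(phantom, sens))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape)
        k = k + noise_sigma * noise
    return k


def random_phantom_spec(rng: np.random.Generator, size: int = 64,
                        n_coils: int = 4, noise_sigma: float = 0.01,
                        oversample: int = 16) -> PhantomSpec:
    """Draw a randomised ellipse-composite phantom spec (oversampled width)."""
    n_ell = int(rng.integers(3, 7))
    ellipses = []
    # one large background ellipse plus smaller internal structures
    ellipses.append(Ellipse(
        center=(float(rng.uniform(-0.05, 0.05)), float(rng.uniform(-0.05, 0.05))),
        axes=(float(rng.uniform(0.55, 0.75)), float(rng.uniform(0.45, 0.65))),
        angle=float(rng.uniform(0, np.pi)),
        amplitude=complex(rng.uniform(0.6, 1.0), 0.0),
    ))
    for _ in range(n_ell - 1):
        amp = rng.uniform(-0.5, 0.7)
        ellipses.append(Ellipse(
            center=(float(rng.uniform(-0.4, 0.4)), float(rng.uniform(-0.4, 0.4))),
            axes=(float(rng.uniform(0.05, 0.3)), float(rng.uniform(0.05, 0.3))),
            angle=float(rng.uniform(0, np.pi)),
            amplitude=complex(amp, 0.0),
        ))
    return PhantomSpec(
        shape=(size, size + oversample),
        ellipses=tuple(ellipses),
        phase_coeffs=tuple(float(v) for v in rng.uniform(-1.5, 1.5, size=3)),
        n_coils=n_coils,
        coil_width=float(rng.uniform(0.6, 1.0)),
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def _simulate_slice(spec: PhantomSpec, target: int):
    """One slice through the oversampled acquisition + crop pipeline.

    Returns (kspace [c, target, target], ground-truth RSS [target, target]).
    """
    h, w = spec.shape
    phantom = make_phantom(spec)
    sens = make_coil_maps(spec.n_coils, h, w, spec.coil_width, spec.seed)
    k_full = simulate_acquisition(phantom, sens, spec.noise_sigma, spec.seed + 1)
    coil_imgs = crop_quadratic(ifft2c(k_full), target)
    kspace = fft2c(coil_imgs)
    clean = crop_quadratic(coil_expand(phantom, sens), target)
    target_rss = rss(clean)
    return kspace, target_rss


def make_dataset(out_dir, n_volumes: int, slices_per_volume: int, seed: int = 0,
                 size: int = 64, n_coils: int = 4, noise_sigma: float = 0.01,
                 oversample: int = 16, prefix: str = "synthetic") -> list[Path]:
    """Write fastMRI-style multi-coil HDF5 volumes; reproducible per seed."""
    if n_volumes < 1:
        raise ValueError("need at least one volume")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    for v in range(n_volumes):
        contrast = CONTRASTS[v % len(CONTRASTS)]
        ks = np.empty((slices_per_volume, n_coils, size, size), np.complex64)
        gts = np.empty((slices_per_volume, size, size), np.float32)
        for s in range(slices_per_volume):
            spec = random_phantom_spec(rng, size, n_coils, noise_sigma, oversample)
            k, gt = _simulate_slice(spec, size)
            ks[s] = k.astype(np.complex64)
            gts[s] = gt.astype(np.float32)
        path = out_dir / f"{prefix}_{v:03d}.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("kspace", data=ks)
            f.create_dataset("reconstruction_rss", data=gts)
            f.attrs["contrast"] = contrast
            f.attrs["seed"] = seed
        paths.append(path)
    return paths


@dataclass
class SliceDataset:
    """Flat index over the slices of a directory of multi-coil HDF5 files."""

    files: list[Path] = field(default_factory=list)
    index: list[tuple[int, int]] = field(default_factory=list)  # (file, slice)
    contrasts: list[str] = field(default_factory=list)

    @staticmethod
    def from_dir(data_dir) -> "SliceDataset":
        files = sorted(Path(data_dir).glob("*.h5"))
        if not files:
            raise FileNotFoundError(f"no .h5 volumes under {data_dir}")
        ds = SliceDataset(files=files)
        for fi, path in enumerate(files):
            with h5py.File(path, "r") as f:
                n = f["kspace"].shape[0]
                ds.contrasts.append(str(f.attrs.get("contrast", "unknown")))
            ds.index.extend((fi, si) for si in range(n))
        return ds

    def __len__(self) -> int:
        return len(self.index)

    def __getitem__(self, i: int):
        fi, si = self.index[i]
        with h5py.File(self.files[fi], "r") as f:
            kspace = np.asarray(f["kspace"][si])
            target = np.asarray(f["reconstruction_rss"][si])
        return kspace, target, self.contrasts[fi]

    def volume(self, fi: int):
        with h5py.File(self.files[fi], "r") as f:
            return (np.asarray(f["kspace"]), np.asarray(f["reconstruction_rss"]),
                    self.contrasts[fi])
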