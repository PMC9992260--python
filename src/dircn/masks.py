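"""Line-wise equidistant Cartesian undersampling masks with a fully sampled centre.

A mask is a binary pattern over the phase-encoding lines (the last k-space
axis).  A contiguous central block of ``round(center_fraction * n_ky)``
lines is always sampled (the autocalibration region); outside the centre,
every ``acceleration``-th line is kept, starting at ``offset``.

Two dialects are provided:

* the default keeps literally every R-th line plus the centre, so the
  realised acceleration is somewhat below the nominal R;
* ``exact_rate=True`` widens the equidistant spacing to compensate for the
  centre block so the total number of sampled lines is approximately
  ``n_ky / R`` (the fastMRI-leaderboard convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UndersamplingMask",
    "MaskStats",
    "make_equidistant_mask",
    "mask_stats",
    "apply_mask",
    "choose_acceleration",
    "CENTER_FRACTIONS",
]

# centre fractions paired with the nominal accelerations: fourfold keeps 8%
# of phase-encoding lines fully sampled, eightfold keeps 4%
CENTER_FRACTIONS = {4: 0.08, 8: 0.04}


@dataclass(frozen=True)
class UndersamplingMask:
    lines: np.ndarray          # binary [n_ky]
    acceleration: int
    center_fraction: float
    offset: int = 0

    @property
    def n_ky(self) -> int:
        return self.lines.shape[0]

    @property
    def center_lines(self) -> int:
        return int(round(self.center_fraction * self.n_ky))

    @property
    def center_slice(self) -> slice:
        count = self.center_lines
        start = (self.n_ky - count) // 2
        return slice(start, start + count)

    def center_only(self) -> np.ndarray:
        """Binary vector selecting only the fully sampled centre block."""
        out = np.zeros(self.n_ky, dtype=self.lines.dtype)
        out[self.center_slice] = 1
        return out

    def as_array(self) -> np.ndarray:
        return self.lines


@dataclass(frozen=True)
class MaskStats:
    center_lines: int
    sampled_lines: int
    sampled_fraction: float
    effective_acceleration: float


def make_equidistant_mask(n_ky: int, acceleration: int, center_fraction: float,
                          offset: int = 0, exact_rate: bool = False) -> UndersamplingMask:
    """Build a deterministic equidistant mask.

    Parameters
    ----------
    n_ky:
        Number of phase-encoding lines (>= 8).
    acceleration:
        Nominal acceleration factor R >= 1; every R-th line outside the
        centre is kept (default dialect).
    center_fraction:
        Fraction of lines in the fully sampled contiguous centre block
        (count rounded to nearest integer).
    offset:
        Index of the first equidistant line, ``0 <= offset < acceleration``.
    exact_rate:
        Widen the equidistant spacing so the total sampled count is close
        to ``n_ky / acceleration``.
    """
    if n_ky < 8:
        raise ValueError(f"n_ky must be >= 8, got {n_ky}")
    if acceleration < 1:
        raise ValueError(f"acceleration must be >= 1, got {acceleration}")
    if not (0.0 < center_fraction < 1.0):
        raise ValueError(f"center_fraction must lie in (0, 1), got {center_fraction}")
    n_center = int(round(center_fraction * n_ky))
    if n_center < 1 or n_center > n_ky:
        raise ValueError(f"centre of {n_center} lines invalid for n_ky={n_ky}")

    lines = np.zeros(n_ky, dtype=np.float32)
    if acceleration == 1:
        lines[:] = 1
    elif exact_rate and n_ky > acceleration * n_center:
        # spacing adjusted so centre + equidistant lines ≈ n_ky / R in total
        spacing = (acceleration * (n_center - n_ky)) / (n_center * acceleration - n_ky)
        idx = np.around(np.arange(offset, n_ky - 1, spacing)).astype(int)
        lines[idx[idx < n_ky]] = 1
    else:
        lines[offset % acceleration::acceleration] = 1
    start = (n_ky - n_center) // 2
    lines[start:start + n_center] = 1
    return UndersamplingMask(lines=lines, acceleration=acceleration,
                             center_fraction=center_fraction, offset=offset)


def mask_stats(mask: UndersamplingMask) -> MaskStats:
    """Counts and the conventional effective acceleration ``n_ky / sampled``."""
    sampled = int(mask.lines.sum())
    return MaskStats(
        center_lines=mask.center_lines,
        sampled_lines=sampled,
        sampled_fraction=sampled / mask.n_ky,
        effective_acceleration=mask.n_ky / sampled,
    )


def apply_mask(kspace: np.ndarray, mask: UndersamplingMask) -> np.ndarray:
    """Zero out unsampled phase-encoding lines: ``k_u = U ∘ k``.

    Sampled lines are returned bit-identical; the mask broadcasts over all
    leading axes (coils, slices).
    """
    if kspace.shape[-1] != mask.n_ky:
        raise ValueError(
            f"kspace has {kspace.shape[-1]} phase-encoding lines, mask has {mask.n_ky}"
        )
    return np.where(mask.lines.astype(bool), kspace, 0)


def choose_acceleration(rng: np.random.Generator,
                        accelerations=(4, 8)) -> tuple[int, float]:
    """Draw an acceleration with equal probability; returns (R, center_fraction)."""
    r = int(rng.choice(accelerations))
    return r, CENTER_FRACTIONS.get(r, 0.08)
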