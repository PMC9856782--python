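"""Box-counting fractal dimension of 3D binary objects.

The fractal dimension (FD) of a voxelized object follows from the power law
N(r) ~ r^-FD, where N(r) is the number of cubes of side r (in voxels) needed
to cover the object.  Taking base-2 logarithms linearizes this to

    log2 N(r) = FD * log2(1/r) + k,

so FD is the slope of a least-squares line through the (log2(1/r), log2 N)
points.  Counts are taken over a schedule of integer box sizes from r = 10
down to r = 2; the slope is estimated on the contiguous sub-window of that
schedule whose ordinary least-squares fit attains the highest R^2 (the
"linear portion" of the log-log plot), with a minimum window length of 4
points.

Boxes tile the array from the origin with no offset search; partial boxes at
the far faces count when non-empty, so the tiling always covers the whole
object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import LabeledParcellation
from .volume import VoxelVolume

__all__ = [
    "BoxCountSeries",
    "FDFit",
    "count_boxes",
    "boxcount_series",
    "fit_fd",
    "estimate_fd",
    "region_fd",
    "fd_table",
]

DEFAULT_R_MAX = 10
DEFAULT_R_MIN = 2
DEFAULT_MIN_WINDOW = 4


@dataclass
class BoxCountSeries:
    """Ordered (r, N) pairs, r strictly decreasing."""

    pairs: list[tuple[int, int]]

    def __post_init__(self):
        rs = [r for r, _ in self.pairs]
        ns = [n for _, n in self.pairs]
        if any(r2 >= r1 for r1, r2 in zip(rs, rs[1:])):
            raise ValueError("box sizes must be strictly decreasing")
        if any(n < 1 for n in ns):
            raise ValueError("all box counts must be >= 1")
        # Note: N(r) from origin-anchored tiling is *not* guaranteed monotone
        # in r (unlike the minimal covering number): a grid aligned with the
        # object's structure can need fewer boxes at a smaller r.  The Menger
        # sponge at r=9 vs r=10 is a concrete example, so monotonicity is not
        # enforced here.

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def r(self) -> np.ndarray:
        return np.array([r for r, _ in self.pairs], dtype=int)

    @property
    def n(self) -> np.ndarray:
        # float dtype: counts are integers from real volumes, but synthetic
        # exact-line series are legitimate fit inputs too
        return np.array([n for _, n in self.pairs], dtype=float)

    @property
    def x(self) -> np.ndarray:
        """Regression abscissa log2(1/r)."""
        return -np.log2(self.r.astype(float))

    @property
    def y(self) -> np.ndarray:
        """Regression ordinate log2 N(r)."""
        return np.log2(self.n)


@dataclass
class FDFit:
    """Result of the log-log slope fit.

    ``window`` is the (start, end) pair of inclusive indices into the series
    over which the slope was taken; ``fd`` is the least-squares slope on that
    window and ``r_squared`` its coefficient of determination, maximal over
    all admissible windows.
    """

    fd: float
    intercept: float
    r_squared: float
    window: tuple[int, int]
    x: np.ndarray
    y: np.ndarray

    @property
    def window_r(self) -> tuple[int, int]:
        """(largest, smallest) box size inside the selected window."""
        r = np.round(2.0 ** (-self.x)).astype(int)
        i, j = self.window
        return int(r[i]), int(r[j])


def _as_grid(volume: VoxelVolume | np.ndarray) -> np.ndarray:
    if isinstance(volume, VoxelVolume):
        return volume.grid
    return VoxelVolume(np.asarray(volume)).grid


def count_boxes(volume: VoxelVolume | np.ndarray, r: int) -> int:
    """Number of grid-aligned r^3 boxes containing at least one filled voxel.

    Boxes are anchored at the array origin and tiled side by side; partial
    boxes at the far faces are included.
    """
    if r < 1:
        raise ValueError(f"box size must be >= 1, got {r}")
    grid = _as_grid(volume)
    if r == 1:
        return int(grid.sum())
    padded_shape = [-(-s // r) * r for s in grid.shape]
    padded = np.zeros(padded_shape, dtype=bool)
    padded[: grid.shape[0], : grid.shape[1], : grid.shape[2]] = grid
    nb = [s // r for s in padded_shape]
    blocks = padded.reshape(nb[0], r, nb[1], r, nb[2], r)
    return int(blocks.any(axis=(1, 3, 5)).sum())


def boxcount_series(
    volume: VoxelVolume | np.ndarray,
    r_max: int = DEFAULT_R_MAX,
    r_min: int = DEFAULT_R_MIN,
) -> BoxCountSeries:
    """Box counts for every integer box size from r_max down to r_min."""
    if r_min < 1:
        raise ValueError("r_min must be >= 1")
    if r_max < r_min:
        raise ValueError("r_max must be >= r_min")
    grid = _as_grid(volume)
    if not grid.any():
        raise ValueError("cannot box-count an empty volume")
    pairs = [(r, count_boxes(grid, r)) for r in range(r_max, r_min - 1, -1)]
    return BoxCountSeries(pairs)


def _ols_window(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R^2 of ordinary least squares y = a*x + b.

    A window with zero variance in y gets R^2 = 0 by convention, so it is
    never selected over any informative window.
    """
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    syy = float(np.sum((y - ym) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    if syy == 0.0:
        return slope, intercept, 0.0
    ss_res = syy - sxy**2 / sxx
    r2 = max(0.0, 1.0 - ss_res / syy)
    return slope, intercept, r2


def fit_fd(series: BoxCountSeries, min_window: int = DEFAULT_MIN_WINDOW) -> FDFit:
    """Highest-R^2 window fit of log2 N against log2(1/r).

    All contiguous windows of length >= ``min_window`` are scored by OLS R^2;
    the best window's slope is the FD estimate.  Ties on R^2 are broken by
    longer window, then by the window containing larger boxes (smaller start
    index) — a deterministic rule.  R^2 values are compared at 1e-12
    resolution so the tie rules are not defeated by float rounding (on an
    exactly linear series every window scores 1 and the longest must win).
    """
    npts = len(series)
    if npts < min_window:
        raise ValueError(
            f"series has {npts} points; need at least min_window={min_window}"
        )
    if min_window < 2:
        raise ValueError("min_window must be >= 2")
    x, y = series.x, series.y
    if float(np.ptp(y)) == 0.0:
        raise ValueError("all box counts equal; slope is undefined in every window")
    best = None
    best_key = None
    for start in range(0, npts - min_window + 1):
        for end in range(start + min_window - 1, npts):
            slope, intercept, r2 = _ols_window(x[start : end + 1], y[start : end + 1])
            key = (round(r2, 12), end - start + 1, -start)
            if best_key is None or key > best_key:
                best_key = key
                best = (slope, intercept, r2, (start, end))
    slope, intercept, r2, window = best
    return FDFit(
        fd=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        window=window,
        x=x,
        y=y,
    )


def estimate_fd(
    volume: VoxelVolume | np.ndarray,
    r_max: int = DEFAULT_R_MAX,
    r_min: int = DEFAULT_R_MIN,
    min_window: int = DEFAULT_MIN_WINDOW,
) -> FDFit:
    """Convenience: box-count a volume and fit its fractal dimension."""
    return fit_fd(boxcount_series(volume, r_max=r_max, r_min=r_min), min_window)


def _crop_to_bounding_box(mask: np.ndarray) -> np.ndarray:
    slices = []
    for axis in range(3):
        axes = tuple(a for a in range(3) if a != axis)
        filled = np.flatnonzero(mask.any(axis=axes))
        slices.append(slice(filled[0], filled[-1] + 1))
    return mask[tuple(slices)]


def region_fd(
    parcellation: LabeledParcellation,
    region_id: int,
    crop: bool = True,
    r_max: int = DEFAULT_R_MAX,
    r_min: int = DEFAULT_R_MIN,
    min_window: int = DEFAULT_MIN_WINDOW,
) -> FDFit:
    """Fractal dimension of one labeled region.

    The region's voxels are binarized and, by default, cropped to their tight
    bounding box so counts are object-relative rather than field-of-view
    relative (``crop=False`` keeps the full grid).
    """
    mask = parcellation.region_mask(region_id)
    if not mask.any():
        raise ValueError(f"region {region_id} has no voxels")
    if crop:
        mask = _crop_to_bounding_box(mask)
    return estimate_fd(mask, r_max=r_max, r_min=r_min, min_window=min_window)


def fd_table(
    parcellation: LabeledParcellation,
    crop: bool = True,
    r_max: int = DEFAULT_R_MAX,
    r_min: int = DEFAULT_R_MIN,
    min_window: int = DEFAULT_MIN_WINDOW,
):
    """Per-region FD table (region_id, abbreviation, fd, r_squared, window)."""
    import pandas as pd

    table = parcellation.region_table
    rows = []
    for rid in parcellation.present_regions():
        fit = region_fd(
            parcellation, int(rid), crop=crop, r_max=r_max, r_min=r_min,
            min_window=min_window,
        )
        w_max, w_min = fit.window_r
        rows.append(
            {
                "region_id": int(rid),
                "abbreviation": table.abbreviations[int(rid) - 1],
                "fd": fit.fd,
                "r_squared": fit.r_squared,
                "window_r_max": w_max,
                "window_r_min": w_min,
            }
        )
    return pd.DataFrame(rows)
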