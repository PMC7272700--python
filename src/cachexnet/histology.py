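"""Connective-tissue staining quantification on micrographs.

Binarizes Picrosirius-red-style images (Otsu on a red-dominance channel,
or a fixed threshold), measures the stained-area fraction normalized by
an externally counted cell density (PRA/CD), and estimates tissue
disorganization as the box-counting fractal dimension of the binary
mask: D is minus the least-squares slope of log N(s) versus log s over a
geometric ladder of box sizes anchored at the image origin, expected in
[0, 2] for planar images (values near 2 indicate a plane-filling,
disorganized stain pattern).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class BinaryImage:
    """Binarized micrograph with provenance of the threshold used."""

    mask: np.ndarray
    source_id: str = ""
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or self.mask.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")

    @property
    def foreground_fraction(self) -> float:
        return float(self.mask.mean())


def red_dominance(image: np.ndarray) -> np.ndarray:
    """R - (G + B)/2 channel, highlighting Picrosirius-red stain."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("red_dominance needs an RGB image")
    return img[..., 0] - (img[..., 1] + img[..., 2]) / 2.0


def binarize(
    image: np.ndarray,
    threshold_method: str | float = "otsu",
    source_id: str = "",
    foreground: str = "above",
) -> BinaryImage:
    """Threshold a greyscale or RGB image into a stained-pixel mask.

    RGB input is first reduced to the red-dominance channel. ``otsu``
    picks the threshold from the channel histogram; a numeric value is
    used as a fixed threshold. ``foreground`` sets polarity: ``above``
    (default, stain brighter than threshold) or ``below``.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = red_dominance(img)
    img = img.astype(float)
    if threshold_method == "otsu":
        from skimage.filters import threshold_otsu

        thresh = float(threshold_otsu(img))
    else:
        thresh = float(threshold_method)
    mask = img > thresh if foreground == "above" else img <= thresh
    return BinaryImage(mask, source_id=source_id, threshold=thresh)


@dataclass
class FractalEstimate:
    """Box-counting dimension with log-log fit diagnostics."""

    dimension: float
    sizes: np.ndarray
    counts: np.ndarray
    slope: float
    intercept: float
    r_squared: float


def geometric_sizes(shape: tuple[int, int], base: int = 2) -> list[int]:
    """Box-size ladder base^1 .. <= min(H, W)/2."""
    limit = min(shape) // 2
    sizes = []
    s = base
    while s <= limit:
        sizes.append(s)
        s *= base
    return sizes


def box_counts(mask: np.ndarray, size: int) -> int:
    """Number of size x size boxes (grid anchored at the origin) that
    contain at least one foreground pixel."""
    h, w = mask.shape
    ph = (-h) % size
    pw = (-w) % size
    padded = np.pad(mask, ((0, ph), (0, pw)))
    blocks = padded.reshape(
        padded.shape[0] // size, size, padded.shape[1] // size, size
    )
    return int(blocks.any(axis=(1, 3)).sum())


def box_count_dimension(
    img: BinaryImage, sizes: list[int] | None = None
) -> FractalEstimate:
    """Box-counting fractal dimension of the foreground set.

    ``D`` is the least-squares slope of log N(s) against log(1/s) over
    the supplied (or default power-of-2) box sizes. Requires >= 4 sizes
    and a non-empty foreground. A constant N(s) (single pixel) yields
    D = 0 with R^2 defined as 1.
    """
    if not img.mask.any():
        raise ValueError("no foreground: cannot estimate fractal dimension")
    if sizes is None:
        sizes = geometric_sizes(img.mask.shape)
    if len(sizes) < 4:
        raise ValueError(
            "need >= 4 box sizes; image too small for the default ladder"
        )
    sizes = sorted(int(s) for s in sizes)
    counts = np.array([box_counts(img.mask, s) for s in sizes], dtype=float)
    x = np.log(1.0 / np.asarray(sizes, dtype=float))
    y = np.log(counts)
    if np.allclose(y, y[0]):
        return FractalEstimate(0.0, np.asarray(sizes), counts, 0.0, float(y[0]), 1.0)
    fit = stats.linregress(x, y)
    return FractalEstimate(
        float(fit.slope),
        np.asarray(sizes),
        counts,
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue**2),
    )


def stained_area_fraction(img: BinaryImage, cell_density: float) -> float:
    """Stained-area fraction normalized by cell density (PRA/CD).

    ``score = (foreground pixels / total pixels) / cell_density``; the
    density (cells per field area) is counted externally and normalizes
    for individual fiber atrophy.
    """
    if cell_density <= 0:
        raise ValueError("cell_density must be > 0")
    return img.foreground_fraction / cell_density


def group_compare(scores_control, scores_case) -> tuple[float, float]:
    """Two-tailed equal-variance two-sample t-test between groups."""
    t, p = stats.ttest_ind(scores_control, scores_case, equal_var=True)
    if np.isnan(t):  # zero variance in both groups
        ident = np.allclose(
            np.mean(scores_control), np.mean(scores_case)
        )
        return (0.0, 1.0) if ident else (np.inf, 0.0)
    return float(t), float(p)
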