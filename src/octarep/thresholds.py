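"""Grey-level thresholding of 8-bit en-face angiograms.

Implements the manual foveal-avascular-zone (FAZ) reference procedure and six
automated global histogram algorithms (Huang, Li, Otsu, Moments, Mean,
Percentile) commonly applied to OCTA vessel-density analysis.  All automated
algorithms operate on the 256-bin grey-level histogram of the whole image;
the manual method uses the maximum grey value inside a delineated FAZ as a
background ceiling.

Conventions, applied uniformly:

* foreground (vessel) pixels are those *strictly greater* than the threshold;
* fractional threshold computations floor to an integer grey level;
* argmin/argmax ties resolve to the lowest grey level;
* a single-populated-level histogram is degenerate: that level is returned
  with ``degenerate=True`` instead of raising, so batch runs survive
  pathological inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.draw import polygon as _draw_polygon

ALGORITHMS = ("Manual", "Huang", "Li", "Otsu", "Moments", "Mean", "Percentile")
AUTOMATED_ALGORITHMS = ALGORITHMS[1:]

LAYERS = ("superficial", "deep")


@dataclass(frozen=True)
class GreyImage:
    """An 8-bit greyscale en-face angiogram with physical scale and layer label."""

    pixels: np.ndarray
    mm_per_pixel: float
    layer: str = "superficial"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("image must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if np.any((px < 0) | (px > 255)):
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ThresholdResult:
    """A binarization threshold with its provenance.

    ``degenerate`` marks fallback paths (single-level histogram, invalid
    moment-equation roots, Li non-convergence).
    """

    algorithm: str
    threshold: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold outside [0, 255]")


def _as_image_array(image: GreyImage | np.ndarray) -> np.ndarray:
    if isinstance(image, GreyImage):
        return image.pixels
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grey image")
    if np.any((arr < 0) | (arr > 255)):
        raise ValueError("pixel values must lie in [0, 255]")
    return arr.astype(np.uint8)


def grey_histogram(image: GreyImage | np.ndarray) -> np.ndarray:
    """256-bin grey-level histogram; ``hist[g]`` counts pixels of value ``g``."""
    arr = _as_image_array(image)
    return np.bincount(arr.ravel(), minlength=256).astype(np.int64)


def _validate_hist(hist: Sequence[int]) -> np.ndarray:
    h = np.asarray(hist, dtype=np.float64)
    if h.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if np.any(h < 0) or h.sum() < 1:
        raise ValueError("histogram counts must be non-negative with total >= 1")
    return h


def _populated_range(h: np.ndarray) -> tuple[int, int]:
    nz = np.flatnonzero(h)
    return int(nz[0]), int(nz[-1])


def threshold_mean(hist: Sequence[int]) -> ThresholdResult:
    """Mean of grey levels, floored to an integer level."""
    h = _validate_hist(hist)
    g = np.arange(256)
    t = int(math.floor((g * h).sum() / h.sum()))
    return ThresholdResult("Mean", t)


def threshold_percentile(hist: Sequence[int], p: float = 0.5) -> ThresholdResult:
    """Grey level whose cumulative fraction is closest to percentile ``p``.

    Ties break toward the lower level.  ``p`` defaults to the median (0.5).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    h = _validate_hist(hist)
    lo, hi = _populated_range(h)
    cum = np.cumsum(h) / h.sum()
    dist = np.abs(cum - p)
    t = lo + int(np.argmin(dist[lo : hi + 1]))   # candidates: populated range
    return ThresholdResult("Percentile", t)


def threshold_otsu(hist: Sequence[int]) -> ThresholdResult:
    """Maximize between-class variance w0*w1*(mu0-mu1)^2 over all splits."""
    h = _validate_hist(hist)
    lo, hi = _populated_range(h)
    if lo == hi:
        return ThresholdResult("Otsu", lo, degenerate=True)
    g = np.arange(256, dtype=np.float64)
    total = h.sum()
    w0 = np.cumsum(h) / total                 # mass at levels <= T
    s0 = np.cumsum(g * h)
    mu_all = s0[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / (w0 * total)
        mu1 = (s0[-1] - s0) / ((1.0 - w0) * total)
        crit = w0 * (1.0 - w0) * (mu0 - mu1) ** 2
    crit[(w0 <= 0) | (w0 >= 1)] = -np.inf     # both classes must be populated
    crit = np.nan_to_num(crit, nan=-np.inf)
    return ThresholdResult("Otsu", int(np.argmax(crit)))


def _binary_entropy(mu: np.ndarray) -> np.ndarray:
    """Shannon entropy S(mu) = -mu ln mu - (1-mu) ln(1-mu), with S(0)=S(1)=0."""
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return -mu * np.log(mu) - (1.0 - mu) * np.log(1.0 - mu)


def threshold_huang(hist: Sequence[int]) -> ThresholdResult:
    """Minimize the Shannon-entropy fuzziness of pixelwise fuzzy memberships.

    For a candidate split T the membership of level g is
    ``mu_T(g) = 1 / (1 + |g - m| / C)`` where m is the mean of g's class
    (background <= T < foreground) and C the populated grey-level range.
    """
    h = _validate_hist(hist)
    lo, hi = _populated_range(h)
    if lo == hi:
        return ThresholdResult("Huang", lo, degenerate=True)
    g = np.arange(256, dtype=np.float64)
    crange = float(hi - lo)
    cum_n = np.cumsum(h)
    cum_s = np.cumsum(g * h)
    total_n, total_s = cum_n[-1], cum_s[-1]

    best_t, best_f = lo, np.inf
    for t in range(lo, hi):                   # both classes populated
        n0 = cum_n[t]
        mu0 = cum_s[t] / n0
        mu1 = (total_s - cum_s[t]) / (total_n - n0)
        m = np.where(g <= t, mu0, mu1)
        member = 1.0 / (1.0 + np.abs(g - m) / crange)
        fuzz = float((h * _binary_entropy(member)).sum())
        if fuzz < best_f - 1e-12:
            best_t, best_f = t, fuzz
    return ThresholdResult("Huang", best_t)


def _li_cross_entropy(h: np.ndarray, t: int) -> float:
    """Minimum-cross-entropy criterion for the split background<=t<foreground."""
    g = np.arange(256, dtype=np.float64)
    gh = g * h
    s0, n0 = gh[: t + 1].sum(), h[: t + 1].sum()
    s1, n1 = gh[t + 1 :].sum(), h[t + 1 :].sum()
    crit = 0.0
    if s0 > 0:
        crit -= s0 * math.log(s0 / n0)
    if s1 > 0:
        crit -= s1 * math.log(s1 / n1)
    return crit


def threshold_li(hist: Sequence[int], max_iter: int = 100) -> ThresholdResult:
    """Li & Lee minimum cross-entropy threshold by fixed-point iteration.

    Initialized at the image mean; the iteration
    ``t <- (mu0 - mu1) / (ln mu0 - ln mu1)`` runs until the update falls
    below 0.5 grey levels.  Among the visited integer candidates the one with
    the lowest cross-entropy criterion is returned; hitting the iteration cap
    flags the result degenerate.
    """
    h = _validate_hist(hist)
    lo, hi = _populated_range(h)
    if lo == hi:
        return ThresholdResult("Li", lo, degenerate=True)
    g = np.arange(256, dtype=np.float64)
    gh = g * h
    mean = gh.sum() / h.sum()
    if mean <= 0:
        raise ValueError("Li threshold requires a positive grey mean")

    t = mean
    visited: list[int] = []
    converged = False
    for _ in range(max_iter):
        ti = min(max(int(math.floor(t)), lo), hi - 1)
        # visit both integers bracketing the continuous iterate
        visited.extend((ti, min(ti + 1, hi - 1)))
        n0, n1 = h[: ti + 1].sum(), h[ti + 1 :].sum()
        mu0 = gh[: ti + 1].sum() / n0 if n0 > 0 else 0.0
        mu1 = gh[ti + 1 :].sum() / n1 if n1 > 0 else 0.0
        if mu0 <= 0 or mu1 <= 0:
            break
        t_next = (mu0 - mu1) / (math.log(mu0) - math.log(mu1))
        if abs(t_next - t) < 0.5:
            converged = True
            tn = min(max(int(math.floor(t_next)), lo), hi - 1)
            visited.extend((tn, min(tn + 1, hi - 1)))
            break
        t = t_next
    # the continuous fixed point can sit a few levels off the discrete
    # optimum: refine by walking down the criterion basin on both sides,
    # crossing plateaus caused by empty bins
    start = visited[-1]
    for direction in (-1, 1):
        cur = start
        while lo <= cur + direction <= hi - 1 and (
            _li_cross_entropy(h, cur + direction) <= _li_cross_entropy(h, cur)
        ):
            cur += direction
            visited.append(cur)
    best = min(set(visited), key=lambda ti: (_li_cross_entropy(h, ti), ti))
    return ThresholdResult("Li", best, degenerate=not converged)


def threshold_moments(hist: Sequence[int]) -> ThresholdResult:
    """Tsai moment-preserving threshold.

    Solves for the background fraction p0 that lets a two-level image preserve
    the first three grey moments, then returns the level whose cumulative
    fraction is nearest p0 (ties toward the lower level).  Invalid roots fall
    back to the mean threshold, flagged degenerate.
    """
    h = _validate_hist(hist)
    lo, hi = _populated_range(h)
    if lo == hi:
        return ThresholdResult("Moments", lo, degenerate=True)
    g = np.arange(256, dtype=np.float64)
    total = h.sum()
    m1 = (g * h).sum() / total
    m2 = (g**2 * h).sum() / total
    m3 = (g**3 * h).sum() / total

    cd = m2 - m1 * m1
    if cd <= 0:
        return ThresholdResult("Moments", threshold_mean(hist).threshold, degenerate=True)
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        return ThresholdResult("Moments", threshold_mean(hist).threshold, degenerate=True)
    z0 = 0.5 * (-c1 - math.sqrt(disc))
    z1 = 0.5 * (-c1 + math.sqrt(disc))
    if z1 == z0:
        return ThresholdResult("Moments", threshold_mean(hist).threshold, degenerate=True)
    p0 = (z1 - m1) / (z1 - z0)
    if not 0.0 < p0 < 1.0:
        return ThresholdResult("Moments", threshold_mean(hist).threshold, degenerate=True)

    cum = np.cumsum(h) / total
    t = int(np.argmin(np.abs(cum - p0)))
    return ThresholdResult("Moments", t)


def threshold_manual_faz(image: GreyImage | np.ndarray, faz_mask: np.ndarray) -> ThresholdResult:
    """Manual method: maximum grey value inside the delineated FAZ."""
    arr = _as_image_array(image)
    mask = np.asarray(faz_mask, dtype=bool)
    if mask.shape != arr.shape:
        raise ValueError("FAZ mask dimensions must match the image")
    if not mask.any():
        raise ValueError("FAZ mask is empty")
    return ThresholdResult("Manual", int(arr[mask].max()))


def manual_threshold_protocol(
    t1: int, t2: int, t3_provider: Callable[[], int]
) -> ThresholdResult:
    """Combine repeated manual measurements per the study protocol.

    Two measurements differing by < 5 grey levels average (rounded half up);
    a difference >= 5 triggers a third measurement and the median of the
    three is used.
    """
    for t in (t1, t2):
        if not 0 <= t <= 255:
            raise ValueError("manual thresholds must lie in [0, 255]")
    if abs(t1 - t2) < 5:
        t = int(math.floor((t1 + t2) / 2.0 + 0.5))
    else:
        t3 = int(t3_provider())
        t = int(np.median([t1, t2, t3]))
    return ThresholdResult("Manual", t)


def transfer_faz_to_deep(
    faz_superficial: np.ndarray, deep_image: GreyImage | np.ndarray
) -> ThresholdResult:
    """Apply the superficial FAZ selection verbatim to the deep-layer image."""
    arr = _as_image_array(deep_image)
    mask = np.asarray(faz_superficial, dtype=bool)
    if mask.shape != arr.shape:
        raise ValueError(
            f"FAZ mask shape {mask.shape} does not match deep image shape {arr.shape}"
        )
    return threshold_manual_faz(arr, mask)


def binarize(image: GreyImage | np.ndarray, threshold: int) -> np.ndarray:
    """White (vessel) iff pixel value strictly exceeds the threshold."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return _as_image_array(image) > threshold


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a simple polygon (row, col vertex list) to a boolean mask."""
    v = np.asarray(vertices, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    rr, cc = _draw_polygon(v[:, 0], v[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


_AUTOMATED_DISPATCH: dict[str, Callable[[np.ndarray], ThresholdResult]] = {
    "Huang": threshold_huang,
    "Li": threshold_li,
    "Otsu": threshold_otsu,
    "Moments": threshold_moments,
    "Mean": threshold_mean,
    "Percentile": threshold_percentile,
}


def automated_threshold(algorithm: str, hist: Sequence[int]) -> ThresholdResult:
    """Dispatch one of the six automated algorithms by name."""
    try:
        fn = _AUTOMATED_DISPATCH[algorithm]
    except KeyError:
        raise ValueError(
            f"unknown automated algorithm {algorithm!r}; choose from {AUTOMATED_ALGORITHMS}"
        ) from None
    return fn(hist)
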