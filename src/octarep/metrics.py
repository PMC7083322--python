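"""Vessel density (VD) and vessel skeleton density (VSD) from binarized maps.

VD follows the printed study formula, the *squared* white-pixel fraction
``(n_white / n_total)**2``; because much of the OCTA literature uses the
plain fraction, both conventions are implemented and the one used is stamped
into every output row (``vd_convention``).

VSD is ``n_skeleton_white / n_total**2`` — a length-like, calibre-insensitive
quantity whose magnitude lands near 1e-8 for megapixel scans.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.morphology import skeletonize as _sk_skeletonize

from .thresholds import (
    ALGORITHMS,
    GreyImage,
    automated_threshold,
    binarize,
    grey_histogram,
    threshold_manual_faz,
)

VD_CONVENTIONS = ("squared_fraction", "fraction")

#: fixed column order of the measurement table
MEASUREMENT_COLUMNS = (
    "eye",
    "layer",
    "algorithm",
    "acquisition",
    "threshold",
    "vd",
    "vsd",
    "vd_convention",
)


def _as_binary(binary: np.ndarray) -> np.ndarray:
    arr = np.asarray(binary)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D binary image")
    return arr.astype(bool)


def skeletonize(binary: np.ndarray) -> np.ndarray:
    """Zhang–Suen iterative thinning to 1-pixel-wide centrelines.

    The image is padded with background before thinning (so border-touching
    vessels thin correctly) and the padding stripped afterwards.
    """
    arr = _as_binary(binary)
    padded = np.pad(arr, 1, mode="constant", constant_values=False)
    skel = _sk_skeletonize(padded, method="zhang")
    return skel[1:-1, 1:-1]


def vessel_density(binary: np.ndarray, convention: str = "squared_fraction") -> float:
    """VD of a binarized image under the chosen convention."""
    if convention not in VD_CONVENTIONS:
        raise ValueError(f"vd_convention must be one of {VD_CONVENTIONS}")
    arr = _as_binary(binary)
    frac = float(arr.sum()) / arr.size
    return frac**2 if convention == "squared_fraction" else frac


def vessel_skeleton_density(skeleton: np.ndarray) -> float:
    """VSD = skeleton white-pixel count / (total pixel count)^2."""
    arr = _as_binary(skeleton)
    return float(arr.sum()) / float(arr.size) ** 2


def measure_image(
    image: GreyImage | np.ndarray,
    threshold: int,
    vd_convention: str = "squared_fraction",
) -> tuple[float, float]:
    """Binarize at ``threshold`` and return (VD, VSD)."""
    binary = binarize(image, threshold)
    vd = vessel_density(binary, vd_convention)
    vsd = vessel_skeleton_density(skeletonize(binary))
    return vd, vsd


def measure_eye(
    record,
    algorithms: Sequence[str] = ALGORITHMS,
    faz_masks: Mapping[int, np.ndarray] | None = None,
    vd_convention: str = "squared_fraction",
) -> pd.DataFrame:
    """Measure one eye: threshold -> binarize -> VD; skeletonize -> VSD.

    ``record`` is an :class:`~octarep.simulate.EyeRecord` (or anything with
    the same ``eye_id`` / ``images`` / ``manual_thresholds`` surface).  For
    the manual algorithm, per-acquisition manual thresholds are taken from
    the record (superficial) and transferred to the deep layer; pre-computed
    ``faz_masks`` keyed by acquisition override the record's own masks.

    Returns ``len(layers) * 2 acquisitions * len(algorithms)`` measurement
    rows (28 per eye for the full battery).
    """
    unknown = set(algorithms) - set(ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithms: {sorted(unknown)}")
    if not algorithms:
        raise ValueError("algorithm list must be non-empty")

    rows = []
    for layer in record.layers:
        for acq in (1, 2):
            if (layer, acq) not in record.images:
                raise ValueError(
                    f"eye {record.eye_id}: missing acquisition {acq} of layer {layer}"
                )
    manual_cache: dict[int, int] = {}
    for layer in record.layers:
        for acq in (1, 2):
            image = record.images[(layer, acq)]
            hist = grey_histogram(image)
            for algorithm in algorithms:
                if algorithm == "Manual":
                    if acq not in manual_cache and layer != record.layers[0]:
                        raise ValueError("manual threshold requires the superficial layer")
                    if acq not in manual_cache:
                        mask = None if faz_masks is None else faz_masks.get(acq)
                        t = _manual_threshold_for_acquisition(record, acq, mask)
                        manual_cache[acq] = t
                    if layer == "superficial":
                        threshold = manual_cache[acq]
                    else:
                        # FAZ selection transfers; the deep threshold is the max
                        # grey under the superficial mask applied to the deep image
                        threshold = record.deep_manual_threshold(acq)
                else:
                    result = automated_threshold(algorithm, hist)
                    threshold = result.threshold
                vd, vsd = measure_image(image, threshold, vd_convention)
                rows.append(
                    {
                        "eye": record.eye_id,
                        "layer": layer,
                        "algorithm": algorithm,
                        "acquisition": acq,
                        "threshold": threshold,
                        "vd": vd,
                        "vsd": vsd,
                        "vd_convention": vd_convention,
                    }
                )
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def _manual_threshold_for_acquisition(record, acq: int, mask: np.ndarray | None) -> int:
    if mask is not None:
        image = record.images[(record.layers[0], acq)]
        return threshold_manual_faz(image, mask).threshold
    return record.manual_threshold(acq)


def measure_cohort(
    records: Iterable,
    algorithms: Sequence[str] = ALGORITHMS,
    vd_convention: str = "squared_fraction",
) -> pd.DataFrame:
    """Concatenate :func:`measure_eye` over a cohort of eye records."""
    frames = [measure_eye(r, algorithms, vd_convention=vd_convention) for r in records]
    return pd.concat(frames, ignore_index=True)
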