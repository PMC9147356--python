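"""Image-quality metrics used as the optimization objective.

The primary metric is the grayscale variance J = (1/MN) * sum (I - Ibar)^2,
which grows as the image becomes brighter and more contrasted, i.e. as the
aberration shrinks.  Sharpness (mean squared intensity) and brightness (mean
intensity) are provided as optional alternatives; their exact definitions are
conventional choices.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "variance_metric",
    "sharpness_metric",
    "brightness_metric",
    "get_metric",
    "scale_to_8bit_range",
]


def _check(image: np.ndarray) -> np.ndarray:
    a = np.asarray(image, dtype=float)
    if a.size == 0:
        raise ValueError("image is empty")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    return a


def variance_metric(image: np.ndarray) -> float:
    """Population variance of the pixel values (divisor MN, not MN - 1)."""
    a = _check(image)
    return float(np.mean((a - a.mean()) ** 2))


def sharpness_metric(image: np.ndarray) -> float:
    """Mean squared pixel intensity (intensity-squared sharpness)."""
    a = _check(image)
    return float(np.mean(a * a))


def brightness_metric(image: np.ndarray) -> float:
    """Mean pixel intensity."""
    a = _check(image)
    return float(a.mean())


_METRICS = {
    "variance": variance_metric,
    "sharpness": sharpness_metric,
    "brightness": brightness_metric,
}


def get_metric(name: str):
    """Look up a metric function by its configuration key."""
    try:
        return _METRICS[name]
    except KeyError:
        raise ValueError(
            f"unknown metric {name!r}; choose from {sorted(_METRICS)}"
        ) from None


def scale_to_8bit_range(image: np.ndarray, reference_max: float | None = None) -> np.ndarray:
    """Map an image linearly onto [0, 255] for display-scale metric values.

    ``reference_max`` fixes the value mapped to 255 (e.g. the peak of an
    unaberrated reference) so that metric magnitudes are comparable across a
    run; by default the image's own maximum is used.  Values are not
    quantized.
    """
    a = _check(image)
    m = float(a.max()) if reference_max is None else float(reference_max)
    if m <= 0:
        raise ValueError("reference_max must be positive")
    return a * (255.0 / m)
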