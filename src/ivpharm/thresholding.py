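"""Global and locally-adaptive thresholding of fluorescence images.

Three families are implemented, reflecting the three styles most useful for
intravital nuclear segmentation:

* :func:`otsu_threshold` — global clustering: the threshold maximizing
  between-class variance over 256 quantized candidate levels.
* :func:`huang_threshold` — global fuzzy object-attribute: the threshold
  minimizing the Shannon-entropy index of fuzziness of the pixel membership
  function.
* :func:`ray_threshold` — iterative locally-adaptive thresholding with three
  user inputs (iteration cap, selectivity ``power``, termination ``epsilon``),
  suited to images whose brightness varies across the field.

Conventions shared by all methods: images are floats in [0, 1]; candidate
levels for the global methods are the 256 uniform quantization levels
``k / 255``; foreground is *strictly greater than* the threshold; ties among
equally-good candidate levels are broken toward the smallest level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import rank as _rank
from skimage.morphology import disk as _disk

from .errors import ConfigError, DegenerateInputError

__all__ = [
    "RayParams",
    "ThresholdResult",
    "gamma_adjust",
    "otsu_threshold",
    "huang_threshold",
    "ray_threshold",
    "threshold",
]

_N_LEVELS = 256


@dataclass
class RayParams:
    """Inputs of the iterative locally-adaptive thresholder.

    iterations : hard cap on refinement iterations (the method typically
        needs on the order of 1000 in the worst case; it stops much earlier
        once the surface stabilizes).
    power : selectivity exponent weighting the foreground/background class
        means; larger values pull the threshold toward the majority class.
    epsilon : termination tolerance on the mean absolute per-pixel change of
        the threshold surface between iterations.
    window_radius : radius (px) of the disk window over which local
        background statistics are gathered; should straddle one nucleus and
        its surround.
    """

    iterations: int = 1000
    power: float = 1.0
    epsilon: float = 1e-4
    window_radius: int = 15

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        if not self.power > 0:
            raise ConfigError("power must be > 0")
        if self.epsilon < 0:
            raise ConfigError("epsilon must be >= 0")
        if self.window_radius < 1:
            raise ConfigError("window_radius must be >= 1")


@dataclass
class ThresholdResult:
    """A binarization together with the threshold surface that produced it.

    ``mask == (frame > surface)`` elementwise; for the global methods the
    surface is a constant array.  ``surface_changes`` records the mean
    absolute per-pixel surface change at each iteration (length
    ``iterations_used``; a single entry of 0.0 for the one-shot global
    methods).
    """

    mask: np.ndarray
    surface: np.ndarray
    method: str
    iterations_used: int = 1
    converged: bool = True
    surface_changes: list[float] = field(default_factory=list)

    @property
    def threshold(self) -> float:
        """The global threshold value (only meaningful for constant surfaces)."""
        return float(self.surface.flat[0])


def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ConfigError(f"frame must be 2-D, got shape {frame.shape}")
    if frame.size == 0:
        raise DegenerateInputError("empty frame")
    if frame.min() < 0 or frame.max() > 1:
        raise ConfigError("frame values must lie in [0, 1]")
    return frame


def gamma_adjust(frame: np.ndarray, gamma: float) -> np.ndarray:
    """Elementwise power-law contrast adjustment ``frame ** gamma``.

    gamma < 1 brightens dim structures, gamma > 1 suppresses them; the map is
    strictly order-preserving so it never reorders pixel intensities.
    """
    if not gamma > 0:
        raise ConfigError(f"gamma must be > 0, got {gamma}")
    frame = _check_frame(frame)
    return frame**gamma


def _quantize(frame: np.ndarray) -> np.ndarray:
    """Map [0,1] floats onto the 256 uniform candidate levels 0..255."""
    return np.clip(np.round(frame * (_N_LEVELS - 1)), 0, _N_LEVELS - 1).astype(np.int64)


def _histogram(frame: np.ndarray) -> np.ndarray:
    h = np.bincount(_quantize(frame).ravel(), minlength=_N_LEVELS).astype(float)
    return h


def _global_result(frame: np.ndarray, level: int, method: str) -> ThresholdResult:
    t = level / (_N_LEVELS - 1)
    surface = np.full(frame.shape, t)
    return ThresholdResult(
        mask=frame > surface,
        surface=surface,
        method=method,
        iterations_used=1,
        surface_changes=[0.0],
    )


def otsu_threshold(frame: np.ndarray) -> ThresholdResult:
    """Global clustering threshold maximizing between-class variance.

    All 256 candidate levels are scanned; a candidate level ``k`` assigns
    quantized levels ``<= k`` to background and ``> k`` to foreground.  Ties
    are broken by the smallest maximizing level.

    Raises
    ------
    DegenerateInputError
        If the frame quantizes to a single level.
    """
    frame = _check_frame(frame)
    hist = _histogram(frame)
    if np.count_nonzero(hist) < 2:
        raise DegenerateInputError("constant frame: no threshold separates one level")
    levels = np.arange(_N_LEVELS, dtype=float)
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    s0 = np.cumsum(hist * levels)
    total = s0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = (total - s0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf
    best = int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer
    return _global_result(frame, best, "otsu")


def _huang_fuzziness(hist: np.ndarray, value_range: float) -> np.ndarray:
    """Entropy-based index of fuzziness for every candidate level.

    For candidate ``t`` each pixel's membership in its own class is
    ``mu = 1 / (1 + |x - m_class| / C)`` with ``m_class`` the mean of the
    pixel's class and ``C`` the intensity range; the index is the summed
    Shannon entropy ``S(mu) = -mu ln mu - (1-mu) ln(1-mu)`` over all pixels.
    Candidates leaving a class empty score +inf.
    """
    levels = np.arange(_N_LEVELS, dtype=float)
    w0 = np.cumsum(hist)
    s0 = np.cumsum(hist * levels)
    w1 = w0[-1] - w0
    s1 = s0[-1] - s0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0  # background mean per candidate
        mu1 = s1 / w1
    cost = np.full(_N_LEVELS, np.inf)
    C = max(value_range, 1.0)  # in quantized level units
    for t in range(_N_LEVELS):
        if w0[t] == 0 or w1[t] == 0:
            continue
        m = np.where(levels <= t, mu0[t], mu1[t])
        mu = 1.0 / (1.0 + np.abs(levels - m) / C)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = -mu * np.log(mu) - (1 - mu) * np.log(1 - mu)
        s = np.nan_to_num(s, nan=0.0)  # mu == 1 contributes zero entropy
        cost[t] = float(np.dot(hist, s))
    return cost


def huang_threshold(frame: np.ndarray) -> ThresholdResult:
    """Global fuzzy threshold minimizing the entropy index of fuzziness.

    Ties are broken by the smallest minimizing level.
    """
    frame = _check_frame(frame)
    hist = _histogram(frame)
    nz = np.nonzero(hist)[0]
    if nz.size < 2:
        raise DegenerateInputError("constant frame: fuzziness index undefined")
    cost = _huang_fuzziness(hist, float(nz[-1] - nz[0]))
    best = int(np.argmin(cost))
    return _global_result(frame, best, "huang")


def _isodata_level(frame: np.ndarray) -> float:
    """Global two-means threshold used to seed the adaptive iteration."""
    hist = _histogram(frame)
    levels = np.arange(_N_LEVELS, dtype=float)
    t = float((levels * hist).sum() / hist.sum())
    for _ in range(100):
        lo = hist[: int(t) + 1]
        hi = hist[int(t) + 1 :]
        if lo.sum() == 0 or hi.sum() == 0:
            break
        m0 = (levels[: int(t) + 1] * lo).sum() / lo.sum()
        m1 = (levels[int(t) + 1 :] * hi).sum() / hi.sum()
        t_new = 0.5 * (m0 + m1)
        if abs(t_new - t) < 0.5:
            t = t_new
            break
        t = t_new
    return t / (_N_LEVELS - 1)


def ray_threshold(frame: np.ndarray, params: RayParams | None = None) -> ThresholdResult:
    """Iterative locally-adaptive thresholding.

    The threshold surface is refined from windowed class statistics: at each
    iteration the current background class defines a local background surface
    (the windowed median of background-classified pixels within
    ``window_radius``); the background-subtracted residual is then split by a
    power-weighted combination of its class means,

    ``t = (f**power * m_F + (1 - f)**power * m_B) / (f**power + (1-f)**power)``

    with ``f`` the current foreground fraction and ``m_F``/``m_B`` the class
    means of the residual, floored at ``m_B + 3 * sd_B`` so the threshold
    never descends into the background noise band.  The surface is
    ``background + t``; iteration stops when its mean absolute per-pixel
    change drops below ``epsilon`` or the cap is reached.  Hitting the cap is
    not an error — the surface at the cap is returned with
    ``converged=False``.

    Because the background surface follows local image content, nuclei of
    very different brightness — and nuclei sitting on uneven illumination —
    are recovered with a single parameter setting, which a global threshold
    cannot do.
    """
    params = params or RayParams()
    frame = _check_frame(frame)
    if np.ptp(frame) == 0:
        raise DegenerateInputError("constant frame: no local threshold exists")

    footprint = _disk(params.window_radius)
    q8 = np.round(frame * 255).astype(np.uint8)

    t0 = _isodata_level(frame)
    surface = np.full(frame.shape, t0)
    fg = frame > surface
    changes: list[float] = []
    converged = False
    iterations_used = 0
    for _ in range(params.iterations):
        iterations_used += 1
        bg = ~fg
        if bg.any() and fg.any():
            background = (
                _rank.median(q8, footprint, mask=bg.astype(np.uint8)).astype(float) / 255.0
            )
            resid = frame - background
            f = fg.mean()
            m_f = resid[fg].mean()
            m_b = resid[bg].mean()
            sd_b = resid[bg].std()
            w_f = f**params.power
            w_b = (1.0 - f) ** params.power
            t = (w_f * m_f + w_b * m_b) / (w_f + w_b)
            t = max(t, m_b + 3.0 * sd_b)
            new_surface = background + t
        else:
            # single-class state: fall back to the global seed level
            new_surface = np.full(frame.shape, t0)
        delta = float(np.abs(new_surface - surface).mean())
        changes.append(delta)
        surface = new_surface
        fg = frame > surface
        if delta < params.epsilon:
            converged = True
            break
    return ThresholdResult(
        mask=fg,
        surface=surface,
        method="ray",
        iterations_used=iterations_used,
        converged=converged,
        surface_changes=changes,
    )


_METHODS = {
    "otsu": lambda frame, params: otsu_threshold(frame),
    "huang": lambda frame, params: huang_threshold(frame),
    "ray": lambda frame, params: ray_threshold(frame, params),
}


def threshold(frame: np.ndarray, method: str, ray_params: RayParams | None = None) -> ThresholdResult:
    """Dispatch to a thresholding method by name (``otsu``/``huang``/``ray``)."""
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ConfigError(f"unknown thresholding method {method!r}; choose from {sorted(_METHODS)}")
    return fn(frame, ray_params)
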