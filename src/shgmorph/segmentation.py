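"""Collagen/background segmentation of SHG images.

A second-harmonic-generation (SHG) image of fibrillar collagen has a
bimodal intensity histogram: a dark background mode and a brighter
collagen mode.  Segmentation fits a two-component Gaussian mixture to the
pooled pixel intensities by expectation-maximisation and labels a pixel
collagen when the posterior probability of the brighter component is at
least one half.

The EM fit is deterministic: it is initialised from the Otsu threshold of
the intensity histogram (per-side means, standard deviations and weights),
so no random restarts are involved and a given image always yields the
same mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

DEFAULT_PIXEL_SIZE_UM = 0.554
"""Physical pixel pitch (μm/pixel) of the imaging system emulated here."""

__all__ = [
    "DEFAULT_PIXEL_SIZE_UM",
    "SHGImage",
    "BinaryMask",
    "GMM2",
    "DegenerateImageError",
    "NonConvergenceWarning",
    "fit_gmm2",
    "binarize",
    "segment",
]


class DegenerateImageError(ValueError):
    """Raised when an image has too little intensity structure to fit a
    two-component mixture (e.g. a constant image).  Callers that want a
    mask anyway should treat the whole image as background."""


class NonConvergenceWarning(UserWarning):
    """EM reached ``max_iter`` before the log-likelihood stabilised."""


@dataclass(frozen=True)
class SHGImage:
    """A 2-D grayscale SHG intensity raster with its physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("SHGImage requires a 2-D raster of at least 2x2 pixels")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class BinaryMask:
    """Per-pixel collagen (True) / background (False) labels."""

    labels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=bool)
        if lab.ndim != 2:
            raise ValueError("BinaryMask requires a 2-D label array")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def area_um2(self) -> float:
        """Physical area of the full raster in μm²."""
        return self.labels.size * self.pixel_size_um**2


@dataclass(frozen=True)
class GMM2:
    """A fitted two-component 1-D Gaussian mixture.

    Components are ordered by mean so component 1 (index 1) is the
    brighter, collagen class.  ``loglik_path`` records the total
    log-likelihood after every EM iteration; it is non-decreasing.
    """

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    loglik: float
    n_iter: int
    converged: bool = True
    loglik_path: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if not abs(self.weights[0] + self.weights[1] - 1.0) < 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not (self.sds[0] > 0 and self.sds[1] > 0):
            raise ValueError("mixture sds must be positive")
        if self.means[0] > self.means[1]:
            raise ValueError("components must be ordered by mean")


def _log_gauss(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2.0 * np.pi)


def _responsibilities(x: np.ndarray, means, sds, weights) -> tuple[np.ndarray, float]:
    """Posterior membership of each value for both components, plus the
    total log-likelihood, computed stably in log space."""
    la = np.log(weights[0]) + _log_gauss(x, means[0], sds[0])
    lb = np.log(weights[1]) + _log_gauss(x, means[1], sds[1])
    m = np.maximum(la, lb)
    lse = m + np.log(np.exp(la - m) + np.exp(lb - m))
    resp = np.exp(lb - lse)  # posterior of the brighter component
    return resp, float(lse.sum())


_MIN_SD = 1e-6  # floor against single-point collapse


def fit_gmm2(image: SHGImage, tol: float = 1e-6, max_iter: int = 500) -> GMM2:
    """Fit a two-component Gaussian mixture to the pooled pixel intensities.

    Parameters
    ----------
    image:
        The SHG image; 8- and 16-bit inputs are treated identically after
        the container's cast to float.
    tol:
        Convergence threshold on the *per-pixel* log-likelihood
        improvement between successive EM iterations.
    max_iter:
        Iteration cap; hitting it emits :class:`NonConvergenceWarning`
        and returns the current fit with ``converged=False``.

    Raises
    ------
    DegenerateImageError
        If the image is constant (fewer than two distinct intensities).
        The caller should fall back to an all-background mask.
    """
    x = image.pixels.ravel().astype(float)
    if np.unique(x).size < 2:
        raise DegenerateImageError(
            "constant image: cannot fit a two-component mixture; "
            "treat the image as all background"
        )
    n = x.size

    # Deterministic initialisation: split the histogram at the Otsu
    # threshold and moment-match each side.
    thr = threshold_otsu(x)
    lo, hi = x[x <= thr], x[x > thr]
    if lo.size == 0 or hi.size == 0:  # Otsu put everything on one side
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
    pooled_sd = max(float(x.std()), _MIN_SD)
    means = [float(lo.mean()), float(hi.mean())]
    sds = [max(float(lo.std()), 0.05 * pooled_sd, _MIN_SD),
           max(float(hi.std()), 0.05 * pooled_sd, _MIN_SD)]
    weights = [lo.size / n, hi.size / n]

    path: list[float] = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resp, ll = _responsibilities(x, means, sds, weights)
        path.append(ll)
        # M step
        r1 = resp.sum()
        r0 = n - r1
        weights = [r0 / n, r1 / n]
        m0 = float(((1.0 - resp) * x).sum() / max(r0, 1e-300))
        m1 = float((resp * x).sum() / max(r1, 1e-300))
        v0 = float(((1.0 - resp) * (x - m0) ** 2).sum() / max(r0, 1e-300))
        v1 = float((resp * (x - m1) ** 2).sum() / max(r1, 1e-300))
        means = [m0, m1]
        sds = [max(np.sqrt(v0), _MIN_SD), max(np.sqrt(v1), _MIN_SD)]
        if (ll - prev_ll) / n < tol and it > 1:
            converged = True
            break
        prev_ll = ll

    _, final_ll = _responsibilities(x, means, sds, weights)
    if not converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations",
            NonConvergenceWarning,
            stacklevel=2,
        )
    if means[0] > means[1]:  # keep the collagen class second
        means = means[::-1]
        sds = sds[::-1]
        weights = weights[::-1]
    return GMM2(
        means=(means[0], means[1]),
        sds=(sds[0], sds[1]),
        weights=(weights[0] / (weights[0] + weights[1]),
                 weights[1] / (weights[0] + weights[1])),
        loglik=final_ll,
        n_iter=it,
        converged=converged,
        loglik_path=tuple(path),
    )


def binarize(image: SHGImage, model: GMM2) -> BinaryMask:
    """Label each pixel collagen iff the posterior of the brighter mixture
    component is >= 0.5 (ties go to collagen).

    The comparison is done on weighted log-densities, which is exact: the
    posterior reaches 0.5 precisely where the two weighted densities are
    equal.
    """
    x = image.pixels.ravel().astype(float)
    la = np.log(model.weights[0]) + _log_gauss(x, model.means[0], model.sds[0])
    lb = np.log(model.weights[1]) + _log_gauss(x, model.means[1], model.sds[1])
    labels = (lb >= la).reshape(image.shape)
    return BinaryMask(labels=labels, pixel_size_um=image.pixel_size_um)


def segment(image: SHGImage, tol: float = 1e-6, max_iter: int = 500) -> BinaryMask:
    """Fit the mixture and binarize in one step.

    A degenerate (constant) image yields an all-background mask instead of
    an error, which is the right behaviour inside a batch pipeline.
    """
    try:
        model = fit_gmm2(image, tol=tol, max_iter=max_iter)
    except DegenerateImageError:
        return BinaryMask(
            labels=np.zeros(image.shape, dtype=bool),
            pixel_size_um=image.pixel_size_um,
        )
    return binarize(image, model)
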