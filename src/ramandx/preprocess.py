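"""Spectral preprocessing: Savitzky-Golay smoothing, airPLS baseline removal,
min-max scaling — applied per spectrum, in that order.

The airPLS (adaptive iteratively reweighted penalized least squares) baseline
estimator fits a Whittaker smoother — minimising ||W^(1/2)(y-z)||^2 +
lambda*||D2 z||^2 with D2 the second-difference operator — and iteratively
drives the weights of points lying above the current fit to zero, so the
smooth curve settles under the peaks onto the fluorescence background.
Weights of points below the fit grow as exp(t*|d_i|/|d^-|) with iteration t,
where d = y - z and |d^-| is the total mass of negative residuals; iteration
stops once |d^-| < ratio * ||y||_1.

The penalized system (W + lambda*D2'D2) z = W y is symmetric positive
definite and pentadiagonal, solved exactly in O(L) by a banded Cholesky
factorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.signal
import scipy.sparse

from .errors import ConfigError, DataError, NumericalError
from .types import SpectrumSet


@dataclass
class PreprocessConfig:
    """Tunable parameters of the three-stage preprocessing chain.

    ``sg_window``/``sg_order`` control the Savitzky-Golay filter (window must
    be odd and exceed the polynomial order).  ``airpls_lambda`` is the
    Whittaker smoothness penalty — larger values give stiffer baselines;
    1e5 suits broad serum fluorescence backgrounds on a ~1700-point axis.
    """

    sg_window: int = 11
    sg_order: int = 3
    airpls_lambda: float = 1e5
    airpls_ratio: float = 1e-3
    airpls_maxiter: int = 30

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ConfigError(f"sg_window must be odd, got {self.sg_window}")
        if self.sg_order >= self.sg_window:
            raise ConfigError(
                f"sg_order ({self.sg_order}) must be smaller than sg_window ({self.sg_window})"
            )
        if self.airpls_lambda <= 0:
            raise ConfigError(f"airpls_lambda must be positive, got {self.airpls_lambda}")
        if not 0 < self.airpls_ratio < 1:
            raise ConfigError(f"airpls_ratio must lie in (0, 1), got {self.airpls_ratio}")
        if self.airpls_maxiter < 1:
            raise ConfigError(f"airpls_maxiter must be >= 1, got {self.airpls_maxiter}")


@dataclass
class AirPLSResult:
    """Baseline estimate with convergence diagnostics.

    ``corrected + baseline`` reconstructs the input to float precision.
    """

    baseline: np.ndarray
    corrected: np.ndarray
    n_iterations: int
    converged: bool


def savitzky_golay(intensity: np.ndarray, window: int = 11, order: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing: local least-squares polynomial fit.

    Exact on polynomials of degree <= ``order``; attenuates high-frequency
    noise while preserving band width and shape.
    """
    y = np.asarray(intensity, dtype=float)
    if window % 2 == 0:
        raise ConfigError(f"window must be odd, got {window}")
    if order >= window:
        raise ConfigError(f"order ({order}) must be smaller than window ({window})")
    if y.size < window:
        raise DataError(f"spectrum of length {y.size} shorter than window {window}")
    return scipy.signal.savgol_filter(y, window_length=window, polyorder=order)


def _penalty_bands(n: int, lam: float) -> np.ndarray:
    """Upper banded form (for solveh_banded) of lambda * D2'D2, shape (3, n)."""
    d2 = scipy.sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    dtd = (d2.T @ d2).todia()
    ab = np.zeros((3, n))
    offsets = {int(o): i for i, o in enumerate(dtd.offsets)}
    data = dtd.data
    # row u+i-j of the banded matrix holds super-diagonal j-i = 2-row index
    for off in (0, 1, 2):
        if off in offsets:
            ab[2 - off] = data[offsets[off]]
    return lam * ab


def airpls(
    intensity: np.ndarray,
    lam: float = 1e5,
    ratio: float = 1e-3,
    maxiter: int = 30,
) -> AirPLSResult:
    """Estimate and remove a smooth baseline by adaptive reweighting.

    Returns the baseline ``z`` and the corrected signal ``y - z``.  A signal
    that is itself smooth (zero second difference, e.g. a straight line) is
    returned as its own baseline.
    """
    y = np.asarray(intensity, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise DataError(f"airpls needs a 1-D signal of length >= 4, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise NumericalError("airpls input contains non-finite values")
    if lam <= 0:
        raise ConfigError(f"lambda must be positive, got {lam}")

    n = y.size
    penalty = _penalty_bands(n, lam)
    norm_y = np.abs(y).sum()
    w = np.ones(n)
    z = np.zeros(n)
    converged = False
    t = 0
    for t in range(1, maxiter + 1):
        ab = penalty.copy()
        ab[2] += w
        try:
            z = scipy.linalg.solveh_banded(ab, w * y, lower=False)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate weights
            raise NumericalError(f"airpls system became singular at iteration {t}") from exc
        d = y - z
        neg = d < 0
        d_neg = np.abs(d[neg]).sum()
        if d_neg <= ratio * norm_y:  # '<=' so an exactly-zero signal converges at once
            converged = True
            break
        w = np.zeros(n)
        w[neg] = np.exp(t * np.abs(d[neg]) / d_neg)

    return AirPLSResult(baseline=z, corrected=y - z, n_iterations=t, converged=converged)


def minmax_scale(intensity: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]: (y - min) / (max - min).

    Raises on constant spectra, which cannot be scaled.
    """
    y = np.asarray(intensity, dtype=float)
    lo, hi = y.min(), y.max()
    if hi == lo:
        raise DataError("cannot min-max scale a constant spectrum")
    return (y - lo) / (hi - lo)


def preprocess_set(spectra: SpectrumSet, cfg: PreprocessConfig | None = None) -> SpectrumSet:
    """Smooth, baseline-correct and scale every spectrum independently.

    Stage order is fixed (Savitzky-Golay -> airPLS -> min-max); labels and
    sample ids pass through unchanged.  Errors from any stage are re-raised
    annotated with the offending sample id.
    """
    cfg = cfg or PreprocessConfig()
    out = np.empty_like(spectra.intensities)
    for i in range(len(spectra)):
        sid = spectra.sample_ids[i]
        try:
            smooth = savitzky_golay(spectra.intensities[i], cfg.sg_window, cfg.sg_order)
            corrected = airpls(
                smooth, cfg.airpls_lambda, cfg.airpls_ratio, cfg.airpls_maxiter
            ).corrected
            out[i] = minmax_scale(corrected)
        except (DataError, NumericalError) as exc:
            raise type(exc)(f"sample {sid!r}: {exc}") from exc
        assert out[i].min() == 0.0 and out[i].max() == 1.0
    return SpectrumSet(
        axis=spectra.axis,
        intensities=out,
        labels=spectra.labels,
        sample_ids=list(spectra.sample_ids),
    )
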