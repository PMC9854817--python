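"""Synthetic serum-like Raman spectrum generator.

Patient serum spectra for the diagnostic task (healthy controls vs breast
cancer vs DCIS) are not publicly available, so this module generates labelled
surrogates carrying the same statistical structure the downstream analysis
assumes: a 1698-point axis spanning 400-4000 cm^-1, Lorentzian Raman bands at
the canonical serum peak positions (strongest at the 1154 and 1514 cm^-1
beta-carotene bands), a smooth fluorescence-like polynomial background,
per-sample multiplicative amplitude jitter with class-dependent peak scaling,
additive Gaussian detector noise, and averaging of 5 replicate acquisitions
per sample.

Class separation enters only through ``PeakSpec.class_multipliers``; the
magnitudes of the default multipliers are a modelling choice (real
between-class differences were reported graphically, not numerically) and are
fully configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigError
from .types import CLASSES, SpectrumSet, Spectrum, validate_axis


def make_axis(start: float, stop: float, n_points: int) -> np.ndarray:
    """Evenly spaced wavenumber axis with exact endpoints.

    Parameters
    ----------
    start, stop : float
        First and last Raman shift in cm^-1; ``stop`` must exceed ``start``.
    n_points : int
        Axis length, at least 8.
    """
    if stop <= start:
        raise ConfigError(f"axis range must increase: start={start}, stop={stop}")
    if n_points < 8:
        raise ConfigError(f"axis needs at least 8 points, got {n_points}")
    return validate_axis(np.linspace(start, stop, n_points))


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian Raman band.

    ``base_amplitude`` is the peak height in arbitrary intensity units before
    class scaling; ``class_multipliers`` maps each class label to a positive
    factor applied on top of it, which is where all class signal originates.
    """

    center: float
    width: float  # FWHM, cm^-1
    base_amplitude: float
    class_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in CLASSES}
    )

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"peak width must be positive, got {self.width}")
        if self.base_amplitude < 0:
            raise ConfigError(f"base_amplitude must be >= 0, got {self.base_amplitude}")
        for cls, m in self.class_multipliers.items():
            if m <= 0:
                raise ConfigError(f"multiplier for {cls!r} must be positive, got {m}")

    def multiplier(self, label: Optional[str]) -> float:
        if label is None:
            return 1.0
        return float(self.class_multipliers.get(label, 1.0))


# Canonical serum Raman band positions (cm^-1) with their broad biochemical
# origin.  The 1154/1514 beta-carotene bands dominate; amplitudes and class
# multipliers below are generator defaults, not measured values.
_CAROTENE = {"HC": 1.00, "BC": 0.60, "DCIS": 0.78}
_PROTEIN = {"HC": 1.00, "BC": 1.15, "DCIS": 1.08}
_NEUTRAL = {"HC": 1.00, "BC": 1.00, "DCIS": 1.00}

_DEFAULT_PEAK_TABLE: tuple[tuple[float, float, dict[str, float]], ...] = (
    (593.0, 0.25, _NEUTRAL),   # ascorbic acid / amide-VI
    (810.0, 0.20, _NEUTRAL),   # L-serine, glutathione C-C-O stretch
    (950.0, 0.40, _PROTEIN),   # proline/valine C-C stretch
    (1004.0, 0.45, _PROTEIN),  # phenylalanine symmetric C-C stretch
    (1154.0, 1.00, _CAROTENE),  # beta-carotene C-C stretch (strongest)
    (1280.0, 0.30, _PROTEIN),  # amide III / nucleic-acid CH2 wag
    (1445.0, 0.50, _PROTEIN),  # collagen/phospholipid CH2 bend
    (1514.0, 0.95, _CAROTENE),  # beta-carotene C-C stretch (second strongest)
    (1576.0, 0.30, _PROTEIN),  # phenylalanine C-C bend
    (2517.0, 0.35, _PROTEIN),  # protein O-H stretch
    (2662.0, 0.30, _PROTEIN),  # protein O-H stretch
)

DEFAULT_FWHM = 16.0  # cm^-1; well above the 4.5 cm^-1 instrument resolution


def default_peaks(fwhm: float = DEFAULT_FWHM) -> list[PeakSpec]:
    """The default 11-band serum peak set with class-dependent scaling."""
    return [
        PeakSpec(center=c, width=fwhm, base_amplitude=a, class_multipliers=dict(m))
        for c, a, m in _DEFAULT_PEAK_TABLE
    ]


# Fluorescence-like background: cubic in the normalised axis position
# u = (nu - nu0)/(nu1 - nu0), monotonically decaying from 1.2 to 0.4 —
# strictly positive, range comparable to the strongest peak height.
DEFAULT_BASELINE_COEFFS: tuple[float, ...] = (1.2, -1.5, 0.9, -0.2)


@dataclass
class GeneratorConfig:
    """Full description of one synthetic cohort.

    Defaults reproduce the study design being emulated: 804 samples
    (241 HC / 463 BC / 100 DCIS), 5 replicate acquisitions averaged per
    sample, 1698 axis points on 400-4000 cm^-1.
    """

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"HC": 241, "BC": 463, "DCIS": 100}
    )
    peaks: Sequence[PeakSpec] = field(default_factory=default_peaks)
    baseline_coeffs: Sequence[float] = DEFAULT_BASELINE_COEFFS
    noise_sd: float = 0.01
    jitter_sd: float = 0.08
    replicates: int = 5
    seed: int = 0
    axis_start: float = 400.0
    axis_stop: float = 4000.0
    axis_points: int = 1698

    def __post_init__(self) -> None:
        for cls, n in self.n_per_class.items():
            if cls not in CLASSES:
                raise ConfigError(f"unknown class {cls!r} in n_per_class")
            if n <= 0:
                raise ConfigError(f"count for class {cls!r} must be positive, got {n}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.jitter_sd < 0:
            raise ConfigError(f"jitter_sd must be >= 0, got {self.jitter_sd}")
        if self.replicates < 1:
            raise ConfigError(f"replicates must be >= 1, got {self.replicates}")

    def axis(self) -> np.ndarray:
        return make_axis(self.axis_start, self.axis_stop, self.axis_points)

    def no_signal(self) -> "GeneratorConfig":
        """Copy with all class multipliers forced to 1 (negative control)."""
        flat = [
            replace(p, class_multipliers={c: 1.0 for c in CLASSES}) for p in self.peaks
        ]
        return replace(self, peaks=flat)


def lorentzian(axis: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-height Lorentzian line shape."""
    half = fwhm / 2.0
    return half**2 / ((axis - center) ** 2 + half**2)


def baseline_curve(axis: np.ndarray, coeffs: Sequence[float]) -> np.ndarray:
    """Polynomial background evaluated on the normalised axis position u in [0, 1]."""
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    return np.polynomial.polynomial.polyval(u, np.asarray(coeffs, dtype=float))


def render_clean_spectrum(
    axis: np.ndarray,
    peaks: Sequence[PeakSpec],
    baseline_coeffs: Sequence[float],
    label: Optional[str] = None,
    peak_scales: Optional[Sequence[float]] = None,
) -> Spectrum:
    """Deterministic noise-free rendering: background plus scaled Lorentzians.

    ``peak_scales`` (one factor per peak) is used by the generator to inject
    per-sample amplitude jitter; defaults to 1 for every peak.
    """
    axis = validate_axis(axis)
    y = baseline_curve(axis, baseline_coeffs)
    scales = np.ones(len(peaks)) if peak_scales is None else np.asarray(peak_scales, float)
    if scales.size != len(peaks):
        raise ConfigError(f"{scales.size} peak_scales for {len(peaks)} peaks")
    for peak, s in zip(peaks, scales):
        if not (axis[0] - peak.width <= peak.center <= axis[-1] + peak.width):
            warnings.warn(
                f"peak at {peak.center} cm^-1 lies outside the axis "
                f"[{axis[0]}, {axis[-1]}]; rendered anyway",
                stacklevel=2,
            )
        y = y + peak.base_amplitude * peak.multiplier(label) * s * lorentzian(
            axis, peak.center, peak.width
        )
    return Spectrum(axis=axis, intensity=y, label=label)


def generate_dataset(config: GeneratorConfig) -> SpectrumSet:
    """Generate the full labelled cohort described by ``config``.

    For each sample: draw one lognormal jitter factor per peak, render the
    clean class spectrum, add i.i.d. Gaussian noise to ``replicates``
    acquisitions and average them.  Per-sample RNG streams are derived from
    (seed, sample counter) so generation is order-independent and fully
    reproducible.
    """
    axis = config.axis()
    n_total = sum(config.n_per_class.values())
    intensities = np.empty((n_total, axis.size))
    labels: list[str] = []
    sample_ids: list[str] = []

    i = 0
    for cls in CLASSES:
        n_cls = config.n_per_class.get(cls, 0)
        for j in range(n_cls):
            rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), i]))
            jitter = rng.lognormal(mean=0.0, sigma=config.jitter_sd, size=len(config.peaks))
            clean = render_clean_spectrum(
                axis, config.peaks, config.baseline_coeffs, label=cls, peak_scales=jitter
            )
            noise = rng.normal(0.0, config.noise_sd, size=(config.replicates, axis.size))
            intensities[i] = clean.intensity + noise.mean(axis=0)
            labels.append(cls)
            sample_ids.append(f"{cls}-{j:04d}")
            i += 1

    return SpectrumSet(
        axis=axis,
        intensities=intensities,
        labels=np.array(labels, dtype=object),
        sample_ids=sample_ids,
    )
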