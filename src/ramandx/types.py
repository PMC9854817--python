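"""Core data containers: spectra and aligned spectrum sets.

A spectrum is an intensity vector on a shared wavenumber axis (Raman shift,
cm^-1) with an optional diagnostic class label.  The three-class vocabulary is
fixed: HC (healthy controls), BC (breast cancer), DCIS (ductal carcinoma in
situ).  Class order matters — integer encodings, confusion-matrix layout and
tie-breaking all follow this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DataError

#: Fixed class vocabulary, in canonical order.
CLASSES: tuple[str, ...] = ("HC", "BC", "DCIS")

#: Label -> integer code in canonical order.
CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}


def validate_axis(values: np.ndarray) -> np.ndarray:
    """Validate a wavenumber axis: 1-D, length >= 8, strictly increasing, first >= 0."""
    axis = np.asarray(values, dtype=float)
    if axis.ndim != 1:
        raise DataError(f"axis must be 1-D, got shape {axis.shape}")
    if axis.size < 8:
        raise DataError(f"axis must have at least 8 points, got {axis.size}")
    if not np.all(np.diff(axis) > 0):
        raise DataError("axis must be strictly increasing")
    if axis[0] < 0:
        raise DataError("axis must start at a non-negative wavenumber")
    return axis


@dataclass
class Spectrum:
    """One intensity vector on a wavenumber axis, optionally labelled."""

    axis: np.ndarray
    intensity: np.ndarray
    label: Optional[str] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.axis = validate_axis(self.axis)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.axis.shape:
            raise DataError(
                f"intensity length {self.intensity.size} != axis length {self.axis.size}"
                + (f" (sample {self.sample_id})" if self.sample_id else "")
            )
        if not np.all(np.isfinite(self.intensity)):
            raise DataError(f"non-finite intensity values (sample {self.sample_id!r})")
        if self.label is not None and self.label not in CLASS_INDEX:
            raise DataError(f"unknown label {self.label!r}; expected one of {CLASSES}")


@dataclass
class SpectrumSet:
    """N aligned spectra sharing one axis, with labels and sample ids.

    ``intensities`` is an (N, L) matrix; row i belongs to ``sample_ids[i]``
    with class ``labels[i]``.
    """

    axis: np.ndarray
    intensities: np.ndarray
    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axis = validate_axis(self.axis)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        n = self.intensities.shape[0]
        if self.intensities.size and self.intensities.shape[1] != self.axis.size:
            raise DataError(
                f"intensity rows of length {self.intensities.shape[1]} "
                f"!= axis length {self.axis.size}"
            )
        if self.labels.size != n:
            raise DataError(f"{self.labels.size} labels for {n} spectra")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:05d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise DataError(f"{len(self.sample_ids)} sample_ids for {n} spectra")
        if not np.all(np.isfinite(self.intensities)):
            bad = int(np.flatnonzero(~np.isfinite(self.intensities).all(axis=1))[0])
            raise DataError(f"non-finite intensities in sample {self.sample_ids[bad]!r}")
        for lab in self.labels:
            if lab is not None and lab not in CLASS_INDEX:
                raise DataError(f"unknown label {lab!r}; expected one of {CLASSES}")

    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.axis.size

    def encoded_labels(self) -> np.ndarray:
        """Integer-encode labels in canonical class order."""
        return np.array([CLASS_INDEX[lab] for lab in self.labels], dtype=int)

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in CLASSES if np.any(self.labels == c)}

    def subset(self, indices: Sequence[int]) -> "SpectrumSet":
        idx = np.asarray(indices, dtype=int)
        return SpectrumSet(
            axis=self.axis,
            intensities=self.intensities[idx],
            labels=self.labels[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.intensities[i], self.labels[i], self.sample_ids[i])

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectrumSet":
        if not spectra:
            raise DataError("cannot build a SpectrumSet from zero spectra")
        axis = spectra[0].axis
        for s in spectra[1:]:
            if s.axis.shape != axis.shape or not np.array_equal(s.axis, axis):
                raise DataError(f"axis mismatch for sample {s.sample_id!r}")
        return cls(
            axis=axis,
            intensities=np.stack([s.intensity for s in spectra]),
            labels=np.array([s.label for s in spectra], dtype=object),
            sample_ids=[s.sample_id for s in spectra],
        )
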