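"""Reading and writing spectrum sets as plain-text CSV.

Two dialects:

``perfile``
    A directory with one CSV per spectrum (columns ``wavenumber_cm1,
    intensity``) plus ``manifest.csv`` (``sample_id, label, path``).

``wide``
    A single CSV: first row is ``label`` followed by the axis values; each
    subsequent row is a sample's label followed by its intensities.

Floats are serialised with ``repr`` (shortest round-trip form), so a
write -> read cycle reproduces every matrix bit-exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .errors import DataError
from .types import SpectrumSet

DIALECTS = ("perfile", "wide")


def _fmt(x: float) -> str:
    return repr(float(x))


def write_spectrum_set(spectra: SpectrumSet, path: str | Path, dialect: str = "wide") -> Path:
    """Serialise a spectrum set; returns the file (wide) or directory (perfile)."""
    path = Path(path)
    if dialect == "wide":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label"] + [_fmt(v) for v in spectra.axis])
            for i in range(len(spectra)):
                writer.writerow(
                    [spectra.labels[i] or ""] + [_fmt(v) for v in spectra.intensities[i]]
                )
        return path
    if dialect == "perfile":
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for i in range(len(spectra)):
            fname = f"{spectra.sample_ids[i]}.csv"
            with open(path / fname, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["wavenumber_cm1", "intensity"])
                for w, y in zip(spectra.axis, spectra.intensities[i]):
                    writer.writerow([_fmt(w), _fmt(y)])
            rows.append([spectra.sample_ids[i], spectra.labels[i] or "", fname])
        with open(path / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sample_id", "label", "path"])
            writer.writerows(rows)
        return path
    raise DataError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def read_spectrum_set(path: str | Path, dialect: str = "wide") -> SpectrumSet:
    """Parse a spectrum set written by :func:`write_spectrum_set`."""
    path = Path(path)
    if dialect == "wide":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        if not rows or rows[0][0] != "label":
            raise DataError(f"{path}: not a wide spectrum CSV (missing 'label' header)")
        axis = np.array([float(v) for v in rows[0][1:]])
        labels, intensities = [], []
        for r, row in enumerate(rows[1:], start=2):
            if len(row) != axis.size + 1:
                raise DataError(f"{path}: ragged row {r} ({len(row)} columns, expected {axis.size + 1})")
            labels.append(row[0] or None)
            intensities.append([float(v) for v in row[1:]])
        return SpectrumSet(
            axis=axis,
            intensities=np.array(intensities) if intensities else np.empty((0, axis.size)),
            labels=np.array(labels, dtype=object),
        )
    if dialect == "perfile":
        manifest = path / "manifest.csv"
        if not manifest.exists():
            raise DataError(f"no manifest.csv under {path}")
        with open(manifest, newline="") as fh:
            reader = csv.DictReader(fh)
            entries = list(reader)
        axis = None
        labels, ids, intensities = [], [], []
        for entry in entries:
            sid = entry["sample_id"]
            fpath = path / entry["path"]
            if not fpath.exists():
                raise DataError(f"manifest references missing file for sample {sid!r}: {fpath}")
            data = np.loadtxt(fpath, delimiter=",", skiprows=1, ndmin=2)
            if axis is None:
                axis = data[:, 0]
            elif data.shape[0] != axis.size or not np.array_equal(data[:, 0], axis):
                raise DataError(f"axis mismatch in sample {sid!r}")
            intensities.append(data[:, 1])
            labels.append(entry["label"] or None)
            ids.append(sid)
        if axis is None:
            raise DataError(f"empty manifest under {path}")
        return SpectrumSet(
            axis=axis,
            intensities=np.stack(intensities),
            labels=np.array(labels, dtype=object),
            sample_ids=ids,
        )
    raise DataError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
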