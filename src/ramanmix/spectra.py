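"""Shared container for wide-format spectra tables.

A :class:`SpectraMatrix` bundles the intensity matrix (rows = measurements,
columns = spectral points) with its axis, per-row class labels and a
processing-stage tag, and validates the alignment invariants that every
downstream module relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

AXIS_KINDS = ("wavenumber", "wavelength")
STAGES = ("raw", "baseline_removed", "smoothed", "rescaled")

CLASS_LABELS = ("NS", "K", "BCC", "MM", "PN")


@dataclass
class SpectraMatrix:
    """Samples x points intensity matrix with an aligned spectral axis.

    Parameters
    ----------
    axis
        Strictly increasing vector of wavelengths (nm) or Raman shifts
        (cm^-1); ``axis_kind`` records which.
    values
        2-D array, one spectrum per row.  Arbitrary intensity units.
    labels
        Per-row class tag (length == number of rows).
    axis_kind
        ``"wavenumber"`` (Raman shift, cm^-1) or ``"wavelength"`` (nm).
    stage
        Provenance tag: raw / baseline_removed / smoothed / rescaled.
    """

    axis: np.ndarray
    values: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    axis_kind: str = "wavenumber"
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.labels is None:
            self.labels = np.array([""] * self.values.shape[0], dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
        if self.axis.ndim != 1:
            raise ValueError("axis must be 1-D")
        if self.axis.size != self.values.shape[1]:
            raise ValueError(
                f"axis length {self.axis.size} != number of columns "
                f"{self.values.shape[1]}"
            )
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectral values must be finite")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels length != number of rows")
        if self.axis_kind not in AXIS_KINDS:
            raise ValueError(f"axis_kind must be one of {AXIS_KINDS}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, stage: str | None = None) -> "SpectraMatrix":
        """Copy with replaced intensities (same axis, labels preserved)."""
        return replace(self, values=values, stage=stage or self.stage)

    def subset(self, row_index: np.ndarray) -> "SpectraMatrix":
        """Row subset; keeps labels aligned."""
        return replace(
            self, values=self.values[row_index], labels=self.labels[row_index]
        )
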