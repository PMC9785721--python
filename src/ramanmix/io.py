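"""CSV / YAML / JSON readers and writers with a fixed header convention.

Spectra tables are wide CSV: first column ``sample_id``, remaining column
headers are the axis values (decimal cm^-1 or nm), one row per measurement.
All writers are deterministic (no timestamps, fixed float formatting) so that
seeded reruns produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectra import SpectraMatrix

FLOAT_FORMAT = "%.12g"


def write_spectra_csv(spectra: SpectraMatrix, path) -> None:
    df = pd.DataFrame(
        spectra.values,
        columns=[FLOAT_FORMAT % v for v in spectra.axis],
    )
    df.insert(0, "sample_id", np.arange(spectra.n_samples))
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_spectra_csv(path, labels=None, axis_kind: str = "wavenumber") -> SpectraMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise ValueError("spectra CSV must start with a 'sample_id' column")
    axis = np.array([float(c) for c in df.columns[1:]])
    return SpectraMatrix(
        axis=axis,
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        labels=labels,
        axis_kind=axis_kind,
    )


def write_labels_csv(labels, path) -> None:
    pd.DataFrame(
        {"sample_id": np.arange(len(labels)), "label": list(labels)}
    ).to_csv(path, index=False)


def read_labels_csv(path) -> np.ndarray:
    return pd.read_csv(path)["label"].to_numpy(dtype=object)


def write_matrix_csv(matrix, path, colnames=None) -> None:
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    cols = list(colnames) if colnames is not None else [
        f"c{j}" for j in range(m.shape[1])
    ]
    pd.DataFrame(m, columns=cols).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_matrix_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)


def write_basis_csv(basis_with_nan, path, axis=None) -> None:
    """Basis convention: numeric rows = fixed spectra, all-NaN rows = free
    components (written as empty cells)."""
    m = np.atleast_2d(np.asarray(basis_with_nan, dtype=float))
    cols = (
        [FLOAT_FORMAT % v for v in axis] if axis is not None
        else [f"p{j}" for j in range(m.shape[1])]
    )
    pd.DataFrame(m, columns=cols).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_basis_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")


def write_config_echo(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(_jsonify(config), sort_keys=True))
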