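"""Reading and writing the epoch container and result tables.

Epoch container layout (HDF5)
-----------------------------
One dataset per subject-source::

    /epochs/<subject_id>/<source_id>     float64, shape (n_trials, n_samples)
        attrs: sampling_rate (Hz), subject (str), source (str), group (str)

A cohort file additionally carries a JSON manifest and, for synthetic
cohorts, a ground-truth table, both stored as sidecar text files next to
the container (``<stem>.manifest.json``, ``<stem>.truth.csv``).

Wide delimited text (one row per trial) is supported as a minimal
interchange format for single subject-source epochs.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import EpochedSeries
from .synthetic import Cohort, CohortConfig

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_cohort",
    "load_cohort_epochs",
    "load_manifest",
    "read_wide_text",
    "write_wide_text",
]


def save_epochs(h5: h5py.Group, epochs: EpochedSeries) -> None:
    grp = h5.require_group(f"epochs/{epochs.subject_id}")
    ds = grp.create_dataset(epochs.source_id, data=epochs.values)
    ds.attrs["sampling_rate"] = float(epochs.sampling_rate)
    ds.attrs["subject"] = epochs.subject_id
    ds.attrs["source"] = epochs.source_id
    ds.attrs["group"] = epochs.group


def load_epochs(h5: h5py.Group, subject_id: str, source_id: str) -> EpochedSeries:
    ds = h5[f"epochs/{subject_id}/{source_id}"]
    return EpochedSeries(
        values=ds[()],
        sampling_rate=float(ds.attrs["sampling_rate"]),
        subject_id=str(ds.attrs["subject"]),
        source_id=str(ds.attrs["source"]),
        group=str(ds.attrs["group"]),
    )


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.manifest.json"), Path(f"{stem}.truth.csv")


def save_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to an HDF5 container plus manifest/ground-truth sidecars."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for (_, _), ep in sorted(cohort.epochs.items()):
            save_epochs(f, ep)
    manifest_path, truth_path = _sidecar_paths(path)
    manifest = {
        "subjects": cohort.manifest.to_dict(orient="records"),
        "sources": sorted({src for (_, src) in cohort.epochs}),
        "sampling_rate": cohort.config.sampling_rate,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    cohort.ground_truth.to_csv(truth_path, index=False)


def load_manifest(path: str | Path) -> dict:
    manifest_path, _ = _sidecar_paths(Path(path))
    return json.loads(manifest_path.read_text())


def load_cohort_epochs(path: str | Path) -> dict[tuple[str, str], EpochedSeries]:
    """Load every subject-source dataset from a cohort container."""
    out: dict[tuple[str, str], EpochedSeries] = {}
    with h5py.File(path, "r") as f:
        for subject_id in sorted(f["epochs"]):
            for source_id in sorted(f[f"epochs/{subject_id}"]):
                out[(subject_id, source_id)] = load_epochs(f, subject_id, source_id)
    return out


def read_wide_text(
    path: str | Path,
    sampling_rate: float,
    delimiter: str = "\t",
    subject_id: str = "",
    source_id: str = "",
    group: str = "",
) -> EpochedSeries:
    """Read epochs from wide delimited text, one row per trial."""
    values = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return EpochedSeries(
        values=values,
        sampling_rate=sampling_rate,
        subject_id=subject_id,
        source_id=source_id,
        group=group,
    )


def write_wide_text(epochs: EpochedSeries, path: str | Path, delimiter: str = "\t") -> None:
    np.savetxt(path, epochs.values, delimiter=delimiter)
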