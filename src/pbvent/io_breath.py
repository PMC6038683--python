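"""CSV readers/writers for breath series and cohort manifests.

The series dialect is fixed: header ``breath_index,time_s,ve_l_min``,
0-based contiguous breath index, strictly increasing times, positive VE.
Manifests use header ``subject_id,label,path`` with relative paths resolved
against the manifest's own directory.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import SeriesFormatError
from .series import BreathSeries

__all__ = ["CohortManifest", "read_series", "write_series",
           "read_manifest", "write_manifest"]

SERIES_HEADER = ["breath_index", "time_s", "ve_l_min"]
MANIFEST_HEADER = ["subject_id", "label", "path"]

_LABEL_NORM = {"pb": "PB", "npb": "nPB", "non-pb": "nPB", "nonpb": "nPB"}


@dataclass
class CohortManifest:
    """Subjects of a cohort: (subject_id, label in {PB, nPB}, series path)."""

    entries: list[tuple[str, str, Path]]

    def __post_init__(self) -> None:
        ids = [sid for sid, _, _ in self.entries]
        if len(ids) != len(set(ids)):
            dup = next(s for s in ids if ids.count(s) > 1)
            raise SeriesFormatError(f"duplicate subject_id in manifest: {dup!r}")
        for sid, label, _ in self.entries:
            if label not in ("PB", "nPB"):
                raise SeriesFormatError(
                    f"unknown label {label!r} for subject {sid!r}")

    def counts(self) -> tuple[int, int]:
        """(number of PB subjects, number of nPB subjects)."""
        n_pb = sum(1 for _, lab, _ in self.entries if lab == "PB")
        return n_pb, len(self.entries) - n_pb

    def __len__(self) -> int:
        return len(self.entries)


def read_series(path: str | Path) -> BreathSeries:
    """Read one breath series CSV; subject_id is taken from the file stem."""
    path = Path(path)
    if not path.exists():
        raise SeriesFormatError(f"series file not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SeriesFormatError(f"{path}: empty file, expected header") from None
        if header != SERIES_HEADER:
            raise SeriesFormatError(
                f"{path}: malformed header {header!r}, expected {SERIES_HEADER!r}")
        times, ve = [], []
        for lineno, row in enumerate(reader):
            if len(row) != 3:
                raise SeriesFormatError(f"{path}: row {lineno} has {len(row)} fields")
            try:
                idx, t, v = int(row[0]), float(row[1]), float(row[2])
            except ValueError as exc:
                raise SeriesFormatError(f"{path}: row {lineno}: {exc}") from None
            if idx != lineno:
                raise SeriesFormatError(
                    f"{path}: breath_index must be contiguous from 0; "
                    f"row {lineno} has index {idx}")
            if v <= 0:
                raise SeriesFormatError(
                    f"{path}: non-positive ve_l_min at row {lineno}")
            if times and t <= times[-1]:
                raise SeriesFormatError(
                    f"{path}: time_s not strictly increasing at row {lineno}")
            times.append(t)
            ve.append(v)
    return BreathSeries(subject_id=path.stem, times=np.array(times), ve=np.array(ve))


def write_series(series: BreathSeries, path: str | Path) -> Path:
    """Write a breath series to CSV (VE with 6 decimal places)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SERIES_HEADER)
        for i, (t, v) in enumerate(zip(series.times, series.ve)):
            writer.writerow([i, f"{t:.6f}", f"{v:.6f}"])
    return path


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV; labels are matched case-insensitively and
    normalized to {PB, nPB}; relative paths resolve against the manifest dir."""
    path = Path(path)
    if not path.exists():
        raise SeriesFormatError(f"manifest file not found: {path}")
    base = path.parent
    entries: list[tuple[str, str, Path]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SeriesFormatError(f"{path}: empty manifest") from None
        if header != MANIFEST_HEADER:
            raise SeriesFormatError(
                f"{path}: malformed header {header!r}, expected {MANIFEST_HEADER!r}")
        for lineno, row in enumerate(reader):
            if len(row) != 3:
                raise SeriesFormatError(f"{path}: row {lineno} has {len(row)} fields")
            sid, raw_label, rel = row
            label = _LABEL_NORM.get(raw_label.strip().lower())
            if label is None:
                raise SeriesFormatError(
                    f"{path}: unknown label {raw_label!r} at row {lineno}")
            p = Path(rel)
            entries.append((sid, label, p if p.is_absolute() else base / p))
    return CohortManifest(entries=entries)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    """Write a cohort manifest CSV with paths relative to the manifest dir
    when possible."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_HEADER)
        for sid, label, p in manifest.entries:
            try:
                rel = Path(p).relative_to(path.parent)
            except ValueError:
                rel = Path(p)
            writer.writerow([sid, label, str(rel)])
    return path
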