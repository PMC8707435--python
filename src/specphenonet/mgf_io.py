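"""Reading/writing Mascot Generic Format peak lists and the dataset catalog.

The pipeline is retention-time driven: every spectrum must carry an RT, taken
from the ``RTINSECONDS`` header or, as a fallback, from an ``RT=<float>``
token in the ``TITLE`` line.  A missing RT is a hard error rather than a
silent default.

The catalog maps mgf files to omics layer, phenotype label, train/test split
and provenance (original vs augmented) and is persisted as a plain CSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from pyteomics import mgf as _pyt_mgf

PROTEOMIC = "proteomic"
METABOLOMIC = "metabolomic"
LAYERS = (PROTEOMIC, METABOLOMIC)

#: phenotype labels: control, ovarian, renal (kidney) and prostate cancer
CLASS_LABELS = ("CNT", "OVC", "RNC", "PRC")

SPLITS = ("train", "test", "validation", "unassigned")

_RT_TITLE_RE = re.compile(r"RT[=:]\s*([0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)")


class MGFParseError(ValueError):
    """Raised for malformed mgf content; the message names the offending line."""


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """One tandem scan: precursor info, retention time and the fragment list.

    Fragments are stored as parallel numpy arrays sorted ascending by m/z.
    """

    title: str
    precursor_mz: float
    rt_seconds: float
    mz: np.ndarray
    intensity: np.ndarray
    charge: int | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must be parallel")
        if self.rt_seconds < 0:
            raise ValueError(f"negative retention time on spectrum {self.title!r}")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class SpectraFile:
    """Parsed content of one mgf file plus its catalog identity."""

    file_id: str
    omics_layer: str
    spectra: list[Spectrum] = field(default_factory=list)
    class_label: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.omics_layer not in LAYERS:
            raise ValueError(f"unknown omics layer {self.omics_layer!r}")
        rts = [s.rt_seconds for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.spectra = sorted(self.spectra, key=lambda s: s.rt_seconds)

    @property
    def rt_values(self) -> np.ndarray:
        return np.array([s.rt_seconds for s in self.spectra], dtype=float)

    def __len__(self) -> int:
        return len(self.spectra)


def _validate_block_structure(path: Path) -> None:
    """Cheap structural pass so malformed files fail with a line number."""
    open_line = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().upper()
            if token == "BEGIN IONS":
                if open_line is not None:
                    raise MGFParseError(
                        f"{path}: BEGIN IONS at line {lineno} before the block "
                        f"opened at line {open_line} was closed (missing END IONS)"
                    )
                open_line = lineno
            elif token == "END IONS":
                if open_line is None:
                    raise MGFParseError(f"{path}: stray END IONS at line {lineno}")
                open_line = None
    if open_line is not None:
        raise MGFParseError(
            f"{path}: block opened at line {open_line} is never closed (missing END IONS)"
        )


def _rt_from_params(params: dict, title: str, index: int, rt_unit: str) -> float:
    raw = params.get("rtinseconds")
    if raw is None:
        m = _RT_TITLE_RE.search(title)
        if m is None:
            raise MGFParseError(
                f"spectrum #{index} ({title!r}): no RTINSECONDS header and no "
                "RT=<float> token in TITLE; retention time is required"
            )
        raw = m.group(1)
    rt = float(raw)
    # some exporters write minutes despite the header name; only plausible
    # minute-scale values are converted, and only when asked
    if rt_unit == "minutes" and rt < 200.0:
        rt *= 60.0
    return rt


def read_mgf(
    path: str | Path,
    file_id: str | None = None,
    omics_layer: str = PROTEOMIC,
    class_label: str | None = None,
    rt_unit: str = "seconds",
) -> SpectraFile:
    """Parse an mgf file into a :class:`SpectraFile`.

    Parameters
    ----------
    rt_unit:
        ``"seconds"`` (default) or ``"minutes"``; the minutes dialect converts
        header values below 200 to seconds.
    """
    path = Path(path)
    if rt_unit not in ("seconds", "minutes"):
        raise ValueError(f"rt_unit must be 'seconds' or 'minutes', got {rt_unit!r}")
    _validate_block_structure(path)
    spectra: list[Spectrum] = []
    with _pyt_mgf.MGF(str(path), convert_arrays=1, read_charges=False) as reader:
        for idx, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"index={idx}"))
            pepmass = params.get("pepmass", (0.0,))
            precursor = float(pepmass[0]) if pepmass and pepmass[0] is not None else 0.0
            charge = None
            if params.get("charge"):
                charge = int(params["charge"][0])
            rt = _rt_from_params(params, title, idx, rt_unit)
            spectra.append(
                Spectrum(
                    title=title,
                    precursor_mz=precursor,
                    rt_seconds=rt,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    charge=charge,
                )
            )
    return SpectraFile(
        file_id=file_id or path.stem,
        omics_layer=omics_layer,
        spectra=spectra,
        class_label=class_label,
    )


def write_mgf(sf: SpectraFile, path: str | Path) -> Path:
    """Write a :class:`SpectraFile` as standard mgf text.

    Numeric fields keep full float repr so a write/read round trip is lossless
    well below 1e-6 relative precision.
    """
    path = Path(path)
    entries = []
    for s in sf.spectra:
        params: dict = {
            "TITLE": s.title,
            "PEPMASS": s.precursor_mz,
            "RTINSECONDS": repr(float(s.rt_seconds)),
        }
        if s.charge is not None:
            params["CHARGE"] = f"{abs(s.charge)}{'+' if s.charge >= 0 else '-'}"
        entries.append(
            {
                "m/z array": [float(v) for v in s.mz],
                "intensity array": [float(v) for v in s.intensity],
                "params": params,
            }
        )
    with open(path, "w") as fh:
        _pyt_mgf.write(entries, fh, fragment_format="{!r} {!r}")
    return path


# ---------------------------------------------------------------------------
# dataset catalog

_CATALOG_COLUMNS = [
    "file_id", "layer", "label", "split", "provenance", "path", "source_file_id",
]


@dataclass
class DatasetCatalog:
    """Tabular manifest of the cohort: one row per (file_id, layer)."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_CATALOG_COLUMNS)
    )

    def __post_init__(self) -> None:
        for col in _CATALOG_COLUMNS:
            if col not in self.entries.columns:
                self.entries[col] = "" if col != "source_file_id" else None
        dup = self.entries.duplicated(subset=["file_id", "layer"])
        if dup.any():
            raise ValueError(
                f"duplicate (file_id, layer) rows: "
                f"{self.entries.loc[dup, 'file_id'].tolist()}"
            )

    def add(
        self,
        file_id: str,
        layer: str,
        label: str,
        split: str = "unassigned",
        provenance: str = "original",
        path: str = "",
        source_file_id: str | None = None,
    ) -> None:
        row = pd.DataFrame(
            [[file_id, layer, label, split, provenance, path, source_file_id]],
            columns=_CATALOG_COLUMNS,
        )
        self.entries = pd.concat([self.entries, row], ignore_index=True)

    def split_of(self, file_id: str) -> str:
        rows = self.entries[self.entries.file_id == file_id]
        if rows.empty:
            raise KeyError(f"file_id {file_id!r} not in catalog")
        return str(rows.iloc[0]["split"])

    def save_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.entries.to_csv(path, index=False)
        return path

    @classmethod
    def load_csv(cls, path: str | Path) -> "DatasetCatalog":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df["source_file_id"] = df["source_file_id"].replace("", None)
        return cls(df)

    def __len__(self) -> int:
        return len(self.entries)


def assign_splits(
    catalog: DatasetCatalog,
    train_fraction: float = 0.6,
    validation_fraction: float = 0.0,
    seed: int = 0,
) -> DatasetCatalog:
    """Stratified per-class train/test(/validation) assignment.

    Splitting is done at the *subject* level: both omics layers of a file_id
    receive the same split, so paired files never straddle splits.  Augmented
    entries inherit the split of their source file and are never reassigned.
    """
    if not (0 < train_fraction < 1) or validation_fraction < 0:
        raise ValueError("fractions must lie in (0, 1)")
    if train_fraction + validation_fraction > 1:
        raise ValueError("train + validation fractions exceed 1")
    df = catalog.entries.copy()
    original = df[df.provenance == "original"]
    if (original.label.isin(["", "unknown"]) | original.label.isna()).any():
        raise ValueError("every original entry needs a class label before splitting")

    n_splits = 2 + (1 if validation_fraction > 0 else 0)
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label in sorted(original.label.unique()):
        ids = sorted(original.loc[original.label == label, "file_id"].unique())
        if len(ids) < n_splits:
            raise ValueError(
                f"class {label!r} has only {len(ids)} files for {n_splits} splits"
            )
        ids = list(rng.permutation(ids))
        n_train = round(train_fraction * len(ids))
        n_val = round(validation_fraction * len(ids))
        for fid in ids[:n_train]:
            assignment[fid] = "train"
        for fid in ids[n_train:n_train + n_val]:
            assignment[fid] = "validation"
        for fid in ids[n_train + n_val:]:
            assignment[fid] = "test"

    def _resolve(row) -> str:
        if row.provenance == "augmented":
            src = row.source_file_id or row.file_id
            return assignment.get(src, row.split)
        return assignment[row.file_id]

    df["split"] = df.apply(_resolve, axis=1)
    return DatasetCatalog(df)


def split_counts(catalog: DatasetCatalog, provenance: str = "original") -> pd.Series:
    sub = catalog.entries[catalog.entries.provenance == provenance]
    return sub.groupby("split").size()
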