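"""Data model and delimited-text I/O for 1D NMR spectra and feature matrices.

Spectra are stored on a strictly descending ppm axis (standard NMR display
orientation). Readers accept ascending input and reverse it, logging the
conversion. All interchange formats are plain delimited text so that every
artifact in the pipeline is human-inspectable and diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AcquisitionParams",
    "Spectrum1D",
    "FeatureMatrix",
    "ResponseVector",
    "ppm_axis_from_acquisition",
    "read_spectra_table",
    "write_spectra_table",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_labels",
    "response_from_labels",
]


class SpectraIOError(ValueError):
    """Raised on malformed spectral input files or invalid parameters."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition settings needed to reconstruct a chemical-shift axis.

    Defaults correspond to a 1D proton experiment on a 400 MHz instrument
    with a 6200 Hz spectral width, 32K real points and the water
    presaturation carrier at 4.7 ppm.
    """

    n_points: int = 32768
    spectral_width: float = 6200.0  # Hz
    spectrometer_freq: float = 400.0  # MHz
    center_ppm: float = 4.7

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise SpectraIOError(f"n_points must be >= 2, got {self.n_points}")
        if self.spectral_width <= 0:
            raise SpectraIOError(
                f"spectral_width must be > 0 Hz, got {self.spectral_width}"
            )
        if self.spectrometer_freq <= 0:
            raise SpectraIOError(
                f"spectrometer_freq must be > 0 MHz, got {self.spectrometer_freq}"
            )


@dataclass
class Spectrum1D:
    """One sample's intensity trace on a shared ppm axis.

    The axis must be strictly monotone; internally it is always held
    descending (high ppm first).
    """

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise SpectraIOError("ppm and intensity must be 1-D arrays")
        if self.ppm.size != self.intensity.size:
            raise SpectraIOError(
                f"{self.sample_id}: ppm length {self.ppm.size} != "
                f"intensity length {self.intensity.size}"
            )
        d = np.diff(self.ppm)
        if np.all(d < 0):
            pass  # canonical descending
        elif np.all(d > 0):
            logger.info("spectrum %s: ascending ppm axis reversed", self.sample_id)
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        else:
            raise SpectraIOError(f"{self.sample_id}: ppm axis is not strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise SpectraIOError(f"{self.sample_id}: non-finite intensity values")

    def copy(self) -> "Spectrum1D":
        return Spectrum1D(self.sample_id, self.ppm.copy(), self.intensity.copy())


@dataclass
class FeatureMatrix:
    """n samples x m bins of summed intensities — the predictor matrix X."""

    sample_ids: list[str]
    bin_centers: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise SpectraIOError("sample_ids length does not match row count")
        if self.bin_centers.size != m:
            raise SpectraIOError("bin_centers length does not match column count")
        if n < 2 or m < 2:
            raise SpectraIOError(f"feature matrix needs n >= 2 and m >= 2, got {n}x{m}")
        d = np.diff(self.bin_centers)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise SpectraIOError("bin_centers must be strictly monotone")
        if not np.all(np.isfinite(self.values)):
            raise SpectraIOError("feature matrix contains non-finite values")
        if len(set(self.sample_ids)) != n:
            raise SpectraIOError("duplicate sample ids in feature matrix")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def subset(self, ids: Sequence[str]) -> "FeatureMatrix":
        """Row subset in the order of ``ids``."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise SpectraIOError(f"sample ids not in matrix: {missing}")
        rows = [index[s] for s in ids]
        return FeatureMatrix(list(ids), self.bin_centers.copy(), self.values[rows])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.bin_centers
        )


@dataclass
class ResponseVector:
    """Per-sample response: 0/1 class code or a continuous value (months)."""

    sample_ids: list[str]
    values: np.ndarray
    kind: str = "class"  # "class" (0 = benign, 1 = malignant) or "continuous"

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.sample_ids):
            raise SpectraIOError("response length does not match sample ids")
        if self.kind not in ("class", "continuous"):
            raise SpectraIOError(f"unknown response kind {self.kind!r}")
        if self.kind == "class" and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise SpectraIOError("class responses must be coded 0 (benign) / 1 (malignant)")


def ppm_axis_from_acquisition(params: AcquisitionParams) -> np.ndarray:
    """Uniform descending ppm axis implied by the acquisition parameters.

    The axis spans ``spectral_width / spectrometer_freq`` ppm, is centred on
    ``center_ppm`` (the presaturation carrier) and has ``n_points`` entries,
    high ppm first.
    """
    span = params.spectral_width / params.spectrometer_freq
    high = params.center_ppm + span / 2.0
    low = params.center_ppm - span / 2.0
    return np.linspace(high, low, params.n_points)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_spectra_table(path: str | Path, dialect: str = "wide") -> list[Spectrum1D]:
    """Read spectra from delimited text.

    ``wide``: first column is ppm, each remaining column one sample.
    ``long``: columns sample_id, ppm, intensity.
    """
    path = Path(path)
    if not path.exists():
        raise SpectraIOError(f"no such file: {path}")
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    df = pd.read_csv(path, sep=sep)
    if dialect == "wide":
        if df.shape[1] < 2:
            raise SpectraIOError(f"{path}: wide table needs ppm + >= 1 sample column")
        if len(set(header[1:])) != len(header[1:]):
            raise SpectraIOError(f"{path}: duplicate sample ids in header")
        bad = np.argwhere(df.isna().to_numpy())
        if bad.size:
            r, c = bad[0]
            raise SpectraIOError(
                f"{path}: non-numeric/missing cell at row {r + 2}, column "
                f"{df.columns[c]!r}"
            )
        ids = list(df.columns[1:])
        if len(set(ids)) != len(ids):
            raise SpectraIOError(f"{path}: duplicate sample ids in header")
        ppm = df.iloc[:, 0].to_numpy(dtype=float)
        return [
            Spectrum1D(sid, ppm, df[sid].to_numpy(dtype=float)) for sid in ids
        ]
    if dialect == "long":
        need = {"sample_id", "ppm", "intensity"}
        if not need.issubset(df.columns):
            raise SpectraIOError(f"{path}: long table needs columns {sorted(need)}")
        if df[["ppm", "intensity"]].isna().any().any():
            raise SpectraIOError(f"{path}: missing ppm/intensity values")
        out = []
        for sid, grp in df.groupby("sample_id", sort=False):
            out.append(
                Spectrum1D(
                    str(sid),
                    grp["ppm"].to_numpy(dtype=float),
                    grp["intensity"].to_numpy(dtype=float),
                )
            )
        return out
    raise SpectraIOError(f"unknown dialect {dialect!r}")


def write_spectra_table(
    spectra: Iterable[Spectrum1D], path: str | Path, dialect: str = "wide"
) -> None:
    """Write spectra as delimited text (inverse of :func:`read_spectra_table`)."""
    spectra = list(spectra)
    path = Path(path)
    sep = _sep_for(path)
    if dialect == "wide":
        axis = spectra[0].ppm
        for s in spectra[1:]:
            if s.ppm.shape != axis.shape or not np.allclose(s.ppm, axis):
                raise SpectraIOError("wide layout requires a shared ppm axis")
        df = pd.DataFrame({"ppm": axis})
        for s in spectra:
            df[s.sample_id] = s.intensity
        df.to_csv(path, sep=sep, index=False, float_format="%.10g")
    elif dialect == "long":
        frames = [
            pd.DataFrame(
                {"sample_id": s.sample_id, "ppm": s.ppm, "intensity": s.intensity}
            )
            for s in spectra
        ]
        pd.concat(frames, ignore_index=True).to_csv(
            path, sep=sep, index=False, float_format="%.10g"
        )
    else:
        raise SpectraIOError(f"unknown dialect {dialect!r}")


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """CSV with a sample_id column and one header entry per bin centre.

    Bin centres are written with 10 significant digits so adjacent 0.04-ppm
    bins never collide on re-read.
    """
    path = Path(path)
    header = ["sample_id"] + [f"{c:.10g}" for c in fm.bin_centers]
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for sid, row in zip(fm.sample_ids, fm.values):
            fh.write(sid + "," + ",".join(f"{v:.10g}" for v in row) + "\n")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    if not path.exists():
        raise SpectraIOError(f"no such file: {path}")
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise SpectraIOError(f"{path}: first column must be 'sample_id'")
    try:
        centers = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise SpectraIOError(f"{path}: non-numeric bin centre in header") from exc
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if values.shape[1] != centers.size:
        raise SpectraIOError(f"{path}: header width does not match data width")
    if np.isnan(values).any():
        raise SpectraIOError(f"{path}: missing values in feature matrix")
    return FeatureMatrix(list(df["sample_id"].astype(str)), centers, values)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Label table: sample_id, class in {benign, malignant}, optional
    months_since_extraction."""
    path = Path(path)
    if not path.exists():
        raise SpectraIOError(f"no such file: {path}")
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "class" not in df.columns:
        raise SpectraIOError(f"{path}: label table needs sample_id and class columns")
    bad = set(df["class"].unique()) - {"benign", "malignant"}
    if bad:
        raise SpectraIOError(f"{path}: unknown class labels {sorted(bad)}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def response_from_labels(
    labels: pd.DataFrame, sample_ids: Sequence[str], kind: str = "class"
) -> ResponseVector:
    """Build a ResponseVector aligned row-for-row with ``sample_ids``."""
    table = labels.set_index("sample_id")
    missing = [s for s in sample_ids if s not in table.index]
    if missing:
        raise SpectraIOError(f"labels missing for samples: {missing}")
    if kind == "class":
        vals = [1.0 if table.loc[s, "class"] == "malignant" else 0.0 for s in sample_ids]
    elif kind == "continuous":
        if "months_since_extraction" not in table.columns:
            raise SpectraIOError("label table lacks months_since_extraction")
        vals = [float(table.loc[s, "months_since_extraction"]) for s in sample_ids]
    else:
        raise SpectraIOError(f"unknown response kind {kind!r}")
    return ResponseVector(list(sample_ids), np.asarray(vals), kind=kind)
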