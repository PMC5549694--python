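"""Spectral standardization: alignment, binning, normalization, baseline.

The fixed pipeline order is align -> bin -> normalize. Alignment operates on
full-resolution spectra against a reference (median by default); binning sums
intensities into fixed-width ppm buckets laid from the high edge of the
window downward; probabilistic quotient normalization (PQN) removes
per-sample dilution against a median reference spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra_io import FeatureMatrix, Spectrum1D

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "AlignmentReport",
    "rspa_align",
    "bin_spectrum",
    "bin_spectra",
    "pqn_normalize",
    "baseline_correct",
    "median_reference_spectrum",
]


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    """Tunables for the standardization pipeline.

    ``ppm_window`` is ``(low, high)`` in ppm; ``None`` means the full axis of
    the first spectrum. ``bin_statistic`` is ``"sum"`` (canonical) or
    ``"mean"``.
    """

    bin_width: float = 0.04
    ppm_window: tuple[float, float] | None = None
    exclude_regions: tuple[tuple[float, float], ...] = ()
    pqn_enabled: bool = True
    pqn_prenormalize_area: float | None = 100.0
    rspa_max_shift: int = 10
    rspa_min_segment: int = 50
    rspa_corr_gain_min: float = 0.01
    baseline_enabled: bool = False
    baseline_degree: int = 2
    bin_statistic: str = "sum"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise PreprocessError(f"bin_width must be > 0, got {self.bin_width}")
        if self.ppm_window is not None and self.ppm_window[0] >= self.ppm_window[1]:
            raise PreprocessError("ppm_window must be (low, high) with low < high")
        if self.rspa_max_shift < 0:
            raise PreprocessError("rspa_max_shift must be >= 0")
        if self.rspa_min_segment < 3:
            raise PreprocessError("rspa_min_segment must be >= 3")
        if self.bin_statistic not in ("sum", "mean"):
            raise PreprocessError(f"unknown bin_statistic {self.bin_statistic!r}")


@dataclass
class AlignmentReport:
    """Audit trail of every segment shift applied during alignment."""

    records: list[dict] = field(default_factory=list)

    def add(self, **kw) -> None:
        self.records.append(kw)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def shifts_for(self, sample_id: str) -> list[int]:
        return [r["shift"] for r in self.records if r["sample_id"] == sample_id]


# ---------------------------------------------------------------------------
# recursive segment-wise peak alignment
# ---------------------------------------------------------------------------


def shift_segment(x: np.ndarray, shift: int) -> np.ndarray:
    """Shift values by ``shift`` index positions; vacated edge points are
    filled by repeating the boundary value."""
    if shift == 0:
        return x.copy()
    out = np.empty_like(x)
    if shift > 0:
        out[shift:] = x[:-shift]
        out[:shift] = x[0]
    else:
        out[:shift] = x[-shift:]
        out[shift:] = x[-1]
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.dot(a - a.mean(), b - b.mean()) / (a.size * sa * sb))


def _best_shift(x: np.ndarray, ref: np.ndarray, max_shift: int) -> tuple[int, float, float]:
    """Integer shift in [-max_shift, max_shift] maximizing Pearson correlation
    with the reference; ties break to the smaller |shift|."""
    corr0 = _pearson(x, ref)
    best_shift, best_corr = 0, corr0
    for mag in range(1, max_shift + 1):
        for s in (mag, -mag):
            c = _pearson(shift_segment(x, s), ref)
            if c > best_corr:
                best_shift, best_corr = s, c
    return best_shift, corr0, best_corr


def _split_point(ref_seg: np.ndarray) -> int:
    """Index (within segment) of the minimum-intensity interior point of the
    middle third of the reference segment."""
    n = ref_seg.size
    lo, hi = n // 3, max(n // 3 + 1, 2 * n // 3)
    lo = max(lo, 1)
    hi = min(hi, n - 1)
    return lo + int(np.argmin(ref_seg[lo:hi]))


def _align_recursive(
    x: np.ndarray,
    ref: np.ndarray,
    ppm: np.ndarray,
    lo: int,
    hi: int,
    cfg: PreprocessConfig,
    report: AlignmentReport,
    sample_id: str,
) -> None:
    seg_len = hi - lo
    if seg_len < cfg.rspa_min_segment or cfg.rspa_max_shift >= seg_len:
        return
    shift, corr_before, corr_after = _best_shift(
        x[lo:hi], ref[lo:hi], cfg.rspa_max_shift
    )
    # gain is judged relative to the remaining decorrelation: a 1%-of-residual
    # improvement counts even when the segment already correlates at 0.999
    gain = (corr_after - corr_before) / max(1.0 - corr_before, 1e-12)
    if gain < cfg.rspa_corr_gain_min:
        # below threshold: leave segment unshifted, stop recursing here
        report.add(
            sample_id=sample_id,
            ppm_high=float(ppm[lo]),
            ppm_low=float(ppm[hi - 1]),
            shift=0,
            corr_before=corr_before,
            corr_after=corr_before,
            accepted=False,
            intensity_change=0.0,
        )
        return
    before_total = float(np.abs(x[lo:hi]).sum())
    x[lo:hi] = shift_segment(x[lo:hi], shift)
    report.add(
        sample_id=sample_id,
        ppm_high=float(ppm[lo]),
        ppm_low=float(ppm[hi - 1]),
        shift=int(shift),
        corr_before=corr_before,
        corr_after=corr_after,
        accepted=True,
        intensity_change=float(np.abs(x[lo:hi]).sum()) - before_total,
    )
    mid = lo + _split_point(ref[lo:hi])
    _align_recursive(x, ref, ppm, lo, mid, cfg, report, sample_id)
    _align_recursive(x, ref, ppm, mid, hi, cfg, report, sample_id)


def residual_shift(s: Spectrum1D, reference: Spectrum1D, max_shift: int = 10) -> int:
    """Whole-spectrum lag (points) that best cross-correlates with the
    reference — a noise-robust measure of remaining misalignment."""
    shift, _, _ = _best_shift(s.intensity, reference.intensity, max_shift)
    return -shift  # positive = spectrum displaced toward lower index


def median_reference_spectrum(spectra: Sequence[Spectrum1D]) -> Spectrum1D:
    """Element-wise median spectrum of a cohort sharing one axis."""
    axis = spectra[0].ppm
    stack = np.vstack([s.intensity for s in spectra])
    return Spectrum1D("__median__", axis.copy(), np.median(stack, axis=0))


def rspa_align(
    spectra: Sequence[Spectrum1D],
    reference: Spectrum1D | str = "median",
    cfg: PreprocessConfig | None = None,
) -> tuple[list[Spectrum1D], AlignmentReport]:
    """Recursive segment-wise peak alignment against a reference spectrum.

    Each segment is shifted by the integer offset (bounded by
    ``rspa_max_shift``) that maximizes Pearson correlation with the
    reference; if the correlation gain reaches ``rspa_corr_gain_min`` the
    shift is applied and the segment is split at the minimum-intensity
    interior point of its middle third (on the reference) and both halves are
    aligned recursively. Vacated edge points are filled by boundary-value
    repetition.
    """
    cfg = cfg or PreprocessConfig()
    spectra = list(spectra)
    if not spectra:
        raise PreprocessError("no spectra to align")
    axis = spectra[0].ppm
    for s in spectra:
        if s.ppm.shape != axis.shape or not np.allclose(s.ppm, axis):
            raise PreprocessError(f"spectrum {s.sample_id} not on the shared axis")
    if isinstance(reference, str):
        if reference != "median":
            raise PreprocessError(f"unknown reference {reference!r}")
        reference = median_reference_spectrum(spectra)
    elif reference.ppm.shape != axis.shape or not np.allclose(reference.ppm, axis):
        raise PreprocessError("reference not on the shared axis")
    if cfg.rspa_max_shift >= axis.size:
        raise PreprocessError(
            f"rspa_max_shift {cfg.rspa_max_shift} >= spectrum length {axis.size}"
        )
    report = AlignmentReport()
    aligned = []
    for s in spectra:
        x = s.intensity.copy()
        _align_recursive(
            x, reference.intensity, axis, 0, axis.size, cfg, report, s.sample_id
        )
        aligned.append(Spectrum1D(s.sample_id, axis.copy(), x))
    return aligned, report


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def bin_spectrum(
    s: Spectrum1D, cfg: PreprocessConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Bucket a spectrum into fixed-width ppm bins.

    The grid is anchored at the high edge of the window and laid downward in
    ``bin_width`` steps; each bin sums the intensities of points whose ppm
    falls in ``[centre - w/2, centre + w/2)``; a trailing partial bin is
    dropped. Excluded regions are removed after binning (a bin is dropped
    when its centre lies inside an excluded ``[low, high]``). Returns
    ``(values, bin_centers)`` with centres descending.
    """
    ppm = s.ppm
    if cfg.ppm_window is None:
        low, high = float(ppm.min()), float(ppm.max())
    else:
        low, high = cfg.ppm_window
        tol = 1e-9
        if high > ppm.max() + tol or low < ppm.min() - tol:
            raise PreprocessError(
                f"window ({low}, {high}) outside spectrum axis "
                f"({ppm.min():.4f}, {ppm.max():.4f})"
            )
    w = cfg.bin_width
    m = int(np.floor((high - low) / w + 1e-9))
    if m < 1:
        raise PreprocessError("window narrower than one bin")
    # bin index by distance below the high edge; bin i covers
    # [high - (i+1)w, high - i*w)
    idx = np.floor((high - ppm) / w - 1e-9).astype(int)
    idx[np.isclose(ppm, high)] = 0
    valid = (idx >= 0) & (idx < m)
    values = np.bincount(idx[valid], weights=s.intensity[valid], minlength=m)
    if cfg.bin_statistic == "mean":
        counts = np.bincount(idx[valid], minlength=m)
        values = np.divide(values, counts, out=np.zeros(m), where=counts > 0)
    centers = high - (np.arange(m) + 0.5) * w
    if cfg.exclude_regions:
        keep = np.ones(m, dtype=bool)
        for lo_ex, hi_ex in cfg.exclude_regions:
            keep &= ~((centers >= lo_ex) & (centers <= hi_ex))
        values, centers = values[keep], centers[keep]
    return values, centers


def bin_spectra(spectra: Sequence[Spectrum1D], cfg: PreprocessConfig) -> FeatureMatrix:
    """Bin a cohort sharing one axis into a FeatureMatrix."""
    rows, centers = [], None
    for s in spectra:
        v, c = bin_spectrum(s, cfg)
        if centers is None:
            centers = c
        elif not np.allclose(c, centers):
            raise PreprocessError("inconsistent bin grids across spectra")
        rows.append(v)
    return FeatureMatrix([s.sample_id for s in spectra], centers, np.vstack(rows))


# ---------------------------------------------------------------------------
# probabilistic quotient normalization
# ---------------------------------------------------------------------------


def pqn_normalize(
    fm: FeatureMatrix,
    cfg: PreprocessConfig | None = None,
    reference: np.ndarray | None = None,
) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Probabilistic quotient normalization (Dieterle-style).

    1. clip negative bin values to 0 (count logged);
    2. scale every spectrum to total area ``pqn_prenormalize_area`` (skipped
       when that field is None/0);
    3. reference = element-wise median spectrum of the cohort, unless a
       training-derived ``reference`` is supplied (leakage-safe test-set use);
    4. per-sample quotients x_j / ref_j over bins with ref_j > 0, dilution
       factor d = median quotient, sample divided by d.

    Returns ``(normalized matrix, dilution factors, reference)`` where the
    dilution factor is the total divisor applied to the raw row (area factor
    x quotient median), i.e. ``x_norm = x_raw / d`` exactly.
    """
    cfg = cfg or PreprocessConfig()
    X = fm.values.copy()
    n_neg = int((X < 0).sum())
    if n_neg:
        logger.info("pqn: clipped %d negative bin values to 0", n_neg)
        X = np.clip(X, 0.0, None)
    areas = X.sum(axis=1)
    zero = np.where(areas <= 0)[0]
    if zero.size:
        raise PreprocessError(
            f"sample(s) with zero total area: {[fm.sample_ids[i] for i in zero]}"
        )
    area_factor = np.ones(fm.n_samples)
    if cfg.pqn_prenormalize_area:
        area_factor = areas / cfg.pqn_prenormalize_area
        X = X / area_factor[:, None]
    if reference is None:
        reference = np.median(X, axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.size != fm.n_bins:
        raise PreprocessError("reference length does not match bin count")
    mask = reference > 0
    if not mask.any():
        raise PreprocessError("PQN reference spectrum is all zero")
    quotients = X[:, mask] / reference[mask]
    d_quot = np.median(quotients, axis=1)
    if np.any(d_quot <= 0):
        bad = [fm.sample_ids[i] for i in np.where(d_quot <= 0)[0]]
        raise PreprocessError(f"non-positive PQN quotient median for {bad}")
    X = X / d_quot[:, None]
    dilution = area_factor * d_quot
    return (
        FeatureMatrix(list(fm.sample_ids), fm.bin_centers.copy(), X),
        dilution,
        reference,
    )


# ---------------------------------------------------------------------------
# baseline (automated stand-in for a manual step; plumbing)
# ---------------------------------------------------------------------------


def baseline_correct(s: Spectrum1D, degree: int = 2, n_iter: int = 100) -> Spectrum1D:
    """Iterative polynomial baseline subtraction (modified-polyfit scheme).

    A polynomial of the given degree is fitted repeatedly, each pass clipping
    the working trace to the current fit so that peaks are progressively
    excluded and only low-intensity baseline points constrain the fit.
    """
    if not 0 <= degree <= 5:
        raise PreprocessError(f"baseline degree must be in 0..5, got {degree}")
    x = np.linspace(-1.0, 1.0, s.ppm.size)  # scaled abscissa for conditioning
    work = s.intensity.astype(float).copy()
    base = np.zeros_like(work)
    for _ in range(n_iter):
        coeffs = np.polynomial.polynomial.polyfit(x, work, degree)
        base = np.polynomial.polynomial.polyval(x, coeffs)
        new_work = np.minimum(work, base)
        if np.allclose(new_work, work, rtol=0, atol=1e-12):
            work = new_work
            break
        work = new_work
    return Spectrum1D(s.sample_id, s.ppm.copy(), s.intensity - base)
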