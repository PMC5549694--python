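"""Synthetic 1D proton-NMR lymph-node cohorts for pipeline benchmarking.

Each spectrum is a sum of Lorentzian/Gaussian resonances on an acquisition-
derived ppm axis. The cohort structure mirrors a two-phase tissue study:
45 training samples (20 benign, 25 malignant) and a 24-sample blinded test
cohort (11 benign, 13 malignant). The dominant feature is a composite
lipid/lactate envelope at 1-1.5 ppm; the class signal is a single resonance
at 3.8 ppm, elevated in benign tissue. On top of that the generator injects
class-independent nuisance variation (a shared latent factor scaling a
subset of peaks), per-sample dilution, small integer chemical-shift jitter,
and additive Gaussian noise — the imperfections the preprocessing stages
exist to remove.

Every sample draws from its own RNG stream keyed by (seed, sample index), so
changing cohort sizes never silently re-randomizes other samples. Tissue
ages (months since extraction, 1-80) are drawn independently of the spectra
unless the age-effect positive control is enabled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra_io import (
    AcquisitionParams,
    Spectrum1D,
    ppm_axis_from_acquisition,
    write_spectra_table,
)
from .preprocess import shift_segment

__all__ = ["Peak", "SyntheticConfig", "Cohort", "simulate_spectrum",
           "generate_cohort", "default_benchmark", "DEFAULT_BENCHMARK_SEED"]

DEFAULT_BENCHMARK_SEED = 1234


@dataclass(frozen=True)
class Peak:
    """One resonance: centre (ppm), half-width-at-half-max-like width (ppm),
    lineshape, mean apex amplitude (a.u.), log-normal amplitude CV, and a
    role tag (base / marker / nuisance / age)."""

    center: float
    width: float
    shape: str = "lorentzian"  # or "gaussian"
    amplitude: float = 1.0
    amplitude_cv: float = 0.2
    center_jitter_sd: float = 0.0  # ppm; per-sample chemical-shift wobble
    role: str = "base"

    def profile(self, ppm: np.ndarray, center: float | None = None) -> np.ndarray:
        d = (ppm - (self.center if center is None else center)) / self.width
        if self.shape == "lorentzian":
            return 1.0 / (1.0 + d * d)
        if self.shape == "gaussian":
            return np.exp(-0.5 * d * d)
        raise ValueError(f"unknown lineshape {self.shape!r}")


def default_peak_library() -> tuple[Peak, ...]:
    """Twelve-plus resonances loosely evocative of tissue extracts.

    Only two features are fidelity claims: the 1.0-1.5 ppm lipid/lactate
    envelope dominates every spectrum, and the 3.8 ppm marker carries the
    benign/malignant contrast. Everything else is invented filler placed
    across 0.8-8.5 ppm with plausible relative amplitudes.
    """
    L, G = "lorentzian", "gaussian"
    cv = 0.10  # between-sample amplitude CV for uninformative resonances
    return (
        Peak(0.90, 0.050, L, 30.0, cv),                     # lipid CH3
        Peak(1.05, 0.060, L, 55.0, cv),                     # lipid envelope
        Peak(1.15, 0.080, L, 75.0, cv),
        Peak(1.30, 0.070, L, 100.0, cv),                    # dominant lipid CH2
        Peak(1.33, 0.030, G, 70.0, cv, 0.003),              # lactate CH3 (pH shift)
        Peak(1.45, 0.050, L, 45.0, cv),
        Peak(2.05, 0.050, L, 20.0, cv, role="nuisance"),    # N-acetyl region
        Peak(2.35, 0.040, L, 15.0, cv),
        Peak(3.03, 0.030, G, 18.0, cv, 0.003),              # creatine
        Peak(3.22, 0.030, G, 22.0, cv, role="nuisance"),    # choline
        Peak(3.65, 0.040, G, 10.0, cv),
        # marker: tight biological CV so the 2x class effect dominates it;
        # pH-style position wobble like the other small metabolites
        Peak(3.80, 0.060, G, 18.0, 0.02, 0.004, role="marker"),
        Peak(4.12, 0.035, G, 12.0, cv, 0.003),              # lactate CH (pH shift)
        Peak(5.30, 0.040, L, 8.0, cv),
        Peak(7.10, 0.040, L, 5.0, cv, role="nuisance"),
        Peak(8.20, 0.040, L, 4.0, cv),
    )


@dataclass
class SyntheticConfig:
    """Cohort-level generator settings (defaults are the study conditions)."""

    seed: int = DEFAULT_BENCHMARK_SEED
    n_train_benign: int = 20
    n_train_malignant: int = 25
    n_test_benign: int = 11
    n_test_malignant: int = 13
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    peak_library: tuple[Peak, ...] = field(default_factory=default_peak_library)
    class_effect: float = 2.0          # benign multiplier on the 3.8 ppm marker
    nuisance_factor_sd: float = 1.0    # latent factor strength (log-scale 0.25/unit)
    dilution_lognorm_sd: float = 0.3
    shift_jitter_max: int = 3          # points, whole-spectrum
    noise_sd: float = 0.05             # fraction of median library amplitude
    age_months_range: tuple[int, int] = (1, 80)
    age_effect_amplitude: float = 0.0  # a.u. per month on the 2.70 ppm peak
    age_peak: Peak = field(
        default_factory=lambda: Peak(2.70, 0.040, "gaussian", 0.0, 0.0, role="age")
    )

    def __post_init__(self) -> None:
        for name in ("n_train_benign", "n_train_malignant",
                     "n_test_benign", "n_test_malignant"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(p.width <= 0 for p in self.peak_library):
            raise ValueError("peak widths must be > 0")
        if self.shift_jitter_max < 0:
            raise ValueError("shift_jitter_max must be >= 0")

    def to_json(self) -> str:
        doc = {
            k: v for k, v in self.__dict__.items()
            if k not in ("acquisition", "peak_library", "age_peak")
        }
        doc["acquisition"] = self.acquisition.__dict__.copy()
        doc["peak_library"] = [p.__dict__.copy() for p in self.peak_library]
        doc["age_peak"] = self.age_peak.__dict__.copy()
        return json.dumps(doc, indent=1, sort_keys=True)


NUISANCE_LOG_SCALE = 0.25  # log-amplitude per unit latent factor


def simulate_spectrum(
    cfg: SyntheticConfig,
    class_label: int,
    rng: np.random.Generator,
    age_months: float | None = None,
    sample_id: str = "synthetic",
) -> Spectrum1D:
    """Draw one spectrum (benign: class_label=0, malignant: 1).

    Draw order from ``rng`` is fixed (amplitudes, latent factor, shift,
    dilution, noise) so identical RNG states give identical samples.
    """
    ppm = ppm_axis_from_acquisition(cfg.acquisition)
    intensity = np.zeros_like(ppm)
    # per-peak log-normal amplitude jitter + per-peak chemical-shift wobble
    z = rng.standard_normal(len(cfg.peak_library))
    dc = rng.standard_normal(len(cfg.peak_library))
    latent = rng.standard_normal()  # shared class-independent factor
    nuisance_scale = np.exp(NUISANCE_LOG_SCALE * cfg.nuisance_factor_sd * latent)
    for peak, zi, dci in zip(cfg.peak_library, z, dc):
        amp = peak.amplitude * np.exp(peak.amplitude_cv * zi
                                      - 0.5 * peak.amplitude_cv ** 2)
        if peak.role == "marker" and class_label == 0:
            amp *= cfg.class_effect
        if peak.role == "nuisance":
            amp *= nuisance_scale
        center = peak.center + peak.center_jitter_sd * dci
        intensity += amp * peak.profile(ppm, center)
    if cfg.age_effect_amplitude and age_months is not None:
        intensity += (cfg.age_effect_amplitude * age_months
                      * cfg.age_peak.profile(ppm))
    if cfg.shift_jitter_max > 0:
        shift = int(rng.integers(-cfg.shift_jitter_max, cfg.shift_jitter_max + 1))
    else:
        shift = 0
    if shift:
        intensity = shift_segment(intensity, shift)
    dilution = float(np.exp(cfg.dilution_lognorm_sd * rng.standard_normal())) \
        if cfg.dilution_lognorm_sd > 0 else 1.0
    intensity *= dilution
    if cfg.noise_sd > 0:
        median_amp = float(np.median([p.amplitude for p in cfg.peak_library]))
        intensity = intensity + rng.normal(
            0.0, cfg.noise_sd * median_amp, ppm.size
        )
    spec = Spectrum1D(sample_id, ppm, intensity)
    spec.meta = {"dilution": dilution, "shift": shift, "latent": latent}
    return spec


@dataclass
class Cohort:
    """Generated spectra plus the label table and the study split."""

    spectra: list[Spectrum1D]
    labels: pd.DataFrame  # sample_id, class, months_since_extraction, split
    train_ids: list[str]
    test_ids: list[str]
    config: SyntheticConfig
    truth: pd.DataFrame   # per-sample injected dilution / shift / latent

    def spectra_by_id(self) -> dict[str, Spectrum1D]:
        return {s.sample_id: s for s in self.spectra}


def _roster(cfg: SyntheticConfig) -> list[tuple[str, str, int]]:
    """Deterministic (sample_id, split, class) roster; classes interleaved so
    venetian-blind folds stay balanced."""
    def interleave(nb: int, nm: int) -> list[int]:
        order, b, m = [], nb, nm
        while b or m:
            if b and (not m or b / max(nb, 1) >= m / max(nm, 1)):
                order.append(0); b -= 1
            else:
                order.append(1); m -= 1
        return order
    roster = []
    for i, c in enumerate(interleave(cfg.n_train_benign, cfg.n_train_malignant)):
        roster.append((f"TR{i + 1:02d}", "train", c))
    for i, c in enumerate(interleave(cfg.n_test_benign, cfg.n_test_malignant)):
        roster.append((f"TE{i + 1:02d}", "test", c))
    return roster


def generate_cohort(cfg: SyntheticConfig | None = None) -> Cohort:
    """Generate the full train + blinded-test cohort, reproducibly from seed."""
    cfg = cfg or SyntheticConfig()
    roster = _roster(cfg)
    spectra, rows, truth_rows = [], [], []
    lo, hi = cfg.age_months_range
    for idx, (sid, split, cls) in enumerate(roster):
        rng = np.random.default_rng([cfg.seed, idx])
        age = int(rng.integers(lo, hi + 1))
        spec = simulate_spectrum(cfg, cls, rng, age_months=age, sample_id=sid)
        spectra.append(spec)
        rows.append({
            "sample_id": sid,
            "class": "malignant" if cls == 1 else "benign",
            "months_since_extraction": age,
            "split": split,
        })
        truth_rows.append({"sample_id": sid, **spec.meta})
    labels = pd.DataFrame(rows)
    return Cohort(
        spectra=spectra,
        labels=labels,
        train_ids=[r[0] for r in roster if r[1] == "train"],
        test_ids=[r[0] for r in roster if r[1] == "test"],
        config=cfg,
        truth=pd.DataFrame(truth_rows),
    )


def default_benchmark(
    out_dir: str | Path | None = None, seed: int = DEFAULT_BENCHMARK_SEED
) -> Cohort:
    """The canonical frozen benchmark: default config at the fixed seed.

    When ``out_dir`` is given, writes spectra (wide TSV), labels CSV, the
    injected ground truth CSV and the exact generator config as JSON.
    """
    cohort = generate_cohort(SyntheticConfig(seed=seed))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_spectra_table(cohort.spectra, out / "spectra.tsv", dialect="wide")
        cohort.labels.to_csv(out / "labels.csv", index=False)
        cohort.truth.to_csv(out / "truth.csv", index=False)
        (out / "config.json").write_text(cohort.config.to_json())
    return cohort
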