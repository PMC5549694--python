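"""End-to-end study pipeline: train, blindly predict, and the age control.

The training run fixes every data-dependent constant — the alignment
reference (median training spectrum), the bin grid, the PQN reference and
the centring/scaling constants — so the blinded-test run touches training
statistics only and can never leak test information backwards. The blinded
protocol is enforced by call order: predictions are rendered and hashed into
the run log before the sealed labels are read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .oplsda import (
    DiagnosticResult,
    EvalReport,
    OplsModel,
    classify,
    confusion_metrics,
    cross_validate_q2,
    dmodx,
    fit_opls,
    hotelling_t2,
    predict_opls,
)
from .preprocess import (
    PreprocessConfig,
    baseline_correct,
    bin_spectra,
    pqn_normalize,
    rspa_align,
    median_reference_spectrum,
)
from .spectra_io import FeatureMatrix, ResponseVector, Spectrum1D, response_from_labels

__all__ = ["StudyDesign", "PipelineState", "TrainResult", "RunLog",
           "run_train", "run_blinded_test", "run_age_control"]


class WorkflowError(ValueError):
    pass


#: Analysis window for the study pipeline: the informative proton region.
#: With the 0.04-ppm grid anchored at 9.5, one bin is centred exactly on the
#: 3.8-ppm marker. 225 bins.
DEFAULT_ANALYSIS_WINDOW = (0.5, 9.5)


def default_study_preprocess() -> PreprocessConfig:
    return PreprocessConfig(ppm_window=DEFAULT_ANALYSIS_WINDOW)


@dataclass
class StudyDesign:
    """Which samples train, which are blinded, and the model settings."""

    train_ids: list[str]
    test_ids: list[str]
    n_ortho: int = 3
    scaling_mode: str = "uv"
    cv_folds: int = 7
    preprocess: PreprocessConfig = field(default_factory=default_study_preprocess)

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise WorkflowError(f"train/test overlap: {sorted(overlap)}")


class RunLog:
    """Append-only structured run log (JSON lines)."""

    def __init__(self) -> None:
        self.events: list[dict] = []

    def add(self, event: str, **kw) -> None:
        self.events.append({"event": event, **kw})

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev, sort_keys=True, default=str) + "\n")


@dataclass
class PipelineState:
    """Training-derived constants needed to process new samples."""

    config: PreprocessConfig
    align_reference: Spectrum1D
    pqn_reference: np.ndarray
    bin_centers: np.ndarray
    model: OplsModel


@dataclass
class TrainResult:
    state: PipelineState
    features: FeatureMatrix          # normalized training X
    response: ResponseVector
    report: EvalReport
    diagnostics: DiagnosticResult
    log: RunLog


def _select(spectra: Sequence[Spectrum1D], ids: Sequence[str]) -> list[Spectrum1D]:
    by_id = {s.sample_id: s for s in spectra}
    missing = [s for s in ids if s not in by_id]
    if missing:
        raise WorkflowError(f"spectra missing for samples: {missing}")
    return [by_id[s] for s in ids]


def _preprocess_train(
    spectra: Sequence[Spectrum1D], cfg: PreprocessConfig, log: RunLog
) -> tuple[FeatureMatrix, Spectrum1D, np.ndarray]:
    if cfg.baseline_enabled:
        spectra = [baseline_correct(s, cfg.baseline_degree) for s in spectra]
        log.add("baseline", degree=cfg.baseline_degree,
                note="automated polynomial operator replacing a manual step")
    reference = median_reference_spectrum(list(spectra))
    aligned, align_report = rspa_align(spectra, reference, cfg)
    log.add("align", segments=len(align_report.records),
            reference="median of training cohort")
    fm = bin_spectra(aligned, cfg)
    log.add("bin", bin_width=cfg.bin_width, n_bins=fm.n_bins,
            statistic=cfg.bin_statistic)
    pqn_ref = None
    if cfg.pqn_enabled:
        fm, dilution, pqn_ref = pqn_normalize(fm, cfg)
        log.add("pqn", reference="median of training cohort",
                dilution_range=[float(dilution.min()), float(dilution.max())])
    log.add("pipeline_order", order=["align", "bin", "normalize"])
    return fm, reference, pqn_ref


def _preprocess_test(
    spectra: Sequence[Spectrum1D], state: PipelineState, log: RunLog
) -> FeatureMatrix:
    cfg = state.config
    if cfg.baseline_enabled:
        spectra = [baseline_correct(s, cfg.baseline_degree) for s in spectra]
    aligned, _ = rspa_align(spectra, state.align_reference, cfg)
    fm = bin_spectra(aligned, cfg)
    if not np.allclose(fm.bin_centers, state.bin_centers):
        raise WorkflowError("test bin grid differs from training grid")
    if cfg.pqn_enabled:
        fm, _, _ = pqn_normalize(fm, cfg, reference=state.pqn_reference)
        log.add("pqn_test", reference="training-derived (leakage-safe)")
    return fm


def run_train(
    spectra: Sequence[Spectrum1D],
    labels: pd.DataFrame,
    design: StudyDesign,
    y_kind: str = "class",
) -> TrainResult:
    """Fit the full pipeline on the training cohort.

    Preprocess (alignment/bin/PQN constants fit on training data only), fit
    the O-PLS model with ``design.n_ortho`` orthogonal components, compute
    R2Y, venetian-blind Q2Y, and DModX / Hotelling T2 diagnostics.
    """
    log = RunLog()
    train_spectra = _select(spectra, design.train_ids)
    y = response_from_labels(labels, design.train_ids, kind=y_kind)
    if y_kind == "class" and len(set(y.values)) < 2:
        raise WorkflowError("training set contains a single class")
    if y_kind == "continuous" and np.ptp(y.values) == 0:
        raise WorkflowError("constant continuous response")
    fm, align_ref, pqn_ref = _preprocess_train(train_spectra, design.preprocess, log)
    if pqn_ref is None:
        pqn_ref = np.array([])
    model = fit_opls(fm.values, y.values, design.n_ortho,
                     design.scaling_mode, y_kind)
    report = cross_validate_q2(fm.values, y.values, design.n_ortho,
                               design.cv_folds, design.scaling_mode, y_kind)
    diag = DiagnosticResult()
    diag.dmodx = dmodx(model)
    diag.t2, diag.t2_crit = hotelling_t2(model)
    log.add("fit", n_ortho=design.n_ortho, scaling=design.scaling_mode,
            r2y=report.r2y, q2y=report.q2y, folds=report.folds)
    state = PipelineState(design.preprocess, align_ref, pqn_ref,
                          fm.bin_centers.copy(), model)
    return TrainResult(state, fm, y, report, diag, log)


def run_blinded_test(
    train: TrainResult,
    spectra_test: Sequence[Spectrum1D],
    sealed_labels: pd.DataFrame,
    test_ids: Sequence[str],
) -> tuple[EvalReport, pd.DataFrame]:
    """Predict a blinded cohort, then unseal labels and score the calls.

    The prediction table is rendered and hashed into the run log *before*
    the label table is consulted; the hash pins down what was predicted
    prior to unsealing. Returns the evaluation report and the prediction
    table (t1, y_hat, call per sample).
    """
    log = train.log
    train_set = {s for s in train.features.sample_ids}
    overlap = train_set & set(test_ids)
    if overlap:
        raise WorkflowError(f"test samples overlap training set: {sorted(overlap)}")
    test_spectra = _select(spectra_test, test_ids)
    fm = _preprocess_test(test_spectra, train.state, log)
    t1_new, _, y_hat = predict_opls(train.state.model, fm.values)
    calls = classify(y_hat, train.state.model)
    n_tie = int((np.asarray(y_hat) == 0.5).sum())
    if n_tie:
        log.add("classify_tie", n=n_tie, rule="ties call malignant")
    pred = pd.DataFrame({
        "sample_id": list(test_ids),
        "t1": t1_new,
        "y_hat": y_hat,
        "call": np.where(calls == 1, "malignant", "benign"),
    })
    pred_text = pred.to_csv(index=False, float_format="%.10g")
    log.add("predictions_sealed",
            sha256=hashlib.sha256(pred_text.encode()).hexdigest(),
            n=len(pred))
    # --- labels unsealed only after the hash is recorded ---
    y_true = response_from_labels(sealed_labels, test_ids, kind="class")
    log.add("labels_unsealed", n=len(test_ids))
    confusion, sens, spec = confusion_metrics(y_true.values, calls)
    report = EvalReport(confusion=confusion, sensitivity=sens, specificity=spec)
    log.add("blinded_eval", confusion=list(confusion),
            sensitivity=sens, specificity=spec)
    return report, pred


def run_age_control(
    spectra: Sequence[Spectrum1D],
    labels: pd.DataFrame,
    design: StudyDesign,
) -> dict:
    """Tissue-age control: the same pipeline with continuous y = months since
    extraction, fitted on the training cohort and projected onto the test
    cohort.

    Returns training R2Y/Q2Y and the Pearson correlation between predicted
    and true test-set ages. On cohorts whose ages are independent of the
    spectra, Q2Y should hover at or below zero and the test correlation near
    zero — the control that class separation is not a tissue-decay artifact.
    """
    if len(design.train_ids) < design.cv_folds:
        raise WorkflowError(
            f"need >= {design.cv_folds} training samples for {design.cv_folds}-fold CV"
        )
    train = run_train(spectra, labels, design, y_kind="continuous")
    test_spectra = _select(spectra, design.test_ids)
    fm_test = _preprocess_test(test_spectra, train.state, train.log)
    _, _, age_hat = predict_opls(train.state.model, fm_test.values)
    y_true = response_from_labels(labels, design.test_ids, kind="continuous")
    if np.std(age_hat) == 0 or np.std(y_true.values) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(age_hat, y_true.values)[0, 1])
    return {
        "r2y": train.report.r2y,
        "q2y": train.report.q2y,
        "test_correlation": r,
        "age_hat": age_hat,
        "age_true": y_true.values,
        "log": train.log,
    }
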