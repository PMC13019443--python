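"""Leave-one-subject-out reconstruction of exposed-bone spectra.

The headline pipeline: a PLS2 model maps 6-mm transcutaneous SORS spectra
(soft-tissue dominated) to 3-mm exposed-bone spectra.  Evaluation is
leave-one-subject-out — every spectrum of one subject is held out while a
model is trained on all remaining subjects' rows — so repeated
measurements of the same specimen can never leak between splits.  The
number of latent components is fixed across folds (default 10).

Reconstruction quality is scored by the Pearson correlation between each
predicted spectrum and its measured (or ground-truth) counterpart across
wavenumber points; correlation is affine-invariant, so display
normalization does not affect the reported values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import RankError
from .pls_engine import fit_pls2, predict
from .spectra_io import PairedDataset, Spectrum, normalize_to_band
from .clinical_eval import SubjectRecord

logger = logging.getLogger(__name__)

DEFAULT_COMPONENTS = 10


def spectral_correlation(pred: np.ndarray | Spectrum, ref: np.ndarray | Spectrum) -> float:
    """Pearson correlation between two spectra across wavenumber points.

    Invariant to affine intensity transforms of either argument; raises on
    zero-variance input, where the correlation is undefined.
    """
    a = pred.intensities if isinstance(pred, Spectrum) else np.asarray(pred, float)
    b = ref.intensities if isinstance(ref, Spectrum) else np.asarray(ref, float)
    if a.shape != b.shape:
        raise ValueError("spectra must share an axis")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a zero-variance spectrum")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class ReconstructionResult:
    """Held-out predictions and their correlations for one LOSO run."""

    predictions: np.ndarray          # N × Q, in input row order
    row_correlations: np.ndarray     # N, prediction vs measured bone
    subjects: list[str]
    per_subject: dict[str, float]    # mean held-out correlation per subject
    A: int

    def per_class(self, classes: dict[str, str]) -> dict[str, float]:
        """Mean per-subject correlation within each WHO class."""
        out: dict[str, list[float]] = {}
        for sid, c in self.per_subject.items():
            out.setdefault(classes[sid], []).append(c)
        return {k: float(np.mean(v)) for k, v in out.items()}


def loso_reconstruct(
    data: PairedDataset, A: int = DEFAULT_COMPONENTS
) -> ReconstructionResult:
    """Reconstruct every subject's bone spectra from held-out models.

    One PLS2 model per subject, trained on all other subjects' rows with a
    fixed number of latent components; predictions are assembled in input
    row order.  Deterministic: identical inputs give bit-identical output.
    """
    subjects = np.asarray(data.subjects)
    uniq = list(dict.fromkeys(data.subjects))
    if len(uniq) < 3:
        raise ValueError("need at least 3 subjects for LOSO")
    preds = np.empty_like(data.Y)
    for sid in uniq:
        test = subjects == sid
        if not test.any():
            warnings.warn(f"subject {sid} has zero rows; skipped")
            continue
        train = ~test
        n_train = int(train.sum())
        if A > min(n_train - 1, data.X.shape[1]):
            raise RankError(
                f"A={A} infeasible for training split of {n_train} rows"
            )
        model = fit_pls2(data.X[train], data.Y[train], A)
        preds[test] = predict(model, data.X[test])
    row_corr = np.array(
        [spectral_correlation(p, y) for p, y in zip(preds, data.Y)]
    )
    per_subject = {
        sid: float(row_corr[subjects == sid].mean()) for sid in uniq
    }
    return ReconstructionResult(
        predictions=preds,
        row_correlations=row_corr,
        subjects=list(data.subjects),
        per_subject=per_subject,
        A=A,
    )


def class_average_spectra(
    result: ReconstructionResult,
    data: PairedDataset,
    records: list[SubjectRecord],
    normalize_window: tuple[float, float] | None = None,
) -> dict[str, np.ndarray]:
    """Class-mean reconstructed spectra, subject means first.

    Each subject contributes one mean spectrum (over its rows) before the
    class average, so subjects with more sites do not dominate.  With
    ``normalize_window`` each class mean is scaled to unit maximum inside
    that window (phosphate-band normalization for display).  Empty classes
    are omitted with a warning.
    """
    classes = {r.subject_id: r.who_class for r in records}
    missing = set(result.subjects) - set(classes)
    if missing:
        raise ValueError(f"subjects without a WHO class: {sorted(missing)}")
    subjects = np.asarray(result.subjects)
    subj_means: dict[str, np.ndarray] = {
        sid: result.predictions[subjects == sid].mean(axis=0)
        for sid in dict.fromkeys(result.subjects)
    }
    by_class: dict[str, list[np.ndarray]] = {}
    for sid, spec in subj_means.items():
        by_class.setdefault(classes[sid], []).append(spec)
    out: dict[str, np.ndarray] = {}
    for cls in ("Normal", "Osteopenia", "Osteoporosis"):
        if cls not in by_class:
            warnings.warn(f"class {cls} has no subjects; omitted")
            continue
        mean = np.mean(by_class[cls], axis=0)
        if normalize_window is not None:
            from .spectra_io import AcquisitionMeta, Spectrum as _S
            s = _S(data.axis, mean, AcquisitionMeta(subject_id=f"mean_{cls}"))
            s, _ = normalize_to_band(s, normalize_window)
            mean = s.intensities
        out[cls] = mean
    return out
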