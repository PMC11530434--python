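"""Evaluation metrics for estimated signature exposures.

All metrics compare an estimated exposure matrix against the ground
truth, aligned on the union of their signature sets (absent entries count
as zero weight) and on identical sample ids.  Per-sample quantities are
averaged over samples.

* **fitting error** — half the total absolute difference between true and
  estimated relative weights of a sample; 0 for a perfect estimate, 1 when
  the full estimated mass sits on inactive signatures.
* **false-positive weight** — total estimated weight on signatures that
  are truly inactive in the sample.
* **precision / sensitivity / F1** — binary classification of signatures
  as active (weight > 0) vs inactive, per sample, then averaged.
* **Pearson agreement** — per-sample correlation between true and
  estimated weights over the support union, computed only for samples
  where at least three signatures are active in either vector.
* **FP decomposition** — false-positive weight split into *relevant*
  (signatures active somewhere in the cohort) and *irrelevant*
  (signatures inactive cohort-wide) components.
* **consensus truth / disagreement** — utilities for building a consensus
  ground truth from several tools' estimates and for quantifying how much
  two tools differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalogs import ExposureMatrix

__all__ = [
    "MetricReport",
    "align",
    "fitting_error",
    "false_positive_weight",
    "classification_metrics",
    "pearson_agreement",
    "fp_decomposition",
    "consensus_truth",
    "method_disagreement",
    "pairwise_mean_disagreement",
    "evaluate",
]


@dataclass(frozen=True)
class MetricReport:
    """The full metric suite for one (cohort, method) pair."""

    fitting_error: float
    false_positive_weight: float
    precision: float
    sensitivity: float
    f1: float
    pearson_agreement: float  # NaN when no sample qualifies
    n_samples: int
    n_samples_precision: int  # samples with at least one predicted signature
    n_samples_pearson: int  # samples entering the correlation average

    def to_dict(self) -> dict:
        return {
            "fitting_error": self.fitting_error,
            "false_positive_weight": self.false_positive_weight,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "f1": self.f1,
            "pearson_agreement": self.pearson_agreement,
            "n_samples": self.n_samples,
            "n_samples_precision": self.n_samples_precision,
            "n_samples_pearson": self.n_samples_pearson,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def align(
    truth: ExposureMatrix, est: ExposureMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align two exposure matrices on the signature union and common samples.

    Raises if the sample sets differ; missing signatures are filled with 0.
    """
    mismatch = set(truth.sample_ids) ^ set(est.sample_ids)
    if mismatch:
        raise ValueError(f"sample ids differ between truth and estimate: {sorted(mismatch)}")
    sigs = sorted(set(truth.signature_names) | set(est.signature_names))
    samples = truth.sample_ids
    T = truth.weights.reindex(index=sigs, columns=samples, fill_value=0.0).fillna(0.0)
    E = est.weights.reindex(index=sigs, columns=samples, fill_value=0.0).fillna(0.0)
    return T, E


def fitting_error(truth: ExposureMatrix, est: ExposureMatrix) -> float:
    """Mean over samples of half the total absolute weight difference."""
    T, E = align(truth, est)
    return float(((T - E).abs().sum(axis=0) / 2.0).mean())


def false_positive_weight(truth: ExposureMatrix, est: ExposureMatrix) -> float:
    """Mean estimated weight assigned to truly inactive signatures."""
    T, E = align(truth, est)
    return float(E.where(T == 0, 0.0).sum(axis=0).mean())


def classification_metrics(
    truth: ExposureMatrix, est: ExposureMatrix
) -> tuple[float, float, float, int, int]:
    """Per-sample precision, sensitivity and F1, averaged over samples.

    A signature is classified active when its weight is strictly positive.
    Samples with no predicted signatures have undefined precision; they
    are excluded from the precision average (their count is returned) and
    contribute F1 = 0 when the truth is non-empty.

    Returns ``(precision, sensitivity, f1, n_samples, n_samples_precision)``.
    """
    T, E = align(truth, est)
    precisions, sensitivities, f1s = [], [], []
    for sid in T.columns:
        t, e = T[sid] > 0, E[sid] > 0
        tp = int((t & e).sum())
        fp = int((~t & e).sum())
        fn = int((t & ~e).sum())
        if tp + fp > 0:
            prec = tp / (tp + fp)
            precisions.append(prec)
        else:
            prec = None
        sens = tp / (tp + fn) if tp + fn > 0 else 1.0
        sensitivities.append(sens)
        if prec is None or prec + sens == 0:
            f1s.append(0.0)
        else:
            f1s.append(2 * prec * sens / (prec + sens))
    n = len(T.columns)
    precision = float(np.mean(precisions)) if precisions else float("nan")
    return (
        precision,
        float(np.mean(sensitivities)),
        float(np.mean(f1s)),
        n,
        len(precisions),
    )


def pearson_agreement(
    truth: ExposureMatrix, est: ExposureMatrix
) -> tuple[float, int]:
    """Mean per-sample Pearson r between true and estimated weights.

    Only samples where at least three signatures are positive in either
    vector qualify; within a qualifying sample the correlation is computed
    over the support union (signatures zero in both are excluded).  Samples
    where the correlation is undefined (a constant vector) are skipped.
    Returns ``(mean_r, n_samples_used)``; ``mean_r`` is NaN when no sample
    qualifies.
    """
    T, E = align(truth, est)
    rs = []
    for sid in T.columns:
        support = (T[sid] > 0) | (E[sid] > 0)
        if int(support.sum()) < 3:
            continue
        t = T.loc[support, sid].to_numpy()
        e = E.loc[support, sid].to_numpy()
        if np.ptp(t) == 0 or np.ptp(e) == 0:
            continue
        rs.append(float(np.corrcoef(t, e)[0, 1]))
    return (float(np.mean(rs)) if rs else float("nan"), len(rs))


def fp_decomposition(
    truth: ExposureMatrix, est: ExposureMatrix
) -> tuple[float, float]:
    """Split misassigned weight into relevant and irrelevant false positives.

    The cohort support is the union of all samples' true supports.
    Per sample, *irrelevant* FP weight goes to signatures outside the
    cohort support; *relevant* FP weight is the weight on cohort-active
    signatures that are inactive in this sample, plus any positive excess
    ``max(w~ - w, 0)`` on the sample's own active signatures.  Both terms
    are averaged over samples and returned as ``(relevant, irrelevant)``.
    """
    T, E = align(truth, est)
    cohort_support = T.index[(T > 0).any(axis=1)]
    in_cohort = T.index.isin(cohort_support)
    relevant, irrelevant = [], []
    for sid in T.columns:
        t, e = T[sid], E[sid]
        irrelevant.append(float(e[~in_cohort].sum()))
        inactive_here = in_cohort & (t == 0).to_numpy()
        excess = (e - t).clip(lower=0.0)[in_cohort & (t > 0).to_numpy()]
        relevant.append(float(e[inactive_here].sum() + excess.sum()))
    return float(np.mean(relevant)), float(np.mean(irrelevant))


def consensus_truth(estimates: Sequence[ExposureMatrix]) -> ExposureMatrix:
    """Consensus ground truth from several tools' estimates.

    Per sample and signature: weights found active by fewer than two
    estimates are zeroed; otherwise the mean of the *positive* weights is
    taken.  Columns are renormalized to sum 1.
    """
    if len(estimates) < 2:
        raise ValueError("consensus needs at least 2 estimates")
    base = estimates[0]
    for e in estimates[1:]:
        mismatch = set(base.sample_ids) ^ set(e.sample_ids)
        if mismatch:
            raise ValueError(f"estimates cover different samples: {sorted(mismatch)}")
    sigs = sorted(set().union(*(e.signature_names for e in estimates)))
    samples = base.sample_ids
    stack = np.stack(
        [
            e.weights.reindex(index=sigs, columns=samples, fill_value=0.0)
            .fillna(0.0)
            .to_numpy()
            for e in estimates
        ]
    )
    positive = stack > 0
    n_active = positive.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_pos = np.where(
            n_active >= 2, stack.sum(axis=0) / np.maximum(n_active, 1), 0.0
        )
    out = pd.DataFrame(mean_pos, index=sigs, columns=samples)
    sums = out.sum(axis=0)
    if (sums == 0).any():
        bad = sums.index[sums == 0].tolist()
        raise ValueError(f"no consensus signatures for samples: {bad}")
    return ExposureMatrix(out / sums)


def method_disagreement(estA: ExposureMatrix, estB: ExposureMatrix) -> pd.Series:
    """Per-sample total absolute difference between two estimates."""
    A, B = align(estA, estB)
    return (A - B).abs().sum(axis=0)


def pairwise_mean_disagreement(estimates: Sequence[ExposureMatrix]) -> float:
    """Mean disagreement over all unordered pairs of estimates and samples."""
    if len(estimates) < 2:
        raise ValueError("need at least 2 estimates")
    vals = []
    for i in range(len(estimates)):
        for j in range(i + 1, len(estimates)):
            vals.append(method_disagreement(estimates[i], estimates[j]).mean())
    return float(np.mean(vals))


def evaluate(truth: ExposureMatrix, est: ExposureMatrix) -> MetricReport:
    """Compute the full metric suite for one truth/estimate pair."""
    precision, sensitivity, f1, n, n_prec = classification_metrics(truth, est)
    r, n_r = pearson_agreement(truth, est)
    return MetricReport(
        fitting_error=fitting_error(truth, est),
        false_positive_weight=false_positive_weight(truth, est),
        precision=precision,
        sensitivity=sensitivity,
        f1=f1,
        pearson_agreement=r,
        n_samples=n,
        n_samples_precision=n_prec,
        n_samples_pearson=n_r,
    )
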