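"""Baseline signature-refitting algorithms.

Refitting estimates, for each sample, the relative weights ``w`` of known
reference signatures ``R`` that best reproduce the sample's normalized
mutation spectrum ``m``, i.e. it solves ``m = R w`` with ``w >= 0``.  Two
baseline solvers are provided:

* **NNLS** — per-sample non-negative least squares on the normalized
  spectrum, representative of the simple, overfitting-prone tool class;
* **greedy** — forward selection (add the signature whose NNLS refit most
  improves cosine reconstruction similarity, while the gain exceeds a
  tolerance) followed by backward pruning, representative of the iterative
  tool class.

Both then normalize the weights to sum 1 and apply the conventional
output cutoff: signatures contributing fewer than ``min_mutations``
(default 10) mutations are zeroed.  The zeroed mass is *not*
redistributed; it is reported as the per-sample unassigned fraction.

The statsmodels-style entry point is :class:`SignatureRefit` whose
``fit()`` returns a :class:`RefitResults`; the functional wrappers
:func:`fit_nnls` and :func:`fit_greedy` are equivalent.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .catalogs import (
    ExposureMatrix,
    MutationalCatalog,
    SignatureCatalog,
    cosine_similarity,
)

__all__ = [
    "FitterConfig",
    "SignatureRefit",
    "RefitResults",
    "fit_nnls",
    "fit_greedy",
    "apply_min_mutation_filter",
    "reconstruction_accuracy",
    "external_adapter",
]

DECONSTRUCTSIGS_WEIGHT_FLOOR = 0.06  # optional post-filter used by some tools


@dataclass(frozen=True)
class FitterConfig:
    """Knobs shared by the baseline fitters.

    min_mutations
        Output cutoff: estimated activities contributing fewer than this
        many mutations in a sample are set to zero (the COSMIC convention
        of 10).
    greedy_tol
        Minimum cosine reconstruction-similarity gain required to add a
        signature in the greedy forward phase (and to keep one in the
        backward phase).
    weight_floor
        Optional extra post-filter zeroing relative weights below a floor
        (0.06 in some published tools); disabled by default.
    """

    min_mutations: float = 10.0
    greedy_tol: float = 0.01
    max_iter: int = 96
    weight_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.min_mutations < 0 or self.greedy_tol < 0 or self.weight_floor < 0:
            raise ValueError("config values must be non-negative")


@dataclass(frozen=True)
class RefitResults:
    """Estimated exposures plus per-sample diagnostics.

    Attributes
    ----------
    exposures : ExposureMatrix
        Estimated relative weights (post-cutoff; per-sample sums <= 1).
    unassigned : pd.Series
        Fraction of each sample's mutations not assigned to any signature.
    reconstruction : pd.Series
        Cosine similarity between the observed spectrum and the spectrum
        implied by the estimate, per sample.
    """

    exposures: ExposureMatrix
    unassigned: pd.Series
    reconstruction: pd.Series
    method: str
    reference_fingerprint: str

    def __post_init__(self) -> None:
        total = self.exposures.weights.sum(axis=0) + self.unassigned
        if (total > 1.0 + 1e-9).any() or (total < -1e-9).any():
            raise ValueError("assigned + unassigned mass must lie in [0, 1]")
        recon = self.reconstruction.dropna()
        if ((recon < -1e-9) | (recon > 1.0 + 1e-9)).any():
            raise ValueError("reconstruction similarity must lie in [0, 1]")

    @property
    def weights(self) -> pd.DataFrame:
        return self.exposures.weights

    def summary(self) -> str:
        """Human-readable per-fit summary table."""
        w = self.exposures.weights
        active = (w > 0).sum(axis=0)
        lines = [
            f"Signature refit ({self.method})",
            f"  reference: {self.reference_fingerprint}",
            f"  samples: {w.shape[1]}  signatures in reference: {w.shape[0]}",
            f"  mean active signatures/sample: {active.mean():.2f}",
            f"  mean unassigned fraction: {self.unassigned.mean():.4f}",
            f"  mean reconstruction similarity: {self.reconstruction.mean():.4f}",
            "",
            "  per-sample:",
            "  sample            active  unassigned  reconstruction",
        ]
        for sid in w.columns:
            lines.append(
                f"  {sid:<16} {int(active[sid]):>6}  {self.unassigned[sid]:>10.4f}"
                f"  {self.reconstruction[sid]:>14.4f}"
            )
        return "\n".join(lines)


def _fingerprint(reference: SignatureCatalog) -> str:
    h = hashlib.sha256()
    h.update(",".join(reference.names).encode())
    h.update(np.ascontiguousarray(reference.matrix()).tobytes())
    return f"{reference.n_signatures} signatures [{h.hexdigest()[:12]}]"


class SignatureRefit:
    """Model object binding a mutational catalog to a reference catalog.

    Parameters
    ----------
    catalog : MutationalCatalog
        Observed 96 x N mutation counts; every sample needs >= 1 mutation.
    reference : SignatureCatalog
        Candidate signature profiles (the matrix ``R``).
    config : FitterConfig, optional

    Examples
    --------
    >>> model = SignatureRefit(catalog, reference)
    >>> res = model.fit(method="nnls")
    >>> res.exposures.weights  # S x N relative activities
    """

    def __init__(
        self,
        catalog: MutationalCatalog,
        reference: SignatureCatalog,
        config: FitterConfig | None = None,
    ) -> None:
        self.catalog = catalog
        self.reference = reference
        self.config = config or FitterConfig()
        totals = catalog.totals()
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"samples with zero mutations cannot be fitted: {empty}")
        R = reference.matrix()
        if np.linalg.matrix_rank(R) < reference.n_signatures:
            warnings.warn(
                "reference signatures are linearly dependent; the NNLS solution "
                "is not unique",
                stacklevel=2,
            )

    # -- solvers ------------------------------------------------------------

    def _nnls_weights(self, spectrum: np.ndarray, columns: list[str]) -> np.ndarray:
        R = self.reference.profile[columns].to_numpy()
        w, _ = _scipy_nnls(R, spectrum, maxiter=10 * R.shape[1])
        return w

    def _fit_sample_nnls(self, spectrum: np.ndarray) -> np.ndarray:
        w = self._nnls_weights(spectrum, self.reference.names)
        total = w.sum()
        if total == 0:
            raise RuntimeError("NNLS produced an all-zero solution")
        return w / total

    def _fit_sample_greedy(self, spectrum: np.ndarray) -> np.ndarray:
        names = self.reference.names
        tol = self.config.greedy_tol
        selected: list[str] = []
        best_sim = 0.0

        def sim_for(subset: list[str]) -> tuple[float, np.ndarray]:
            w = self._nnls_weights(spectrum, subset)
            recon = self.reference.profile[subset].to_numpy() @ w
            if not recon.any():
                return 0.0, w
            return cosine_similarity(spectrum, recon), w

        # forward: add while the best candidate improves similarity by >= tol
        for _ in range(min(len(names), self.config.max_iter)):
            best_gain, best_name = -np.inf, None
            for cand in names:
                if cand in selected:
                    continue
                sim, _ = sim_for(selected + [cand])
                gain = sim - best_sim
                if gain > best_gain:
                    best_gain, best_name = gain, cand
            if best_name is None or best_gain < tol:
                break
            selected.append(best_name)
            best_sim += best_gain
        # backward: drop signatures whose removal costs < tol
        changed = True
        while changed and len(selected) > 1:
            changed = False
            for cand in list(selected):
                rest = [s for s in selected if s != cand]
                sim, _ = sim_for(rest)
                if best_sim - sim < tol:
                    selected = rest
                    best_sim = sim
                    changed = True
                    break
        w = np.zeros(len(names))
        if selected:
            _, w_sel = sim_for(selected)
            if w_sel.sum() > 0:
                w_sel = w_sel / w_sel.sum()
            idx = [names.index(s) for s in selected]
            w[idx] = w_sel
        return w

    # -- public API ---------------------------------------------------------

    def fit(self, method: str = "nnls") -> RefitResults:
        """Estimate relative signature activities for every sample."""
        if method not in ("nnls", "greedy"):
            raise ValueError(f"unknown method {method!r}")
        M = self.catalog.normalized()
        cols = {}
        for sid in M.columns:
            spectrum = M[sid].to_numpy()
            try:
                if method == "nnls":
                    cols[sid] = self._fit_sample_nnls(spectrum)
                else:
                    cols[sid] = self._fit_sample_greedy(spectrum)
            except RuntimeError as exc:
                raise RuntimeError(f"sample {sid!r}: {exc}") from exc
        raw = ExposureMatrix(
            pd.DataFrame(cols, index=self.reference.names).clip(lower=0.0)
        )
        result = RefitResults(
            exposures=raw,
            unassigned=(1.0 - raw.weights.sum(axis=0)).clip(lower=0.0),
            reconstruction=_safe_reconstruction(self.catalog, self.reference, raw),
            method=method,
            reference_fingerprint=_fingerprint(self.reference),
        )
        result = apply_min_mutation_filter(
            result, self.catalog, self.config.min_mutations
        )
        if self.config.weight_floor > 0:
            result = _apply_weight_floor(result, self.config.weight_floor)
        return result


def _apply_weight_floor(result: RefitResults, floor: float) -> RefitResults:
    w = result.weights.where(result.weights >= floor, 0.0)
    exposures = ExposureMatrix(w)
    return replace(
        result,
        exposures=exposures,
        unassigned=(1.0 - w.sum(axis=0)).clip(lower=0.0),
    )


def apply_min_mutation_filter(
    result: RefitResults, catalog: MutationalCatalog, threshold: float
) -> RefitResults:
    """Zero activities contributing fewer than ``threshold`` mutations.

    For a sample with ``m_i`` total mutations, any weight with
    ``w * m_i < threshold`` is set to zero.  Surviving weights are not
    renormalized; the removed mass is added to the unassigned fraction.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if threshold == 0:
        return result
    totals = catalog.totals()
    w = result.weights.copy()
    for sid in w.columns:
        contrib = w[sid] * totals[sid]
        w.loc[contrib < threshold, sid] = 0.0
    exposures = ExposureMatrix(w)
    return replace(
        result,
        exposures=exposures,
        unassigned=(1.0 - w.sum(axis=0)).clip(lower=0.0),
    )


def _safe_reconstruction(
    catalog: MutationalCatalog,
    reference: SignatureCatalog,
    exposures: ExposureMatrix,
) -> pd.Series:
    """Like :func:`reconstruction_accuracy` but NaN for all-zero estimates."""
    M = catalog.normalized()
    R = reference.profile[exposures.signature_names].to_numpy()
    out = {}
    for sid in exposures.sample_ids:
        recon = R @ exposures.weights[sid].to_numpy()
        out[sid] = (
            float(np.clip(cosine_similarity(M[sid].to_numpy(), recon), 0.0, 1.0))
            if recon.any()
            else float("nan")
        )
    return pd.Series(out, name="reconstruction")


def reconstruction_accuracy(
    catalog: MutationalCatalog,
    reference: SignatureCatalog,
    exposures: ExposureMatrix,
) -> pd.Series:
    """Cosine similarity of observed vs reconstructed spectra, per sample.

    The reconstruction is ``R w-tilde``; cosine similarity is scale
    invariant, so relative and absolute exposures give the same score.
    """
    missing = [s for s in exposures.signature_names if s not in reference]
    if missing:
        raise KeyError(f"exposures name signatures absent from reference: {missing}")
    M = catalog.normalized()
    R = reference.profile[exposures.signature_names].to_numpy()
    out = {}
    for sid in exposures.sample_ids:
        recon = R @ exposures.weights[sid].to_numpy()
        if not recon.any():
            raise ValueError(f"sample {sid!r}: reconstructed spectrum is zero")
        out[sid] = float(np.clip(cosine_similarity(M[sid].to_numpy(), recon), 0.0, 1.0))
    return pd.Series(out, name="reconstruction")


def fit_nnls(
    catalog: MutationalCatalog,
    reference: SignatureCatalog,
    config: FitterConfig | None = None,
) -> RefitResults:
    """Per-sample non-negative least squares refit (see :class:`SignatureRefit`)."""
    return SignatureRefit(catalog, reference, config).fit(method="nnls")


def fit_greedy(
    catalog: MutationalCatalog,
    reference: SignatureCatalog,
    config: FitterConfig | None = None,
) -> RefitResults:
    """Greedy forward/backward selection refit (see :class:`SignatureRefit`)."""
    return SignatureRefit(catalog, reference, config).fit(method="greedy")


def external_adapter(
    path,
    catalog: MutationalCatalog,
    reference: SignatureCatalog,
    absolute: bool = False,
    min_mutations: float = 10.0,
    renormalize: bool = False,
) -> RefitResults:
    """Score an external tool's exposure file against this framework.

    The file must follow the exposure TSV contract (rows = signatures,
    columns = samples).  Absolute exposures (mutation counts per
    signature) are first divided by each sample's total mutation count;
    the standard output cutoff and reconstruction score are then applied.
    ``renormalize`` optionally rescales the surviving weights to sum 1
    after the cutoff (some published pipelines do; the default keeps the
    removed mass unassigned).
    """
    from .catalogs import read_exposures

    est = read_exposures(path) if absolute is False else None
    if absolute:
        raw = pd.read_csv(path, sep="\t", index_col=0)
        raw.index = raw.index.astype(str)
        raw.columns = raw.columns.astype(str)
        if (raw.to_numpy() < 0).any():
            raise ValueError("exposure file contains negative values")
        totals = catalog.totals()
        missing_samples = set(raw.columns) ^ set(catalog.sample_ids)
        if missing_samples:
            raise ValueError(
                f"sample ids differ between file and catalog: {sorted(missing_samples)}"
            )
        est = ExposureMatrix((raw / totals[raw.columns]).clip(upper=1.0))
    else:
        mismatch = set(est.sample_ids) ^ set(catalog.sample_ids)
        if mismatch:
            raise ValueError(
                f"sample ids differ between file and catalog: {sorted(mismatch)}"
            )
    unknown = [s for s in est.signature_names if s not in reference]
    if unknown:
        raise KeyError(f"exposure file names signatures absent from reference: {unknown}")
    est = ExposureMatrix(est.weights[catalog.sample_ids])
    result = RefitResults(
        exposures=est,
        unassigned=(1.0 - est.weights.sum(axis=0)).clip(lower=0.0),
        reconstruction=reconstruction_accuracy(catalog, reference, est),
        method="external",
        reference_fingerprint=_fingerprint(reference),
    )
    result = apply_min_mutation_filter(result, catalog, min_mutations)
    if renormalize:
        w = result.weights
        sums = w.sum(axis=0)
        w = w.div(sums.where(sums > 0, 1.0), axis=1)
        result = replace(
            result,
            exposures=ExposureMatrix(w),
            unassigned=(1.0 - w.sum(axis=0)).clip(lower=0.0),
        )
    return result
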