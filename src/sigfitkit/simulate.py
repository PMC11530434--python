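"""Synthetic mutational catalogs with known ground-truth signature activities.

A cohort of ``n`` samples with ``m`` mutations each is generated by

1. drawing each sample's relative signature weights ``w_si`` — either all
   mass on one signature (single-signature cohorts) or a row sampled with
   replacement from an empirical per-donor weight table (heterogeneous
   cohorts);
2. dropping signatures whose expected contribution ``m * w_si`` falls below
   ``min_contribution`` (default 10) mutations and renormalizing the rest —
   a fitter working at the standard <10-mutation output cutoff cannot be
   expected to recover them, so they are removed from the truth as well;
3. mixing the reference profiles, ``W_ci = sum_s omega_cs * w_si``; and
4. drawing one multinomial sample of size ``m`` over the 96 contexts per
   sample, so context counts have mean ``m * W_ci``.

Two adversarial perturbations of the truth are provided: a systematic
group difference (one signature's weight multiplied/divided by a factor in
even/odd samples) and out-of-reference activity (part of each sample's
weight moved onto signatures that the fitter's reference catalog lacks).
Catalog subsampling (without replacement) emulates reduced sequencing
depth on an existing catalog.

Randomness: every generator takes one root seed; per-sample child streams
are spawned from it, so sample ``i`` of a cohort is unchanged when ``n``
grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalogs import (
    CatalogValidationError,
    ExposureMatrix,
    MutationalCatalog,
    SignatureCatalog,
)
from .contexts import N_CONTEXTS, context_labels

__all__ = [
    "CohortSpec",
    "EmpiricalWeightTable",
    "SimulatedCohort",
    "sample_weights",
    "mixture_spectrum",
    "draw_counts",
    "single_signature_cohort",
    "heterogeneous_cohort",
    "inject_group_difference",
    "inject_out_of_reference",
    "subsample_catalog",
    "synth_signature_catalog",
    "synth_weight_table",
    "glioblastoma_like_weight_table",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_CONTRIBUTION = 10


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort."""

    mode: str  # "single" | "heterogeneous"
    source: str  # signature name (single) or weight-table id
    n_samples: int = 100
    m: int = 2000
    seed: int = 0
    min_contribution: float = DEFAULT_MIN_CONTRIBUTION

    def __post_init__(self) -> None:
        if self.mode not in ("single", "heterogeneous"):
            raise ValueError(f"unknown cohort mode {self.mode!r}")
        if self.n_samples < 1 or self.m < 1:
            raise ValueError("n_samples and m must be >= 1")
        if self.min_contribution < 0:
            raise ValueError("min_contribution must be >= 0")


@dataclass(frozen=True)
class EmpiricalWeightTable:
    """Per-donor relative signature weights for one cancer type.

    Rows are donors, columns signatures; each row is non-negative and sums
    to 1 (within 1e-6).
    """

    cancer_type: str
    weights: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.weights.astype(float)
        if df.shape[0] < 1:
            raise ValueError("weight table has no donors")
        if (df.to_numpy() < 0).any():
            raise ValueError("weight table contains negative weights")
        sums = df.sum(axis=1)
        bad = sums[(sums - 1.0).abs() > 1e-6]
        if not bad.empty:
            raise ValueError(
                f"donor {bad.index[0]!r} weights sum to {bad.iloc[0]:.6g}, not 1"
            )
        object.__setattr__(self, "weights", df)

    @property
    def signature_names(self) -> list[str]:
        return self.weights.columns.tolist()

    @property
    def n_donors(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class SimulatedCohort:
    """A mutational catalog plus the truth it was generated from."""

    catalog: MutationalCatalog
    truth: ExposureMatrix
    provenance: pd.DataFrame  # one row per sample: donor, seed, perturbations

    def __post_init__(self) -> None:
        sums = self.truth.weights.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise CatalogValidationError("ground-truth columns must sum to 1")


def _sample_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-sample streams; stream i does not depend on n."""
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def _filter_and_renormalize(
    w: pd.Series, m: int, min_contribution: float, sample_id: str
) -> pd.Series:
    """Drop signatures expected to contribute < min_contribution mutations."""
    keep = w * m >= min_contribution
    kept = w[keep & (w > 0)]
    if kept.empty:
        # every weight fails the cutoff (possible at very low burden):
        # keep the dominant signature alone rather than dropping the sample
        top = w.idxmax()
        logger.warning(
            "sample %s: all signature contributions below cutoff %g at m=%d; "
            "keeping %s at weight 1",
            sample_id,
            min_contribution,
            m,
            top,
        )
        out = pd.Series(0.0, index=w.index)
        out[top] = 1.0
        return out
    out = pd.Series(0.0, index=w.index)
    out[kept.index] = kept / kept.sum()
    return out


def sample_weights(
    table: EmpiricalWeightTable,
    n: int,
    m: int,
    min_contribution: float = DEFAULT_MIN_CONTRIBUTION,
    seed: int = 0,
) -> tuple[ExposureMatrix, pd.DataFrame]:
    """Draw ground-truth weights for ``n`` samples from an empirical table.

    Donors are chosen uniformly with replacement; each drawn weight vector
    is passed through the expected-contribution cutoff and renormalized.
    Returns the truth and a provenance frame recording the source donor of
    every sample.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    donors = rng.integers(0, table.n_donors, size=n)
    cols = {}
    prov = []
    for i, d in enumerate(donors):
        sid = f"s{i}"
        row = table.weights.iloc[d]
        cols[sid] = _filter_and_renormalize(row, m, min_contribution, sid)
        prov.append({"sample_id": sid, "donor": str(table.weights.index[d])})
    truth = ExposureMatrix(pd.DataFrame(cols))
    return truth, pd.DataFrame(prov).set_index("sample_id")


def mixture_spectrum(
    truth: ExposureMatrix, reference: SignatureCatalog
) -> pd.DataFrame:
    """Per-sample context distribution implied by the truth.

    ``W_ci = sum_s omega_cs * w_si``; columns sum to 1 whenever the truth
    columns do.
    """
    missing = [s for s in truth.signature_names if s not in reference]
    if missing:
        raise KeyError(f"truth names signatures absent from reference: {missing}")
    R = reference.profile[truth.signature_names]
    return pd.DataFrame(
        R.to_numpy() @ truth.weights.to_numpy(),
        index=list(context_labels()),
        columns=truth.sample_ids,
    )


def draw_counts(W: pd.DataFrame, m: int, seed: int = 0) -> MutationalCatalog:
    """One multinomial draw of size ``m`` per sample from spectrum ``W``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    arr = W.to_numpy(dtype=float)
    if arr.shape[0] != N_CONTEXTS:
        raise ValueError(f"spectrum must have {N_CONTEXTS} rows")
    sums = arr.sum(axis=0)
    if (arr < 0).any() or not np.allclose(sums, 1.0, atol=1e-8):
        bad = W.columns[np.where(~np.isclose(sums, 1.0, atol=1e-8))[0]].tolist()
        raise ValueError(f"non-stochastic spectrum columns: {bad}")
    rngs = _sample_rngs(seed, arr.shape[1])
    counts = np.column_stack(
        [rngs[i].multinomial(m, arr[:, i] / sums[i]) for i in range(arr.shape[1])]
    )
    return MutationalCatalog(
        pd.DataFrame(counts, index=list(context_labels()), columns=W.columns)
    )


def single_signature_cohort(
    signature: str,
    n: int,
    m: int,
    reference: SignatureCatalog,
    seed: int = 0,
) -> SimulatedCohort:
    """Cohort where one signature generates every mutation in every sample."""
    if signature not in reference:
        raise KeyError(f"signature {signature!r} not in reference")
    sample_ids = [f"s{i}" for i in range(n)]
    truth = ExposureMatrix(
        pd.DataFrame(1.0, index=[signature], columns=sample_ids)
    )
    W = mixture_spectrum(truth, reference)
    catalog = draw_counts(W, m, seed=seed)
    prov = pd.DataFrame(
        {"sample_id": sample_ids, "donor": signature}
    ).set_index("sample_id")
    prov["perturbations"] = ""
    return SimulatedCohort(catalog=catalog, truth=truth, provenance=prov)


def heterogeneous_cohort(
    table: EmpiricalWeightTable,
    n: int,
    m: int,
    reference: SignatureCatalog,
    seed: int = 0,
    min_contribution: float = DEFAULT_MIN_CONTRIBUTION,
    group_difference: tuple[str, float] | None = None,
    out_of_reference: dict | None = None,
) -> SimulatedCohort:
    """Cohort with empirically heterogeneous signature activities.

    Optional perturbations, applied to the truth before mixing:

    * ``group_difference=(signature, factor)`` — systematic even/odd
      difference in one signature's weight (see
      :func:`inject_group_difference`);
    * ``out_of_reference=dict(pool=..., x=..., split=(0.7, 0.3))`` — part of
      each sample's weight moved to signatures outside the fitting
      reference (see :func:`inject_out_of_reference`).  ``pool`` profiles
      must be available in ``reference`` for mixing, but the caller fits
      with a reference that excludes them.
    """
    ss = np.random.SeedSequence(seed)
    s_weights, s_perturb, s_counts = (int(c.generate_state(1)[0] >> 1) for c in ss.spawn(3))
    truth, prov = sample_weights(
        table, n, m, min_contribution=min_contribution, seed=s_weights
    )
    applied = []
    if group_difference is not None:
        sig, factor = group_difference
        truth = inject_group_difference(truth, sig, factor)
        applied.append(f"group_difference:{sig}x{factor}")
    if out_of_reference is not None:
        oor = dict(out_of_reference)
        truth = inject_out_of_reference(
            truth,
            pool=oor["pool"],
            x=oor["x"],
            split=tuple(oor.get("split", (0.7, 0.3))),
            seed=s_perturb,
        )
        applied.append(f"out_of_reference:x={oor['x']}")
    prov = prov.copy()
    prov["perturbations"] = ";".join(applied)
    W = mixture_spectrum(truth.drop_zero_rows(), reference)
    catalog = draw_counts(W, m, seed=s_counts)
    return SimulatedCohort(catalog=catalog, truth=truth, provenance=prov)


def inject_group_difference(
    truth: ExposureMatrix, signature: str, factor: float
) -> ExposureMatrix:
    """Introduce a systematic even/odd difference in one signature's weight.

    Even-indexed samples (0, 2, 4, ...) get the target weight multiplied by
    ``factor``; odd-indexed samples get it divided; every column is then
    renormalized to 1.  Samples where the signature is inactive pass
    through unchanged.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    W = truth.weights.copy()
    if signature in W.index:
        for j in range(W.shape[1]):
            mult = factor if j % 2 == 0 else 1.0 / factor
            W.iloc[W.index.get_loc(signature), j] *= mult
    W = W / W.sum(axis=0)
    return ExposureMatrix(W)


def inject_out_of_reference(
    truth: ExposureMatrix,
    pool: Sequence[str],
    x: float,
    split: tuple[float, float] = (0.7, 0.3),
    seed: int = 0,
) -> ExposureMatrix:
    """Move total weight ``x`` of every sample onto out-of-reference signatures.

    Existing weights are scaled by ``1 - x``; two pool signatures are drawn
    at random (per sample, without replacement) and assigned ``x * split``.
    Column sums remain 1.
    """
    pool = list(pool)
    if len(pool) < 2:
        raise ValueError("out-of-reference pool must have at least 2 signatures")
    if not 0 <= x < 1:
        raise ValueError("x must be in [0, 1)")
    if abs(sum(split) - 1.0) > 1e-9 or len(split) != 2:
        raise ValueError("split must be a pair summing to 1")
    overlap = set(pool) & set(
        truth.weights.index[(truth.weights > 0).any(axis=1)]
    )
    if overlap:
        raise ValueError(f"pool signatures already active in truth: {sorted(overlap)}")
    if x == 0:
        return truth
    W = truth.weights.copy() * (1.0 - x)
    extra = pd.DataFrame(0.0, index=[p for p in pool if p not in W.index], columns=W.columns)
    W = pd.concat([W, extra])
    rngs = _sample_rngs(seed, W.shape[1])
    for j, rng in enumerate(rngs):
        chosen = rng.choice(len(pool), size=2, replace=False)
        W.iloc[W.index.get_loc(pool[chosen[0]]), j] += x * split[0]
        W.iloc[W.index.get_loc(pool[chosen[1]]), j] += x * split[1]
    return ExposureMatrix(W)


def subsample_catalog(
    catalog: MutationalCatalog, m: int, n_replicates: int = 1, seed: int = 0
) -> list[MutationalCatalog]:
    """Downsample every sample to ``m`` mutations, without replacement.

    Each sample's mutation multiset is treated as a finite population and
    ``m`` of its mutations are drawn hypergeometrically, per replicate.
    """
    totals = catalog.totals()
    short = totals[totals < m]
    if not short.empty:
        raise ValueError(
            f"sample {short.index[0]!r} has {short.iloc[0]} mutations, fewer than m={m}"
        )
    counts = catalog.counts.to_numpy()
    reps = []
    rng_root = np.random.SeedSequence(seed)
    for rep_ss in rng_root.spawn(n_replicates):
        rngs = [np.random.default_rng(c) for c in rep_ss.spawn(counts.shape[1])]
        sub = np.column_stack(
            [
                rngs[j].multivariate_hypergeometric(counts[:, j], m)
                for j in range(counts.shape[1])
            ]
        )
        reps.append(
            MutationalCatalog(
                pd.DataFrame(
                    sub, index=catalog.counts.index, columns=catalog.counts.columns
                )
            )
        )
    return reps


# ---------------------------------------------------------------------------
# Synthetic fixtures: signature catalogs and weight tables
# ---------------------------------------------------------------------------

def synth_signature_catalog(
    n_signatures: int,
    concentration: float = 0.05,
    seed: int = 0,
    prefix: str = "SYN",
) -> SignatureCatalog:
    """Synthetic reference catalog drawn from a symmetric Dirichlet.

    Small ``concentration`` yields peaked, easy-to-fit profiles (effective
    context count near 1-3); large values approach the flat profile whose
    effective context count is 96.
    """
    if n_signatures < 1:
        raise ValueError("n_signatures must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    profiles = rng.dirichlet([concentration] * N_CONTEXTS, size=n_signatures).T
    names = [f"{prefix}{i + 1}" for i in range(n_signatures)]
    return SignatureCatalog(
        pd.DataFrame(profiles, index=list(context_labels()), columns=names)
    )


def synth_weight_table(
    n_donors: int,
    signature_names: Sequence[str],
    active_range: tuple[int, int] = (1, 11),
    seed: int = 0,
    cancer_type: str = "Synthetic",
) -> EmpiricalWeightTable:
    """Synthetic per-donor weight table with heavy-tailed activities.

    Each donor activates between ``active_range[0]`` and ``active_range[1]``
    signatures (uniformly, capped at the catalog size), mirroring the 1-11
    active signatures observed per tumor sample; active weights are drawn
    from a Dirichlet(0.5) so that one or two signatures usually dominate.
    """
    names = list(signature_names)
    lo, hi = active_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid active_range")
    hi = min(hi, len(names))
    lo = min(lo, hi)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = np.zeros((n_donors, len(names)))
    for i in range(n_donors):
        k = int(rng.integers(lo, hi + 1))
        active = rng.choice(len(names), size=k, replace=False)
        rows[i, active] = rng.dirichlet([0.5] * k)
    return EmpiricalWeightTable(
        cancer_type=cancer_type,
        weights=pd.DataFrame(
            rows, index=[f"donor{i}" for i in range(n_donors)], columns=names
        ),
    )


def glioblastoma_like_weight_table(
    n_donors: int = 63, seed: int = 0
) -> EmpiricalWeightTable:
    """Synthetic stand-in for a glioblastoma (CNS-GBM) activity table.

    Emulates the summary features reported for WGS glioblastoma cohorts:
    the flat signature SBS40 is active in essentially every donor with a
    median relative weight of about 0.485, the clock-like signatures SBS1
    and SBS5 carry most of the remaining weight, and a minority of donors
    show small contributions of additional processes.  This is a synthetic
    object, not redistributed patient data; only the quoted summary
    statistics are emulated.
    """
    from scipy.stats import beta as _beta

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sigs = ["SBS1", "SBS5", "SBS8", "SBS11", "SBS15", "SBS30", "SBS37", "SBS40"]
    rows = np.zeros((n_donors, len(sigs)))
    j40 = sigs.index("SBS40")
    # SBS40 activities as stratified quantiles of Beta(8, 8.5) (median ~0.485,
    # SD ~0.12), shuffled across donors: the table reproduces the emulated
    # median exactly instead of inheriting sampling noise from a 63-donor draw
    w40_all = _beta.ppf((np.arange(n_donors) + 0.5) / n_donors, 8.0, 8.5)
    rng.shuffle(w40_all)
    for i in range(n_donors):
        w40 = w40_all[i]
        rest = 1.0 - w40
        w1, w5 = rng.dirichlet([2.0, 3.0])
        rows[i, sigs.index("SBS1")] = rest * w1 * 0.9
        rows[i, sigs.index("SBS5")] = rest * w5 * 0.9
        minor_pool = [sigs.index(s) for s in ("SBS8", "SBS11", "SBS15", "SBS30", "SBS37")]
        k = int(rng.integers(0, 3))
        if k:
            minors = rng.choice(minor_pool, size=k, replace=False)
            rows[i, minors] = rest * 0.1 * rng.dirichlet([1.0] * k)
        else:
            rows[i, sigs.index("SBS1")] += rest * 0.1 * 0.4
            rows[i, sigs.index("SBS5")] += rest * 0.1 * 0.6
        rows[i, j40] = w40
        rows[i] /= rows[i].sum()
    return EmpiricalWeightTable(
        cancer_type="CNS-GBM-like (synthetic)",
        weights=pd.DataFrame(
            rows, index=[f"donor{i}" for i in range(n_donors)], columns=sigs
        ),
    )
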