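"""Containers and I/O for signature catalogs, mutation catalogs and exposures.

Three matrices drive everything in this package:

* a **reference signature catalog** ``R`` (96 contexts x S signatures),
  each column a probability distribution over contexts;
* a **mutational catalog** ``M`` (96 contexts x N samples) of non-negative
  integer mutation counts;
* an **exposure matrix** ``w`` (S signatures x N samples) of relative
  signature weights — either ground truth (columns sum to 1) or a fitter's
  estimate (columns may sum to less than 1 when mutations are left
  unassigned).

All three are thin wrappers around a pandas DataFrame with validated
invariants, read from and written to plain TSV in the COSMIC layout
(first column ``Type`` holding context labels, or ``Signature`` holding
signature names).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contexts import context_labels

__all__ = [
    "SignatureCatalog",
    "MutationalCatalog",
    "ExposureMatrix",
    "DifficultyScore",
    "CatalogFormatError",
    "CatalogValidationError",
    "read_signature_catalog",
    "read_catalog",
    "write_catalog",
    "read_exposures",
    "write_exposures",
    "exp_shannon",
    "cosine_similarity",
    "cosine_distance",
    "signature_difficulty",
    "cohort_heterogeneity",
]

_FLOAT_FMT = "%.12g"  # lossless round trip for <= 12 significant digits


class CatalogFormatError(ValueError):
    """A file does not follow the expected TSV layout."""


class CatalogValidationError(ValueError):
    """Parsed values violate a container invariant."""


def _canonicalize_context_rows(df: pd.DataFrame) -> pd.DataFrame:
    labels = list(context_labels())
    seen = df.index.tolist()
    dupes = [x for x in pd.Index(seen)[pd.Index(seen).duplicated()].unique()]
    if dupes:
        raise CatalogFormatError(f"duplicated context labels: {dupes}")
    missing = sorted(set(labels) - set(seen))
    if missing:
        raise CatalogFormatError(
            f"missing {len(missing)} context labels (e.g. {missing[:3]})"
        )
    extra = sorted(set(seen) - set(labels))
    if extra:
        raise CatalogFormatError(
            f"{len(extra)} rows are not SBS96 context labels (e.g. {extra[:3]})"
        )
    return df.loc[labels]


@dataclass(frozen=True)
class SignatureCatalog:
    """Reference signature profiles: 96 contexts x S signatures.

    Each column is the probability distribution of a mutational process
    over the 96 contexts; columns must sum to one within ``tol``.
    """

    profile: pd.DataFrame
    tol: float = 1e-6

    def __post_init__(self) -> None:
        df = self.profile
        object.__setattr__(self, "profile", _canonicalize_context_rows(df).astype(float))
        df = self.profile
        if df.columns.duplicated().any():
            raise CatalogValidationError(
                f"duplicate signature names: {df.columns[df.columns.duplicated()].tolist()}"
            )
        if (df.to_numpy() < 0).any():
            raise CatalogValidationError("signature profiles contain negative entries")
        sums = df.sum(axis=0)
        bad = sums[(sums - 1.0).abs() > self.tol]
        if not bad.empty:
            name, total = bad.index[0], bad.iloc[0]
            raise CatalogValidationError(
                f"signature {name!r} sums to {total:.6g}, not 1 (tolerance {self.tol:g})"
            )

    @property
    def names(self) -> list[str]:
        return self.profile.columns.tolist()

    @property
    def n_signatures(self) -> int:
        return self.profile.shape[1]

    def __contains__(self, name: str) -> bool:
        return name in self.profile.columns

    def subset(self, names: Sequence[str]) -> "SignatureCatalog":
        """Restrict to the given signatures, preserving catalog order."""
        missing = [n for n in names if n not in self.profile.columns]
        if missing:
            raise KeyError(f"signatures not in catalog: {missing}")
        keep = [n for n in self.names if n in set(names)]
        return SignatureCatalog(self.profile[keep], tol=self.tol)

    def matrix(self) -> np.ndarray:
        return self.profile.to_numpy()


@dataclass(frozen=True)
class MutationalCatalog:
    """Mutation counts: 96 contexts x N samples, non-negative integers."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = _canonicalize_context_rows(self.counts)
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0):
                raise CatalogValidationError("mutation counts must be integers")
            df = df.round().astype(np.int64)
        if (df.to_numpy() < 0).any():
            raise CatalogValidationError("mutation counts must be non-negative")
        object.__setattr__(self, "counts", df)

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def totals(self) -> pd.Series:
        """Total mutation burden per sample."""
        return self.counts.sum(axis=0)

    def normalized(self) -> pd.DataFrame:
        """Column-stochastic view: fraction of mutations per context."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise CatalogValidationError(f"samples with zero mutations: {empty}")
        return self.counts / totals


@dataclass(frozen=True)
class ExposureMatrix:
    """Relative signature weights: S signatures x N samples.

    Ground truths have columns summing to exactly 1; fitter estimates may
    sum to less when part of the spectrum is left unassigned.
    """

    weights: pd.DataFrame
    _SUM_TOL: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        df = self.weights.astype(float)
        if df.index.duplicated().any():
            raise CatalogValidationError(
                f"duplicate signature names: {df.index[df.index.duplicated()].tolist()}"
            )
        if (df.to_numpy() < 0).any():
            raise CatalogValidationError("exposure weights must be non-negative")
        sums = df.sum(axis=0)
        over = sums[sums > 1.0 + self._SUM_TOL]
        if not over.empty:
            raise CatalogValidationError(
                f"sample {over.index[0]!r} has weights summing to {over.iloc[0]:.6g} > 1"
            )
        object.__setattr__(self, "weights", df)

    @property
    def signature_names(self) -> list[str]:
        return self.weights.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.weights.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.weights.shape[1]

    def support(self, sample: str) -> list[str]:
        """Signatures with strictly positive weight in one sample."""
        col = self.weights[sample]
        return col.index[col > 0].tolist()

    def drop_zero_rows(self) -> "ExposureMatrix":
        keep = self.weights.index[(self.weights > 0).any(axis=1)]
        return ExposureMatrix(self.weights.loc[keep])


@dataclass(frozen=True)
class DifficultyScore:
    """How hard a signature is to fit: flat, promiscuous profiles are hard.

    ``exp_shannon`` is the effective number of active contexts (1 for a
    one-hot profile, 96 for the uniform profile); ``similarity`` aggregates
    cosine similarity to the other signatures of the same catalog; the
    combined score is their product.
    """

    name: str
    exp_shannon: float
    similarity: float

    @property
    def combined(self) -> float:
        return self.exp_shannon * self.similarity


# ---------------------------------------------------------------------------
# TSV I/O (COSMIC layout)
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, index_name: str) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise CatalogFormatError(f"{path}: no data columns after {index_name!r}")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df


def read_signature_catalog(path: str | Path, tol: float = 1e-4) -> SignatureCatalog:
    """Read a COSMIC-style SBS96 signature TSV.

    First column ``Type`` holds context labels like ``A[C>A]A``; every other
    column is one signature.  Rows may appear in any order; they are
    canonicalized on read.  ``tol`` bounds the acceptable deviation of the
    column sums from 1 (COSMIC files are rounded, hence the loose default).
    """
    df = _read_tsv(path, "Type")
    return SignatureCatalog(df, tol=tol)


def read_catalog(path: str | Path) -> MutationalCatalog:
    """Read a 96 x N mutation-count TSV (first column ``Type``)."""
    return MutationalCatalog(_read_tsv(path, "Type"))


def write_catalog(catalog: MutationalCatalog, path: str | Path) -> None:
    catalog.counts.rename_axis("Type").to_csv(path, sep="\t")


def read_exposures(path: str | Path) -> ExposureMatrix:
    """Read an exposure TSV (first column ``Signature``, one column per sample)."""
    return ExposureMatrix(_read_tsv(path, "Signature"))


def write_exposures(exposures: ExposureMatrix, path: str | Path) -> None:
    exposures.weights.rename_axis("Signature").to_csv(
        path, sep="\t", float_format=_FLOAT_FMT
    )


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    catalog.profile.rename_axis("Type").to_csv(path, sep="\t", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Diversity and similarity scores
# ---------------------------------------------------------------------------

def exp_shannon(profile: Iterable[float], tol: float = 1e-4) -> float:
    """Exponentiated Shannon index of a probability profile.

    The effective number of active categories, ``exp(-sum p log p)`` with
    ``0 log 0 = 0``: 1 when all mass sits in one context, 96 for the
    uniform SBS96 profile.  Permutation-invariant.
    """
    p = np.asarray(list(profile), dtype=float)
    if (p < 0).any():
        raise ValueError("profile entries must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("profile sums to zero")
    if abs(total - 1.0) > tol:
        raise ValueError(f"profile sums to {total:.6g}, not 1 (tolerance {tol:g})")
    p = p / total
    nz = p[p > 0]
    return float(math.exp(-np.sum(nz * np.log(nz))))


def cosine_similarity(u: Iterable[float], v: Iterable[float]) -> float:
    u = np.asarray(list(u), dtype=float)
    v = np.asarray(list(v), dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def cosine_distance(u: Iterable[float], v: Iterable[float]) -> float:
    """1 - cosine similarity; in [0, 1] for non-negative vectors."""
    return 1.0 - cosine_similarity(u, v)


def signature_difficulty(
    catalog: SignatureCatalog, name: str, aggregate: str = "mean"
) -> DifficultyScore:
    """Combined fitting-difficulty score for one catalog signature.

    Multiplies the effective context count of the signature's profile by
    its aggregate cosine similarity (``mean`` by default, ``max`` as an
    option) to every other signature in the catalog.  Flat signatures that
    resemble many others score highest and are empirically hardest to fit.
    """
    if name not in catalog:
        raise KeyError(f"signature {name!r} not in catalog")
    if catalog.n_signatures < 2:
        raise ValueError("difficulty needs a catalog with at least 2 signatures")
    target = catalog.profile[name].to_numpy()
    sims = [
        cosine_similarity(target, catalog.profile[other].to_numpy())
        for other in catalog.names
        if other != name
    ]
    if aggregate == "mean":
        sim = float(np.mean(sims))
    elif aggregate == "max":
        sim = float(np.max(sims))
    else:
        raise ValueError(f"aggregate must be 'mean' or 'max', got {aggregate!r}")
    return DifficultyScore(
        name=name, exp_shannon=exp_shannon(target, tol=1e-3), similarity=sim
    )


def cohort_heterogeneity(exposures: ExposureMatrix) -> float:
    """Mean pairwise cosine distance between samples' signature weights.

    0 when every sample has the same signature composition; 1 when samples
    load on mutually disjoint signature sets.  Requires >= 2 samples.
    """
    W = exposures.weights.to_numpy().T  # samples x signatures
    if W.shape[0] < 2:
        raise ValueError("cohort heterogeneity needs at least 2 samples")
    zero = np.where(W.sum(axis=1) == 0)[0]
    if zero.size:
        bad = [exposures.sample_ids[i] for i in zero]
        raise ValueError(f"samples with all-zero weights: {bad}")
    from scipy.spatial.distance import pdist

    return float(np.mean(pdist(W, metric="cosine")))
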