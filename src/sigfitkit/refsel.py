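"""Two-step pruning of the reference signature catalog.

Fitting with a large reference catalog invites overfitting; a common
remedy is to (1) fit every sample with the full catalog and (2) keep only
the signatures whose relative weight exceeds a threshold ``w0`` in at
least ``min_samples`` samples, then refit with the reduced catalog.  The
default thresholds track the mutational burden: w0 = 0.1 at m = 100,
0.03 at m = 2000 and 0.01 at m = 50,000 (absolute contributions of 10, 60
and 500 mutations respectively); between these anchors the log-nearest
anchor's threshold is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .catalogs import SignatureCatalog

__all__ = ["PruneConfig", "default_threshold", "two_step_prune", "COSMIC_ARTIFACT_SIGNATURES"]

# COSMICv3 signatures attributed to sequencing/processing artifacts rather
# than biology; experiments that restrict the reference to a cancer type's
# signatures conventionally keep these available.
COSMIC_ARTIFACT_SIGNATURES: tuple[str, ...] = (
    "SBS27", "SBS43", "SBS45", "SBS46", "SBS47", "SBS48", "SBS49", "SBS50",
    "SBS51", "SBS52", "SBS53", "SBS54", "SBS55", "SBS56", "SBS57", "SBS58",
    "SBS59", "SBS60",
)

_ANCHORS: tuple[tuple[int, float], ...] = ((100, 0.1), (2000, 0.03), (50_000, 0.01))


@dataclass(frozen=True)
class PruneConfig:
    """Thresholds for the second pruning step.

    w0
        Relative-weight threshold a signature must *exceed* to count as
        supported in a sample.
    min_samples
        Number of supporting samples required to keep a signature
        (default 5, for cohorts of ~100 samples).
    always_keep
        Signatures exempt from pruning (e.g. artifact signatures).
    """

    w0: float
    min_samples: int = 5
    always_keep: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 <= self.w0 <= 1:
            raise ValueError("w0 must be in [0, 1]")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


def default_threshold(m: int) -> float:
    """Burden-dependent default for ``w0``.

    Returns the anchor value at m = 100, 2000 and 50,000; elsewhere the
    threshold of the nearest anchor on a log scale.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(_ANCHORS, key=lambda a: abs(math.log(m) - math.log(a[0])))[1]


def two_step_prune(
    first_fit,
    reference: SignatureCatalog,
    config: PruneConfig,
) -> SignatureCatalog:
    """Reduce the reference catalog based on a full-catalog first fit.

    ``first_fit`` is a :class:`~sigfitkit.refit.RefitResults` or a bare
    exposure matrix produced against the full reference.  Keeps every
    signature whose estimated relative weight exceeds ``config.w0`` in at
    least ``config.min_samples`` samples, plus any ``always_keep`` names
    present in the reference; catalog order is preserved.  Refitting with
    the reduced catalog is the caller's second step.
    """
    w = first_fit.weights
    support = (w > config.w0).sum(axis=1)
    kept = set(support.index[support >= config.min_samples])
    kept |= set(config.always_keep) & set(reference.names)
    kept_ordered = [s for s in reference.names if s in kept]
    if not kept_ordered:
        raise ValueError(
            f"no signature exceeds w0={config.w0} in >= {config.min_samples} samples; "
            "lower the threshold"
        )
    return reference.subset(kept_ordered)
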