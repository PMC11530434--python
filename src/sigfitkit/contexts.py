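"""The SBS96 trinucleotide context space.

Single base substitutions are classified by the substituted pyrimidine
(C>A, C>G, C>T, T>A, T>C, T>G) together with the bases immediately 5'
and 3' of the mutated base, giving 6 x 4 x 4 = 96 mutation contexts.
Every matrix in this package uses the canonical COSMIC row order:
substitution class major, then 5' flank, then 3' flank, both flanks
in alphabetical order (A, C, G, T).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES: tuple[str, ...] = ("A", "C", "G", "T")
N_CONTEXTS = 96

_LABEL_RE = re.compile(r"^([ACGT])\[([CT])>([ACGT])\]([ACGT])$")


@dataclass(frozen=True, order=False)
class MutationContext:
    """One of the 96 SBS trinucleotide contexts, e.g. ``A[C>A]A``."""

    substitution: str
    flank5: str
    flank3: str

    def __post_init__(self) -> None:
        if self.substitution not in SUBSTITUTIONS:
            raise ValueError(f"unknown substitution class {self.substitution!r}")
        if self.flank5 not in BASES or self.flank3 not in BASES:
            raise ValueError(
                f"flanks must be one of {BASES}, got {self.flank5!r}/{self.flank3!r}"
            )

    @property
    def label(self) -> str:
        ref, alt = self.substitution.split(">")
        return f"{self.flank5}[{ref}>{alt}]{self.flank3}"

    @classmethod
    def from_label(cls, label: str) -> "MutationContext":
        m = _LABEL_RE.match(label)
        if m is None:
            raise ValueError(f"not a valid SBS96 context label: {label!r}")
        flank5, ref, alt, flank3 = m.groups()
        sub = f"{ref}>{alt}"
        if sub not in SUBSTITUTIONS:
            raise ValueError(f"not a valid SBS96 context label: {label!r}")
        return cls(substitution=sub, flank5=flank5, flank3=flank3)

    def __str__(self) -> str:
        return self.label


@lru_cache(maxsize=1)
def enumerate_contexts() -> tuple[MutationContext, ...]:
    """Return the 96 contexts in canonical order.

    Ordering is substitution-class major (C>A, C>G, C>T, T>A, T>C, T>G),
    then 5' flank, then 3' flank, flanks ordered A < C < G < T.  The first
    context is ``A[C>A]A`` and the last is ``T[T>G]T``.
    """
    return tuple(
        MutationContext(substitution=sub, flank5=f5, flank3=f3)
        for sub in SUBSTITUTIONS
        for f5 in BASES
        for f3 in BASES
    )


@lru_cache(maxsize=1)
def context_labels() -> tuple[str, ...]:
    """The 96 canonical context labels, in canonical order."""
    return tuple(c.label for c in enumerate_contexts())


def context_index(label: str) -> int:
    """Position of a context label in the canonical order (0-based)."""
    try:
        return context_labels().index(label)
    except ValueError:
        raise KeyError(f"unknown SBS96 context label: {label!r}") from None
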