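"""Risk-factor patterns: the conditioning sets the incidence analysis works on.

A :class:`FactorPattern` names 0-3 of the eight risk factors together with its
conditioning semantics:

``marginal``
    condition on the named factors being positive, leaving the remaining
    factors unconstrained (the per-combination network view);
``exact``
    condition on the full 8-factor configuration — named factors positive,
    every other factor negative.  The crude no-factor baseline is the exact
    empty pattern.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .factors import FACTORS, canonical_sort

SEMANTICS = ("marginal", "exact")


@dataclass(frozen=True)
class FactorPattern:
    """A subset of the eight risk factors plus conditioning semantics."""

    positive_factors: tuple[str, ...]
    semantics: str = "marginal"

    def __init__(self, positive_factors=(), semantics: str = "marginal"):
        factors = tuple(canonical_sort(positive_factors))
        if semantics not in SEMANTICS:
            raise ValueError(f"semantics must be one of {SEMANTICS}, got {semantics!r}")
        object.__setattr__(self, "positive_factors", factors)
        object.__setattr__(self, "semantics", semantics)

    @property
    def k(self) -> int:
        return len(self.positive_factors)

    def label(self) -> str:
        """Stable text form, e.g. ``hypertension;smoking``; empty pattern -> ``(none)``."""
        return ";".join(self.positive_factors) if self.positive_factors else "(none)"

    @classmethod
    def from_label(cls, label: str, semantics: str = "marginal") -> "FactorPattern":
        label = label.strip()
        if label in ("", "(none)"):
            return cls((), semantics)
        return cls(tuple(p.strip() for p in label.split(";")), semantics)

    def mask(self) -> tuple[bool, ...]:
        """Boolean vector over the canonical factor order (named factors True)."""
        pos = set(self.positive_factors)
        return tuple(f in pos for f in FACTORS)


def enumerate_patterns(k: int, semantics: str = "marginal") -> list[FactorPattern]:
    """All size-``k`` factor combinations in canonical (lexicographic) order.

    k=1, 2, 3 give the 8, 28 and 56 combinations the analysis evaluates.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    return [FactorPattern(combo, semantics) for combo in itertools.combinations(FACTORS, k)]
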