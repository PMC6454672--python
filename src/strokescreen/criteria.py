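"""Screening-criteria derivation from combination-conditional incidence tables.

The screening program flags a person "potential high-risk" when they carry
three or more of the eight risk factors.  The incidence tables show that
several single factors and two-factor combinations carry a higher conditional
incidence than many three-factor combinations, so a count-based rule misses
high-risk people.  The remedy analysed here is a *variable threshold*: the
ratio of a combination's conditional incidence to the no-factor baseline
(0.0070 over 4 years).  Combinations whose ratio reaches the threshold become
preliminary-screening criteria; lowering the threshold trades screening cost
for sensitivity.

The module operates on complete incidence tables — one entry per enumerated
combination of size k, with combinations absent from a source table
represented as explicit zeros — either freshly estimated or loaded from the
packaged reference tables (``load_reference_tables``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .patterns import FactorPattern, enumerate_patterns


@dataclass
class IncidenceTable:
    """Complete size-k incidence table: one probability per factor combination."""

    k: int
    entries: dict[FactorPattern, float]
    baseline: float
    ci: dict[FactorPattern, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for pattern, p in self.entries.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {pattern.label()} out of [0,1]: {p}")
        if self.baseline <= 0.0:
            raise ValueError(f"baseline incidence must be > 0, got {self.baseline}")

    def _complete_patterns(self) -> list[FactorPattern]:
        expected = enumerate_patterns(self.k)
        have = {p.positive_factors for p in self.entries}
        missing = [p for p in expected if p.positive_factors not in have]
        if missing:
            raise ValueError(
                f"incidence table for k={self.k} is incomplete; missing: "
                + ", ".join(p.label() for p in missing)
            )
        return expected

    def value(self, pattern: FactorPattern) -> float:
        for p, v in self.entries.items():
            if p.positive_factors == pattern.positive_factors:
                return v
        raise KeyError(pattern.label())

    @classmethod
    def from_partial(cls, k: int, nonzero: dict[FactorPattern, float], baseline: float) -> "IncidenceTable":
        """Build a complete table from the non-zero rows of a printed table (rest = 0)."""
        have = {p.positive_factors for p in nonzero}
        entries = dict(nonzero)
        for p in enumerate_patterns(k):
            if p.positive_factors not in have:
                entries[p] = 0.0
        return cls(k=k, entries=entries, baseline=baseline)


def incidence_ratio(p: float, baseline: float) -> float:
    """Ratio of a combination's incidence to the no-factor baseline ("X times higher")."""
    if baseline <= 0.0:
        raise ValueError(f"baseline incidence must be > 0, got {baseline}")
    return p / baseline


def count_nonzero(table: IncidenceTable) -> tuple[int, int]:
    """(number of combinations with non-zero incidence, total enumerated)."""
    patterns = table._complete_patterns()
    nonzero = sum(1 for p in table.entries.values() if p > 0.0)
    return nonzero, len(patterns)


def median_incidence(table: IncidenceTable) -> tuple[float, FactorPattern | None]:
    """Zero-inclusive median of the table (upper-middle element for even totals).

    All C(8,k) values — explicit zeros included — are sorted ascending and the
    element at 1-based position n//2 + 1 is taken for even n (the exact middle
    for odd n).  This upper-middle convention is the one consistent with the
    reference tables' printed medians; the average-of-middle-two convention is
    not.  Returns the value and, when non-zero, its pattern.
    """
    table._complete_patterns()
    items = sorted(table.entries.items(), key=lambda kv: (kv[1],) + kv[0].positive_factors)
    n = len(items)
    pos = n // 2 if n % 2 == 0 else (n - 1) // 2  # 0-based upper-middle
    pattern, value = items[pos]
    return value, (pattern if value > 0 else None)


@dataclass
class CriteriaSet:
    """Threshold-derived preliminary-screening criteria.

    ``singles``/``pairs``/``triples`` hold the patterns whose incidence ratio
    reaches ``threshold`` (descending incidence).  When a ``reference_threshold``
    is given, ``newly_added_pairs`` are the pairs meeting ``threshold`` but not
    the reference (pairs at the reference level count as already proposed),
    while ``newly_added_singles`` are *all* qualifying singles — the program's
    existing count-based criteria contain every triple but no single factor,
    so no single is ever "already covered".
    """

    threshold: float
    singles: list[FactorPattern] = field(default_factory=list)
    pairs: list[FactorPattern] = field(default_factory=list)
    triples: list[FactorPattern] = field(default_factory=list)
    reference_threshold: float | None = None
    newly_added_pairs: list[FactorPattern] = field(default_factory=list)
    newly_added_singles: list[FactorPattern] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "threshold": self.threshold,
            "singles": [p.label() for p in self.singles],
            "pairs": [p.label() for p in self.pairs],
            "triples": [p.label() for p in self.triples],
        }
        if self.reference_threshold is not None:
            d["reference_threshold"] = self.reference_threshold
            d["newly_added_pairs"] = [p.label() for p in self.newly_added_pairs]
            d["newly_added_singles"] = [p.label() for p in self.newly_added_singles]
        return d

    def to_markdown(self) -> str:
        lines = [f"# Preliminary-screening criteria (incidence ratio >= {self.threshold})", ""]
        for name, pats in (("Single factors", self.singles), ("Two-factor combinations", self.pairs),
                           ("Three-factor combinations", self.triples)):
            lines.append(f"## {name}")
            lines += [f"- {p.label()}" for p in pats] or ["- (none)"]
            lines.append("")
        if self.reference_threshold is not None:
            lines.append(f"## Newly added vs reference threshold {self.reference_threshold}")
            lines += [f"- pair: {p.label()}" for p in self.newly_added_pairs]
            lines += [f"- single: {p.label()}" for p in self.newly_added_singles]
            lines.append("")
        return "\n".join(lines)


def _members(table: IncidenceTable, threshold: float) -> list[FactorPattern]:
    """Patterns whose ratio reaches the threshold, descending incidence, canonical ties."""
    table._complete_patterns()
    order = {p.positive_factors: i for i, p in enumerate(enumerate_patterns(table.k))}
    qualifying = [
        (v, order[p.positive_factors], p)
        for p, v in table.entries.items()
        if v > 0.0 and incidence_ratio(v, table.baseline) >= threshold
    ]
    qualifying.sort(key=lambda t: (-t[0], t[1]))
    return [p for _, _, p in qualifying]


def derive_criteria(tables: dict[int, IncidenceTable], threshold: float,
                    reference_threshold: float | None = None) -> CriteriaSet:
    """Derive threshold-based criteria from complete k=1,2,3 incidence tables."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if reference_threshold is not None and reference_threshold < threshold:
        raise ValueError("reference_threshold must be >= threshold")
    singles = _members(tables[1], threshold) if 1 in tables else []
    pairs = _members(tables[2], threshold) if 2 in tables else []
    triples = _members(tables[3], threshold) if 3 in tables else []
    cs = CriteriaSet(threshold=threshold, singles=singles, pairs=pairs, triples=triples,
                     reference_threshold=reference_threshold)
    if reference_threshold is not None:
        ref_pairs = {p.positive_factors for p in _members(tables[2], reference_threshold)} if 2 in tables else set()
        cs.newly_added_pairs = [p for p in pairs if p.positive_factors not in ref_pairs]
        cs.newly_added_singles = list(singles)
    return cs


# -- packaged reference tables ---------------------------------------------

def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("strokescreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_baseline() -> float:
    """The packaged crude no-factor 4-year incidence (0.0070)."""
    return float(resources.files("strokescreen.data").joinpath("baseline.txt").read_text().strip())


def load_reference_tables() -> dict[int, IncidenceTable]:
    """The packaged k=1,2,3 incidence tables, zero-completed, keyed by k."""
    baseline = load_baseline()
    out: dict[int, IncidenceTable] = {}
    for k, name in ((1, "table2.csv"), (2, "table3.csv"), (3, "table4.csv")):
        df = _read_packaged(name)
        nonzero = {FactorPattern.from_label(r.factors): float(r.probability) for r in df.itertuples()}
        out[k] = IncidenceTable.from_partial(k, nonzero, baseline)
    return out


def table_from_estimates(estimates: pd.DataFrame, k: int, baseline: float,
                         value_column: str = "point") -> IncidenceTable:
    """Build a complete IncidenceTable from an ``estimate_table`` DataFrame."""
    sub = estimates[estimates["k"] == k]
    entries = {FactorPattern.from_label(r.factors): float(getattr(r, value_column)) for r in sub.itertuples()}
    return IncidenceTable.from_partial(k, entries, baseline)
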