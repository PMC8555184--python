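"""Directional capped component indices and the IRDP/IRPCDU composites.

Each WHO/INRUD indicator is converted into a unitless component index
against a single WHO optimal point:

* lower-is-better indicators (medicines per encounter, antibiotic %,
  injection %): ``optimal / observed``;
* higher-is-better indicators (generic %, EML %, dispensed %, labelled %):
  ``observed / optimal``;

capped at 1.0 — performing at or better than the optimal scores exactly 1.
The Index of Rational Drug Prescribing (IRDP, range 0–5) is the sum of the
five prescribing component indices; the Index of Rational Patient-Care
Drug Use (IRPCDU, range 0–2) sums the dispensed and labelled indices.

Rounding convention
-------------------
Published index tables are computed from indicator values at their printed
precision (one decimal place); each component is rounded half-to-even to
two decimals, and the composites sum the *rounded* components.  That is
the default (``mode="printed"``), and it reproduces published tables cell
for cell.  ``mode="raw"`` keeps full precision throughout for new
analyses; only the final composite is then rounded for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Mapping

import pandas as pd

from .indicators import (IndicatorSet, StratifiedIndicators, WHO_RANGES,
                         round_half_even)

#: Direction of each indicator: ``lower`` means a smaller observed value is
#: better (the ratio is optimal/observed), ``higher`` the reverse.
DIRECTIONS: dict[str, str] = {
    "medicines_per_encounter": "lower",
    "pct_antibiotic": "lower",
    "pct_injection": "lower",
    "pct_generic": "higher",
    "pct_eml": "higher",
    "pct_dispensed": "higher",
    "pct_labelled": "higher",
}

#: Single optimal points used in index computation: midpoints of the WHO
#: ranges for the bounded indicators, 100 for the rest.
DEFAULT_OPTIMAL_POINTS: dict[str, float] = {
    "medicines_per_encounter": 1.7,
    "pct_antibiotic": 23.4,
    "pct_injection": 18.75,
    "pct_generic": 100.0,
    "pct_eml": 100.0,
    "pct_dispensed": 100.0,
    "pct_labelled": 100.0,
}

PRESCRIBING_COMPONENTS = ("idx_non_polypharmacy", "idx_rational_antibiotic",
                          "idx_safe_injection", "idx_generic", "idx_eml")
PATIENT_CARE_COMPONENTS = ("idx_dispensed", "idx_labelled")

#: component name -> indicator it is built from
COMPONENT_SOURCE: dict[str, str] = {
    "idx_non_polypharmacy": "medicines_per_encounter",
    "idx_rational_antibiotic": "pct_antibiotic",
    "idx_safe_injection": "pct_injection",
    "idx_generic": "pct_generic",
    "idx_eml": "pct_eml",
    "idx_dispensed": "pct_dispensed",
    "idx_labelled": "pct_labelled",
}


@dataclass
class OptimalValues:
    """WHO reference ranges and the single optimal points used for indices."""

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(WHO_RANGES))
    points: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OPTIMAL_POINTS))

    def __post_init__(self) -> None:
        for ind, pt in self.points.items():
            if pt <= 0:
                raise ValueError(f"optimal point for {ind} must be positive")
            lo, hi = self.ranges.get(ind, (pt, pt))
            if not lo <= pt <= hi:
                raise ValueError(
                    f"optimal point {pt} for {ind} outside range [{lo}, {hi}]")


def _quantize(x: Decimal, places: int) -> Decimal:
    return x.quantize(Decimal(1).scaleb(-places), rounding=ROUND_HALF_EVEN)


def component_index(observed: float, optimal_point: float, direction: str,
                    mode: str = "printed") -> float:
    """One directional capped component index.

    ``direction`` is ``"lower"`` (ratio optimal/observed) or ``"higher"``
    (observed/optimal); results better than optimal are capped at 1.0.  An
    observed value of 0 under ``lower`` is better than optimal and scores
    1.0 rather than raising.  In ``printed`` mode the observed value is
    taken at one decimal place and the index rounded half-even to two.
    """
    if direction not in ("lower", "higher"):
        raise ValueError(f"direction must be 'lower' or 'higher', "
                         f"got {direction!r}")
    if optimal_point <= 0:
        raise ValueError("optimal_point must be positive")
    if observed < 0:
        raise ValueError("observed must be non-negative")
    opt = Decimal(repr(float(optimal_point)))
    obs = Decimal(repr(float(observed)))
    if mode == "printed":
        obs = _quantize(obs, 1)
    elif mode != "raw":
        raise ValueError(f"mode must be 'printed' or 'raw', got {mode!r}")
    if direction == "lower":
        if obs == 0:
            return 1.0  # no events at all: better than the optimal target
        ratio = opt / obs
    else:
        ratio = obs / opt
    ratio = min(ratio, Decimal(1))
    if mode == "printed":
        return float(_quantize(ratio, 2))
    return float(ratio)


@dataclass
class IndexSet:
    """Component indices and composites for one stratum.

    Any component may be None when its source indicator was undefined;
    the IndexSet is then incomplete and its composites are None.
    """

    idx_non_polypharmacy: float | None = None
    idx_rational_antibiotic: float | None = None
    idx_safe_injection: float | None = None
    idx_generic: float | None = None
    idx_eml: float | None = None
    idx_dispensed: float | None = None
    idx_labelled: float | None = None

    @property
    def complete(self) -> bool:
        return all(getattr(self, c) is not None
                   for c in (*PRESCRIBING_COMPONENTS, *PATIENT_CARE_COMPONENTS))

    @property
    def irdp(self) -> float | None:
        try:
            return irdp({c: getattr(self, c) for c in PRESCRIBING_COMPONENTS})
        except KeyError:
            return None

    @property
    def irpcdu(self) -> float | None:
        try:
            return irpcdu({c: getattr(self, c)
                           for c in PATIENT_CARE_COMPONENTS})
        except KeyError:
            return None


def _sum_components(components: Mapping[str, float | None],
                    names: tuple[str, ...]) -> float:
    total = Decimal(0)
    for name in names:
        v = components.get(name)
        if v is None:
            raise KeyError(f"missing component index: {name}")
        total += Decimal(repr(float(v)))
    return float(_quantize(total, 2))


def irdp(components: Mapping[str, float | None]) -> float:
    """Index of Rational Drug Prescribing: sum of the five prescribing
    component indices (range 0–5; 5 = fully rational prescribing)."""
    return _sum_components(components, PRESCRIBING_COMPONENTS)


def irpcdu(components: Mapping[str, float | None]) -> float:
    """Index of Rational Patient-Care Drug Use: sum of the dispensed and
    labelled component indices (range 0–2)."""
    return _sum_components(components, PATIENT_CARE_COMPONENTS)


def index_set_from_observed(observed: Mapping[str, float | None],
                            optimal: OptimalValues | None = None,
                            mode: str = "printed") -> IndexSet:
    """IndexSet from the seven observed indicator values (keys as in
    :data:`DIRECTIONS`); missing/None indicators leave their component
    None."""
    optimal = optimal or OptimalValues()
    kwargs: dict[str, float | None] = {}
    for comp, ind in COMPONENT_SOURCE.items():
        obs = observed.get(ind)
        kwargs[comp] = (None if obs is None else component_index(
            obs, optimal.points[ind], DIRECTIONS[ind], mode))
    return IndexSet(**kwargs)


def index_table(strat: StratifiedIndicators | Mapping[str, IndicatorSet
                                                      | Mapping[str, float]],
                optimal: OptimalValues | None = None,
                mode: str = "printed") -> dict[str, IndexSet]:
    """Per-group IndexSet for stratified indicators.

    Accepts a :class:`StratifiedIndicators` (the overall stratum appears
    under ``"overall"``) or any mapping group -> IndicatorSet / observed
    values.  Groups with undefined indicators yield incomplete IndexSets
    (their composites are None) rather than failing the whole table.
    """
    if isinstance(strat, StratifiedIndicators):
        items: dict[str, IndicatorSet | Mapping[str, float]] = {
            "overall": strat.overall, **strat.groups}
    else:
        items = dict(strat)
    out: dict[str, IndexSet] = {}
    for group, iset in items.items():
        obs = (iset.observed_values() if isinstance(iset, IndicatorSet)
               else dict(iset))
        out[group] = index_set_from_observed(obs, optimal, mode)
    return out


# --------------------------------------------------------------------------
# Output
# --------------------------------------------------------------------------

def indices_to_frame(table: Mapping[str, IndexSet],
                     observed: Mapping[str, Mapping[str, float | None]]
                     | None = None,
                     optimal: OptimalValues | None = None) -> pd.DataFrame:
    """Tidy table: group, index_name, observed, optimal, direction, index."""
    optimal = optimal or OptimalValues()
    rows = []
    for group, iset in table.items():
        for comp, ind in COMPONENT_SOURCE.items():
            rows.append({
                "group": group,
                "index_name": comp,
                "observed": (observed or {}).get(group, {}).get(ind),
                "optimal": optimal.points[ind],
                "direction": DIRECTIONS[ind],
                "index": getattr(iset, comp),
            })
        for agg in ("irdp", "irpcdu"):
            rows.append({"group": group, "index_name": agg, "observed": None,
                         "optimal": None, "direction": None,
                         "index": getattr(iset, agg)})
    return pd.DataFrame(rows)


_INDEX_LABELS = {
    "idx_non_polypharmacy": "1. Index of non-polypharmacy",
    "idx_rational_antibiotic": "2. Index of rational antibiotic use",
    "idx_safe_injection": "3. Index of safe injection use",
    "idx_generic": "4. Index of generic prescribing",
    "idx_eml": "5. Index of EML prescribing",
    "idx_dispensed": "1. Index of actually dispensed drugs",
    "idx_labelled": "2. Index of labeling of drugs",
}


def render_index_table(table: Mapping[str, IndexSet]) -> str:
    """Markdown rendering of component indices and composites per group."""
    from .indicators import _markdown_table

    groups = list(table)
    def row(label, getter):
        cells = []
        for g in groups:
            v = getter(table[g])
            cells.append("—" if v is None else f"{v:.2f}")
        return [label] + cells

    rows = [row(_INDEX_LABELS[c], lambda s, c=c: getattr(s, c))
            for c in PRESCRIBING_COMPONENTS]
    rows.append(row("Index of rational drug prescribing (1+2+3+4+5)",
                    lambda s: s.irdp))
    rows += [row(_INDEX_LABELS[c], lambda s, c=c: getattr(s, c))
             for c in PATIENT_CARE_COMPONENTS]
    rows.append(row("Index of Rational Patient-Care Drug Use (1+2)",
                    lambda s: s.irpcdu))
    return _markdown_table(["Index"] + groups, rows)
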