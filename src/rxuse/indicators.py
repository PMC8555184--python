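"""WHO/INRUD core drug use indicators.

Prescribing indicators (per stratum of encounters):

* average number of (different) medicines per encounter,
* % of encounters with an antibiotic,
* % of encounters with an injection,
* % of medicines prescribed by generic name,
* % of medicines prescribed from the Essential Medicines List (EML);

patient-care indicators:

* % of prescribed medicines actually dispensed (brand substitution counts
  as dispensed),
* % of dispensed medicines accurately labelled — note the denominator is
  *dispensed*, not prescribed, medicines.

Also: the polypharmacy rate (encounters at or above a medicine-count
threshold) and the ranking of most-prescribed medicines.  All operations
accept any stratum (overall, per pharmacy category, per district) and
carry their numerators/denominators so stratified results can be checked
for conservation against the overall ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import Encounter, SurveyDataset

#: WHO recommended reference ranges, as printed in survey reports.
WHO_RANGES: dict[str, tuple[float, float]] = {
    "medicines_per_encounter": (1.6, 1.8),
    "pct_antibiotic": (20.0, 26.8),
    "pct_injection": (13.4, 24.1),
    "pct_generic": (100.0, 100.0),
    "pct_eml": (100.0, 100.0),
    "pct_dispensed": (100.0, 100.0),
    "pct_labelled": (100.0, 100.0),
}

STRATIFY_KEYS = ("overall", "pharmacy_category", "district")


class EmptyStratumError(ValueError):
    """An indicator was requested on a stratum with no data."""


def round_half_even(x: float, places: int) -> float:
    """Decimal round-half-even at the printed precision of survey tables."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


def medicine_count(enc: Encounter, dedupe: bool = True) -> int:
    """Number of medicines on one encounter.

    With ``dedupe`` (the default) duplicate entries of the same medicine
    entity count once, matching the "different medicines prescribed"
    wording of the indicator; ``dedupe=False`` counts raw rows.
    """
    if dedupe:
        return len({m.entity_key for m in enc.medicines})
    return len(enc.medicines)


@dataclass
class DispersionSummary:
    mean: float
    sd: float
    median: float
    min: int
    max: int

    def __str__(self) -> str:  # "3.1 ± 1.9 (3; 1–12)"
        return (f"{self.mean:.1f} ± {self.sd:.1f} "
                f"({self.median:g}; {self.min}–{self.max})")


@dataclass
class IndicatorSet:
    """The seven indicator values with their backing counts for one stratum."""

    n_encounters: int
    n_medicines: int          # all prescribed medicine rows (denominator)
    avg_medicines: DispersionSummary | None
    counts: dict[str, int] = field(default_factory=dict)
    # counts keys: antibiotic, injection (encounter events);
    #              generic, eml, dispensed, labelled (medicine events)

    def _pct(self, num_key: str, denom: int) -> float | None:
        if denom == 0:
            return None  # undefined indicator: explicit missing, never zero
        return 100.0 * self.counts[num_key] / denom

    @property
    def pct_antibiotic(self) -> float | None:
        return self._pct("antibiotic", self.n_encounters)

    @property
    def pct_injection(self) -> float | None:
        return self._pct("injection", self.n_encounters)

    @property
    def pct_generic(self) -> float | None:
        return self._pct("generic", self.n_medicines)

    @property
    def pct_eml(self) -> float | None:
        return self._pct("eml", self.n_medicines)

    @property
    def pct_dispensed(self) -> float | None:
        return self._pct("dispensed", self.n_medicines)

    @property
    def pct_labelled(self) -> float | None:
        # denominator: dispensed medicines only
        return self._pct("labelled", self.counts.get("dispensed", 0))

    def observed_values(self) -> dict[str, float | None]:
        """The seven indicator values keyed by canonical indicator name."""
        return {
            "medicines_per_encounter": (self.avg_medicines.mean
                                        if self.avg_medicines else None),
            "pct_antibiotic": self.pct_antibiotic,
            "pct_injection": self.pct_injection,
            "pct_generic": self.pct_generic,
            "pct_eml": self.pct_eml,
            "pct_dispensed": self.pct_dispensed,
            "pct_labelled": self.pct_labelled,
        }

    def __post_init__(self) -> None:
        for key in ("antibiotic", "injection"):
            if self.counts.get(key, 0) > self.n_encounters:
                raise ValueError(f"{key} numerator exceeds encounter count")
        for key in ("generic", "eml", "dispensed"):
            if self.counts.get(key, 0) > self.n_medicines:
                raise ValueError(f"{key} numerator exceeds medicine count")
        if self.counts.get("labelled", 0) > self.counts.get("dispensed", 0):
            raise ValueError("labelled numerator exceeds dispensed numerator")

    @classmethod
    def from_counts(cls, n_encounters: int, n_medicines: int,
                    counts: Mapping[str, int],
                    avg: DispersionSummary | None = None) -> "IndicatorSet":
        """Build directly from printed/reported counts (aggregate use)."""
        return cls(n_encounters=n_encounters, n_medicines=n_medicines,
                   avg_medicines=avg, counts=dict(counts))


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def _require_nonempty(encounters: Sequence[Encounter]) -> None:
    if not encounters:
        raise EmptyStratumError("stratum contains no encounters")


def avg_medicines_per_encounter(encounters: Sequence[Encounter],
                                dedupe: bool = True) -> DispersionSummary:
    """Mean/SD/median/range of medicines per encounter in a stratum.

    SD is the sample SD (ddof=1); by convention 0.0 for a single
    encounter.
    """
    _require_nonempty(encounters)
    counts = np.array([medicine_count(e, dedupe) for e in encounters])
    sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return DispersionSummary(mean=float(counts.mean()), sd=sd,
                             median=float(np.median(counts)),
                             min=int(counts.min()), max=int(counts.max()))


def pct_encounters_with(event: str, encounters: Sequence[Encounter],
                        ) -> tuple[float, int]:
    """(% of encounters with >=1 flagged medicine, numerator).

    ``event`` is ``"antibiotic"`` or ``"injection"``.  An encounter with
    several flagged medicines counts once.
    """
    _require_nonempty(encounters)
    attr = {"antibiotic": "is_antibiotic", "injection": "is_injection"}[event]
    num = sum(any(getattr(m, attr) for m in e.medicines) for e in encounters)
    return 100.0 * num / len(encounters), num


def pct_medicines_with(event: str, encounters: Sequence[Encounter],
                       ) -> tuple[float, int]:
    """(% of all prescribed medicines with the event, numerator).

    ``event`` is ``"generic"``, ``"eml"`` or ``"dispensed"``; the
    denominator is every prescribed medicine in the stratum.
    """
    attr = {"generic": "prescribed_by_generic", "eml": "on_eml",
            "dispensed": "dispensed"}[event]
    meds = [m for e in encounters for m in e.medicines]
    if not meds:
        raise EmptyStratumError("stratum contains no medicines")
    num = sum(bool(getattr(m, attr)) for m in meds)
    return 100.0 * num / len(meds), num


def pct_labelled(encounters: Sequence[Encounter],
                 ) -> tuple[float | None, int]:
    """(% of *dispensed* medicines accurately labelled, numerator).

    Returns (None, 0) when no medicine was dispensed — the indicator is
    undefined there, not zero.
    """
    meds = [m for e in encounters for m in e.medicines]
    dispensed = [m for m in meds if m.dispensed]
    num = sum(bool(m.labelled) for m in dispensed)
    if not dispensed:
        return None, num
    return 100.0 * num / len(dispensed), num


def polypharmacy_rate(encounters: Sequence[Encounter], threshold: int = 4,
                      strict: bool = False, dedupe: bool = True) -> float:
    """% of encounters with >= ``threshold`` medicines (> with ``strict``)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    _require_nonempty(encounters)
    if strict:
        num = sum(medicine_count(e, dedupe) > threshold for e in encounters)
    else:
        num = sum(medicine_count(e, dedupe) >= threshold for e in encounters)
    return 100.0 * num / len(encounters)


def top_medicines(encounters: Sequence[Encounter], n: int = 10,
                  ) -> list[tuple[str, int, float]]:
    """Ranked (generic_name, count, % of all medicines) — count descending,
    ties broken alphabetically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    meds = [m.entity_key for e in encounters for m in e.medicines]
    if not meds:
        return []
    counts: dict[str, int] = {}
    for name in meds:
        counts[name] = counts.get(name, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    total = len(meds)
    return [(name, c, 100.0 * c / total) for name, c in ranked]


def compute_indicator_set(encounters: Sequence[Encounter],
                          dedupe: bool = True) -> IndicatorSet:
    """All seven indicators with counts for one stratum."""
    _require_nonempty(encounters)
    avg = avg_medicines_per_encounter(encounters, dedupe)
    _, n_ab = pct_encounters_with("antibiotic", encounters)
    _, n_inj = pct_encounters_with("injection", encounters)
    _, n_gen = pct_medicines_with("generic", encounters)
    _, n_eml = pct_medicines_with("eml", encounters)
    _, n_disp = pct_medicines_with("dispensed", encounters)
    _, n_lab = pct_labelled(encounters)
    return IndicatorSet(
        n_encounters=len(encounters),
        n_medicines=sum(e.n_medicines for e in encounters),
        avg_medicines=avg,
        counts={"antibiotic": n_ab, "injection": n_inj, "generic": n_gen,
                "eml": n_eml, "dispensed": n_disp, "labelled": n_lab},
    )


@dataclass
class StratifiedIndicators:
    """Overall indicators plus one IndicatorSet per group of a key."""

    key: str
    overall: IndicatorSet
    groups: dict[str, IndicatorSet] = field(default_factory=dict)


def stratify(dataset: SurveyDataset, key: str = "overall",
             dedupe: bool = True) -> StratifiedIndicators:
    """Indicators per group of ``key`` plus the overall stratum.

    ``key`` is one of ``overall``, ``pharmacy_category``, ``district``.
    Group numerators and denominators sum to the overall ones.
    """
    if key not in STRATIFY_KEYS:
        raise ValueError(f"unknown stratification key {key!r}; "
                         f"accepted: {', '.join(STRATIFY_KEYS)}")
    overall = compute_indicator_set(dataset.encounters, dedupe)
    groups: dict[str, IndicatorSet] = {}
    if key != "overall":
        by_group: dict[str, list[Encounter]] = {}
        for enc in dataset.encounters:
            by_group.setdefault(getattr(enc, key), []).append(enc)
        groups = {g: compute_indicator_set(encs, dedupe)
                  for g, encs in sorted(by_group.items())}
    return StratifiedIndicators(key=key, overall=overall, groups=groups)


def encounter_counts_by_group(dataset: SurveyDataset, key: str,
                              dedupe: bool = True) -> dict[str, np.ndarray]:
    """Per-encounter medicine counts split by group (for mean comparisons)."""
    out: dict[str, list[int]] = {}
    for enc in dataset.encounters:
        out.setdefault(getattr(enc, key), []).append(
            medicine_count(enc, dedupe))
    return {g: np.array(v) for g, v in sorted(out.items())}


# --------------------------------------------------------------------------
# Output
# --------------------------------------------------------------------------

_TIDY_ROWS = (
    ("medicines_per_encounter", None, "n_encounters"),
    ("pct_antibiotic", "antibiotic", "n_encounters"),
    ("pct_injection", "injection", "n_encounters"),
    ("pct_generic", "generic", "n_medicines"),
    ("pct_eml", "eml", "n_medicines"),
    ("pct_dispensed", "dispensed", "n_medicines"),
    ("pct_labelled", "labelled", "dispensed"),
)


def indicators_to_frame(strat: StratifiedIndicators) -> pd.DataFrame:
    """Tidy table: stratum, group, indicator, numerator, denominator, value."""
    rows = []
    items = [("overall", strat.overall)] + list(strat.groups.items())
    for group, iset in items:
        obs = iset.observed_values()
        for ind, num_key, den_key in _TIDY_ROWS:
            if den_key == "dispensed":
                denom = iset.counts.get("dispensed", 0)
            else:
                denom = getattr(iset, den_key)
            rows.append({
                "stratum": strat.key,
                "group": group,
                "indicator": ind,
                "numerator": (iset.counts.get(num_key, "")
                              if num_key else iset.n_medicines),
                "denominator": denom,
                "value": obs[ind],
            })
    return pd.DataFrame(rows)


_PRETTY = {
    "medicines_per_encounter": "Average medicines per encounter",
    "pct_antibiotic": "Encounters with an antibiotic (%)",
    "pct_injection": "Encounters with an injection (%)",
    "pct_generic": "Medicines prescribed in generic name (%)",
    "pct_eml": "Medicines prescribed from EML (%)",
    "pct_dispensed": "Medicines actually dispensed (%)",
    "pct_labelled": "Medicines accurately labelled (%)",
}


def _markdown_table(header: list[str], rows: list[list[str]]) -> str:
    widths = [max(len(str(r[i])) for r in [header] + rows)
              for i in range(len(header))]
    def fmt(row):
        return "| " + " | ".join(str(c).ljust(w)
                                 for c, w in zip(row, widths)) + " |"
    sep = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
    return "\n".join([fmt(header), sep] + [fmt(r) for r in rows])


def render_indicator_table(strat: StratifiedIndicators,
                           marks: Mapping[str, Mapping[str, str]] | None = None,
                           ) -> str:
    """Survey-report-style markdown table with WHO ranges in the headers.

    ``marks`` optionally carries significance symbols per indicator/group
    (groups sharing a symbol in a row differ significantly).
    """
    marks = marks or {}
    cols = ["overall"] + list(strat.groups)
    items = {"overall": strat.overall, **strat.groups}
    header = ["Indicator (WHO reference)"] + cols
    rows = []
    for ind, num_key, _ in _TIDY_ROWS:
        lo, hi = WHO_RANGES[ind]
        ref = f"{lo:g}" if lo == hi else f"{lo:g}–{hi:g}"
        row = [f"{_PRETTY[ind]} ({ref})"]
        for g in cols:
            iset = items[g]
            sym = marks.get(ind, {}).get(g, "")
            if ind == "medicines_per_encounter":
                cell = str(iset.avg_medicines) if iset.avg_medicines else "—"
            else:
                v = iset.observed_values()[ind]
                num = iset.counts.get(num_key, "")
                cell = ("—" if v is None
                        else f"{num} ({round_half_even(v, 1):.1f})")
            row.append(cell + (f" {sym}" if sym else ""))
        rows.append(row)
    counts_row = ["Encounters surveyed (n)"] + [
        str(items[g].n_encounters) for g in cols]
    return _markdown_table(header, [counts_row] + rows)
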