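"""Seeded synthetic prescription-survey generator.

Real raw survey data of this kind (prescription-level records from retail
pharmacies) are rarely deposited, so this module generates datasets with
the same sampling architecture and marginal rates the analysis assumes:

* survey areas allocated per WHO/HAI survey methodology — each area covers
  at least 100,000 population (under-sized districts merge with a declared
  neighbour), areas above one million population contribute two sample
  sets, and each set contains one outlet per pharmacy category available
  in that area;
* 30 consecutive prescriptions per outlet;
* per-encounter medicine counts from a shifted negative-binomial
  distribution truncated to [1, 12] and moment-matched to mean 3.1,
  SD 1.9;
* encounter-level antibiotic (23.8%) and injection (1.2%) events, pushed
  down onto one medicine of the encounter;
* per-medicine Bernoulli flags for generic-name prescribing (35.5%), EML
  membership (68.8%), dispensing (92.4%) and labelling given dispensing
  (98.5%);
* an exact, uniformly placed 3% of encounters corrupted with one
  completeness violation each, so the intake filter has work to do.

Identical seed and configuration give byte-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .data_model import (CATEGORIES, Encounter, MedicineRecord, ReferenceLists,
                         SurveyDataset)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Default fixtures
# --------------------------------------------------------------------------

#: Commonly prescribed generic medicines with sampling weights roughly
#: proportional to observed prescription shares in Sri Lankan retail
#: pharmacies, plus their classification used when emitting datasets.
#: Columns: (generic name, weight, is_antibiotic, on_eml-eligible form).
DEFAULT_MEDICINE_TABLE: tuple[tuple[str, float], ...] = (
    ("atorvastatin", 3.9), ("losartan", 3.2), ("metformin", 3.0),
    ("paracetamol", 2.7), ("omeprazole", 2.6), ("aspirin", 2.5),
    ("domperidone", 2.0), ("clopidogrel", 1.8), ("cetirizine", 1.6),
    ("gliclazide", 1.5), ("co-amoxyclav", 1.5), ("amoxycillin", 1.3),
    ("salbutamol", 1.2), ("prednisolone", 1.1), ("enalapril", 1.1),
    ("metoprolol", 1.0), ("insulin", 0.9), ("azithromycin", 0.8),
    ("frusemide", 0.8), ("amlodipine", 0.8), ("ranitidine", 0.7),
    ("ciprofloxacin", 0.7), ("ibuprofen", 0.7), ("chlorpheniramine", 0.6),
    ("vitamin c", 0.5),
)

#: Antibiotic entities within the default table.
DEFAULT_ANTIBIOTICS: frozenset[str] = frozenset(
    {"co-amoxyclav", "amoxycillin", "azithromycin", "ciprofloxacin"})

#: Brand aliases used when a generated medicine is *not* prescribed by
#: generic name; the reverse map feeds the default brand->generic list.
DEFAULT_BRAND_ALIASES: dict[str, str] = {
    "atorvastatin": "Atorwin", "losartan": "Losacar", "metformin": "Glucophage",
    "paracetamol": "Panadol", "omeprazole": "Omez", "aspirin": "Disprin",
    "domperidone": "Motilium", "clopidogrel": "Plavix", "cetirizine": "Zyrtec",
    "gliclazide": "Diamicron", "co-amoxyclav": "Augmentin",
    "amoxycillin": "Amoxil", "salbutamol": "Ventolin",
    "prednisolone": "Precortyl", "enalapril": "Envas",
    "metoprolol": "Betaloc", "insulin": "Actrapid", "azithromycin": "Zithromax",
    "frusemide": "Lasix", "amlodipine": "Norvasc", "ranitidine": "Zantac",
    "ciprofloxacin": "Ciplox", "ibuprofen": "Brufen",
    "chlorpheniramine": "Piriton", "vitamin c": "Ceevit",
}


@dataclass(frozen=True)
class DistrictSpec:
    """One administrative district eligible to host survey outlets."""

    name: str
    population: int
    categories_available: tuple[str, ...] = CATEGORIES
    neighbor: str | None = None

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError(f"{self.name}: population must be positive")
        if not self.categories_available:
            raise ValueError(f"{self.name}: needs at least one category")


def _d(name, pop_thousands, cats=CATEGORIES, neighbor=None) -> DistrictSpec:
    return DistrictSpec(name, pop_thousands * 1000, tuple(cats), neighbor)


_PS = ("private", "state_owned")
_PF = ("private", "spc_franchise")
_P = ("private",)

#: Editable fixture approximating relative Sri Lankan district populations
#: (thousands, ~2012 census order of magnitude) and per-district pharmacy
#: category availability.  Under the default allocation rules this plan
#: yields 24 survey areas, 80 outlets and 2400 planned encounters.
DEFAULT_DISTRICTS: tuple[DistrictSpec, ...] = (
    _d("Colombo", 2324), _d("Gampaha", 2305), _d("Kurunegala", 1618),
    _d("Kandy", 1375), _d("Kalutara", 1222), _d("Ratnapura", 1088),
    _d("Galle", 1063),
    _d("Anuradhapura", 860), _d("Kegalle", 840, _PF), _d("Badulla", 815),
    _d("Matara", 814), _d("Puttalam", 762, _PF), _d("Nuwara Eliya", 711, _PF),
    _d("Ampara", 649, _PS), _d("Hambantota", 599), _d("Jaffna", 584),
    _d("Batticaloa", 526, _PF), _d("Matale", 484, _PF),
    _d("Monaragala", 451, _PF), _d("Polonnaruwa", 406),
    _d("Trincomalee", 379, _PF), _d("Vavuniya", 172, _PF),
    _d("Kilinochchi", 113, _P),
    _d("Mannar", 99, _P, neighbor="Mullaitivu"),
    _d("Mullaitivu", 92, _P, neighbor="Mannar"),
)

_RATE_FIELDS = ("p_encounter_antibiotic", "p_encounter_injection", "p_generic",
                "p_eml", "p_dispensed", "p_labelled_given_dispensed")


@dataclass
class GeneratorConfig:
    """Survey-design parameters and marginal rates of the generator.

    The defaults are the study conditions of a 2015 island-wide Sri Lankan
    pharmacy survey: 30 encounters per outlet, counts ~3.1 ± 1.9 on 1–12,
    23.8% antibiotic / 1.2% injection encounters, 35.5% generic, 68.8%
    EML, 92.4% dispensed, 98.5% labelled-given-dispensed, and a 3%
    incomplete-record rate (72 of 2400).
    """

    districts: tuple[DistrictSpec, ...] = DEFAULT_DISTRICTS
    encounters_per_outlet: int = 30
    min_area_population: int = 100_000
    double_set_population: int = 1_000_000
    count_mean: float = 3.1
    count_sd: float = 1.9
    count_min: int = 1
    count_max: int = 12
    p_encounter_antibiotic: float = 0.238
    p_encounter_injection: float = 0.012
    p_generic: float = 0.355
    p_eml: float = 0.688
    p_dispensed: float = 0.924
    p_labelled_given_dispensed: float = 0.985
    p_incomplete: float = 0.03
    medicine_name_table: tuple[tuple[str, float], ...] = DEFAULT_MEDICINE_TABLE
    #: optional per-category overrides, e.g.
    #: ``{"state_owned": {"p_encounter_antibiotic": 0.15, "count_mean": 3.6}}``
    category_overrides: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (*_RATE_FIELDS, "p_incomplete"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.count_min > self.count_max:
            raise ValueError("count_min must be <= count_max")
        if not self.count_min <= self.count_mean <= self.count_max:
            raise ValueError(
                f"count_mean={self.count_mean} outside "
                f"[{self.count_min}, {self.count_max}]: truncation infeasible")
        if any(w <= 0 for _, w in self.medicine_name_table):
            raise ValueError("medicine name weights must be positive")
        if len(self.medicine_name_table) < self.count_max:
            raise ValueError("medicine_name_table must hold at least "
                             f"{self.count_max} names (drawn without "
                             "replacement within an encounter)")
        for cat, over in self.category_overrides.items():
            unknown = set(over) - {*_RATE_FIELDS, "count_mean", "count_sd"}
            if unknown:
                raise ValueError(f"category_overrides[{cat!r}]: unknown "
                                 f"parameter(s) {sorted(unknown)}")

    def for_category(self, category: str) -> "GeneratorConfig":
        over = dict(self.category_overrides.get(category, {}))
        return replace(self, category_overrides={}, **over) if over else self

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        """Load a config from YAML or JSON (fields as in this dataclass;
        districts as lists ``[name, population, [categories], neighbor]``)."""
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorConfig":
        raw = dict(raw)
        if "districts" in raw:
            raw["districts"] = tuple(
                DistrictSpec(d[0], int(d[1]), tuple(d[2]),
                             d[3] if len(d) > 3 and d[3] else None)
                for d in raw["districts"])
        if "medicine_name_table" in raw:
            raw["medicine_name_table"] = tuple(
                (str(n), float(w)) for n, w in raw["medicine_name_table"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["districts"] = [[s.name, s.population, list(s.categories_available),
                           s.neighbor] for s in self.districts]
        d["medicine_name_table"] = [list(t) for t in self.medicine_name_table]
        d["category_overrides"] = {k: dict(v)
                                   for k, v in self.category_overrides.items()}
        return d


# --------------------------------------------------------------------------
# Area allocation (WHO/HAI-style)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveyArea:
    name: str
    population: int
    categories: tuple[str, ...]
    n_sets: int


@dataclass(frozen=True)
class Outlet:
    outlet_id: str
    area: str
    category: str


class AllocationError(ValueError):
    """A district cannot be placed into a valid survey area."""


def allocate_survey_areas(districts: Sequence[DistrictSpec],
                          config: GeneratorConfig,
                          ) -> list[tuple[SurveyArea, list[Outlet]]]:
    """Turn districts into survey areas with outlet plans.

    Districts below ``min_area_population`` merge with their declared
    neighbour into one area (hard error when no neighbour is declared);
    areas above ``double_set_population`` receive two sample sets; each
    set holds one outlet per category available in the area.
    """
    by_name = {d.name: d for d in districts}
    merged: set[str] = set()
    areas: list[SurveyArea] = []
    for d in districts:
        if d.name in merged:
            continue
        name, pop, cats = d.name, d.population, set(d.categories_available)
        if d.population < config.min_area_population:
            if not d.neighbor:
                raise AllocationError(
                    f"district {d.name!r} (population {d.population}) is below "
                    f"the {config.min_area_population} survey-area minimum and "
                    "declares no neighbor to merge with")
            if d.neighbor not in by_name:
                raise AllocationError(
                    f"district {d.name!r}: neighbor {d.neighbor!r} unknown")
            nb = by_name[d.neighbor]
            merged.update({d.name, nb.name})
            name = f"{d.name}/{nb.name}"
            pop = d.population + nb.population
            cats |= set(nb.categories_available)
        n_sets = 2 if pop > config.double_set_population else 1
        areas.append(SurveyArea(name, pop,
                                tuple(c for c in CATEGORIES if c in cats),
                                n_sets))
    plan: list[tuple[SurveyArea, list[Outlet]]] = []
    for area in areas:
        outlets = [Outlet(f"{area.name}|set{s + 1}|{cat}", area.name, cat)
                   for s in range(area.n_sets) for cat in area.categories]
        plan.append((area, outlets))
    return plan


# --------------------------------------------------------------------------
# Count distribution
# --------------------------------------------------------------------------

def truncated_count_pmf(mean: float, sd: float, lo: int, hi: int,
                        ) -> np.ndarray:
    """PMF over {lo..hi} of a shifted, truncated count distribution.

    A negative binomial on ``k - lo`` is moment-matched to
    ``(mean - lo, sd**2)`` and renormalized on [lo, hi]; when the target is
    not overdispersed relative to a Poisson (``sd**2 <= mean - lo``) a
    Poisson is used instead.  Returned array has length ``hi - lo + 1``.
    """
    if not lo <= mean <= hi:
        raise ValueError(f"mean {mean} outside truncation range [{lo}, {hi}]")
    m = mean - lo
    var = sd ** 2
    k = np.arange(lo, hi + 1)
    if m <= 0:
        pmf = np.zeros(hi - lo + 1)
        pmf[0] = 1.0
        return pmf
    if var > m:
        p = m / var
        r = m * p / (1 - p)
        pmf = stats.nbinom.pmf(k - lo, r, p)
    else:
        pmf = stats.poisson.pmf(k - lo, m)
    total = pmf.sum()
    if total <= 0:
        raise ValueError("degenerate truncated count distribution")
    return pmf / total


def count_distribution_moments(pmf: np.ndarray, lo: int) -> tuple[float, float]:
    """(mean, sd) implied by a truncated pmf starting at ``lo``."""
    k = np.arange(lo, lo + len(pmf))
    mean = float((k * pmf).sum())
    sd = float(np.sqrt(((k - mean) ** 2 * pmf).sum()))
    return mean, sd


# --------------------------------------------------------------------------
# Dataset generation
# --------------------------------------------------------------------------

def _corrupt(enc: Encounter, kind: int) -> None:
    """Apply one completeness violation in place."""
    if kind == 0:
        enc.medicines.clear()
    elif kind == 1:
        enc.medicines[0] = replace(enc.medicines[0], name_as_written="")
    elif kind == 2:
        enc.district = ""
    elif kind == 3:
        enc.medicines[0] = replace(enc.medicines[0], dispensed=None,
                                   labelled=None)
    else:
        enc.medicines[0] = replace(enc.medicines[0], dispensed=False,
                                   labelled=True)


def generate_dataset(config: GeneratorConfig,
                     ) -> tuple[SurveyDataset, dict]:
    """Generate a pre-validation survey dataset plus its truth record.

    The truth record echoes every configured parameter and adds the
    realized design sizes and the truncated count distribution's implied
    mean/SD, so downstream parameter-recovery checks have an exact target.
    """
    rng = np.random.default_rng(config.seed)
    plan = allocate_survey_areas(config.districts, config)
    outlets = [o for _, outs in plan for o in outs]

    names = np.array([n for n, _ in config.medicine_name_table])
    weights = np.array([w for _, w in config.medicine_name_table], dtype=float)
    weights /= weights.sum()
    antibiotic_name_idx = np.array(
        [i for i, n in enumerate(names) if n in DEFAULT_ANTIBIOTICS])

    pmf_cache: dict[tuple[float, float], np.ndarray] = {}

    def pmf_for(cfg: GeneratorConfig) -> np.ndarray:
        key = (cfg.count_mean, cfg.count_sd)
        if key not in pmf_cache:
            pmf_cache[key] = truncated_count_pmf(
                cfg.count_mean, cfg.count_sd, cfg.count_min, cfg.count_max)
        return pmf_cache[key]

    support = np.arange(config.count_min, config.count_max + 1)
    encounters: list[Encounter] = []
    eid = 0
    for outlet in outlets:
        cfg = config.for_category(outlet.category)
        pmf = pmf_for(cfg)
        n = config.encounters_per_outlet
        counts = rng.choice(support, size=n, p=pmf)
        has_ab = rng.random(n) < cfg.p_encounter_antibiotic
        has_inj = rng.random(n) < cfg.p_encounter_injection
        for i in range(n):
            c = int(counts[i])
            idx = rng.choice(len(names), size=c, replace=False, p=weights)
            generic = rng.random(c) < cfg.p_generic
            eml = rng.random(c) < cfg.p_eml
            disp = rng.random(c) < cfg.p_dispensed
            lab = disp & (rng.random(c) < cfg.p_labelled_given_dispensed)
            is_ab = np.zeros(c, dtype=bool)
            is_inj = np.zeros(c, dtype=bool)
            if has_ab[i]:
                j = int(rng.integers(c))
                is_ab[j] = True
                if names[idx[j]] not in DEFAULT_ANTIBIOTICS:
                    # swap in an antibiotic entity not already drawn
                    free = [a for a in antibiotic_name_idx if a not in idx]
                    if free:
                        idx[j] = free[int(rng.integers(len(free)))]
            if has_inj[i]:
                j = int(rng.integers(c))
                is_inj[j] = True
            eid += 1
            meds = []
            for j in range(c):
                g = str(names[idx[j]])
                by_generic = bool(generic[j])
                written = g if by_generic else DEFAULT_BRAND_ALIASES.get(
                    g, g.title())
                meds.append(MedicineRecord(
                    name_as_written=written, generic_name=g,
                    form="injection" if is_inj[j] else "tablet",
                    prescribed_by_generic=by_generic,
                    is_antibiotic=bool(is_ab[j]),
                    is_injection=bool(is_inj[j]),
                    on_eml=bool(eml[j]),
                    dispensed=bool(disp[j]), labelled=bool(lab[j])))
            encounters.append(Encounter(
                encounter_id=f"E{eid:05d}", district=outlet.area,
                pharmacy_category=outlet.category,
                outlet_id=outlet.outlet_id, medicines=meds))

    # exact-count uniform corruption: round(p * N) encounters receive one
    # randomly chosen completeness violation each
    n_corrupt = int(round(config.p_incomplete * len(encounters)))
    corrupt_idx = rng.choice(len(encounters), size=n_corrupt, replace=False)
    for i in corrupt_idx:
        _corrupt(encounters[i], int(rng.integers(5)))

    base_pmf = truncated_count_pmf(config.count_mean, config.count_sd,
                                   config.count_min, config.count_max)
    implied_mean, implied_sd = count_distribution_moments(
        base_pmf, config.count_min)
    truth = {
        "config": config.to_dict(),
        "n_areas": len(plan),
        "n_outlets": len(outlets),
        "n_encounters": len(encounters),
        "n_corrupted": n_corrupt,
        "implied_count_mean": implied_mean,
        "implied_count_sd": implied_sd,
    }
    logger.info("generated %d encounters from %d outlets in %d areas "
                "(%d corrupted)", len(encounters), len(outlets), len(plan),
                n_corrupt)
    return SurveyDataset(encounters=encounters), truth


def default_reference_lists() -> ReferenceLists:
    """Reference lists consistent with the default medicine name table.

    The EML here is a synthetic toy subset standing in for a national
    Essential Medicines List (the real list is an external document).
    """
    inn = {n for n, _ in DEFAULT_MEDICINE_TABLE}
    non_eml = {"vitamin c", "cetirizine", "ranitidine", "ibuprofen",
               "chlorpheniramine", "clopidogrel", "domperidone"}
    return ReferenceLists(
        inn=inn,
        eml=inn - non_eml,
        antibiotics=set(DEFAULT_ANTIBIOTICS),
        injectables={("insulin", "injection")},
        brand_to_generic={b: g for g, b in DEFAULT_BRAND_ALIASES.items()},
    )


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
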