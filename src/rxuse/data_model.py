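"""Survey data schema, reading/validation, and medicine classification.

The unit of a prescribing survey is the *encounter*: one prescription
presented at one pharmacy outlet, carrying one or more prescribed
medicines.  Each medicine carries the event flags that the WHO/INRUD core
drug use indicators count: prescribed by generic name (INN), antibiotic,
injection, on the national Essential Medicines List (EML), actually
dispensed, and (if dispensed) accurately labelled.

Flags may arrive pre-coded in the input file, or be derived from the raw
medicine name and dosage-form against reference lists
(:func:`classify_medicine`).  Encounters with incomplete details are
excluded by an explicit five-rule checklist (:func:`validate_encounter`)
and logged, mirroring the exclusion step of a real survey analysis.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The three pharmacy ownership categories of the Sri Lankan fee-levying
#: retail sector: privately owned outlets, state-owned retail pharmacies
#: run by the State Pharmaceuticals Corporation ("Rajya Osusala"), and
#: SPC franchisee outlets.
CATEGORIES: tuple[str, ...] = ("private", "state_owned", "spc_franchise")

#: Hard cap on medicines per encounter accepted as plausible.
DEFAULT_MAX_MEDICINES = 12

_TRUE_TOKENS = frozenset({"1", "true", "yes", "y", "t"})
_FALSE_TOKENS = frozenset({"0", "false", "no", "n", "f"})

LONG_COLUMNS = (
    "encounter_id", "district", "pharmacy_category", "outlet_id",
    "medicine_name", "form", "prescribed_by_generic", "is_antibiotic",
    "is_injection", "on_eml", "dispensed", "labelled",
)
ENCOUNTER_COLUMNS = ("encounter_id", "district", "pharmacy_category", "outlet_id")
MEDICINE_COLUMNS = tuple(c for c in LONG_COLUMNS if c not in
                         ("district", "pharmacy_category", "outlet_id"))
#: Flag columns that may be omitted and derived via classify_medicine.
OPTIONAL_FLAG_COLUMNS = ("prescribed_by_generic", "is_antibiotic",
                         "is_injection", "on_eml")


class SurveyFormatError(ValueError):
    """Raised when an input table violates the documented layout."""


def parse_bool(token: object) -> bool | None:
    """Parse ``1/0``, ``true/false``, ``yes/no`` (case-insensitive).

    Returns None for an empty/missing cell so callers can treat the flag
    as absent rather than guessing a default.
    """
    if token is None:
        return None
    s = str(token).strip().lower()
    if not s:
        return None
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise SurveyFormatError(
        f"unparseable boolean {token!r}; accepted: 1/0, true/false, yes/no")


# --------------------------------------------------------------------------
# Name canonicalization
# --------------------------------------------------------------------------

# Trailing dose/strength tokens stripped from medicine names: a number with
# an optional unit (mg, g, mcg, ml, iu, ...), optionally a ratio such as
# 125mg/5ml, or a bare trailing number.
# a bare number ("20"), a number+unit with an optional ratio tail
# ("20mg", "125mg/5ml", "100iu/ml"), or a bare unit ("mg"); a unitless
# ratio like "30/70" is treated as part of the name, not a dose
_UNIT = r"(?:mg|mcg|ug|g|kg|ml|l|iu|u|units?|%)"
_DOSE_TOKEN = re.compile(
    rf"^(?:\d+(?:\.\d+)?{_UNIT}(?:/(?:\d+(?:\.\d+)?)?{_UNIT}?)?"
    rf"|\d+(?:\.\d+)?|{_UNIT})$",
    re.IGNORECASE,
)

_PARENTERAL_TOKENS = frozenset({
    "injection", "inj", "injectable", "iv", "im", "sc", "subcutaneous",
    "intravenous", "intramuscular", "ampoule", "amp", "vial", "infusion",
    "parenteral", "prefilled", "pen",
})


def canonical_name(name: str) -> str:
    """Canonical form of a medicine name.

    Lowercase, whitespace collapsed, trailing dose/strength tokens removed
    (``"Atorvastatin 20mg"`` -> ``"atorvastatin"``).  Idempotent.
    """
    tokens = name.strip().lower().split()
    while tokens and _DOSE_TOKEN.match(tokens[-1]):
        tokens.pop()
    return " ".join(tokens)


def is_parenteral_form(form: str) -> bool:
    """True when a dosage-form string indicates a parenteral route."""
    return any(t in _PARENTERAL_TOKENS for t in form.strip().lower().split())


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MedicineRecord:
    """One prescribed item on an encounter, with its indicator flags.

    ``labelled`` is meaningful only when ``dispensed`` is True; ``dispensed``
    / ``labelled`` may be None while a record is still unvalidated.
    """

    name_as_written: str
    generic_name: str = ""
    form: str = ""
    prescribed_by_generic: bool = False
    is_antibiotic: bool = False
    is_injection: bool = False
    on_eml: bool = False
    dispensed: bool | None = None
    labelled: bool | None = None

    @property
    def entity_key(self) -> str:
        """Key identifying the medicine entity, used to count *different*
        medicines in an encounter: resolved generic name when known,
        otherwise the canonical written name."""
        return self.generic_name or canonical_name(self.name_as_written)


@dataclass
class Encounter:
    """One prescription, with outlet/district/category metadata."""

    encounter_id: str
    district: str
    pharmacy_category: str
    outlet_id: str
    medicines: list[MedicineRecord] = field(default_factory=list)

    @property
    def n_medicines(self) -> int:
        return len(self.medicines)


@dataclass
class ReferenceLists:
    """Reference name sets used to classify raw medicine names.

    All entries are canonicalized on construction.  ``antibiotics`` must be
    a subset of ``inn`` (an antibiotic reference is by generic name).
    """

    inn: set[str] = field(default_factory=set)
    eml: set[str] = field(default_factory=set)
    antibiotics: set[str] = field(default_factory=set)
    injectables: set[tuple[str, str]] = field(default_factory=set)
    brand_to_generic: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.inn = {canonical_name(x) for x in self.inn}
        self.eml = {canonical_name(x) for x in self.eml}
        self.antibiotics = {canonical_name(x) for x in self.antibiotics}
        self.injectables = {(canonical_name(n), f.strip().lower())
                            for n, f in self.injectables}
        self.brand_to_generic = {canonical_name(b): canonical_name(g)
                                 for b, g in self.brand_to_generic.items()}
        missing = self.antibiotics - self.inn
        if missing:
            raise ValueError(
                f"antibiotic entries missing from INN list: {sorted(missing)}")

    @classmethod
    def from_csv(cls, inn: str | Path, eml: str | Path,
                 antibiotics: str | Path, injectables: str | Path | None = None,
                 brand_map: str | Path | None = None) -> "ReferenceLists":
        """Load reference lists from single-column CSVs.

        Headers: ``generic_name`` for inn/eml/antibiotics;
        ``generic_name,form`` for injectables; ``brand,generic_name`` for
        the brand map.
        """
        def one_col(path, col="generic_name"):
            df = _read_table(path)
            if col not in df.columns:
                raise SurveyFormatError(f"{path}: missing column '{col}'")
            return set(df[col].astype(str))

        inj: set[tuple[str, str]] = set()
        if injectables is not None:
            df = _read_table(injectables)
            for col in ("generic_name", "form"):
                if col not in df.columns:
                    raise SurveyFormatError(f"{injectables}: missing column '{col}'")
            inj = set(zip(df["generic_name"].astype(str), df["form"].astype(str)))
        b2g: dict[str, str] = {}
        if brand_map is not None:
            df = _read_table(brand_map)
            for col in ("brand", "generic_name"):
                if col not in df.columns:
                    raise SurveyFormatError(f"{brand_map}: missing column '{col}'")
            b2g = dict(zip(df["brand"].astype(str), df["generic_name"].astype(str)))
        return cls(inn=one_col(inn), eml=one_col(eml),
                   antibiotics=one_col(antibiotics), injectables=inj,
                   brand_to_generic=b2g)


@dataclass
class SurveyDataset:
    """Validated encounters plus the exclusion log of the intake filter."""

    encounters: list[Encounter] = field(default_factory=list)
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    @property
    def excluded_count(self) -> int:
        return len(self.exclusion_log)

    @property
    def n_encounters(self) -> int:
        return len(self.encounters)

    @property
    def n_medicines(self) -> int:
        return sum(e.n_medicines for e in self.encounters)


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def classify_medicine(raw_name: str, raw_form: str,
                      refs: ReferenceLists) -> MedicineRecord:
    """Derive indicator flags for one raw medicine name + dosage form.

    The written name is canonicalized; if it is a recognized INN the item
    was prescribed by generic name, otherwise the brand map is consulted to
    resolve the generic entity (a brand with no map entry leaves
    ``generic_name`` empty, ``on_eml`` False, and logs a warning).
    Antibiotic and EML membership are resolved on the generic name; the
    injection flag is set by the injectables list or a parenteral form
    token.  ``dispensed``/``labelled`` are observational and left unset.
    """
    if not raw_name or not raw_name.strip():
        raise ValueError("raw_name must be non-empty")
    canon = canonical_name(raw_name)
    if canon in refs.inn:
        generic = canon
        by_generic = True
    else:
        by_generic = False
        generic = refs.brand_to_generic.get(canon, "")
        if not generic:
            logger.warning("unresolvable medicine name %r: no INN match and "
                           "no brand map entry", raw_name)
    form = raw_form.strip().lower()
    return MedicineRecord(
        name_as_written=raw_name.strip(),
        generic_name=generic,
        form=form,
        prescribed_by_generic=by_generic,
        is_antibiotic=bool(generic) and generic in refs.antibiotics,
        on_eml=bool(generic) and generic in refs.eml,
        is_injection=((generic, form) in refs.injectables
                      or is_parenteral_form(form)),
    )


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

def validate_encounter(enc: Encounter,
                       max_medicines: int = DEFAULT_MAX_MEDICINES,
                       ) -> tuple[bool, str | None]:
    """Classify an encounter as valid or excluded (never raises).

    Checklist, in order; the reason names the first failing rule:

    1. at least one medicine;
    2. every medicine has a non-empty written name;
    3. district and pharmacy category present;
    4. every medicine has a dispensed flag recorded;
    5. no medicine labelled without being dispensed;
    6. medicine count within the plausibility cap (default 12).
    """
    if not enc.medicines:
        return False, "no medicines"
    if any(not m.name_as_written.strip() for m in enc.medicines):
        return False, "empty medicine name"
    if not enc.district.strip() or not enc.pharmacy_category.strip():
        return False, "missing district or category"
    if any(m.dispensed is None for m in enc.medicines):
        return False, "missing dispensed flag"
    if any(m.labelled and not m.dispensed for m in enc.medicines):
        return False, "labelled without dispensed"
    if len(enc.medicines) > max_medicines:
        return False, f"more than {max_medicines} medicines"
    return True, None


def validate_dataset(encounters: Iterable[Encounter],
                     max_medicines: int = DEFAULT_MAX_MEDICINES,
                     ) -> SurveyDataset:
    """Split parsed encounters into valid ones and an exclusion log."""
    ds = SurveyDataset()
    for enc in encounters:
        ok, reason = validate_encounter(enc, max_medicines)
        if ok:
            ds.encounters.append(enc)
        else:
            ds.exclusion_log.append((enc.encounter_id, reason))
    logger.info("validation: %d encounters in, %d retained, %d excluded",
                ds.n_encounters + ds.excluded_count, ds.n_encounters,
                ds.excluded_count)
    return ds


# --------------------------------------------------------------------------
# Reading / writing
# --------------------------------------------------------------------------

def _read_table(source: str | Path | IO[str]) -> pd.DataFrame:
    return pd.read_csv(source, dtype=str, keep_default_na=False,
                       sep=None, engine="python")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"{what}: missing mandatory column(s) "
                                f"{', '.join(missing)}")


def _check_categories(labels: Iterable[str],
                      extra_categories: Sequence[str]) -> None:
    accepted = set(CATEGORIES) | set(extra_categories)
    unknown = {c for c in labels if c.strip() and c not in accepted}
    if unknown:
        raise SurveyFormatError(
            f"unknown pharmacy_category label(s) {sorted(unknown)}; "
            f"accepted: {sorted(accepted)}")


def _row_to_medicine(row: Mapping[str, str], refs: ReferenceLists | None,
                     ) -> MedicineRecord:
    name = str(row.get("medicine_name", "")).strip()
    form = str(row.get("form", "")).strip().lower()
    flags_present = all(str(row.get(c, "")).strip() != ""
                        for c in OPTIONAL_FLAG_COLUMNS)
    if flags_present:
        rec = MedicineRecord(
            name_as_written=name,
            generic_name=canonical_name(name) if name else "",
            form=form,
            prescribed_by_generic=bool(parse_bool(row["prescribed_by_generic"])),
            is_antibiotic=bool(parse_bool(row["is_antibiotic"])),
            is_injection=bool(parse_bool(row["is_injection"])),
            on_eml=bool(parse_bool(row["on_eml"])),
        )
    else:
        if refs is None:
            raise SurveyFormatError(
                "flag columns absent and no reference lists supplied; "
                "cannot classify medicines")
        if not name:
            rec = MedicineRecord(name_as_written="")
        else:
            rec = classify_medicine(name, form, refs)
    return replace(rec,
                   dispensed=parse_bool(row.get("dispensed")),
                   labelled=parse_bool(row.get("labelled")))


def read_survey(source, layout: str = "long", *,
                refs: ReferenceLists | None = None,
                max_medicines: int = DEFAULT_MAX_MEDICINES,
                extra_categories: Sequence[str] = (),
                ) -> SurveyDataset:
    """Read a survey table (CSV/TSV) and return validated encounters.

    Parameters
    ----------
    source
        For ``layout="long"``: one path/buffer with one row per medicine
        and the encounter metadata repeated.  For ``layout="two_table"``: a
        pair ``(encounters, medicines)`` joined on ``encounter_id``.
    refs
        Reference lists; required only when the classification flag columns
        are absent from the input.

    Rows with a blank ``encounter_id`` are logged and skipped.  Parsing is
    deterministic and order-preserving (encounters appear in order of first
    occurrence).  Unknown category labels and missing mandatory columns are
    hard errors.
    """
    if layout == "long":
        df = _read_table(source)
        _require_columns(df, ("encounter_id", "district", "pharmacy_category",
                              "outlet_id", "medicine_name", "dispensed",
                              "labelled"), "long layout")
        meta = df
        meds = df
    elif layout == "two_table":
        enc_src, med_src = source
        meta = _read_table(enc_src)
        meds = _read_table(med_src)
        _require_columns(meta, ENCOUNTER_COLUMNS, "encounters table")
        _require_columns(meds, ("encounter_id", "medicine_name", "dispensed",
                                "labelled"), "medicines table")
    else:
        raise SurveyFormatError(f"unknown layout {layout!r}; "
                                "accepted: long, two_table")

    _check_categories(meta["pharmacy_category"], extra_categories)

    pre_log: list[tuple[str, str]] = []
    encounters: dict[str, Encounter] = {}
    meta_by_id: dict[str, Mapping[str, str]] = {}
    for _, row in meta.iterrows():
        eid = str(row["encounter_id"]).strip()
        if not eid:
            pre_log.append(("<blank>", "blank encounter_id"))
            continue
        meta_by_id.setdefault(eid, row)
    for _, row in meds.iterrows():
        eid = str(row["encounter_id"]).strip()
        if not eid:
            if layout == "two_table":  # long layout already logged it above
                pre_log.append(("<blank>", "blank encounter_id"))
            continue
        head = meta_by_id.get(eid)
        if head is None:
            pre_log.append((eid, "medicine row without encounter row"))
            continue
        placeholder = (not str(row.get("medicine_name", "")).strip()
                       and all(not str(row.get(c, "")).strip()
                               for c in ("dispensed", "labelled",
                                         *OPTIONAL_FLAG_COLUMNS)))
        enc = encounters.get(eid)
        if enc is None:
            enc = Encounter(
                encounter_id=eid,
                district=str(head["district"]).strip(),
                pharmacy_category=str(head["pharmacy_category"]).strip(),
                outlet_id=str(head["outlet_id"]).strip(),
            )
            encounters[eid] = enc
        if not placeholder:  # a fully blank medicine row marks a
            enc.medicines.append(_row_to_medicine(row, refs))  # medicine-less encounter
    # encounter rows that never received a medicine row still enter
    # validation (and are excluded there with "no medicines")
    for eid, head in meta_by_id.items():
        if eid not in encounters:
            encounters[eid] = Encounter(
                encounter_id=eid,
                district=str(head["district"]).strip(),
                pharmacy_category=str(head["pharmacy_category"]).strip(),
                outlet_id=str(head["outlet_id"]).strip(),
            )
    ds = validate_dataset(encounters.values(), max_medicines)
    ds.exclusion_log = pre_log + ds.exclusion_log
    return ds


def _bool_cell(v: bool | None) -> str:
    return "" if v is None else ("1" if v else "0")


def survey_to_frame(dataset: SurveyDataset) -> pd.DataFrame:
    """Long-layout DataFrame of a dataset (booleans as 1/0)."""
    rows = []
    for enc in dataset.encounters:
        for m in enc.medicines:
            rows.append({
                "encounter_id": enc.encounter_id,
                "district": enc.district,
                "pharmacy_category": enc.pharmacy_category,
                "outlet_id": enc.outlet_id,
                "medicine_name": m.name_as_written,
                "form": m.form,
                "prescribed_by_generic": _bool_cell(m.prescribed_by_generic),
                "is_antibiotic": _bool_cell(m.is_antibiotic),
                "is_injection": _bool_cell(m.is_injection),
                "on_eml": _bool_cell(m.on_eml),
                "dispensed": _bool_cell(m.dispensed),
                "labelled": _bool_cell(m.labelled),
            })
        if not enc.medicines:  # preserve medicine-less encounters on disk
            rows.append({
                "encounter_id": enc.encounter_id,
                "district": enc.district,
                "pharmacy_category": enc.pharmacy_category,
                "outlet_id": enc.outlet_id,
                "medicine_name": "", "form": "",
                "prescribed_by_generic": "", "is_antibiotic": "",
                "is_injection": "", "on_eml": "", "dispensed": "",
                "labelled": "",
            })
    return pd.DataFrame(rows, columns=list(LONG_COLUMNS))


def write_survey(dataset: SurveyDataset, target: str | Path | IO[str],
                 layout: str = "long") -> None:
    """Write a dataset in the long CSV layout (UTF-8, booleans as 1/0)."""
    if layout != "long":
        raise SurveyFormatError("only the long layout is written")
    survey_to_frame(dataset).to_csv(target, index=False)


def write_exclusions(dataset: SurveyDataset,
                     target: str | Path | IO[str]) -> None:
    pd.DataFrame(dataset.exclusion_log,
                 columns=["encounter_id", "reason"]).to_csv(target, index=False)


def survey_to_csv_bytes(dataset: SurveyDataset) -> bytes:
    buf = io.StringIO()
    write_survey(dataset, buf)
    return buf.getvalue().encode("utf-8")
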