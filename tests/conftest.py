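import pathlib

import pytest
from hypothesis import settings

from rxuse import (Encounter, GeneratorConfig, MedicineRecord, ReferenceLists,
                   SurveyDataset)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

REPO_ROOT = pathlib.Path(__file__).resolve().parent.parent
EXAMPLE_INDICATORS = REPO_ROOT / "examples" / "survey2015_indicators.csv"


def med(name="paracetamol", generic=None, by_generic=True, antibiotic=False,
        injection=False, eml=True, dispensed=True, labelled=True,
        form="tablet"):
    return MedicineRecord(
        name_as_written=name, generic_name=generic if generic is not None
        else name, form=form, prescribed_by_generic=by_generic,
        is_antibiotic=antibiotic, is_injection=injection, on_eml=eml,
        dispensed=dispensed, labelled=labelled)


def enc(eid="E1", meds=None, district="Colombo", category="private",
        outlet="O1"):
    return Encounter(encounter_id=eid, district=district,
                     pharmacy_category=category, outlet_id=outlet,
                     medicines=list(meds) if meds is not None else [med()])


@pytest.fixture
def toy_refs():
    return ReferenceLists(
        inn={"atorvastatin", "paracetamol", "co-amoxyclav", "amoxycillin",
             "insulin", "losartan"},
        eml={"atorvastatin", "paracetamol", "co-amoxyclav", "insulin"},
        antibiotics={"co-amoxyclav", "amoxycillin"},
        injectables={("insulin", "injection")},
        brand_to_generic={"panadol": "paracetamol", "augmentin": "co-amoxyclav"},
    )


@pytest.fixture
def small_dataset():
    """Five encounters across two categories and two districts."""
    encounters = [
        enc("E1", [med("atorvastatin"), med("losartan", eml=False)],
            district="Colombo", category="private"),
        enc("E2", [med("co-amoxyclav", antibiotic=True)],
            district="Colombo", category="private"),
        enc("E3", [med("paracetamol"), med("atorvastatin"),
                   med("insulin", injection=True, form="injection")],
            district="Galle", category="state_owned"),
        enc("E4", [med("losartan", dispensed=False, labelled=False)],
            district="Galle", category="state_owned"),
        enc("E5", [med("Panadol", generic="paracetamol", by_generic=False)],
            district="Galle", category="private"),
    ]
    return SurveyDataset(encounters=encounters)


@pytest.fixture(scope="session")
def default_survey():
    """One full-size generated survey (80 outlets x 30 encounters), shared
    across tests that only read it."""
    from rxuse import generate_dataset, validate_dataset

    raw, truth = generate_dataset(GeneratorConfig(seed=20150801))
    return validate_dataset(raw.encounters), truth
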