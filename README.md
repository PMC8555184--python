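# rxuse

Analysis toolkit for **WHO/INRUD drug-use surveys** of retail pharmacies:
from prescription-level records to the seven core drug use indicators,
and from those to the **Index of Rational Drug Prescribing (IRDP)** and
**Index of Rational Patient-Care Drug Use (IRPCDU)**.

It is written for pharmacoepidemiologists and health-policy analysts who
run (or re-analyse) facility surveys of the WHO/INRUD design — for
example a national survey of Sri Lankan private, state-owned ("Rajya
Osusala"/SPC) and SPC-franchise pharmacies — and want the whole chain,
from intake filtering to the composite indices and significance tests,
reproducible from one seeded command.

## The indicators and indices

For a stratum of encounters (prescriptions), the WHO/INRUD core
indicators are

* prescribing: average number of different medicines per encounter
  (WHO reference 1.6–1.8); % of encounters with an antibiotic (20–26.8%);
  % of encounters with an injection (13.4–24.1%); % of medicines
  prescribed by generic name (100%); % of medicines from the Essential
  Medicines List, EML (100%);
* patient care: % of prescribed medicines actually dispensed (100%);
  % of **dispensed** medicines accurately labelled (100%).

Each indicator *x* is converted to a directional component index against
a single WHO optimal point *x\**:

```
index = min(x*/x, 1)   for lower-is-better indicators (medicines, antibiotic, injection)
index = min(x/x*, 1)   for higher-is-better indicators (generic, EML, dispensed, labelled)
```

with optimal points 1.7, 23.4, 18.75 (range midpoints) and 100.  The
composites are sums of components:

```
IRDP   = Σ (five prescribing indices)      ∈ (0, 5],  5 = fully rational prescribing
IRPCDU = idx_dispensed + idx_labelled      ∈ (0, 2]
```

By default components are computed from indicator values at their
printed one-decimal precision and rounded half-to-even to two decimals —
the convention under which published index tables reproduce cell for
cell (`mode="raw"` keeps full precision for new analyses).

Because raw prescription-level data from such surveys are essentially
never deposited, the package includes a first-class seeded generator
(`rxuse.synthetic_survey`) that emulates the survey design: WHO/HAI
survey-area allocation (≥100,000 population per area, neighbour merging,
double sample sets above one million), 30 consecutive prescriptions per
outlet, truncated negative-binomial medicine counts, and configurable
encounter- and medicine-level event rates.

## Worked example

Indices straight from published indicator values (aggregate mode — no
raw data needed).  `examples/survey2015_indicators.csv` holds the
overall and per-category indicator values reported by a 2015 island-wide
Sri Lankan pharmacy survey (3.1 medicines/encounter, 23.8% antibiotic,
1.2% injection, 35.5% generic, 68.8% EML, 92.4% dispensed, 98.5%
labelled, plus the three category columns):

```bash
$ rxuse indices examples/survey2015_indicators.csv
group,idx_non_polypharmacy,idx_rational_antibiotic,idx_safe_injection,idx_generic,idx_eml,idx_dispensed,idx_labelled,irdp,irpcdu
overall,0.55,0.98,1.0,0.36,0.69,0.92,0.98,3.58,1.9
private,0.59,0.86,1.0,0.32,0.7,0.94,0.98,3.47,1.92
state_owned,0.47,1.0,1.0,0.41,0.68,0.9,0.99,3.56,1.89
spc_franchise,0.55,0.91,1.0,0.35,0.69,0.93,0.99,3.5,1.92
```

Reading the overall row: prescribing is far from the WHO optimum on
polypharmacy (0.55 — 3.1 medicines per encounter against an optimum of
1.7) and generic prescribing (0.36), at the optimum for antibiotics
(0.98) and injections (1.00, capped — 1.2% observed is *better* than the
18.75% optimal point), giving IRDP 3.58 of a possible 5.  Patient care
is close to optimal: IRPCDU 1.90 of 2.  The state-owned column's
antibiotic index is capped at 1.00 because its observed 15.0% is below
the 23.4% optimal point.

Full raw-data pipeline on a synthetic survey:

```bash
$ rxuse generate --seed 7 --out demo
wrote 2400 encounters (72 corrupted) to demo/survey.csv
$ rxuse analyze demo/survey.csv --out demo/report
```

`demo/report/tables_pharmacy_category.md` then contains (abridged):

```
| Indicator (WHO reference)                      | overall             | private             | ...
| Encounters surveyed (n)                        | 2328                | 907                 |
| Average medicines per encounter (1.6–1.8)      | 3.1 ± 1.9 (3; 1–12) | 3.1 ± 1.9 (3; 1–12) |
| Encounters with an antibiotic (%) (20–26.8)    | 550 (23.6)          | 203 (22.4)          |
| Medicines prescribed in generic name (%) (100) | 2605 (36.0)         | 1023 (36.0)         |
...
| Index of rational drug prescribing (1+2+3+4+5) | 3.59    | 3.59    | ...
| Index of Rational Patient-Care Drug Use (1+2)  | 1.91    | 1.91    | ...
```

i.e. the intake filter retained 2328 of the 2400 generated encounters
(72 were corrupted with completeness violations and excluded, with
reasons in `exclusions.csv`), and the recovered indicators/indices sit
at the generator's configured truth.  Letters such as `a` in a row mark
pairs of groups that differ significantly (chi-square / t test,
α = 0.05); full statistics are in `comparisons.csv`.

The same is available as a library:

```python
from rxuse import GeneratorConfig, generate_dataset, validate_dataset, stratify, index_table

raw, truth = generate_dataset(GeneratorConfig(seed=7))
dataset = validate_dataset(raw.encounters)          # 2400 -> 2328
strat = stratify(dataset, "pharmacy_category")
table = index_table(strat)
print(table["overall"].irdp, table["overall"].irpcdu)  # 3.59 1.91
```

## Layout

* `rxuse.data_model` — schema, CSV intake (long and two-table layouts),
  validation/exclusion, medicine-name classification
* `rxuse.synthetic_survey` — WHO/HAI area allocation and the seeded
  generator
* `rxuse.indicators` — the seven indicators, polypharmacy rate, top
  medicines, stratification
* `rxuse.rational_indices` — component indices, IRDP, IRPCDU
* `rxuse.comparisons` — chi-square / t / ANOVA comparisons and table
  annotation
* `rxuse.pipeline`, `rxuse.cli` — report bundles and the `rxuse`
  command (`generate`, `analyze`, `indices`, `compare`, `report`)

See `docs/methods.md` for modelling assumptions, parameter defaults and
limitations.
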