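"""End-to-end pipeline: configuration, orchestration, report bundle.

Two first-class entry modes:

* **raw mode** — prescription-level encounters (read from disk or drawn
  from the synthetic generator) are validated, stratified, converted to
  indicators, indices and comparisons, and written as a report bundle;
* **aggregate mode** — a small table of already-computed indicator values
  per group (the form in which surveys are published) is converted
  directly to component indices and composites, enabling exact
  reproduction of published index tables without any raw data.

A bundle is deterministic: identical configuration and seed produce
byte-identical files, and the manifest echoes everything needed to rerun.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .comparisons import annotate_table, comparisons_to_frame, \
    omnibus_comparisons
from .data_model import (ReferenceLists, SurveyDataset, read_survey,
                         write_exclusions, write_survey)
from .indicators import (indicators_to_frame, render_indicator_table,
                         stratify)
from .rational_indices import (COMPONENT_SOURCE, OptimalValues,
                               index_set_from_observed, index_table,
                               indices_to_frame, render_index_table)
from .synthetic_survey import GeneratorConfig, generate_dataset, write_truth

logger = logging.getLogger(__name__)

#: Aggregate-mode input columns (one row per group).
AGGREGATE_COLUMNS = ("group", "medicines_per_encounter", "pct_antibiotic",
                     "pct_injection", "pct_generic", "pct_eml",
                     "pct_dispensed", "pct_labelled")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of ``survey_path`` /
    ``generator`` must be supplied."""

    survey_path: str | None = None
    survey_layout: str = "long"
    generator: GeneratorConfig | None = None
    refs_paths: Mapping[str, str] | None = None   # inn/eml/antibiotics/...
    stratify_keys: tuple[str, ...] = ("overall", "pharmacy_category")
    optimal_points: Mapping[str, float] | None = None
    rounding_mode: str = "printed"                # printed_precision | raw
    polypharmacy_threshold: int = 4
    alpha: float = 0.05
    out_dir: str = "report"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.survey_path is None) == (self.generator is None):
            raise ValueError("exactly one of survey_path / generator "
                             "must be supplied")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.rounding_mode in ("printed_precision",):
            self.rounding_mode = "printed"
        if self.rounding_mode not in ("printed", "raw"):
            raise ValueError("rounding_mode must be 'printed_precision' "
                             "or 'raw'")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw.get("generator") is not None:
            raw["generator"] = GeneratorConfig.from_dict(raw["generator"])
        if "stratify_keys" in raw:
            raw["stratify_keys"] = tuple(raw["stratify_keys"])
        return cls(**raw)


def _optimal(config: PipelineConfig) -> OptimalValues:
    opt = OptimalValues()
    if config.optimal_points:
        opt.points.update(config.optimal_points)
        opt.__post_init__()
    return opt


def _load_refs(paths: Mapping[str, str] | None) -> ReferenceLists | None:
    if not paths:
        return None
    for key in ("inn", "eml", "antibiotics"):
        if key not in paths:
            raise PipelineError(f"reference lists: missing path for {key!r}")
        if not Path(paths[key]).exists():
            raise PipelineError(f"reference lists: file not found: "
                                f"{paths[key]}")
    return ReferenceLists.from_csv(
        inn=paths["inn"], eml=paths["eml"], antibiotics=paths["antibiotics"],
        injectables=paths.get("injectables"), brand_map=paths.get("brand_map"))


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis; returns the paths of the written bundle.

    Bundle contents: the (generated or echoed) survey data, exclusion log,
    per-key indicator tables (tidy CSV + rendered markdown with
    significance marks), index tables (tidy CSV + markdown), comparison
    results, and a manifest (config echo, seed, version).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mode = "printed" if config.rounding_mode == "printed" else "raw"
    optimal = _optimal(config)
    written: dict[str, Path] = {}

    try:
        refs = _load_refs(config.refs_paths)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - report the stage
        raise PipelineError(f"stage reference-lists: {exc}") from exc

    try:
        if config.generator is not None:
            gen_cfg = dataclasses.replace(config.generator, seed=config.seed)
            raw_ds, truth = generate_dataset(gen_cfg)
            write_truth(truth, out / "truth.json")
            written["truth"] = out / "truth.json"
            from .data_model import validate_dataset
            dataset = validate_dataset(raw_ds.encounters)
            write_survey(raw_ds, out / "survey.csv")
            written["survey"] = out / "survey.csv"
        else:
            dataset = read_survey(config.survey_path,
                                  layout=config.survey_layout, refs=refs)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage intake: {exc}") from exc

    write_exclusions(dataset, out / "exclusions.csv")
    written["exclusions"] = out / "exclusions.csv"
    logger.info("intake: %d encounters retained, %d excluded",
                dataset.n_encounters, dataset.excluded_count)

    all_results = []
    for key in config.stratify_keys:
        try:
            strat = stratify(dataset, key)
            marks: dict = {}
            if key != "overall" and len(strat.groups) >= 2:
                marks, pairwise = annotate_table(
                    dataset, key, alpha=config.alpha, strat=strat)
                results = omnibus_comparisons(dataset, key, strat=strat)
                all_results += results + pairwise
            table = index_table(strat, optimal, mode)
            observed = {g: s.observed_values()
                        for g, s in [("overall", strat.overall),
                                     *strat.groups.items()]}
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage indicators[{key}]: {exc}") from exc

        indicators_to_frame(strat).to_csv(out / f"indicators_{key}.csv",
                                          index=False)
        indices_to_frame(table, observed, optimal).to_csv(
            out / f"indices_{key}.csv", index=False)
        md = (render_indicator_table(strat, marks) + "\n\n"
              + render_index_table(table) + "\n")
        (out / f"tables_{key}.md").write_text(md)
        for name in (f"indicators_{key}.csv", f"indices_{key}.csv",
                     f"tables_{key}.md"):
            written[name] = out / name

    if all_results:
        comparisons_to_frame(all_results).to_csv(out / "comparisons.csv",
                                                 index=False)
        written["comparisons"] = out / "comparisons.csv"

    manifest = {
        "rxuse_version": __version__,
        "seed": config.seed,
        "rounding_mode": config.rounding_mode,
        "alpha": config.alpha,
        "polypharmacy_threshold": config.polypharmacy_threshold,
        "stratify_keys": list(config.stratify_keys),
        "optimal_points": optimal.points,
        "n_encounters": dataset.n_encounters,
        "n_excluded": dataset.excluded_count,
        "n_medicines": dataset.n_medicines,
        "generator": (config.generator and
                      dataclasses.replace(config.generator,
                                          seed=config.seed).to_dict()),
        "survey_path": config.survey_path,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    written["manifest"] = out / "manifest.json"
    return written


def aggregate_mode(indicator_table: pd.DataFrame | str | Path,
                   optimal: OptimalValues | None = None,
                   mode: str = "printed") -> pd.DataFrame:
    """Component indices and composites from published indicator values.

    Input: one row per group with columns :data:`AGGREGATE_COLUMNS` (CSV
    path or DataFrame).  Output: one row per group with the seven
    component indices plus ``irdp`` and ``irpcdu``.  No raw encounter data
    is needed, so a published indicator table reproduces its published
    index table exactly.
    """
    df = (pd.read_csv(indicator_table)
          if not isinstance(indicator_table, pd.DataFrame)
          else indicator_table.copy())
    missing = [c for c in AGGREGATE_COLUMNS if c not in df.columns]
    if missing:
        raise PipelineError("aggregate mode: missing indicator column(s) "
                            + ", ".join(missing))
    rows = []
    for _, rec in df.iterrows():
        observed = {ind: float(rec[ind]) for ind in AGGREGATE_COLUMNS[1:]}
        iset = index_set_from_observed(observed, optimal, mode)
        row = {"group": rec["group"]}
        row.update({c: getattr(iset, c) for c in COMPONENT_SOURCE})
        row["irdp"] = iset.irdp
        row["irpcdu"] = iset.irpcdu
        rows.append(row)
    return pd.DataFrame(rows)
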