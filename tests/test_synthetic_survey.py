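"""Generator: allocation rules, determinism, marginal rates, corruption."""

import dataclasses
import math

import numpy as np
import pytest

from rxuse import (DEFAULT_DISTRICTS, DistrictSpec, GeneratorConfig,
                   allocate_survey_areas, generate_dataset,
                   truncated_count_pmf, validate_dataset)
from rxuse.data_model import survey_to_frame
from rxuse.synthetic_survey import (AllocationError,
                                    count_distribution_moments)


def small_config(**kw):
    districts = kw.pop("districts", (
        DistrictSpec("A", 500_000, ("private", "state_owned",
                                    "spc_franchise")),
        DistrictSpec("B", 300_000, ("private",)),
    ))
    return GeneratorConfig(districts=districts, **kw)


class TestAllocation:
    def test_under_sized_districts_merge_with_neighbor(self):
        districts = (DistrictSpec("X", 50_000, ("private",), neighbor="Y"),
                     DistrictSpec("Y", 60_000, ("private",), neighbor="X"))
        plan = allocate_survey_areas(districts, small_config())
        assert len(plan) == 1
        area, outlets = plan[0]
        assert area.name == "X/Y" and area.population == 110_000
        assert area.n_sets == 1 and len(outlets) == 1

    def test_large_district_gets_two_sets(self):
        districts = (DistrictSpec("Big", 1_200_000,
                                  ("private", "state_owned",
                                   "spc_franchise")),)
        plan = allocate_survey_areas(districts, small_config())
        area, outlets = plan[0]
        assert area.n_sets == 2 and len(outlets) == 6

    def test_single_category_district_gets_one_outlet(self):
        districts = (DistrictSpec("Solo", 500_000, ("private",)),)
        _, outlets = allocate_survey_areas(districts, small_config())[0]
        assert len(outlets) == 1 and outlets[0].category == "private"

    def test_under_sized_without_neighbor_is_hard_error(self):
        districts = (DistrictSpec("Tiny", 50_000, ("private",)),)
        with pytest.raises(AllocationError, match="Tiny"):
            allocate_survey_areas(districts, small_config())

    def test_default_plan_gives_80_outlets_2400_encounters(self):
        cfg = GeneratorConfig()
        plan = allocate_survey_areas(DEFAULT_DISTRICTS, cfg)
        outlets = [o for _, outs in plan for o in outs]
        assert len(plan) == 24          # 25 districts, one merged pair
        assert len(outlets) == 80
        assert len(outlets) * cfg.encounters_per_outlet == 2400
        doubles = [a for a, _ in plan if a.n_sets == 2]
        assert len(doubles) == 7        # the districts above one million


class TestCountDistribution:
    def test_moment_match_close_to_target(self):
        pmf = truncated_count_pmf(3.1, 1.9, 1, 12)
        mean, sd = count_distribution_moments(pmf, 1)
        assert mean == pytest.approx(3.1, abs=0.05)
        assert sd == pytest.approx(1.9, abs=0.05)

    def test_truncation_support_respected(self):
        ds, _ = generate_dataset(small_config(seed=3))
        counts = [e.n_medicines for e in ds.encounters if e.medicines]
        assert min(counts) >= 1 and max(counts) <= 12

    def test_infeasible_mean_is_hard_error(self):
        with pytest.raises(ValueError, match="truncation infeasible"):
            small_config(count_mean=15.0)

    def test_underdispersed_target_falls_back_to_poisson(self):
        pmf = truncated_count_pmf(2.0, 0.5, 1, 12)
        mean, _ = count_distribution_moments(pmf, 1)
        assert mean == pytest.approx(2.0, abs=0.35)


class TestGeneration:
    def test_same_seed_byte_identical(self):
        cfg = small_config(seed=11)
        a, _ = generate_dataset(cfg)
        b, _ = generate_dataset(cfg)
        assert survey_to_frame(a).equals(survey_to_frame(b))

    def test_different_seed_differs(self):
        a, _ = generate_dataset(small_config(seed=1))
        b, _ = generate_dataset(small_config(seed=2))
        assert not survey_to_frame(a).equals(survey_to_frame(b))

    def test_zero_antibiotic_probability_degenerate(self):
        ds, _ = generate_dataset(small_config(
            seed=5, p_encounter_antibiotic=0.0, p_incomplete=0.0))
        assert not any(m.is_antibiotic
                       for e in ds.encounters for m in e.medicines)

    def test_encounter_flag_consistent_with_medicine_flags(self):
        ds, _ = generate_dataset(small_config(seed=7, p_incomplete=0.0,
                                              p_encounter_antibiotic=0.5))
        for e in ds.encounters:
            n_ab = sum(m.is_antibiotic for m in e.medicines)
            assert n_ab in (0, 1)  # pushed down to exactly one medicine

    def test_exact_corruption_count(self):
        cfg = small_config(seed=13)   # 4 outlets x 30 = 120, 3% -> 4
        ds, truth = generate_dataset(cfg)
        assert truth["n_corrupted"] == round(0.03 * truth["n_encounters"])
        valid = validate_dataset(ds.encounters)
        assert valid.excluded_count == truth["n_corrupted"]

    def test_truth_record_echoes_parameters(self):
        _, truth = generate_dataset(small_config(seed=1))
        assert truth["config"]["p_generic"] == 0.355
        assert truth["config"]["seed"] == 1
        assert "implied_count_mean" in truth

    def test_category_overrides_shift_rates(self):
        cfg = small_config(seed=23, category_overrides={
            "state_owned": {"p_encounter_antibiotic": 0.0}})
        ds, _ = generate_dataset(cfg)
        state = [e for e in ds.encounters
                 if e.pharmacy_category == "state_owned" and e.medicines]
        assert state and not any(m.is_antibiotic
                                 for e in state for m in e.medicines)

    def test_unknown_override_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            small_config(category_overrides={"private": {"p_magic": 0.5}})


class TestParameterRecovery:
    def test_realized_rates_within_3_se_at_full_size(self, default_survey):
        """At 80 outlets x 30 encounters every realized indicator sits
        within three standard errors of its configured truth."""
        from rxuse import compute_indicator_set

        dataset, truth = default_survey
        cfg = truth["config"]
        iset = compute_indicator_set(dataset.encounters)
        n_enc = iset.n_encounters
        n_med = iset.n_medicines

        def check_binomial(observed_pct, p, n):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(observed_pct / 100.0 - p) <= 3 * se, (
                f"{observed_pct} vs {p} (n={n})")

        check_binomial(iset.pct_antibiotic, cfg["p_encounter_antibiotic"],
                       n_enc)
        check_binomial(iset.pct_injection, cfg["p_encounter_injection"],
                       n_enc)
        check_binomial(iset.pct_generic, cfg["p_generic"], n_med)
        check_binomial(iset.pct_eml, cfg["p_eml"], n_med)
        check_binomial(iset.pct_dispensed, cfg["p_dispensed"], n_med)
        check_binomial(iset.pct_labelled,
                       cfg["p_labelled_given_dispensed"],
                       iset.counts["dispensed"])
        se_mean = truth["implied_count_sd"] / math.sqrt(n_enc)
        assert abs(iset.avg_medicines.mean
                   - truth["implied_count_mean"]) <= 3 * se_mean

    def test_estimates_tighten_with_more_outlets(self):
        """Deviation from configured truth shrinks from 10 to 80 outlets
        (averaged over a few seeds to damp single-draw noise)."""
        from rxuse import compute_indicator_set

        ten = tuple(DistrictSpec(f"D{i}", 500_000,
                                 ("private", "state_owned",
                                  "spc_franchise")) for i in range(3))
        p = 0.238

        def mean_abs_dev(districts, seeds):
            devs = []
            for seed in seeds:
                cfg = GeneratorConfig(districts=districts, seed=seed,
                                      p_incomplete=0.0)
                ds, _ = generate_dataset(cfg)
                iset = compute_indicator_set(ds.encounters)
                devs.append(abs(iset.pct_antibiotic / 100 - p))
            return np.mean(devs)

        small = mean_abs_dev(ten, seeds=range(6))                   # 9 outlets
        large = mean_abs_dev(DEFAULT_DISTRICTS, seeds=range(6))     # 80
        assert large < small
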