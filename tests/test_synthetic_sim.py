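"""Environment bank, drive simulation and the synthetic outcome model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zonescreen.experiments import (drive_duration_experiment,
                                    prevalence_calibration)
from zonescreen.synthetic_sim import (ARCHETYPES, ZONE_TYPES, DriverProfile,
                                      SimParams, assign_ore_score,
                                      draw_zone_archetypes, generate_cohort,
                                      generate_environment_bank,
                                      load_environments, save_environments,
                                      simulate_drive)

from .conftest import SMALL_BANK


class TestEnvironmentBank:
    def test_default_bank_structure(self):
        envs = generate_environment_bank(seed=3)
        assert len(envs) == 10
        ids = [z.zone_id for e in envs for z in e.zones]
        assert sorted(ids) == list(range(1, 167))
        assert {len(e.zones) for e in envs} == {16, 17}
        for env in envs:
            entries = [z.entry.s for z in env.zones]
            assert entries == sorted(entries)
            for a, b in zip(env.zones, env.zones[1:]):
                assert a.exit.s <= b.entry.s

    def test_single_env_three_zones(self):
        envs = generate_environment_bank(n_env=1, total_zones=3, seed=0,
                                         route_length=900.0)
        assert len(envs) == 1 and len(envs[0].zones) == 3

    def test_too_few_zones_rejected(self):
        with pytest.raises(ValueError):
            generate_environment_bank(n_env=5, total_zones=3)

    def test_deterministic_given_seed(self):
        a = generate_environment_bank(seed=9)
        b = generate_environment_bank(seed=9)
        for ea, eb in zip(a, b):
            assert [(z.zone_id, z.entry.s, z.exit.s) for z in ea.zones] == \
                   [(z.zone_id, z.entry.s, z.exit.s) for z in eb.zones]
            np.testing.assert_array_equal(ea.centerline, eb.centerline)

    def test_json_round_trip(self, small_bank, tmp_path):
        save_environments(small_bank, tmp_path / "envs.json")
        back = load_environments(tmp_path / "envs.json")
        for ea, eb in zip(small_bank, back):
            assert [(z.zone_id, z.zone_type, z.entry.s, z.exit.s, z.zone_limit)
                    for z in ea.zones] == \
                   [(z.zone_id, z.zone_type, z.entry.s, z.exit.s, z.zone_limit)
                    for z in eb.zones]


class TestArchetypeLibrary:
    def test_three_plus_archetypes_per_zone_type(self):
        for zt in ZONE_TYPES:
            archs = ARCHETYPES[zt]
            assert len(archs) >= 3
            assert any(a.infraction_weight == 0 for a in archs)
            assert any(a.infraction_weight > 0 for a in archs)

    def test_templates_respect_channel_ranges(self):
        u = np.linspace(0, 1, 101)
        for archs in ARCHETYPES.values():
            for a in archs:
                assert np.all(a.profile(u, "brake") >= 0)
                assert np.all(a.profile(u, "brake") <= 1)
                assert np.all(a.profile(u, "throttle") >= 0)
                assert np.all(a.profile(u, "throttle") <= 1)
                assert np.all(np.abs(a.profile(u, "steering")) <= 1)
                assert np.all(a.profile(u, "speed") >= 0)


class TestSimulateDrive:
    def test_deterministic(self, small_bank):
        p = DriverProfile(theta=0.3, seed=5)
        a = simulate_drive(small_bank[0], p)
        b = simulate_drive(small_bank[0], p)
        pd.testing.assert_frame_equal(a.frames, b.frames)

    def test_skilled_driver_noise_free_is_compliant(self, small_bank):
        """theta=1, sigma=0: only compliant archetypes, limits respected."""
        env = small_bank[0]
        p = DriverProfile(theta=1.0, seed=11)
        draws = draw_zone_archetypes(env, p)
        assert all(a.infraction_weight == 0 for _, a in draws)
        rec = simulate_drive(env, p, SimParams(noise_sigma=0.0))
        speed = rec.channel("speed")
        limit = rec.channel("posted_limit")
        assert np.all(speed <= limit + 1e-9)

    def test_risky_frequency_decreases_with_skill(self, small_bank):
        env = small_bank[1]
        freqs = []
        for theta in np.linspace(0, 1, 6):
            risky = 0
            total = 0
            for seed in range(40):
                p = DriverProfile(theta=float(theta), seed=1000 + seed)
                for _, a in draw_zone_archetypes(env, p):
                    risky += a.infraction_weight > 0
                    total += 1
            freqs.append(risky / total)
        # monotone trend: negative regression slope, endpoints ordered
        slope = stats.linregress(np.linspace(0, 1, 6), freqs).slope
        assert slope < -0.5
        assert freqs[0] > freqs[-1]

    def test_full_scale_duration_near_eight_minutes(self):
        r = drive_duration_experiment(n=8, seed=2)
        assert 480 * 0.8 <= r["mean_duration_s"] <= 480 * 1.2


class TestOutcomeModel:
    def test_noise_free_extremes(self):
        perfect = assign_ore_score(DriverProfile(1.0, 1), a=45, b=0, sigma_e=0)
        hopeless = assign_ore_score(DriverProfile(0.0, 1), a=45, b=0, sigma_e=0)
        assert perfect == 0
        assert hopeless == 45

    def test_default_prevalence_near_quarter(self):
        r = prevalence_calibration(n=4000, seed=1)
        assert abs(r["prevalence_pct"] - 25.4) <= 3.0

    def test_deterministic_given_seed(self):
        p = DriverProfile(0.37, 999)
        assert assign_ore_score(p) == assign_ore_score(p)


class TestGenerateCohort:
    def test_alignment_and_determinism(self, small_bank):
        recs, records = generate_cohort(30, small_bank, seed=4)
        assert len(recs) == len(records) == 30
        assert [r.drive_id for r in recs] == [c.drive_id for c in records]
        recs2, records2 = generate_cohort(30, small_bank, seed=4)
        assert [c.ore_score for c in records] == [c.ore_score for c in records2]
        pd.testing.assert_frame_equal(recs[7].frames, recs2[7].frames)

    def test_environment_assignment_uniform(self):
        envs = generate_environment_bank(seed=8, n_env=10, total_zones=20,
                                         route_length=650.0, zone_scale=0.4)
        recs, _ = generate_cohort(600, envs, seed=8)
        counts = np.bincount([r.environment_id - 1 for r in recs],
                             minlength=10)
        p = stats.chisquare(counts).pvalue
        assert p > 1e-3

    def test_null_parameters_decouple_scores_from_skill(self, small_bank):
        params = SimParams(a=0.0, b=0.0, sigma_e=40.0)
        _, records = generate_cohort(300, small_bank, params=params, seed=6)
        # scores exist and are pure noise: correlation with theta ~ 0
        master = np.random.default_rng(np.random.SeedSequence([6, 10]))
        thetas = master.uniform(0, 1, 300)
        scores = np.array([r.ore_score for r in records])
        assert abs(stats.pearsonr(thetas, scores)[0]) < 0.15
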