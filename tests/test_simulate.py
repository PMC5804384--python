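import numpy as np
import pytest

from tmjmetrics import (
    SimulationConfig,
    SceneConfig,
    ValidationError,
    add_rater_noise,
    icc,
    measure_cohort,
    reliability_icc,
    simulate_cohort,
)


def cohort_equal(a, b, atol=0.0):
    if len(a) != len(b):
        return False
    for ra, rb in zip(a.records, b.records):
        if (ra.joint_id, ra.diagnosis, ra.side) != (rb.joint_id, rb.diagnosis, rb.side):
            return False
        if set(ra.landmarks) != set(rb.landmarks):
            return False
        for pos in ra.landmarks:
            la, lb = ra.landmarks[pos], rb.landmarks[pos]
            for name in ("T", "P", "G", "C", "D"):
                if not np.allclose(getattr(la, name), getattr(lb, name), atol=atol, rtol=0):
                    return False
    return True


class TestDeterminism:
    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=123)
        a = simulate_cohort(cfg)
        b = simulate_cohort(SimulationConfig(seed=123))
        assert cohort_equal(a, b)
        assert a.meta.keys() == b.meta.keys()
        for k in a.meta:
            assert a.meta[k] == b.meta[k]

    def test_different_seed_differs(self):
        a = simulate_cohort(SimulationConfig(seed=1))
        b = simulate_cohort(SimulationConfig(seed=2))
        assert not cohort_equal(a, b, atol=1e-6)


class TestRoundTrip:
    def test_measurement_recovers_drawn_values(self):
        # the central consistency check: the geometry pipeline re-measures
        # exactly what the generator drew
        cohort = measure_cohort(simulate_cohort(SimulationConfig(seed=7)))
        checked = 0
        for rec in cohort.records:
            for pos, truth in rec.truth.items():
                got = rec.measurements[pos]
                assert got.angle == pytest.approx(truth.angle, abs=1e-9)
                assert got.condyle.x == pytest.approx(truth.condyle.x, abs=1e-9)
                assert got.condyle.y == pytest.approx(truth.condyle.y, abs=1e-9)
                assert got.disc.x == pytest.approx(truth.disc.x, abs=1e-9)
                assert got.disc.y == pytest.approx(truth.disc.y, abs=1e-9)
                checked += 1
        assert checked == 74 * 3

    def test_left_and_right_sides_both_roundtrip(self):
        cohort = measure_cohort(simulate_cohort(SimulationConfig(seed=11)))
        sides = {rec.side for rec in cohort.records}
        assert sides == {"left", "right"}


class TestCalibration:
    def test_large_cohort_recovers_configured_moments(self):
        cfg = SimulationConfig(n_normal=0, n_ddwor=0, n_ddwr=10_000, seed=5)
        cohort = measure_cohort(simulate_cohort(cfg))
        angles = np.array([r.measurements[1].angle for r in cohort.records])
        mean, sd = cfg.angle_params["DDwR"][1]
        assert abs(angles.mean() - mean) < 3 * sd / np.sqrt(len(angles))
        cx = np.array([r.measurements[1].condyle.x for r in cohort.records])
        cy = np.array([r.measurements[1].condyle.y for r in cohort.records])
        (mx, sdx), (my, sdy) = cfg.condyle_params["DDwR"][1]
        assert abs(cx.mean() - mx) < 3 * sdx / np.sqrt(len(cx))
        assert abs(cy.mean() - my) < 3 * sdy / np.sqrt(len(cy))

    def test_recapture_fraction_concentrates(self):
        cfg = SimulationConfig(n_normal=0, n_ddwor=0, n_ddwr=5_000, seed=13)
        cohort = measure_cohort(simulate_cohort(cfg))
        for pos in (2, 3):
            in_band = np.mean(
                [abs(r.measurements[pos].angle) <= 15 for r in cohort.records]
            )
            p = cfg.recapture_prob[pos]
            se = np.sqrt(p * (1 - p) / len(cohort.records))
            assert abs(in_band - p) < 4 * se

    def test_treated_mixture_components_respect_band(self):
        cohort = measure_cohort(
            simulate_cohort(SimulationConfig(n_normal=0, n_ddwor=0, n_ddwr=500, seed=3))
        )
        for rec in cohort.records:
            for pos in (2, 3):
                a = rec.measurements[pos].angle
                assert abs(a) <= 15 + 1e-9 or a > 15  # never posteriorly displaced


class TestSceneInvariance:
    def test_scene_nuisance_does_not_move_derived_values(self):
        # same seed, different rigid-motion/jitter settings: identical latent
        # draws, hence identical measured angles and coordinates
        base = SimulationConfig(seed=31)
        wild = SimulationConfig(
            seed=31,
            scene=SceneConfig(rotation_range_deg=45.0, translation_range_mm=40.0,
                              landmark_jitter_sd=1.5),
        )
        a = measure_cohort(simulate_cohort(base))
        b = measure_cohort(simulate_cohort(wild))
        for ra, rb in zip(a.records, b.records):
            for pos in (1, 2, 3):
                assert ra.measurements[pos].angle == pytest.approx(
                    rb.measurements[pos].angle, abs=1e-9)
                assert ra.measurements[pos].condyle.x == pytest.approx(
                    rb.measurements[pos].condyle.x, abs=1e-9)
                assert ra.measurements[pos].condyle.y == pytest.approx(
                    rb.measurements[pos].condyle.y, abs=1e-9)


class TestRaterNoise:
    def test_zero_noise_identity_and_perfect_icc(self):
        cohort = simulate_cohort(SimulationConfig(n_normal=5, n_ddwr=10, n_ddwor=0, seed=2))
        replica = add_rater_noise(cohort, 0.0, seed=99)
        assert cohort_equal(cohort, replica)
        res = reliability_icc([cohort, replica], variables=("angle",))
        assert res["angle"].icc == pytest.approx(1.0, abs=1e-12)

    def test_original_untouched(self):
        cohort = simulate_cohort(SimulationConfig(n_normal=2, n_ddwr=2, n_ddwor=0, seed=4))
        before = {(r.joint_id, pos): lm.C.copy()
                  for r in cohort.records for pos, lm in r.landmarks.items()}
        add_rater_noise(cohort, 0.8, seed=5)
        for r in cohort.records:
            for pos, lm in r.landmarks.items():
                assert np.array_equal(lm.C, before[(r.joint_id, pos)])

    def test_noise_determinism(self):
        cohort = simulate_cohort(SimulationConfig(n_normal=2, n_ddwr=3, n_ddwor=0, seed=6))
        a = add_rater_noise(cohort, 0.4, seed=8)
        b = add_rater_noise(cohort, 0.4, seed=8)
        assert cohort_equal(a, b)

    def test_angle_icc_matches_variance_ratio(self):
        # two replicates of a heterogeneous cohort: ICC of measured angles
        # should approximate sb2 / (sb2 + sm2) with the measurement variance
        # sm2 propagated empirically from many replicates
        cfg = SimulationConfig(n_normal=0, n_ddwor=0, n_ddwr=2000, seed=10)
        cohort = simulate_cohort(cfg)
        noise_sd = 0.3
        reps = [
            measure_cohort(add_rater_noise(cohort, noise_sd, seed=100 + k))
            for k in range(4)
        ]
        angles = np.array(
            [[rep.records[i].measurements[1].angle for rep in reps]
             for i in range(len(cohort.records))]
        )
        sm2 = angles.var(axis=1, ddof=1).mean()  # propagated measurement variance
        sb2 = angles.mean(axis=1).var(ddof=1) - sm2 / angles.shape[1]
        expected = sb2 / (sb2 + sm2)
        got = icc(angles[:, :2], model="twoway_random_absolute").icc
        assert got == pytest.approx(expected, abs=0.03)

    def test_icc_decreases_with_noise(self):
        cfg = SimulationConfig(n_normal=0, n_ddwor=0, n_ddwr=300, seed=12)
        cohort = simulate_cohort(cfg)
        mean_iccs = []
        for noise_sd in (0.1, 0.5, 1.5):
            vals = []
            for s in range(3):  # average over noise seeds
                reps = [
                    measure_cohort(add_rater_noise(cohort, noise_sd, seed=1000 * s + k))
                    for k in range(2)
                ]
                mat = np.array(
                    [[rep.records[i].measurements[1].angle for rep in reps]
                     for i in range(len(cohort.records))]
                )
                vals.append(icc(mat, model="twoway_random_absolute").icc)
            mean_iccs.append(np.mean(vals))
        assert mean_iccs[0] > mean_iccs[1] > mean_iccs[2]

    def test_negative_noise_rejected(self):
        cohort = simulate_cohort(SimulationConfig(n_normal=1, n_ddwr=1, n_ddwor=0, seed=1))
        with pytest.raises(ValidationError):
            add_rater_noise(cohort, -0.1, seed=0)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_ddwr=-1)
        with pytest.raises(ValidationError):
            SimulationConfig(disc_radius_sd=0.0)
        with pytest.raises(ValidationError):
            SimulationConfig(recapture_prob={2: 1.5, 3: 0.3})
        with pytest.raises(ValidationError):
            SimulationConfig(position_corr=-0.2)
        bad_angles = {
            "normal": {1: (-1.1, 0.0), 2: (-11.7, 12.0), 3: (-2.7, 15.5)},
            "DDwR": {1: (53.4, 16.7), 2: (-10.5, 17.1), 3: (30.1, 26.9)},
            "DDwoR": {1: (82.1, 16.7), 2: (65.5, 16.7), 3: (70.1, 16.7)},
        }
        with pytest.raises(ValidationError):
            SimulationConfig(angle_params=bad_angles)

    def test_from_dict_round_trip(self):
        cfg = SimulationConfig(n_ddwr=12, seed=77)
        rebuilt = SimulationConfig.from_dict(cfg.to_dict())
        assert rebuilt.n_ddwr == 12 and rebuilt.seed == 77
        assert rebuilt.angle_params == cfg.angle_params
        assert rebuilt.condyle_params == cfg.condyle_params
        a = simulate_cohort(cfg)
        b = simulate_cohort(rebuilt)
        assert cohort_equal(a, b)

    def test_from_dict_string_position_keys(self):
        cfg = SimulationConfig.from_dict(
            {"n_ddwr": 4, "n_normal": 0, "n_ddwor": 0,
             "recapture_prob": {"2": 0.9, "3": 0.2}, "seed": 3}
        )
        assert cfg.recapture_prob == {2: 0.9, 3: 0.2}

    def test_position_correlation_links_positions(self):
        # with full correlation a joint's condyle z-scores agree across positions
        cfg = SimulationConfig(n_normal=0, n_ddwor=0, n_ddwr=400, seed=21,
                               position_corr=1.0)
        cohort = measure_cohort(simulate_cohort(cfg))
        z1, z2 = [], []
        for rec in cohort.records:
            (m1, s1), _ = cfg.condyle_params["DDwR"][1]
            (m2, s2), _ = cfg.condyle_params["DDwR"][2]
            z1.append((rec.measurements[1].condyle.x - m1) / s1)
            z2.append((rec.measurements[2].condyle.x - m2) / s2)
        assert np.corrcoef(z1, z2)[0, 1] > 0.999
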