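import numpy as np
import pytest

from cstval.agreement import confusion_matrix, normalize_confusion, summary_metrics
from cstval.hypnogram import WAKE, align_to_reference
from cstval.measures import derive_measures
from cstval.report import device_table
from cstval.simulate import (
    CohortConfig,
    ConfigError,
    DeviceErrorModel,
    DeviceSpec,
    SiteConfig,
    SleepArchitectureParams,
    deep_biased_error_model,
    default_cohort_config,
    identity_error_model,
    nearable_error_model,
    simulate_cohort,
    simulate_device,
    simulate_psg,
    sticky_resampling_matrix,
)
from cstval.pipeline import session_results_from_cohort


def tiny_site(n=2, site_id="S1"):
    return SiteConfig(site_id, n, 0.5, 40, 10, 23, 3, 12, 8, 7.0, 0.5)


class TestSimulatePsg:
    def test_absorbing_wake_chain(self):
        params = SleepArchitectureParams(transition_matrix=np.eye(4))
        h = simulate_psg(params, 0)
        assert (h.labels == WAKE).all()

    def test_uniform_chain_occupancies(self):
        # ~10,000 epochs: every stage near 25 %
        params = SleepArchitectureParams(
            tib_mean_h=10_000 * 30 / 3600,
            tib_sd_h=0.0,
            transition_matrix=np.full((4, 4), 0.25),
        )
        h = simulate_psg(params, 123)
        occ = np.bincount(h.labels, minlength=4) / h.n_epochs
        assert np.abs(occ - 0.25).max() < 0.02

    def test_deterministic_given_seed(self):
        params = SleepArchitectureParams()
        a = simulate_psg(params, 99)
        b = simulate_psg(params, 99)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_invalid_transition_matrix_rejected(self):
        with pytest.raises(ValueError):
            SleepArchitectureParams(transition_matrix=np.ones((4, 4)))

    def test_calibrated_defaults_recover_cohort_targets(self):
        """500 nights under the default architecture: cohort mean sleep
        efficiency within two standard errors of the 81 % target, and
        SOL/WASO near their 0.27 h / 1.15 h targets."""
        params = SleepArchitectureParams()
        rng = np.random.default_rng(2023)
        se, sol, waso = [], [], []
        for _ in range(500):
            m = derive_measures(simulate_psg(params, rng))
            se.append(m.se_pct)
            sol.append(m.sol_h)
            waso.append(m.waso_h)
        se = np.array(se)
        assert abs(se.mean() - 81.0) < 2 * se.std(ddof=1) / np.sqrt(len(se))
        assert abs(np.mean(sol) - params.target_sol_mean_h) < 0.05
        assert abs(np.mean(waso) - params.target_waso_mean_h) < 0.15


class TestSimulateDevice:
    def test_identity_emission_gives_perfect_agreement(self):
        psg = simulate_psg(SleepArchitectureParams(), 7)
        dev = simulate_device(psg, identity_error_model(), 8)
        pair = align_to_reference(dev, psg)
        s = summary_metrics(confusion_matrix(pair))
        assert s.accuracy == 1.0 and s.kappa == 1.0 and s.macro_f1 == 1.0

    def test_wake_to_light_confusion_recovered(self):
        emission = np.eye(4)
        emission[0] = [0.3, 0.7, 0.0, 0.0]
        model = DeviceErrorModel(emission_matrix=emission)
        rng = np.random.default_rng(11)
        total = None
        for _ in range(30):
            psg = simulate_psg(SleepArchitectureParams(tib_mean_h=8.0), rng)
            dev = simulate_device(psg, model, rng)
            cm = confusion_matrix(align_to_reference(dev, psg))
            total = cm if total is None else total + cm
        wake_row = normalize_confusion(total).proportions[0]
        np.testing.assert_allclose(wake_row, [0.3, 0.7, 0, 0], atol=0.02)

    def test_dropout_certain(self):
        psg = simulate_psg(SleepArchitectureParams(), 1)
        model = identity_error_model(dropout_prob=1.0)
        assert simulate_device(psg, model, 2) is None

    def test_offset_and_grid_respected(self):
        psg = simulate_psg(SleepArchitectureParams(), 3)
        model = identity_error_model(start_offset_s=90, epoch_duration=60)
        dev = simulate_device(psg, model, 4)
        assert dev.start_time == psg.start_time + 90
        assert dev.epoch_duration == 60
        assert dev.end_time >= psg.end_time

    def test_deep_biased_archetype_dominates_deep_column(self):
        rng = np.random.default_rng(21)
        total = None
        for _ in range(10):
            psg = simulate_psg(SleepArchitectureParams(), rng)
            dev = simulate_device(psg, deep_biased_error_model(), rng)
            cm = confusion_matrix(align_to_reference(dev, psg))
            total = cm if total is None else total + cm
        deep_share = total.col_support[2] / total.total_seconds
        assert deep_share > 0.5  # the device calls most of the night deep


class TestSimulateCohort:
    def test_conflicting_devices_in_one_group_rejected(self):
        devices = (
            DeviceSpec("radarA", "nearable", nearable_error_model(), groups=("A",)),
            DeviceSpec("radarB", "nearable", nearable_error_model(), groups=("A", "B")),
        )
        with pytest.raises(ConfigError, match="conflicting devices"):
            CohortConfig(
                sites=(tiny_site(),),
                devices=devices,
                conflicts=(("radarA", "radarB"),),
            )

    def test_zero_participants_rejected(self):
        with pytest.raises(ConfigError):
            SiteConfig("S1", 0, 0.5, 40, 10, 23, 3, 12, 8, 7.0, 0.5)

    def test_single_participant_single_device(self):
        config = CohortConfig(
            sites=(tiny_site(1),),
            devices=(DeviceSpec("dev", "wearable", identity_error_model()),),
        )
        cohort = simulate_cohort(config)
        assert len(cohort.hypnograms) == 2  # one PSG + one device reading
        assert set(cohort.manifest["role"]) == {"reference", "device"}

    def test_same_seed_byte_identical_output(self, tmp_path):
        config = CohortConfig(
            sites=(tiny_site(3),),
            devices=(DeviceSpec("dev", "wearable", identity_error_model()),),
            seed=5,
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(config, out_dir=d1)
        simulate_cohort(config, out_dir=d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_adding_a_device_does_not_perturb_existing_sessions(self):
        base_dev = DeviceSpec("dev", "wearable", identity_error_model())
        extra = DeviceSpec("extra", "airable", identity_error_model())
        c1 = CohortConfig(sites=(tiny_site(2),), devices=(base_dev,), seed=9)
        c2 = CohortConfig(sites=(tiny_site(2),), devices=(base_dev, extra), seed=9)
        h1 = simulate_cohort(c1).hypnograms
        h2 = simulate_cohort(c2).hypnograms
        for key, h in h1.items():
            np.testing.assert_array_equal(h.labels, h2[key].labels)

    def test_group_split_devices_reach_about_half_the_cohort(self):
        config = default_cohort_config(seed=4)
        cohort = simulate_cohort(config)
        manifest = cohort.manifest
        devices = manifest[manifest["role"] == "device"]
        n_total = manifest["participant_id"].nunique()
        split_only = {
            d.device_id for d in config.devices if d.groups != ("A", "B")
        }
        for device_id in split_only:
            n_dev = devices[devices["device_id"] == device_id][
                "participant_id"
            ].nunique()
            assert n_dev <= (n_total + 1) // 2

    def test_demographics_recovery(self):
        site = SiteConfig("S", 400, 0.6, 45, 12, 24, 4, 15, 10, 7.2, 0.9)
        config = CohortConfig(
            sites=(site,),
            devices=(DeviceSpec("dev", "wearable", identity_error_model()),),
            seed=3,
        )
        manifest = simulate_cohort(config).manifest
        people = manifest.drop_duplicates("participant_id")
        n = len(people)
        # means within ~2 standard errors of the configured moments
        assert abs(people["bmi"].mean() - 24) < 2 * 4 / np.sqrt(n) + 0.1
        male_frac = (people["sex"] == "male").mean()
        assert abs(male_frac - 0.6) < 2 * np.sqrt(0.6 * 0.4 / n) + 0.01

    def test_full_dropout_excludes_device_from_tables(self):
        devices = (
            DeviceSpec("gone", "wearable", identity_error_model(dropout_prob=1.0)),
            DeviceSpec("ok", "wearable", identity_error_model()),
        )
        config = CohortConfig(sites=(tiny_site(2),), devices=devices, seed=1)
        cohort = simulate_cohort(config)
        results = session_results_from_cohort(cohort)
        table = device_table(results)
        assert "gone" not in table.index
        assert table.loc["ok", "n"] == 2
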