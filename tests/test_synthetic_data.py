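import numpy as np
import pandas as pd
import pytest

from csme import (
    SimulationConfig,
    draw_proportions,
    generate_cell_profiles,
    generate_cell_sorted_samples,
    generate_dataset,
    mix_samples,
)
from csme.data_io import CellTypeScheme
from csme.exceptions import InvalidArgumentError, SchemaError
from csme.synthetic_data import write_bundle


class TestGenerateCellProfiles:
    def test_no_differential_signal_gives_identical_columns(self, scheme):
        truth = generate_cell_profiles(100, scheme, diff_fraction=0.0, effect_size=0.4, seed=0)
        arr = truth.cell_profiles.to_numpy()
        assert (arr == arr[:, [0]]).all()
        assert all(len(s) == 0 for s in truth.differential_sets.values())

    def test_differential_counts(self, scheme):
        truth = generate_cell_profiles(1000, scheme, diff_fraction=0.05, effect_size=0.4, seed=1)
        assert all(len(truth.differential_sets[t]) == 50 for t in scheme.base_types)

    def test_differential_sets_disjoint(self, scheme):
        truth = generate_cell_profiles(1000, scheme, diff_fraction=0.05, effect_size=0.4, seed=1)
        sets = list(truth.differential_sets.values())
        union = set().union(*sets)
        assert len(union) == sum(len(s) for s in sets)

    def test_planted_effect_exact_when_unclipped(self, scheme):
        truth = generate_cell_profiles(
            2000, scheme, diff_fraction=0.05, effect_size=0.2, seed=3,
            baseline_levels=(0.3, 0.5, 0.7),
        )
        assert truth.n_clipped_profiles == 0
        profiles = truth.cell_profiles
        for t_idx, cell_type in enumerate(scheme.base_types):
            cpgs = sorted(truth.differential_sets[cell_type])
            x = profiles.loc[cpgs].to_numpy()
            others = np.delete(x, t_idx, axis=1).mean(axis=1)
            np.testing.assert_allclose(np.abs(x[:, t_idx] - others), 0.2, atol=1e-12)

    def test_clipping_recorded_at_upper_bound(self, scheme):
        truth = generate_cell_profiles(
            200, scheme, diff_fraction=0.05, effect_size=0.4, seed=5,
            baseline_levels=(0.9,), baseline_weights=(1.0,),
        )
        assert truth.n_clipped_profiles > 0
        assert truth.cell_profiles.to_numpy().max() <= 1.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_cpgs": 0, "diff_fraction": 0.1, "effect_size": 0.4},
            {"n_cpgs": 100, "diff_fraction": -0.1, "effect_size": 0.4},
            {"n_cpgs": 100, "diff_fraction": 0.1, "effect_size": 0.0},
            {"n_cpgs": 100, "diff_fraction": 0.1, "effect_size": 1.5},
            {"n_cpgs": 10, "diff_fraction": 0.9, "effect_size": 0.4},  # disjointness overflow
        ],
    )
    def test_invalid_arguments(self, scheme, kwargs):
        with pytest.raises(InvalidArgumentError):
            generate_cell_profiles(seed=0, scheme=scheme, **kwargs)


class TestDrawProportions:
    @pytest.fixture
    def truth(self, scheme):
        return generate_cell_profiles(
            50, scheme, 0.1, 0.4, seed=0, proportion_mode="dirichlet"
        )

    def test_default_means_follow_configured_table(self, truth):
        # printed FACS means, normalized (they sum to 99.1%)
        expected = {
            "Neutrophil": 65.0, "CD4T": 13.4, "CD8T": 6.1, "CD56NK": 2.4,
            "CD19B": 3.0, "CD14Mono": 5.4, "Eosinophil": 3.8,
        }
        total = sum(expected.values())
        for t, pct in expected.items():
            assert truth.mean_proportions[t] == pytest.approx(pct / total)

    def test_high_concentration_rows_near_mean(self, truth, scheme):
        props = draw_proportions(5, truth, concentration=1e9, seed=1)
        means = np.array([truth.mean_proportions[t] for t in scheme.base_types])
        got = props.fractions[list(scheme.base_types)].to_numpy()
        np.testing.assert_allclose(got, np.broadcast_to(means, got.shape), atol=1e-3)

    def test_dirichlet_monte_carlo_means(self, truth, scheme):
        props = draw_proportions(10000, truth, concentration=50.0, seed=7)
        means = np.array([truth.mean_proportions[t] for t in scheme.base_types])
        emp = props.fractions[list(scheme.base_types)].to_numpy().mean(axis=0)
        np.testing.assert_allclose(emp, means, atol=0.01)

    def test_dirichlet_means_within_three_standard_errors(self, truth, scheme):
        conc = 50.0
        n = 4000
        props = draw_proportions(n, truth, concentration=conc, seed=13)
        means = np.array([truth.mean_proportions[t] for t in scheme.base_types])
        var = means * (1 - means) / (conc + 1)
        se = np.sqrt(var / n)
        emp = props.fractions[list(scheme.base_types)].to_numpy().mean(axis=0)
        assert (np.abs(emp - means) <= 3 * se).all()

    def test_fixed_remainder_structure(self, scheme):
        truth = generate_cell_profiles(50, scheme, 0.1, 0.4, seed=0)
        props = draw_proportions(6, truth, seed=0, target="CD8T", scheme=scheme)
        frac = props.fractions
        target = frac["CD8T"].to_numpy()
        assert np.ptp(target) > 0
        others = [t for t in scheme.base_types if t != "CD8T"]
        rest = frac[others].to_numpy()
        expected = np.broadcast_to(((1 - target) / 6)[:, None], rest.shape)
        np.testing.assert_allclose(rest, expected, atol=1e-12)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-9)

    def test_too_few_subjects_rejected(self, truth):
        with pytest.raises(InvalidArgumentError):
            draw_proportions(1, truth, seed=0)

    def test_degenerate_mean_rejected(self, scheme):
        with pytest.raises(InvalidArgumentError):
            generate_cell_profiles(
                50, scheme, 0.1, 0.4, seed=0,
                mean_proportions={t: (0.0 if t == "CD4T" else 1.0) for t in scheme.base_types},
            )


class TestMixSamples:
    def test_weighted_average_two_types(self):
        scheme2 = CellTypeScheme(("A", "B"))
        truth = generate_cell_profiles(
            1, scheme2, 0.0, 0.4, seed=0,
            mean_proportions={"A": 0.6, "B": 0.4},
        )
        truth.cell_profiles.iloc[0] = [0.5, 0.25]
        props = draw_proportions(2, truth, seed=0, scheme=scheme2)
        props.fractions.iloc[0] = [0.6, 0.4]
        mixed = mix_samples(truth, props, seed=0)
        assert mixed.values.iloc[0, 0] == pytest.approx(0.4, abs=1e-15)

    def test_identity_mixture_returns_first_profile(self, scheme):
        truth = generate_cell_profiles(100, scheme, 0.1, 0.4, seed=2)
        props = draw_proportions(3, truth, seed=0, scheme=scheme)
        rows = np.zeros((3, 7))
        rows[:, 0] = 1.0
        props.fractions.iloc[:, :] = rows
        mixed = mix_samples(truth, props, seed=0)
        for i in range(3):
            np.testing.assert_array_equal(
                mixed.values.iloc[i].to_numpy(), truth.cell_profiles.iloc[:, 0].to_numpy()
            )

    def test_noise_mean_clt_bound(self, scheme):
        truth = generate_cell_profiles(
            10000, scheme, 0.0, 0.4, seed=3, noise_sd=0.01,
            baseline_levels=(0.5,), baseline_weights=(1.0,),
        )
        props = draw_proportions(4, truth, seed=1, scheme=scheme)
        noisy = mix_samples(truth, props, seed=9)
        truth0 = generate_cell_profiles(
            10000, scheme, 0.0, 0.4, seed=3, noise_sd=0.0,
            baseline_levels=(0.5,), baseline_weights=(1.0,),
        )
        clean = mix_samples(truth0, props, seed=9)
        resid = (noisy.values - clean.values).to_numpy()
        assert abs(resid.mean(axis=1)).max() <= 3 * 0.01 / np.sqrt(10000)

    def test_column_mismatch_schema_error(self, scheme):
        truth = generate_cell_profiles(10, scheme, 0.0, 0.4, seed=0)
        scheme2 = CellTypeScheme(("A", "B"))
        truth2 = generate_cell_profiles(
            10, scheme2, 0.0, 0.4, seed=0, mean_proportions={"A": 0.5, "B": 0.5}
        )
        props2 = draw_proportions(3, truth2, seed=0, scheme=scheme2)
        with pytest.raises(SchemaError):
            mix_samples(truth, props2, seed=0)


class TestCellSortedSamples:
    def test_zero_sd_reproduces_profiles(self, scheme):
        truth = generate_cell_profiles(200, scheme, 0.05, 0.4, seed=4)
        sorted_bm = generate_cell_sorted_samples(truth, 3, 0.0, seed=0)
        for sid in sorted_bm.sample_ids:
            label = sorted_bm.samples.loc[sid, "cell_label"]
            np.testing.assert_array_equal(
                sorted_bm.values.loc[sid].to_numpy(),
                truth.cell_profiles[label].to_numpy(),
            )

    def test_design_count_six_subjects_seven_types(self, scheme):
        truth = generate_cell_profiles(10, scheme, 0.0, 0.4, seed=0)
        sorted_bm = generate_cell_sorted_samples(truth, 6, 0.01, seed=0)
        assert sorted_bm.n_samples == 42
        counts = sorted_bm.samples.groupby(["subject_id", "cell_label"]).size()
        assert (counts == 1).all()

    def test_per_cpg_mean_tail_bound(self, scheme):
        sd, n_subj = 0.02, 6
        truth = generate_cell_profiles(
            5000, scheme, 0.0, 0.4, seed=5, baseline_levels=(0.5,), baseline_weights=(1.0,)
        )
        sorted_bm = generate_cell_sorted_samples(truth, n_subj, sd, seed=2)
        one_type = sorted_bm.select_samples(sorted_bm.samples["cell_label"] == "CD4T")
        means = one_type.values.to_numpy().mean(axis=0)
        dev = np.abs(means - truth.cell_profiles["CD4T"].to_numpy())
        assert (dev <= 4 * sd / np.sqrt(n_subj)).mean() >= 0.99

    def test_negative_sd_rejected(self, scheme):
        truth = generate_cell_profiles(10, scheme, 0.0, 0.4, seed=0)
        with pytest.raises(InvalidArgumentError):
            generate_cell_sorted_samples(truth, 3, -0.1, seed=0)


class TestGenerateDataset:
    def test_seed_determinism_byte_identical(self, tmp_path):
        config = SimulationConfig(n_cpgs=300, n_subjects=4, noise_sd=0.01,
                                  within_subject_sd=0.01, seed=42)
        for name in ("one", "two"):
            write_bundle(generate_dataset(config), tmp_path / name)
        for fname in ("betas_sorted.tsv", "betas_mixed.tsv", "proportions.tsv", "truth.json"):
            assert (tmp_path / "one" / fname).read_bytes() == (
                tmp_path / "two" / fname
            ).read_bytes()

    def test_different_seeds_differ(self):
        base = SimulationConfig(n_cpgs=100, n_subjects=4, noise_sd=0.01, seed=1).to_dict()
        b1 = generate_dataset(SimulationConfig.from_dict(base))
        b2 = generate_dataset(SimulationConfig.from_dict({**base, "seed": 2}))
        assert not np.array_equal(b1.mixed_data.values.to_numpy(), b2.mixed_data.values.to_numpy())

    def test_shapes(self):
        config = SimulationConfig(n_cpgs=500, n_subjects=6, seed=0)
        bundle = generate_dataset(config)
        assert bundle.mixed_data.values.shape == (6, 500)
        assert bundle.sorted_data.values.shape == (42, 500)
        assert bundle.proportions.fractions.shape == (6, 7)

    def test_conservation_zero_noise(self):
        config = SimulationConfig(n_cpgs=400, n_subjects=5, noise_sd=0.0, seed=3,
                                  proportion_mode="dirichlet")
        bundle = generate_dataset(config)
        p = bundle.proportions.fractions.to_numpy()
        x = bundle.truth.cell_profiles.to_numpy()
        np.testing.assert_allclose(
            bundle.mixed_data.values.to_numpy(), p @ x.T, atol=1e-12
        )

    def test_all_values_bounded(self, noisy_bundle):
        _, bundle = noisy_bundle
        for bm in (bundle.mixed_data, bundle.sorted_data):
            arr = bm.values.to_numpy()
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_invalid_config_fields_named(self):
        with pytest.raises(InvalidArgumentError, match="n_subjects"):
            SimulationConfig(n_subjects=1)
        with pytest.raises(InvalidArgumentError, match="effect_size"):
            SimulationConfig(effect_size=0.0)
        with pytest.raises(InvalidArgumentError, match="unknown config fields"):
            SimulationConfig.from_dict({"n_cpg": 10})

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        config = SimulationConfig(n_cpgs=50, n_subjects=4, seed=9)
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(config.to_dict()))
        assert SimulationConfig.from_yaml(path) == config
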