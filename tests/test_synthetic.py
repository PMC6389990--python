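import numpy as np
import pytest

from semdecode.synthetic import (
    BetaStack,
    GenerationConfig,
    GroundTruth,
    assemble_trials,
    generate_dataset,
    generate_ground_truth,
    generate_space_and_norms,
    read_fixtures,
    simulate_betas,
    write_fixtures,
)


def small_config(**overrides):
    base = dict(
        items_per_category=2,
        dim=12,
        grid_shape=(7, 7, 7),
        n_informative=20,
        nonclue_features_per_target=3,
        seed=4,
    )
    base.update(overrides)
    return GenerationConfig(**base)


class TestConfig:
    def test_validation_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            GenerationConfig(n_categories=0)
        with pytest.raises(ValueError):
            GenerationConfig(noise_sd=-1.0)
        with pytest.raises(ValueError):
            small_config(n_informative=10_000)

    def test_roundtrip_dict(self):
        cfg = small_config(noise_sd=3.5)
        assert GenerationConfig.from_dict(cfg.to_dict()) == cfg


class TestSpaceAndNorms:
    def test_study_scale_counts(self):
        """Default design: 60 targets in 4 categories, 9 clues each = 540
        clue descriptions, plus non-clue features."""
        space, norms, kmap = generate_space_and_norms(GenerationConfig())
        assert len(norms.targets) == 60
        assert int(norms.table["is_clue"].sum()) == 540
        assert norms.table.groupby("target").size().eq(19).all()
        # every feature and target resolves to a vector
        for text, token in kmap.mapping.items():
            assert token in space

    def test_degenerate_dispersion_collapses_features(self):
        cfg = small_config(sigma_item=0.0, sigma_feat=0.0, alpha=1.0)
        space, norms, _ = generate_space_and_norms(cfg)
        for target in norms.targets:
            tvec = space.vector(target)
            for j in range(cfg.clues_per_target + cfg.nonclue_features_per_target):
                np.testing.assert_array_equal(space.vector(f"{target}_f{j + 1:02d}"), tvec)

    def test_same_seed_identical_output(self):
        cfg = small_config()
        s1, n1, k1 = generate_space_and_norms(cfg)
        s2, n2, k2 = generate_space_and_norms(cfg)
        assert n1.table.equals(n2.table) and k1.mapping == k2.mapping
        for token in s1.vectors:
            np.testing.assert_array_equal(s1.vector(token), s2.vector(token))


@pytest.fixture(scope="module")
def trials():
    cfg = small_config()
    _, norms, _ = generate_space_and_norms(cfg)
    return assemble_trials(norms, cfg), norms


class TestTrialAssembly:

    def test_six_trials_per_target(self, trials):
        table, norms = trials
        assert table.groupby("target").size().eq(6).all()
        assert len(table) == 6 * len(norms.targets)

    def test_each_clue_twice_same_position(self, trials):
        table, _ = trials
        for target, sub in table.groupby("target"):
            for pos in ("clue1", "clue2", "clue3"):
                per_set = sub.groupby("set")[pos].apply(set)
                assert per_set[1] == per_set[2]  # same clues at this position
            counts = sub[["clue1", "clue2", "clue3"]].stack().value_counts()
            assert counts.eq(2).all()  # every clue appears in exactly 2 trials

    def test_triplets_pairwise_distinct(self, trials):
        table, _ = trials
        for _, sub in table.groupby("target"):
            triplets = [frozenset(r) for r in sub[["clue1", "clue2", "clue3"]].to_numpy()]
            assert len(set(triplets)) == 6

    def test_donor_shares_target_but_no_clue(self, trials):
        """Exhaustive check of MIXED_CLUES donor validity on every trial."""
        table, _ = trials
        by_id = table.set_index("trial_id")
        for _, row in table.iterrows():
            donor = by_id.loc[row["donor_trial"]]
            assert donor["target"] == row["target"]
            own = {row["clue1"], row["clue2"], row["clue3"]}
            assert not own & {donor["clue1"], donor["clue2"], donor["clue3"]}

    def test_duplicate_clue_texts_rejected(self):
        cfg = small_config()
        _, norms, _ = generate_space_and_norms(cfg)
        table = norms.table.copy()
        first_clues = table[(table["target"] == norms.targets[0]) & table["is_clue"]]
        table.loc[first_clues.index[1], "feature"] = first_clues["feature"].iloc[0]
        from semdecode.semantic_space import FeatureNorms

        with pytest.raises(ValueError):
            assemble_trials(FeatureNorms(table), cfg)


class TestBetaSimulation:
    def test_noise_free_repetitions_identical(self):
        cfg = small_config(noise_sd=0.0)
        ds = generate_dataset(cfg, n_subjects=1)
        betas, trials = ds.beta_stacks[0].betas, ds.trials
        for target, sub in trials.groupby("target"):
            rows = betas[sub.index.to_numpy()]
            assert np.ptp(rows, axis=0).max() == 0.0

    def test_identity_forward_model_reproduces_coordinates(self):
        cfg = small_config(noise_sd=0.0)
        space, norms, kmap = generate_space_and_norms(cfg)
        trials = assemble_trials(norms, cfg)
        truth = generate_ground_truth(space, norms, kmap, cfg, 0)
        W = np.zeros_like(truth.forward_weights)
        W[truth.informative[: cfg.dim], np.arange(cfg.dim)] = 1.0
        ident = GroundTruth(
            forward_weights=W,
            informative=truth.informative,
            target_coordinates=truth.target_coordinates,
            targets=truth.targets,
            categories=truth.categories,
        )
        stack = simulate_betas(trials, space, norms, kmap, ident, cfg, 0)
        coord = dict(zip(truth.targets, truth.target_coordinates))
        for pos, target in enumerate(trials["target"]):
            np.testing.assert_allclose(
                stack.betas[pos, truth.informative[: cfg.dim]], coord[target]
            )

    def test_noninformative_voxels_pure_noise_scale(self):
        cfg = small_config(noise_sd=1.0, seed=9)
        ds = generate_dataset(cfg, n_subjects=1)
        truth, stack = ds.ground_truths[0], ds.beta_stacks[0]
        noise_vox = np.setdiff1d(np.arange(stack.n_voxels), truth.informative)
        sd = stack.betas[:, noise_vox].std()
        assert 0.9 < sd < 1.1

    def test_dimension_mismatch_rejected(self):
        cfg = small_config()
        space, norms, kmap = generate_space_and_norms(cfg)
        trials = assemble_trials(norms, cfg)
        truth = generate_ground_truth(space, norms, kmap, cfg, 0)
        bad = GroundTruth(
            forward_weights=truth.forward_weights[:, :-1],
            informative=truth.informative,
            target_coordinates=truth.target_coordinates[:, :-1],
            targets=truth.targets,
            categories=truth.categories,
        )
        with pytest.raises(ValueError):
            simulate_betas(trials, space, norms, kmap, bad, cfg, 0)

    def test_full_determinism_under_master_seed(self):
        cfg = small_config(seed=21)
        d1 = generate_dataset(cfg, n_subjects=2)
        d2 = generate_dataset(cfg, n_subjects=2)
        for s in range(2):
            np.testing.assert_array_equal(
                d1.beta_stacks[s].betas, d2.beta_stacks[s].betas
            )
            np.testing.assert_array_equal(
                d1.ground_truths[s].informative, d2.ground_truths[s].informative
            )

    def test_contiguous_blob_shared_across_subjects(self):
        cfg = small_config(contiguous_informative=True)
        ds = generate_dataset(cfg, n_subjects=3)
        base = ds.ground_truths[0].informative
        for gt in ds.ground_truths[1:]:
            np.testing.assert_array_equal(gt.informative, base)
        # contiguity: every blob voxel within 2 voxels of another blob voxel
        coords = np.argwhere(cfg.build_mask())[base]
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(coords))
        np.fill_diagonal(d, np.inf)
        assert d.min(axis=1).max() <= 2.0


class TestFixtureIO:
    def test_roundtrip_bit_identical(self, tmp_path, tiny_dataset):
        write_fixtures(tiny_dataset, tmp_path)
        back = read_fixtures(tmp_path)
        np.testing.assert_array_equal(
            back.beta_stacks[0].betas, tiny_dataset.beta_stacks[0].betas
        )
        assert back.trials.equals(tiny_dataset.trials)
        assert back.config == tiny_dataset.config

    def test_mask_count_matches_columns_and_affine(self, tmp_path, tiny_dataset):
        import nibabel as nib

        paths = write_fixtures(tiny_dataset, tmp_path)
        mask_img = nib.load(paths["mask"])
        stack = tiny_dataset.beta_stacks[0]
        assert int(np.asarray(mask_img.dataobj).sum()) == stack.n_voxels
        np.testing.assert_allclose(np.diag(mask_img.affine)[:3], 3.1)
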