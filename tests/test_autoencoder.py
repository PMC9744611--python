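"""Autoencoder contracts: splits, standardization, architecture, training,
grid search and score orientation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from crossdeg.autoencoder import (
    AeConfig,
    HyperGrid,
    build_autoencoder,
    encode_and_orient,
    fit_encoder,
    fit_standardizer,
    grid_search,
    split_train_holdout,
    train_autoencoder,
)
from .conftest import make_cohort

FAST = AeConfig(hidden_widths=(16, 8, 4), max_epochs=80, patience=15, n_restarts=2)


def rank1_matrix(n_genes=40, n_samples=30, noise=0.2, seed=0, cohort="X"):
    """Single latent factor with low noise; returns (matrix, meta, z)."""
    rng = np.random.default_rng(seed)
    z = rng.normal(0, 1, n_samples)
    lam = rng.uniform(0.8, 1.2, n_genes) * np.sign(rng.normal(size=n_genes))
    x = 7.0 + np.outer(lam, z) + rng.normal(0, noise, (n_genes, n_samples))
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"{cohort}s{i:02d}" for i in range(n_samples)]
    # call the top-half of z "cases" so orientation has a meaning
    group = np.where(z > np.median(z), "case", "control")
    meta = pd.DataFrame(
        {"sample_id": samples, "cohort": cohort, "group": group, "batch": "b"}
    )
    return pd.DataFrame(x, index=genes, columns=samples), meta, pd.Series(z, index=samples)


class TestSplit:
    def test_three_to_two_ratio(self):
        _, meta = make_cohort(n_cases=50, n_controls=50)
        split = split_train_holdout(meta, seed=4)
        assert (split == "train").sum() == 60
        assert (split == "holdout").sum() == 40
        cases_train = ((split == "train") & meta.set_index("sample_id")["group"].eq("case").loc[split.index]).sum()
        assert abs(cases_train - 30) <= 1

    def test_seeded_determinism_and_partition(self):
        _, meta = make_cohort(n_cases=13, n_controls=9)
        s1 = split_train_holdout(meta, seed=7)
        s2 = split_train_holdout(meta, seed=7)
        pd.testing.assert_series_equal(s1, s2)
        assert set(s1.index) == set(meta["sample_id"])
        assert set(s1.unique()) == {"train", "holdout"}

    def test_tiny_group_rejected(self):
        _, meta = make_cohort(n_cases=1, n_controls=5)
        with pytest.raises(ValueError, match="case"):
            split_train_holdout(meta, seed=0)


class TestStandardizer:
    def test_training_split_self_transform_is_zero_mean_unit_sd(self, tiny_cohort):
        expr, meta = tiny_cohort
        split = split_train_holdout(meta, seed=1)
        std = fit_standardizer(expr, split)
        train_cols = split.index[split == "train"]
        z = std.transform(expr[list(train_cols)])
        assert z.mean(axis=1).abs().max() < 1e-10
        assert (z.std(axis=1, ddof=1) - 1).abs().max() < 1e-10

    def test_holdout_transform_matches_formula(self, tiny_cohort):
        expr, meta = tiny_cohort
        split = split_train_holdout(meta, seed=1)
        std = fit_standardizer(expr, split)
        hold = list(split.index[split == "holdout"])
        train = list(split.index[split == "train"])
        mu = expr[train].mean(axis=1)
        sd = expr[train].std(axis=1, ddof=1)
        expected = expr[hold].sub(mu, axis=0).div(sd, axis=0)
        pd.testing.assert_frame_equal(std.transform(expr[hold]), expected)

    def test_constant_gene_maps_to_zero_with_warning(self, tiny_cohort):
        expr, meta = tiny_cohort
        expr = expr.copy()
        expr.iloc[0] = 3.14
        split = split_train_holdout(meta, seed=1)
        with pytest.warns(UserWarning, match="zero training variance"):
            std = fit_standardizer(expr, split)
        assert (std.transform(expr).iloc[0] == 0).all()


class TestArchitecture:
    def test_default_widths_for_266_genes(self):
        net = build_autoencoder(266, AeConfig())
        assert net.widths == [266, 128, 64, 10, 1, 10, 64, 128, 266]

    def test_parameter_count_closed_form(self):
        net = build_autoencoder(50, AeConfig(hidden_widths=(16, 8, 4)))
        widths = [50, 16, 8, 4, 1, 4, 8, 16, 50]
        expected = sum(a * b + b for a, b in zip(widths[:-1], widths[1:]))
        assert net.parameter_count() == expected

    def test_bottleneck_is_one_dimensional(self):
        net = build_autoencoder(20, FAST)
        x = np.random.default_rng(0).normal(size=(7, 20))
        assert net.encode(x).shape == (7, 1)

    @pytest.mark.parametrize("widths", [(8, 16), (4,) * 2, (0, 2)])
    def test_invalid_widths_rejected(self, widths):
        with pytest.raises(ValueError, match="hidden_widths"):
            build_autoencoder(20, AeConfig(hidden_widths=widths))


class TestTraining:
    def test_seeded_training_is_bit_reproducible(self):
        expr, meta, _ = rank1_matrix(seed=5)
        split = split_train_holdout(meta, seed=5)
        std = fit_standardizer(expr, split)
        z = std.transform(expr)
        nets = []
        for _ in range(2):
            net = build_autoencoder(expr.shape[0], FAST)
            net, *_ = train_autoencoder(net, z, split, FAST)
            nets.append(net)
        for w1, w2 in zip(nets[0].weights, nets[1].weights):
            np.testing.assert_array_equal(w1, w2)

    def test_best_epoch_weights_restored(self):
        expr, meta, _ = rank1_matrix(seed=6)
        split = split_train_holdout(meta, seed=6)
        z = fit_standardizer(expr, split).transform(expr)
        net = build_autoencoder(expr.shape[0], FAST)
        net, history, best_epoch = train_autoencoder(net, z, split, FAST)
        assert best_epoch == history.loc[history["val_mse"].idxmin(), "epoch"]
        # restored network reproduces the best holdout MSE exactly
        hold = [s for s in split.index if split[s] == "holdout"]
        x_hold = z[hold].to_numpy().T
        out, _ = net.forward(x_hold, train=False)
        assert float(np.mean((out - x_hold) ** 2)) == pytest.approx(
            history["val_mse"].min(), abs=1e-12
        )

    def test_nonfinite_loss_cites_learning_rate(self):
        expr, meta, _ = rank1_matrix(seed=6)
        split = split_train_holdout(meta, seed=6)
        z = fit_standardizer(expr, split).transform(expr)
        cfg = AeConfig(hidden_widths=(16, 8, 4), max_epochs=50)
        net = build_autoencoder(expr.shape[0], cfg)
        net.weights[0][:] = np.nan  # simulate a diverged update
        with pytest.raises(FloatingPointError, match="learning rate"):
            train_autoencoder(net, z, split, cfg)


class TestOrientationAndInference:
    @pytest.fixture(scope="class")
    def fitted(self):
        expr, meta, z = rank1_matrix(seed=8)
        split = split_train_holdout(meta, seed=8)
        enc = fit_encoder(expr, meta, split, FAST)
        return expr, meta, z, split, enc

    def test_inference_deterministic(self, fitted):
        expr, _, _, _, enc = fitted
        pd.testing.assert_series_equal(enc.encode(expr), enc.encode(expr))

    def test_orientation_contract_on_training_samples(self, fitted):
        expr, meta, _, split, enc = fitted
        train = [s for s in split.index if split[s] == "train"]
        scores = enc.encode(expr[train])
        groups = meta.set_index("sample_id")["group"]
        assert (
            scores[[s for s in train if groups[s] == "case"]].mean()
            >= scores[[s for s in train if groups[s] == "control"]].mean()
        )

    def test_negating_orientation_negates_scores(self, fitted):
        expr, _, _, _, enc = fitted
        s1 = enc.encode(expr)
        enc.orientation *= -1
        s2 = enc.encode(expr)
        enc.orientation *= -1
        np.testing.assert_allclose(s1.values, -s2.values)

    def test_serialization_round_trip(self, fitted, tmp_path):
        expr, _, _, _, enc = fitted
        from crossdeg.autoencoder import TrainedEncoder

        enc.save(tmp_path / "enc.npz", tmp_path / "enc.yaml")
        loaded = TrainedEncoder.load(tmp_path / "enc.npz", tmp_path / "enc.yaml")
        pd.testing.assert_series_equal(enc.encode(expr), loaded.encode(expr))
        assert loaded.orientation == enc.orientation
        assert loaded.genes == enc.genes

    def test_missing_genes_listed(self, fitted):
        expr, meta, _, _, enc = fitted
        with pytest.raises(ValueError, match="g000"):
            encode_and_orient(enc, expr.drop(index=["g000"]), meta)


class TestGridSearch:
    def test_full_grid_enumerates_972_combinations(self):
        grid = HyperGrid()
        assert len(grid) == 972
        assert len(grid.combinations()) == 972

    def test_singleton_grid_returns_that_config(self):
        expr, meta, _ = rank1_matrix(n_genes=20, n_samples=20, seed=9)
        split = split_train_holdout(meta, seed=9)
        z = fit_standardizer(expr, split).transform(expr)
        grid = HyperGrid(
            learning_rates=(0.001,), depths=(6,), w1_options=(8,),
            w2_options=(4,), w3_options=(10,), dropouts=(0.1,),
        )
        base = AeConfig(hidden_widths=(8, 4), max_epochs=20, patience=5)
        best, records = grid_search(z, split, grid, base)
        assert best.hidden_widths == (8, 4)
        assert len(records) == 1

    def test_toy_grid_minimum_and_order_invariance(self):
        expr, meta, _ = rank1_matrix(n_genes=20, n_samples=20, seed=10)
        split = split_train_holdout(meta, seed=10)
        z = fit_standardizer(expr, split).transform(expr)
        base = AeConfig(max_epochs=20, patience=5)
        kw = dict(learning_rates=(0.001, 0.005), depths=(6,), w2_options=(4,),
                  w3_options=(10,), dropouts=(0.1,))
        grid = HyperGrid(w1_options=(8, 12), **kw)
        best, records = grid_search(z, split, grid, base)
        assert len(records) == 4
        assert records.loc[records["val_mse"].idxmin(), "hidden_widths"] == best.hidden_widths
        assert records["val_mse"].min() == records.loc[
            records["learning_rate"] == best.learning_rate
        ].loc[lambda d: d["hidden_widths"] == best.hidden_widths, "val_mse"].min()
        # reordering an option list selects the same model
        grid_r = HyperGrid(w1_options=(12, 8), **kw)
        best_r, _ = grid_search(z, split, grid_r, base)
        assert (best_r.hidden_widths, best_r.learning_rate) == (
            best.hidden_widths, best.learning_rate,
        )


class TestLatentRecovery:
    def test_rank1_latent_recovered_on_holdout(self):
        """On near-noiseless single-factor data the holdout pseudogene ranks
        samples like the true latent severity in >= 8/10 seeds."""
        cfg = AeConfig(hidden_widths=(16, 8, 4), max_epochs=300, patience=30, n_restarts=2)
        hits = 0
        for seed in range(10):
            expr, meta, z = rank1_matrix(n_genes=40, n_samples=40, noise=0.2, seed=30 + seed)
            split = split_train_holdout(meta, seed=seed)
            enc = fit_encoder(expr, meta, split, cfg)
            hold = [s for s in split.index if split[s] == "holdout"]
            rho = spearmanr(enc.encode(expr[hold]), z[hold]).statistic
            hits += abs(rho) >= 0.8
        assert hits >= 8

    def test_training_improves_holdout_mse(self):
        """Final holdout MSE beats the first epoch's in >= 9/10 seeds on a
        266-gene synthetic cohort."""
        from crossdeg.simulate import SyntheticConfig, generate_cohort_pair

        hits = 0
        for seed in range(10):
            cfg = SyntheticConfig(
                n_genes=266, n_shared_deg=100, n_private_deg_per_cohort=0,
                n_cases=30, n_controls=30, seed=60 + seed,
            )
            expr, meta, *_ = generate_cohort_pair(cfg)
            split = split_train_holdout(meta, seed=seed)
            z = fit_standardizer(expr, split).transform(expr)
            net = build_autoencoder(266, AeConfig(seed=seed))
            _, history, _ = train_autoencoder(net, z, split, AeConfig(seed=seed))
            hits += history["val_mse"].iloc[-1] < history["val_mse"].iloc[0]
        assert hits >= 9
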