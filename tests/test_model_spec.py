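"""Specification, loading patterns, implied moments, parameter counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import itemfx as fx
from itemfx.latent_moments import switch_matrix

from conftest import random_admissible_params


class TestBuildSpec:
    @pytest.mark.parametrize(
        "variant, ref, expected",
        [
            ("item_effects", 3,
             ("eta1", "eta2", "eta3", "delta1", "delta2", "delta4", "delta5")),
            ("item_effects", 5,
             ("eta1", "eta2", "eta3", "delta1", "delta2", "delta3", "delta4")),
            ("states_only", 3, ("eta1", "eta2", "eta3")),
        ],
    )
    def test_latent_labels(self, variant, ref, expected):
        spec = fx.build_spec(variant, ref)
        assert spec.latent_labels == expected
        assert spec.m == len(expected)

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError, match="reference_item"):
            fx.build_spec("item_effects", 6)

    def test_too_few_occasions_rejected_citing_identification(self):
        with pytest.raises(ValueError, match="identified"):
            fx.build_spec("item_effects", 1, n_occasions=2)

    def test_spec_dict_roundtrip(self, spec5):
        assert fx.LSTSpec.from_dict(spec5.to_dict()) == spec5


class TestLoadingMatrix:
    def test_item_effect_row_pattern_small_design(self):
        spec = fx.build_spec("item_effects", 1, n_items=2, n_occasions=3)
        L = fx.loading_matrix(spec)
        # row of (item 2, occasion 1): state eta1 plus its delta
        row = L[spec.design.index(2, 1)]
        assert row.tolist() == [1.0, 0.0, 0.0, 1.0]

    def test_states_only_single_nonzero_per_row(self):
        spec = fx.build_spec("states_only", 3)
        lam = np.array([0.9, 1.1, 1.0, 0.8, 1.2])
        L = fx.loading_matrix(spec, lam)
        for i in range(1, 6):
            for t in range(1, 4):
                row = L[spec.design.index(i, t)]
                assert np.count_nonzero(row) == 1
                assert row[t - 1] == lam[i - 1]

    def test_row_sums_identify_reference_item(self, spec3):
        L = fx.loading_matrix(spec3)
        sums = L.sum(axis=1)
        for t in range(1, 4):
            for i in range(1, 6):
                expected = 1.0 if i == 3 else 2.0
                assert sums[spec3.design.index(i, t)] == expected


class TestImpliedMoments:
    def test_pure_noise_gives_identity(self, spec3):
        pv = fx.ParameterVector(
            kappa=np.zeros(7), Phi=np.zeros((7, 7)),
            lam=np.ones(5), alpha=np.zeros(5), theta=np.ones(15),
        )
        im = fx.implied_moments(spec3, pv)
        assert np.allclose(im.Sigma, np.eye(15))
        assert np.allclose(im.mu, 0.0)

    def test_single_state_block_of_ones(self):
        spec = fx.build_spec("states_only", 1, n_items=3, n_occasions=3)
        Phi = np.eye(3) * 1e-12
        Phi[0, 0] = 1.0
        pv = fx.ParameterVector(
            kappa=np.zeros(3), Phi=Phi, lam=np.ones(3), alpha=np.zeros(3),
            theta=np.full(9, 1e-12),
        )
        im = fx.implied_moments(spec, pv)
        block = im.Sigma[:3, :3]
        assert np.allclose(block, np.ones((3, 3)), atol=1e-9)

    def test_indefinite_phi_rejected(self, spec3):
        Phi = np.eye(7)
        Phi[0, 0] = -0.5
        pv = fx.ParameterVector(
            kappa=np.zeros(7), Phi=Phi, lam=np.ones(5), alpha=np.zeros(5),
            theta=np.ones(15),
        )
        with pytest.raises(ValueError, match="semidefinite"):
            fx.implied_moments(spec3, pv)

    def test_monte_carlo_moments_match_implied(self, spec3, truth):
        im = fx.implied_moments(spec3, truth)
        df = fx.simulate_panel(
            fx.SimConfig(spec=spec3, params=truth, n=200_000, seed=77)
        )
        Y = df.to_numpy()
        assert np.abs(Y.mean(axis=0) - im.mu).max() < 0.02
        emp = np.cov(Y, rowvar=False, bias=True)
        assert np.abs(emp - im.Sigma).max() < 0.04

    def test_cholesky_succeeds_for_random_admissible_params(self, spec3):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pv = random_admissible_params(spec3, rng)
            im = fx.implied_moments(spec3, pv)
            np.linalg.cholesky(im.Sigma)  # PD assertion


class TestParameterCounts:
    @pytest.mark.parametrize(
        "variant, n_items, q, df",
        [
            ("states_only", 5, 32, 103),
            ("item_effects", 5, 50, 85),
            ("item_effects", 2, 20, 7),
        ],
    )
    def test_counts(self, variant, n_items, q, df):
        spec = fx.build_spec(variant, 1 if n_items == 2 else 3,
                             n_items=n_items)
        assert fx.count_free_parameters(spec) == q
        assert fx.count_df(spec) == df

    @given(n_items=st.integers(2, 8), n_occasions=st.integers(3, 6))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_item_effects_model_always_less_constrained(self, n_items,
                                                        n_occasions):
        s1 = fx.build_spec("states_only", 1, n_items=n_items,
                           n_occasions=n_occasions)
        s2 = fx.build_spec("item_effects", 1, n_items=n_items,
                           n_occasions=n_occasions)
        assert fx.count_df(s1) > fx.count_df(s2)
        assert fx.count_df(s2) >= 0


class TestReferenceParameterizationEquivalence:
    def test_mapped_parameters_give_identical_observed_moments(self, spec3,
                                                               spec5):
        """The reference-3 and reference-5 parameterizations describe the
        same set of observed-moment structures."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            pv3 = random_admissible_params(spec3, rng)
            A, labels = switch_matrix(spec3.latent_labels, 3, 5, 3)
            assert labels == spec5.latent_labels
            pv5 = fx.ParameterVector(
                kappa=A @ pv3.kappa, Phi=A @ pv3.Phi @ A.T,
                lam=pv3.lam, alpha=pv3.alpha, theta=pv3.theta,
            )
            im3 = fx.implied_moments(spec3, pv3)
            im5 = fx.implied_moments(spec5, pv5)
            assert np.abs(im3.mu - im5.mu).max() < 1e-10
            assert np.abs(im3.Sigma - im5.Sigma).max() < 1e-10
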