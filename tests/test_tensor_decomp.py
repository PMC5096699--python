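import numpy as np
import pytest

from popfactor import (
    TrialTensor,
    infer_core,
    orthogonal_tucker2,
    reconstruction_error,
    space_by_time_nmf,
)


def _tensor_from(counts):
    counts = np.asarray(counts)
    s, t, n = counts.shape
    return TrialTensor(
        counts=counts,
        bin_width=10.0,
        window=(0.0, 10.0 * t),
        labels=np.array([f"s{i}" for i in range(s)]),
    )


@pytest.fixture(scope="module")
def exact_sbt_tensor():
    """Noiseless data generated from known (P=2, L=2) factors."""
    rng = np.random.default_rng(3)
    Btem = rng.uniform(size=(6, 2))
    Bspa = rng.uniform(size=(2, 5))
    H = rng.uniform(size=(8, 2, 2))
    data = np.einsum("tp,spl,ln->stn", Btem, H, Bspa)
    return _tensor_from(data), (Btem, H, Bspa)


class TestSpaceByTimeNMF:
    def test_rank_one_model_fit_exactly(self):
        rng = np.random.default_rng(0)
        btem = rng.uniform(size=6)
        bspa = rng.uniform(size=5)
        h = rng.uniform(1, 2, size=7)
        data = h[:, None, None] * np.outer(btem, bspa)[None]
        tensor = _tensor_from(data)
        decomp = space_by_time_nmf(tensor, 1, 1, seed=0)
        total = float((data**2).sum())
        assert decomp.reconstruction_error / total < 1e-6

    def test_objective_monotone_non_increasing(self, small_mixture_tensor):
        decomp = space_by_time_nmf(
            small_mixture_tensor, 3, 3, seed=1, n_restarts=1, max_iter=80
        )
        diffs = np.diff(decomp.objective_history)
        assert np.all(diffs <= 1e-9 * decomp.objective_history[0])

    def test_non_negativity_and_normalization(self, small_mixture_tensor):
        decomp = space_by_time_nmf(
            small_mixture_tensor, 2, 2, seed=2, n_restarts=1, max_iter=60
        )
        assert np.all(decomp.temporal_modules >= 0)
        assert np.all(decomp.spatial_modules >= 0)
        assert np.all(decomp.core >= 0)
        assert np.allclose(
            np.linalg.norm(decomp.temporal_modules, axis=0), 1.0
        )
        assert np.allclose(np.linalg.norm(decomp.spatial_modules, axis=1), 1.0)

    def test_normalization_preserves_reconstruction_error(
        self, small_mixture_tensor
    ):
        decomp = space_by_time_nmf(
            small_mixture_tensor, 2, 2, seed=2, n_restarts=1, max_iter=60
        )
        recomputed = reconstruction_error(decomp, small_mixture_tensor)
        assert recomputed == pytest.approx(
            decomp.reconstruction_error, rel=1e-9
        )

    def test_seeded_determinism(self, small_mixture_tensor):
        a = space_by_time_nmf(
            small_mixture_tensor, 2, 2, seed=9, n_restarts=2, max_iter=40
        )
        b = space_by_time_nmf(
            small_mixture_tensor, 2, 2, seed=9, n_restarts=2, max_iter=40
        )
        assert np.array_equal(a.temporal_modules, b.temporal_modules)
        assert np.array_equal(a.core, b.core)

    def test_restart_stability_exceeds_random_baseline(
        self, small_mixture_tensor
    ):
        # solutions from independent random restarts agree with each other
        # far more than random non-negative module sets do
        from popfactor import module_set_similarity

        runs = [
            space_by_time_nmf(
                small_mixture_tensor, 2, 2, seed=s, n_restarts=1, max_iter=200
            )
            for s in range(4)
        ]
        fitted = np.mean(
            [
                module_set_similarity(
                    runs[i].expanded_modules(), runs[j].expanded_modules()
                )
                for i in range(4)
                for j in range(i + 1, 4)
            ]
        )
        rng = np.random.default_rng(0)
        shape = runs[0].expanded_modules()[0].shape
        random_sets = [
            [rng.uniform(size=shape) for _ in range(4)] for _ in range(4)
        ]
        baseline = np.mean(
            [
                module_set_similarity(random_sets[i], random_sets[j])
                for i in range(4)
                for j in range(i + 1, 4)
            ]
        )
        assert fitted > baseline
        assert fitted > 95.0

    def test_invalid_counts_rejected(self, small_mixture_tensor):
        with pytest.raises(ValueError):
            space_by_time_nmf(small_mixture_tensor, 0, 2, seed=0)
        with pytest.raises(ValueError):
            space_by_time_nmf(small_mixture_tensor, 2, 21, seed=0)


class TestOrthogonalTucker2:
    def test_factors_orthonormal(self, small_mixture_tensor):
        decomp = orthogonal_tucker2(small_mixture_tensor, 3, 4)
        Bt = decomp.temporal_modules
        Bs = decomp.spatial_modules
        assert np.allclose(Bt.T @ Bt, np.eye(3), atol=1e-8)
        assert np.allclose(Bs @ Bs.T, np.eye(4), atol=1e-8)

    def test_full_rank_reconstruction_is_exact(self, tiny_tensor):
        decomp = orthogonal_tucker2(tiny_tensor, 2, 2)
        assert reconstruction_error(decomp, tiny_tensor) < 1e-16 * 100

    def test_matches_best_of_many_restarts_on_tiny_tensor(self):
        rng = np.random.default_rng(7)
        tensor = _tensor_from(rng.integers(0, 5, size=(3, 3, 3)))
        fit = orthogonal_tucker2(tensor, 2, 2)
        # oracle: HOOI from many random orthonormal starts
        R = tensor.counts.astype(float)
        best = np.inf
        for s in range(20):
            g = np.random.default_rng(s)
            Bt = np.linalg.qr(g.normal(size=(3, 2)))[0]
            W = np.linalg.qr(g.normal(size=(3, 2)))[0]
            for _ in range(60):
                proj = np.einsum("stn,nl->stl", R, W)
                Bt = np.linalg.svd(
                    np.transpose(proj, (1, 0, 2)).reshape(3, -1),
                    full_matrices=False,
                )[0][:, :2]
                proj = np.einsum("stn,tp->spn", R, Bt)
                W = np.linalg.svd(
                    np.transpose(proj, (2, 0, 1)).reshape(3, -1),
                    full_matrices=False,
                )[0][:, :2]
            core = np.einsum("tp,stn,nl->spl", Bt, R, W)
            err = (R**2).sum() - (core**2).sum()
            best = min(best, err)
        assert fit.reconstruction_error <= best + 1e-6 * (R**2).sum()

    def test_deterministic(self, small_mixture_tensor):
        a = orthogonal_tucker2(small_mixture_tensor, 2, 2)
        b = orthogonal_tucker2(small_mixture_tensor, 2, 2)
        assert np.array_equal(a.temporal_modules, b.temporal_modules)

    def test_rank_bounds_enforced(self, tiny_tensor):
        with pytest.raises(ValueError, match="rank"):
            orthogonal_tucker2(tiny_tensor, 5, 2)


class TestInferCore:
    def test_orthogonal_inference_recovers_exact_core(self, exact_sbt_tensor):
        tensor, _ = exact_sbt_tensor
        decomp = orthogonal_tucker2(tensor, 2, 2)
        H = infer_core(decomp, tensor)
        assert np.allclose(H, decomp.core, atol=1e-10)

    def test_zero_trial_gives_zero_core(self, small_mixture_tensor):
        decomp = space_by_time_nmf(
            small_mixture_tensor, 2, 2, seed=0, n_restarts=1, max_iter=40
        )
        zero = small_mixture_tensor.select_trials([0]).with_counts(
            np.zeros((1,) + small_mixture_tensor.shape[1:])
        )
        H = infer_core(decomp, zero, max_iter=1, seed=0)
        assert np.allclose(H, 0.0)

    def test_frozen_factor_error_at_least_joint(self, small_mixture_tensor):
        joint = space_by_time_nmf(small_mixture_tensor, 2, 2, seed=5)
        other = space_by_time_nmf(
            small_mixture_tensor.select_trials(np.arange(60)), 2, 2, seed=6
        )
        H = infer_core(other, small_mixture_tensor, seed=0)
        frozen_err = reconstruction_error(
            type(other)(
                temporal_modules=other.temporal_modules,
                spatial_modules=other.spatial_modules,
                core=H,
                method="sbt-nmf",
                reconstruction_error=np.nan,
            ),
            small_mixture_tensor,
        )
        assert frozen_err >= joint.reconstruction_error - 1e-9

    def test_shape_mismatch_rejected(self, small_mixture_tensor, tiny_tensor):
        decomp = space_by_time_nmf(
            small_mixture_tensor, 2, 2, seed=0, n_restarts=1, max_iter=20
        )
        with pytest.raises(ValueError, match="does not match"):
            infer_core(decomp, tiny_tensor)


class TestReconstructionError:
    def test_equals_brute_force_residual_sum(self, exact_sbt_tensor):
        tensor, (Btem, H, Bspa) = exact_sbt_tensor
        from popfactor import SbTDecomposition

        decomp = SbTDecomposition(
            temporal_modules=Btem,
            spatial_modules=Bspa,
            core=H,
            method="sbt-nmf",
            reconstruction_error=np.nan,
        )
        brute = 0.0
        for s in range(tensor.n_trials):
            resid = tensor.counts[s] - Btem @ H[s] @ Bspa
            brute += float((resid**2).sum())
        assert reconstruction_error(decomp, tensor) == pytest.approx(brute)
        assert reconstruction_error(decomp, tensor) < 1e-18

    def test_monotone_in_added_noise(self, exact_sbt_tensor):
        tensor, (Btem, H, Bspa) = exact_sbt_tensor
        from popfactor import SbTDecomposition

        decomp = SbTDecomposition(
            temporal_modules=Btem,
            spatial_modules=Bspa,
            core=H,
            method="sbt-nmf",
            reconstruction_error=np.nan,
        )
        rng = np.random.default_rng(1)
        noise = np.abs(rng.normal(size=tensor.shape))
        errs = [
            reconstruction_error(
                decomp, tensor.with_counts(tensor.counts + eps * noise)
            )
            for eps in (0.0, 0.1, 0.5, 1.0)
        ]
        assert all(a < b for a, b in zip(errs, errs[1:]))
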