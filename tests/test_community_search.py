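from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medibench import community_search as cs
from medibench import mediator_sim as ms
from medibench.ground_truth import structural_presence


def make_breakdown(x_hat, presence, **kwargs):
    return cs.score_from_xhat(np.asarray(x_hat), np.asarray(presence), **kwargs)


class TestScore:
    def test_no_major_species_zero(self):
        bd = make_breakdown([1e-3] * 5, np.zeros((5, 5), dtype=bool))
        assert bd.z == 0.0
        assert bd.s_star == 0

    def test_five_equal_majors_half_connectance(self):
        # D = sqrt(5) for equal shares; 4c - 4c^2 = 1 at c = 1/2
        presence = np.zeros((5, 5), dtype=bool)
        pairs = [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3), (2, 4), (3, 4),
                 (3, 0), (4, 0), (4, 1)]
        for i, j in pairs:
            presence[i, j] = True
        bd = make_breakdown([0.2] * 5, presence)
        assert bd.connectance == pytest.approx(0.5)
        assert bd.z == pytest.approx(5 * np.sqrt(5), rel=1e-12)
        assert bd.z == pytest.approx(11.180, abs=1e-3)

    def test_connectance_factor_max_at_half(self):
        c = np.linspace(0, 1, 10_001)
        factor = 4 * c - 4 * c**2
        assert c[np.argmax(factor)] == pytest.approx(0.5)

    def test_minor_species_excluded(self):
        # only the first two species are major; links outside ignored
        presence = np.ones((4, 4), dtype=bool)
        np.fill_diagonal(presence, False)
        bd = make_breakdown([0.5, 0.5, 1e-3, 1e-3], presence)
        assert bd.s_star == 2
        assert bd.links == 2
        assert bd.connectance == pytest.approx(1.0)
        assert bd.z == 0.0  # 4c - 4c^2 vanishes at c = 1

    def test_single_major_defined_as_zero(self):
        bd = make_breakdown([0.5, 1e-3], np.ones((2, 2), dtype=bool))
        assert bd.s_star == 1
        assert bd.connectance == 0.0
        assert bd.z == 0.0

    def test_inv_simpson_option(self):
        presence = np.zeros((2, 2), dtype=bool)
        presence[0, 1] = True  # c = 1/2 for S* = 2
        bd = make_breakdown([0.3, 0.1], presence, diversity_form="inv_simpson")
        p = np.array([0.75, 0.25])
        assert bd.diversity == pytest.approx(1.0 / np.sum(p**2))

    def test_permutation_equivariance(self, rng):
        x_hat = rng.uniform(0, 0.5, 6)
        presence = rng.random((6, 6)) < 0.4
        np.fill_diagonal(presence, False)
        perm = rng.permutation(6)
        bd1 = make_breakdown(x_hat, presence)
        bd2 = make_breakdown(x_hat[perm], presence[np.ix_(perm, perm)])
        assert bd1.z == pytest.approx(bd2.z)
        assert bd1.s_star == bd2.s_star

    def test_score_upper_bound(self, rng):
        # z <= S*^{3/2} for the square-root diversity form
        for _ in range(200):
            x_hat = rng.uniform(0, 0.5, 8)
            presence = rng.random((8, 8)) < rng.random()
            bd = make_breakdown(x_hat, presence)
            assert bd.z <= bd.s_star ** 1.5 + 1e-9


class TestMutate:
    def test_value_multisets_preserved(self, rng):
        p = ms.sample_mediator_params(rng)
        mutant = cs.mutate(p, rng)
        for name in cs.MUTABLE_MATRICES:
            before = Counter(getattr(p, name).ravel().tolist())
            after = Counter(getattr(mutant, name).ravel().tolist())
            assert before == after

    def test_sigma_and_r_untouched(self, rng):
        p = ms.sample_mediator_params(rng)
        mutant = cs.mutate(p, rng)
        np.testing.assert_array_equal(mutant.r, p.r)

    def test_single_entry_relocation_uniform(self):
        # a lone nonzero entry moves to each of the 3 other cells equally often
        rng = np.random.default_rng(0)
        counts = Counter()
        reps = 4000
        p = ms.MediatorParams(
            n=2, m=2, r=[0.1, 0.1], K=1.0, delta=0.01,
            kappa=np.full((2, 2), 1e-3),
            rho_plus=[[0.2, 0.0], [0.0, 0.0]], rho_minus=np.zeros((2, 2)),
            alpha=np.zeros((2, 2)), beta=np.zeros((2, 2)),
        )
        for _ in range(reps):
            mutant = cs.mutate_single(p, rng, matrix="rho_plus")
            pos = np.flatnonzero(mutant.rho_plus.ravel())
            assert len(pos) == 1 and pos[0] != 0  # the value always relocates
            counts[int(pos[0])] += 1
        observed = np.array([counts[i] for i in (1, 2, 3)])
        expected = np.full(3, reps / 3)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < 16.27  # chi-square_{2, 0.0003} -- loose determinism guard

    def test_expected_swap_count(self):
        rng = np.random.default_rng(1)
        draws = rng.integers(1, 5, size=200_000)
        assert draws.mean() == pytest.approx(2.5, abs=0.01)

    def test_all_zero_matrix_raises(self, rng):
        p = ms.sample_mediator_params(rng)
        p.beta[:] = 0.0
        with pytest.raises(ValueError, match="mutate"):
            cs.mutate_single(p, rng, matrix="beta")


def _fast_search_cfg(**kwargs):
    base = dict(Mp=8, mp=2, Tmax=4, omega=-1.0, N=1)
    base.update(kwargs)
    return cs.SearchConfig(**base)


def _fast_sim_cfg(**kwargs):
    base = dict(t_max=600, t0=200, sigma=1.0, seed=None)
    base.update(kwargs)
    return ms.SimConfig(**base)


class TestEvolve:
    def test_accepts_with_disabled_threshold(self):
        rng = np.random.default_rng(0)
        res = cs.evolve("Mprime", _fast_search_cfg(), _fast_sim_cfg(), rng)
        assert res is not None
        assert res.trajectory.x.shape[0] == 601
        assert res.breakdown.z >= 0

    def test_seeded_reproducibility(self):
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            res = cs.evolve("Dprime", _fast_search_cfg(), _fast_sim_cfg(), rng)
            runs.append(res)
        np.testing.assert_array_equal(runs[0].trajectory.x, runs[1].trajectory.x)
        assert runs[0].breakdown.z == runs[1].breakdown.z

    def test_rejection_on_impossible_threshold(self):
        rng = np.random.default_rng(3)
        cfg = _fast_search_cfg(omega=1e9)
        assert cs.evolve("M", cfg, _fast_sim_cfg(), rng) is None

    def test_generation_composition(self, monkeypatch):
        # parents + mutants fill the population exactly
        rng = np.random.default_rng(5)
        calls = []
        orig = cs.mutate

        def counting_mutate(params, rng_):
            calls.append(1)
            return orig(params, rng_)

        monkeypatch.setattr(cs, "mutate", counting_mutate)
        cfg = _fast_search_cfg(Mp=8, mp=2, Tmax=3)
        cs.evolve("Mprime", cfg, _fast_sim_cfg(), rng)
        # Tmax - 1 refills of (Mp - mp) mutants each
        assert len(calls) == (cfg.Tmax - 1) * (cfg.Mp - cfg.mp)

    def test_monotone_best_score_deterministic_mode(self):
        # sigma = 0, no X0 perturbation, parents keep their scores
        rng = np.random.default_rng(11)
        cfg = _fast_search_cfg(
            Mp=8, mp=2, Tmax=6, perturb_x0=False, rescore_parents=False
        )
        sim = _fast_sim_cfg(sigma=0.0)
        best_per_gen = []
        orig = cs.score_from_xhat

        def recording(x_hat, presence, **kw):
            bd = orig(x_hat, presence, **kw)
            best_per_gen.append(bd.z)
            return bd

        cs_score = cs.score_from_xhat
        cs.score_from_xhat = recording
        try:
            cs.evolve("Dprime", cfg, sim, rng)
        finally:
            cs.score_from_xhat = cs_score
        # reconstruct per-generation maxima: first gen evaluates Mp, later
        # generations only the mutants; the running best must not decrease
        gen0 = best_per_gen[: cfg.Mp]
        rest = best_per_gen[cfg.Mp : cfg.Mp + (cfg.Tmax - 2) * (cfg.Mp - cfg.mp)]
        running = max(gen0)
        for g in range(cfg.Tmax - 2):
            chunk = rest[g * (cfg.Mp - cfg.mp) : (g + 1) * (cfg.Mp - cfg.mp)]
            new_best = max([running] + chunk)
            assert new_best >= running - 1e-12
            running = new_best

    def test_accepted_scores_exceed_omega_and_bound(self):
        rng = np.random.default_rng(21)
        cfg = _fast_search_cfg(Mp=12, mp=3, Tmax=8, omega=5.0)
        res = None
        for _ in range(10):
            res = cs.evolve("Mprime", cfg, _fast_sim_cfg(t_max=2000, t0=500), rng)
            if res is not None:
                break
        assert res is not None, "no acceptance in 10 restarts"
        assert res.breakdown.z > 5.0
        # z <= S*^{3/2} forces S* >= 3 whenever z > 5
        assert res.breakdown.s_star >= 3

    def test_initial_state_ranges(self):
        rng = np.random.default_rng(1)
        cands = cs._init_candidates(20, rng, sigma=1.0, eps=1e-7)
        for c in cands:
            assert np.all(c.x0 >= 10 * 1e-7) and np.all(c.x0 <= 100 * 1e-7)


class TestPopulationSimulatorAgreement:
    @pytest.mark.parametrize("model_id", ms.MODEL_IDS)
    def test_matches_reference_integrator_deterministic(self, model_id):
        rng = np.random.default_rng(13)
        p = ms.sample_mediator_params(rng)
        cand = cs.Candidate(params=p, x0=rng.uniform(1e-3, 0.5, 10), sigma=0.0)
        sim = ms.SimConfig(sigma=0.0, t_max=400, t0=100, seed=0)
        x_hat, ok = cs._simulate_population(
            model_id, [cand], cand.x0[None, :], sim, rng
        )
        params = (
            p if model_id in ms.MEDIATOR_MODELS else ms.derive_direct_matrix(p)
        )
        traj = ms.integrate(model_id, params, cand.x0, sim)
        assert ok[0]
        np.testing.assert_allclose(x_hat[0], traj.post_transient_mean(), rtol=1e-10)


class TestGenerateDataset:
    def test_default_grid_shape(self):
        rng = np.random.default_rng(2)
        grid = cs.ConditionGrid(taus=(2, 4), sigmas=(0.5, 1.0), tau_ref=4, sigma_ref=1.0)
        datasets = cs.generate_dataset(
            "Dprime", grid, N=1, rng=rng,
            search_cfg=_fast_search_cfg(),
            sim_cfg=_fast_sim_cfg(),
            n_points=50,
        )
        assert len(datasets) == 4  # 2 taus + 2 sigmas (ref condition twice)
        conditions = [(d.tau, d.sigma) for d in datasets]
        assert conditions == [(2, 1.0), (4, 1.0), (4, 0.5), (4, 1.0)]
        for ds in datasets:
            assert ds.n_communities == 1
            for e in ds.entries:
                assert e.series.n_points == 50

    def test_series_point_count_default(self):
        rng = np.random.default_rng(4)
        grid = cs.ConditionGrid(taus=(5,), sigmas=(1.0,), tau_ref=5, sigma_ref=1.0)
        (ds, ds2) = cs.generate_dataset(
            "Mprime", grid, N=1, rng=rng,
            search_cfg=_fast_search_cfg(),
            sim_cfg=_fast_sim_cfg(t_max=600, t0=100),
            n_points=100,
        )
        assert all(e.series.n_points == 100 for e in ds.entries)

    def test_roundtrip_persistence(self, tmp_path):
        rng = np.random.default_rng(6)
        grid = cs.ConditionGrid(taus=(4,), sigmas=(1.0,), tau_ref=4, sigma_ref=1.0)
        datasets = cs.generate_dataset(
            "Mprime", grid, N=2, rng=rng,
            search_cfg=_fast_search_cfg(N=2),
            sim_cfg=_fast_sim_cfg(),
            n_points=40,
        )
        ds = datasets[0]
        cs.save_dataset(ds, tmp_path / "ds")
        back = cs.load_dataset(tmp_path / "ds")
        assert back.model_id == ds.model_id
        assert back.n_communities == ds.n_communities
        for a, b in zip(ds.entries, back.entries):
            np.testing.assert_allclose(a.series.values, b.series.values)
            np.testing.assert_array_equal(a.truth.presence, b.truth.presence)
            np.testing.assert_array_equal(a.candidate.params.beta, b.candidate.params.beta)

    def test_truth_consistent_with_candidate(self):
        rng = np.random.default_rng(8)
        grid = cs.ConditionGrid(taus=(4,), sigmas=(1.0,), tau_ref=4, sigma_ref=1.0)
        datasets = cs.generate_dataset(
            "Mprime", grid, N=1, rng=rng,
            search_cfg=_fast_search_cfg(), sim_cfg=_fast_sim_cfg(), n_points=40,
        )
        for ds in datasets:
            for e in ds.entries:
                np.testing.assert_array_equal(
                    e.truth.presence, structural_presence(e.candidate.params)
                )


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), n_swaps_seed=st.integers(0, 2**31 - 1))
def test_mutation_multiset_property(seed, n_swaps_seed):
    rng = np.random.default_rng(seed)
    p = ms.sample_mediator_params(rng, n=4, m=3)
    mutant = cs.mutate(p, np.random.default_rng(n_swaps_seed))
    for name in cs.MUTABLE_MATRICES:
        assert sorted(getattr(p, name).ravel()) == sorted(getattr(mutant, name).ravel())
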