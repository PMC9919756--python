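import math

import numpy as np
import pytest
from scipy import stats

from hspoly.chain_model import (Configuration, SystemParams, bond_geometry,
                                minimum_image, validate_configuration)
from hspoly.mc_engine import (CBSettings, MCEngine, MoveSchedule,
                              build_cell_list, cb_accept, compress,
                              generate_dilute, run_mc)



class TestMoveSchedule:
    def test_default_sums_to_one(self):
        assert MoveSchedule().probabilities().sum() == pytest.approx(1.0,
                                                                     abs=1e-15)

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError):
            MoveSchedule(flip=0.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            MoveSchedule(reptation=-0.1, rotation=0.3, flip=0.448)


class TestCellList:
    def test_matches_brute_force(self):
        """Stencil neighbor search finds exactly the brute-force pair set."""
        rng = np.random.default_rng(0)
        L = 8.0
        pts = rng.uniform(0, L, size=(200, 3))
        cfg = Configuration(L, [p.reshape(1, 3) for p in pts])
        cl = build_cell_list(cfg, cutoff=2.0)
        found = cl.neighbor_pairs(2.0)
        brute = set()
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.linalg.norm(minimum_image(pts[i] - pts[j], L)) <= 2.0:
                    brute.add((i, j))
        assert found == brute

    def test_adjacent_cells_pair_found(self):
        cfg = Configuration(10.0, [np.array([[1.9, 1, 1]]),
                                   np.array([[2.91, 1, 1]])])
        cl = build_cell_list(cfg, cutoff=2.0)
        assert (0, 1) in cl.neighbor_pairs(1.2)

    def test_empty_config(self):
        cfg = Configuration(10.0, [])
        cl = build_cell_list(cfg, cutoff=2.0)
        assert cl.neighbor_pairs(2.0) == set()

    def test_small_box_brute_fallback(self):
        rng = np.random.default_rng(1)
        L = 3.0
        pts = rng.uniform(0, L, size=(20, 3))
        cfg = Configuration(L, [p.reshape(1, 3) for p in pts])
        cl = build_cell_list(cfg, cutoff=2.0)
        brute = set()
        for i in range(20):
            for j in range(i + 1, 20):
                if np.linalg.norm(minimum_image(pts[i] - pts[j], L)) <= 2.0:
                    brute.add((i, j))
        assert cl.neighbor_pairs(2.0) == brute


class TestCBAccept:
    def test_equal_weights_always_accept(self):
        rng = np.random.default_rng(0)
        assert all(cb_accept(1.0, 1.0, 0.0, rng) for _ in range(100))

    def test_zero_new_weight_always_reject(self):
        rng = np.random.default_rng(0)
        assert not any(cb_accept(0.0, 1.0, 0.0, rng) for _ in range(100))

    def test_empirical_rate_matches_ratio(self):
        """Monte Carlo check of the acceptance rule at ratio 1/2."""
        rng = np.random.default_rng(42)
        n = 10**5
        acc = sum(cb_accept(0.5, 1.0, 0.0, rng) for _ in range(n))
        sigma = math.sqrt(n * 0.5 * 0.5)
        assert abs(acc - 0.5 * n) < 3 * sigma

    def test_invalid_weights(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            cb_accept(-1.0, 1.0, 0.0, rng)
        with pytest.raises(ValueError):
            cb_accept(1.0, 0.0, 0.0, rng)


def _dilute_engine(seed=1, n_chains=12, schedule=None, **pkw):
    params = SystemParams(n_chains=n_chains, **pkw)
    cfg = generate_dilute(params, seed=seed)
    return MCEngine(cfg, params, schedule or MoveSchedule(), CBSettings(),
                    seed=seed + 1), params


class TestLocalMoves:
    def test_hard_invariants_hold_along_run(self):
        """After any accepted move: no overlap, bonds in window, lengths
        in bounds (checked on snapshots)."""
        eng, params = _dilute_engine(seed=3)
        for _ in range(6):
            eng.run(1000)
            assert validate_configuration(eng.config(), params) == []

    def test_monomer_count_conserved(self):
        eng, params = _dilute_engine(seed=4)
        n0 = eng.config().n_atoms
        eng.run(5000)
        assert eng.config().n_atoms == n0

    def test_chain_connectivity_preserved(self):
        """Every chain remains a connected path of in-window bonds."""
        eng, params = _dilute_engine(seed=5)
        eng.run(4000)
        for chain in eng.config().chains:
            lengths, _, _ = bond_geometry(chain)
            assert np.all(lengths >= params.sigma * (1 - 1e-9))
            assert np.all(lengths <= (params.sigma + params.dl) * (1 + 1e-9))

    def test_intermolecular_reptation_respects_bounds(self):
        """Two 6-mers can never donate a monomer (a 5-mer would result)."""
        params = SystemParams(n_chains=2, n_av=6, length_bounds=(6, 6))
        cfg = generate_dilute(params, seed=6)
        sched = MoveSchedule(reptation=0.0, rotation=0.0, flip=0.0,
                             intermolecular_reptation=1.0,
                             end_segment_regrowth=0.0, sEB=0.0, sIEB=0.0)
        eng = MCEngine(cfg, params, sched, CBSettings(), seed=7)
        eng.run(500)
        assert eng.accepts["intermolecular_reptation"] == 0
        assert sorted(eng.config().chain_lengths) == [6, 6]


def _bridging_fixture(dl):
    """A 12-mer whose head sits inside the bond window of an 18-mer
    interior monomer: the canonical end-bridging geometry."""
    b = np.array([[float(i), 0.0, 0.0] for i in range(18)])
    a0 = np.array([5.0, 1.0 + dl / 2, 0.0])
    a = a0 + np.array([[0.0, float(i), 0.0] for i in range(12)])
    return Configuration(60.0, [a, b])


class TestBridgingMoves:
    def test_seb_conserves_monomers_and_bounds(self):
        params = SystemParams(n_chains=2, n_av=12, length_bounds=(6, 18),
                              k_theta=0.0)
        cfg = _bridging_fixture(params.dl)
        sched = MoveSchedule(reptation=0.0, rotation=0.0, flip=0.0,
                             intermolecular_reptation=0.0,
                             end_segment_regrowth=0.0, sEB=1.0, sIEB=0.0)
        accepted = False
        for seed in range(12):
            eng = MCEngine(cfg, params, sched, CBSettings(), seed=seed)
            for _ in range(30):            # stop at the FIRST acceptance
                eng.step()
                if eng.accepts["sEB"]:
                    break
            if eng.accepts["sEB"]:
                accepted = True
                out = eng.config()
                lengths = sorted(out.chain_lengths)
                assert sum(lengths) == 30
                assert all(6 <= n <= 18 for n in lengths)
                # the bridged chain mixes monomers of both parents:
                # parent A lies at y >= 1, parent B at y = 0
                mixed = any(
                    len({bool(y > 0.5) for y in chain[:, 1]}) == 2
                    for chain in out.chains)
                assert mixed, "connectivity did not change"
                assert validate_configuration(out, params) == []
                break
        assert accepted, "no sEB move accepted in any replicate"

    def test_seb_rejected_when_lengths_would_escape_bounds(self):
        """A bridging that would create an over-long chain is never proposed."""
        params = SystemParams(n_chains=2, n_av=15, length_bounds=(6, 18),
                              k_theta=0.0)
        # the attacking end belongs to an 18-mer: absorbing either side of
        # the severed 12-mer would create a 24- or 25-mer
        b = np.array([[float(i), 0.0, 0.0] for i in range(12)])
        a = np.array([5.0, 1.0 + params.dl / 2, 0.0]) \
            + np.array([[0.0, float(i), 0.0] for i in range(18)])
        cfg = Configuration(60.0, [a, b])
        sched = MoveSchedule(reptation=0.0, rotation=0.0, flip=0.0,
                             intermolecular_reptation=0.0,
                             end_segment_regrowth=0.0, sEB=1.0, sIEB=0.0)
        eng = MCEngine(cfg, params, sched, CBSettings(), seed=0)
        eng.run(50)
        assert eng.accepts["sEB"] == 0
        assert sorted(eng.config().chain_lengths) == [12, 18]

    def test_sieb_preserves_length_and_path(self):
        """Intramolecular rebridging keeps chain count/length; the contour
        stays a simple path with in-window bonds."""
        # 7-mer whose tail closes onto monomer 1 at exactly sigma
        hexa = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0],
                         [2.5, math.sqrt(3) / 2, 0],
                         [2, math.sqrt(3), 0], [1, math.sqrt(3), 0],
                         [0.5, math.sqrt(3) / 2, 0]])
        hexa = hexa + 20.0
        params = SystemParams(n_chains=1, n_av=7, length_bounds=(7, 7),
                              k_theta=0.0)
        cfg = Configuration(60.0, [hexa])
        sched = MoveSchedule(reptation=0.0, rotation=0.0, flip=0.0,
                             intermolecular_reptation=0.0,
                             end_segment_regrowth=0.0, sEB=0.0, sIEB=1.0)
        accepted = False
        for seed in range(12):
            eng = MCEngine(cfg, params, sched, CBSettings(), seed=seed)
            eng.run(30)
            if eng.accepts["sIEB"]:
                accepted = True
                out = eng.config()
                assert out.chain_lengths.tolist() == [7]
                assert validate_configuration(out, params) == []
                break
        assert accepted, "no sIEB move accepted in any replicate"


class TestRunMC:
    def test_attempt_frequencies_match_schedule(self):
        """Move-type attempt counts follow the prescribed mix (3-sigma)."""
        eng, _ = _dilute_engine(seed=8, n_chains=8)
        n = 30000
        eng.run(n)
        for kind, prob in zip(
                ("reptation", "rotation", "flip", "intermolecular_reptation",
                 "end_segment_regrowth", "sEB", "sIEB"),
                MoveSchedule().probabilities()):
            expected = n * prob
            sigma = math.sqrt(n * prob * (1 - prob))
            assert abs(eng.attempts[kind] - expected) <= 3 * sigma + 1, kind

    def test_snapshot_cadence_and_validity(self):
        params = SystemParams(n_chains=6)
        cfg = generate_dilute(params, seed=9)
        traj = run_mc(cfg, params, n_steps=3000, seed=10,
                      snapshot_interval=1000)
        assert traj.steps == [1000, 2000, 3000]
        for _, snap in traj:
            assert validate_configuration(snap, params) == []

    def test_bit_reproducibility(self):
        params = SystemParams(n_chains=6)
        cfg = generate_dilute(params, seed=11)
        t1 = run_mc(cfg, params, n_steps=2000, seed=12, snapshot_interval=2000)
        t2 = run_mc(cfg, params, n_steps=2000, seed=12, snapshot_interval=2000)
        for c1, c2 in zip(t1.configurations, t2.configurations):
            assert np.array_equal(c1.positions_unwrapped(),
                                  c2.positions_unwrapped())

    def test_dimer_position_distribution_uniform(self):
        """Detailed-balance smoke test: a free dimer's monomer positions
        are uniform over the box (chi-squared on discretized x)."""
        L = 4.0
        params = SystemParams(n_chains=1, n_av=2, length_bounds=(2, 2),
                              k_theta=0.0)
        cfg = Configuration(L, [np.array([[1.0, 1, 1], [2.0, 1, 1]])])
        sched = MoveSchedule(reptation=0.5, rotation=0.5, flip=0.0,
                             intermolecular_reptation=0.0,
                             end_segment_regrowth=0.0, sEB=0.0, sIEB=0.0)
        eng = MCEngine(cfg, params, sched, CBSettings(), seed=13)
        eng.run(2000)
        xs = []
        for _ in range(4000):
            eng.run(40)
            xs.extend(np.mod(eng.chains[0][:, 0], L))
        obs, _ = np.histogram(xs, bins=8, range=(0, L))
        exp = len(xs) / 8
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 < stats.chi2.ppf(0.99, 7)


class TestGenerateDilute:
    def test_counts_and_validity(self, default_params):
        params = SystemParams(n_chains=30)
        cfg = generate_dilute(params, seed=14)
        assert cfg.n_chains == 30
        assert np.all(cfg.chain_lengths >= 6)
        assert np.all(cfg.chain_lengths <= 18)
        # mean 12 with uniform dispersity: N_at ~ n_chains * 12
        assert abs(cfg.n_atoms - 360) < 5 * math.sqrt(30 * 12.25)
        assert validate_configuration(cfg, params) == []

    def test_length_histogram_uniform(self):
        """Generated chain lengths are uniform on [6, 18] (chi-squared, 1%)."""
        lengths = []
        for seed in range(100):
            params = SystemParams(n_chains=10)
            lengths.extend(generate_dilute(params, seed=seed).chain_lengths)
        obs = np.array([(np.array(lengths) == k).sum() for k in range(6, 19)])
        exp = len(lengths) / 13
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 < stats.chi2.ppf(0.99, 12)

    def test_dense_request_rejected(self):
        with pytest.raises(ValueError):
            generate_dilute(SystemParams(), phi_init=0.2)


class TestCompress:
    def test_reaches_target_and_stays_valid(self):
        params = SystemParams(n_chains=8)
        cfg = generate_dilute(params, seed=15)
        out = compress(cfg, params, target_phi=0.15, seed=16,
                       shrink_factor=0.98, relax_moves=100)
        assert out.packing_fraction() == pytest.approx(0.15, abs=1e-6)
        assert validate_configuration(out, params) == []

    def test_phi_trace_monotone(self):
        params = SystemParams(n_chains=6)
        cfg = generate_dilute(params, seed=17)
        eng = MCEngine(cfg, params, MoveSchedule(), CBSettings(), seed=18)
        phis = [eng.phi]
        L_target = (math.pi / 6 * eng.n_at / 0.05) ** (1 / 3)
        while eng.phi < 0.05 - 1e-9:
            eng.attempt_rescale(max(L_target, eng.L * 0.97))
            phis.append(eng.phi)
            eng.run(50)
        assert all(b >= a for a, b in zip(phis, phis[1:]))

    def test_rejected_shrink_restores_box(self):
        """A rescale that would create an overlap leaves the box unchanged."""
        params = SystemParams(n_chains=2, n_av=2, length_bounds=(2, 2))
        chains = [np.array([[1.0, 1, 1], [2.0, 1, 1]]),
                  np.array([[1.0, 2.05, 1], [2.0, 2.05, 1]])]
        cfg = Configuration(4.0, chains)
        eng = MCEngine(cfg, params, MoveSchedule(), CBSettings(), seed=19)
        L0 = eng.L
        # chains 1.05 sigma apart: a 10% shrink moves their centers closer
        # than sigma, so the attempt must be rejected
        assert not eng.attempt_rescale(L0 * 0.80)
        assert eng.L == L0
        assert validate_configuration(eng.config(), params) == []

    def test_target_below_current_rejected(self):
        params = SystemParams(n_chains=4)
        cfg = generate_dilute(params, seed=20)
        with pytest.raises(ValueError):
            compress(cfg, params, target_phi=0.0005, seed=21)
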