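"""Mechanics of the polymerase population model: initiation and occlusion,
elongation hops, state transitions, collisions, termination, conservation."""

import numpy as np
import pytest

from netpol.errors import ConfigError
from netpol.simulator import (
    Action,
    ModelParameters,
    PolymeraseEnsemble,
    State,
    _Pol,
    advance_and_transition,
    initiate,
    resolve_collision,
    simulate_population,
)


class TestParameters:
    def test_rejects_negative_rates(self):
        with pytest.raises(ConfigError):
            ModelParameters(initiation_rate=-1)

    def test_rejects_probability_overflow(self):
        # a per-step transition probability above 1 means dt is too coarse
        with pytest.raises(ConfigError, match="reduce dt"):
            ModelParameters(stall_rate_w1=300.0)

    def test_rejects_bad_window(self):
        with pytest.raises(ConfigError):
            ModelParameters(window1_end=2000)

    def test_rejects_bad_term_prob(self):
        with pytest.raises(ConfigError):
            ModelParameters(early_term_prob=1.5)


class TestCollisionRules:
    @pytest.mark.parametrize("down, expected", [
        (State.MOVING, (Action.STALL, Action.UNCHANGED)),
        (State.STALLED, (Action.STALL, Action.TERMINATE)),
        (State.BACKTRACKED, (Action.STALL, Action.UNCHANGED)),
    ])
    def test_rule_table(self, down, expected):
        assert resolve_collision(State.MOVING, down) == expected

    @pytest.mark.parametrize("up", [State.STALLED, State.BACKTRACKED])
    def test_only_moving_collides(self, up):
        with pytest.raises(ValueError):
            resolve_collision(up, State.MOVING)


class TestInitiation:
    def test_zero_rate_never_initiates(self):
        params = ModelParameters(initiation_rate=0.0, total_time=2.0)
        occ, met = simulate_population(params, 50, seed=1)
        assert occ.counts.sum() == 0
        assert met.initiated == 0
        # reference engine agrees
        occ_r, met_r = simulate_population(params, 20, seed=1, engine="reference")
        assert met_r.initiated == 0

    def test_occlusion_blocks_position_one(self, rng):
        params = ModelParameters(initiation_rate=1e6)  # p_init clamps to 1
        ens = PolymeraseEnsemble.empty(1, params)
        ens.genes[0].append(_Pol(30, State.MOVING))
        ens.initiated[0] = 1
        initiate(ens, params, rng)
        assert len(ens.genes[0]) == 1  # blocked: 30 - 1 < footprint 40

    def test_initiation_proceeds_when_clear(self, rng):
        params = ModelParameters(initiation_rate=1e6)
        ens = PolymeraseEnsemble.empty(1, params)
        ens.genes[0].append(_Pol(41, State.MOVING))
        ens.initiated[0] = 1
        initiate(ens, params, rng)
        assert [p.position for p in ens.genes[0]] == [41, 1]

    def test_early_termination_site_distribution(self, rng):
        """Assigned sites average to the Poisson mean (law of large numbers);
        oracle: direct Poisson sampling has SE = sqrt(mean/n)."""
        params = ModelParameters(initiation_rate=1e6, early_term_prob=1.0,
                                 early_term_mean=200.0)
        n = 10_000
        ens = PolymeraseEnsemble.empty(n, params)
        initiate(ens, params, rng)
        sites = np.array([g[0].early_term_site for g in ens.genes if g])
        assert len(sites) == n
        se = np.sqrt(200.0 / n)
        assert abs(sites.mean() - 200.0) < 3 * se


class TestAdvance:
    def test_unhindered_transit_time(self, rng):
        """A lone polymerase with no stalling crosses the gene in about
        L / elongation_rate; oracle is the first-passage time of summed
        Poisson hops."""
        params = ModelParameters(initiation_rate=0.0, elongation_rate=2.0,
                                 stall_rate_w1=0, stall_rate_w2=0,
                                 backtrack_rate_w1=0, backtrack_rate_w2=0,
                                 early_term_prob=0.0)
        n_rep = 400
        steps_taken = []
        for _ in range(n_rep):
            ens = PolymeraseEnsemble.empty(1, params)
            ens.genes[0].append(_Pol(1, State.MOVING))
            ens.initiated[0] = 1
            steps = 0
            while ens.genes[0]:
                advance_and_transition(ens, params, rng)
                steps += 1
            steps_taken.append(steps)
            assert ens.completed[0] == 1
        # oracle: simulate the hop sums directly
        hops = rng.poisson(params.hop_mean, size=(4000, 200)).cumsum(axis=1)
        oracle_steps = (hops < params.gene_length - 1).sum(axis=1) + 1
        obs = np.mean(steps_taken)
        se = np.std(steps_taken, ddof=1) / np.sqrt(n_rep)
        assert abs(obs - oracle_steps.mean()) < 3.5 * se

    def test_stall_resume_two_state_fraction(self):
        """With backtracking off and no collisions, the engaged moving
        fraction converges to resume / (resume + stall)."""
        params = ModelParameters(initiation_rate=0.3, elongation_rate=1.0,
                                 stall_rate_w1=3.0, resume_stall_w1=6.0,
                                 stall_rate_w2=3.0, resume_stall_w2=6.0,
                                 backtrack_rate_w1=0, backtrack_rate_w2=0,
                                 early_term_prob=0.0, total_time=20.0)
        occ, met = simulate_population(params, 3000, seed=9)
        f_expected = 6.0 / (6.0 + 3.0)
        moving = met.moving_w1 + met.moving_w2
        n = met.engaged
        f_obs = moving / n
        se = np.sqrt(f_expected * (1 - f_expected) / n)
        assert abs(f_obs - f_expected) < 3 * se

    def test_blocked_hop_records_collision_and_stalls(self, rng):
        """MOVING 40 nt behind a BACKTRACKED polymerase cannot advance."""
        params = ModelParameters(initiation_rate=0.0, elongation_rate=4.0,
                                 stall_rate_w1=0, stall_rate_w2=0,
                                 backtrack_rate_w1=0, backtrack_rate_w2=0,
                                 resume_backtrack_w1=0, resume_backtrack_w2=0,
                                 early_term_prob=0.0)
        ens = PolymeraseEnsemble.empty(1, params)
        ens.genes[0] = [_Pol(80, State.BACKTRACKED), _Pol(40, State.MOVING)]
        ens.initiated[0] = 2
        advance_and_transition(ens, params, rng)
        up = ens.genes[0][1]
        assert up.position == 40  # truncated to 80 - footprint
        assert up.state is State.STALLED
        assert ens.collisions == 1
        assert ens.collision_terminated[0] == 0  # backtracked survivor

    def test_collision_with_stalled_terminates_downstream(self, rng):
        params = ModelParameters(initiation_rate=0.0, elongation_rate=4.0,
                                 stall_rate_w1=0, stall_rate_w2=0,
                                 backtrack_rate_w1=0, backtrack_rate_w2=0,
                                 resume_stall_w1=0, resume_stall_w2=0,
                                 early_term_prob=0.0)
        ens = PolymeraseEnsemble.empty(1, params)
        ens.genes[0] = [_Pol(80, State.STALLED), _Pol(40, State.MOVING)]
        ens.initiated[0] = 2
        advance_and_transition(ens, params, rng)
        assert ens.collision_terminated[0] == 1
        assert len(ens.genes[0]) == 1
        survivor = ens.genes[0][0]
        assert survivor.position == 40 and survivor.state is State.STALLED
        ens.check_invariants()


class TestPopulation:
    def test_processivity_without_obstacles(self, short_params):
        params = short_params.with_(initiation_rate=0.5, stall_rate_w1=0,
                                    stall_rate_w2=0, backtrack_rate_w1=0,
                                    backtrack_rate_w2=0, early_term_prob=0.0)
        occ, met = simulate_population(params, 300, seed=4)
        # no early termination; collisions can still stall-and-terminate the
        # occasional polymerase caught from behind
        assert met.early_terminated == 0
        assert met.initiated == (met.completed + met.engaged +
                                 met.collision_terminated)
        assert met.processivity > 80.0

    def test_early_termination_sets_processivity(self):
        """With termination the only removal process, processivity matches
        the binomial expectation 1 - early_term_prob."""
        params = ModelParameters(initiation_rate=0.2, early_term_prob=0.3,
                                 early_term_mean=300.0, stall_rate_w1=0,
                                 stall_rate_w2=0, backtrack_rate_w1=0,
                                 backtrack_rate_w2=0, total_time=30.0)
        occ, met = simulate_population(params, 2000, seed=5)
        finished = met.completed + met.early_terminated
        assert finished > 2000
        frac_term = met.early_terminated / finished
        se = np.sqrt(0.3 * 0.7 / finished)
        assert abs(frac_term - 0.3) < 3 * se

    def test_conservation_and_footprint_over_full_run(self, short_params):
        occ, met = simulate_population(short_params.with_(initiation_rate=4.0),
                                       200, seed=6, validate=True)
        assert met.initiated == (met.engaged + met.completed +
                                 met.early_terminated + met.collision_terminated)

    def test_seed_reproducibility(self, short_params):
        a, ma = simulate_population(short_params, 100, seed=11)
        b, mb = simulate_population(short_params, 100, seed=11)
        assert np.array_equal(a.counts, b.counts)
        assert ma == mb
        c, _ = simulate_population(short_params, 100, seed=12)
        assert not np.array_equal(a.counts, c.counts)

    def test_population_scaling_leaves_shape_invariant(self):
        """Two independent half-populations give the same normalized,
        binned occupancy up to sampling error."""
        from netpol.fitting import bin_and_normalize, ks_distance
        params = ModelParameters(total_time=15.0)
        a, _ = simulate_population(params, 2000, seed=21)
        b, _ = simulate_population(params, 2000, seed=22)
        d = ks_distance(bin_and_normalize(a.counts), bin_and_normalize(b.counts))
        assert d < 0.08

    def test_engines_agree_statistically(self):
        from netpol.fitting import bin_and_normalize, ks_distance
        params = ModelParameters(total_time=6.0)
        occ_f, met_f = simulate_population(params, 400, seed=31)
        occ_r, met_r = simulate_population(params, 400, seed=32, engine="reference",
                                           validate=True)
        assert abs(met_f.processivity - met_r.processivity) < 8.0
        d = ks_distance(bin_and_normalize(occ_f.counts),
                        bin_and_normalize(occ_r.counts))
        assert d < 0.1

    def test_zero_population_rejected(self, short_params):
        with pytest.raises(ConfigError):
            simulate_population(short_params, 0, seed=1)
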