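"""Stepping engine: seeding, movement, attachment, death, proliferation."""

import numpy as np
import pytest

import recellsim as r
from recellsim.simulator import (
    attachment_step,
    calibrate_time_scale,
    death_step,
    extract_slice,
    movement_step,
    proliferation_step,
)


def make_sim(config=None, rules=None, seed=0):
    return r.Simulation(rules or r.hypothesis1(), config or r.SimConfig(), rng=seed)


def add_engrafted(sim, coords, T_life=100, T_prol=100):
    cid = sim._new_agent()
    sim.pos[cid] = coords
    sim.T_life[cid], sim.T_prol[cid] = T_life, T_prol
    sim.alive[cid] = sim.engrafted[cid] = True
    sim._occupy(coords, cid)
    return cid


def add_motile(sim, coords):
    cid = sim._new_agent()
    sim.pos[cid] = coords
    sim.alive[cid] = True
    sim.heading[cid] = sim._random_unit()
    sim._occupy(coords, cid)
    return cid


# -- seeding -----------------------------------------------------------------


def test_seed_counts_match_binomial_expectation():
    sim = make_sim(r.SimConfig(n_cells=30_000), seed=5)
    sim.seed()
    n = sim.n_engrafted
    # Binomial(30000, 0.95): mean 28500, sd ~38; allow 5 sd
    assert abs(n - 28_500) < 5 * np.sqrt(30_000 * 0.95 * 0.05)
    assert sim.n_motile == 0  # instant_cull eliminates the rest at seeding
    # distinct patches: occupancy bookkeeping must agree with the census
    assert (sim.state.occupancy != -1).sum() == n


def test_seed_degenerate_probabilities():
    sim = make_sim(r.SimConfig(grid_size=12, n_cells=500))
    sim.seed(engraft_prob=1.0)
    assert sim.n_engrafted == 500 and sim.n_motile == 0
    sim2 = make_sim(r.SimConfig(grid_size=12, n_cells=0))
    sim2.seed()
    assert sim2.n_engrafted == 0 and sim2.n_motile == 0


def test_seed_rejects_overfull_lattice():
    sim = make_sim(r.SimConfig(grid_size=4, n_cells=100))
    with pytest.raises(ValueError):
        sim.seed()


def test_one_step_grace_retains_motile_until_first_step():
    cfg = r.SimConfig(grid_size=16, n_cells=2000, seeding_mode="one_step_grace")
    sim = make_sim(cfg, seed=3)
    sim.seed()
    assert sim.n_motile > 0
    sim.step()
    assert sim.n_motile == 0  # survivors of the grace step are culled


# -- movement ----------------------------------------------------------------


def test_strong_ahead_signal_moves_to_strongest_patch(scripted_rng_cls):
    """With c_ahead = (21.3, 0, 0) and x1 = 0.5, S = 10.65 > 1: the cell moves
    to the straight-ahead patch."""
    sim = make_sim()
    cid = add_motile(sim, (0, 0, 0))
    sim.state.substrate[:] = 0.0
    sim.state.substrate[sim.state._index((1, 0, 0))] = 21.3
    # heading +x: ahead patches are (1,0,0), (1,±1,0)
    sim.rng = scripted_rng_cls(normals=[np.array([1.0, 0.0, 0.0])],
                               uniforms=[np.array([0.5, 0.5, 0.5])])
    cell = movement_step(sim, cid)
    assert cell.position == (1, 0, 0)


def test_zero_concentration_forces_random_adjacent_move():
    sim = make_sim()
    sim.state.substrate[:] = 0.0
    cid = add_motile(sim, (0, 0, 0))
    before = (0, 0, 0)
    cell = movement_step(sim, cid)
    assert cell.position != before
    assert max(abs(a - b) for a, b in zip(cell.position, before)) == 1


def test_fully_blocked_cell_stays_put():
    sim = make_sim()
    sim.state.substrate[:] = 0.0
    cid = add_motile(sim, (0, 0, 0))
    for n in sim.state.neighbors((0, 0, 0)):
        add_engrafted(sim, n)
    cell = movement_step(sim, cid)
    assert cell.position == (0, 0, 0)


def test_ahead_directions_are_unit_lattice_steps():
    sim = make_sim(seed=9)
    for _ in range(50):
        dirs = sim.ahead_directions(sim._random_unit())
        assert len(dirs) == 3
        for d in dirs:
            assert np.max(np.abs(d)) == 1


# -- attachment --------------------------------------------------------------


def test_attachment_threshold(scripted_rng_cls):
    sim = make_sim()
    cid = add_motile(sim, (2, 2, 2))
    sim.rng = scripted_rng_cls(uniforms=[3.0])  # N = 3 <= N_crit = 5
    cell = attachment_step(sim, cid)
    assert isinstance(cell, r.MotileCell)
    sim.rng = scripted_rng_cls(uniforms=[50.0])  # N = 50 > 5
    cell = attachment_step(sim, cid)
    assert isinstance(cell, r.EngraftedCell)


def test_attachment_fraction_near_95_percent():
    sim = make_sim(r.SimConfig(grid_size=32, n_cells=20_000), seed=11)
    sim.seed()  # seeding applies the same N > N_crit draw
    frac = sim.n_engrafted / 20_000
    assert frac == pytest.approx(0.95, abs=0.01)


def test_engraftment_deposits_substrate(scripted_rng_cls):
    sim = make_sim()
    c0 = sim.state.concentration_at((3, 4, 7))
    cid = add_motile(sim, (3, 4, 7))
    sim.rng = scripted_rng_cls(uniforms=[99.0])
    attachment_step(sim, cid)
    assert sim.state.concentration_at((3, 4, 7)) == pytest.approx(c0 + 1.0)


def test_no_engraftment_when_ncrit_is_100():
    sim = make_sim(rules=r.hypothesis1().replace(N_crit=100.0), seed=2)
    cid = add_motile(sim, (0, 0, 0))
    for _ in range(300):
        attachment_step(sim, cid)
    assert not sim.engrafted[cid]


# -- death and proliferation -------------------------------------------------


def test_death_triggers_at_lifespan():
    sim = make_sim()
    cid = add_engrafted(sim, (5, 5, 5), T_life=10)
    for step in range(1, 10):
        assert death_step(sim, cid)
    assert not death_step(sim, cid)  # N_life reaches 10 = T_life
    assert not sim.alive[cid]
    assert not sim.state.is_occupied((5, 5, 5))


def test_zero_lifespan_dies_at_first_death_step():
    sim = make_sim()
    cid = add_engrafted(sim, (5, 5, 5), T_life=0)
    assert not death_step(sim, cid)


def test_death_withdraws_substrate_deposit():
    sim = make_sim()
    coords = (3, 4, 7)
    c0 = sim.state.concentration_at(coords)
    cid = add_engrafted(sim, coords, T_life=1)
    sim.state.deposit_substrate(coords)  # the cell's engraftment deposit
    death_step(sim, cid)
    assert sim.state.concentration_at(coords) == pytest.approx(c0)


def test_proliferation_places_exactly_one_offspring():
    sim = make_sim()
    cid = add_engrafted(sim, (0, 0, 0), T_prol=1)
    child = proliferation_step(sim, cid)
    assert child is not None
    assert sim.n_engrafted == 2
    assert max(abs(a - b) for a, b in zip(child.position, (0, 0, 0))) == 1
    # one opportunity per cell: no second offspring on later steps
    assert proliferation_step(sim, cid) is None


def test_proliferation_deferred_when_no_eligible_target():
    sim = make_sim()
    cid = add_engrafted(sim, (0, 0, 0), T_prol=1)
    for n in sim.state.neighbors((0, 0, 0))[:26]:
        add_engrafted(sim, n)
    assert proliferation_step(sim, cid) is None
    assert sim.N_prol[cid] == sim.T_prol[cid]  # counter held, retried later
    # free a corner neighbor plus one of its own neighbors, bringing the
    # corner's occupied-neighbor count down to the cap of 6
    for coords in ((1, 1, 1), (0, 0, 1)):
        sim._die(int(sim.state.occupancy[sim.state._index(coords)]))
    assert sim.state.occupied_neighbor_count((1, 1, 1)) == 6
    child = proliferation_step(sim, cid)
    assert child is not None and child.position == (1, 1, 1)


def test_proliferation_respects_crowding_cap():
    """Offspring may only land on patches with at most 6 occupied neighbors."""
    sim = make_sim()
    cid = add_engrafted(sim, (0, 0, 0), T_prol=1)
    # crowd the neighborhood so every free neighbor patch sees > 6 occupied ones
    for dx in range(-2, 3):
        for dy in range(-2, 3):
            for dz in range(-2, 3):
                c = (dx, dy, dz)
                if c != (0, 0, 0) and max(map(abs, c)) == 2:
                    add_engrafted(sim, c)
    eligible = sim._eligible_targets(cid)
    for t in eligible:
        assert sim.state.occupied_neighbor_count(t) <= 6
    assert eligible == []  # each free neighbor touches >= 9 occupied patches


def test_counter_advances_below_threshold():
    sim = make_sim()
    cid = add_engrafted(sim, (0, 0, 0), T_life=36, T_prol=50)
    for _ in range(5):
        assert death_step(sim, cid)
        assert proliferation_step(sim, cid) is None
    assert sim.N_life[cid] == 5 and sim.N_prol[cid] == 5


# -- run loop ----------------------------------------------------------------


def test_per_step_conservation(small_config):
    sim = make_sim(small_config, seed=21)
    sim.seed()
    for _ in range(8):
        before = sim.n_engrafted
        sim.step()
        s = sim.last_step_stats
        assert sim.n_engrafted == before + s["attachments"] + s["births"] - s["deaths"]
        # occupancy stays single-valued and consistent with the census
        occ = sim.state.occupancy
        assert (occ != -1).sum() == sim.n_engrafted + sim.n_motile


def test_immortal_population_is_constant():
    rules = r.hypothesis1().replace(
        initial_T_life=r.UniformSpec(10**6, 10**6),
        initial_T_prol=r.UniformSpec(10**6, 10**6),
    )
    cfg = r.SimConfig(grid_size=12, n_cells=300, n_steps=10, record_every=1,
                      n_slices=12, record_cvhv=False)
    sim = r.Simulation(rules, cfg, rng=4)
    sim.seed()
    n0 = sim.n_engrafted
    for _ in range(10):
        sim.step()
        assert sim.n_engrafted == n0


def test_same_seed_gives_identical_trajectories():
    cfg = r.SimConfig(grid_size=12, n_cells=300, n_steps=10, record_every=2,
                      n_slices=12)
    a = r.run("hypothesis1", seed=77, config=cfg)
    b = r.run("hypothesis1", seed=77, config=cfg)
    assert np.array_equal(a.counts, b.counts)
    assert np.allclose(a.cvhv, b.cvhv)
    c = r.run("hypothesis1", seed=78, config=cfg)
    assert not np.array_equal(a.counts, c.counts)


def test_engines_agree_statistically():
    """The vectorized engine and the plain per-agent reference loop produce
    the same population dynamics (replicate means within Monte-Carlo error)."""
    cfg_base = dict(grid_size=12, n_cells=600, n_steps=12, record_every=4,
                    n_slices=12, record_cvhv=False,
                    seeding_mode="one_step_grace")  # exercises motile turns too
    means = {}
    for engine in ("fast", "reference"):
        cfg = r.SimConfig(engine=engine, **cfg_base)
        runs = np.array([
            r.run("hypothesis1", seed=500 + i, config=cfg).counts.sum(axis=1)
            for i in range(15)
        ])
        means[engine] = (runs.mean(axis=0), runs.std(axis=0, ddof=1))
    m_f, s_f = means["fast"]
    m_r, s_r = means["reference"]
    se = np.sqrt((s_f**2 + s_r**2) / 15)
    assert np.all(np.abs(m_f - m_r) < 4 * np.maximum(se, 1.0))


def test_hypothesis2_retains_more_cells_early(full_runs):
    """Longer lifespans under Hypothesis 2 keep more cells engrafted at the
    early recorded time points (replicate means)."""
    for tp in (10, 20, 30):
        m = {
            h: full_runs[h][full_runs[h]["time_step"] == tp]
            .groupby("replicate")["n_cells"].mean().mean()
            for h in (1, 2)
        }
        assert m[2] > m[1]


# -- slices and calibration --------------------------------------------------


def test_extract_slice_identities():
    sim = make_sim()
    assert extract_slice(sim, "z", 5).shape == (0, 2)
    add_engrafted(sim, (0, 0, 5))
    pts = extract_slice(sim, "z", 5)
    assert pts.tolist() == [[0, 0]]
    with pytest.raises(IndexError):
        extract_slice(sim, "z", 99)


def test_slice_counts_partition_total(small_config):
    sim = make_sim(small_config, seed=13)
    sim.seed()
    sim.step()
    all_slices = list(range(sim.state.lo, sim.state.hi + 1))
    assert sim.slice_counts(all_slices).sum() == sim.n_engrafted


def test_calibration_matches_printed_values():
    patch, rate, vel = calibrate_time_scale(32, 1000.0, 80, 28.0)
    assert patch == pytest.approx(31.25)
    assert rate == pytest.approx(0.002, abs=2e-5)
    assert vel == pytest.approx(0.06, abs=0.003)


def test_calibration_scales_inversely_with_duration():
    _, rate1, vel1 = calibrate_time_scale(32, 1000.0, 80, 28.0)
    _, rate2, vel2 = calibrate_time_scale(32, 1000.0, 80, 56.0)
    assert rate2 == pytest.approx(rate1 / 2)
    assert vel2 == pytest.approx(vel1 / 2)
    with pytest.raises(ValueError):
        calibrate_time_scale(0, 1000.0, 80, 28.0)
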