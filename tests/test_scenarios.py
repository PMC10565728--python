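"""Scenario protocols: clade initiation, tracking, rescue, disturbance
regimes, adaptive radiation, and the replicate aggregation utilities."""

import numpy as np
import pytest

from evodyn import (
    Environment,
    ModelParams,
    REGIME_PRESETS,
    ScenarioConfig,
    SpeciationRule,
    Species,
    extinction_summary,
    make_founders,
    run_adaptive_radiation,
    run_clade_initiation,
    run_disturbance_regime,
    run_rescue,
    run_tracking,
    simulate,
)
from evodyn.dynamics import Event, Trajectory
from evodyn.scenarios import _run_single


def clade(u0, **kw):
    return ScenarioConfig("clade_initiation", u0=u0, **kw)


class TestCladeInitiation:
    def test_close_start_kills_the_fast_evolver(self):
        traj = run_clade_initiation(clade(0.5))
        t = traj.extinction_time("fast_0")
        assert t == pytest.approx(315.0, rel=0.15)
        assert traj.extinction_time("slow_0") is None

    def test_far_start_kills_the_slow_evolver(self):
        traj = run_clade_initiation(clade(10.0))
        t = traj.extinction_time("slow_0")
        assert t == pytest.approx(11.0, rel=0.15)
        assert traj.extinction_time("fast_0") is None

    def test_winner_ordering_across_starting_distances(self):
        """Close and medium starts favor the slow evolver; far starts favor
        the fast evolver (it climbs the landscape first)."""
        winners = {}
        for u0 in (0.5, 4.0, 10.0):
            traj = run_clade_initiation(clade(u0))
            winners[u0] = traj.extant_ids()
        assert winners[0.5] == ["slow_0"]
        assert winners[4.0] == ["slow_0"]
        assert winners[10.0] == ["fast_0"]

    def test_neutral_pair_never_goes_extinct(self):
        cfg = clade(6.0, k_fast=0.2, params=ModelParams(d=0.0))
        traj = run_clade_initiation(cfg)
        assert not [ev for ev in traj.events if ev.kind == "extinction"]


class TestRescue:
    @pytest.mark.parametrize(
        "step_time, expected",
        [(600.0, 665.0), (750.0, 910.0)],
    )
    def test_early_disturbance_dooms_the_slow_evolver(self, step_time, expected):
        env = Environment(mode="step", steps=((step_time, -4.0),))
        cfg = ScenarioConfig("rescue", env=env)
        traj = run_rescue(cfg)
        assert traj.extinction_time("slow_0") == pytest.approx(expected, rel=0.15)
        assert traj.extinction_time("fast_0") is None

    def test_late_disturbance_rescues_the_slow_evolver(self):
        """Disturbance while the slow evolver dominates: it survives,
        converges on the new optimum, and (because of the evolvability
        cost) eventually outcompetes the fast evolver."""
        # horizon long enough for the slow evolver (e-folding ~300 time
        # units) to close in on the new optimum
        env = Environment(mode="step", steps=((900.0, -4.0),))
        traj = run_rescue(ScenarioConfig("rescue", env=env, t_end=2600.0))
        assert traj.extinction_time("slow_0") is None
        j = traj.index("slow_0")
        assert abs(traj.strategy[-1, j] - (-4.0)) < 0.1

    def test_rescue_requires_a_step_schedule(self):
        with pytest.raises(ValueError):
            ScenarioConfig("rescue", env=Environment(mode="constant"))


class TestDisturbanceRegimes:
    @pytest.mark.parametrize(
        "preset, expected",
        [
            ("collapse_rare", "slow_survives"),
            ("collapse_intermediate", "coexistence"),
            ("collapse_frequent", "fast_survives"),
        ],
    )
    def test_disturbance_timing_selects_the_survivor(self, preset, expected):
        """Rare shifts favor the slow evolver, frequent shifts the fast
        one, and intermediate timing yields (transient) coexistence:
        the storage-effect pattern."""
        env = Environment(mode="step", steps=REGIME_PRESETS[preset])
        cfg = ScenarioConfig("disturbance_regime", env=env)
        _, outcome = run_disturbance_regime(cfg)
        assert outcome == expected


class TestTracking:
    def test_stochastic_close_start_always_kills_fast_evolver(self):
        cfg = ScenarioConfig(
            "tracking_stochastic", u0=0.5, n_trials=6, t_end=450.0, seed=7
        )
        trajectories, summary = run_tracking(cfg)
        assert len(trajectories) == 6
        assert summary.loc["fast_0", "n_extinct"] == 6
        assert summary.loc["slow_0", "n_extinct"] == 0
        assert 280 < summary.loc["fast_0", "mean_time"] < 350

    def test_replicates_use_independent_environments(self):
        cfg = ScenarioConfig(
            "tracking_stochastic", u0=0.5, n_trials=2, t_end=30.0, seed=7
        )
        (a, b), _ = run_tracking(cfg)
        assert not np.array_equal(a.gamma, b.gamma)

    def test_sinusoidal_close_start_spares_the_slow_evolver(self):
        cfg = ScenarioConfig("tracking_deterministic", u0=0.5, t_end=600.0)
        (traj,), summary = run_tracking(cfg)
        assert summary is None
        assert traj.extinction_time("slow_0") is None
        # while both live, the fast evolver tracks the moving peak with
        # larger strategy oscillations than the slow one
        i, j = traj.index("slow_0"), traj.index("fast_0")
        window = (traj.times > 150) & (traj.times < 330)
        amp_slow = np.ptp(traj.strategy[window, i])
        amp_fast = np.ptp(traj.strategy[window, j])
        assert amp_fast > amp_slow


def _traj_with_extinctions(times_by_id):
    events = [
        Event(t, "extinction", sid) for sid, t in times_by_id.items()
        if t is not None
    ]
    ids = list(times_by_id)
    n = len(ids)
    return Trajectory(
        times=np.array([0.0]),
        species_ids=ids,
        density=np.zeros((1, n)),
        strategy=np.zeros((1, n)),
        gamma=np.zeros(1),
        events=events,
        species=[Species(id=s, k=0.2, u=0.0, x=1.0) for s in ids],
    )


class TestExtinctionSummary:
    def test_identical_times_have_zero_spread(self):
        trajs = [_traj_with_extinctions({"a": 10.0}) for _ in range(3)]
        s = extinction_summary(trajs)
        assert s.loc["a", "n_extinct"] == 3
        assert s.loc["a", "mean_time"] == 10.0
        assert s.loc["a", "sd_time"] == 0.0

    def test_sample_standard_deviation_over_extinct_replicates_only(self):
        trajs = [
            _traj_with_extinctions({"a": 5.0}),
            _traj_with_extinctions({"a": 15.0}),
            _traj_with_extinctions({"a": None}),
        ]
        s = extinction_summary(trajs)
        assert s.loc["a", "n_extinct"] == 2
        assert s.loc["a", "mean_time"] == 10.0
        assert s.loc["a", "sd_time"] == pytest.approx(7.0710678, rel=1e-6)

    def test_no_extinctions_reported_as_undefined(self):
        s = extinction_summary([_traj_with_extinctions({"a": None})])
        assert s.loc["a", "n_extinct"] == 0
        assert np.isnan(s.loc["a", "mean_time"])

    def test_requires_at_least_one_trajectory(self):
        with pytest.raises(ValueError):
            extinction_summary([])


@pytest.fixture(scope="module")
def radiation_run():
    cfg = ScenarioConfig(
        "adaptive_radiation", u0=0.5, t_end=2600.0, max_species=8, seed=3
    )
    return run_adaptive_radiation(cfg)


class TestAdaptiveRadiation:
    def test_equilibrium_independent_of_starting_distance(self):
        """Before any speciation, fast + slow settle into the same
        two-minimum configuration from any starting strategy."""
        finals = []
        for u0 in (0.5, 4.0, 10.0):
            cfg = ScenarioConfig("adaptive_radiation", u0=u0, t_end=4000.0)
            traj = _run_single(cfg)
            finals.append(sorted(s.u for s in traj.species if s.extant))
        assert np.allclose(finals[0], finals[1], atol=0.01)
        assert np.allclose(finals[0], finals[2], atol=0.01)

    def test_gaussian_wide_kernel_never_triggers_speciation(self):
        """Under the single-peak regime (Gaussian kernel, sigma_a2=100)
        there are no convergent minima, hence no speciation."""
        p = ModelParams()  # gaussian, sigma_a2=100
        founders = make_founders(clade(0.5))
        traj = simulate(
            founders, Environment(), p, t_end=1200.0,
            speciation=SpeciationRule(), rng_seed=1,
        )
        assert not [ev for ev in traj.events if ev.kind == "speciation"]

    def test_only_fast_lineages_speciate_and_slow_persists(self, radiation_run):
        traj, phylo = radiation_run
        spec = [ev for ev in traj.events if ev.kind == "speciation"]
        assert spec, "expected at least one speciation event"
        assert all(ev.info["parent_id"].startswith("fast") for ev in spec)
        slow = next(s for s in traj.species if s.id == "slow_0")
        assert slow.extant

    def test_daughters_offset_within_bounds_and_seeded_at_unit_density(
        self, radiation_run
    ):
        traj, _ = radiation_run
        for ev in traj.events:
            if ev.kind != "speciation":
                continue
            i_child = traj.index(ev.species_id)
            i_parent = traj.index(ev.info["parent_id"])
            row = int(np.searchsorted(traj.times, ev.time))
            assert abs(
                traj.strategy[row, i_child] - traj.strategy[row, i_parent]
            ) <= 0.02 + 1e-12
            assert traj.density[row, i_child] == 1.0

    def test_branching_pair_diverges_after_speciation(self):
        """Diffuse coevolution: disruptive selection at the minimum drives
        parent and daughter apart monotonically after a short transient."""
        cfg = ScenarioConfig(
            "adaptive_radiation", u0=0.5, t_end=1500.0, max_species=4, seed=3
        )
        traj, _ = run_adaptive_radiation(cfg)
        ev = next(e for e in traj.events if e.kind == "speciation")
        i = traj.index(ev.info["parent_id"])
        j = traj.index(ev.species_id)
        window = traj.times >= ev.time + 100.0
        gap = np.abs(traj.strategy[window, i] - traj.strategy[window, j])
        # monotone apart from a small settling overshoot at the new minima
        assert np.all(gap >= 0.98 * np.maximum.accumulate(gap))
        assert gap[-1] > 10 * gap[0]

    def test_phylogeny_accounts_for_every_speciation(self, radiation_run):
        traj, phylo = radiation_run
        n_spec = sum(1 for ev in traj.events if ev.kind == "speciation")
        assert len(phylo.nodes) == 2 + n_spec
        assert {r.id for r in phylo.roots} == {"fast_0", "slow_0"}


class TestConfigPlumbing:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig("meteor_strike")

    def test_round_trip_through_dict(self):
        cfg = ScenarioConfig(
            "rescue",
            u0=4.0,
            env=Environment(mode="step", steps=((600.0, -4.0),)),
            seed=9,
        )
        again = ScenarioConfig.from_dict(cfg.to_dict())
        assert again.resolved_env() == cfg.resolved_env()
        assert again.resolved_params() == cfg.resolved_params()
        assert again.seed == 9

    def test_radiation_defaults_to_bounded_kernel(self):
        cfg = ScenarioConfig("adaptive_radiation")
        p = cfg.resolved_params()
        assert p.kernel == "bounded"
        assert p.sigma_a2 == 2.0
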