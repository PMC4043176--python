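"""Data model, I/O round-trips and observation construction."""

import math

import numpy as np
import pytest

from applause.event_data import (
    Bout,
    ClapRecord,
    ValidationError,
    audience_state,
    audience_trajectory,
    make_start_observations,
    make_stop_observations,
    read_bouts,
    write_bouts,
)
from conftest import best_fit_study


def test_csv_read_minimal(tmp_path):
    path = tmp_path / "two.csv"
    path.write_text(
        "group_id,talk_id,individual_id,seat_row,seat_col,start_time,stop_time,clap_times\n"
        "g,1,a,0,0,0.0,3.0,\n"
        "g,1,b,0,1,0.5,3.5,\n"
    )
    (bout,) = read_bouts(path)
    assert bout.n == 2
    assert min(r.start_time for r in bout.starters) == 0.0


def test_read_shifts_time_origin(tmp_path):
    path = tmp_path / "shifted.csv"
    path.write_text(
        "group_id,talk_id,individual_id,seat_row,seat_col,start_time,stop_time,clap_times\n"
        "g,1,a,0,0,10.0,13.0,10.0;11.5;13.0\n"
        "g,1,b,0,1,10.5,13.5,10.5;13.5\n"
    )
    (bout,) = read_bouts(path)
    assert bout.record_of("a").start_time == 0.0
    assert bout.record_of("a").clap_times == (0.0, 1.5, 3.0)
    assert bout.record_of("b").stop_time == pytest.approx(3.5)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(start_time=2.0, stop_time=1.0),  # stop before start
        dict(start_time=0.0, stop_time=3.0, clap_times=(0.0, 2.5, 2.0, 3.0)),
        dict(start_time=0.0, stop_time=3.0, clap_times=(0.5, 3.0)),  # first != start
        dict(start_time=None, stop_time=3.0),  # non-starter with a stop
    ],
)
def test_record_invariant_violations(kwargs):
    with pytest.raises(ValidationError):
        ClapRecord("g", 1, "x", 0, 0, **kwargs)


def test_roundtrip_csv_and_json(tmp_path):
    bouts = best_fit_study(seed=17)
    for fmt in ("csv", "json"):
        path = tmp_path / f"study.{fmt}"
        write_bouts(bouts, path)
        back = read_bouts(path)
        assert len(back) == len(bouts)
        for a, b in zip(sorted(bouts, key=lambda x: (x.group_id, x.talk_id)), back):
            assert a.n == b.n
            for ra in a.records:
                rb = b.record_of(ra.individual_id)
                assert rb.start_time == ra.start_time
                assert rb.stop_time == ra.stop_time
                assert rb.clap_times == ra.clap_times
                assert (rb.seat_row, rb.seat_col) == (ra.seat_row, ra.seat_col)


def test_trajectory_hand_enumeration(toy):
    grid = [0.0, 0.5, 1.0, 2.0, 3.9, 4.0, 5.0, 6.0, 7.0]
    states = audience_trajectory(toy, grid)
    clapping = [s.rho_clapping for s in states]
    stopped = [s.rho_stopped for s in states]
    third = 1 / 3
    assert clapping == pytest.approx([third, third, 2 * third, 1, 1, 1, 1, 1, 1])
    assert stopped == pytest.approx([0, 0, 0, 0, 0, third, 2 * third, 1, 1])
    # at t=0 exactly one person (the initiator) claps; past the last stop
    # everyone who started has stopped
    assert states[0].rho_clapping == pytest.approx(1 / toy.n)
    assert states[-1].rho_stopped == pytest.approx(len(toy.starters) / toy.n)


def test_trajectory_fractions_monotone():
    for seed in (1, 2):
        bouts = best_fit_study(seed=seed)
        grid = np.linspace(0, bouts[0].end_time, 200)
        states = audience_trajectory(bouts[0], grid)
        clap = np.array([s.rho_clapping for s in states])
        stop = np.array([s.rho_stopped for s in states])
        assert (np.diff(clap) >= 0).all() and (np.diff(stop) >= 0).all()
        assert (stop <= clap + 1e-12).all()


def test_neighbour_adjacency(toy):
    nbrs = toy.neighbours()
    assert set(nbrs["A"]) == {"B", "C"}
    assert nbrs["B"] == ("A",)
    diag = toy.neighbours(include_diagonals=True)
    assert set(diag["B"]) == {"A", "C"}


def test_start_observations_toy_hand_count(toy):
    obs = make_start_observations(toy, dt=0.5)
    # initiator A contributes nothing; B has 2 frames, C has 4
    assert {o.individual_id for o in obs} == {"B", "C"}
    b_frames = [o for o in obs if o.individual_id == "B"]
    c_frames = [o for o in obs if o.individual_id == "C"]
    assert len(b_frames) == 2 and len(c_frames) == 4
    assert [o.outcome for o in b_frames] == ["not_started", "started"]
    assert [o.rho_clapping for o in c_frames] == pytest.approx([1 / 3, 1 / 3, 2 / 3, 2 / 3])
    assert sum(o.started for o in obs) == 2


def test_start_observation_exposure_conservation():
    """Frame counts x dt recover each individual's susceptible exposure."""
    bouts = best_fit_study(seed=3)
    bout, dt = bouts[0], 0.1
    obs = make_start_observations(bout, dt)
    per_ind = {}
    for o in obs:
        per_ind[o.individual_id] = per_ind.get(o.individual_id, 0) + 1
    for iid, frames in per_ind.items():
        r = bout.record_of(iid)
        expected = math.floor((r.start_time - 1e-9) / dt) + 1
        assert frames == expected


def test_start_observations_non_starter_followed_to_bout_end():
    from applause.synthetic_data import StudyDesign

    bouts = best_fit_study(seed=5, design=StudyDesign())
    bout = next(b for b in bouts if any(not r.is_starter for r in b.records))
    non = next(r for r in bout.records if not r.is_starter)
    obs = [o for o in make_start_observations(bout, 0.1) if o.individual_id == non.individual_id]
    assert all(o.outcome == "not_started" for o in obs)
    assert len(obs) == math.ceil((bout.end_time - 1e-9) / 0.1)


def test_stop_observations_toy(toy):
    obs = make_stop_observations(toy)
    assert len(obs) == 5 + 4 + 3
    a_obs = [o for o in obs if o.individual_id == "A"]
    assert [o.n_claps for o in a_obs] == [1, 2, 3, 4, 5]
    assert [o.outcome for o in a_obs[:-1]] == ["continued"] * 4
    assert a_obs[-1].outcome == "stopped"
    assert a_obs[-1].rho_stopped == 0.0  # first stopper sees nobody stopped
    b_final = [o for o in obs if o.individual_id == "B"][-1]
    c_final = [o for o in obs if o.individual_id == "C"][-1]
    assert b_final.rho_stopped == pytest.approx(1 / 3)
    assert c_final.rho_stopped == pytest.approx(2 / 3)


def test_stop_observations_restricted_filter(toy):
    full = make_stop_observations(toy)
    restricted = make_stop_observations(toy, restrict_after_first_stop=True)
    # the bout's first stop is at 4.0 s: everything before is excluded,
    # as is the first stop itself (no-one had stopped when it happened)
    assert all(o.time >= 4.0 for o in restricted)
    assert all(o.rho_stopped > 0 for o in restricted)
    pre = [o for o in full if o.rho_stopped == 0.0]
    assert len(restricted) == len(full) - len(pre)


def test_stop_observations_missing_claps_error():
    rec = ClapRecord("g", 1, "a", 0, 0, 0.0, 2.8, n_claps=11)
    bout = Bout((rec,))
    with pytest.raises(ValidationError, match="reconstruct"):
        make_stop_observations(bout)
    fixed = bout.with_reconstructed_claps()
    assert len(fixed.record_of("a").clap_times) == 11
    assert len(make_stop_observations(fixed)) == 11


def test_empty_bout_rejected():
    with pytest.raises(ValidationError):
        Bout(())
    with pytest.raises(ValidationError):  # no starter sets the origin
        Bout((ClapRecord("g", 1, "a", 0, 0, None),))
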