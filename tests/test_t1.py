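"""T1 detection, trajectory pooling, threshold and predictive statistics."""

import math

import numpy as np
import pytest

import tigon as tg
from tigon.quartet import ModelParams, ensemble, simulate_active
from tigon.t1 import T1Event, events_from_trajectories

SQRT2, SQRT3 = math.sqrt(2), math.sqrt(3)


def test_detect_single_programmed_flip(active_sequence):
    seq, gt = active_sequence
    events, rosettes = tg.detect_events(seq)
    assert len(events) == len(gt.events) == 1
    L, R, T, B, t_flip = gt.events[0]
    ev = events[0]
    assert set(ev.losing) == {L, R}
    assert set(ev.gaining) == {T, B}
    assert abs(ev.t_star - t_flip) <= 0.25  # within one frame
    assert not rosettes


def test_detect_multiple_events_no_false_positives():
    seq, gt = tg.generate_t1_sequence("active", nx=12, ny=12, n_events=3,
                                      seed=5)
    events, _ = tg.detect_events(seq)
    assert len(events) == len(gt.events) == 3
    assert {frozenset(e.losing) for e in events} == {
        frozenset((e[0], e[1])) for e in gt.events
    }


def test_detect_nothing_on_static_lattice():
    seq, gt = tg.generate_t1_sequence("none", t_max=1.0, seed=0)
    events, rosettes = tg.detect_events(seq)
    assert events == [] and gt.events == []


def test_detect_rosette():
    # five wedge cells sharing the central vertex
    loops = {}
    for k in range(5):
        a0 = 2 * math.pi * k / 5
        a1 = 2 * math.pi * (k + 1) / 5
        loops[k + 1] = [
            (0.0, 0.0),
            (math.cos(a0), math.sin(a0)),
            (math.cos(a1), math.sin(a1)),
        ]
    mesh = tg.mesh_from_cells(loops, frame_time=0.0)
    mesh2 = tg.mesh_from_cells(loops, frame_time=1.0)
    _, rosettes = tg.detect_events(tg.TrackedSequence([mesh, mesh2]))
    assert rosettes
    assert len(rosettes[0].cells) == 5


def test_reversing_flip_flagged(active_sequence):
    seq, _ = active_sequence
    # forward then reversed frame order: the quartet flips and un-flips
    frames = []
    t = 0.0
    for m in list(seq.frames) + list(seq.frames)[::-1]:
        frames.append(tg.CellMesh(m.vertices, m.cells, frame_time=t))
        t += 0.25
    events, _ = tg.detect_events(tg.TrackedSequence(frames))
    assert len(events) == 2
    assert all(ev.reversed for ev in events)


def test_untracked_cell_warns_and_is_excluded(active_sequence):
    seq, _ = active_sequence
    m0 = seq.frames[0]
    m1 = seq.frames[1]
    # inject a cell id in frame 1 only
    cells = dict(m1.cells)
    v0 = len(m1.vertices) + 10000
    verts = dict(m1.vertices)
    verts.update({v0: [500.0, 500.0], v0 + 1: [501.0, 500.0],
                  v0 + 2: [500.5, 501.0]})
    cells[9999] = tg.Cell(9999, [v0, v0 + 1, v0 + 2], "")
    m1b = tg.CellMesh(verts, cells, frame_time=m1.frame_time)
    with pytest.warns(UserWarning, match="mid-sequence"):
        tg.detect_events(tg.TrackedSequence([m0, m1b]))


def test_pooling_single_event_has_zero_sd():
    traj = simulate_active(np.array([1.05, 0.975, 0.975]), ModelParams())
    events = events_from_trajectories([traj])
    pooled = tg.pool_trajectories(events, window=10.0)
    np.testing.assert_allclose(pooled.collapsing.sd_T.dropna(), 0.0,
                               atol=1e-12)
    assert pooled.n_events == 1


def test_pooling_sem_identity_and_merge_consistency():
    runs = ensemble("active", 8, seed=3)
    events = events_from_trajectories(runs)
    pooled = tg.pool_trajectories(events, window=8.0)
    df = pooled.collapsing
    ok = df.n > 0
    np.testing.assert_allclose(
        df.sem_l[ok], df.sd_l[ok] / np.sqrt(df.n[ok]), atol=1e-12
    )
    # pooling two disjoint halves reproduces the full first and second
    # moments at every offset
    p1 = tg.pool_trajectories(events[:4], window=8.0,
                              dt_grid=pooled.dt_grid)
    p2 = tg.pool_trajectories(events[4:], window=8.0,
                              dt_grid=pooled.dt_grid)
    m = df.merge(p1.collapsing, on="t_rel_min", suffixes=("", "_a")).merge(
        p2.collapsing, on="t_rel_min", suffixes=("", "_b")
    )
    recomputed = (
        m.mean_l_a * m.n_a + m.mean_l_b * m.n_b
    ) / (m.n_a + m.n_b)
    np.testing.assert_allclose(m.mean_l, recomputed, atol=1e-12)


def test_pooled_active_shape_rise_drop_relax():
    """Active T1s: tension rises nonlinearly to a peak at the exchange,
    drops discontinuously, then relaxes toward 1."""
    p = ModelParams()
    rng = np.random.default_rng(6)
    trajs = []
    for _ in range(10):
        t0 = np.sort(1 + 0.05 * rng.standard_normal(3))[::-1]
        t0 = t0 / t0.mean()
        trajs.append(
            simulate_active(t0, p, hold_dl_iso=1.9, post_flip_window=6.0)
        )
    events = events_from_trajectories(trajs)
    pooled = tg.pool_trajectories(events, window=8.0)
    col, em = pooled.collapsing, pooled.emerging
    col = col[(col.t_rel_min > -5.0) & (col.n == pooled.n_events)]
    pre = col.mean_T.to_numpy()
    assert np.all(np.diff(pre) > 0)  # monotone rise
    # accelerating (nonlinear) rise
    assert np.diff(pre)[-1] > 2 * np.diff(pre)[0]
    peak = pre[-1]
    post = em.mean_T.to_numpy()
    assert post[0] < peak - 0.1  # discontinuous drop
    assert abs(post[-1] - 1.0) < abs(post[0] - 1.0)  # relaxes toward 1
    # pooled length monotone decreasing pre-flip
    lpre = col.mean_l.to_numpy()
    assert np.all(np.diff(lpre) < 1e-9)


def test_pooled_passive_shape_flat_then_elevated():
    """Passive T1s: tension stays at 1 before the exchange, jumps to
    ~sqrt(3) and decays slowly after."""
    runs = ensemble("passive", 8, seed=4)
    events = events_from_trajectories(runs)
    pooled = tg.pool_trajectories(events, window=8.0)
    np.testing.assert_allclose(pooled.collapsing.mean_T.dropna(), 1.0,
                               atol=1e-9)
    post = pooled.emerging.mean_T.to_numpy()
    assert post[0] == pytest.approx(SQRT3, abs=0.15)
    assert np.all(np.diff(post) < 1e-9)  # slow monotone decay
    assert post[-1] > 1.0


def test_estimate_threshold_single_event_exact():
    traj = simulate_active(np.array([1.05, 0.975, 0.975]), ModelParams())
    events = events_from_trajectories([traj])
    est = tg.estimate_threshold(events)
    pre = events[0].tensions[events[0].times < 0]
    assert est.mean == pre[-1]
    assert est.sd == 0.0


def test_estimate_threshold_active_matches_analytic():
    runs = ensemble("active", 12, seed=2)
    events = events_from_trajectories(runs)
    est = tg.estimate_threshold(events)
    assert est.mean == pytest.approx(SQRT2, rel=0.02)


def test_estimate_threshold_passive_is_unity():
    runs = ensemble("passive", 5, seed=2)
    est = tg.estimate_threshold(events_from_trajectories(runs))
    assert est.mean == pytest.approx(1.0, abs=1e-9)


def _graded_events(seed=0, n=14):
    """Simulator runs with graded initial tensions: higher tension flips
    sooner."""
    p = ModelParams()
    rng = np.random.default_rng(seed)
    ref, events = {}, []
    for i in range(n):
        excess = rng.uniform(0.02, 0.25)
        t0 = np.array([1 + excess, 1 - excess / 2, 1 - excess / 2])
        t0 = t0 / t0.mean()
        traj = simulate_active(t0, p, t_max=60.0)
        if traj.flip_time is None:
            continue
        pair = frozenset((2 * i, 2 * i + 1))
        ref[pair] = t0[0] / (0.5 * (t0[1] + t0[2]))
        events.append(
            T1Event(losing=(2 * i, 2 * i + 1),
                    gaining=(1000 + i, 2000 + i),
                    t_star=traj.flip_time, frame_pre=0, frame_post=0)
        )
    return ref, events


def test_time_to_collapse_negative_correlation_for_active():
    ref, events = _graded_events()
    stats = tg.time_to_collapse_stats(ref, events, t_ref=0.0)
    assert stats["spearman_rho"] < -0.8


def test_time_to_collapse_no_signal_when_shuffled():
    ref, events = _graded_events()
    rng = np.random.default_rng(1)
    rhos = []
    vals = list(ref.values())
    for _ in range(100):
        shuffled = dict(zip(ref.keys(), rng.permutation(vals)))
        rhos.append(
            tg.time_to_collapse_stats(shuffled, events, 0.0)["spearman_rho"]
        )
    assert abs(np.mean(rhos)) < 0.1


def test_time_to_collapse_requires_three_events():
    ref, events = _graded_events(n=3)
    with pytest.raises(ValueError):
        tg.time_to_collapse_stats(ref, events[:2], t_ref=0.0)


def test_classification_matches_generating_mode():
    for mode, seed in (("active", 3), ("passive", 2)):
        seq, gt = tg.generate_t1_sequence(mode, nx=7, ny=7, seed=seed)
        events, _ = tg.detect_events(seq)
        label, scores = tg.classify_active_passive(events[0], seq)
        assert label == mode, scores


def test_classification_mixed_construction():
    """Feedback plus prescribed isogonal contraction of comparable
    magnitude lands in the mixed band."""
    seq, _ = tg.generate_t1_sequence("mixed", nx=7, ny=7, seed=0)
    events, _ = tg.detect_events(seq)
    label, scores = tg.classify_active_passive(events[0], seq)
    assert label == "mixed", scores


def test_classification_too_short_is_unclassified(passive_sequence):
    seq, _ = passive_sequence
    events, _ = tg.detect_events(seq)
    short = tg.TrackedSequence(seq.frames[events[0].frame_pre - 1:])
    label, _ = tg.classify_active_passive(events[0], short)
    assert label == "unclassified"
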