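"""Detection and analysis of T1 neighbor exchanges in tracked sequences.

A T1 is recorded when a cell pair loses adjacency between consecutive
frames while a new adjacency appears within the same quartet; vertices
transiently shared by five or more cells are recorded as rosettes.
Length and tension trajectories of the collapsing (t < 0) and emerging
(t > 0) interfaces are aligned to the exchange time and pooled over
events; the mean relative tension at the last pre-collapse frame
estimates the collapse threshold <T_crit>.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .geometry import DEFAULT_L0
from .isogonal import quartet_isogonal_of_edge, quartet_shape_aspect
from .inference import infer_all_tensions, vertex_tension_nodes
from .mesh import TrackedSequence

__all__ = [
    "T1Event",
    "PooledTrajectory",
    "ThresholdEstimate",
    "detect_events",
    "attach_trajectories",
    "pool_trajectories",
    "estimate_threshold",
    "time_to_collapse_stats",
    "classify_active_passive",
]


@dataclass
class T1Event:
    """One detected neighbor exchange.

    ``losing`` were adjacent before the collapse frame, ``gaining`` after;
    ``t_star`` is the midpoint of the two frame times.  ``times``,
    ``lengths`` and ``tensions`` are aligned trajectories of the central
    interface (collapsing for t < 0, emerging for t > 0), filled by
    :func:`attach_trajectories`.
    """

    losing: tuple[int, int]
    gaining: tuple[int, int]
    t_star: float
    frame_pre: int
    frame_post: int
    kind: str = "t1"
    reversed: bool = False
    times: np.ndarray | None = None
    lengths: np.ndarray | None = None
    tensions: np.ndarray | None = None

    @property
    def quartet(self) -> tuple[int, int, int, int]:
        return (*self.losing, *self.gaining)


@dataclass
class RosetteEvent:
    cells: tuple[int, ...]
    frame: int
    time: float
    kind: str = "rosette"


@dataclass
class PooledTrajectory:
    """Event-aligned ensemble statistics on a common relative-time grid."""

    collapsing: pd.DataFrame
    emerging: pd.DataFrame
    dt_grid: float
    n_events: int


@dataclass
class ThresholdEstimate:
    mean: float
    sd: float
    sem: float
    per_event: np.ndarray

    def __repr__(self):
        return (
            f"ThresholdEstimate(<T_crit> = {self.mean:.4f} +/- "
            f"{self.sem:.4f} SEM, n = {len(self.per_event)})"
        )


def detect_events(
    seq: TrackedSequence,
) -> tuple[list[T1Event], list[RosetteEvent]]:
    """Detect neighbor exchanges and rosettes in a tracked sequence.

    Cell ids appearing after the first frame they could have been tracked
    from are warned about and excluded.  A flip that later reverses is
    recorded as two events, both flagged ``reversed``.
    """
    if len(seq) < 2:
        raise ValueError("at least two frames required")
    first_seen: dict[int, int] = {}
    for k, mesh in enumerate(seq):
        for cid in mesh.cells:
            first_seen.setdefault(cid, k)
    untracked = {cid for cid, k in first_seen.items() if k > 0}
    if untracked:
        warnings.warn(
            f"cell ids appearing mid-sequence excluded: {sorted(untracked)}"
        )

    adjacencies = []
    for mesh in seq:
        adjacencies.append(
            {
                pair
                for pair in mesh.adjacency()
                if not (pair & untracked)
            }
        )

    events: list[T1Event] = []
    rosettes: list[RosetteEvent] = []
    patience = 4  # frames a transient fourfold vertex may persist
    consumed: set[tuple[int, frozenset]] = set()
    for k in range(len(seq) - 1):
        lost = adjacencies[k] - adjacencies[k + 1]
        for pair in lost:
            a, b = tuple(pair)
            nbrs_a = {next(iter(p - {a})) for p in adjacencies[k] if a in p}
            nbrs_b = {next(iter(p - {b})) for p in adjacencies[k] if b in p}
            common = nbrs_a & nbrs_b
            # the gaining pair may appear a few frames later if the
            # exchange passes through a transient fourfold configuration
            for j in range(k, min(k + 1 + patience, len(seq)) - 1):
                gained = adjacencies[j + 1] - adjacencies[j]
                match = [
                    g for g in gained
                    if g <= common and not (g & pair)
                    and (j, g) not in consumed
                ]
                if len(match) == 1:
                    consumed.add((j, match[0]))
                    c, d = tuple(match[0])
                    events.append(
                        T1Event(
                            losing=(a, b),
                            gaining=(c, d),
                            t_star=0.5 * (seq.frames[k].frame_time
                                          + seq.frames[j + 1].frame_time),
                            frame_pre=k,
                            frame_post=j + 1,
                        )
                    )
                    break
    # rosettes: vertices shared by >= 5 cells
    for k, mesh in enumerate(seq):
        for vid in mesh.vertices:
            cells = mesh.cells_at_vertex(vid)
            if len(cells) >= 5:
                rosettes.append(
                    RosetteEvent(
                        cells=tuple(sorted(cells)),
                        frame=k,
                        time=mesh.frame_time,
                    )
                )
    # flag reversals: same quartet flipping back
    by_quartet: dict[frozenset, list[T1Event]] = {}
    for ev in events:
        by_quartet.setdefault(frozenset(ev.quartet), []).append(ev)
    for evs in by_quartet.values():
        if len(evs) > 1:
            for ev in evs:
                ev.reversed = True
    return events, rosettes


def attach_trajectories(
    seq: TrackedSequence,
    events: list[T1Event],
    tensions: list[pd.DataFrame] | None = None,
    only_event_interfaces: bool = True,
) -> list[T1Event]:
    """Fill each event's length/tension trajectories.

    ``tensions`` is one edge table per frame (from
    :func:`tigon.inference.infer_all_tensions`), matched by adjacent cell
    pair; if omitted the tensions are inferred here — over the whole frame
    or, with ``only_event_interfaces`` (the default), just at the events'
    central interfaces.  For t < t* the collapsing interface (losing pair)
    is followed, for t > t* the emerging one; no interpolation across the
    exchange.
    """
    if tensions is None and only_event_interfaces:
        from .inference import infer_edge_tension

        pairs = {frozenset(ev.losing) for ev in events}
        pairs |= {frozenset(ev.gaining) for ev in events}
        lookup = []
        for mesh in seq:
            d = {}
            for pair in pairs:
                eid = mesh.interface_between(*pair)
                if eid is None:
                    continue
                try:
                    d[pair] = infer_edge_tension(mesh, eid).t_rel
                except Exception:
                    pass
            lookup.append(d)
        tensions = False  # sentinel: lookup already built
    if tensions is not False:
        if tensions is None:
            tensions = [infer_all_tensions(m, frame=k)[0]
                        for k, m in enumerate(seq)]
        lookup = []
        for df in tensions:
            d = {}
            for row in df.itertuples():
                d[frozenset((row.cell_a, row.cell_b))] = row.T_rel
            lookup.append(d)
    for ev in events:
        times, lengths, tens = [], [], []
        for k, mesh in enumerate(seq):
            pair = ev.losing if mesh.frame_time < ev.t_star else ev.gaining
            eid = mesh.interface_between(*pair)
            if eid is None:
                continue
            times.append(mesh.frame_time - ev.t_star)
            lengths.append(mesh.interface_length(eid))
            tens.append(lookup[k].get(frozenset(pair), np.nan))
        ev.times = np.array(times)
        ev.lengths = np.array(lengths)
        ev.tensions = np.array(tens)
    return events


def events_from_trajectories(
    trajs, frame_interval: float = 0.25
) -> list[T1Event]:
    """Bridge quartet-model trajectories into the event-pooling analysis.

    Each flipped trajectory becomes a :class:`T1Event` whose length and
    relative-tension trajectories are the model's central interface,
    sampled at ``frame_interval`` minutes relative to the exchange.
    """
    events = []
    for i, traj in enumerate(trajs):
        if traj.flip_time is None:
            continue
        times = traj.times
        t_rel = traj.t_rel
        lengths = traj.central_length
        # sample on a grid aligned to the exchange, half a step off zero
        # so pre- and post-exchange samples stay distinct
        n_pre = int(traj.flip_time / frame_interval)
        n_post = int((times[-1] - traj.flip_time) / frame_interval)
        rel = (np.arange(-n_pre, n_post) + 0.5) * frame_interval
        grid = traj.flip_time + rel
        idx = np.searchsorted(times, grid, side="right") - 1
        idx = np.clip(idx, 0, len(times) - 1)
        events.append(
            T1Event(
                losing=(4 * i, 4 * i + 1),
                gaining=(4 * i + 2, 4 * i + 3),
                t_star=float(traj.flip_time),
                frame_pre=0,
                frame_post=0,
                times=rel,
                lengths=lengths[idx],
                tensions=t_rel[idx],
            )
        )
    return events


def pool_trajectories(
    events: list[T1Event],
    window: float = 15.0,
    dt_grid: float | None = None,
) -> PooledTrajectory:
    """Pool event-aligned trajectories on a common relative-time grid.

    The grid spacing defaults to the median frame interval of the events'
    samples.  Collapsing (t < 0) and emerging (t > 0) interfaces are
    pooled separately; per grid point the mean, SD (population) and
    SEM = SD/sqrt(n) of length and relative tension are reported.
    """
    events = [ev for ev in events if ev.times is not None and len(ev.times)]
    if not events:
        raise ValueError("no events with trajectories to pool")
    if dt_grid is None:
        diffs = np.concatenate(
            [np.diff(ev.times) for ev in events if len(ev.times) > 1]
        )
        dt_grid = float(np.median(diffs)) if len(diffs) else 1.0

    def _pool(side: str) -> pd.DataFrame:
        buckets: dict[int, list[tuple[float, float]]] = {}
        for ev in events:
            sel = (ev.times < 0) if side == "collapsing" else (ev.times > 0)
            sel &= np.abs(ev.times) <= window
            for t, l, T in zip(ev.times[sel], ev.lengths[sel],
                               ev.tensions[sel]):
                q = round(t / (0.5 * dt_grid))
                buckets.setdefault(q, []).append((l, T))
        rows = []
        for q in sorted(buckets):
            arr = np.array(buckets[q])
            l, T = arr[:, 0], arr[:, 1]
            n = len(arr)
            n_T = int(np.sum(~np.isnan(T)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rows.append(
                    {
                        "t_rel_min": q * 0.5 * dt_grid,
                        "mean_l": float(np.mean(l)),
                        "sd_l": float(np.std(l)),
                        "sem_l": float(np.std(l) / math.sqrt(n)),
                        "mean_T": float(np.nanmean(T)) if n_T else np.nan,
                        "sd_T": float(np.nanstd(T)) if n_T else np.nan,
                        "sem_T": float(np.nanstd(T) / math.sqrt(n_T))
                        if n_T else np.nan,
                        "n": n,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["t_rel_min", "mean_l", "sd_l", "sem_l", "mean_T",
                     "sd_T", "sem_T", "n"],
        )

    return PooledTrajectory(
        collapsing=_pool("collapsing"),
        emerging=_pool("emerging"),
        dt_grid=dt_grid,
        n_events=len(events),
    )


def estimate_threshold(
    events: list[T1Event], exclude_reversed: bool = True
) -> ThresholdEstimate:
    """<T_crit>: mean relative tension at the last pre-collapse frame.

    Reversing T1s are excluded by default.  SD is the population standard
    deviation over events and SEM = SD/sqrt(n).
    """
    vals = []
    for ev in events:
        if exclude_reversed and ev.reversed:
            continue
        if ev.times is None:
            continue
        pre = np.where((ev.times < 0) & ~np.isnan(ev.tensions))[0]
        if len(pre):
            vals.append(ev.tensions[pre[-1]])
    if not vals:
        raise ValueError("no events with a valid pre-collapse tension")
    v = np.array(vals)
    sd = float(np.std(v))
    return ThresholdEstimate(
        mean=float(np.mean(v)),
        sd=sd,
        sem=sd / math.sqrt(len(v)),
        per_event=v,
    )


def time_to_collapse_stats(
    reference_tensions: dict[frozenset, float],
    events: list[T1Event],
    t_ref: float,
) -> dict:
    """Does relative tension at a reference time predict collapse?

    ``reference_tensions`` maps adjacent cell pairs to their relative
    tension around ``t_ref`` (e.g. averaged over a few frames).  Returns
    the Spearman rank correlation between reference tension and time to
    collapse over the events collapsing after ``t_ref``, and the reference
    tension distributions of collapsing vs never-collapsing interfaces.
    """
    pairs_collapsing = {}
    for ev in events:
        if ev.t_star > t_ref:
            pairs_collapsing[frozenset(ev.losing)] = ev.t_star - t_ref
    tens, dt = [], []
    for pair, ttc in pairs_collapsing.items():
        if pair in reference_tensions:
            tens.append(reference_tensions[pair])
            dt.append(ttc)
    if len(tens) < 3:
        raise ValueError(
            f"correlation undefined: only {len(tens)} collapsing interfaces"
        )
    rho, pval = spearmanr(tens, dt)
    t_noncollapse = np.array(
        [
            T
            for pair, T in reference_tensions.items()
            if pair not in pairs_collapsing
        ]
    )
    return {
        "spearman_rho": float(rho),
        "p_value": float(pval),
        "n": len(tens),
        "tension_collapsing": np.array(tens),
        "time_to_collapse": np.array(dt),
        "tension_noncollapsing": t_noncollapse,
    }


def classify_active_passive(
    event: T1Event,
    seq: TrackedSequence,
    l0: float = DEFAULT_L0,
    margin: float = 2.0,
) -> tuple[str, dict]:
    """Classify an exchange as active, passive or mixed.

    Active T1s deform the tension triangulation at constant isogonal mode;
    passive T1s deform the isogonal mode at constant tension shape.  The
    scores are the total pre-collapse changes (absolute log ratio, last
    pre-collapse frame vs first) of the tension-triangle aspect ratio and
    of the quartet isogonal-tensor aspect ratio; the label is 'active'
    ('passive') when one score exceeds ``margin`` times the other, else
    'mixed'.  Events with fewer than 3 pre-collapse frames are
    'unclassified'.
    """
    aspects_t, aspects_i, times = [], [], []
    for k, mesh in enumerate(seq):
        if mesh.frame_time >= event.t_star:
            break
        eid = mesh.interface_between(*event.losing)
        if eid is None:
            continue
        try:
            u = mesh.interfaces[eid].vertex_pair[0]
            _, nodes = vertex_tension_nodes(mesh, u)
            a_t = quartet_shape_aspect(nodes)
            a_i = quartet_isogonal_of_edge(mesh, eid, l0=l0).aspect_ratio
        except Exception:
            continue
        times.append(mesh.frame_time)
        aspects_t.append(a_t)
        aspects_i.append(a_i)
    scores = {
        "n_frames": len(times),
        "tension_aspect": np.array(aspects_t),
        "isogonal_aspect": np.array(aspects_i),
    }
    if len(times) < 3:
        return "unclassified", scores
    s_t = abs(math.log(aspects_t[-1] / aspects_t[0]))
    s_i = abs(math.log(aspects_i[-1] / aspects_i[0]))
    scores["score_tension"] = s_t
    scores["score_isogonal"] = s_i
    if s_t >= margin * s_i:
        return "active", scores
    if s_i >= margin * s_t:
        return "passive", scores
    return "mixed", scores
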