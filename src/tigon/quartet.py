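"""Minimal model of an intercalating cell quartet.

A periodic array of identical hexagonal cells with three interface
classes: the central (collapsing) interface and the two flank classes.
The state is (active tensions, passive tension, vertex angles, interface
lengths).  Dynamics:

* positive tension feedback on the active (myosin-borne) tensions,
  ``tau_T dT_i/dt = T_i^n - (1/3) sum_k T_k^n`` (n = 4 by default), which
  conserves the total active tension (finite myosin pool);
* vertex angles follow the total tensions instantaneously through force
  balance (tension-triangle complementarity);
* interface lengths minimize a cell elastic energy
  ``E_C = lambda Tr(S_C - S_0)^2 + mu Tr[(S_C - S_0)^2]`` at fixed angles,
  with the subdivision-invariant shape tensor
  ``S_C = sum_i l_i e_i (x) e_i`` over unit edge directions weighted by
  length;
* at the neighbor exchange the new total tension is fixed by the flipped
  tension geometry (the other diagonal of the tension parallelogram), the
  active part by myosin *handover* (mean of the gaining cells' flank
  tensions) and the remainder is a passive tension that decays with
  remodeling time tau_p while feedback continues on the active tensions.

With an isotropic target shape the relaxed central length vanishes exactly
when the two tension triangles become concyclic, so the simulator flips at
the geometric T1 threshold (relative tension sqrt(2) for a symmetric
quartet at zero isogonal strain) without this being imposed anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import nnls

from .geometry import DEFAULT_L0, ForceBalanceError, TensionKite, \
    voronoi_reference_length

__all__ = [
    "ModelParams",
    "QuartetState",
    "QuartetTrajectory",
    "tension_feedback_step",
    "angles_from_tensions",
    "relax_lengths",
    "handover",
    "simulate_active",
    "simulate_passive",
    "ensemble",
    "dl_iso_of_state",
]


@dataclass
class ModelParams:
    """Parameters of the quartet model.

    tau_t : tension-feedback timescale (min); sets the active T1 duration
        (a symmetric run started a few percent above the fixed point
        collapses in roughly 0.5 * tau_t).
    n : feedback exponent (>= 2).
    lam, mu : elastic coefficients for isotropic compression and shear;
        only their ratio matters under the separation of scales.
    tau_p : passive-tension remodeling time (min).
    l0 : tension-to-length scale (um).
    l_rest : resting interface length (um); defaults to the hexagonal
        Voronoi value l0 / sqrt(3).
    s0 : 2x2 target shape tensor; defaults to (3/2) * l_rest * identity,
        the shape tensor of the resting hexagon.
    dt : integrator step (min); defaults to 1e-3 * tau_t.
    eps_flip : central length (um) at which the exchange is executed;
        defaults to 1e-3 * l0.
    """

    tau_t: float = 28.0
    n: int = 4
    lam: float = 1.0
    mu: float = 1.0
    tau_p: float = 2.0
    l0: float = DEFAULT_L0
    l_rest: float | None = None
    s0: np.ndarray | None = None
    dt: float | None = None
    eps_flip: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.tau_t <= 0 or self.tau_p <= 0:
            raise ValueError("timescales must be positive")
        if self.n < 2:
            raise ValueError("feedback exponent must be >= 2")
        if self.lam < 0 or self.mu < 0 or (self.lam == 0 and self.mu == 0):
            raise ValueError("lambda, mu must be >= 0 and not both 0")
        if self.l_rest is None:
            self.l_rest = self.l0 / math.sqrt(3.0)
        if self.s0 is None:
            self.s0 = 1.5 * self.l_rest * np.eye(2)
        else:
            self.s0 = np.asarray(self.s0, dtype=float).reshape(2, 2)
        if self.dt is None:
            self.dt = 1e-3 * self.tau_t
        if self.eps_flip is None:
            self.eps_flip = 1e-3 * self.l0


@dataclass
class QuartetState:
    """Instantaneous state of the quartet."""

    time: float
    t_myo: np.ndarray
    t_passive: float
    topology: str  # 'pre' | 'post'
    phis: np.ndarray
    lengths: np.ndarray
    energy: float

    @property
    def totals(self) -> np.ndarray:
        extra = np.array([self.t_passive, 0.0, 0.0])
        return self.t_myo + extra

    @property
    def t_rel(self) -> float:
        """Central tension relative to the mean of the four flanks."""
        t = self.totals
        return float(t[0] / (0.5 * (t[1] + t[2])))


@dataclass
class QuartetTrajectory:
    params: ModelParams
    states: list[QuartetState] = field(default_factory=list)
    flip_time: float | None = None
    flip_tension: float | None = None

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    @property
    def t_rel(self) -> np.ndarray:
        return np.array([s.t_rel for s in self.states])

    @property
    def central_length(self) -> np.ndarray:
        return np.array([s.lengths[0] for s in self.states])

    def pre_flip(self) -> list[QuartetState]:
        return [s for s in self.states if s.topology == "pre"]

    def post_flip(self) -> list[QuartetState]:
        return [s for s in self.states if s.topology == "post"]

    def to_frame(self):
        import pandas as pd

        rows = []
        for s in self.states:
            rows.append(
                {
                    "time_min": s.time,
                    "T0": s.t_myo[0],
                    "T1": s.t_myo[1],
                    "T2": s.t_myo[2],
                    "Tp": s.t_passive,
                    "l0": s.lengths[0],
                    "l1": s.lengths[1],
                    "l2": s.lengths[2],
                    "phi0_deg": math.degrees(s.phis[0]),
                    "phi1_deg": math.degrees(s.phis[1]),
                    "phi2_deg": math.degrees(s.phis[2]),
                    "topology": s.topology,
                    "EC": s.energy,
                }
            )
        return pd.DataFrame(rows)


def tension_feedback_step(t: np.ndarray, params: ModelParams) -> np.ndarray:
    """Right-hand side of the tension-feedback law.

    ``tau_T dT_i/dt = T_i^n - (1/3) sum_k T_k^n``; the sum of the rates is
    exactly zero (myosin-pool conservation) and the largest tension grows
    whenever the tensions are unequal.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ForceBalanceError(f"non-positive tension {tuple(t)}")
    p = t ** params.n
    return (p - p.mean()) / params.tau_t


def angles_from_tensions(totals: np.ndarray) -> np.ndarray:
    """Vertex angles from the total tensions.

    ``phi_i`` is the cell-array angle between the two interfaces j, k != i,
    complementary to the tension-triangle angle opposite side i; the three
    angles sum to 2*pi.  Raises :class:`ForceBalanceError` when the
    triangle inequality fails (force balance lost).
    """
    a, b, c = np.asarray(totals, dtype=float)
    s = np.sort([a, b, c])
    if s[0] + s[1] <= s[2]:
        raise ForceBalanceError(
            f"force balance lost: tensions {(a, b, c)} violate the "
            "triangle inequality"
        )
    gam = np.array(
        [
            math.acos(np.clip((b * b + c * c - a * a) / (2 * b * c), -1, 1)),
            math.acos(np.clip((a * a + c * c - b * b) / (2 * a * c), -1, 1)),
            math.acos(np.clip((a * a + b * b - c * c) / (2 * a * b), -1, 1)),
        ]
    )
    return math.pi - gam


def _edge_directions(phis: np.ndarray, theta_c: float) -> np.ndarray:
    """Unit direction of each interface class (central at angle theta_c)."""
    th = np.array(
        [theta_c, theta_c + phis[2], theta_c + phis[2] + phis[0]]
    )
    return np.stack([np.cos(th), np.sin(th)], axis=1)


def relax_lengths(
    phis: np.ndarray,
    params: ModelParams,
    theta_c: float = math.pi / 2,
    s0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Interface lengths minimizing the cell elastic energy at fixed angles.

    The energy is quadratic in the lengths, so the constrained minimizer
    (l_i >= 0) is found by non-negative least squares.  Returns
    ``(lengths, E_C)``.
    """
    s0 = params.s0 if s0 is None else np.asarray(s0, dtype=float)
    dirs = _edge_directions(np.asarray(phis, dtype=float), theta_c)
    # stack Frobenius rows (xx, yy, sqrt(2)*xy) and the trace row
    A = np.zeros((4, 3))
    b = np.zeros(4)
    sm = math.sqrt(params.mu)
    for i in range(3):
        u = dirs[i]
        A[0, i] = sm * u[0] * u[0]
        A[1, i] = sm * u[1] * u[1]
        A[2, i] = sm * math.sqrt(2) * u[0] * u[1]
    b[0] = sm * s0[0, 0]
    b[1] = sm * s0[1, 1]
    b[2] = sm * math.sqrt(2) * s0[0, 1]
    sl = math.sqrt(params.lam)
    A[3, :] = sl
    b[3] = sl * np.trace(s0)
    lengths, rnorm = nnls(A, b)
    return lengths, float(rnorm ** 2)


def handover(t_myo: np.ndarray) -> float:
    """Active tension on the emerging interface after the exchange.

    Each interface's tension is carried half per abutting cortex and the
    myosin concentration is continuous across vertices within each cell, so
    the new interface's two cortices inherit the gaining cells' flank
    cortices: ``T_myo_new = (T_1 + T_2) / 2``.  Always below the total
    post-flip tension fixed by geometry on convex kites.
    """
    return float(0.5 * (t_myo[1] + t_myo[2]))


def _post_flip_total(totals: np.ndarray) -> float:
    """Total tension on the new interface: the other diagonal of the
    tension parallelogram (the periodic quartet's two tension triangles are
    point reflections of each other)."""
    t0, t1, t2 = totals
    d2 = 2 * t1 * t1 + 2 * t2 * t2 - t0 * t0
    if d2 <= 0:
        raise ForceBalanceError("flip undefined: degenerate tension quadrilateral")
    return math.sqrt(d2)


def dl_iso_of_state(state: QuartetState, params: ModelParams) -> float:
    """Isogonal length of the central interface, l - l_ref, from the
    state's tension kite (relative tensions, mean flank tension 1)."""
    t = state.totals
    fm = 0.5 * (t[1] + t[2])
    kite = TensionKite(
        shared=t[0] / fm,
        left=(t[1] / fm, t[2] / fm),
        right=(t[2] / fm, t[1] / fm),
    )
    return float(state.lengths[0] - voronoi_reference_length(kite, l0=params.l0))


def _make_state(
    time: float,
    t_myo: np.ndarray,
    t_passive: float,
    topology: str,
    params: ModelParams,
    s0: np.ndarray | None = None,
) -> QuartetState:
    totals = t_myo + np.array([t_passive, 0.0, 0.0])
    phis = angles_from_tensions(totals)
    theta_c = math.pi / 2 if topology == "pre" else 0.0
    lengths, energy = relax_lengths(phis, params, theta_c=theta_c, s0=s0)
    return QuartetState(time, t_myo.copy(), t_passive, topology, phis,
                        lengths, energy)


def _rk4(t: np.ndarray, dt: float, params: ModelParams) -> np.ndarray:
    k1 = tension_feedback_step(t, params)
    k2 = tension_feedback_step(t + 0.5 * dt * k1, params)
    k3 = tension_feedback_step(t + 0.5 * dt * k2, params)
    k4 = tension_feedback_step(t + dt * k3, params)
    return t + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0


def _hold_s0(params: ModelParams, totals: np.ndarray, dl_iso: float) -> np.ndarray:
    """Target shape holding the central isogonal length at ``dl_iso``.

    The DV component of S0 is adjusted so that the relaxed central length
    equals l_ref(tensions) + dl_iso, emulating a constant external stretch.
    Symmetric closed form: l_central = s_yy - s_xx * tan^2(gamma0 / 2).
    """
    fm = 0.5 * (totals[1] + totals[2])
    kite = TensionKite(
        shared=totals[0] / fm,
        left=(totals[1] / fm, totals[2] / fm),
        right=(totals[2] / fm, totals[1] / fm),
    )
    l_target = voronoi_reference_length(kite, l0=params.l0) + dl_iso
    gam0 = math.pi - angles_from_tensions(totals)[0]
    sxx = params.s0[0, 0]
    syy = l_target + sxx * math.tan(gam0 / 2) ** 2
    return np.array([[sxx, 0.0], [0.0, syy]])


def simulate_active(
    t_init: np.ndarray,
    params: ModelParams,
    t_max: float = 40.0,
    hold_dl_iso: float | None = None,
    dl_iso_rate: float = 0.0,
    record_every: int = 10,
    post_flip_window: float | None = None,
) -> QuartetTrajectory:
    """Integrate an active T1: positive tension feedback drives the
    central interface (class 0, the one with the highest initial tension)
    to collapse; after the exchange the passive tension relaxes while
    feedback continues.

    ``hold_dl_iso`` pins the central isogonal length by adjusting the
    target-shape tensor each step (constant external stretch); with the
    default isotropic target the isogonal length at the flip is zero and
    the collapse occurs at relative tension sqrt(2).  A nonzero
    ``dl_iso_rate`` (um/min) additionally drifts the held isogonal length,
    combining tension feedback with prescribed external deformation (a
    mixed active/passive T1).

    The single-quartet description ends when a *flank* interface reaches
    its own force-balance limit (the next intercalation); the trajectory
    is truncated there.  ``post_flip_window`` stops the run that many
    minutes after the exchange.
    """
    t_myo = np.asarray(t_init, dtype=float).copy()
    if not t_myo[0] >= max(t_myo[1], t_myo[2]):
        raise ValueError("central tension (index 0) must be the largest")
    dt = params.dt
    traj = QuartetTrajectory(params=params)
    time = 0.0
    t_flip = None
    tp0 = 0.0
    step = 0

    def s0_of(totals, tt=0.0):
        if hold_dl_iso is None and dl_iso_rate == 0.0:
            return None
        base = hold_dl_iso if hold_dl_iso is not None else 0.0
        return _hold_s0(params, totals, base + dl_iso_rate * tt)

    state = _make_state(time, t_myo, 0.0, "pre", params, s0_of(t_myo))
    traj.states.append(state)
    prev = state
    while time < t_max:
        if state.topology == "pre":
            t_new = _rk4(t_myo, dt, params)
            time += dt
            cand = _make_state(time, t_new, 0.0, "pre", params,
                               s0_of(t_new, time))
            if cand.lengths[0] <= params.eps_flip:
                # locate the crossing by linear interpolation
                l_a, l_b = prev.lengths[0], cand.lengths[0]
                frac = 1.0 if l_a == l_b else float(
                    np.clip((l_a - params.eps_flip) / (l_a - l_b), 0.0, 1.0)
                )
                t_flip = prev.time + frac * dt
                t_myo = prev.t_myo + frac * (t_new - prev.t_myo)
                totals = t_myo.copy()
                traj.flip_tension = float(
                    totals[0] / (0.5 * (totals[1] + totals[2]))
                )
                total_new = _post_flip_total(totals)
                myo_new = handover(t_myo)
                tp0 = total_new - myo_new
                # the prescribed stretch acts on the collapsing geometry;
                # after the exchange the target shape is frozen
                s0_frozen = s0_of(totals, t_flip)
                t_myo = np.array([myo_new, t_myo[1], t_myo[2]])
                time = t_flip
                state = _make_state(time, t_myo, tp0, "post", params,
                                    s0_frozen)
                traj.flip_time = t_flip
                traj.states.append(state)
                prev = state
                step += 1
                continue
            t_myo = t_new
            state = cand
        else:
            if (post_flip_window is not None
                    and time - t_flip >= post_flip_window):
                break
            t_myo = _rk4(t_myo, dt, params)
            time += dt
            tp = tp0 * math.exp(-(time - t_flip) / params.tau_p)
            try:
                state = _make_state(time, t_myo, tp, "post", params,
                                    s0_frozen)
            except ForceBalanceError:
                break  # a flank reached its own threshold; model domain ends
        step += 1
        if step % record_every == 0 or state.topology != prev.topology:
            traj.states.append(state)
        prev = state
    if traj.states[-1] is not state:
        traj.states.append(state)
    return traj


def simulate_passive(
    params: ModelParams,
    rate: float | None = None,
    t_max: float = 30.0,
    record_every: int = 10,
) -> QuartetTrajectory:
    """Integrate a passive T1: tension feedback disabled, tensions held at
    1, and the collapse driven by a prescribed contraction of the target
    shape (mimicking centroid displacement by external stress).

    ``rate`` is the contraction rate of the DV target-shape component in
    um/min; the default collapses the central interface in ~15 min.
    Driving stops at the flip; the new interface then extends as the
    passive tension decays.
    """
    if rate is None:
        rate = params.l_rest / 15.0
    t_myo = np.ones(3)
    dt = params.dt
    traj = QuartetTrajectory(params=params)
    time = 0.0
    t_flip = None
    tp0 = 0.0
    s0_flip = None
    step = 0

    def s0_pre(tt):
        s = params.s0.copy()
        s[1, 1] = s[1, 1] - rate * tt
        return s

    state = _make_state(0.0, t_myo, 0.0, "pre", params, s0_pre(0.0))
    traj.states.append(state)
    prev = state
    while time < t_max:
        time += dt
        if t_flip is None:
            cand = _make_state(time, t_myo, 0.0, "pre", params, s0_pre(time))
            if cand.lengths[0] <= params.eps_flip:
                l_a, l_b = prev.lengths[0], cand.lengths[0]
                frac = 1.0 if l_a == l_b else float(
                    np.clip((l_a - params.eps_flip) / (l_a - l_b), 0.0, 1.0)
                )
                t_flip = prev.time + frac * dt
                time = t_flip
                traj.flip_tension = 1.0
                total_new = _post_flip_total(t_myo)  # sqrt(3) for symmetric
                myo_new = handover(t_myo)
                tp0 = total_new - myo_new
                t_myo = np.array([myo_new, t_myo[1], t_myo[2]])
                s0_flip = s0_pre(t_flip)
                state = _make_state(time, t_myo, tp0, "post", params, s0_flip)
                traj.flip_time = t_flip
                traj.states.append(state)
                prev = state
                step += 1
                continue
            state = cand
        else:
            tp = tp0 * math.exp(-(time - t_flip) / params.tau_p)
            state = _make_state(time, t_myo, tp, "post", params, s0_flip)
        step += 1
        if step % record_every == 0 or state.topology != prev.topology:
            traj.states.append(state)
        prev = state
    if traj.states[-1] is not state:
        traj.states.append(state)
    return traj


def ensemble(
    mode: str,
    n_runs: int,
    seed: int,
    params: ModelParams | None = None,
    angle_sigma_deg: float = 5.0,
    t_max: float = 40.0,
) -> list[QuartetTrajectory]:
    """Seed-reproducible ensemble of quartet simulations.

    Initial vertex angles are drawn as Gaussian jitter (sigma
    ``angle_sigma_deg``) about the symmetric 120-degree configuration and
    converted to initial tensions; the interface with the highest tension
    is labelled central.  Passive runs jitter the driving rate by the same
    relative amount instead (tensions stay homeostatic at 1).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    params = params or ModelParams()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_runs):
        if mode == "active":
            ang = np.radians(120.0 + angle_sigma_deg * rng.standard_normal(3))
            ang *= 2 * math.pi / ang.sum()
            t = np.sin(np.roll(ang, -1))
            t = t / t.mean()
            order = np.argsort(t)[::-1]
            t = t[[order[0], order[1], order[2]]]
            out.append(simulate_active(t, params, t_max=t_max))
        elif mode == "passive":
            rate = (params.l_rest / 15.0) * (
                1.0 + (angle_sigma_deg / 120.0) * rng.standard_normal()
            )
            out.append(simulate_passive(params, rate=max(rate, 1e-3),
                                        t_max=t_max))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out
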