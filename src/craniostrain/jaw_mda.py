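"""Rigid-mandible bite-cycle simulation with optimized muscle activations.

The mandible is a rigid body suspended from the cranium at the two
temporomandibular joints (TMJs).  Its motion during a bite cycle is
prescribed by two generalized coordinates:

* ``theta`` — gape, rotation in the mid-sagittal plane about the
  mediolateral axis through both TMJs (degrees, 0 = closed);
* ``phi`` — frontal-plane excursion toward the working side, rotation about
  the anteroposterior axis through the working-side TMJ (degrees).

Muscle strands run from fixed cranial origins (optionally through fixed via
points representing wrapping) to insertions that move with the mandible.
At every time step, the activations that make the strand forces balance the
external resistances along the mobile directions are found by a convex
quadratic program in the spirit of Dynamic Geometric Optimization: minimise
``sum_i (a_i / w_i)^2`` subject to the generalized force balance and
``0 <= a_i <= 1``, where ``w_i`` is an EMG-derived coordination weight.
Instantaneous strand orientations enter the balance, so working- and
balancing-side muscles are coordinated through the weights exactly at the
moments the motion needs them.

A bite cycle has three phases: opening (to maximum gape), fast closing
(jaw swings toward the working side for molar bites), and slow closing
(the food bolus is compressed; vertical resistance ramps up to its full
value and a constant mediolateral resistance opposes the return to the
midline).  The finite-element snapshot of each bite is taken at the instant
of maximum bite force.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from craniostrain.phantom_geometry import PhantomParams, phantom_layout

__all__ = [
    "PassiveParams",
    "MuscleStrand",
    "JawModel",
    "BiteCycleSpec",
    "BiteTrajectory",
    "LoadRegime",
    "InsufficientMuscleCapacityError",
    "make_jaw_model",
    "strand_kinematics",
    "passive_tension",
    "inverse_required_load",
    "dgo_solve",
    "solve_activation_qp",
    "simulate_bite_cycle",
    "extract_load_regime",
    "reflect_load_regime",
    "enumerate_bite_regimes",
    "default_emg_profiles",
]

_MIRROR = np.array([-1.0, 1.0, 1.0])


class InsufficientMuscleCapacityError(RuntimeError):
    """The required generalized load is unreachable with activations in [0, 1]."""


# ---------------------------------------------------------------------------
# muscle strands


@dataclass
class PassiveParams:
    """Passive-tension law: a normalized exponential in strand strain.

    ``T(s) = p_cap * F_max * (exp(k*s) - 1) / (exp(k*s_max) - 1)`` for
    strain ``s = (L - L0)/L0`` in ``[0, s_max]``, clipped at the cap beyond
    ``s_max``; zero at or below the slack length.  The cap fraction
    ``p_cap = 0.001`` makes the maximum passive force 0.1 % of the maximum
    isometric force.
    """

    p_cap: float = 0.001
    k: float = 3.0
    s_max: float = 0.05


@dataclass
class MuscleStrand:
    """One muscle strand: a straight or via-point polyline force element."""

    id: str
    group: str
    side: str                      #: anatomical side, "left" | "right"
    origin: np.ndarray             #: cranial attachment (mm, cranium frame)
    insertion: np.ndarray          #: mandibular attachment at closed pose (mm)
    via_points: list = field(default_factory=list)  #: fixed wrapping points
    f_max: float = 1.0             #: maximum isometric force (N)
    passive: PassiveParams = field(default_factory=PassiveParams)
    slack_length: float | None = None  #: L0; default: length at closed pose

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.insertion = np.asarray(self.insertion, float)
        self.via_points = [np.asarray(v, float) for v in self.via_points]
        if self.f_max <= 0:
            raise ValueError(f"strand {self.id}: f_max must be positive")

    def path_points(self, posed_insertion: np.ndarray) -> np.ndarray:
        return np.vstack([self.origin, *self.via_points, posed_insertion])


def strand_kinematics(strand: MuscleStrand, pose=None):
    """Length and unit lines of action of a strand under a mandible pose.

    ``pose`` maps mandible-frame points to the cranium frame (None =
    identity/closed).  Returns ``(length, u_origin, u_insertion)`` where
    ``u_origin`` points from the origin along the strand (direction of pull
    on the cranium) and ``u_insertion`` points from the insertion back along
    the strand (direction of pull on the mandible).
    """
    ins = strand.insertion if pose is None else pose(strand.insertion)
    pts = strand.path_points(ins)
    segs = np.diff(pts, axis=0)
    seglen = np.linalg.norm(segs, axis=1)
    if np.any(seglen < 1e-9):
        raise ValueError(f"strand {strand.id}: coincident consecutive path points")
    length = float(seglen.sum())
    u_origin = segs[0] / seglen[0]
    u_insertion = -segs[-1] / seglen[-1]
    return length, u_origin, u_insertion


def passive_tension(strand: MuscleStrand, length: float) -> float:
    """Passive force (N) of a strand at the given length (mm)."""
    L0 = strand.slack_length
    if L0 is None:
        raise ValueError(f"strand {strand.id}: slack length not set")
    p = strand.passive
    s = max(0.0, (length - L0) / L0)
    if s <= 0.0:
        return 0.0
    s = min(s, p.s_max)
    return p.p_cap * strand.f_max * np.expm1(p.k * s) / np.expm1(p.k * p.s_max)


# ---------------------------------------------------------------------------
# jaw model


@dataclass
class JawModel:
    """Rigid mandible, TMJ pivots and the full bilateral strand set."""

    strands: list
    tmj_left: np.ndarray
    tmj_right: np.ndarray
    bite_points: dict            #: tooth id -> contact point at closed pose (mm)
    mass: float = 0.010          #: mandible mass (kg)
    inertia: np.ndarray = field(default_factory=lambda: np.diag([3.0, 3.0, 3.0]))
    #: kg mm^2 about the centre of mass
    com: np.ndarray = field(default_factory=lambda: np.array([0.0, 15.0, -8.0]))

    def __post_init__(self) -> None:
        self.tmj_left = np.asarray(self.tmj_left, float)
        self.tmj_right = np.asarray(self.tmj_right, float)
        self.bite_points = {k: np.asarray(v, float) for k, v in self.bite_points.items()}

    @property
    def tmj_mid(self) -> np.ndarray:
        return 0.5 * (self.tmj_left + self.tmj_right)

    def tmj(self, side: str) -> np.ndarray:
        return self.tmj_right if side == "right" else self.tmj_left

    def strand_index(self) -> dict:
        return {s.id: i for i, s in enumerate(self.strands)}


#: default per-strand maximum isometric force by muscle group (N).
#: Synthetic values sized so group totals follow the usual masticatory
#: hierarchy (masseter > temporalis/pterygoids in a gnawing herbivore).
DEFAULT_F_MAX = {
    "masseter": 6.0,
    "zygomaticomandibularis": 3.0,
    "temporalis": 2.5,
    "pterygoid_medial": 5.0,
    "pterygoid_lateral": 2.0,
}


def make_jaw_model(params: PhantomParams | None = None,
                   f_max: dict | None = None) -> JawModel:
    """Build the jaw model matched to the cranium phantom's landmark layout.

    Right-side strands come first, mirrored left-side strands follow in the
    same order, so the mirror partner of strand ``i`` is ``i + n/2``.
    """
    lay = phantom_layout(params or PhantomParams())
    f_max = {**DEFAULT_F_MAX, **(f_max or {})}
    strands: list[MuscleStrand] = []
    for sid, grp, origin, vias, ins in lay["strands"]:
        strands.append(MuscleStrand(id=sid, group=grp, side="right", origin=origin,
                                    insertion=ins, via_points=list(vias),
                                    f_max=f_max[grp]))
    for sid, grp, origin, vias, ins in lay["strands"]:
        strands.append(MuscleStrand(id=sid.replace("_R_", "_L_"), group=grp, side="left",
                                    origin=origin * _MIRROR, insertion=ins * _MIRROR,
                                    via_points=[v * _MIRROR for v in vias],
                                    f_max=f_max[grp]))
    bite_points = {tid: tip.copy() for tid, tip in lay["tooth_tips"].items()}
    bite_points.update({f"{tid[:-2]}_L": tip * _MIRROR for tid, tip in lay["tooth_tips"].items()})
    model = JawModel(strands=strands, tmj_left=lay["tmj_left"], tmj_right=lay["tmj_right"],
                     bite_points=bite_points)
    for s in model.strands:
        s.slack_length = strand_kinematics(s)[0]
    return model


# ---------------------------------------------------------------------------
# pose and bite-cycle kinematics


def mandible_pose(model: JawModel, theta_deg: float, phi_deg: float, working_side: str):
    """Map mandible-frame points to the cranium frame for a pose.

    Gape rotates by ``-theta`` about +x through the TMJ line (anterior points
    move ventrally); excursion rotates about +y through the working TMJ with
    the sign that moves ventral points toward the working side.
    """
    th = np.radians(theta_deg)
    ph = np.radians(phi_deg)
    s_exc = -1.0 if working_side == "right" else 1.0
    ct, st = np.cos(-th), np.sin(-th)
    Rg = np.array([[1, 0, 0], [0, ct, -st], [0, st, ct]])
    a = s_exc * ph
    ca, sa = np.cos(a), np.sin(a)
    Re = np.array([[ca, 0, sa], [0, 1, 0], [-sa, 0, ca]])
    pg = model.tmj_mid
    pe = model.tmj(working_side)

    def pose(p):
        p = np.asarray(p, float)
        q = Rg @ (p - pg) + pg
        return Re @ (q - pe) + pe

    return pose


@dataclass
class BiteCycleSpec:
    """Kinematic and resistance parameters of one simulated bite cycle."""

    mode: str                    #: "incisor" | "molar"
    bite_tooth: str              #: tooth id, e.g. "cheek3_R" or "incisor_R"
    working_side: str = "right"
    max_gape_deg: float = 12.0   #: mid-sagittal gape reached in opening
    excursion_deg: float = 5.5   #: working-side frontal excursion (molar)
    contact_gape_deg: float = 2.0  #: gape at first food contact
    bolus_vertical_N: float = 30.0   #: resistance when fully compressed
    bolus_mediolateral_N: float = 30.0  #: resistance to the return to midline
    t_open: float = 0.085        #: phase durations (s)
    t_fast: float = 0.065
    t_slow: float = 0.100
    dt: float = 0.005
    gravity: bool = False
    dynamic: bool = False        #: include mandible inertia terms

    def __post_init__(self) -> None:
        if self.mode not in ("incisor", "molar"):
            raise ValueError(f"unknown bite mode {self.mode!r}")
        if min(self.t_open, self.t_fast, self.t_slow) <= 0:
            raise ValueError("phase durations must be strictly positive")
        if self.mode == "incisor":
            # incisor biting: symmetrical rotation about the midline
            self.excursion_deg = 0.0
            self.bolus_mediolateral_N = 0.0
        elif self.excursion_deg <= 0:
            raise ValueError("molar bites need a positive working-side excursion")
        if not 0 < self.contact_gape_deg < self.max_gape_deg:
            raise ValueError("contact gape must lie strictly inside (0, max gape)")

    @property
    def duration(self) -> float:
        return self.t_open + self.t_fast + self.t_slow

    def phase(self, t: float) -> str:
        if t < self.t_open:
            return "open"
        if t < self.t_open + self.t_fast:
            return "fast"
        return "slow"

    def prescribed_pose(self, t: float) -> tuple[float, float, float]:
        """(theta_deg, phi_deg, bolus compression fraction) at time t."""
        g, e, gc = self.max_gape_deg, self.excursion_deg, self.contact_gape_deg
        if t <= 0:
            return 0.0, 0.0, 0.0
        if t < self.t_open:
            tau = t / self.t_open
            return g * 0.5 * (1 - np.cos(np.pi * tau)), 0.0, 0.0
        if t < self.t_open + self.t_fast:
            tau = (t - self.t_open) / self.t_fast
            th = g - (g - gc) * 0.5 * (1 - np.cos(np.pi * tau))
            return th, e * 0.5 * (1 - np.cos(np.pi * tau)), 0.0
        tau = min(1.0, (t - self.t_open - self.t_fast) / self.t_slow)
        return gc * (1 - tau), e * 0.5 * (1 + np.cos(np.pi * tau)), tau


def default_emg_profiles() -> dict:
    """Per-group EMG coordination weights by (mode, role, phase).

    Synthetic trapezoid-style profiles standing in for in vivo chewing
    recordings: jaw closers dominate the closing phases with the usual
    working/balancing asymmetry during molar chewing; the working-side
    medial pterygoid drives the return to the midline; everything keeps a
    small floor weight so the optimizer stays well-conditioned.
    """
    floor = 0.05
    prof = {}
    for grp in ("masseter", "zygomaticomandibularis", "temporalis"):
        prof[grp] = {
            ("molar", "working"): {"open": floor, "fast": 0.4, "slow": 1.0},
            ("molar", "balancing"): {"open": floor, "fast": 0.4, "slow": 0.6},
            ("incisor", "working"): {"open": floor, "fast": 0.4, "slow": 1.0},
            ("incisor", "balancing"): {"open": floor, "fast": 0.4, "slow": 1.0},
        }
    prof["pterygoid_medial"] = {
        ("molar", "working"): {"open": floor, "fast": 0.3, "slow": 1.0},
        ("molar", "balancing"): {"open": floor, "fast": 0.3, "slow": 0.4},
        ("incisor", "working"): {"open": floor, "fast": 0.3, "slow": 0.8},
        ("incisor", "balancing"): {"open": floor, "fast": 0.3, "slow": 0.8},
    }
    prof["pterygoid_lateral"] = {
        (m, r): {"open": 0.3, "fast": 0.2, "slow": 0.2}
        for m in ("molar", "incisor") for r in ("working", "balancing")
    }
    return prof


def emg_weight(profiles: dict, group: str, role: str, mode: str, phase: str,
               floor: float = 0.05) -> float:
    return max(floor, profiles[group][(mode, role)][phase])


# ---------------------------------------------------------------------------
# required load and activation QP


def _wrench_about(point_forces, ref):
    """Total (force, moment) of (point, force) pairs about ``ref``."""
    F = np.zeros(3)
    M = np.zeros(3)
    for p, f in point_forces:
        F += f
        M += np.cross(np.asarray(p, float) - ref, f)
    return np.concatenate([F, M])


def _external_loads(model: JawModel, spec: BiteCycleSpec, t: float):
    """External (point, force) pairs acting on the mandible at time t.

    The vertical bolus resistance ramps linearly with compression up to its
    full value; the mediolateral resistance opposes the return to the
    midline and is transmitted in proportion to the vertical engagement of
    the bolus (an unengaged bolus cannot shear sideways), vanishing once
    the jaw is back at the midline.
    """
    th, ph, c = spec.prescribed_pose(t)
    pose = mandible_pose(model, th, ph, spec.working_side)
    bite_pt = pose(model.bite_points[spec.bite_tooth])
    loads = []
    if c > 0:
        loads.append((bite_pt, np.array([0.0, 0.0, -spec.bolus_vertical_N * c])))
        if spec.mode == "molar" and ph > 1e-9 and spec.phase(t) == "slow":
            s_work = 1.0 if spec.working_side == "right" else -1.0
            loads.append((bite_pt,
                          np.array([s_work * spec.bolus_mediolateral_N * c, 0.0, 0.0])))
    if spec.gravity:
        loads.append((pose(model.com), np.array([0.0, 0.0, -9.81 * model.mass])))
    return loads, pose


def _inertia_wrench(model: JawModel, spec: BiteCycleSpec, t: float, ref) -> np.ndarray:
    """(force, moment) the muscles must add to sustain the accelerations.

    Central finite differences of the rigid pose give the centre-of-mass
    acceleration and angular acceleration; gyroscopic terms are negligible
    at chewing rates and omitted.
    """
    h = 1e-4

    def com_at(tt):
        th, ph, _ = spec.prescribed_pose(tt)
        return mandible_pose(model, th, ph, spec.working_side)(model.com)

    def angles(tt):
        th, ph, _ = spec.prescribed_pose(tt)
        s_exc = -1.0 if spec.working_side == "right" else 1.0
        return np.array([-np.radians(th), s_exc * np.radians(ph)])

    a_com = (com_at(t + h) - 2 * com_at(t) + com_at(t - h)) / h**2  # mm/s^2
    ang = (angles(t + h) - 2 * angles(t) + angles(t - h)) / h**2    # rad/s^2
    alpha = ang[0] * np.array([1.0, 0, 0]) + ang[1] * np.array([0, 1.0, 0])
    F = model.mass * a_com * 1e-3                      # N
    M = (model.inertia @ alpha) * 1e-3                 # N mm
    M = M + np.cross(com_at(t) - ref, F)
    return np.concatenate([F, M])


def inverse_required_load(model: JawModel, spec: BiteCycleSpec, t: float) -> np.ndarray:
    """Net 6-vector (force N, moment N·mm about the TMJ midpoint) the muscles
    must supply at time ``t``, given bolus resistances, optional gravity and
    (in dynamic mode) mandible inertia."""
    ref = model.tmj_mid
    loads, _pose = _external_loads(model, spec, t)
    W_ext = _wrench_about(loads, ref)
    W = -W_ext
    if spec.dynamic:
        W = W + _inertia_wrench(model, spec, t, ref)
    return W


def _mode_screws(model: JawModel, spec: BiteCycleSpec):
    """Mobility directions: (axis direction, point on axis) per coordinate."""
    s_exc = -1.0 if spec.working_side == "right" else 1.0
    screws = [(np.array([-1.0, 0, 0]), model.tmj_mid)]  # increasing gape
    if spec.mode == "molar":
        screws.append((s_exc * np.array([0, 1.0, 0]), model.tmj(spec.working_side)))
    return screws


def _generalized(wrench: np.ndarray, ref, screws) -> np.ndarray:
    """Project a (force, moment-about-ref) wrench onto rotation screws."""
    F, M = wrench[:3], wrench[3:]
    out = np.empty(len(screws))
    for j, (d, pa) in enumerate(screws):
        out[j] = (M + np.cross(ref - pa, F)) @ d
    return out


def solve_activation_qp(A: np.ndarray, b: np.ndarray, w: np.ndarray,
                        tol: float = 1e-8, max_iter: int = 200):
    """Minimise ``sum (a_i/w_i)^2`` s.t. ``A a = b``, ``0 <= a <= 1``.

    Active-set solver exploiting the diagonal Hessian: on the free set the
    minimiser is ``a = W A' (A W A')^{-1} b`` with ``W = diag(w^2)``.  Bound
    violations are clamped one at a time; KKT multipliers of clamped
    variables are checked before termination.  Raises
    :class:`InsufficientMuscleCapacityError` when the equality constraint
    cannot be met within the bounds.
    """
    from scipy.optimize import lsq_linear

    A = np.atleast_2d(np.asarray(A, float))
    b = np.atleast_1d(np.asarray(b, float))
    w = np.asarray(w, float)
    m, n = A.shape
    scale = max(1.0, np.abs(A).max() * 1.0, np.abs(b).max())

    # feasibility: is b reachable at all with activations in [0, 1]?
    if np.abs(b).max() > 0:
        feas = lsq_linear(A, b, bounds=(0.0, 1.0), tol=1e-12)
        gap = A @ feas.x - b
        if np.abs(gap).max() > 1e-6 * scale:
            j = int(np.argmax(np.abs(gap)))
            raise InsufficientMuscleCapacityError(
                f"insufficient muscle capacity: generalized component {j} "
                f"short by {gap[j]:.4g} (required {b[j]:.4g})")

    a = np.zeros(n)
    state = np.zeros(n, dtype=int)  # 0 free, -1 at lower, +1 at upper

    for _ in range(max_iter):
        free = state == 0
        a_fix = np.where(state > 0, 1.0, 0.0)
        b_eff = b - A[:, ~free] @ a_fix[~free]
        if free.any():
            Wf = w[free] ** 2
            Af = A[:, free]
            G = (Af * Wf) @ Af.T
            try:
                lam = np.linalg.solve(G, b_eff)
            except np.linalg.LinAlgError:
                lam, *_ = np.linalg.lstsq(G, b_eff, rcond=None)
            a_free = Wf * (Af.T @ lam)
        else:
            lam = np.linalg.lstsq((A * (w**2)) @ A.T, b_eff, rcond=None)[0]
            a_free = np.empty(0)
        a = a_fix.copy()
        a[free] = a_free

        # clamp the worst bound violation, if any
        viol_lo = np.where(free & (a < -1e-12), -a, 0.0)
        viol_hi = np.where(free & (a > 1 + 1e-12), a - 1, 0.0)
        if viol_lo.max(initial=0.0) > 0 or viol_hi.max(initial=0.0) > 0:
            if viol_lo.max(initial=0.0) >= viol_hi.max(initial=0.0):
                state[int(np.argmax(viol_lo))] = -1
            else:
                state[int(np.argmax(viol_hi))] = +1
            continue

        # KKT: release the clamped variable with the most negative multiplier
        grad = 2 * a / w**2 - A.T @ lam
        release, worst = None, -1e-9
        for i in np.nonzero(state != 0)[0]:
            mu = grad[i] if state[i] == -1 else -grad[i]
            if mu < worst:
                release, worst = int(i), mu
        if release is not None:
            state[release] = 0
            continue
        break

    resid = A @ a - b
    if np.abs(resid).max() > 1e-6 * scale:
        raise RuntimeError("activation QP did not converge (feasible problem); "
                           f"residual {np.abs(resid).max():.3g}")
    return np.clip(a, 0.0, 1.0)


def dgo_solve(model: JawModel, spec: BiteCycleSpec, t: float,
              weights: np.ndarray | None = None,
              profiles: dict | None = None,
              include_passive: bool = False) -> np.ndarray:
    """Activations of all strands at time ``t`` for the prescribed motion.

    Builds the generalized force-balance rows from the instantaneous strand
    lines of action and solves the weighted activation QP.  By default the
    (tiny, 0.1 %-capped) passive tensions do not enter the activation
    balance — the model has no jaw-opener strands, so compensating the
    passive closing moment during the opening phase would be infeasible;
    passive tension is still added to every transmitted strand force.  Set
    ``include_passive=True`` to subtract passive contributions from the
    required load instead.
    """
    th, ph, _c = spec.prescribed_pose(t)
    pose = mandible_pose(model, th, ph, spec.working_side)
    screws = _mode_screws(model, spec)
    ref = model.tmj_mid
    required = inverse_required_load(model, spec, t)
    b = _generalized(required, ref, screws)

    n = len(model.strands)
    A = np.zeros((len(screws), n))
    passive_Q = np.zeros(len(screws))
    if weights is None:
        profiles = profiles or default_emg_profiles()
        phase = spec.phase(t)
        weights = np.empty(n)
        for i, s in enumerate(model.strands):
            role = "working" if s.side == spec.working_side else "balancing"
            weights[i] = emg_weight(profiles, s.group, role, spec.mode, phase)
    for i, s in enumerate(model.strands):
        length, _uo, ui = strand_kinematics(s, pose)
        ins = pose(s.insertion)
        unit_wrench = np.concatenate([ui, np.cross(ins - ref, ui)])
        q = _generalized(unit_wrench, ref, screws)
        A[:, i] = s.f_max * q
        passive_Q += passive_tension(s, length) * q
    if include_passive:
        b = b - passive_Q
    return solve_activation_qp(A, b, weights)


# ---------------------------------------------------------------------------
# bite-cycle simulation


@dataclass
class BiteTrajectory:
    """Time series of one simulated bite cycle."""

    model: JawModel
    spec: BiteCycleSpec
    t: np.ndarray
    theta_deg: np.ndarray
    phi_deg: np.ndarray
    activations: np.ndarray      #: (nt, n_strands)
    strand_forces: np.ndarray    #: (nt, n_strands) total force a*F_max + T_p
    bite_force: np.ndarray       #: (nt,) food-reaction magnitude (N)
    tmj_left: np.ndarray         #: (nt, 3) reaction on the mandible (N)
    tmj_right: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.t, "theta_deg": self.theta_deg, "phi_deg": self.phi_deg,
            "bite_force": self.bite_force,
        })


def _tmj_reactions(model: JawModel, residual_wrench: np.ndarray, ref):
    """Distribute the residual wrench over point forces at the two TMJs.

    Six unknowns against six equations of rank five (no moment about the
    TMJ axis is producible); the least-squares solution is the minimum-norm
    distribution and is exact because the activation QP has already closed
    the gape component.
    """
    rL = model.tmj_left - ref
    rR = model.tmj_right - ref
    A = np.zeros((6, 6))
    A[:3, :3] = np.eye(3)
    A[:3, 3:] = np.eye(3)

    def skew(r):
        return np.array([[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0]])

    A[3:, :3] = skew(rL)
    A[3:, 3:] = skew(rR)
    sol, *_ = np.linalg.lstsq(A, -residual_wrench, rcond=None)
    return sol[:3], sol[3:]


def simulate_bite_cycle(model: JawModel, spec: BiteCycleSpec,
                        profiles: dict | None = None) -> BiteTrajectory:
    """Run one bite cycle; raises if any instant is infeasible."""
    profiles = profiles or default_emg_profiles()
    nt = int(round(spec.duration / spec.dt)) + 1
    ts = np.linspace(0.0, spec.duration, nt)
    n = len(model.strands)
    th = np.empty(nt)
    ph = np.empty(nt)
    act = np.empty((nt, n))
    sf = np.empty((nt, n))
    bf = np.empty(nt)
    tl = np.empty((nt, 3))
    tr = np.empty((nt, 3))
    ref = model.tmj_mid
    for k, t in enumerate(ts):
        th[k], ph[k], c = spec.prescribed_pose(t)
        a = dgo_solve(model, spec, t, profiles=profiles)
        act[k] = a
        pose = mandible_pose(model, th[k], ph[k], spec.working_side)
        point_forces = []
        for i, s in enumerate(model.strands):
            length, _uo, ui = strand_kinematics(s, pose)
            sf[k, i] = a[i] * s.f_max + passive_tension(s, length)
            point_forces.append((pose(s.insertion), sf[k, i] * ui))
        _th, _ph, c = spec.prescribed_pose(t)
        ext, _ = _external_loads(model, spec, t)
        bf[k] = spec.bolus_vertical_N * c  # occlusal (normal) bite force
        W = _wrench_about(point_forces + ext, ref)
        if spec.dynamic:
            W = W - _inertia_wrench(model, spec, t, ref)
        tl[k], tr[k] = _tmj_reactions(model, W, ref)
    return BiteTrajectory(model=model, spec=spec, t=ts, theta_deg=th, phi_deg=ph,
                          activations=act, strand_forces=sf, bite_force=bf,
                          tmj_left=tl, tmj_right=tr)


# ---------------------------------------------------------------------------
# load regimes


@dataclass
class LoadRegime:
    """One bite's finite-element input, snapshotted at maximum bite force."""

    regime_id: str
    mode: str
    working_side: str
    bite_tooth: str
    strand_forces: dict          #: strand id -> 3-vector at the origin (N)
    wrapping_paths: dict         #: strand id -> (k, 3) on-cranium polyline
    bite_force: float
    bite_point: np.ndarray
    tmj_reactions: dict          #: side -> reaction on the mandible (N)

    def total_muscle_force(self) -> np.ndarray:
        return np.sum(list(self.strand_forces.values()), axis=0)


def extract_load_regime(traj: BiteTrajectory, regime_id: str | None = None) -> LoadRegime:
    """Snapshot the trajectory at the instant of maximum bite force.

    Ties resolve to the earliest time step.  Strand force vectors act at the
    cranial origins along the instantaneous first path segment; strands with
    via points contribute their on-cranium polyline for link elements.
    """
    spec = traj.spec
    model = traj.model
    k = int(np.argmax(traj.bite_force))
    pose = mandible_pose(model, traj.theta_deg[k], traj.phi_deg[k], spec.working_side)
    forces = {}
    paths = {}
    for i, s in enumerate(model.strands):
        _L, uo, _ui = strand_kinematics(s, pose)
        forces[s.id] = traj.strand_forces[k, i] * uo
        if s.via_points:
            paths[s.id] = np.vstack([s.origin, *s.via_points])
    rid = regime_id or f"{spec.mode}_{spec.bite_tooth}"
    return LoadRegime(
        regime_id=rid, mode=spec.mode, working_side=spec.working_side,
        bite_tooth=spec.bite_tooth, strand_forces=forces, wrapping_paths=paths,
        bite_force=float(traj.bite_force[k]),
        bite_point=pose(model.bite_points[spec.bite_tooth]),
        tmj_reactions={"left": traj.tmj_left[k].copy(), "right": traj.tmj_right[k].copy()},
    )


def _mirror_id(sid: str) -> str:
    if "_R" in sid:
        return sid.replace("_R_", "_L_") if "_R_" in sid else sid.replace("_R", "_L")
    return sid.replace("_L_", "_R_") if "_L_" in sid else sid.replace("_L", "_R")


def reflect_load_regime(regime: LoadRegime) -> LoadRegime:
    """Mirror a regime across the mid-sagittal plane (an involution)."""
    return LoadRegime(
        regime_id=_mirror_id(regime.regime_id),
        mode=regime.mode,
        working_side="left" if regime.working_side == "right" else "right",
        bite_tooth=_mirror_id(regime.bite_tooth),
        strand_forces={_mirror_id(k): v * _MIRROR for k, v in regime.strand_forces.items()},
        wrapping_paths={_mirror_id(k): p * _MIRROR for k, p in regime.wrapping_paths.items()},
        bite_force=regime.bite_force,
        bite_point=regime.bite_point * _MIRROR,
        tmj_reactions={("left" if side == "right" else "right"): v * _MIRROR
                       for side, v in regime.tmj_reactions.items()},
    )


def enumerate_bite_regimes(model: JawModel, spec_defaults: BiteCycleSpec | None = None,
                           profiles: dict | None = None) -> list[LoadRegime]:
    """All bite loading regimes: one right-side simulation per bite point
    (incisor plus every cheek tooth), each reflected to the left side.

    With the default tooth row (1 incisor + 5 cheek teeth per side) this
    yields 12 regimes.
    """
    right_teeth = sorted(t for t in model.bite_points if t.endswith("_R"))
    cheek = [t for t in right_teeth if t.startswith("cheek")]
    out = []
    for tooth in ["incisor_R"] + cheek:
        mode = "incisor" if tooth.startswith("incisor") else "molar"
        base = spec_defaults or BiteCycleSpec(mode=mode, bite_tooth=tooth)
        spec = replace(base, mode=mode, bite_tooth=tooth, working_side="right")
        traj = simulate_bite_cycle(model, spec, profiles=profiles)
        reg = extract_load_regime(traj)
        out.append(reg)
        out.append(reflect_load_regime(reg))
    return out
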