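"""Planar rigid-body plant for perturbed standing balance.

The skeleton is a sagittal-plane kinematic tree: a fused pelvis+torso (HAT)
segment carried by three floating-base coordinates (AP translation, vertical
translation, forward tilt), and bilateral thigh/shank/foot chains through
revolute hip, knee and ankle joints — 9 body degrees of freedom.  The model
stands on a platform that slides in the anterior-posterior direction; the
platform coordinate is kinematically prescribed and is therefore not a
dynamic degree of freedom.

Angle conventions are physiological: hip and knee flexion positive, ankle
dorsiflexion positive, forward pelvis tilt positive.  Radians internally,
degrees at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .contact import ContactParams, ContactSphere
from .muscle import MuscleSpec, UNIQUE_MUSCLES

GRAVITY_DEFAULT = 9.80665

#: generalized-coordinate order; the platform slider comes first and is
#: kinematically prescribed, the remaining nine are the body DOFs.
COORD_NAMES = (
    "platform_x",
    "pelvis_tx", "pelvis_ty", "pelvis_tilt",
    "hip_r", "knee_r", "ankle_r",
    "hip_l", "knee_l", "ankle_l",
)
BODY_COORDS = COORD_NAMES[1:]
JOINT_COORDS = ("hip_r", "knee_r", "ankle_r", "hip_l", "knee_l", "ankle_l")


@dataclass(frozen=True)
class SegmentSpec:
    """Rigid segment: mass, COM offset along the segment axis, inertia."""

    name: str
    mass: float               # kg
    com_offset: float         # m from the proximal joint along the axis
    moment_of_inertia: float  # kg m^2 about the segment COM, out-of-plane
    length: float             # m

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"segment {self.name}: mass must be >= 0")
        if not (0.0 <= self.com_offset <= self.length + 1e-12):
            raise ValueError(f"segment {self.name}: com_offset outside [0, length]")
        if self.moment_of_inertia < 0:
            raise ValueError(f"segment {self.name}: negative inertia")


@dataclass(frozen=True)
class JointSpec:
    name: str
    kind: str                 # "revolute" | "slider"
    parent: str
    child: str
    sign_convention: float = 1.0  # +1 if flexion-positive equals CCW rotation


@dataclass(frozen=True)
class Posture:
    """Symmetric bilateral posture, degrees."""

    pelvis_tilt: float = 10.0
    hip_flexion: float = 20.0
    knee_flexion: float = 20.0
    ankle_dorsiflexion: float = 10.0


DEFAULT_POSTURE = Posture()


@dataclass
class SimState:
    """One integration frame: time, coordinates, velocities, activations."""

    t: float
    q: np.ndarray      # (10,) in COORD_NAMES order; angles rad
    qdot: np.ndarray   # (10,)
    act: np.ndarray    # (18,) muscle activations in [0, 1]

    def copy(self) -> "SimState":
        return SimState(self.t, self.q.copy(), self.qdot.copy(), self.act.copy())

    def validate(self) -> None:
        if self.q.shape != (10,) or self.qdot.shape != (10,):
            raise ValueError("q/qdot must have 10 entries (platform + 9 body DOFs)")
        if self.act.shape != (18,):
            raise ValueError("act must have 18 entries")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qdot))
                and np.all(np.isfinite(self.act))):
            raise ValueError("non-finite state")
        if np.any(self.act < -1e-12) or np.any(self.act > 1 + 1e-12):
            raise ValueError("activations outside [0, 1]")


@dataclass
class PlanarModel:
    """The full mechanical plant: segments, joints, muscles, contact."""

    segments: list[SegmentSpec]
    joints: list[JointSpec]
    muscles: list[MuscleSpec]
    contact_spheres: list[ContactSphere]
    contact_params: ContactParams
    gravity: float = GRAVITY_DEFAULT
    platform_mass: float = 10.0
    posture: Posture = field(default_factory=Posture)
    foot_geometry: dict = field(default_factory=dict)
    locked_coords: tuple = ()  # body coordinates pinned at zero motion
    joint_limits: dict = field(default_factory=dict)  # passive ROM stops
    #: joint angles (deg) where fibers sit at optimal length
    muscle_reference_posture: dict = field(default_factory=dict)
    muscle_dynamics: dict = field(default_factory=lambda: {
        "tau_act": 0.010, "tau_deact": 0.040, "v_max": 10.0})

    _packed: object = field(default=None, repr=False, compare=False)

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        names = {s.name for s in self.segments}
        if len(self.body_dof_names()) != 9:
            raise ValueError("body DOF count must be 9")
        if len(self.muscles) != 18:
            raise ValueError("muscle count must be 18")
        if len(self.contact_spheres) != 4:
            raise ValueError("contact sphere count must be 4")
        sliders = [j for j in self.joints if j.kind == "slider"]
        if len(sliders) != 1 or sliders[0].parent != "ground":
            raise ValueError("exactly one ground->platform slider required")
        for j in self.joints:
            if j.parent not in names | {"ground"} or j.child not in names:
                raise ValueError(f"joint {j.name} references unknown segment")

    def body_dof_names(self) -> tuple[str, ...]:
        return BODY_COORDS

    @property
    def body_mass(self) -> float:
        """Total body mass, platform excluded."""
        return sum(s.mass for s in self.segments if s.name != "platform")

    def segment(self, name: str) -> SegmentSpec:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    # -- cached engine arrays ----------------------------------------------
    def packed(self):
        if self._packed is None:
            from .engine import pack_model
            self._packed = pack_model(self)
        return self._packed

    def with_changes(self, **kw) -> "PlanarModel":
        m = replace(self, **kw)
        m._packed = None
        return m


def _load_defaults() -> dict:
    text = resources.files("balancesim.data").joinpath("default_model.yaml").read_text()
    return yaml.safe_load(text)


def build_default_model(total_mass: float = 74.5, height: float = 1.8,
                        posture: Posture = DEFAULT_POSTURE,
                        config: dict | None = None) -> PlanarModel:
    """Build the 9-DOF, 18-muscle plant scaled to the given anthropometry.

    Segment masses, lengths and inertias come from standard anthropometric
    fractions in the packaged configuration; the default posture is the
    slightly crouched stance used for all simulations (pelvis tilted 10
    degrees forward, hips and knees flexed 20 degrees, ankles dorsiflexed 10
    degrees).
    """
    if total_mass <= 0 or height <= 0:
        raise ValueError("total_mass and height must be positive")
    cfg = config if config is not None else _load_defaults()

    segs = []
    segdefs = cfg["segments"]
    for name, sides in (("hat", ("",)), ("thigh", ("_r", "_l")),
                        ("shank", ("_r", "_l")), ("foot", ("_r", "_l"))):
        d = segdefs[name]
        length = d["length_frac"] * height
        mass = d["mass_frac"] * total_mass
        rog = d["rog_frac"] * length
        for side in sides:
            segs.append(SegmentSpec(name + side, mass, d["com_frac"] * length,
                                    mass * rog * rog, length))
    segs.append(SegmentSpec("platform", cfg.get("platform_mass", 10.0),
                            0.0, 0.0, 0.0))

    joints = [JointSpec("platform_slider", "slider", "ground", "platform")]
    joints += [JointSpec("pelvis_tx", "slider-dof", "ground", "hat"),
               JointSpec("pelvis_ty", "slider-dof", "ground", "hat"),
               JointSpec("pelvis_tilt", "revolute", "ground", "hat", -1.0)]
    for side in ("r", "l"):
        joints += [
            JointSpec(f"hip_{side}", "revolute", "hat", f"thigh_{side}", +1.0),
            JointSpec(f"knee_{side}", "revolute", f"thigh_{side}", f"shank_{side}", -1.0),
            JointSpec(f"ankle_{side}", "revolute", f"shank_{side}", f"foot_{side}", +1.0),
        ]

    muscles = []
    for side in ("r", "l"):
        for name in UNIQUE_MUSCLES:
            d = cfg["muscles"][name]
            arms = {f"{j}_{side}": r for j, r in d["moment_arms"].items()}
            muscles.append(MuscleSpec(
                name=f"{name}_{side}", f_max=d["f_max"], l_opt=d["l_opt"],
                l_slack=d.get("l_slack", 0.0), v_max=cfg["muscle_dynamics"]["v_max"],
                moment_arms=arms, reflex_delay=d["reflex_delay"]))

    fg = cfg["foot_geometry"]
    ankle_h = fg["ankle_height_frac"] * height
    heel_back = fg["heel_back_frac"] * height
    foot_len = segdefs["foot"]["length_frac"] * height
    radius = fg["sphere_radius"]
    y_c = -(ankle_h - radius)  # sphere centers; sphere bottom = sole plane
    spheres = []
    for side in ("r", "l"):
        spheres.append(ContactSphere(f"foot_{side}", (foot_len - heel_back, y_c),
                                     radius, label=f"toe_{side}"))
        spheres.append(ContactSphere(f"foot_{side}", (-heel_back, y_c),
                                     radius, label=f"heel_{side}"))

    c = cfg["contact"]
    params = ContactParams(
        stiffness=c["stiffness"], dissipation=c["dissipation"],
        mu_static=c["mu_static"], mu_dynamic=c["mu_dynamic"],
        mu_viscous=c["mu_viscous"], transition_velocity=c["transition_velocity"])

    model = PlanarModel(segments=segs, joints=joints, muscles=muscles,
                        contact_spheres=spheres, contact_params=params,
                        gravity=cfg.get("gravity", GRAVITY_DEFAULT),
                        platform_mass=cfg.get("platform_mass", 10.0),
                        posture=posture, foot_geometry={
                            "ankle_height": ankle_h, "heel_back": heel_back,
                            "foot_length": foot_len, "radius": radius},
                        joint_limits=dict(cfg.get("joint_limits", {})),
                        muscle_reference_posture=dict(
                            cfg.get("muscle_reference_posture", {})),
                        muscle_dynamics=dict(cfg["muscle_dynamics"]))
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Kinematics (reference Python implementation; the integration kernel has its
# own compiled mirror of these formulas)
# ---------------------------------------------------------------------------

def _posture_q(model: PlanarModel) -> np.ndarray:
    p = model.posture
    q = np.zeros(10)
    q[3] = math.radians(p.pelvis_tilt)
    q[4] = q[7] = math.radians(p.hip_flexion)
    q[5] = q[8] = math.radians(p.knee_flexion)
    q[6] = q[9] = math.radians(p.ankle_dorsiflexion)
    return q


def muscle_reference_angles(model: PlanarModel) -> dict[str, float]:
    """Per-joint angles (rad) at which each fiber is at optimal length.

    Falls back to the model's initial posture when no explicit reference
    posture is configured.
    """
    ref = model.muscle_reference_posture
    p = model.posture
    hip = math.radians(ref.get("hip", p.hip_flexion))
    knee = math.radians(ref.get("knee", p.knee_flexion))
    ankle = math.radians(ref.get("ankle", p.ankle_dorsiflexion))
    out = {}
    for side in ("r", "l"):
        out[f"hip_{side}"] = hip
        out[f"knee_{side}"] = knee
        out[f"ankle_{side}"] = ankle
    return out


def body_frames(model: PlanarModel, q: np.ndarray, qdot: np.ndarray | None = None):
    """World angle, origin, angular velocity and origin velocity per segment.

    Returns dict name -> (phi, origin(2,), omega, v_origin(2,)).  The HAT
    origin sits at the (coincident bilateral) hip joint centers.
    """
    if qdot is None:
        qdot = np.zeros_like(q)
    hat = model.segment("hat")
    thigh = model.segment("thigh_r")
    shank = model.segment("shank_r")

    out = {}

    def rot(phi):
        c, s = math.cos(phi), math.sin(phi)
        return np.array([[c, -s], [s, c]])

    # HAT carried by the floating base; tilt is forward-positive (CW in the
    # x-forward / y-up plane), hence the -1 sign.
    phi_hat = -q[3]
    o_hat = np.array([q[1], q[2]])
    w_hat = -qdot[3]
    v_hat = np.array([qdot[1], qdot[2]])
    out["hat"] = (phi_hat, o_hat, w_hat, v_hat)

    for side, (ih, ik, ia) in (("r", (4, 5, 6)), ("l", (7, 8, 9))):
        phi_th = phi_hat + q[ih]
        w_th = w_hat + qdot[ih]
        o_th = o_hat.copy()
        v_th = v_hat.copy()
        out[f"thigh_{side}"] = (phi_th, o_th, w_th, v_th)

        knee = o_th + rot(phi_th) @ np.array([0.0, -thigh.length])
        v_knee = v_th + w_th * np.array([-(knee - o_th)[1], (knee - o_th)[0]])
        phi_sh = phi_th - q[ik]
        w_sh = w_th - qdot[ik]
        out[f"shank_{side}"] = (phi_sh, knee, w_sh, v_knee)

        ankle = knee + rot(phi_sh) @ np.array([0.0, -shank.length])
        v_ankle = v_knee + w_sh * np.array([-(ankle - knee)[1], (ankle - knee)[0]])
        phi_ft = phi_sh + q[ia]
        w_ft = w_sh + qdot[ia]
        out[f"foot_{side}"] = (phi_ft, ankle, w_ft, v_ankle)
    return out


def _segment_axis_dir(name: str) -> np.ndarray:
    # HAT extends upward from the hip; limb segments extend downward; the
    # foot COM offset is measured along its local +x (toe-ward) axis.
    if name == "hat":
        return np.array([0.0, 1.0])
    if name.startswith("foot"):
        return np.array([1.0, 0.0])
    return np.array([0.0, -1.0])


def segment_com_positions(model: PlanarModel, state: SimState):
    """World COM position and velocity per body segment (platform excluded)."""
    frames = body_frames(model, state.q, state.qdot)
    out = {}
    fg = model.foot_geometry
    for seg in model.segments:
        if seg.name == "platform":
            continue
        phi, o, w, vo = frames[seg.name]
        c, s = math.cos(phi), math.sin(phi)
        R = np.array([[c, -s], [s, c]])
        local = _segment_axis_dir(seg.name) * seg.com_offset
        if seg.name.startswith("foot"):
            # measured from the heel end, a touch below the ankle
            local = np.array([seg.com_offset - fg["heel_back"],
                              -0.5 * fg["ankle_height"]])
        r = R @ local
        pos = o + r
        vel = vo + w * np.array([-r[1], r[0]])
        out[seg.name] = (seg.mass, pos, vel)
    return out


def whole_body_com(model: PlanarModel, state: SimState, subset: str = "all-body"):
    """Mass-weighted COM position and velocity over the chosen segment subset.

    ``subset`` is ``"all-body"`` (every segment except the platform) or
    ``"feet-only"`` (the two foot segments).
    """
    coms = segment_com_positions(model, state)
    if subset == "feet-only":
        items = [v for k, v in coms.items() if k.startswith("foot")]
    elif subset == "all-body":
        items = list(coms.values())
    else:
        raise ValueError(f"unknown subset {subset!r}")
    mtot = sum(m for m, _, _ in items)
    pos = sum(m * p for m, p, _ in items) / mtot
    vel = sum(m * v for m, _, v in items) / mtot
    return pos, vel


def joint_moments(model: PlanarModel, state: SimState,
                  muscle_forces: np.ndarray) -> dict[str, float]:
    """Net muscle moment (N m, flexion-positive) at each hip/knee/ankle.

    With constant moment arms the mapping is the moment-arm matrix transpose;
    the state argument is part of the interface for geometry-dependent arms.
    """
    muscle_forces = np.asarray(muscle_forces, dtype=float)
    if muscle_forces.shape != (18,):
        raise ValueError("expected 18 muscle forces")
    if np.any(muscle_forces < 0):
        raise ValueError("muscle forces must be non-negative (muscles pull)")
    out = {j: 0.0 for j in JOINT_COORDS}
    for m, F in zip(model.muscles, muscle_forces):
        for joint, r in m.moment_arms.items():
            out[joint] += r * F
    return out


def initial_state(model: PlanarModel) -> SimState:
    """Default state: prescribed posture, feet flat on the platform with the
    lowest contact point penetrating 1 mm (near static load), at rest."""
    q = _posture_q(model)
    frames = body_frames(model, q)
    lowest = math.inf
    for sp in model.contact_spheres:
        phi, o, _, _ = frames[sp.segment]
        c, s = math.cos(phi), math.sin(phi)
        center = o + np.array([c * sp.local_offset[0] - s * sp.local_offset[1],
                               s * sp.local_offset[0] + c * sp.local_offset[1]])
        lowest = min(lowest, center[1] - sp.radius)
    q[2] -= lowest + 1e-3
    return SimState(0.0, q, np.zeros(10), np.zeros(18))


def forward_step(model: PlanarModel, state: SimState, excitations: np.ndarray,
                 platform_drive, dt: float) -> SimState:
    """Advance the plant one fixed step under externally supplied excitations.

    Composes activation dynamics, Hill muscle forces through constant moment
    arms, compliant foot-platform contact and gravity, with the platform
    slider kinematically driven to the prescribed sinusoid.  Deterministic
    given identical inputs.
    """
    from .engine import step_once
    if not (0 < dt <= 5e-3):
        raise ValueError("dt must be in (0, 5 ms]")
    excitations = np.asarray(excitations, dtype=float)
    if np.any(excitations < 0) or np.any(excitations > 1):
        raise ValueError("excitations must lie in [0, 1]")
    state.validate()
    return step_once(model, state, excitations, platform_drive, dt)
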