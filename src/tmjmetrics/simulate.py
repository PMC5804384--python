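"""Synthetic landmark-level cohort generator.

Emulates a clinical MRI cohort of TMJ joints — normal, disc displacement
with reduction (DDwR) and without reduction (DDwoR) — measured in three
bite positions (1 habitual closure, 2 protruded/anterior-repositioning,
3 stabilization).  Default generative parameters are the published group
statistics of the study cohort this package models: per-group/position
disc-condyle angle mean±SD, condyle fossa-frame coordinate mean±SD, and
the observed recapture counts in the treated positions (58/60 and 20/60).

Generation is *angle-first*: the disc-condyle angle is drawn directly and
the disc landmark D is placed at that angle and a drawn radius around the
condyle center C.  For DDwR joints in treated positions the angle comes
from a two-component mixture — with probability ``recapture_prob`` a
truncated normal inside the ±15° band, otherwise truncated above it —
because a plain normal calibrated to the treated-position moments would
put far more mass outside the band than the observed 2/60 failures.
A consequence is that disc *coordinate* distributions are matched only
approximately; angle moments and recapture fractions are matched exactly
in expectation.

Landmarks are embedded in a jittered scene (T, P, G placement) under a
random rigid motion, constructed so that measuring the scene with the
geometry module recovers the drawn angle and coordinates to ~1e-12.  The
global seed is expanded into independent substreams for latent clinical
draws, scene nuisance and metadata, so changing scene settings never
perturbs the latent values.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.stats import truncnorm

from .errors import ValidationError
from .geometry import LandmarkSet
from .kinematics import Cohort, FrameCoords, JointMeasurement, JointRecord, PatientMeta

__all__ = [
    "SceneConfig",
    "MetaParams",
    "SimulationConfig",
    "DEFAULT_ANGLE_PARAMS",
    "DEFAULT_CONDYLE_PARAMS",
    "DEFAULT_RECAPTURE_PROB",
    "simulate_cohort",
    "add_rater_noise",
]

MeanSd = Tuple[float, float]

#: Disc-condyle angle mean/SD (degrees) per diagnosis group and position.
#: DDwoR spreads default to the DDwR position-1 SD (none are published).
DEFAULT_ANGLE_PARAMS: Dict[str, Dict[int, MeanSd]] = {
    "normal": {1: (-1.1, 10.8), 2: (-11.7, 12.0), 3: (-2.7, 15.5)},
    "DDwR": {1: (53.4, 16.7), 2: (-10.5, 17.1), 3: (30.1, 26.9)},
    "DDwoR": {1: (82.1, 16.7), 2: (65.5, 16.7), 3: (70.1, 16.7)},
}

#: Condyle fossa-frame coordinates ((x mean, x sd), (y mean, y sd)) in mm.
#: DDwoR reuses the DDwR values (no DDwoR coordinates are published).
DEFAULT_CONDYLE_PARAMS: Dict[str, Dict[int, Tuple[MeanSd, MeanSd]]] = {
    "normal": {
        1: ((0.11, 1.40), (-7.02, 0.80)),
        2: ((-2.11, 2.14), (-8.51, 0.82)),
        3: ((-0.59, 1.27), (-7.08, 0.87)),
    },
    "DDwR": {
        1: ((1.21, 1.19), (-6.36, 0.94)),
        2: ((-2.07, 1.53), (-8.96, 1.10)),
        3: ((0.24, 1.32), (-7.04, 1.11)),
    },
    "DDwoR": {
        1: ((1.21, 1.19), (-6.36, 0.94)),
        2: ((-2.07, 1.53), (-8.96, 1.10)),
        3: ((0.24, 1.32), (-7.04, 1.11)),
    },
}

#: Probability that a DDwR disc is recaptured in a treated position
#: (observed fractions 58/60 for position 2, 20/60 for position 3).
DEFAULT_RECAPTURE_PROB: Dict[int, float] = {2: 58.0 / 60.0, 3: 20.0 / 60.0}


@dataclass
class SceneConfig:
    """Nuisance geometry of the simulated image scene (mm / degrees).

    T sits anterior-inferior and P posterior-inferior of the fossa point G
    at roughly anatomical offsets; each placement is jittered per joint.
    The whole scene then undergoes a random rigid motion, to which every
    derived measurement is invariant.
    """

    t_offset: Tuple[float, float] = (-8.0, -5.0)
    p_offset: Tuple[float, float] = (10.0, -4.0)
    landmark_jitter_sd: float = 0.5
    rotation_range_deg: float = 10.0
    translation_range_mm: float = 10.0
    fh_tilt_deg: float = 0.0  # Frankfort trace tilt relative to the T-P tangent


@dataclass
class MetaParams:
    """Generative mean/SD for incisor distances and overjet (mm)."""

    d1: MeanSd = (14.2, 2.0)
    opening: MeanSd = (2.7, 0.8)  # D2 - D1; truncated at 0
    overjet_p1: MeanSd = (3.1, 1.1)
    overjet_p3: MeanSd = (3.0, 1.2)


@dataclass
class SimulationConfig:
    """All generative parameters of the synthetic cohort."""

    n_normal: int = 10
    n_ddwr: int = 60
    n_ddwor: int = 4
    angle_params: Dict[str, Dict[int, MeanSd]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_ANGLE_PARAMS)
    )
    condyle_params: Dict[str, Dict[int, Tuple[MeanSd, MeanSd]]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_CONDYLE_PARAMS)
    )
    disc_radius_mean: float = 4.8  # ||D - C|| in mm; 4.8 is the DDwR P1 mean offset norm
    disc_radius_sd: float = 0.5
    recapture_prob: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RECAPTURE_PROB)
    )
    normal_band: float = 15.0
    position_corr: float = 0.0  # within-joint correlation of condyle coords across positions
    scene: SceneConfig = field(default_factory=SceneConfig)
    meta_params: MetaParams = field(default_factory=MetaParams)
    seed: int = 0

    def __post_init__(self):
        for n in (self.n_normal, self.n_ddwr, self.n_ddwor):
            if n < 0:
                raise ValidationError("group sizes must be >= 0")
        for grp, per_pos in self.angle_params.items():
            for pos, (_, sd) in per_pos.items():
                if sd <= 0:
                    raise ValidationError(f"angle SD for {grp} position {pos} must be > 0")
        for grp, per_pos in self.condyle_params.items():
            for pos, ((_, sdx), (_, sdy)) in per_pos.items():
                if sdx <= 0 or sdy <= 0:
                    raise ValidationError(
                        f"condyle SD for {grp} position {pos} must be > 0"
                    )
        if self.disc_radius_sd <= 0 or self.disc_radius_mean <= 0:
            raise ValidationError("disc radius mean and SD must be > 0")
        for pos, p in self.recapture_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"recapture_prob[{pos}]={p} outside [0, 1]")
        if not 0.0 <= self.position_corr <= 1.0:
            raise ValidationError("position_corr must be in [0, 1]")
        if self.normal_band <= 0:
            raise ValidationError("normal_band must be > 0")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        """Build a config from a plain (YAML/JSON-loaded) mapping.

        Nested keys may use string position keys; unknown keys raise."""
        data = copy.deepcopy(data)

        def intkeys(d):
            return {int(k): v for k, v in d.items()}

        kwargs = {}
        for key, value in data.items():
            if key == "angle_params":
                kwargs[key] = {g: {p: tuple(v) for p, v in intkeys(d).items()}
                               for g, d in value.items()}
            elif key == "condyle_params":
                kwargs[key] = {
                    g: {p: (tuple(v[0]), tuple(v[1])) for p, v in intkeys(d).items()}
                    for g, d in value.items()
                }
            elif key == "recapture_prob":
                kwargs[key] = intkeys(value)
            elif key == "scene":
                sc = dict(value)
                for off in ("t_offset", "p_offset"):
                    if off in sc:
                        sc[off] = tuple(sc[off])
                kwargs[key] = SceneConfig(**sc)
            elif key == "meta_params":
                kwargs[key] = MetaParams(**{k: tuple(v) for k, v in value.items()})
            else:
                kwargs[key] = value
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ValidationError(f"invalid simulation config: {exc}") from exc

    def to_dict(self) -> dict:
        return asdict(self)


def _rot(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def _draw_angle(
    rng: np.random.Generator,
    group: str,
    pos: int,
    cfg: SimulationConfig,
    recaptured: Optional[bool],
) -> float:
    mean, sd = cfg.angle_params[group][pos]
    if group != "DDwR" or pos == 1 or recaptured is None:
        return float(rng.normal(mean, sd))
    band = cfg.normal_band
    if recaptured:
        a, b = (-band - mean) / sd, (band - mean) / sd
    else:
        a, b = (band - mean) / sd, np.inf
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _build_scene(
    rng_scene: np.random.Generator,
    cfg: SimulationConfig,
    cx: float,
    cy: float,
    angle_deg: float,
    radius: float,
    side: str,
) -> Tuple[LandmarkSet, FrameCoords]:
    """Embed drawn frame-level values into an image-space landmark scene.

    Returns the landmark set and the disc's canonical frame coordinates
    (the generator's ground truth for D)."""
    sc = cfg.scene
    jit = sc.landmark_jitter_sd
    G0 = np.zeros(2)
    T0 = np.asarray(sc.t_offset) + rng_scene.normal(0.0, jit, 2)
    P0 = np.asarray(sc.p_offset) + rng_scene.normal(0.0, jit, 2)
    sup0 = np.array([0.0, 1.0])

    x_hat = P0 - T0
    x_hat = x_hat / np.linalg.norm(x_hat)
    y_hat = np.array([-x_hat[1], x_hat[0]])
    if y_hat @ sup0 < 0:
        y_hat = -y_hat

    C0 = G0 + cx * x_hat + cy * y_hat

    # Frankfort trace: tangent direction tilted by fh_tilt (posterior end up)
    s_fh = 1.0 if (x_hat[0] * sup0[1] - x_hat[1] * sup0[0]) > 0 else -1.0
    fh0 = _rot(s_fh * sc.fh_tilt_deg) @ x_hat
    u0 = np.array([-fh0[1], fh0[0]])
    if u0 @ sup0 < 0:
        u0 = -u0
    anterior = -x_hat
    s = 1.0 if (u0[0] * anterior[1] - u0[1] * anterior[0]) > 0 else -1.0
    D0 = C0 + radius * (_rot(s * angle_deg) @ u0)
    disc_truth = FrameCoords(
        x=float((D0 - G0) @ x_hat), y=float((D0 - G0) @ y_hat)
    )

    # random rigid motion of the whole scene
    psi = rng_scene.uniform(-sc.rotation_range_deg, sc.rotation_range_deg)
    trans = rng_scene.uniform(-sc.translation_range_mm, sc.translation_range_mm, 2)
    R = _rot(psi)
    pts = {k: R @ v + trans for k, v in
           {"T": T0, "P": P0, "G": G0, "C": C0, "D": D0}.items()}
    fh = R @ fh0
    sup = R @ sup0

    if side == "left":  # left-side images are mirror images of right-side anatomy
        M = np.array([[-1.0, 0.0], [0.0, 1.0]])
        pts = {k: M @ v for k, v in pts.items()}
        fh = M @ fh
        sup = M @ sup

    lm = LandmarkSet(
        T=pts["T"], P=pts["P"], G=pts["G"], C=pts["C"], D=pts["D"],
        fh_dir=fh, superior_dir=sup, side=side,
    )
    return lm, disc_truth


def simulate_cohort(config: Optional[SimulationConfig] = None) -> Cohort:
    """Generate a landmark-level cohort; deterministic given ``config.seed``.

    Every joint record carries the image-space landmarks for positions 1-3
    plus the generator's drawn values in ``record.truth`` so round-trip
    fidelity of the measurement pipeline can be checked.
    """
    cfg = config if config is not None else SimulationConfig()
    ss = np.random.SeedSequence(cfg.seed)
    latent_ss, scene_ss, meta_ss = ss.spawn(3)
    rng_latent = np.random.default_rng(latent_ss)
    rng_scene = np.random.default_rng(scene_ss)
    rng_meta = np.random.default_rng(meta_ss)

    groups = (
        [("normal", i) for i in range(cfg.n_normal)]
        + [("DDwR", i) for i in range(cfg.n_ddwr)]
        + [("DDwoR", i) for i in range(cfg.n_ddwor)]
    )
    cohort = Cohort()
    rho = cfg.position_corr
    for idx, (group, i) in enumerate(groups):
        joint_id = f"{group.lower()}-{i + 1:03d}"
        patient_id = f"pt-{idx + 1:03d}"
        side = "right" if idx % 2 == 0 else "left"
        rec = JointRecord(
            joint_id=joint_id, patient_id=patient_id, side=side, diagnosis=group
        )
        # shared joint-level effect for optional across-position correlation
        z_joint = rng_latent.normal(0.0, 1.0, 2)
        recap = {
            pos: (bool(rng_latent.random() < cfg.recapture_prob.get(pos, 0.0))
                  if group == "DDwR" else None)
            for pos in (2, 3)
        }
        for pos in (1, 2, 3):
            (mx, sdx), (my, sdy) = cfg.condyle_params[group][pos]
            z_pos = rng_latent.normal(0.0, 1.0, 2)
            z = np.sqrt(rho) * z_joint + np.sqrt(1.0 - rho) * z_pos
            cx = mx + sdx * z[0]
            cy = my + sdy * z[1]
            theta = _draw_angle(rng_latent, group, pos, cfg, recap.get(pos))
            radius = max(0.5, float(rng_latent.normal(cfg.disc_radius_mean, cfg.disc_radius_sd)))
            lm, disc_truth = _build_scene(rng_scene, cfg, cx, cy, theta, radius, side)
            rec.landmarks[pos] = lm
            rec.truth[pos] = JointMeasurement(
                angle=theta, condyle=FrameCoords(cx, cy), disc=disc_truth
            )
        cohort.records.append(rec)

        mp = cfg.meta_params
        d1 = max(5.0, rng_meta.normal(*mp.d1))
        opening = max(0.0, rng_meta.normal(*mp.opening))
        d2 = d1 + opening
        cohort.meta[patient_id] = PatientMeta(
            D1=d1, D2=d2, D3=d2,
            overjet_p1=max(0.0, rng_meta.normal(*mp.overjet_p1)),
            overjet_p3=max(0.0, rng_meta.normal(*mp.overjet_p3)),
        )
    return cohort


def add_rater_noise(cohort: Cohort, noise_sd: float, seed: int) -> Cohort:
    """A replicate measurement session: every landmark point perturbed by
    isotropic Gaussian noise of SD ``noise_sd`` mm.  The input cohort is
    untouched; derived measurements and generator truth are dropped from
    the replicate (they must be re-measured)."""
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    out = Cohort(meta=dict(cohort.meta))
    for rec in cohort.records:
        new = JointRecord(
            joint_id=rec.joint_id, patient_id=rec.patient_id,
            side=rec.side, diagnosis=rec.diagnosis,
        )
        for pos, lm in sorted(rec.landmarks.items()):
            pts = {k: getattr(lm, k) + rng.normal(0.0, noise_sd, 2)
                   for k in ("T", "P", "G", "C", "D")}
            new.landmarks[pos] = LandmarkSet(
                fh_dir=None if lm.fh_dir is None else lm.fh_dir.copy(),
                superior_dir=lm.superior_dir.copy(), side=lm.side, **pts,
            )
        out.records.append(new)
    return out
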