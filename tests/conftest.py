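import numpy as np
import pytest

from tmjmetrics import LandmarkSet


def rigid_transform(angle_deg: float, translation, pivot=(0.0, 0.0)):
    """Explicit 2D rigid transform oracle: rotation about a pivot plus a
    translation.  Returns (point_fn, direction_fn)."""
    a = np.deg2rad(angle_deg)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    pivot = np.asarray(pivot, dtype=float)
    t = np.asarray(translation, dtype=float)

    def point(p):
        return R @ (np.asarray(p, dtype=float) - pivot) + pivot + t

    def direction(d):
        return R @ np.asarray(d, dtype=float)

    return point, direction


def transform_landmarks(lm: LandmarkSet, angle_deg, translation, pivot=(0, 0)) -> LandmarkSet:
    """Apply one rigid motion to every landmark and direction of a scene."""
    pt, dr = rigid_transform(angle_deg, translation, pivot)
    return LandmarkSet(
        T=pt(lm.T), P=pt(lm.P), G=pt(lm.G), C=pt(lm.C), D=pt(lm.D),
        fh_dir=None if lm.fh_dir is None else dr(lm.fh_dir),
        superior_dir=dr(lm.superior_dir), side=lm.side,
    )


def mirror_landmarks(lm: LandmarkSet) -> LandmarkSet:
    """Reflect a scene across the vertical axis and flip the side flag."""
    M = np.array([[-1.0, 0.0], [0.0, 1.0]])
    return LandmarkSet(
        T=M @ lm.T, P=M @ lm.P, G=M @ lm.G, C=M @ lm.C, D=M @ lm.D,
        fh_dir=None if lm.fh_dir is None else M @ lm.fh_dir,
        superior_dir=M @ lm.superior_dir,
        side="left" if lm.side == "right" else "right",
    )


def make_axis_scene(C=(0.0, 0.0), D=(0.0, 3.0), G=(0.0, 0.0), fh_dir=None):
    """Axis-aligned right-side scene: tangent horizontal, anterior = -x."""
    return LandmarkSet(
        T=(-10.0, -3.0), P=(10.0, -3.0), G=G, C=C, D=D,
        fh_dir=fh_dir, superior_dir=(0.0, 1.0), side="right",
    )


@pytest.fixture
def axis_scene():
    return make_axis_scene


@pytest.fixture
def random_scene():
    """Generic (tilted, offset) scene built from a seeded RNG."""

    def make(rng: np.random.Generator):
        tilt = rng.uniform(-30, 30)
        pt, dr = rigid_transform(tilt, rng.uniform(-20, 20, 2))
        C = rng.uniform(-4, 4, 2) + np.array([0.0, -7.0])
        D = C + rng.uniform(2, 7) * np.array(
            [np.sin(rng.uniform(-np.pi, np.pi)), np.cos(rng.uniform(-np.pi, np.pi))]
        )
        return LandmarkSet(
            T=pt((-9.0, -5.0)), P=pt((10.0, -4.0)), G=pt((0.0, 0.0)),
            C=pt(C), D=pt(D), fh_dir=dr((1.0, 0.0)), superior_dir=dr((0.0, 1.0)),
        )

    return make
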