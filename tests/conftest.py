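import numpy as np
import pytest

from larvakin.kinematics import Trajectory
from larvakin.thigmotaxis import ArenaGeometry


@pytest.fixture
def arena() -> ArenaGeometry:
    return ArenaGeometry()


def make_trajectory(x, y, frame_rate=30.0, flags=None) -> Trajectory:
    return Trajectory(
        frame_rate=frame_rate,
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        flags=flags,
    )


def trajectory_from_displacements(disp, frame_rate=30.0) -> Trajectory:
    """Straight-line trajectory whose per-frame step lengths equal `disp`.

    disp[0] is ignored (first frame has no predecessor).
    """
    disp = np.asarray(disp, dtype=float)
    x = np.concatenate(([0.0], np.cumsum(disp[1:])))
    return make_trajectory(x, np.zeros_like(x), frame_rate=frame_rate)


def radial_trajectory(radii, frame_rate=30.0, angle=0.0) -> Trajectory:
    r = np.asarray(radii, dtype=float)
    return make_trajectory(r * np.cos(angle), r * np.sin(angle), frame_rate=frame_rate)
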