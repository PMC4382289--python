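import numpy as np
import pytest

from reflexgait.model_core import SkeletonModel
from reflexgait.mtu import MuscleSet
from reflexgait.optimizer import DesignVector
from reflexgait.simulation import Trajectory


@pytest.fixture(scope="session")
def model():
    return SkeletonModel.default()


@pytest.fixture(scope="session")
def muscles():
    return MuscleSet.default()


@pytest.fixture(scope="session")
def codec():
    return DesignVector()


def make_trajectory(duration=10.0, fell=False, t_fall=None, com_height=0.9,
                    metabolic=80.0, hpe=0.0, head_vel=0.0, body_mass=80.0,
                    back_mass=0.0, heel_strikes_r=(), heel_strikes_l=(),
                    com_speed=1.5, fs=100.0):
    """Hand-constructed minimal trajectory for objective/analysis tests."""
    n = int(duration * fs) + 1
    t = np.arange(n) / fs
    com = np.column_stack([com_speed * t, np.full(n, com_height)])
    zeros9 = np.zeros((n, 9))
    zeros16 = np.zeros((n, 16))
    zeros6 = np.zeros((n, 6))
    fr_t = t
    return Trajectory(
        t=t, q=zeros9.copy(), qd=zeros9.copy(), excitations=zeros16.copy(),
        activations=zeros16.copy(), fiber_length=zeros16.copy(),
        muscle_force=zeros16.copy(), joint_torques=zeros6.copy(),
        limit_torques=zeros6.copy(),
        hpe=np.full(n, float(hpe)),
        grf=np.zeros((n, 4)), cop_x=np.full((n, 2), np.nan),
        gait_mode=np.zeros((n, 2), dtype=int),
        com=com, com_vel=np.column_stack([np.full(n, com_speed), np.zeros(n)]),
        head_vel=np.full(n, float(head_vel)),
        metabolic_power=np.full(n, float(metabolic)),
        fell=fell,
        t_fall=(duration if t_fall is None else t_fall),
        duration=duration, body_mass=body_mass, back_mass=back_mass,
        extras=dict(fr_t=fr_t, fr_comx=com[:, 0], fr_comy=com[:, 1],
                    fr_mode=np.zeros((n, 2), dtype=int),
                    fr_grfy=np.zeros((n, 2)),
                    heel_strikes={"r": np.asarray(heel_strikes_r, dtype=float),
                                  "l": np.asarray(heel_strikes_l, dtype=float)}),
    )


@pytest.fixture
def trajectory_factory():
    return make_trajectory
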