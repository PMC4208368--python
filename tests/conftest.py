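import numpy as np
import pytest

from fallrisk.synthetic import CohortSpec, SubjectParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_params(**over) -> SubjectParams:
    """A physiologically ordinary subject with every knob overridable."""
    base = dict(
        subject_id="T001",
        group="nonfaller",
        latents={},
        stride_length=1.2,
        step_width=0.09,
        maxfc={"L": 0.12, "R": 0.12},
        minfc={"L": 0.025, "R": 0.025},
        stride_time=1.1,
        stance_frac=0.62,
        phase=0.5,
        stride_time_sd={"L": 0.0, "R": 0.0},
        stride_length_sd=0.0,
        step_width_sd=0.0,
        stance_frac_sd=0.0,
        phase_sd=0.0,
        maxfc_sd=0.0,
        minfc_sd=0.0,
        marker_noise_sd=0.0,
        sway_amp={"QEO": 0.005, "QEC": 0.0075},
        sway_theta={"QEO": 1.0, "QEC": 0.9},
        mvic={"KE": 150.0, "PF": 60.0},
        tremor_cv={"KE": 0.035, "PF": 0.035},
    )
    base.update(over)
    return SubjectParams(**base)


@pytest.fixture
def quiet_params():
    """Noise-free subject: deterministic strides, no tremor, no sway."""
    return make_params(tremor_cv={"KE": 0.0, "PF": 0.0})


@pytest.fixture
def tiny_spec():
    """Smallest spec the design invariants allow (fast full-signal runs)."""
    return CohortSpec(n_fallers=3, n_nonfallers=3, n_ftf=1, seed=7)
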