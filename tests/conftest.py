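"""Shared fixtures: analytic profiles and one rendered reference sequence.

Everything is generated at test time from seeded synthetic truth; no image
data ships with the package.
"""

import numpy as np
import pytest

from capadh.geometry import MeniscusProfile
from capadh.mechanics import FluidProperties
from capadh.pipeline import analyze_frames
from capadh.synthetic import SyntheticTruth, render_frames


@pytest.fixture(scope="session")
def water():
    return FluidProperties.water()


@pytest.fixture()
def slender_profile():
    """Near-snap-off trichome-scale meniscus."""
    return MeniscusProfile(a=47e-6, b=160e-6, c=0.0, r_tip=20e-6)


def sample_profile_points(profile, n_per_flank=50, rng=None, noise=0.0,
                          axis_x=None):
    """Exact (optionally noisy) points on both flanks of a profile,
    sampled along the parametric arc between the contact line and the base."""
    ax = profile.axis_x if axis_x is None else axis_x
    t_tip = np.arcsin(profile.r_tip / profile.a)
    t = np.linspace(t_tip + 0.01, np.pi / 2 - 0.01, n_per_flank)
    x = profile.a * np.sin(t)
    y = profile.b * np.cos(t) + profile.c
    pts = np.vstack([
        np.column_stack([ax + x, y]),
        np.column_stack([ax - x, y]),
    ])
    if noise > 0:
        rng = rng or np.random.default_rng(0)
        pts = pts + rng.normal(0.0, noise, size=pts.shape)
    return pts


@pytest.fixture(scope="session")
def rendered_experiment():
    """One rendered pull sequence with its truth, analyzed once per session.

    Returns (frames, truth_sequence, family_record, analyzed_sequence).
    """
    truth = SyntheticTruth(seed=7)
    frames, tseq, rec = render_frames(truth, 8)
    seq = analyze_frames(frames)
    return frames, tseq, rec, seq
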