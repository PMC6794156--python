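import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ffrplan import LesionSegment, VesselGeometry

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_vessel(length=100.0, r0=2.0, taper=0.0, lesions=(), ds=0.25, label=""):
    """Tapered tube with raised-cosine narrowings.

    ``lesions`` is a sequence of (start_mm, length_mm, depth_fraction).
    """
    s = np.linspace(0.0, length, int(np.ceil(length / ds)) + 1)
    r = r0 * (1.0 - taper * s / length)
    for st, ln, d in lesions:
        m = (s >= st) & (s < st + ln)
        w = 0.5 * (1.0 - np.cos(2.0 * np.pi * (s[m] - st) / ln))
        r[m] = r[m] * (1.0 - d * w)
    return VesselGeometry(s, r, label)


def true_lesions(geom, specs):
    """Ground-truth LesionSegment records for lesions planted by make_vessel."""
    s, r = geom.s, geom.r
    out = []
    for st, ln, _d in specs:
        end = st + ln
        mask = (s >= st) & (s < end)
        idx = np.flatnonzero(mask)
        k = int(idx[np.argmin(r[mask])])
        j0 = max(int(idx[0]) - 1, 0)
        j1 = min(int(idx[-1]) + 1, s.size - 1)
        r_ref = float(r[j0] + (r[j1] - r[j0]) * (s[k] - s[j0]) / (s[j1] - s[j0]))
        out.append(LesionSegment(st, end, float(r[k]), r_ref,
                                 100.0 * (1.0 - r[k] / r_ref)))
    return out


@pytest.fixture
def straight_tube():
    return make_vessel(length=30.0, r0=1.5, ds=0.25, label="tube")


@pytest.fixture
def wide_healthy():
    return make_vessel(length=80.0, r0=2.5, ds=0.25, label="healthy")
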