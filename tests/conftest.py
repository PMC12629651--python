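import math

import pytest

from echopipe.synthetic import PhantomSpec, ellipse_mask, generate_exam


@pytest.fixture(scope="session")
def pristine():
    """One uncorrupted phantom exam with EDV 150, ESV 75, LA 60 mL."""
    return generate_exam(PhantomSpec(edv_ml=150.0, esv_ml=75.0,
                                     la_esv_ml=60.0, seed=1))


def make_ellipse(a_mm: float, b_mm: float, spacing: float,
                 angle_deg: float = 0.0, margin_mm: float = 5.0):
    """Axis-aligned (or rotated) ellipse mask centered on its grid."""
    half = max(a_mm, b_mm) + margin_mm
    n = 2 * int(math.ceil(half / spacing)) + 1
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    return ellipse_mask((n, n), center, (a_mm, b_mm), spacing, angle_deg)
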