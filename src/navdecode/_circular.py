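"""Small circular-statistics helpers shared across modules.

All angles are in degrees. Headings live on [0, 360); signed differences on
(-180, 180] with the diametric offset identified with +180.
"""

from __future__ import annotations

import numpy as np


def wrap_degrees(angle):
    """Reduce an angle (scalar or array) to [0, 360).

    Guards the rounding artifact where (-eps) % 360 returns exactly 360.0.
    """
    w = np.asarray(angle, dtype=float) % 360.0
    return np.where(w >= 360.0, 0.0, w)


def signed_circular_diff(a, b):
    """Signed circular difference a - b mapped to (-180, 180].

    The antipodal case is mapped to +180 (not -180), so that the six
    relative offsets of a 60-degree binning are exactly
    (-120, -60, 0, 60, 120, 180).
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    # map the boundary -180 (exact antipode) to +180
    d = np.where(np.isclose(d, -180.0), 180.0, d)
    if np.ndim(d) == 0:
        return float(d)
    return d


def heading_to_unit(heading_deg):
    """Unit displacement vector(s) for a heading: 0 deg = +x, 90 deg = +y."""
    rad = np.deg2rad(np.asarray(heading_deg, dtype=float))
    return np.cos(rad), np.sin(rad)
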