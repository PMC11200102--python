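"""Small shared helpers: p-values, hashing, float formatting."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
from scipy import stats

# Smallest p-value we report; keeps p in the open interval (0, 1] even for |z| ~ 40.
P_FLOOR = 1e-300


def two_sided_p(z):
    """Two-sided normal p-value for a z-score (scalar or array), floored away from 0."""
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.maximum(p, P_FLOOR)


def normal_ci(theta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    q = stats.norm.ppf(0.5 + level / 2.0)
    return theta - q * se, theta + q * se


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
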