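"""Small shared statistics helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

#: smallest positive subnormal double; keeps p-values in (0, 1]
_TINY = np.nextafter(0.0, 1.0)


def normal_two_sided_p(z):
    """Two-sided standard-normal tail probability of |z|, clipped into (0, 1]."""
    p = 2.0 * _st.norm.sf(np.abs(z))
    return np.clip(p, _TINY, 1.0)
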