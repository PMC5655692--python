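"""Unit conventions.

Internal units throughout the package: kPa for stress and energy density,
mm for length, mN for force (kPa * mm^2 = mN, so forces stay consistent
without conversion factors).  Transmural pressures at the I/O boundary are
given in mmHg, the unit used by pressure transducers, and converted here.
"""

from __future__ import annotations

import numpy as np

#: Conversion factor: 1 mmHg = 0.1333224 kPa (standard gravity, 0 degC Hg).
KPA_PER_MMHG = 0.1333224


def mmhg_to_kpa(p):
    """Convert transmural pressure from mmHg to kPa."""
    return np.asarray(p, dtype=float) * KPA_PER_MMHG


def kpa_to_mmhg(p):
    """Convert pressure from kPa back to mmHg (inverse of :func:`mmhg_to_kpa`)."""
    return np.asarray(p, dtype=float) / KPA_PER_MMHG
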