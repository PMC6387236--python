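"""Bundled reference data: the 83-participant cohort transition counts.

These are the posture-transition contingency tables observed in the
original 83-participant Stroop-test cohort recorded with the sensorized
chair. Rows are the posture in the earlier interval, columns the posture
in the later interval, in order P1..P8. They serve both as the reference
against which the statistics are validated and as the margins from which
:func:`seatpose.simulate.generate_fixture_cohort` reconstructs an exact
synthetic cohort.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cohort_ti1_ti2", "cohort_ti2_ti3", "COHORT_N"]

COHORT_N = 83

# TI1 (rows) -> TI2 (columns) transition counts.
_TI1_TI2 = (
    (31, 2, 1, 0, 0, 9, 2, 3),
    (0, 1, 0, 1, 0, 1, 0, 0),
    (2, 0, 1, 0, 0, 1, 0, 1),
    (0, 1, 0, 0, 0, 0, 0, 0),
    (1, 0, 0, 0, 1, 0, 0, 0),
    (3, 0, 0, 0, 0, 2, 0, 1),
    (0, 1, 0, 0, 0, 3, 0, 2),
    (7, 1, 0, 0, 0, 1, 0, 3),
)

# TI2 (rows) -> TI3 (columns) transition counts.
_TI2_TI3 = (
    (14, 0, 0, 1, 0, 21, 1, 7),
    (1, 0, 0, 1, 0, 2, 2, 0),
    (1, 1, 0, 0, 0, 0, 0, 0),
    (0, 0, 0, 0, 0, 1, 0, 0),
    (1, 0, 0, 0, 0, 0, 0, 0),
    (4, 0, 0, 0, 0, 6, 0, 7),
    (0, 0, 0, 0, 0, 0, 1, 1),
    (4, 1, 0, 1, 0, 1, 1, 2),
)


def cohort_ti1_ti2() -> np.ndarray:
    """8x8 TI1->TI2 transition counts of the reference cohort (N=83)."""
    return np.array(_TI1_TI2, dtype=int)


def cohort_ti2_ti3() -> np.ndarray:
    """8x8 TI2->TI3 transition counts of the reference cohort (N=83)."""
    return np.array(_TI2_TI3, dtype=int)
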