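"""Agreement metrics between two sets of recovery curves.

Given a reference set (e.g. physical measurements) and a test set
(e.g. simulations) indexed by the same configurations j = 1..J, two
per-diameter metrics quantify agreement:

    delta(d) = (1/J) sum_j |RC_ref,j(d) - RC_test,j(d)|
    Delta(d) = (1/J) sum_j |RC_ref,j(d) - mean_ref(d)|

delta measures reference-vs-test deviation; Delta measures the spread
of the reference curves around their own mean and depends only on the
reference set.  delta < Delta means the test set tracks each
configuration better than a single averaged curve would.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rc_curve import RCFitResult, evaluate_fit

#: The six sphere arrangements used for the physical validation
#: measurements: a Standard pattern (each large sphere flanked by small
#: ones, as proposed for accreditation) and a Switch pattern (diameters
#: ascending clockwise), each with the whole insert rotated by 0, 120
#: and 210 degrees.  The 210-degree variants include an extra 30-degree
#: offset of the insert, so they fall between ring positions and are not
#: members of the 720 on-grid permutations.
_STANDARD = (60.0, 13.0, 28.0, 22.0, 37.0, 17.0)
_SWITCH = (13.0, 17.0, 22.0, 28.0, 37.0, 60.0)


def _rotate(assignment: tuple[float, ...], positions: int) -> tuple[float, ...]:
    return assignment[-positions:] + assignment[:-positions]


MEASUREMENT_CONFIGURATIONS: dict[str, dict] = {
    "Standard_0": dict(assignment=_STANDARD, rotation_deg=0, on_grid=True),
    "Standard_120": dict(assignment=_rotate(_STANDARD, 2), rotation_deg=120, on_grid=True),
    "Standard_210": dict(assignment=_rotate(_STANDARD, 3), rotation_deg=210, on_grid=False),
    "Switch_0": dict(assignment=_SWITCH, rotation_deg=0, on_grid=True),
    "Switch_120": dict(assignment=_rotate(_SWITCH, 2), rotation_deg=120, on_grid=True),
    "Switch_210": dict(assignment=_rotate(_SWITCH, 3), rotation_deg=210, on_grid=False),
}


def delta_metrics(
    reference_set: Mapping[str, Sequence[float]],
    test_set: Mapping[str, Sequence[float]],
    diameters_mm: Sequence[float],
) -> pd.DataFrame:
    """Per-diameter delta/Delta metrics over matched configurations.

    Both mappings must carry identical configuration keys; values are RC
    arrays evaluated at ``diameters_mm`` (raw per-sphere RCs or fitted
    curves sampled at the sphere diameters).
    """
    if set(reference_set) != set(test_set):
        raise ValueError("reference and test sets must share configuration keys")
    keys = sorted(reference_set)
    d = np.asarray(diameters_mm, dtype=float)
    ref = np.array([np.asarray(reference_set[k], dtype=float) for k in keys])
    tst = np.array([np.asarray(test_set[k], dtype=float) for k in keys])
    if ref.shape != (len(keys), d.size) or tst.shape != ref.shape:
        raise ValueError("each configuration needs one RC per diameter")
    mean_ref = ref.mean(axis=0)
    delta = np.abs(ref - tst).mean(axis=0)
    big_delta = np.abs(ref - mean_ref).mean(axis=0)
    return pd.DataFrame(
        dict(
            diameter_mm=d,
            delta=delta,
            Delta=big_delta,
            mean_reference_rc=mean_ref,
        )
    )


def curves_from_fits(
    fits: Mapping[str, RCFitResult], diameters_mm: Sequence[float]
) -> dict[str, np.ndarray]:
    """Evaluate fitted recovery curves at the sphere diameters (mm)."""
    d_cm = np.asarray(diameters_mm, dtype=float) / 10.0
    return {k: evaluate_fit(f, d_cm) for k, f in fits.items()}
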