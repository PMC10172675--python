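"""Derive the frozen threshold calibration of the default AUDIT item bank.

The default banks in ``normforge.simulate`` are parameterized as a base
layout (discriminations, first thresholds, threshold gaps) plus two scalar
knobs for the AUDIT-like bank: a common threshold shift and a common gap
scale.  This script solves those two knobs so that the model-implied total
score distribution (Lord-Wingersky likelihoods integrated over a
standard-normal trait on a fine grid) satisfies

    P(total = 0)  = 0.34
    P(total <= 6) = 0.90

and prints the solution, which is frozen into ``_BANK_LAYOUTS``.  Re-running
the script reproduces the constants; the package never re-tunes at run time.

Usage:  python scripts/calibrate_banks.py
"""

import numpy as np
from scipy.optimize import fsolve

from normforge.grm import GRMParams, default_grid, sumscore_likelihoods
from normforge.simulate import _BANK_LAYOUTS

GRID = default_grid(201, 8.0)


def audit_marginals(shift: float, gap_scale: float) -> tuple[float, float]:
    layout = _BANK_LAYOUTS["AUDIT"]
    b = []
    for first, g in zip(layout["b1"], layout["gaps"]):
        cum = np.concatenate([[0.0], np.cumsum(np.asarray(g) * gap_scale)])
        b.append(first + shift + cum)
    params = GRMParams(
        [f"audit{i}" for i in range(1, 11)], np.asarray(layout["a"]), b
    )
    p = sumscore_likelihoods(params, GRID) @ GRID.weights
    return float(p[0]), float(p[: 7].sum())


def objective(x):
    p0, p6 = audit_marginals(x[0], x[1])
    return [p0 - 0.34, p6 - 0.90]


if __name__ == "__main__":
    sol = fsolve(objective, [0.0, 1.0], full_output=False, xtol=1e-12)
    shift, gap_scale = float(sol[0]), float(sol[1])
    p0, p6 = audit_marginals(shift, gap_scale)
    print(f"shift     = {shift:.10f}")
    print(f"gap_scale = {gap_scale:.10f}")
    print(f"P(total=0)  = {p0:.6f}  (target 0.34)")
    print(f"P(total<=6) = {p6:.6f}  (target 0.90)")
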