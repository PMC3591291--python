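"""Sigmoidality of signal-response curves and parameter sweeps.

Ultrasensitivity is quantified by the sigmoidality index

    RS = k5s * s_max

where ``s_max`` is the maximum slope of the steady-state response against
the signal k5 and ``k5s`` the signal level at which that slope occurs.
A hyperbolic (Michaelis-type) curve has its steepest slope at the origin
and RS near 0; sigmoidal curves place the steep region at finite signal
and score higher, so RS separates hyperbolic from switch-like responses
better than slope alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .network import ReactionNetwork, build_basic_network
from .parameters import ParameterSet
from .response import SignalResponseCurve, scan_signal_response


@dataclass(frozen=True)
class SigmoidalityReport:
    """RS metric and supporting quantities for one signal-response curve.

    ``rs`` is computed on the normalized response (dimensionless), so
    values are comparable across parameter sets; ``rs_uM`` is the same
    quantity on the µM response scale (= rs * response_total).  On
    bistable curves the slope is taken along the ascending sweep and the
    fold makes the underlying true slope unbounded, so ``bistable`` is the
    headline result there, not the RS value.
    """

    rs: float
    s_max: float                 # max d(normalized response)/d k5, 1/(1/s)
    k5s: float                   # signal at max slope, 1/s
    max_response_uM: float
    max_response_norm: float
    bistable: bool
    response_total: float

    @property
    def rs_uM(self) -> float:
        return self.rs * self.response_total


def _sigmoidality_xy(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """(RS, s_max, k5s) from a sampled curve by central differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 50:
        raise ValueError("curve must have at least 50 points")
    if np.any(~np.isfinite(y)):
        raise ValueError("curve has gaps (non-finite response)")
    slope = np.gradient(y, x)
    i = int(np.argmax(slope))
    s_max = float(slope[i])
    k5s = float(x[i])
    # quadratic refinement of the slope maximum between grid points
    if 0 < i < len(x) - 1:
        xs, ss = x[i - 1: i + 2], slope[i - 1: i + 2]
        span = xs[2] - xs[0]
        if span > 0 and len(set(xs.tolist())) == 3:
            u = (xs - xs[1]) / span  # centered/scaled for conditioning
            V = np.vander(u, 3)      # exact parabola through the 3 points
            coef = np.linalg.solve(V, ss)
            if coef[0] < 0:
                uv = -coef[1] / (2 * coef[0])
                if u[0] <= uv <= u[2]:
                    k5s = float(xs[1] + uv * span)
                    s_max = float(np.polyval(coef, uv))
    return k5s * s_max, s_max, k5s


def sigmoidality(curve, normalized: bool = True) -> SigmoidalityReport:
    """Sigmoidality report for a traced or analytic signal-response curve.

    Accepts a :class:`~splitkinase.response.SignalResponseCurve` (slope on
    the ascending sweep) or any object exposing ``x``/``response`` arrays
    (e.g. the analytic reference curves of the synthetic-data module).
    """
    if isinstance(curve, SignalResponseCurve):
        if curve.gaps:
            raise ValueError(f"curve has sweep gaps at k5={curve.gaps}")
        x = curve.k5
        total = curve.response_total
        y_uM = curve.response_up
        bistable = curve.bistable
    else:
        x = np.asarray(curve.x, dtype=float)
        y_uM = np.asarray(curve.response, dtype=float)
        total = float(getattr(curve, "total", 1.0))
        bistable = bool(getattr(curve, "bistable", False))
    y = y_uM / total if normalized else y_uM
    rs, s_max, k5s = _sigmoidality_xy(x, y)
    if not normalized:
        # report stores the normalized-scale values by convention
        rs, s_max = rs / total, s_max / total
    return SigmoidalityReport(
        rs=rs, s_max=s_max, k5s=k5s,
        max_response_uM=float(np.max(y_uM)),
        max_response_norm=float(np.max(y_uM) / total),
        bistable=bistable,
        response_total=total,
    )


def log_ratio_grid(decades: float = 1.0, n: int = 13) -> np.ndarray:
    """Log-spaced ratio grid symmetric around 1 (13 points per sweep)."""
    return np.logspace(-decades, decades, n)


def parameter_sweep(
    base: ParameterSet,
    target: str,
    ratio_grid: Optional[Sequence[float]] = None,
    network: Optional[ReactionNetwork] = None,
    k5_range: Tuple[float, float] = (0.0, 10.0),
    n_points: int = 150,
    **scan_kwargs,
) -> pd.DataFrame:
    """RS and max-response ratios as one parameter is scaled from base.

    One full signal-response scan per ratio; ratios are relative to the
    base (literature) value of ``target``.  A failed scan flags its row
    (NaN ratios) and the sweep continues.  Columns:
    ``parameter, ratio, RS, RS_ratio, max_response_ratio, bistable``.
    """
    allowed = {f"k{i}" for i in range(1, 12)} | {"A3_tot", "A4_tot"}
    if target not in allowed:
        raise ValueError(f"target must be one of {sorted(allowed)}, got {target!r}")
    if ratio_grid is None:
        ratio_grid = np.logspace(-1, 1, 13)
    ratio_grid = np.asarray(ratio_grid, dtype=float)
    if np.any(ratio_grid <= 0):
        raise ValueError("ratios must be > 0")
    if network is None:
        network = build_basic_network(base)

    def one(ratio: float):
        params = base.scaled(target, ratio)
        curve = scan_signal_response(network, params, k5_range, n_points, **scan_kwargs)
        return sigmoidality(curve)

    base_rep = one(1.0)
    rows = []
    for r in ratio_grid:
        try:
            rep = one(float(r)) if r != 1.0 else base_rep
            rows.append({
                "parameter": target, "ratio": float(r),
                "RS": rep.rs, "RS_ratio": rep.rs / base_rep.rs,
                "max_response_ratio": rep.max_response_uM / base_rep.max_response_uM,
                "bistable": rep.bistable, "failed": False,
            })
        except Exception:
            rows.append({
                "parameter": target, "ratio": float(r),
                "RS": np.nan, "RS_ratio": np.nan,
                "max_response_ratio": np.nan, "bistable": False, "failed": True,
            })
    return pd.DataFrame(rows)
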