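"""Seeded synthetic data: decay panels and analytic reference curves.

The decay generator emulates phosphorimaging time courses of the in
vitro CheY6-P dephosphorylation assay: per-CheA4-condition decay curves
sampled at discrete times, perturbed by multiplicative log-normal noise
(band intensities are positive and their error roughly proportional to
signal).  Ground-truth parameters are recorded in the dataset metadata so
recovery tests can close the loop without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .invitro import AssayDataset, DEFAULT_A4_PANEL, simulate_assay
from .parameters import ParameterSet

NOISE_KINDS = ("none", "multiplicative_lognormal", "additive_gaussian")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for synthetic phosphorimaging data."""

    kind: str = "multiplicative_lognormal"
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"kind must be one of {NOISE_KINDS}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "none" or self.sigma == 0.0:
            return values.copy()
        rng = np.random.default_rng(self.seed)
        if self.kind == "multiplicative_lognormal":
            return values * rng.lognormal(0.0, self.sigma, size=values.shape)
        return np.maximum(values + rng.normal(0.0, self.sigma, size=values.shape), 0.0)


def gen_decay_dataset(
    true_params: Optional[ParameterSet] = None,
    A4_panel: Sequence[float] = DEFAULT_A4_PANEL,
    t_grid: Optional[Sequence[float]] = None,
    noise: NoiseModel = NoiseModel(kind="none", sigma=0.0),
) -> AssayDataset:
    """Simulated assay panel with seeded measurement noise.

    With ``sigma=0`` the output equals :func:`simulate_assay` exactly;
    the same seed always yields the same dataset.
    """
    if true_params is None:
        true_params = ParameterSet()
    ds = simulate_assay(true_params, A4_panel=A4_panel, t_grid=t_grid)
    noisy = ds.frame.copy()
    noisy["Y6p_signal"] = noise.apply(noisy["Y6p_signal"].to_numpy())
    meta = dict(ds.metadata)
    meta["noise"] = {"kind": noise.kind, "sigma": noise.sigma, "seed": noise.seed}
    meta["ground_truth"] = {k: true_params[k] for k in ("k9", "k10", "k11")}
    return AssayDataset(frame=noisy, metadata=meta)


@dataclass
class ReferenceCurve:
    """Analytic signal-response-like table for exercising the RS metric."""

    x: np.ndarray
    response: np.ndarray
    total: float = 1.0
    bistable: bool = False
    shape: str = "hill"
    params: dict = field(default_factory=dict)


def gen_reference_curve(
    shape: str,
    grid: Optional[Sequence[float]] = None,
    n: float = 1.0,
    K: float = 1.0,
    slope: float = 1.0,
    x0: float = 1.0,
    width: float = 0.1,
    amplitude: float = 1.0,
) -> ReferenceCurve:
    """Exact analytic curve on a grid.

    shapes: ``hill`` — amplitude * x^n/(K^n + x^n); ``linear`` —
    slope * x; ``step`` — a logistic step at ``x0`` with transition
    ``width`` (RS grows without bound as width shrinks).
    """
    if grid is None:
        grid = np.linspace(0.0, 10.0 * K if shape == "hill" else 10.0, 2001)
    x = np.asarray(grid, dtype=float)
    if shape == "hill":
        with np.errstate(divide="ignore", invalid="ignore"):
            y = amplitude * x ** n / (K ** n + x ** n)
        y = np.nan_to_num(y, nan=0.0)
    elif shape == "linear":
        y = slope * x
    elif shape == "step":
        y = amplitude / (1.0 + np.exp(-(x - x0) / width))
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return ReferenceCurve(
        x=x, response=y, total=1.0, shape=shape,
        params={"n": n, "K": K, "slope": slope, "x0": x0, "width": width,
                "amplitude": amplitude},
    )
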