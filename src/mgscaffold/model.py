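"""Isotropic strut-degradation model.

A rectangular strut cross-section (width ``w``, thickness ``h``) recedes at a
constant rate ``k`` (mm/month) on every exposed face, so after ``t`` months the
remaining cross-sectional area fraction is

    f(t) = (1 - 2kt/w) (1 - 2kt/h),   clamped to 0 once a side is consumed.

Because strut length greatly exceeds its cross-section, end losses are
neglected and f(t) doubles as the remaining *volume* fraction.  For a square
strut (w == h) the fraction is (1 - t/T)^2 with complete-degradation period
T = w / (2k), and the 50% point is t50 = T (1 - 1/sqrt(2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "DegradationModelParams",
    "ScenarioCurve",
    "ModelFit",
    "ModelError",
    "area_fraction",
    "k_from_loss_at_1m",
    "t_complete",
    "t50",
    "simulate_scenarios",
    "fit_t_complete",
    "best_scenario",
    "DEFAULT_SCENARIO_LOSSES",
    "DEFAULT_FIT_TIMES",
]

DEFAULT_SCENARIO_LOSSES: tuple[float, ...] = (5.0, 7.5, 10.0)
DEFAULT_FIT_TIMES: tuple[float, ...] = (1.0, 6.0, 12.0, 18.0)


class ModelError(ValueError):
    """Invalid model parameters or unidentifiable fit."""


@dataclass(frozen=True)
class DegradationModelParams:
    """Strut cross-section and per-face recession rate."""

    w: float = 0.1  # strut width, mm
    h: float = 0.1  # strut thickness, mm
    k: float = 0.0  # recession rate per exposed face, mm/month

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ModelError(f"strut sides must be > 0 (w={self.w}, h={self.h})")
        if self.k < 0:
            raise ModelError(f"recession rate k must be >= 0, got {self.k}")

    @property
    def is_square(self) -> bool:
        return math.isclose(self.w, self.h, rel_tol=1e-12)


def area_fraction(t, params: DegradationModelParams):
    """Remaining cross-sectional area (== volume) fraction at time ``t`` months.

    Accepts scalars or arrays; the product is clamped at 0 once either side
    is fully consumed.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ModelError("time must be >= 0")
    fw = np.clip(1.0 - 2.0 * params.k * t / params.w, 0.0, None)
    fh = np.clip(1.0 - 2.0 * params.k * t / params.h, 0.0, None)
    out = fw * fh
    return float(out) if out.ndim == 0 else out


def k_from_loss_at_1m(loss_percent: float, w: float = 0.1, h: float = 0.1) -> float:
    """Recession rate giving ``loss_percent`` area loss at 1 month.

    Square case in closed form: k = s (1 - sqrt(1 - loss/100)) / 2.
    Rectangular case: smaller root of the quadratic
    (1 - 2k/w)(1 - 2k/h) = 1 - loss/100.
    """
    if not (0.0 <= loss_percent <= 100.0):
        raise ModelError(f"loss_percent must be in [0, 100], got {loss_percent}")
    frac = 1.0 - loss_percent / 100.0
    if math.isclose(w, h, rel_tol=1e-12):
        return w * (1.0 - math.sqrt(frac)) / 2.0
    # 4k^2/(wh) - 2k(1/w + 1/h) + (1 - frac) = 0 ; physical root is the smaller
    a = 4.0 / (w * h)
    b = -2.0 * (1.0 / w + 1.0 / h)
    c = 1.0 - frac
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ModelError("no real recession rate for the requested loss")
    return (-b - math.sqrt(disc)) / (2.0 * a)


def t_complete(params: DegradationModelParams) -> float:
    """Complete-degradation period min(w, h) / (2k), months."""
    if params.k == 0:
        raise ModelError("k = 0: strut never degrades (infinite lifetime)")
    return min(params.w, params.h) / (2.0 * params.k)


def t50(params: DegradationModelParams) -> float:
    """Time at which the remaining fraction reaches 0.5.

    Square struts use the closed form T (1 - 1/sqrt(2)); rectangular struts
    solve area_fraction(t) = 0.5 by bracketed root finding.
    """
    tc = t_complete(params)  # validates k > 0
    if params.is_square:
        return tc * (1.0 - 1.0 / math.sqrt(2.0))
    return brentq(lambda t: area_fraction(t, params) - 0.5, 0.0, tc)


@dataclass(frozen=True)
class ScenarioCurve:
    """Remaining-volume curve for one assumed area loss at 1 month."""

    loss_at_1m: float  # percent cross-sectional area lost at t = 1 month
    k: float
    times: np.ndarray
    fractions: np.ndarray

    @property
    def t_complete(self) -> float:
        return t_complete(DegradationModelParams(w=0.1, h=0.1, k=self.k))


def simulate_scenarios(
    losses: Iterable[float] = DEFAULT_SCENARIO_LOSSES,
    times: Sequence[float] | np.ndarray = None,
    w: float = 0.1,
    h: float = 0.1,
) -> list[ScenarioCurve]:
    """One remaining-volume curve per assumed percentage loss at 1 month."""
    if times is None:
        times = np.linspace(0.0, 30.0, 301)
    times = np.asarray(times, dtype=float)
    curves = []
    for loss in losses:
        k = k_from_loss_at_1m(loss, w, h)
        params = DegradationModelParams(w=w, h=h, k=k)
        curves.append(
            ScenarioCurve(
                loss_at_1m=float(loss),
                k=k,
                times=times,
                fractions=area_fraction(times, params),
            )
        )
    return curves


@dataclass(frozen=True)
class ModelFit:
    """Least-squares fit of the square-strut law to observed fractions."""

    t_fit: float  # complete-degradation period, months
    residual_ss: float
    t50: float
    implied_loss_at_1m: float  # percent

    @property
    def t50_rounded(self) -> int:
        return int(round(self.t50))

    def to_dict(self) -> dict:
        return {
            "t_complete_months": self.t_fit,
            "t50_months": self.t50,
            "t50_months_rounded": self.t50_rounded,
            "implied_loss_at_1m_percent": self.implied_loss_at_1m,
            "residual_ss": self.residual_ss,
        }


def _square_fraction(t: np.ndarray, T: float) -> np.ndarray:
    return np.clip(1.0 - t / T, 0.0, None) ** 2


def fit_t_complete(observations: Sequence[tuple[float, float]]) -> ModelFit:
    """Fit f(t) = max(0, 1 - t/T)^2 to (time, remaining fraction) pairs.

    Bounded scalar least squares over T > 0.
    """
    obs = np.asarray(list(observations), dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2 or obs.shape[0] < 2:
        raise ModelError("need at least two (time, fraction) observations")
    t, y = obs[:, 0], obs[:, 1]
    if np.unique(t).size < 2:
        raise ModelError("observations must cover at least two distinct times")
    if np.all(y <= 0):
        raise ModelError("all fractions are zero: T is unidentifiable")

    t_hi = 50.0 * float(t.max())

    def sse(T: float) -> float:
        return float(np.sum((_square_fraction(t, T) - y) ** 2))

    res = minimize_scalar(sse, bounds=(1e-6, t_hi), method="bounded",
                          options={"xatol": 1e-8})
    T = float(res.x)
    params = DegradationModelParams(w=0.1, h=0.1, k=0.1 / (2.0 * T))
    return ModelFit(
        t_fit=T,
        residual_ss=float(res.fun),
        t50=t50(params),
        implied_loss_at_1m=100.0 * (1.0 - float(_square_fraction(np.asarray(1.0), T))),
    )


def plot_scenarios(
    path,
    reference_T: float | None = None,
    observations: "Sequence[tuple[float, float]] | None" = None,
    losses: Iterable[float] = DEFAULT_SCENARIO_LOSSES,
    w: float = 0.1,
    h: float = 0.1,
):
    """Save a remaining-volume-ratio figure: scenario curves, an optional
    fitted model curve, and optional observed points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.linspace(0.0, 30.0, 601)
    fig, ax = plt.subplots(figsize=(5.5, 4))
    styles = [":", "--", "-."]
    for loss, style in zip(losses, styles * 3):
        k = k_from_loss_at_1m(loss, w, h)
        frac = area_fraction(t, DegradationModelParams(w=w, h=h, k=k))
        ax.plot(t, 100 * frac, style, label=f"{loss:g}% loss at 1 M")
    if reference_T is not None:
        ax.plot(t, 100 * _square_fraction(t, reference_T), "-",
                label=f"fit, T = {reference_T:.1f} M")
    if observations:
        obs = np.asarray(list(observations), dtype=float)
        ax.plot(obs[:, 0], 100 * obs[:, 1], "ko", label="observed")
    ax.set_xlabel("implantation period (months)")
    ax.set_ylabel("remaining volume ratio (%)")
    ax.set_ylim(0, 105)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def best_scenario(
    reference: "ModelFit | float",
    losses: Iterable[float] = DEFAULT_SCENARIO_LOSSES,
    times: Sequence[float] = DEFAULT_FIT_TIMES,
    w: float = 0.1,
    h: float = 0.1,
) -> float:
    """Loss percentage whose scenario curve is closest (SSE at ``times``)
    to the square-strut reference curve.

    ``reference`` is a :class:`ModelFit` or a complete-degradation period in
    months.  Ties return the smaller loss.
    """
    T = reference.t_fit if isinstance(reference, ModelFit) else float(reference)
    if T <= 0:
        raise ModelError(f"reference period must be > 0, got {T}")
    times = np.asarray(times, dtype=float)
    ref = _square_fraction(times, T)
    losses = sorted(float(x) for x in losses)
    if not losses:
        raise ModelError("no scenario losses supplied")
    best_loss, best_sse = None, np.inf
    for loss in losses:
        k = k_from_loss_at_1m(loss, w, h)
        frac = area_fraction(times, DegradationModelParams(w=w, h=h, k=k))
        s = float(np.sum((frac - ref) ** 2))
        if s < best_sse - 1e-15:
            best_loss, best_sse = loss, s
    return best_loss
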