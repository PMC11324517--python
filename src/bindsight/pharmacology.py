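"""Dose-response and kinetics models for transporter assays.

Implements the four fitted models used in radiotracer uptake/binding
experiments on the dopamine transporter, with the assay preprocessing
that precedes them:

* Michaelis–Menten uptake kinetics, v = Vmax·S / (Km + S);
* single-site saturation binding, B = Bmax·L / (Kd + L);
* normalized Hill inhibition, y = 100 / (1 + (x/IC50)^h);
* variable Hill inhibition, y = bottom + (top − bottom) / (1 + (x/IC50)^h);
* background subtraction and 100%-of-control normalisation;
* the free-Zn²⁺ bookkeeping (EDTA-washed control → 0; otherwise the
  added concentration plus ~100 nM ambient Zn²⁺ from the assay buffer).

Concentration parameters (Km, Kd, IC50) are fitted on a log scale with a
small multi-start over the concentration quartiles; standard errors come
from the Jacobian at the optimum (delta method back to linear scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseDataset",
    "KineticFit",
    "BindingFit",
    "InhibitionFit",
    "subtract_background_normalize",
    "michaelis_menten_fit",
    "saturation_binding_fit",
    "hill_inhibition_fit",
    "free_zn_concentration",
    "ic50_fold_change",
    "confidence_interval",
    "michaelis_menten",
    "single_site_binding",
    "hill_normalized",
    "hill_variable",
]

AMBIENT_ZN_UM = 0.1  # ~100 nM ambient Zn2+ measured in the uptake buffer


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def michaelis_menten(s: np.ndarray, km: float, vmax: float) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def single_site_binding(l: np.ndarray, kd: float, bmax: float) -> np.ndarray:
    l = np.asarray(l, dtype=float)
    return bmax * l / (kd + l)


def hill_normalized(x: np.ndarray, ic50: float, hill: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return 100.0 / (1.0 + (x / ic50) ** hill)


def hill_variable(
    x: np.ndarray, ic50: float, hill: float, top: float, bottom: float
) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


# ---------------------------------------------------------------------------
# data container & preprocessing
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseDataset:
    """Concentration–response replicates with matched background wells.

    ``y`` has shape (n_concentrations, n_replicates).  ``background``
    holds raw background replicates (e.g. wells with a saturating
    competitor) in the same units as ``y``.
    """

    x: np.ndarray
    y: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.zeros(0))
    unit: str = "uM"
    condition: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.y.shape[0] != self.x.shape[0]:
            if self.y.shape[1] == self.x.shape[0]:
                self.y = self.y.T
            else:
                raise ValueError("y rows must align with x")
        self.background = np.asarray(self.background, dtype=float)

    @property
    def y_mean(self) -> np.ndarray:
        return self.y.mean(axis=1)


def subtract_background_normalize(
    d: DoseResponseDataset,
    control: float | str = "min_x",
) -> DoseResponseDataset:
    """Background-subtract and scale so the control point reads 100%.

    ``specific = total − mean(background)``; the control row (the lowest
    inhibitor concentration by default, or an explicit concentration)
    defines 100%, mirroring the assay convention of setting activity at a
    vanishing inhibitor dose to 100%.
    """
    bg = float(d.background.mean()) if d.background.size else 0.0
    specific = d.y - bg
    if control == "min_x":
        ctrl_idx = int(np.argmin(d.x))
    else:
        matches = np.nonzero(np.isclose(d.x, float(control)))[0]
        if matches.size == 0:
            raise ValueError(f"control concentration {control} not in dataset")
        ctrl_idx = int(matches[0])
    ctrl_mean = float(specific[ctrl_idx].mean())
    if ctrl_mean <= 0:
        raise ValueError("control mean is non-positive after background subtraction")
    percent = 100.0 * specific / ctrl_mean
    return DoseResponseDataset(
        x=d.x.copy(),
        y=percent,
        background=np.zeros(0),
        unit=d.unit,
        condition=d.condition,
    )


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------

def _fit_log_conc(
    x: np.ndarray,
    y: np.ndarray,
    predict: Callable[[np.ndarray, np.ndarray], np.ndarray],
    starts: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Multi-start trust-region least squares.

    ``predict(theta, x)`` evaluates the model; components of ``theta``
    that represent concentrations are passed already log-transformed by
    the caller's ``predict``.  Returns (theta_hat, se(theta_hat), info).
    """
    best = None
    for theta0 in starts:
        try:
            res = least_squares(
                lambda th: predict(th, x) - y, theta0, method="trf", x_scale="jac"
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise RuntimeError("nonlinear fit did not converge")
    resid = best.fun
    dof = max(len(y) - len(best.x), 1)
    s2 = float(resid @ resid) / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(best.x), np.nan)
    info = {
        "cost": float(best.cost),
        "n_points": len(y),
        "n_params": len(best.x),
        "success": bool(best.success),
    }
    return best.x, se, info


def confidence_interval(
    estimate: float, se: float, n_points: int, n_params: int, level: float = 0.95
) -> tuple[float, float]:
    """Nominal Wald interval with the Student-t quantile at the fit's dof."""
    from scipy import stats

    dof = max(n_points - n_params, 1)
    tq = float(stats.t.ppf(0.5 + level / 2.0, dof))
    return estimate - tq * se, estimate + tq * se


def _prepare_xy(
    x: np.ndarray, y: np.ndarray, replicate_means: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 2:
        if replicate_means:
            y = y.mean(axis=1)
        else:
            x = np.repeat(x, y.shape[1])
            y = y.ravel()
    return x, y


@dataclass(frozen=True)
class KineticFit:
    km: float
    vmax: float
    km_se: float
    vmax_se: float
    diagnostics: dict = field(default_factory=dict)


def michaelis_menten_fit(
    x: np.ndarray, v: np.ndarray, replicate_means: bool = True
) -> KineticFit:
    """Fit v = Vmax·S/(Km + S) by nonlinear least squares.

    Requires at least 3 distinct concentrations.  Km is fitted on the
    log scale (positivity is structural).
    """
    x, y = _prepare_xy(x, v, replicate_means)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.all(y == y[0]):
        raise ValueError("responses are all identical; model is degenerate")

    def predict(theta, xs):
        return michaelis_menten(xs, np.exp(theta[0]), theta[1])

    xs_pos = x[x > 0]
    starts = [
        np.array([np.log(q), float(y.max())])
        for q in np.quantile(xs_pos, [0.25, 0.5, 0.75])
    ] + [np.array([np.log(np.exp(np.mean(np.log(xs_pos)))), float(y.max())])]
    theta, se, info = _fit_log_conc(x, y, predict, starts)
    km = float(np.exp(theta[0]))
    if km <= 0 or theta[1] <= 0:
        raise RuntimeError("fit converged to non-positive parameters")
    return KineticFit(
        km=km,
        vmax=float(theta[1]),
        km_se=float(km * se[0]),  # delta method from log scale
        vmax_se=float(se[1]),
        diagnostics=info,
    )


@dataclass(frozen=True)
class BindingFit:
    kd: float
    bmax: float
    kd_se: float
    bmax_se: float
    diagnostics: dict = field(default_factory=dict)


def saturation_binding_fit(
    l: np.ndarray, b: np.ndarray, replicate_means: bool = True
) -> BindingFit:
    """Fit the single-site binding model B = Bmax·L/(Kd + L)."""
    x, y = _prepare_xy(l, b, replicate_means)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.allclose(y, 0.0):
        raise ValueError("all-zero signal; binding model is degenerate")

    def predict(theta, xs):
        return single_site_binding(xs, np.exp(theta[0]), theta[1])

    xs_pos = x[x > 0]
    starts = [
        np.array([np.log(q), float(y.max())])
        for q in np.quantile(xs_pos, [0.25, 0.5, 0.75])
    ]
    theta, se, info = _fit_log_conc(x, y, predict, starts)
    kd = float(np.exp(theta[0]))
    if kd <= 0:
        raise RuntimeError("fit converged to non-positive Kd")
    return BindingFit(
        kd=kd,
        bmax=float(theta[1]),
        kd_se=float(kd * se[0]),
        bmax_se=float(se[1]),
        diagnostics=info,
    )


@dataclass(frozen=True)
class InhibitionFit:
    ic50: float
    hill_slope: float
    top: float
    bottom: float
    ic50_se: float
    hill_se: float
    variant: str = "normalized"
    diagnostics: dict = field(default_factory=dict)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return hill_variable(x, self.ic50, self.hill_slope, self.top, self.bottom)


def hill_inhibition_fit(
    x: np.ndarray,
    y: np.ndarray,
    variant: str = "normalized",
    replicate_means: bool = True,
) -> InhibitionFit:
    """Fit the inhibition dose-response curve (two published variants).

    ``normalized``: y = 100/(1 + (x/IC50)^h), bottom fixed at 0 and top at
    100, so the fitted curve passes through 50% at x = IC50 by identity.
    ``variable``: y = bottom + (top − bottom)/(1 + (x/IC50)^h) with all
    four parameters free.  Note (x^h)/(IC50^h) ≡ (x/IC50)^h.
    """
    if variant not in ("normalized", "variable"):
        raise ValueError(f"unknown variant {variant!r}")
    x, yy = _prepare_xy(x, y, replicate_means)
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.all(yy == yy[0]):
        raise ValueError("responses are all identical; fit is degenerate")
    xs_pos = x[x > 0]
    qs = np.quantile(xs_pos, [0.25, 0.5, 0.75])

    if variant == "normalized":

        def predict(theta, xs):
            return hill_normalized(xs, np.exp(theta[0]), theta[1])

        starts = [np.array([np.log(q), 1.0]) for q in qs]
        theta, se, info = _fit_log_conc(x, yy, predict, starts)
        ic50 = float(np.exp(theta[0]))
        return InhibitionFit(
            ic50=ic50,
            hill_slope=float(theta[1]),
            top=100.0,
            bottom=0.0,
            ic50_se=float(ic50 * se[0]),
            hill_se=float(se[1]),
            variant=variant,
            diagnostics=info,
        )

    def predict(theta, xs):
        return hill_variable(xs, np.exp(theta[0]), theta[1], theta[2], theta[3])

    starts = [
        np.array([np.log(q), 1.0, float(yy.max()), float(yy.min())]) for q in qs
    ]
    theta, se, info = _fit_log_conc(x, yy, predict, starts)
    ic50 = float(np.exp(theta[0]))
    return InhibitionFit(
        ic50=ic50,
        hill_slope=float(theta[1]),
        top=float(theta[2]),
        bottom=float(theta[3]),
        ic50_se=float(ic50 * se[0]),
        hill_se=float(se[1]),
        variant=variant,
        diagnostics=info,
    )


def free_zn_concentration(added_um: float, edta_washed_control: bool = False) -> float:
    """Estimated free Zn²⁺ (µM) in the uptake buffer.

    The EDTA-washed zero-dose control is taken as 0 µM; every other
    condition carries ~100 nM ambient Zn²⁺ on top of the added amount.
    """
    if added_um < 0:
        raise ValueError("added concentration must be non-negative")
    if edta_washed_control:
        return 0.0
    return added_um + AMBIENT_ZN_UM


def ic50_fold_change(
    fit_a: InhibitionFit, fit_b: InhibitionFit
) -> tuple[float, float]:
    """IC50 ratio a/b with delta-method propagated standard error."""
    ratio = fit_a.ic50 / fit_b.ic50
    rel = np.sqrt(
        (fit_a.ic50_se / fit_a.ic50) ** 2 + (fit_b.ic50_se / fit_b.ic50) ** 2
    )
    return float(ratio), float(ratio * rel)
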