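"""C3 and C4 A-Ci photosynthesis curves and curve-based classification.

The C3 model is the Farquhar-von Caemmerer-Berry scheme under saturating
light: net assimilation is the minimum of the Rubisco-limited and
RuBP-regeneration-limited rates minus day respiration,

    Ac = Vcmax (Ci - G*) / (Ci + Kc (1 + O/Ko))
    Aj = J (Ci - G*) / (4 Ci + 8 G*),  J = Jmax
    A  = min(Ac, Aj) - Rd.

The C4 curve is a deliberately simplified two-regime enzyme-limited form:
PEP-carboxylation-limited at low Ci and Rubisco-capacity-limited once the
carbon-concentrating mechanism saturates,

    A = min(Vpmax Ci / (Ci + Kp), Vcmax) - Rd,

which reproduces the qualitative contrast of interest: a much steeper
initial slope and a far lower CO2 compensation point than the C3 curve.
Bundle-sheath leakiness is not modelled.

Ci is carried in ubar throughout; gas-exchange pressures in Pa convert as
1 Pa = 10 ubar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InsufficientRangeError, InvalidSpecError

#: Rubisco kinetics at 25 C (Kc, gamma* in ubar; Ko, O in mbar)
KC_DEFAULT = 404.0
KO_DEFAULT = 248.0
O_DEFAULT = 205.0
GAMMA_STAR_DEFAULT = 38.6

#: measurement pressures (Pa) commonly used for CO2 response curves
MEASUREMENT_PA = (25.0, 19.4, 16.6, 13.5, 7.6, 4.7, 36.7, 60.4, 140.3)
UBAR_PER_PA = 10.0


@dataclass(frozen=True)
class AciModelParams:
    """Photosynthesis model constants.

    Units: vcmax, jmax, rd, vpmax in umol m-2 s-1; kc, kp, gamma_star in
    ubar; ko and o in mbar.  ``rd`` defaults to 1 % of vcmax when omitted.
    """

    model: str
    vcmax: float
    jmax: float = float("nan")
    rd: float | None = None
    kc: float = KC_DEFAULT
    ko: float = KO_DEFAULT
    o: float = O_DEFAULT
    gamma_star: float = GAMMA_STAR_DEFAULT
    vpmax: float = 120.0
    kp: float = 80.0

    def __post_init__(self):
        if self.model not in ("C3", "C4"):
            raise InvalidSpecError("model must be 'C3' or 'C4'")
        if self.rd is None:
            object.__setattr__(self, "rd", 0.01 * self.vcmax)
        if self.vcmax <= 0 or self.rd < 0 or self.rd >= self.vcmax:
            raise InvalidSpecError("require 0 <= rd < vcmax and vcmax > 0")
        if self.model == "C3" and not self.jmax > 0:
            raise InvalidSpecError("C3 model requires jmax > 0")


def c3_defaults(**overrides) -> AciModelParams:
    """C3 parameters matched to a C3 panicoid leaf (Vcmax 77, Jmax 144)."""
    kw = dict(model="C3", vcmax=77.0, jmax=144.0)
    kw.update(overrides)
    return AciModelParams(**kw)


def c4_defaults(**overrides) -> AciModelParams:
    """C4 parameters with Vcmax 35 for comparable maximum rates."""
    kw = dict(model="C4", vcmax=35.0)
    kw.update(overrides)
    return AciModelParams(**kw)


def c3_assimilation(ci, p: AciModelParams):
    """C3 net assimilation at Ci (ubar); scalar or array.

    Returns ``(A, limiting)`` where limiting is 'rubisco' or
    'rubp-regeneration' per point.
    """
    ci_arr = np.asarray(ci, dtype=float)
    if (ci_arr <= 0).any():
        raise InvalidSpecError("ci must be positive")
    km = p.kc * (1.0 + p.o / p.ko)
    ac = p.vcmax * (ci_arr - p.gamma_star) / (ci_arr + km)
    aj = p.jmax * (ci_arr - p.gamma_star) / (4.0 * ci_arr + 8.0 * p.gamma_star)
    a = np.minimum(ac, aj) - p.rd
    limiting = np.where(ac <= aj, "rubisco", "rubp-regeneration")
    if np.isscalar(ci) or np.ndim(ci) == 0:
        return float(a), str(limiting.item() if limiting.ndim == 0 else limiting)
    return a, limiting


def c4_assimilation(ci, p: AciModelParams):
    """Simplified C4 net assimilation at Ci (ubar); scalar or array."""
    ci_arr = np.asarray(ci, dtype=float)
    if (ci_arr < 0).any():
        raise InvalidSpecError("ci must be non-negative")
    vp = p.vpmax * ci_arr / (ci_arr + p.kp)
    a = np.minimum(vp, p.vcmax) - p.rd
    limiting = np.where(vp <= p.vcmax, "pep-carboxylation", "rubisco")
    if np.isscalar(ci) or np.ndim(ci) == 0:
        return float(a), str(limiting.item() if limiting.ndim == 0 else limiting)
    return a, limiting


def assimilation(ci, p: AciModelParams):
    return (c3_assimilation if p.model == "C3" else c4_assimilation)(ci, p)


@dataclass
class AciCurve:
    """Modelled net assimilation along a Ci grid."""

    ci: np.ndarray
    a: np.ndarray
    limiting_process: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ci_ubar": self.ci, "a_umol": self.a, "limiting": self.limiting_process}
        )


def model_curve(ci_grid, p: AciModelParams) -> AciCurve:
    ci_arr = np.asarray(ci_grid, dtype=float)
    a, lim = assimilation(ci_arr, p)
    return AciCurve(ci_arr, a, lim)


def compensation_point(p: AciModelParams, hi: float = 200.0) -> float:
    """Ci (ubar) at which net assimilation crosses zero.

    Found by bracketing root search on (0, ``hi``) to 1e-3 ubar.
    """
    lo = 1e-6

    def f(ci):
        return assimilation(ci, p)[0]

    if f(lo) >= 0 or f(hi) <= 0:
        raise InvalidSpecError(
            f"no sign change on ({lo}, {hi}) ubar: cannot bracket the root"
        )
    return float(brentq(f, lo, hi, xtol=1e-3))


def c3_compensation_closed_form(p: AciModelParams) -> float:
    """Algebraic root of Ac - Rd = 0 (valid while Rubisco limits)."""
    km = p.kc * (1.0 + p.o / p.ko)
    frac = p.rd / p.vcmax
    return (p.gamma_star + km * frac) / (1.0 - frac)


def classify_observations(
    obs: pd.DataFrame,
    c3_params: AciModelParams | None = None,
    c4_params: AciModelParams | None = None,
) -> dict:
    """Classify an observed A-Ci table as C3 or C4 by model RMSE.

    ``obs`` needs columns ``ci_ubar`` and ``a_umol`` with at least four
    points spanning low and high Ci.  Both fixed-parameter model curves are
    evaluated on the observed Ci grid; the verdict is the model with the
    lower root-mean-square error.
    """
    c3_params = c3_params or c3_defaults()
    c4_params = c4_params or c4_defaults()
    ci = np.asarray(obs["ci_ubar"], dtype=float)
    a = np.asarray(obs["a_umol"], dtype=float)
    if len(ci) < 4:
        raise InsufficientRangeError("need at least 4 observation points")
    if ci.max() < 2.0 * ci.min() or ci.max() - ci.min() < 100.0:
        raise InsufficientRangeError(
            "observed Ci range too narrow to separate the models"
        )
    rmse = {}
    for name, p in (("C3", c3_params), ("C4", c4_params)):
        pred, _ = assimilation(ci, p)
        rmse[name] = float(np.sqrt(np.mean((pred - a) ** 2)))
    verdict = min(rmse, key=rmse.get)
    return {
        "verdict": verdict,
        "rmse": rmse,
        "margin": abs(rmse["C3"] - rmse["C4"]),
    }


def plot_aci(curves: dict, obs: pd.DataFrame | None = None, ax=None):
    """Plot modelled A-Ci curves (and optional observations)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        order = np.argsort(curve.ci)
        ax.plot(curve.ci[order], curve.a[order], label=label)
    if obs is not None:
        ax.scatter(obs["ci_ubar"], obs["a_umol"], marker="s", color="k",
                   label="observed")
    ax.set_xlabel("$C_i$ ($\\mu$bar)")
    ax.set_ylabel("$A$ ($\\mu$mol m$^{-2}$ s$^{-1}$)")
    ax.legend()
    return ax
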