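"""Four-parameter logistic (4PL) dose-response fits and resistance indices.

The viability model is

    response(d) = bottom + (top - bottom) / (1 + (d / ic50) ** hill)

fit by nonlinear least squares in log10-dose space with multi-start
initialization (hill in {0.5, 1, 2} crossed with a geometric IC50 grid over
the dose range; best residual sum of squares wins).  Vehicle wells (dose 0)
are excluded from the fit.  A fit whose IC50 lands outside
[min dose / 10, max dose * 10], or data with no dose-dependent inhibition at
all, is reported as a censored bound (e.g. "> max dose") rather than a point
estimate.

The Resistance Index is the ratio IC50(resistant) / IC50(parental) for the
same compound; censoring propagates through the ratio (bound / point = bound),
and opposing or double censoring flags the ratio as indeterminate.

:class:`FourPLRegressor` wraps the same fit as a scikit-learn estimator
(``fit(X, y)`` on dose/viability columns, fitted attributes ``ic50_`` etc.).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

MAX_ITER = 500
HILL_STARTS = (0.5, 1.0, 2.0)
N_IC50_STARTS = 5


@dataclass
class DoseResponseData:
    """Long-form viability measurements for one compound x sample."""

    compound: str
    sample_id: str
    doses: np.ndarray  # concentration, µM; 0 = vehicle
    responses: np.ndarray  # viability fraction, aligned with doses
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, float)
        self.responses = np.asarray(self.responses, float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must align")
        nz = np.unique(self.doses[self.doses > 0])
        if len(nz) < 4:
            raise ValueError("need >= 4 distinct non-zero doses")
        if np.any(self.responses < 0):
            raise ValueError("responses must be >= 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, compound: str, sample_id: str) -> "DoseResponseData":
        sub = df[(df["compound"] == compound) & (df["sample_id"] == sample_id)]
        return cls(compound, sample_id, sub["dose_uM"].to_numpy(),
                   sub["viability"].to_numpy(),
                   sub["replicate"].to_numpy() if "replicate" in sub else None)


@dataclass(frozen=True)
class FourPLFit:
    top: float
    bottom: float
    hill: float
    ic50: float  # µM; the censoring bound when censored
    rss: float
    converged: bool
    censored: str | None = None  # None | "gt" | "lt"

    def predict(self, doses) -> np.ndarray:
        d = np.asarray(doses, float)
        return four_pl(d, self.top, self.bottom, self.hill, self.ic50)

    def ic50_label(self) -> str:
        if self.censored == "gt":
            return f">{self.ic50:g}"
        if self.censored == "lt":
            return f"<{self.ic50:g}"
        return f"{self.ic50:g}"


@dataclass(frozen=True)
class ResistanceIndex:
    compound: str
    resistant_id: str
    parental_id: str
    ri: float
    censored: str | None = None  # None | "gt" | "lt"
    indeterminate: bool = False

    def label(self) -> str:
        if self.indeterminate:
            return "indeterminate"
        if self.censored == "gt":
            return f">{self.ri:g}"
        if self.censored == "lt":
            return f"<{self.ri:g}"
        return f"{self.ri:g}"


def four_pl(d: np.ndarray, top: float, bottom: float, hill: float, ic50: float) -> np.ndarray:
    d = np.asarray(d, float)
    out = np.full_like(d, top, dtype=float)
    pos = d > 0
    out[pos] = bottom + (top - bottom) / (1.0 + (d[pos] / ic50) ** hill)
    return out


def _model_log(logd: np.ndarray, top: float, bottom: float, log_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - log_ic50)))


def fit_4pl(data: DoseResponseData) -> FourPLFit:
    """Multi-start 4PL least-squares fit; censored bound when IC50 is unresolvable."""
    pos = data.doses > 0
    d = data.doses[pos]
    y = data.responses[pos]
    logd = np.log10(d)
    dmin, dmax = d.min(), d.max()

    # mean response per dose, used for initialization and the inhibition check
    order = np.argsort(d)
    uniq, inv = np.unique(d[order], return_inverse=True)
    means = np.bincount(inv, weights=y[order]) / np.bincount(inv)
    slope = np.polyfit(np.log10(uniq), means, 1)[0]
    if slope >= 0:
        # monotone non-decreasing with dose: no inhibition observable
        return FourPLFit(top=float(means.max()), bottom=float(means.max()),
                         hill=1.0, ic50=float(dmax), rss=float(np.sum((y - y.mean()) ** 2)),
                         converged=False, censored="gt")

    top0, bot0 = float(means.max()), float(means.min())
    lo = [-np.inf, -np.inf, np.log10(dmin) - 3.0, 0.05]
    hi = [np.inf, np.inf, np.log10(dmax) + 3.0, 20.0]

    best = None
    for hill0 in HILL_STARTS:
        for lic0 in np.linspace(np.log10(dmin), np.log10(dmax), N_IC50_STARTS):
            x0 = np.clip([top0, bot0, lic0, hill0],
                         [-1e12, -1e12, lo[2], lo[3]], [1e12, 1e12, hi[2], hi[3]])
            try:
                res = least_squares(
                    lambda p: _model_log(logd, *p) - y,
                    x0, bounds=(lo, hi), max_nfev=MAX_ITER,
                )
            except Exception:
                continue
            rss = float(np.sum(res.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, res)
    if best is None:
        return FourPLFit(top0, bot0, 1.0, float(dmax), np.inf, False, censored="gt")
    rss, res = best
    top, bottom, log_ic50, hill = res.x
    ic50 = float(10.0 ** log_ic50)
    if top < bottom:  # enforce bottom <= top by flipping the hill sign convention
        top, bottom, hill = bottom, top, -hill
    if ic50 > dmax * 10.0:
        return FourPLFit(float(top), float(bottom), float(hill), float(dmax),
                         rss, False, censored="gt")
    if ic50 < dmin / 10.0:
        return FourPLFit(float(top), float(bottom), float(hill), float(dmin),
                         rss, False, censored="lt")
    return FourPLFit(float(top), float(bottom), float(hill), ic50, rss, bool(res.success))


def resistance_index(fit_r: FourPLFit, fit_p: FourPLFit, compound: str = "",
                     resistant_id: str = "resistant", parental_id: str = "parental") -> ResistanceIndex:
    """RI = IC50(resistant) / IC50(parental); censoring propagates through the ratio."""
    ratio = fit_r.ic50 / fit_p.ic50
    cr, cp = fit_r.censored, fit_p.censored
    if cr is None and cp is None:
        return ResistanceIndex(compound, resistant_id, parental_id, float(ratio))
    if cr is not None and cp is not None:
        return ResistanceIndex(compound, resistant_id, parental_id, float(ratio),
                               indeterminate=True)
    if cr is not None:
        # bound / point keeps the bound's direction
        return ResistanceIndex(compound, resistant_id, parental_id, float(ratio), censored=cr)
    # point / bound flips the direction: point/(>b) < point/b
    flipped = "lt" if cp == "gt" else "gt"
    return ResistanceIndex(compound, resistant_id, parental_id, float(ratio), censored=flipped)


def resistance_index_from_ic50(ic50_resistant: float, ic50_parental: float,
                               compound: str = "") -> float:
    """The ratio itself, for worked examples with tabulated IC50s."""
    if ic50_resistant <= 0 or ic50_parental <= 0:
        raise ValueError("IC50 values must be positive")
    return ic50_resistant / ic50_parental


class FourPLRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn estimator facade over :func:`fit_4pl`.

    ``fit(X, y)`` takes doses (µM, shape (n,) or (n, 1)) and viability
    fractions; fitted attributes are ``top_``, ``bottom_``, ``hill_``,
    ``ic50_``, ``rss_``, ``converged_``, ``censored_`` and ``fit_``.
    """

    def fit(self, X, y):
        d = np.asarray(X, float).reshape(-1)
        y = np.asarray(y, float).reshape(-1)
        data = DoseResponseData("", "", d, y)
        fit = fit_4pl(data)
        self.fit_ = fit
        self.top_ = fit.top
        self.bottom_ = fit.bottom
        self.hill_ = fit.hill
        self.ic50_ = fit.ic50
        self.rss_ = fit.rss
        self.converged_ = fit.converged
        self.censored_ = fit.censored
        return self

    def predict(self, X):
        if not hasattr(self, "fit_"):
            raise AttributeError("FourPLRegressor is not fitted")
        return self.fit_.predict(np.asarray(X, float).reshape(-1))
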