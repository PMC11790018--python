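"""Dose-response quantification: 4PL fitting, AUC, sensitivity classes.

The four-parameter logistic model

    v(d) = bottom + (top - bottom) / (1 + (d / IC50)^hill)

is fit by bounded nonlinear least squares from a grid of IC50
initializations, with the IC50 parameterized on the log10 scale. All
concentrations are handled internally in nM so that fits are identical
whether doses arrive in uM or nM. AUC is the trapezoidal integral of mean
replicate viability over log10(dose) across the nonzero doses, divided by
the log-dose span, so a flat nonresponder scores exactly 1; it is computed
from the raw measurements rather than the fitted curve so it stays defined
when fits fail.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

NM_PER_UM = 1000.0

#: Canonical sensitivity threshold: IC50 strictly below 2 uM.
SENSITIVE_IC50_UM = 2.0


@dataclass(frozen=True)
class FitResult:
    ic50_nM: float
    log10_ic50_nM: float
    hill: float
    top: float
    bottom: float
    censored: bool
    converged: bool


@dataclass(frozen=True)
class AUCResult:
    auc_raw: float
    auc_normalized: float | None


@dataclass(frozen=True)
class FoldResult:
    ratio: float
    is_bound: bool  # a censored IC50 contributed its bound to the ratio


def _to_nM(doses: np.ndarray, dose_unit: str) -> np.ndarray:
    if dose_unit == "uM":
        return doses * NM_PER_UM
    if dose_unit == "nM":
        return doses
    raise ValueError(f"dose_unit must be 'uM' or 'nM', got {dose_unit!r}")


class FourParamLogistic(BaseEstimator):
    """Scikit-learn style estimator for a single 4PL dose-response curve.

    Parameters
    ----------
    dose_unit : {'uM', 'nM'}
        Unit of the dose vector passed to :meth:`fit` and :meth:`predict`.
    model : {'normalized', 'free'}
        'normalized' (default) fixes top = 1 and bottom = 0, the standard
        model for viability already expressed as fraction of the untreated
        control; 'free' fits all four parameters within bounds (use for
        partial responders or un-normalized readouts).
    n_starts : int
        Number of log-spaced IC50 initializations tried; the best
        sum-of-squares solution wins.

    Fitted attributes (trailing underscore) mirror :class:`FitResult`. A
    fitted IC50 beyond the maximum tested dose, or a curve that never
    crosses the half-response level within the tested range, sets
    ``censored_`` and reports the IC50 at the maximum dose.
    """

    def __init__(
        self,
        dose_unit: str = "uM",
        model: str = "normalized",
        n_starts: int = 7,
        hill_bounds: tuple[float, float] = (0.2, 5.0),
        top_bounds: tuple[float, float] = (0.4, 1.4),
        bottom_bounds: tuple[float, float] = (-0.1, 0.6),
    ):
        self.dose_unit = dose_unit
        self.model = model
        self.n_starts = n_starts
        self.hill_bounds = hill_bounds
        self.top_bounds = top_bounds
        self.bottom_bounds = bottom_bounds

    @staticmethod
    def _model(log_d, log_ic50, hill, top, bottom):
        return bottom + (top - bottom) / (1.0 + 10 ** (hill * (log_d - log_ic50)))

    def fit(self, doses, viability):
        doses = np.asarray(doses, dtype=float)
        viability = np.asarray(viability, dtype=float)
        if doses.shape != viability.shape:
            raise ValueError("doses and viability must have the same length")
        if np.any(~np.isfinite(viability)) or np.any(viability < 0):
            raise ValueError("viability must be finite and >= 0")
        nz = doses > 0
        if len(np.unique(doses[nz])) < 5:
            raise ValueError("need at least 5 distinct nonzero doses to fit")
        d = _to_nM(doses[nz], self.dose_unit)
        v = viability[nz]
        log_d = np.log10(d)
        self.max_dose_nM_ = float(d.max())

        if self.model == "normalized":
            lo = [log_d.min() - 3.0, self.hill_bounds[0]]
            hi = [log_d.max() + 3.0, self.hill_bounds[1]]

            def residuals(theta):
                return self._model(log_d, theta[0], theta[1], 1.0, 0.0) - v

            def unpack(x):
                return x[0], x[1], 1.0, 0.0

            x0_tail = [1.0]
        elif self.model == "free":
            lo = [
                log_d.min() - 3.0,
                self.hill_bounds[0],
                self.top_bounds[0],
                self.bottom_bounds[0],
            ]
            hi = [
                log_d.max() + 3.0,
                self.hill_bounds[1],
                self.top_bounds[1],
                self.bottom_bounds[1],
            ]

            def residuals(theta):
                return self._model(log_d, *theta) - v

            def unpack(x):
                return tuple(x)

            x0_tail = [1.0, 1.0, 0.0]
        else:
            raise ValueError(f"model must be 'normalized' or 'free', got {self.model!r}")

        best = None
        starts = np.linspace(log_d.min() - 1.0, log_d.max() + 1.0, self.n_starts)
        for s in starts:
            x0 = np.clip([s] + x0_tail, lo, hi)
            try:
                sol = least_squares(residuals, x0, bounds=(lo, hi))
            except Exception:  # pragma: no cover - pathological numerics
                continue
            if sol.success and (best is None or sol.cost < best.cost - 1e-15):
                best = sol

        if best is None:
            self.converged_ = False
            self.censored_ = True
            self.ic50_nM_ = self.max_dose_nM_
            self.log10_ic50_nM_ = math.log10(self.max_dose_nM_)
            self.hill_ = float("nan")
            self.top_ = float("nan")
            self.bottom_ = float("nan")
            return self

        log_ic50, hill, top, bottom = unpack(best.x)
        self.converged_ = True
        ic50 = 10 ** log_ic50
        # censoring: IC50 past the dose range, or the fitted curve never
        # reaches the half-response level inside the tested range
        mid = (top + bottom) / 2.0
        vmax_d = self._model(log_d.max(), log_ic50, hill, top, bottom)
        self.censored_ = bool(ic50 > self.max_dose_nM_ or vmax_d > mid + 1e-9)
        if self.censored_:
            ic50 = self.max_dose_nM_
        self.ic50_nM_ = float(ic50)
        self.log10_ic50_nM_ = float(math.log10(ic50))
        self.hill_ = float(hill)
        self.top_ = float(top)
        self.bottom_ = float(bottom)
        return self

    def predict(self, doses):
        doses = np.asarray(doses, dtype=float)
        d = _to_nM(doses, self.dose_unit)
        with np.errstate(divide="ignore"):
            log_d = np.where(d > 0, np.log10(np.maximum(d, 1e-300)), -np.inf)
        return self._model(log_d, self.log10_ic50_nM_, self.hill_, self.top_, self.bottom_)

    def result_(self) -> FitResult:
        return FitResult(
            ic50_nM=self.ic50_nM_,
            log10_ic50_nM=self.log10_ic50_nM_,
            hill=self.hill_,
            top=self.top_,
            bottom=self.bottom_,
            censored=self.censored_,
            converged=self.converged_,
        )


def fit_four_pl(assay: pd.DataFrame, dose_unit: str = "uM") -> FitResult:
    """Fit the 4PL model to a long-format assay table.

    ``assay`` needs ``dose_uM`` (or ``dose_nM`` with ``dose_unit='nM'``) and
    ``viability`` columns; replicates are passed to the fit as repeated
    observations. Zero-dose wells are excluded from the fit (they only
    anchor viability normalization upstream).
    """
    col = "dose_uM" if dose_unit == "uM" else "dose_nM"
    est = FourParamLogistic(dose_unit=dose_unit).fit(
        assay[col].to_numpy(), assay["viability"].to_numpy()
    )
    return est.result_()


def _mean_curve(assay: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    mean = assay[assay["dose_uM"] > 0].groupby("dose_uM")["viability"].mean()
    return mean.index.to_numpy(dtype=float), mean.to_numpy(dtype=float)


def compute_auc(assay: pd.DataFrame, reference_assay: pd.DataFrame | None = None) -> AUCResult:
    """Normalized area under the viability / log10-dose curve.

    ``auc_raw`` integrates the mean replicate viability across the nonzero
    doses and divides by the log-dose span, so viability identically 1 gives
    1 and identically 0 gives 0. ``auc_normalized`` divides by the same
    quantity for the reference assay, which must share the drug's dose grid.
    """
    doses, mean_v = _mean_curve(assay)
    if len(doses) < 2:
        raise ValueError("need at least 2 nonzero doses for AUC")
    log_d = np.log10(doses)
    span = log_d[-1] - log_d[0]
    auc_raw = float(np.trapezoid(mean_v, log_d) / span)
    if reference_assay is None:
        return AUCResult(auc_raw=auc_raw, auc_normalized=None)
    ref_doses, ref_v = _mean_curve(reference_assay)
    if len(ref_doses) != len(doses) or not np.allclose(ref_doses, doses):
        raise ValueError("assay and reference dose grids do not match")
    ref_auc = float(np.trapezoid(ref_v, np.log10(ref_doses)) / span)
    if ref_auc == 0:
        raise ValueError("reference assay has zero AUC; cannot normalize")
    return AUCResult(auc_raw=auc_raw, auc_normalized=auc_raw / ref_auc)


def classify_sensitivity(fit: FitResult, ic50_threshold_uM: float = SENSITIVE_IC50_UM) -> str:
    """'sensitive' iff the fitted IC50 is strictly below the threshold.

    Censored (or non-converged) fits are resistant by construction.
    """
    if fit.censored or not fit.converged:
        return "resistant"
    return "sensitive" if fit.ic50_nM < ic50_threshold_uM * NM_PER_UM else "resistant"


def fold_sensitivity(
    ic50_a: float,
    ic50_b: float,
    a_censored: bool = False,
    b_censored: bool = False,
) -> FoldResult:
    """Ratio ic50_a / ic50_b in common units.

    Censored inputs contribute their bound; the ratio is then itself a bound
    (flagged via ``is_bound``) rather than a point estimate.
    """
    if not (ic50_a > 0 and ic50_b > 0):
        raise ValueError("IC50 values must be positive")
    return FoldResult(ratio=ic50_a / ic50_b, is_bound=a_censored or b_censored)


def fit_cohort(
    dose_response: pd.DataFrame,
    reference_cell_line: str | None = None,
    ic50_threshold_uM: float = SENSITIVE_IC50_UM,
) -> pd.DataFrame:
    """Fit, integrate, and classify every (cell line, drug) assay.

    Returns one row per assay with fit parameters, raw and (when a reference
    cell line is given) normalized AUC, and the sensitivity label.
    """
    ref_by_drug: dict[str, pd.DataFrame] = {}
    if reference_cell_line is not None:
        ref_rows = dose_response[dose_response["cell_line"] == reference_cell_line]
        if ref_rows.empty:
            raise ValueError(f"reference cell line {reference_cell_line!r} not in data")
        ref_by_drug = {drug: grp for drug, grp in ref_rows.groupby("drug")}

    rows = []
    for (cell_line, drug), assay in dose_response.groupby(["cell_line", "drug"]):
        fit = fit_four_pl(assay)
        auc = compute_auc(assay, ref_by_drug.get(drug))
        rows.append(
            {
                "cell_line": cell_line,
                "drug": drug,
                "ic50_nM": fit.ic50_nM,
                "log10_ic50_nM": fit.log10_ic50_nM,
                "hill": fit.hill,
                "top": fit.top,
                "bottom": fit.bottom,
                "censored": fit.censored,
                "converged": fit.converged,
                "auc_raw": auc.auc_raw,
                "auc_normalized": auc.auc_normalized,
                "label": classify_sensitivity(fit, ic50_threshold_uM),
            }
        )
    return pd.DataFrame(rows).set_index(["cell_line", "drug"])
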