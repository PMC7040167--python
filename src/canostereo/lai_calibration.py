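"""Exponential calibration of stereo LAI against reference measurements.

Raw stereo LAI is biased by two opposing mechanisms: the stair-step mesh
artifact inflates area, while leaf overlap in dense canopies hides area from
the nadir cameras.  The net relation between stereo LAI and destructively
measured reference LAI is therefore nonlinear and is calibrated with an
exponential regression ``lai_ref = alpha * exp(beta * lai_stereo)``, assessed
by leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationSet:
    """Paired (stereo, reference) LAI observations with optional group labels."""

    lai_stereo: np.ndarray
    lai_ref: np.ndarray
    groups: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.lai_stereo = np.asarray(self.lai_stereo, dtype=float)
        self.lai_ref = np.asarray(self.lai_ref, dtype=float)
        if self.lai_stereo.shape != self.lai_ref.shape or self.lai_stereo.ndim != 1:
            raise ValueError("lai_stereo and lai_ref must be matching 1-D arrays")
        if np.any(self.lai_stereo < 0) or np.any(self.lai_ref < 0):
            raise ValueError("LAI values must be nonnegative")

    def __len__(self) -> int:
        return len(self.lai_stereo)

    def drop(self, i: int) -> "CalibrationSet":
        keep = np.arange(len(self)) != i
        g = self.groups.iloc[keep].reset_index(drop=True) if self.groups is not None else None
        return CalibrationSet(self.lai_stereo[keep], self.lai_ref[keep], g)

    @classmethod
    def from_csv(cls, path) -> "CalibrationSet":
        df = pd.read_csv(path)
        extra = [c for c in df.columns if c not in ("lai_stereo", "lai_ref")]
        return cls(df["lai_stereo"].to_numpy(), df["lai_ref"].to_numpy(),
                   df[extra] if extra else None)


@dataclass
class ExponentialModel:
    """lai_ref = alpha * exp(beta * lai_stereo)."""

    alpha: float
    beta: float
    r2: float = float("nan")
    rmse_fit: float = float("nan")
    rmse_loocv: float = float("nan")
    n: int = 0

    def report(self) -> str:
        return (f"alpha: {self.alpha:.6g}\nbeta: {self.beta:.6g}\n"
                f"r2: {self.r2:.4f}\nrmse_fit: {self.rmse_fit:.4f}\n"
                f"rmse_loocv: {self.rmse_loocv:.4f}\nn: {self.n}\n")


def fit_exponential(cs: CalibrationSet) -> ExponentialModel:
    """Nonlinear least squares of alpha*exp(beta*x), log-linear initialized.

    The starting point comes from an ordinary regression of log(lai_ref) on
    lai_stereo over the strictly positive responses, refined by damped
    (Levenberg-Marquardt) least squares on the untransformed residuals.
    """
    x, y = cs.lai_stereo, cs.lai_ref
    if len(cs) < 3:
        raise CalibrationError("need at least 3 calibration pairs")
    if np.ptp(x) < 1e-12:
        raise CalibrationError("degenerate predictor: lai_stereo is constant")
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(x[pos]) > 1e-12:
        b0, loga0 = np.polyfit(x[pos], np.log(y[pos]), 1)
        p0 = np.array([np.exp(loga0), b0])
    else:
        p0 = np.array([max(y.mean(), 1e-3), 0.1])

    def resid(p):
        return p[0] * np.exp(np.clip(p[1] * x, -50, 50)) - y

    sol = least_squares(resid, p0, method="lm", xtol=1e-10, ftol=1e-12, gtol=1e-12)
    if not sol.success:
        raise CalibrationError(f"exponential fit failed to converge: {sol.message}")
    alpha, beta = sol.x
    pred = alpha * np.exp(beta * x)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return ExponentialModel(alpha=float(alpha), beta=float(beta), r2=r2,
                            rmse_fit=float(np.sqrt(ss_res / len(cs))), n=len(cs))


def predict(model: ExponentialModel, lai_stereo):
    """Calibrated LAI for raw stereo LAI values."""
    if not np.isfinite(model.alpha) or not np.isfinite(model.beta):
        raise CalibrationError("model is not fitted")
    x = np.asarray(lai_stereo, dtype=float)
    out = model.alpha * np.exp(model.beta * x)
    return float(out) if out.ndim == 0 else out


def loocv_rmse(cs: CalibrationSet) -> float:
    """Leave-one-out cross-validated RMSE of the exponential calibration.

    Each observation is predicted by a model fitted on the other n-1; any
    sub-fit failure is reported with the held-out index.
    """
    if len(cs) < 4:
        raise CalibrationError("leave-one-out requires at least 4 pairs")
    errs = np.empty(len(cs))
    for i in range(len(cs)):
        try:
            sub = fit_exponential(cs.drop(i))
        except CalibrationError as exc:
            raise CalibrationError(f"sub-fit failed holding out index {i}: {exc}")
        errs[i] = predict(sub, cs.lai_stereo[i]) - cs.lai_ref[i]
    return float(np.sqrt(np.mean(errs ** 2)))


def calibrate(cs: CalibrationSet) -> ExponentialModel:
    """Fit plus LOOCV in one call; the returned model carries both RMSEs."""
    model = fit_exponential(cs)
    model.rmse_loocv = loocv_rmse(cs)
    return model
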