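"""Hill concentration-inhibition fitting with asymptotic 95% CIs and R².

The model is the Hill inhibition curve

    inhibition(c) = imax * c**nH / (c**nH + IC50**nH)

fit by least squares on log10 concentration, with IC50 parameterized as
log10(IC50) so the search space is unconstrained-positive.  Three variants
are exposed: the default 3-parameter fit (IC50, nH, imax free), a fixed
nH = 1 variant, and a fixed imax = 1 variant.  Confidence intervals are
asymptotic (t-based, from the Jacobian at the optimum), matching typical
nonlinear-regression reporting; R² = 1 - SS_res/SS_tot about the mean of the
transformed responses (unclipped, can be negative for terrible fits).

Responses from the different assays (uptake cpm, normalized S2/S1 release
ratios, AP counts, charge-transfer percent of control) are first mapped to a
common fraction-inhibited scale by :func:`transform_response`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponseFit",
    "hill_inhibition",
    "fit_hill",
    "transform_response",
]


class DoseResponseError(ValueError):
    pass


def hill_inhibition(
    c: float | np.ndarray, ic50: float, nh: float = 1.0, imax: float = 1.0
) -> float | np.ndarray:
    """Fractional inhibition imax * c^nH / (c^nH + IC50^nH).

    Monotone nondecreasing in c; equals imax/2 exactly at c = IC50 and 0 at
    c = 0.  Evaluated on the log scale for numerical robustness.
    """
    if ic50 <= 0 or nh <= 0:
        raise DoseResponseError("ic50 and nh must be positive")
    c = np.asarray(c, dtype=float)
    out = np.zeros_like(c)
    pos = c > 0
    # c^n/(c^n+ic50^n) = 1/(1 + exp(n*(log ic50 - log c)))
    with np.errstate(over="ignore"):
        out[pos] = imax / (1.0 + np.exp(nh * (np.log(ic50) - np.log(c[pos]))))
    return out if out.ndim else float(out)


@dataclass
class DoseResponseFit:
    """Result of a Hill concentration-inhibition fit."""

    ic50: float
    nh: float
    imax: float
    ci95_ic50: tuple[float, float]
    ci95_nh: tuple[float, float]
    ci95_imax: tuple[float, float]
    r_squared: float
    n_points: int
    converged: bool
    variant: str = "hill3"
    message: str = ""

    def predict(self, c: np.ndarray) -> np.ndarray:
        return hill_inhibition(c, self.ic50, self.nh, self.imax)

    def as_dict(self) -> dict:
        return {
            "variant": self.variant,
            "ic50_uM": self.ic50,
            "nH": self.nh,
            "imax": self.imax,
            "ci95_ic50_uM": list(self.ci95_ic50),
            "ci95_nH": list(self.ci95_nh),
            "ci95_imax": list(self.ci95_imax),
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "converged": self.converged,
            "message": self.message,
        }


def _initial_guess(c: np.ndarray, y: np.ndarray, variant: str) -> tuple[float, float, float]:
    imax0 = float(np.clip(np.max(y) * 1.05, 0.1, 1.2))
    half = imax0 / 2.0
    # log-interpolate the concentration at half-maximal response
    order = np.argsort(c)
    cs, ys = c[order], y[order]
    if ys[-1] > half > ys[0]:
        lc = np.interp(half, ys, np.log10(cs))
    else:
        lc = float(np.mean(np.log10(cs)))
    return lc, 1.0, imax0


def fit_hill(
    concentrations_uM: Sequence[float],
    responses: Sequence[float],
    variant: str = "hill3",
    nh_fixed: float = 1.0,
    imax_fixed: float = 1.0,
) -> DoseResponseFit:
    """Fit the Hill inhibition model to fraction-inhibited responses.

    Parameters
    ----------
    concentrations_uM : array-like
        Drug concentrations in µM.  Zero-concentration (solvent) points are
        excluded from the fit — they anchor the baseline during
        :func:`transform_response`, not the log-concentration regression.
    responses : array-like
        Fraction inhibited, same length.
    variant : str
        ``"hill3"`` (IC50, nH, imax free), ``"fixed_nh"`` (nH fixed, default
        1), or ``"fixed_imax"`` (imax fixed, default 1).
    """
    c = np.asarray(concentrations_uM, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape:
        raise DoseResponseError("concentrations and responses must match in length")
    keep = c > 0
    c, y = c[keep], y[keep]
    if np.unique(c).size < 3:
        raise DoseResponseError("need at least 3 distinct positive concentrations")
    if np.allclose(y, y[0]):
        nan = (float("nan"), float("nan"))
        return DoseResponseFit(
            float("nan"), float("nan"), float("nan"), nan, nan, nan,
            float("nan"), int(c.size), converged=False, variant=variant,
            message="responses carry no concentration dependence",
        )

    logc = np.log(c)
    lc0, nh0, imax0 = _initial_guess(c, y, variant)

    if variant == "hill3":
        free = ("lic50", "nh", "imax")
        p0 = [lc0 * np.log(10), nh0, imax0]
        lo = [np.log(c.min()) - 7, 0.05, 1e-6]
        hi = [np.log(c.max()) + 7, 10.0, 1.5]
    elif variant == "fixed_nh":
        free = ("lic50", "imax")
        p0 = [lc0 * np.log(10), imax0]
        lo = [np.log(c.min()) - 7, 1e-6]
        hi = [np.log(c.max()) + 7, 1.5]
    elif variant == "fixed_imax":
        free = ("lic50", "nh")
        p0 = [lc0 * np.log(10), nh0]
        lo = [np.log(c.min()) - 7, 0.05]
        hi = [np.log(c.max()) + 7, 10.0]
    else:
        raise DoseResponseError(f"unknown variant {variant!r}")

    def unpack(p: np.ndarray) -> tuple[float, float, float]:
        if variant == "hill3":
            return p[0], p[1], p[2]
        if variant == "fixed_nh":
            return p[0], nh_fixed, p[1]
        return p[0], p[1], imax_fixed

    def resid(p: np.ndarray) -> np.ndarray:
        lic50, nh, imax = unpack(p)
        with np.errstate(over="ignore"):
            pred = imax / (1.0 + np.exp(nh * (lic50 - logc)))
        return pred - y

    p0 = np.clip(p0, lo, hi)
    sol = optimize.least_squares(
        resid, p0, bounds=(lo, hi), method="trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000,
    )
    lic50, nh, imax = unpack(sol.x)
    ic50 = float(np.exp(lic50))

    n, p_free = y.size, sol.x.size
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    # asymptotic covariance of the free parameters
    se = np.full(p_free, np.nan)
    dof = n - p_free
    if dof > 0:
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * (ss_res / dof)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass
    tval = stats.t.ppf(0.975, dof) if dof > 0 else float("nan")

    def ci(idx: int, transform=lambda v: v) -> tuple[float, float]:
        if idx is None:
            return (float("nan"), float("nan"))
        est, s = sol.x[idx], se[idx]
        if not np.isfinite(s) or not np.isfinite(tval):
            return (float("nan"), float("nan"))
        return (float(transform(est - tval * s)), float(transform(est + tval * s)))

    idx = {name: i for i, name in enumerate(free)}
    ci_ic50 = ci(idx.get("lic50"), np.exp)
    ci_nh = ci(idx.get("nh")) if "nh" in idx else (nh_fixed, nh_fixed)
    ci_imax = ci(idx.get("imax")) if "imax" in idx else (imax_fixed, imax_fixed)

    return DoseResponseFit(
        ic50=ic50,
        nh=float(nh),
        imax=float(imax),
        ci95_ic50=ci_ic50,
        ci95_nh=ci_nh,
        ci95_imax=ci_imax,
        r_squared=r2,
        n_points=int(n),
        converged=bool(sol.success),
        variant=variant,
        message=sol.message,
    )


def transform_response(
    responses: Sequence[float],
    assay: str,
    baseline: float | None = None,
    tolerance: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Map assay-specific responses to fraction inhibited.

    Assays
    ------
    ``"inhibition"``     responses are already fraction inhibited (identity).
    ``"uptake"``         raw treated values; inhibition = 1 - value/baseline
                         (baseline = solvent-control mean, required).
    ``"release"``        solvent-normalized S2/S1 ratios; inhibition = 1 - r.
    ``"ap_count"``       AP counts; inhibition = 1 - count/baseline (required).
    ``"percent_control"``  Q_Ca % of control; inhibition = 1 - pct/100.

    Returns ``(inhibition, out_of_range)`` where the flag marks values outside
    [-tolerance, 1 + tolerance]; flagged values are retained, not clipped.
    """
    r = np.asarray(responses, dtype=float)
    if assay == "inhibition":
        inh = r.copy()
    elif assay in ("uptake", "ap_count"):
        if baseline is None or baseline <= 0:
            raise DoseResponseError(f"assay {assay!r} needs a positive baseline")
        inh = 1.0 - r / baseline
    elif assay == "release":
        inh = 1.0 - r
    elif assay == "percent_control":
        inh = 1.0 - r / 100.0
    else:
        raise DoseResponseError(f"unknown assay {assay!r}")
    flags = (inh < -tolerance) | (inh > 1.0 + tolerance)
    return inh, flags
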