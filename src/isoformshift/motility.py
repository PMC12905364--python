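"""Calcium dose-response fitting: velocity vs pCa with a Hill curve.

v(x) = v_min + (v_max - v_min) / (1 + 10**(n_H * (x - pCa50)))

so velocity is maximal at low pCa (high calcium) and halfway between the
plateaus at x = pCa50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["DoseResponseFit", "hill", "fit_hill", "parse_pca_label"]


def hill(
    v_min: float, v_max: float, pca50: float, n_h: float, x: np.ndarray | float
) -> np.ndarray | float:
    """Hill velocity at pCa ``x``."""
    return v_min + (v_max - v_min) / (1.0 + 10.0 ** (n_h * (np.asarray(x, dtype=float) - pca50)))


def parse_pca_label(label: str) -> float:
    """Parse labels like 'pca68' -> 6.8 (implied decimal after first digit)."""
    s = str(label).strip().lower()
    if s.startswith("pca"):
        s = s[3:]
    if "." in s:
        return float(s)
    digits = s.strip()
    if not digits.isdigit():
        raise ValueError(f"cannot parse pCa label {label!r}")
    return float(digits[0] + "." + digits[1:]) if len(digits) > 1 else float(digits)


@dataclass
class DoseResponseFit:
    v_max: float
    v_min: float
    pca50: float
    n_h: float
    r_squared: float
    means: pd.DataFrame  # per-pCa: mean, sd, sem, n
    ss_res: float
    vmin_poorly_identified: bool = False

    def predict(self, x: np.ndarray | float):
        return hill(self.v_min, self.v_max, self.pca50, self.n_h, x)

    def curve_table(self, n_points: int = 200) -> pd.DataFrame:
        lo, hi = self.means.index.min(), self.means.index.max()
        x = np.linspace(lo, hi, n_points)
        return pd.DataFrame({"pCa": x, "velocity": self.predict(x)})


def _summarize(table: pd.DataFrame) -> pd.DataFrame:
    grp = table.groupby("pCa")["velocity"]
    out = pd.DataFrame(
        {
            "mean": grp.mean(),
            "sd": grp.std(ddof=1),
            "n": grp.size(),
        }
    )
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.sort_index()


def fit_hill(
    table: pd.DataFrame,
    fix_vmin: float | None = None,
    on_means: bool = True,
) -> DoseResponseFit:
    """Weighted nonlinear least squares Hill fit.

    ``table`` has columns pCa and velocity (pCa may be 'pca68'-style labels).
    By default the fit is on per-pCa means weighted by replicate counts;
    ``on_means=False`` fits raw points.  Multistart over n_H in {1, 2, 4}
    and a grid of pCa50 starts across the observed range.
    """
    table = table.copy()
    if table["pCa"].dtype == object:
        table["pCa"] = table["pCa"].map(parse_pca_label)
    table["pCa"] = table["pCa"].astype(float)
    means = _summarize(table)
    if len(means) < 4:
        raise ValueError("need >= 4 distinct pCa values")
    x_all = means.index.to_numpy()
    if on_means:
        x = x_all
        y = means["mean"].to_numpy()
        w = np.sqrt(means["n"].to_numpy(dtype=float))
    else:
        x = table["pCa"].to_numpy()
        y = table["velocity"].to_numpy()
        w = np.ones_like(y)

    lo_x, hi_x = x_all.min(), x_all.max()
    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    span0 = max(y_hi - y_lo, 1e-6)

    free_vmin = fix_vmin is None

    def residuals(params: np.ndarray) -> np.ndarray:
        if free_vmin:
            vmin, span, p50, nh = params
        else:
            span, p50, nh = params
            vmin = fix_vmin
        return w * (hill(vmin, vmin + span, p50, nh, x) - y)

    best = None
    p50_starts = np.linspace(lo_x + 0.1 * (hi_x - lo_x), hi_x - 0.1 * (hi_x - lo_x), 5)
    for nh0 in (1.0, 2.0, 4.0):
        for p500 in p50_starts:
            if free_vmin:
                x0 = [max(y_lo, 0.0), span0, p500, nh0]
                bounds = ([0.0, 0.0, lo_x, 1e-3], [np.inf, np.inf, hi_x, 50.0])
            else:
                x0 = [span0, p500, nh0]
                bounds = ([0.0, lo_x, 1e-3], [np.inf, hi_x, 50.0])
            try:
                sol = optimize.least_squares(
                    residuals, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14
                )
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
    if best is None:
        raise RuntimeError("Hill fit failed to converge from all starts")
    if free_vmin:
        vmin, span, p50, nh = best.x
    else:
        span, p50, nh = best.x
        vmin = float(fix_vmin)
    vmax = vmin + span

    # R^2 always on the per-pCa means
    fitted_means = hill(vmin, vmax, p50, nh, x_all)
    ss_res = float(np.sum((means["mean"].to_numpy() - fitted_means) ** 2))
    ss_tot = float(np.sum((means["mean"] - means["mean"].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    # low-velocity plateau check: highest observed pCa should sit near v_min
    poorly = False
    plateau_level = vmin + 0.2 * span
    if means["mean"].iloc[-1] > plateau_level:
        warnings.warn("no low-velocity plateau observed; v_min poorly identified")
        poorly = True
    return DoseResponseFit(
        v_max=float(vmax),
        v_min=float(vmin),
        pca50=float(p50),
        n_h=float(nh),
        r_squared=float(r2),
        means=means,
        ss_res=float(np.sum(best.fun**2)),
        vmin_poorly_identified=poorly,
    )
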