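"""Drug-screen dose-response analysis.

Raw luminescence readings are normalized to the mean of the DMSO vehicle
wells (100% viability). Technical replicates are averaged per concentration
and a four-parameter logistic (4PL, variable-slope) curve

    v(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

is fitted by bounded least squares on log10 concentration with a fixed
three-point multistart for determinism. The IC50 is considered *reached*
only when the fitted curve attains 50% viability within the tested
concentration range; otherwise the highest tested concentration is reported
in its place (flagged). Compounds are ranked by the normalized area under
the fitted curve over the tested log-concentration range (mean fitted
viability, 0-100; lower = more potent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .errors import FitError, ValidationError

PLATE_COLUMNS = ("well", "compound", "concentration_nM", "replicate", "reading", "role")
ROLES = {"test", "dmso", "staurosporine"}


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Check the plate-reading schema and value domains."""
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValidationError(f"plate table missing columns: {missing}")
    bad_roles = set(plate["role"]) - ROLES
    if bad_roles:
        raise ValidationError(f"unknown well roles: {sorted(bad_roles)}")
    test = plate[plate["role"] == "test"]
    if (test["concentration_nM"] <= 0).any():
        raise ValidationError("test-well concentrations must be positive")
    if not (plate["role"] == "dmso").any():
        raise ValidationError("plate has no DMSO vehicle wells")
    return plate


def normalize_viability(plate: pd.DataFrame) -> pd.DataFrame:
    """Add a ``viability`` column: 100 x reading / mean(DMSO readings)."""
    plate = validate_plate(plate)
    dmso_mean = plate.loc[plate["role"] == "dmso", "reading"].mean()
    if not dmso_mean > 0:
        raise ValidationError(f"DMSO mean reading must be positive (got {dmso_mean})")
    out = plate.copy()
    out["viability"] = 100.0 * out["reading"] / dmso_mean
    return out


def four_pl(c: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    """Evaluate the 4PL viability curve at concentrations *c*."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters and derived summaries for one compound."""

    compound: str
    top: float
    bottom: float
    ic50: float
    hill: float
    ic50_reached: bool
    ic50_reported: float
    auc: float
    rmse: float
    concentrations: np.ndarray

    def predict(self, c: np.ndarray) -> np.ndarray:
        return four_pl(c, self.top, self.bottom, self.ic50, self.hill)


def _fit_curve(logc: np.ndarray, viab: np.ndarray) -> tuple[np.ndarray, float]:
    """Bounded least-squares 4PL fit on log10 concentration, 3 fixed starts."""
    lo, hi = logc.min(), logc.max()
    bounds_lo = np.array([50.0, -10.0, lo - 2.0, 0.1])
    bounds_hi = np.array([150.0, 60.0, hi + 2.0, 10.0])

    def residuals(p):
        top, bottom, logic50, hill = p
        pred = bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - logic50)))
        return pred - viab

    best = None
    for start_logic50 in (lo, 0.5 * (lo + hi), hi):
        p0 = np.clip(np.array([100.0, 0.0, start_logic50, 1.0]), bounds_lo, bounds_hi)
        try:
            res = scipy.optimize.least_squares(residuals, p0, bounds=(bounds_lo, bounds_hi), method="trf")
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost - 1e-12):
            best = res
    if best is None:
        raise FitError(f"4PL fit failed from all starts (range 10^{lo:.2f}..10^{hi:.2f} nM)")
    rmse = float(np.sqrt(np.mean(best.fun**2)))
    return best.x, rmse


def auc_4pl(top: float, bottom: float, ic50: float, hill: float, cmin: float, cmax: float) -> float:
    """Normalized AUC: mean fitted viability over [cmin, cmax] in log10 space.

    Uses the closed form of the 4PL integral in log concentration.
    """
    ln10 = np.log(10.0)

    def antiderivative(x):  # integral of 1 / (1 + 10^(hill (x - x0))) dx
        x0 = np.log10(ic50)
        return x - np.log1p(10.0 ** (hill * (x - x0))) / (hill * ln10)

    a, b = np.log10(cmin), np.log10(cmax)
    integral = bottom * (b - a) + (top - bottom) * (antiderivative(b) - antiderivative(a))
    return float(integral / (b - a))


def fit_4pl(
    concentrations: np.ndarray, viability: np.ndarray, compound: str = ""
) -> DoseResponseFit:
    """Fit one compound's averaged dose-response data.

    *viability* is in percent, replicates already averaged per
    concentration; at least 4 distinct concentrations are required.
    """
    conc = np.asarray(concentrations, dtype=float)
    viab = np.asarray(viability, dtype=float)
    if conc.shape != viab.shape:
        raise ValidationError("concentration and viability lengths differ")
    if len(np.unique(conc)) < 4:
        raise ValidationError("need at least 4 distinct concentrations to fit a 4PL")
    if np.any(conc <= 0):
        raise ValidationError("concentrations must be positive")
    order = np.argsort(conc)
    conc, viab = conc[order], viab[order]
    (top, bottom, logic50, hill), rmse = _fit_curve(np.log10(conc), viab)
    ic50 = float(10.0**logic50)
    fit = DoseResponseFit(
        compound=compound,
        top=float(top),
        bottom=float(bottom),
        ic50=ic50,
        hill=float(hill),
        ic50_reached=False,
        ic50_reported=float(conc.max()),
        auc=auc_4pl(top, bottom, ic50, hill, conc.min(), conc.max()),
        rmse=rmse,
        concentrations=conc,
    )
    fit.ic50_reached, fit.ic50_reported = ic50_report(fit, conc)
    return fit


def ic50_report(fit: DoseResponseFit, tested: np.ndarray) -> tuple[bool, float]:
    """IC50 with the not-reached fallback.

    The IC50 is reached iff the fitted curve attains viability <= 50% at
    some concentration within the tested range (the curve is monotone
    decreasing, so the minimum is at the highest concentration). When not
    reached, the highest tested concentration is reported instead.
    """
    tested = np.asarray(tested, dtype=float)
    reached = bool(fit.predict(np.array([tested.max()]))[0] <= 50.0)
    return reached, (fit.ic50 if reached else float(tested.max()))


def fit_plate(plate: pd.DataFrame) -> dict[str, DoseResponseFit]:
    """Normalize a plate and fit every test compound on it."""
    viab = normalize_viability(plate)
    test = viab[viab["role"] == "test"]
    fits = {}
    for compound, group in test.groupby("compound", sort=True):
        avg = group.groupby("concentration_nM", sort=True)["viability"].mean()
        fits[str(compound)] = fit_4pl(avg.index.to_numpy(), avg.to_numpy(), compound=str(compound))
    return fits


def auc_rank(fits: dict[str, DoseResponseFit]) -> pd.DataFrame:
    """Rank compounds by normalized AUC, ascending (lower = more effective).

    Ties are broken by compound name for a stable ordering. Emits all fit
    fields plus the rank.
    """
    spans = {name: (f.concentrations.min(), f.concentrations.max()) for name, f in fits.items()}
    if len({s for s in spans.values()}) > 1:
        import warnings

        warnings.warn("compounds were tested on different concentration ranges; AUCs are per-range means", stacklevel=2)
    rows = [
        {
            "compound": name,
            "auc": f.auc,
            "ic50": f.ic50,
            "ic50_reached": f.ic50_reached,
            "ic50_reported": f.ic50_reported,
            "top": f.top,
            "bottom": f.bottom,
            "hill": f.hill,
            "rmse": f.rmse,
        }
        for name, f in fits.items()
    ]
    df = pd.DataFrame(rows).sort_values(["auc", "compound"], kind="stable").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def compare_groups(
    values: pd.DataFrame, group_col: str = "group", value_col: str = "ic50", equal_var: bool = True
) -> pd.DataFrame:
    """Pairwise two-tailed Student's t-tests between groups of IC50 values.

    Each value should be the mean of technical replicates from one
    independent experiment. Groups with fewer than 2 values are skipped with
    a warning. Returns columns ``group_a, group_b, n_a, n_b, t, p_value``.
    """
    import warnings

    groups = {}
    for name, sub in values.groupby(group_col, sort=True):
        v = sub[value_col].to_numpy(dtype=float)
        if len(v) < 2:
            warnings.warn(f"group {name!r} skipped: fewer than 2 values", stacklevel=2)
            continue
        groups[name] = v
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            t, p = scipy.stats.ttest_ind(groups[a], groups[b], equal_var=equal_var)
            rows.append({"group_a": a, "group_b": b, "n_a": len(groups[a]), "n_b": len(groups[b]), "t": float(t), "p_value": float(p)})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "t", "p_value"])
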