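"""From multi-exposure fluorescence to per-peptide fold changes.

The phosphorylation signal of a peptide spot is the ordinary
least-squares slope of its fluorescence intensity against camera
exposure time (with intercept).  Peptides whose signal is nonlinear
(R² < 0.90 in any sample) or undetectable (non-positive slope, or
maximum intensity below a configurable floor) are dropped from the
comparison.  For retained peptides the case/control slope ratio is
computed per replicate pair, averaged across replicates on the ratio
scale, and thresholded at FC >= 1.30 or FC <= 0.70 (inclusive) to call
a peptide differentially phosphorylated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SlopeFit",
    "fit_exposure_slope",
    "fit_run",
    "filter_peptides",
    "compute_fold_change",
    "call_differential",
    "preprocess_run",
    "PreprocessResult",
]

R2_MIN_DEFAULT = 0.90
FC_UP_DEFAULT = 1.30
FC_DOWN_DEFAULT = 0.70


@dataclass(frozen=True)
class SlopeFit:
    peptide_id: str
    sample_id: str
    slope: float
    intercept: float
    r_squared: float
    detectable: bool


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form OLS of y on t with intercept; returns (slope, intercept, R²).

    A residual-free fit (including a constant signal, where the total sum
    of squares vanishes) has R² = 1 by convention.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    tbar, ybar = t.mean(), y.mean()
    sxx = float(((t - tbar) ** 2).sum())
    sxy = float(((t - tbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    ss_res = float(((y - slope * t - intercept) ** 2).sum())
    ss_tot = float(((y - ybar) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return slope, intercept, r2


def fit_exposure_slope(
    exposures_ms: Sequence[float],
    intensities: Sequence[float],
    peptide_id: str = "",
    sample_id: str = "",
    intensity_floor: float = 0.0,
) -> SlopeFit:
    """OLS slope/intercept/R² of one peptide's exposure series.

    ``detectable`` is False when the slope is non-positive or every
    intensity sits below ``intensity_floor``.
    """
    t = np.asarray(exposures_ms, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.shape != y.shape or t.size < 2 or np.unique(t).size < 2:
        raise ValueError("need >= 2 distinct exposure values")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise ValueError("exposures and intensities must be finite")
    slope, intercept, r2 = _ols(t, y)
    detectable = slope > 0.0 and float(y.max()) >= intensity_floor
    return SlopeFit(peptide_id, sample_id, slope, intercept, r2, detectable)


def fit_run(frame: pd.DataFrame, intensity_floor: float = 0.0) -> pd.DataFrame:
    """Fit every (peptide, sample) series of a long-format run table.

    Returns one row per peptide per sample with columns
    ``peptide_id, sample_id, condition, replicate, slope, intercept,
    r_squared, detectable``.  Samples sharing a common exposure grid are
    fit in a single vectorized pass.
    """
    needed = {"sample_id", "condition", "replicate", "peptide_id", "exposure_ms", "intensity"}
    missing = needed - set(frame.columns)
    if missing:
        raise ValueError(f"run table missing columns: {sorted(missing)}")

    out: list[pd.DataFrame] = []
    for (sample_id, condition, replicate), sub in frame.groupby(
        ["sample_id", "condition", "replicate"], sort=True
    ):
        wide = sub.pivot_table(index="peptide_id", columns="exposure_ms", values="intensity")
        if wide.isna().any().any():
            raise ValueError(f"sample {sample_id!r}: ragged exposure grid")
        t = wide.columns.to_numpy(dtype=float)
        if np.unique(t).size < 2:
            raise ValueError(f"sample {sample_id!r}: need >= 2 distinct exposures")
        y = wide.to_numpy(dtype=float)
        tbar = t.mean()
        tc = t - tbar
        sxx = float((tc**2).sum())
        ybar = y.mean(axis=1)
        slope = (y @ tc) / sxx
        intercept = ybar - slope * tbar
        resid = y - (slope[:, None] * t[None, :] + intercept[:, None])
        ss_res = (resid**2).sum(axis=1)
        ss_tot = ((y - ybar[:, None]) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ss_tot == 0.0, 1.0, np.maximum(0.0, 1.0 - ss_res / ss_tot))
        out.append(
            pd.DataFrame(
                {
                    "peptide_id": wide.index,
                    "sample_id": sample_id,
                    "condition": condition,
                    "replicate": replicate,
                    "slope": slope,
                    "intercept": intercept,
                    "r_squared": r2,
                    "detectable": (slope > 0.0) & (y.max(axis=1) >= intensity_floor),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def filter_peptides(
    fits: pd.DataFrame,
    r2_min: float = R2_MIN_DEFAULT,
    control_ids: Iterable[str] = (),
) -> set[str]:
    """Peptides retained for differential calling.

    A peptide survives only if in *every* sample of the comparison its
    fit has R² >= ``r2_min`` and is detectable; internal controls are
    excluded outright.  Raising ``r2_min`` can only shrink the set.
    """
    if fits.empty:
        return set()
    controls = set(control_ids)
    ok = fits.assign(pass_=lambda d: (d["r_squared"] >= r2_min) & d["detectable"])
    all_pass = ok.groupby("peptide_id")["pass_"].all()
    return {p for p, passed in all_pass.items() if passed and p not in controls}


def call_differential(
    fc: float | np.ndarray,
    up: float = FC_UP_DEFAULT,
    down: float = FC_DOWN_DEFAULT,
):
    """Inclusive fold-change thresholding: differential iff fc >= up or fc <= down."""
    if up <= down:
        raise ValueError("fc_up must exceed fc_down")
    arr = np.asarray(fc, dtype=float)
    result = (arr >= up) | (arr <= down)
    return bool(result) if np.isscalar(fc) or arr.ndim == 0 else result


def compute_fold_change(
    fits: pd.DataFrame,
    retained: Iterable[str],
    fc_up: float = FC_UP_DEFAULT,
    fc_down: float = FC_DOWN_DEFAULT,
    ratio_mean: str = "arithmetic",
) -> tuple[pd.DataFrame, set[str]]:
    """Replicate-averaged fold change per retained peptide.

    Replicates are paired by index (case replicate i over control
    replicate i); the per-replicate ratios are averaged on the ratio
    scale (arithmetic mean by default, geometric optionally).  Peptides
    whose control slope is non-positive in any replicate cannot form a
    ratio and are routed to the exclusion set instead of raising.

    Returns ``(table, excluded)`` where the table has columns
    ``peptide_id, fc, log2fc, n_replicates, is_differential``.
    """
    if ratio_mean not in ("arithmetic", "geometric"):
        raise ValueError("ratio_mean must be 'arithmetic' or 'geometric'")
    retained = set(retained)
    sub = fits[fits["peptide_id"].isin(retained)]
    case = sub[sub["condition"] == "case"].set_index(["peptide_id", "replicate"])["slope"]
    ctrl = sub[sub["condition"] == "control"].set_index(["peptide_id", "replicate"])["slope"]

    rows = []
    excluded: set[str] = set()
    for pep in sorted(retained):
        case_p = case.loc[pep] if pep in case.index.get_level_values(0) else None
        ctrl_p = ctrl.loc[pep] if pep in ctrl.index.get_level_values(0) else None
        if case_p is None or ctrl_p is None:
            excluded.add(pep)
            continue
        reps = sorted(set(case_p.index) & set(ctrl_p.index))
        if not reps or any(ctrl_p[r] <= 0 for r in reps):
            excluded.add(pep)
            continue
        ratios = np.array([case_p[r] / ctrl_p[r] for r in reps])
        if ratio_mean == "arithmetic":
            fc = float(ratios.mean())
        else:
            fc = float(np.exp(np.log(ratios).mean()))
        rows.append(
            {
                "peptide_id": pep,
                "fc": fc,
                "log2fc": float(np.log2(fc)),
                "n_replicates": len(reps),
                "is_differential": bool(call_differential(fc, fc_up, fc_down)),
            }
        )
    cols = ["peptide_id", "fc", "log2fc", "n_replicates", "is_differential"]
    table = pd.DataFrame(rows, columns=cols)
    return table, excluded


@dataclass(frozen=True)
class PreprocessResult:
    fits: pd.DataFrame
    retained: frozenset[str]
    excluded: frozenset[str]  # retained by the R²/detectable filter but with no valid ratio
    fold_changes: pd.DataFrame

    @property
    def differential(self) -> frozenset[str]:
        mask = self.fold_changes["is_differential"]
        return frozenset(self.fold_changes.loc[mask, "peptide_id"])

    @property
    def log2fc(self) -> dict[str, float]:
        return dict(zip(self.fold_changes["peptide_id"], self.fold_changes["log2fc"]))


def preprocess_run(
    frame: pd.DataFrame,
    r2_min: float = R2_MIN_DEFAULT,
    fc_up: float = FC_UP_DEFAULT,
    fc_down: float = FC_DOWN_DEFAULT,
    intensity_floor: float = 0.0,
    control_ids: Iterable[str] = (),
    ratio_mean: str = "arithmetic",
) -> PreprocessResult:
    """Full preprocessing of one comparison: fit, filter, fold change."""
    fits = fit_run(frame, intensity_floor=intensity_floor)
    retained = filter_peptides(fits, r2_min=r2_min, control_ids=control_ids)
    table, excluded = compute_fold_change(fits, retained, fc_up, fc_down, ratio_mean)
    return PreprocessResult(
        fits=fits,
        retained=frozenset(retained - excluded),
        excluded=frozenset(excluded),
        fold_changes=table,
    )
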