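"""Calibration of regression estimates and the D accuracy screen.

Regression estimates may be shifted and scaled relative to the cell-sorted
truth (cell-type profiles are correlated), so they are first calibrated by
regressing them on the cell-sorted estimates over the candidate panel and
inverting that affine map. Each calibrated estimate is then compared to its
cell-sorted value via the standardized discrepancy

    D = (calibrated - cell_sorted) / SE(calibrated),
    SE(calibrated) = SE(regression estimate) / |slope of the calibration fit|

which, when the estimate is accurate, follows a Student t distribution with
N - 2 degrees of freedom (it is a regression slope up to sign). CpGs with
two-sided tail probability below alpha are rejected as inaccurately
estimated; the survivors form the robust panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDesignError, InvalidArgumentError
from .lr_estimation import LREstimateSet, _ols_many
from .reference_panels import CandidatePanel, CellSortedReference, bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_D_ALPHA = 0.05

#: Calibration slopes with absolute value below this amplify estimate noise
#: by more than 20x when inverted; such fits are flagged uncalibratable.
DEFAULT_BETA_FLOOR = 0.05

#: Standard errors at or below this are treated as an exact fit: D is 0 when
#: the discrepancy is also negligible (below DISCREPANCY_FLOOR) and +inf
#: otherwise. Keeps noiseless oracles deterministic under float rounding.
SE_FLOOR = 1e-10
DISCREPANCY_FLOOR = 1e-8


@dataclass
class CalibrationFit:
    """Affine map from cell-sorted estimates to regression estimates."""

    intercept: float
    slope: float
    n_cpgs: int
    uncalibratable: bool = False
    reason: str = ""


def fit_calibration(
    lr: LREstimateSet,
    ref: CellSortedReference,
    beta_floor: float = DEFAULT_BETA_FLOOR,
) -> CalibrationFit:
    """OLS of regression estimates (response) on cell-sorted estimates
    (predictor) over their shared CpGs.

    Returns an ``uncalibratable`` fit (never raises) when there are fewer
    than 3 shared CpGs, the predictor has no variance, or |slope| falls
    below ``beta_floor`` (below which calibration amplifies noise by more
    than 1/beta_floor).
    """
    common = lr.table.index.intersection(ref.estimates.index)
    if len(common) < 3:
        return CalibrationFit(np.nan, np.nan, len(common), True, "fewer than 3 shared CpGs")
    y = lr.table.loc[common, "slope"].to_numpy()[:, None]
    x = ref.estimates.loc[common].to_numpy()
    if np.ptp(x) == 0:
        return CalibrationFit(np.nan, np.nan, len(common), True, "zero predictor variance")
    intercept, slope, _, _ = _ols_many(y, x)
    if abs(float(slope[0])) < beta_floor:
        return CalibrationFit(
            float(intercept[0]), float(slope[0]), len(common), True,
            f"|slope| {abs(float(slope[0])):.3g} below floor {beta_floor}",
        )
    return CalibrationFit(float(intercept[0]), float(slope[0]), len(common))


def calibrate(estimate, se, fit: CalibrationFit):
    """Invert the calibration map: ((estimate - intercept) / slope, se / |slope|)."""
    if fit.uncalibratable:
        raise DegenerateDesignError(f"calibration is degenerate: {fit.reason}")
    estimate = np.asarray(estimate, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se < 0).any():
        raise InvalidArgumentError("standard errors must be nonnegative")
    return (estimate - fit.intercept) / fit.slope, se / abs(fit.slope)


def d_statistic(calibrated, cell_sorted, calibrated_se) -> np.ndarray:
    """Standardized discrepancy D = (calibrated - cell_sorted) / calibrated_se.

    Zero-SE convention: an (effectively) exact fit gives D = 0 when the
    discrepancy is also negligible, +inf otherwise (always rejected).
    """
    calibrated = np.asarray(calibrated, dtype=float)
    cell_sorted = np.asarray(cell_sorted, dtype=float)
    se = np.asarray(calibrated_se, dtype=float)
    if (se < 0).any():
        raise InvalidArgumentError("calibrated_se must be nonnegative")
    disc = calibrated - cell_sorted
    exact = se <= SE_FLOOR
    with np.errstate(divide="ignore", invalid="ignore"):
        d = disc / se
    d = np.where(exact, np.where(np.abs(disc) < DISCREPANCY_FLOOR, 0.0, np.inf), d)
    return d


def d_test(d, n_samples: int, alpha: float = DEFAULT_D_ALPHA):
    """Two-sided t(N-2) tail test of D; retained iff p >= alpha.

    Returns (p_values, retained) with the same shape as ``d``.
    """
    if n_samples < 3:
        raise InvalidArgumentError("need n_samples >= 3 for a t(N-2) reference")
    if not 0 < alpha < 1:
        raise InvalidArgumentError(f"alpha must be in (0, 1), got {alpha}")
    d = np.asarray(d, dtype=float)
    p = 2.0 * stats.t.sf(np.abs(d), df=n_samples - 2)
    p = np.where(np.isinf(d), 0.0, p)
    return p, p >= alpha


@dataclass
class RobustPanel:
    """Candidate panel annotated with calibration, D screen, and errors.

    ``table`` is indexed by cpg_id with columns t_stat, p_value, q_value,
    lr_estimate, lr_se, cell_sorted_estimate, calibrated_estimate,
    calibrated_se, d_stat, d_pvalue, retained, absolute_error. The robust
    panel itself is the retained subset.
    """

    target: str
    table: pd.DataFrame
    d_alpha: float
    calibration: CalibrationFit

    @property
    def retained_table(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]

    @property
    def cpg_ids(self) -> pd.Index:
        """CpGs surviving the D screen."""
        return self.retained_table.index

    @property
    def n_candidates(self) -> int:
        return len(self.table)

    @property
    def n_retained(self) -> int:
        return int(self.table["retained"].sum())


def build_robust_panel(
    panel: CandidatePanel,
    lr: LREstimateSet,
    ref: CellSortedReference,
    n_samples: int,
    d_alpha: float = DEFAULT_D_ALPHA,
    *,
    beta_floor: float = DEFAULT_BETA_FLOOR,
    bh_on_d: bool = False,
) -> RobustPanel:
    """Calibrate over the full candidate panel, screen each CpG with the
    D statistic, and keep the accurately estimated CpGs.

    ``bh_on_d`` optionally applies BH adjustment to the D p-values before
    the alpha cut (off by default: the screen is per-CpG).
    """
    if panel.target != lr.target or panel.target != ref.target:
        raise InvalidArgumentError(
            f"target mismatch: panel={panel.target!r}, lr={lr.target!r}, ref={ref.target!r}"
        )
    common = panel.table.index.intersection(lr.table.index).intersection(ref.estimates.index)
    table = panel.table.loc[panel.table.index.isin(common)].copy()
    table["lr_estimate"] = lr.table.loc[table.index, "slope"]
    table["lr_se"] = lr.table.loc[table.index, "slope_se"]
    table["cell_sorted_estimate"] = ref.estimates.loc[table.index]

    fit = fit_calibration(lr, ref, beta_floor=beta_floor)
    if fit.uncalibratable or table.empty:
        if fit.uncalibratable:
            logger.warning("target %s uncalibratable (%s); retaining nothing", panel.target, fit.reason)
        for col in ("calibrated_estimate", "calibrated_se", "d_stat", "d_pvalue", "absolute_error"):
            table[col] = np.nan
        table["retained"] = False
        return RobustPanel(panel.target, table, d_alpha, fit)

    cal, cal_se = calibrate(
        table["lr_estimate"].to_numpy(), table["lr_se"].to_numpy(), fit
    )
    d = d_statistic(cal, table["cell_sorted_estimate"].to_numpy(), cal_se)
    p, retained = d_test(d, n_samples, d_alpha)
    if bh_on_d:
        p_screen = bh_adjust(np.where(np.isfinite(p), p, 0.0))
        retained = p_screen >= d_alpha
    table["calibrated_estimate"] = cal
    table["calibrated_se"] = cal_se
    table["d_stat"] = d
    table["d_pvalue"] = p
    table["retained"] = retained
    table["absolute_error"] = np.abs(cal - table["cell_sorted_estimate"].to_numpy())
    return RobustPanel(panel.target, table, d_alpha, fit)


def write_robust_panel(robust: RobustPanel, path) -> None:
    out = robust.table.copy()
    out = out.rename(columns={"retained": "accurate_flag"})
    out.insert(0, "target", robust.target)
    out.to_csv(path, sep="\t", float_format="%.17g")


def load_robust_panel(path, d_alpha: float = DEFAULT_D_ALPHA) -> RobustPanel:
    df = pd.read_csv(path, sep="\t").set_index("cpg_id")
    targets = df["target"].unique()
    if len(targets) != 1:
        raise InvalidArgumentError(f"robust panel file must hold one target, found {list(targets)}")
    df = df.drop(columns=["target"]).rename(columns={"accurate_flag": "retained"})
    df["retained"] = df["retained"].astype(bool)
    fit = CalibrationFit(np.nan, np.nan, len(df))
    return RobustPanel(str(targets[0]), df, d_alpha, fit)
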