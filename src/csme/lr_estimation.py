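"""Per-CpG simple linear regression of mixed-cell betas on target proportion.

The slope estimates the difference between the target cell type's
methylation and the pooled remainder at that CpG: with mixed beta
y_i = b0 + b1 * p_i + e_i, b0 is the non-target level and b1 the
target-minus-rest difference. Slopes are regression coefficients and are
deliberately NOT constrained to [-1, 1]; an optional post-hoc truncation is
available but is not part of the evaluated method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import (
    BetaMatrix,
    CellTypeScheme,
    ProportionTable,
    agglomerate_proportions,
    align_mixed_samples,
)
from .exceptions import DegenerateDesignError, InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass
class LREstimateSet:
    """Per-CpG regression results for one target.

    ``table`` is indexed by cpg_id with columns intercept, slope, slope_se,
    residual_sd, n.
    """

    target: str
    table: pd.DataFrame

    @property
    def slopes(self) -> pd.Series:
        return self.table["slope"]

    def __len__(self) -> int:
        return len(self.table)


def _ols_many(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, ...]:
    """Simple OLS of each column of y (n, m) on x (n,).

    Returns (intercept, slope, slope_se, residual_sd) arrays of length m,
    with residual_sd^2 = RSS / (n - 2) and slope_se = residual_sd / sqrt(Sxx).
    """
    n = x.shape[0]
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise DegenerateDesignError("predictor has zero variance")
    slope = (xc @ y) / sxx
    intercept = y.mean(axis=0) - slope * x.mean()
    resid = y - intercept[None, :] - np.outer(x, slope)
    rss = (resid**2).sum(axis=0)
    residual_sd = np.sqrt(rss / (n - 2))
    slope_se = residual_sd / np.sqrt(sxx)
    return intercept, slope, slope_se, residual_sd


def fit_cpg(y, p) -> tuple[float, float, float, float]:
    """OLS fit of one CpG's mixed betas on target proportions.

    Returns (intercept, slope, slope_se, residual_sd). An exact linear
    relationship yields slope_se == 0 (up to float rounding).
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise InvalidArgumentError("y and p must be 1-D arrays of equal length")
    if y.size < 3:
        raise InvalidArgumentError(f"need >= 3 samples (df = N - 2 >= 1), got {y.size}")
    if np.ptp(p) == 0:
        raise DegenerateDesignError("target proportion is constant across samples")
    intercept, slope, slope_se, residual_sd = _ols_many(y[:, None], p)
    return float(intercept[0]), float(slope[0]), float(slope_se[0]), float(residual_sd[0])


def estimate_panel(
    mixed: BetaMatrix,
    props: ProportionTable,
    target: str,
    scheme: CellTypeScheme,
    panel,
    *,
    truncate: bool = False,
) -> LREstimateSet:
    """Fit every panel CpG against the (agglomerated) target proportion.

    ``panel`` may be a CandidatePanel or any iterable of CpG IDs. CpGs with
    missing betas in the aligned samples are dropped with a logged count.
    ``truncate=True`` clips slopes to [-1, 1] post hoc (off by default; not
    part of the evaluated method).
    """
    mixed, props = align_mixed_samples(mixed, props)
    p = agglomerate_proportions(props, target, scheme).to_numpy()
    cpg_ids = pd.Index(getattr(panel, "cpg_ids", panel))
    if len(cpg_ids) == 0:
        empty = pd.DataFrame(
            columns=["intercept", "slope", "slope_se", "residual_sd", "n"],
            index=pd.Index([], name="cpg_id"),
        )
        return LREstimateSet(target=target, table=empty)
    sub = mixed.subset_cpgs(cpg_ids)
    values = sub.values.to_numpy()
    keep = ~np.isnan(values).any(axis=0)
    if not keep.all():
        logger.warning(
            "dropping %d/%d panel CpGs with missing mixed betas", int((~keep).sum()), len(cpg_ids)
        )
    values = values[:, keep]
    cpg_ids = cpg_ids[keep]
    if mixed.n_samples < 3:
        raise InvalidArgumentError("need >= 3 mixed samples for per-CpG regression")
    intercept, slope, slope_se, residual_sd = _ols_many(values, p)
    if truncate:
        slope = np.clip(slope, -1.0, 1.0)
    table = pd.DataFrame(
        {
            "intercept": intercept,
            "slope": slope,
            "slope_se": slope_se,
            "residual_sd": residual_sd,
            "n": mixed.n_samples,
        },
        index=cpg_ids.rename("cpg_id"),
    )
    return LREstimateSet(target=target, table=table)


def write_estimates(est: LREstimateSet, path) -> None:
    out = est.table.copy()
    out.insert(0, "target", est.target)
    out.to_csv(path, sep="\t", float_format="%.17g")


def load_estimates(path) -> LREstimateSet:
    df = pd.read_csv(path, sep="\t").set_index("cpg_id")
    targets = df["target"].unique()
    if len(targets) != 1:
        raise InvalidArgumentError(f"estimates file must hold one target, found {list(targets)}")
    return LREstimateSet(target=str(targets[0]), table=df.drop(columns=["target"]))
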