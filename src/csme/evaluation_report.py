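"""Panel-level performance metrics, panel validation, and sample clustering.

MAE measures how far calibrated estimates land from the cell-sorted truth;
MMCE (mean |cell-sorted estimate|) is the error of the trivial all-zero
estimator and serves as the baseline MAE must beat; R^2 is the squared
Pearson correlation between raw regression estimates and the truth (scale
and shift are forgiven because calibration removes them).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .calibration_filter import RobustPanel
from .data_io import BetaMatrix, CellTypeScheme, ProportionTable, agglomerate_proportions
from .exceptions import InvalidArgumentError, UndefinedResultError

logger = logging.getLogger(__name__)

DEFAULT_AE_THRESHOLD = 0.05


def mae(calibrated, reference) -> float:
    """Mean absolute error between calibrated and cell-sorted estimates."""
    calibrated = np.asarray(calibrated, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if calibrated.shape != reference.shape:
        raise InvalidArgumentError("mae requires equal-length inputs")
    if calibrated.size == 0:
        raise UndefinedResultError("mae of an empty panel is undefined")
    return float(np.mean(np.abs(calibrated - reference)))


def mmce(reference) -> float:
    """Mean |cell-sorted estimate|: the error of estimating every difference as 0."""
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise UndefinedResultError("mmce of an empty panel is undefined")
    return float(np.mean(np.abs(reference)))


def r_squared(lr_estimates, reference) -> float:
    """Squared Pearson correlation between regression and cell-sorted estimates."""
    a = np.asarray(lr_estimates, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("r_squared requires equal-length inputs")
    if a.size < 3:
        raise UndefinedResultError("r_squared needs at least 3 points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedResultError("r_squared undefined for zero-variance input")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class EvaluationSummary:
    """One report row for a target's robust panel."""

    target: str
    panel_size: int
    mae: float
    mmce: float
    r_squared: float
    n_accurate: int
    pct_accurate: float
    mean_target_proportion_pct: float
    ae_threshold: float

    def to_series(self) -> pd.Series:
        return pd.Series(asdict(self))


def summarize_panel(
    robust: RobustPanel,
    props: ProportionTable,
    scheme: CellTypeScheme,
    ae_threshold: float = DEFAULT_AE_THRESHOLD,
) -> EvaluationSummary:
    """Metrics over the retained (robust) CpGs of one target.

    An empty robust panel yields a size-0 row with NaN metrics.
    """
    target = robust.target
    mean_prop = float(agglomerate_proportions(props, target, scheme).mean()) * 100.0
    kept = robust.retained_table
    if kept.empty:
        logger.warning("robust panel for %s is empty; metrics reported as NA", target)
        return EvaluationSummary(
            target, 0, math.nan, math.nan, math.nan, 0, math.nan, mean_prop, ae_threshold
        )
    cal = kept["calibrated_estimate"].to_numpy()
    ref = kept["cell_sorted_estimate"].to_numpy()
    lr = kept["lr_estimate"].to_numpy()
    ae = kept["absolute_error"].to_numpy()
    try:
        r2 = r_squared(lr, ref)
    except UndefinedResultError:
        logger.warning("R^2 undefined for %s (zero variance or too few CpGs)", target)
        r2 = math.nan
    n_accurate = int((ae < ae_threshold).sum())
    return EvaluationSummary(
        target=target,
        panel_size=len(kept),
        mae=mae(cal, ref),
        mmce=mmce(ref),
        r_squared=r2,
        n_accurate=n_accurate,
        pct_accurate=100.0 * n_accurate / len(kept),
        mean_target_proportion_pct=mean_prop,
        ae_threshold=ae_threshold,
    )


def build_report(summaries) -> pd.DataFrame:
    """Stack per-target summaries into one report table."""
    rows = [s.to_series() for s in summaries]
    if not rows:
        raise UndefinedResultError("no summaries to report")
    return pd.DataFrame(rows).set_index("target")


def panel_overlap(panel_a, panel_b) -> tuple[int, float]:
    """(|A intersect B|, 100*|A intersect B|/|A|); percent NaN when A is empty."""
    a = set(panel_a)
    b = set(panel_b)
    count = len(a & b)
    pct = 100.0 * count / len(a) if a else math.nan
    return count, pct


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for i, (left, right, height, _) in enumerate(link):
        left, right = int(left), int(right)
        node_id = n + i
        bl_left = height - heights[left]
        bl_right = height - heights[right]
        nodes[node_id] = f"({nodes[left]}:{bl_left:g},{nodes[right]}:{bl_right:g})"
        heights[node_id] = float(height)
        del nodes[left], nodes[right]
    (root,) = nodes.values()
    return root + ";"


def cluster_sorted_samples(
    sorted_data: BetaMatrix,
    panels,
    top_n: int | None = None,
    *,
    metric: str = "euclidean",
    method: str = "average",
) -> tuple[str, float]:
    """Agglomerative clustering of sorted samples on the union of panel CpGs.

    ``panels`` is an iterable of panel objects (CandidatePanel/RobustPanel)
    or of plain CpG-ID iterables. With ``top_n``, only the top_n CpGs per
    panel ranked by candidate t-test p-value are used (panels without
    p-values contribute all their CpGs, logged).

    Returns (newick, purity) where purity is the fraction of samples whose
    cophenetically nearest neighbour shares their cell label.
    """
    cpgs: set[str] = set()
    for panel in panels:
        table = getattr(panel, "table", None)
        ids = getattr(panel, "cpg_ids", panel)
        if top_n is not None and table is not None and "p_value" in table.columns:
            sub = table.loc[table.index.isin(set(ids))]
            ranked = sub.sort_values(["p_value"], kind="stable").index
            if top_n > len(ranked):
                logger.info("top_n %d exceeds panel size %d; using all", top_n, len(ranked))
            cpgs.update(ranked[:top_n])
        else:
            if top_n is not None and table is None:
                logger.info("panel without p-values; top_n ignored, using all CpGs")
            cpgs.update(ids)
    if not cpgs:
        raise InvalidArgumentError("no panel CpGs to cluster on")
    sorted_only = sorted_data.sorted_only()
    if sorted_only.n_samples < 2:
        raise InvalidArgumentError("need at least 2 sorted samples to cluster")
    present = [c for c in sorted_only.cpg_ids if c in cpgs]
    if not present:
        raise InvalidArgumentError("panel CpGs absent from the sorted matrix")
    values = sorted_only.values[present].to_numpy()
    dist = pdist(values, metric=metric)
    link = hierarchy.linkage(dist, method=method)
    newick = _linkage_to_newick(link, list(sorted_only.sample_ids))

    coph = squareform(hierarchy.cophenet(link))
    np.fill_diagonal(coph, np.inf)
    labels = sorted_only.samples["cell_label"].to_numpy()
    # tie-aware: a sample is pure if any cophenetically nearest neighbour
    # (distances within 1e-12 of the minimum) shares its label
    min_d = coph.min(axis=1)
    tied = coph <= min_d[:, None] + 1e-12
    same = labels[None, :] == labels[:, None]
    purity = float(np.mean((tied & same).any(axis=1)))
    return newick, purity
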