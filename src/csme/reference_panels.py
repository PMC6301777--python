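"""Cell-sorted reference estimates and candidate CpG panel selection.

The reference for a target is the difference between the mean beta over
sorted samples purified to the target (or to any member of a lineage
grouping) and the mean over all other sorted samples, per CpG. Candidate
panels are CpGs whose two-group pooled t-test survives Benjamini-Hochberg
FDR control at a nominal threshold (default 1e-4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import BetaMatrix, CellTypeScheme, MIXED_LABEL
from .exceptions import InvalidArgumentError

logger = logging.getLogger(__name__)

DEFAULT_FDR = 1e-4


@dataclass
class CellSortedReference:
    """Per-CpG ground-truth difference of sorted means for one target."""

    target: str
    estimates: pd.Series  # index cpg_id, values in [-1, 1]
    n_subjects: int
    n_types: int
    n_group: int  # members in the target (1 for a base type)

    def __post_init__(self) -> None:
        vals = self.estimates.to_numpy()
        if (np.abs(vals) > 1 + 1e-9).any():
            raise InvalidArgumentError("cell-sorted estimates must lie in [-1, 1]")


@dataclass
class CandidatePanel:
    """CpGs associated with a target at the given FDR, ordered by p-value.

    ``table`` is indexed by cpg_id with columns t_stat, p_value, q_value,
    cell_sorted_estimate; every row satisfies q_value <= fdr_threshold.
    """

    target: str
    table: pd.DataFrame
    fdr_threshold: float

    @property
    def cpg_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


def _split_sorted(
    sorted_data: BetaMatrix, target: str, scheme: CellTypeScheme
) -> tuple[np.ndarray, np.ndarray]:
    """(member-sample rows, complement-sample rows), mixed samples excluded."""
    labels = sorted_data.samples["cell_label"]
    if (labels == MIXED_LABEL).any():
        sorted_data = sorted_data.sorted_only()
        labels = sorted_data.samples["cell_label"]
    members = set(scheme.members(target))
    present = set(labels.unique())
    absent = set(scheme.base_types) - present
    if absent:
        raise InvalidArgumentError(f"sorted data lacks samples for types {sorted(absent)}")
    in_target = labels.isin(members).to_numpy()
    values = sorted_data.values.to_numpy()
    return values[in_target], values[~in_target]


def cell_sorted_estimate(
    sorted_data: BetaMatrix, target: str, scheme: CellTypeScheme
) -> CellSortedReference:
    """Difference of means between target-purified and other sorted samples.

    Every sample carries equal weight within its pool, so for a grouping C
    the estimate is mean over the N*n_C member samples minus mean over the
    N*(K - n_C) remaining samples.
    """
    a, b = _split_sorted(sorted_data, target, scheme)
    est = a.mean(axis=0) - b.mean(axis=0)
    members = scheme.members(target)
    n_subjects = len(a) // max(len(members), 1)
    return CellSortedReference(
        target=target,
        estimates=pd.Series(est, index=sorted_data.sorted_only().cpg_ids, name=target),
        n_subjects=n_subjects,
        n_types=scheme.n_types,
        n_group=len(members),
    )


def pooled_t_test(group_a, group_b) -> tuple[float, float, int]:
    """Two-sided two-sample pooled (equal-variance) t-test.

    Returns (t, p, df) with df = n_a + n_b - 2. Degenerate zero-variance
    inputs: equal means give (0, 1), unequal means give (+/-inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("each group needs at least 2 values")
    t, p = _pooled_t_matrix(a[:, None], b[:, None])
    return float(t[0]), float(p[0]), a.size + b.size - 2


def _pooled_t_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled t over columns of a (na, m) and b (nb, m)."""
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    ss = ((a - a.mean(axis=0)) ** 2).sum(axis=0) + ((b - b.mean(axis=0)) ** 2).sum(axis=0)
    sp2 = ss / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / se
    # constant groups leave ss ~ 1e-32 from float rounding rather than exactly
    # 0, which would otherwise manifest as large spurious t values; treat both
    # ss and mean_diff below rounding scale (values are O(1) betas) as zero
    zero_var = ss <= (na + nb) * 1e-24
    if zero_var.any():
        equal_means = np.abs(mean_diff) <= 1e-12
        n_deg = int((zero_var & ~equal_means).sum())
        if n_deg:
            logger.warning("%d CpGs have zero pooled variance with unequal means", n_deg)
        with np.errstate(invalid="ignore"):
            t = np.where(zero_var, np.where(equal_means, 0.0, np.inf * np.sign(mean_diff)), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return t, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min(1, min_{j >= i} p_(j) * m / j) over the stable ascending
    ordering, so q >= p everywhere and q is nondecreasing in sorted order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def select_candidate_panel(
    sorted_data: BetaMatrix,
    target: str,
    scheme: CellTypeScheme,
    fdr: float = DEFAULT_FDR,
) -> CandidatePanel:
    """Pooled t-test of member vs non-member sorted samples at each CpG,
    BH-adjusted, keeping CpGs with q <= fdr (ascending p, ties by cpg_id)."""
    if not 0 < fdr <= 1:
        raise InvalidArgumentError(f"fdr must be in (0, 1], got {fdr}")
    sorted_only = sorted_data.sorted_only()
    a, b = _split_sorted(sorted_only, target, scheme)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 sorted samples per t-test group")
    t, p = _pooled_t_matrix(a, b)
    q = bh_adjust(p)
    ref = cell_sorted_estimate(sorted_only, target, scheme)
    table = pd.DataFrame(
        {
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "cell_sorted_estimate": ref.estimates.to_numpy(),
        },
        index=sorted_only.cpg_ids.rename("cpg_id"),
    )
    table = table[table["q_value"] <= fdr]
    table = table.sort_values(["p_value", "cpg_id"], kind="stable")
    if table.empty:
        logger.warning("candidate panel for %s is empty at FDR %g", target, fdr)
    return CandidatePanel(target=target, table=table, fdr_threshold=fdr)


def write_panel(panel: CandidatePanel, path) -> None:
    out = panel.table.copy()
    out.insert(0, "target", panel.target)
    out.to_csv(path, sep="\t", float_format="%.17g")


def load_panel(path) -> CandidatePanel:
    df = pd.read_csv(path, sep="\t").set_index("cpg_id")
    targets = df["target"].unique()
    if len(df) == 0:
        logger.warning("panel file %s is empty", path)
        return CandidatePanel(target="", table=df.drop(columns=["target"]),
                              fdr_threshold=DEFAULT_FDR)
    if len(targets) != 1:
        raise InvalidArgumentError(f"panel file must hold one target, found {list(targets)}")
    qmax = float(df["q_value"].max()) if len(df) else 0.0
    return CandidatePanel(
        target=str(targets[0]),
        table=df.drop(columns=["target"]),
        fdr_threshold=max(qmax, DEFAULT_FDR),
    )


def write_reference(ref: CellSortedReference, path) -> None:
    out = pd.DataFrame(
        {"target": ref.target, "cell_sorted_estimate": ref.estimates}
    )
    out.index.name = "cpg_id"
    out.to_csv(path, sep="\t", float_format="%.17g")
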