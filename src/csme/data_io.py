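"""Core data model and I/O: cell-type schemes, beta matrices, proportion tables.

All beta matrices are stored samples-in-rows (samples x CpGs) regardless of
on-disk orientation. CpG identifiers are opaque strings; no genomic
coordinates are used anywhere in the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    BetaValidationError,
    InvalidArgumentError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Tolerance below which a proportion row sum is accepted as exactly 1.
ROW_SUM_EXACT_TOL = 1e-6
#: Row sums deviating from 1 by more than this are rejected outright.
ROW_SUM_RENORM_TOL = 0.02

BETA_BOUND_TOL = 1e-9

ANNOTATION_COLUMNS = ("sample_id", "subject_id", "cell_label")
MIXED_LABEL = "mixed"


@dataclass(frozen=True)
class CellTypeScheme:
    """Ordered base cell types plus named lineage groupings (unions of types).

    A grouping is a nonempty proper subset of ``base_types``; it is a valid
    estimation target whose proportion is the sum of its members' proportions.
    """

    base_types: tuple[str, ...]
    groupings: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.base_types) < 2:
            raise InvalidArgumentError("need at least 2 base cell types")
        if len(set(self.base_types)) != len(self.base_types):
            raise SchemaError("base cell-type names must be unique")
        base = set(self.base_types)
        for name, members in self.groupings.items():
            if not members:
                raise SchemaError(f"grouping {name!r} is empty")
            if not members <= base:
                unknown = sorted(members - base)
                raise SchemaError(f"grouping {name!r} has unknown members {unknown}")
            if members == base:
                raise SchemaError(
                    f"grouping {name!r} equals all base types; no complement exists"
                )
            if name in base:
                raise SchemaError(f"grouping {name!r} shadows a base type name")

    @property
    def n_types(self) -> int:
        return len(self.base_types)

    @property
    def targets(self) -> tuple[str, ...]:
        """All valid estimation targets: base types then groupings."""
        return self.base_types + tuple(self.groupings)

    def is_target(self, name: str) -> bool:
        return name in self.base_types or name in self.groupings

    def members(self, target: str) -> tuple[str, ...]:
        """Base types belonging to a target (singleton for a base type)."""
        if target in self.groupings:
            order = {t: i for i, t in enumerate(self.base_types)}
            return tuple(sorted(self.groupings[target], key=order.__getitem__))
        if target in self.base_types:
            return (target,)
        raise InvalidArgumentError(
            f"unknown target {target!r}; expected one of {list(self.targets)}"
        )

    def complement(self, target: str) -> tuple[str, ...]:
        """Base types outside a target."""
        inside = set(self.members(target))
        return tuple(t for t in self.base_types if t not in inside)


#: The seven-leukocyte scheme used throughout: whole-blood base types with
#: the standard lineage groupings (lymphoid with/without B cells, full
#: myeloid, granulocyte, and pan-T).
DEFAULT_BASE_TYPES = (
    "Neutrophil",
    "Eosinophil",
    "CD4T",
    "CD8T",
    "CD19B",
    "CD56NK",
    "CD14Mono",
)

DEFAULT_GROUPINGS: dict[str, frozenset[str]] = {
    "Lymphocyte-I": frozenset({"CD4T", "CD8T", "CD19B", "CD56NK"}),
    "Lymphocyte-II": frozenset({"CD4T", "CD8T", "CD56NK"}),
    "Myeloid-I": frozenset({"Neutrophil", "CD14Mono", "Eosinophil"}),
    "Myeloid-II": frozenset({"Neutrophil", "Eosinophil"}),
    "Pan-T": frozenset({"CD4T", "CD8T"}),
}

DEFAULT_SCHEME = CellTypeScheme(DEFAULT_BASE_TYPES, dict(DEFAULT_GROUPINGS))

#: FACS-derived mean cell-type fractions (percent) of healthy adult whole
#: blood; used as default simulation means.
DEFAULT_MEAN_PROPORTIONS_PCT: dict[str, float] = {
    "Neutrophil": 65.0,
    "Eosinophil": 3.8,
    "CD4T": 13.4,
    "CD8T": 6.1,
    "CD19B": 3.0,
    "CD56NK": 2.4,
    "CD14Mono": 5.4,
}


class BetaMatrix:
    """Samples x CpGs beta-value matrix with per-sample annotations.

    Parameters
    ----------
    values:
        DataFrame indexed by sample_id with CpG IDs as columns. Values must
        lie in [0, 1] (tolerance ``BETA_BOUND_TOL``) or be NaN (missing).
    samples:
        DataFrame indexed by sample_id with columns ``subject_id`` and
        ``cell_label`` (a base cell-type name or ``"mixed"``).
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame) -> None:
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample_ids: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate cpg_ids: {dups}")
        missing_cols = {"subject_id", "cell_label"} - set(samples.columns)
        if missing_cols:
            raise SchemaError(f"sample annotations lack columns {sorted(missing_cols)}")
        if not values.index.equals(samples.index):
            raise AlignmentError("values and sample annotations have different sample_ids")
        arr = values.to_numpy(dtype=float)
        bad = (arr < -BETA_BOUND_TOL) | (arr > 1 + BETA_BOUND_TOL)
        bad &= ~np.isnan(arr)
        if bad.any():
            rows, cols = np.nonzero(bad)
            cells = [
                f"({values.index[r]}, {values.columns[c]})={arr[r, c]:g}"
                for r, c in zip(rows[:5], cols[:5])
            ]
            raise BetaValidationError(
                f"{bad.sum()} beta values outside [0, 1]; first offenders: "
                + ", ".join(cells)
            )
        self.values = values.astype(float)
        self.samples = samples

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return len(self.values.index)

    @property
    def n_cpgs(self) -> int:
        return len(self.values.columns)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BetaMatrix({self.n_samples} samples x {self.n_cpgs} CpGs)"

    # -- selection helpers ---------------------------------------------------
    def select_samples(self, mask: np.ndarray | pd.Series) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[mask], self.samples.loc[mask])

    def sorted_only(self) -> "BetaMatrix":
        """Samples whose cell_label is a purified cell type (not mixed)."""
        return self.select_samples(self.samples["cell_label"] != MIXED_LABEL)

    def mixed_only(self) -> "BetaMatrix":
        return self.select_samples(self.samples["cell_label"] == MIXED_LABEL)

    def subset_cpgs(self, cpg_ids) -> "BetaMatrix":
        missing = pd.Index(cpg_ids).difference(self.values.columns)
        if len(missing):
            raise AlignmentError(f"{len(missing)} requested CpGs absent, e.g. {missing[:3].tolist()}")
        return BetaMatrix(self.values.loc[:, list(cpg_ids)], self.samples)


class ProportionTable:
    """Per-mixed-sample cell-type fractions, rows indexed by sample_id.

    Fractions are nonnegative and each row sums to 1. Row sums deviating
    from 1 by more than ``ROW_SUM_EXACT_TOL`` but at most
    ``ROW_SUM_RENORM_TOL`` are renormalized with a logged warning unless
    ``renormalize=False``, in which case the raw values are kept (useful
    when the deficit is known rounding error in an external table).
    """

    def __init__(self, fractions: pd.DataFrame, renormalize: bool = True) -> None:
        if fractions.index.has_duplicates:
            raise SchemaError("duplicate sample_ids in proportion table")
        arr = fractions.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise BetaValidationError("proportion table contains missing values")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise BetaValidationError(
                f"negative fraction at ({fractions.index[r]}, {fractions.columns[c]})"
            )
        sums = arr.sum(axis=1)
        off = np.abs(sums - 1.0)
        if (off > ROW_SUM_RENORM_TOL).any():
            bad = fractions.index[off > ROW_SUM_RENORM_TOL].tolist()
            raise BetaValidationError(
                f"proportion rows sum too far from 1 (>±{ROW_SUM_RENORM_TOL}): {bad[:5]}"
            )
        needs = off > ROW_SUM_EXACT_TOL
        if needs.any():
            if renormalize:
                logger.warning(
                    "renormalizing %d proportion rows with sums off 1 by up to %.4g",
                    int(needs.sum()),
                    float(off.max()),
                )
                arr = arr / sums[:, None]
                fractions = pd.DataFrame(arr, index=fractions.index, columns=fractions.columns)
            else:
                logger.warning(
                    "keeping %d un-normalized proportion rows (max deviation %.4g)",
                    int(needs.sum()),
                    float(off.max()),
                )
        self.fractions = fractions.astype(float)

    @property
    def sample_ids(self) -> pd.Index:
        return self.fractions.index

    @property
    def cell_types(self) -> pd.Index:
        return self.fractions.columns

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ProportionTable({len(self.fractions)} samples x {len(self.fractions.columns)} types)"


def agglomerate_proportions(
    props: ProportionTable, target: str, scheme: CellTypeScheme
) -> pd.Series:
    """Per-sample fraction of a target: a base type's column, or the sum of a
    grouping's member columns. Values stay within [0, 1] (+1e-9 headroom)."""
    members = scheme.members(target)
    missing = [m for m in members if m not in props.fractions.columns]
    if missing:
        raise SchemaError(f"proportion table lacks cell-type columns {missing}")
    out = props.fractions[list(members)].sum(axis=1)
    if (out > 1 + 1e-9).any():
        raise BetaValidationError(f"agglomerated fraction for {target!r} exceeds 1")
    out.name = target
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def load_beta_matrix(path: str | Path, orientation: str = "samples_in_rows") -> BetaMatrix:
    """Read a beta matrix from TSV/CSV (delimiter sniffed from the header).

    ``samples_in_rows`` expects columns ``sample_id, subject_id, cell_label``
    followed by one column per CpG. ``cpgs_in_rows`` expects a ``cpg_id``
    column followed by one column per sample (annotations default to
    subject = sample_id, cell_label = "mixed").
    """
    path = Path(path)
    if orientation not in ("samples_in_rows", "cpgs_in_rows"):
        raise InvalidArgumentError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if orientation == "cpgs_in_rows":
        if "cpg_id" not in df.columns:
            raise SchemaError("cpgs_in_rows file must have a 'cpg_id' column")
        if df["cpg_id"].duplicated().any():
            raise SchemaError("duplicate cpg_ids")
        values = df.set_index("cpg_id").T
        values.index.name = "sample_id"
        samples = pd.DataFrame(
            {"subject_id": values.index, "cell_label": MIXED_LABEL}, index=values.index
        )
        return BetaMatrix(values, samples)
    required = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if required:
        raise SchemaError(f"beta matrix file lacks columns {required}")
    df = df.set_index("sample_id")
    samples = df[["subject_id", "cell_label"]].astype(str)
    values = df.drop(columns=["subject_id", "cell_label"])
    return BetaMatrix(values, samples)


def write_beta_matrix(bm: BetaMatrix, path: str | Path) -> None:
    out = pd.concat([bm.samples[["subject_id", "cell_label"]], bm.values], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def load_proportions(path: str | Path, scheme: CellTypeScheme) -> ProportionTable:
    """Read a per-sample proportion table; percent vs fraction units are
    auto-detected from the median row sum (~100 vs ~1) and logged."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise SchemaError("proportion file lacks a 'sample_id' column")
    df = df.set_index("sample_id")
    missing = [t for t in scheme.base_types if t not in df.columns]
    if missing:
        raise SchemaError(f"proportion file lacks cell-type columns {missing}")
    df = df[list(scheme.base_types)].astype(float)
    median_sum = float(df.sum(axis=1).median())
    if median_sum > 10:
        logger.info("proportions read as percent (median row sum %.3g); dividing by 100", median_sum)
        df = df / 100.0
    else:
        logger.info("proportions read as fractions (median row sum %.3g)", median_sum)
    return ProportionTable(df)


def write_proportions(props: ProportionTable, path: str | Path) -> None:
    out = props.fractions.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def align_mixed_samples(
    mixed: BetaMatrix, props: ProportionTable
) -> tuple[BetaMatrix, ProportionTable]:
    """Restrict both inputs to their shared sample_ids, in matrix order."""
    common = mixed.sample_ids.intersection(props.sample_ids)
    if len(common) == 0:
        raise AlignmentError("no overlapping sample_ids between mixed betas and proportions")
    if len(common) < mixed.n_samples or len(common) < len(props.sample_ids):
        logger.warning(
            "aligning on %d shared samples (%d mixed, %d proportion rows)",
            len(common), mixed.n_samples, len(props.sample_ids),
        )
    common = pd.Index([s for s in mixed.sample_ids if s in set(common)])
    return (
        BetaMatrix(mixed.values.loc[common], mixed.samples.loc[common]),
        ProportionTable(props.fractions.loc[common]),
    )
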