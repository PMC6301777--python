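"""Synthetic paired cell-sorted / mixed-cell beta-value data.

The generative model is the one the estimation method assumes: each mixed
sample's beta value is the proportion-weighted average of per-cell-type
profiles plus Normal noise, clipped to [0, 1]. Clipping is counted and
surfaced (heavy clipping means the additive-noise model is violated).

In ``fixed_remainder`` proportion mode the target fraction varies across
subjects while every non-target type takes an equal share of the remainder;
this makes the per-CpG regression slope exactly equal to the unweighted
cell-sorted difference of means, giving a noiseless end-to-end oracle.
``dirichlet`` mode draws realistic correlated compositions and deliberately
does not have that exactness property.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_io import (
    DEFAULT_GROUPINGS,
    DEFAULT_BASE_TYPES,
    DEFAULT_MEAN_PROPORTIONS_PCT,
    MIXED_LABEL,
    BetaMatrix,
    CellTypeScheme,
    ProportionTable,
    write_beta_matrix,
    write_proportions,
)
from .exceptions import InvalidArgumentError, SchemaError

logger = logging.getLogger(__name__)

PROPORTION_MODES = ("fixed_remainder", "dirichlet")

#: Default baseline beta levels (low / intermediate / high) mimicking the
#: bimodal-with-shoulder distribution of array methylation.
DEFAULT_BASELINE_LEVELS = (0.1, 0.5, 0.9)
DEFAULT_BASELINE_WEIGHTS = (0.4, 0.2, 0.4)


def _normalized_means(mean_proportions: dict[str, float] | None,
                      base_types: tuple[str, ...]) -> dict[str, float]:
    if mean_proportions is None:
        mean_proportions = {t: DEFAULT_MEAN_PROPORTIONS_PCT[t] for t in base_types}
    missing = [t for t in base_types if t not in mean_proportions]
    if missing:
        raise InvalidArgumentError(f"mean_proportions lacks types {missing}")
    vals = np.array([float(mean_proportions[t]) for t in base_types])
    if (vals <= 0).any():
        bad = [t for t, v in zip(base_types, vals) if v <= 0]
        raise InvalidArgumentError(f"degenerate (non-positive) mean proportion for {bad}")
    vals = vals / vals.sum()
    return dict(zip(base_types, vals))


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated dataset.

    cell_profiles is a CpGs x base-types DataFrame of true beta values;
    differential_sets maps each base type to the CpG IDs planted as
    differentially methylated for it (disjoint across types).
    """

    cell_profiles: pd.DataFrame
    differential_sets: dict[str, set[str]]
    effect_size: float
    noise_sd: float | np.ndarray
    proportion_mode: str
    mean_proportions: dict[str, float]
    seed: int
    n_clipped_profiles: int = 0

    def __post_init__(self) -> None:
        arr = self.cell_profiles.to_numpy()
        if ((arr < 0) | (arr > 1)).any():
            raise InvalidArgumentError("cell_profiles contains values outside [0, 1]")
        means = np.array([self.mean_proportions[t] for t in self.cell_profiles.columns])
        if (means < 0).any() or abs(means.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("mean_proportions must be nonnegative and sum to 1")
        universe = set(self.cell_profiles.index)
        for k, cpgs in self.differential_sets.items():
            if not set(cpgs) <= universe:
                raise InvalidArgumentError(f"differential set for {k!r} outside CpG universe")

    @property
    def base_types(self) -> tuple[str, ...]:
        return tuple(self.cell_profiles.columns)

    @property
    def cpg_ids(self) -> pd.Index:
        return self.cell_profiles.index

    def noise_sd_vector(self) -> np.ndarray:
        """Per-CpG noise sd, broadcasting a scalar."""
        n = len(self.cell_profiles.index)
        sd = np.asarray(self.noise_sd, dtype=float)
        if sd.ndim == 0:
            return np.full(n, float(sd))
        if sd.shape != (n,):
            raise InvalidArgumentError(f"noise_sd vector has shape {sd.shape}, expected ({n},)")
        return sd


@dataclass
class SyntheticBundle:
    """A complete simulated study: sorted samples, mixed samples, proportions."""

    sorted_data: BetaMatrix
    mixed_data: BetaMatrix
    proportions: ProportionTable
    truth: SyntheticTruth
    n_clipped_mixed: int = 0
    n_clipped_sorted: int = 0

    def __post_init__(self) -> None:
        if not self.mixed_data.sample_ids.equals(self.proportions.sample_ids):
            raise InvalidArgumentError("mixed samples and proportion rows disagree")
        counts = self.sorted_data.samples.groupby(
            ["subject_id", "cell_label"], observed=True
        ).size()
        if (counts != 1).any():
            raise InvalidArgumentError("sorted_data must have one sample per (subject, type)")


def generate_cell_profiles(
    n_cpgs: int,
    scheme: CellTypeScheme,
    diff_fraction: float,
    effect_size: float,
    seed: int,
    *,
    baseline_levels: tuple[float, ...] = DEFAULT_BASELINE_LEVELS,
    baseline_weights: tuple[float, ...] = DEFAULT_BASELINE_WEIGHTS,
    mean_proportions: dict[str, float] | None = None,
    proportion_mode: str = "fixed_remainder",
    noise_sd: float = 0.0,
    diff_targets: tuple[str, ...] | None = None,
) -> SyntheticTruth:
    """Plant per-target differential CpGs on a shared per-CpG baseline.

    For each target in ``diff_targets`` (default: the base cell types),
    ``round(diff_fraction * n_cpgs)`` CpGs — disjoint across targets — get
    every member type's profile shifted by ±effect_size relative to the
    common baseline (direction by fair coin); every other entry is the
    baseline. For a base-type target this plants |x_jk - mean(others)| =
    effect_size; for a grouping it plants the grouping-level contrast at
    effect_size. Shifted values are clipped to [0, 1] and the number of
    clipped entries recorded.
    """
    if n_cpgs < 1:
        raise InvalidArgumentError(f"n_cpgs must be >= 1, got {n_cpgs}")
    if not 0 <= diff_fraction <= 1:
        raise InvalidArgumentError(f"diff_fraction must be in [0, 1], got {diff_fraction}")
    if not 0 < effect_size <= 1:
        raise InvalidArgumentError(f"effect_size must be in (0, 1], got {effect_size}")
    if proportion_mode not in PROPORTION_MODES:
        raise InvalidArgumentError(f"proportion_mode must be one of {PROPORTION_MODES}")
    if diff_targets is None:
        diff_targets = scheme.base_types
    member_idx = {
        t: [scheme.base_types.index(m) for m in scheme.members(t)] for t in diff_targets
    }

    rng = np.random.default_rng(seed)
    k = scheme.n_types
    n_diff = int(round(diff_fraction * n_cpgs))
    if n_diff * len(diff_targets) > n_cpgs:
        raise InvalidArgumentError(
            f"diff_fraction {diff_fraction} too large: {len(diff_targets)} disjoint "
            f"sets of {n_diff} CpGs exceed {n_cpgs} total"
        )

    cpg_ids = pd.Index([f"cg{j:08d}" for j in range(n_cpgs)], name="cpg_id")
    levels = np.asarray(baseline_levels, dtype=float)
    weights = np.asarray(baseline_weights, dtype=float)
    weights = weights / weights.sum()
    baseline = rng.choice(levels, size=n_cpgs, p=weights)

    profiles = np.tile(baseline[:, None], (1, k))
    chosen = rng.choice(n_cpgs, size=n_diff * len(diff_targets), replace=False)
    differential_sets: dict[str, set[str]] = {}
    n_clipped = 0
    for t_idx, target in enumerate(diff_targets):
        idx = chosen[t_idx * n_diff:(t_idx + 1) * n_diff]
        direction = rng.choice([-1.0, 1.0], size=n_diff)
        shifted = baseline[idx] + direction * effect_size
        clipped = np.clip(shifted, 0.0, 1.0)
        n_clipped += int((clipped != shifted).sum()) * len(member_idx[target])
        profiles[np.ix_(idx, member_idx[target])] = clipped[:, None]
        differential_sets[target] = set(cpg_ids[idx])
    if n_clipped:
        logger.warning("clipped %d differential profile values to [0, 1]", n_clipped)

    return SyntheticTruth(
        cell_profiles=pd.DataFrame(profiles, index=cpg_ids, columns=list(scheme.base_types)),
        differential_sets=differential_sets,
        effect_size=effect_size,
        noise_sd=noise_sd,
        proportion_mode=proportion_mode,
        mean_proportions=_normalized_means(mean_proportions, scheme.base_types),
        seed=seed,
        n_clipped_profiles=n_clipped,
    )


def _subject_ids(n_subjects: int) -> list[str]:
    return [f"s{i + 1:03d}" for i in range(n_subjects)]


def mixed_sample_id(subject: str) -> str:
    return f"mixed_{subject}"


def draw_proportions(
    n_subjects: int,
    truth: SyntheticTruth,
    concentration: float = 200.0,
    seed: int = 0,
    *,
    target: str | None = None,
    scheme: CellTypeScheme | None = None,
) -> ProportionTable:
    """Per-subject cell-type fractions under the truth's proportion mode.

    fixed_remainder: the target's agglomerated fraction is evenly spaced
    across subjects around its configured mean (spread half the distance to
    the nearer of 0 and 1); members of the target split it equally and the
    remaining types split the remainder equally. Deterministic given the
    design. dirichlet: rows ~ Dirichlet(concentration * mean_proportions).
    """
    if n_subjects < 2:
        raise InvalidArgumentError("need at least 2 subjects for proportion variation")
    if concentration <= 0:
        raise InvalidArgumentError("concentration must be positive")
    base_types = truth.base_types
    means = np.array([truth.mean_proportions[t] for t in base_types])
    if (means <= 0).any():
        raise InvalidArgumentError("degenerate mean proportion (zero component)")
    index = pd.Index([mixed_sample_id(s) for s in _subject_ids(n_subjects)], name="sample_id")

    if truth.proportion_mode == "dirichlet":
        rng = np.random.default_rng(seed)
        rows = rng.dirichlet(concentration * means, size=n_subjects)
        return ProportionTable(pd.DataFrame(rows, index=index, columns=list(base_types)))

    if scheme is None:
        scheme = CellTypeScheme(base_types)
    if target is None:
        target = base_types[0]
    members = scheme.members(target)
    others = scheme.complement(target)
    if not others:
        raise InvalidArgumentError(f"target {target!r} leaves no remainder types")
    mean_target = float(sum(truth.mean_proportions[t] for t in members))
    spread = 0.5 * min(mean_target, 1.0 - mean_target)
    p_target = np.linspace(mean_target - spread, mean_target + spread, n_subjects)
    rows = np.empty((n_subjects, len(base_types)))
    for j, cell_type in enumerate(base_types):
        if cell_type in members:
            rows[:, j] = p_target / len(members)
        else:
            rows[:, j] = (1.0 - p_target) / len(others)
    return ProportionTable(pd.DataFrame(rows, index=index, columns=list(base_types)))


def mix_samples(truth: SyntheticTruth, proportions: ProportionTable, seed: int = 0) -> BetaMatrix:
    """Mixed-cell betas: proportion-weighted average of profiles + Normal noise.

    Values are clipped to [0, 1]; the clip count is logged and exposed as
    ``result.n_clipped``. With zero noise the output is exactly the weighted
    average.
    """
    if set(proportions.cell_types) != set(truth.base_types):
        raise SchemaError(
            f"proportion columns {list(proportions.cell_types)} do not match "
            f"truth cell types {list(truth.base_types)}"
        )
    p = proportions.fractions[list(truth.base_types)].to_numpy()
    x = truth.cell_profiles.to_numpy()  # (n_cpgs, K)
    y = p @ x.T  # (n_samples, n_cpgs)
    sd = truth.noise_sd_vector()
    if (sd > 0).any():
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, 1.0, size=y.shape) * sd[None, :]
    clipped = np.clip(y, 0.0, 1.0)
    n_clipped = int((clipped != y).sum())
    if n_clipped:
        logger.warning("clipped %d mixed beta values to [0, 1]", n_clipped)
    subjects = [sid.removeprefix("mixed_") for sid in proportions.sample_ids]
    samples = pd.DataFrame(
        {"subject_id": subjects, "cell_label": MIXED_LABEL}, index=proportions.sample_ids
    )
    bm = BetaMatrix(
        pd.DataFrame(clipped, index=proportions.sample_ids, columns=truth.cpg_ids), samples
    )
    bm.n_clipped = n_clipped
    return bm


def generate_cell_sorted_samples(
    truth: SyntheticTruth, n_subjects: int, within_subject_sd: float, seed: int = 0
) -> BetaMatrix:
    """One purified sample per (subject, cell type): profile + Normal jitter,
    clipped to [0, 1] (count exposed as ``result.n_clipped``)."""
    if within_subject_sd < 0:
        raise InvalidArgumentError("within_subject_sd must be >= 0")
    if n_subjects < 1:
        raise InvalidArgumentError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = _subject_ids(n_subjects)
    x = truth.cell_profiles.to_numpy()  # (n_cpgs, K)
    rows, ids, ann_subject, ann_label = [], [], [], []
    for subject in subjects:
        for t_idx, cell_type in enumerate(truth.base_types):
            vals = x[:, t_idx]
            if within_subject_sd > 0:
                vals = vals + rng.normal(0.0, within_subject_sd, size=vals.shape)
            rows.append(vals)
            ids.append(f"{cell_type}_{subject}")
            ann_subject.append(subject)
            ann_label.append(cell_type)
    raw = np.vstack(rows)
    clipped = np.clip(raw, 0.0, 1.0)
    n_clipped = int((clipped != raw).sum())
    if n_clipped:
        logger.warning("clipped %d sorted beta values to [0, 1]", n_clipped)
    index = pd.Index(ids, name="sample_id")
    samples = pd.DataFrame({"subject_id": ann_subject, "cell_label": ann_label}, index=index)
    bm = BetaMatrix(pd.DataFrame(clipped, index=index, columns=truth.cpg_ids), samples)
    bm.n_clipped = n_clipped
    return bm


# ---------------------------------------------------------------------------
# Whole-study configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    n_cpgs: int = 10000
    n_subjects: int = 6
    cell_types: tuple[str, ...] = DEFAULT_BASE_TYPES
    groupings: dict[str, frozenset[str]] = field(default_factory=lambda: dict(DEFAULT_GROUPINGS))
    mean_proportions: dict[str, float] | None = None
    proportion_mode: str = "fixed_remainder"
    target: str | None = None  # varied target in fixed_remainder mode
    concentration: float = 200.0
    diff_fraction: float = 0.05
    diff_targets: tuple[str, ...] | None = None  # default: base types only
    effect_size: float = 0.4
    noise_sd: float = 0.0
    within_subject_sd: float = 0.0
    seed: int = 0
    baseline_levels: tuple[float, ...] = DEFAULT_BASELINE_LEVELS
    baseline_weights: tuple[float, ...] = DEFAULT_BASELINE_WEIGHTS

    def __post_init__(self) -> None:
        if self.n_cpgs < 1:
            raise InvalidArgumentError("config.n_cpgs must be >= 1")
        if self.n_subjects < 2:
            raise InvalidArgumentError("config.n_subjects must be >= 2")
        if self.proportion_mode not in PROPORTION_MODES:
            raise InvalidArgumentError(
                f"config.proportion_mode must be one of {PROPORTION_MODES}"
            )
        if not 0 <= self.diff_fraction <= 1:
            raise InvalidArgumentError("config.diff_fraction must be in [0, 1]")
        if not 0 < self.effect_size <= 1:
            raise InvalidArgumentError("config.effect_size must be in (0, 1]")
        if self.noise_sd < 0:
            raise InvalidArgumentError("config.noise_sd must be >= 0")
        if self.within_subject_sd < 0:
            raise InvalidArgumentError("config.within_subject_sd must be >= 0")
        if self.concentration <= 0:
            raise InvalidArgumentError("config.concentration must be > 0")
        if not isinstance(self.seed, int):
            raise InvalidArgumentError("config.seed must be an integer")
        self.cell_types = tuple(self.cell_types)
        self.groupings = {k: frozenset(v) for k, v in self.groupings.items()}
        scheme = self.scheme()  # validates types/groupings
        if self.target is not None and not scheme.is_target(self.target):
            raise InvalidArgumentError(f"config.target {self.target!r} not in scheme")
        if self.diff_targets is not None:
            self.diff_targets = tuple(self.diff_targets)
            bad = [t for t in self.diff_targets if not scheme.is_target(t)]
            if bad:
                raise InvalidArgumentError(f"config.diff_targets {bad} not in scheme")

    def scheme(self) -> CellTypeScheme:
        return CellTypeScheme(self.cell_types, dict(self.groupings))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config fields {sorted(unknown)}")
        d = dict(d)
        if "groupings" in d:
            d["groupings"] = {k: frozenset(v) for k, v in d["groupings"].items()}
        for tuple_field in ("cell_types", "baseline_levels", "baseline_weights", "diff_targets"):
            if d.get(tuple_field) is not None:
                d[tuple_field] = tuple(d[tuple_field])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_types"] = list(self.cell_types)
        d["groupings"] = {k: sorted(v) for k, v in self.groupings.items()}
        d["baseline_levels"] = list(self.baseline_levels)
        d["baseline_weights"] = list(self.baseline_weights)
        if self.diff_targets is not None:
            d["diff_targets"] = list(self.diff_targets)
        return d


def generate_dataset(config: SimulationConfig) -> SyntheticBundle:
    """Simulate a full paired study; deterministic for a fixed config."""
    scheme = config.scheme()
    root = np.random.SeedSequence(config.seed)
    seed_profiles, seed_props, seed_mix, seed_sorted = (
        int(s.generate_state(1)[0]) for s in root.spawn(4)
    )
    truth = generate_cell_profiles(
        config.n_cpgs,
        scheme,
        config.diff_fraction,
        config.effect_size,
        seed_profiles,
        baseline_levels=config.baseline_levels,
        baseline_weights=config.baseline_weights,
        mean_proportions=config.mean_proportions,
        proportion_mode=config.proportion_mode,
        noise_sd=config.noise_sd,
        diff_targets=config.diff_targets,
    )
    props = draw_proportions(
        config.n_subjects,
        truth,
        concentration=config.concentration,
        seed=seed_props,
        target=config.target,
        scheme=scheme,
    )
    mixed = mix_samples(truth, props, seed=seed_mix)
    sorted_bm = generate_cell_sorted_samples(
        truth, config.n_subjects, config.within_subject_sd, seed=seed_sorted
    )
    return SyntheticBundle(
        sorted_data=sorted_bm,
        mixed_data=mixed,
        proportions=props,
        truth=truth,
        n_clipped_mixed=getattr(mixed, "n_clipped", 0),
        n_clipped_sorted=getattr(sorted_bm, "n_clipped", 0),
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """betas_sorted.tsv, betas_mixed.tsv, proportions.tsv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(bundle.sorted_data, out / "betas_sorted.tsv")
    write_beta_matrix(bundle.mixed_data, out / "betas_mixed.tsv")
    write_proportions(bundle.proportions, out / "proportions.tsv")
    truth = bundle.truth
    payload = {
        "cell_types": list(truth.base_types),
        "cpg_ids": truth.cpg_ids.tolist(),
        "cell_profiles": {t: truth.cell_profiles[t].tolist() for t in truth.base_types},
        "differential_sets": {k: sorted(v) for k, v in truth.differential_sets.items()},
        "effect_size": truth.effect_size,
        "noise_sd": truth.noise_sd_vector().tolist(),
        "proportion_mode": truth.proportion_mode,
        "mean_proportions": truth.mean_proportions,
        "seed": truth.seed,
        "n_clipped_profiles": truth.n_clipped_profiles,
        "n_clipped_mixed": bundle.n_clipped_mixed,
        "n_clipped_sorted": bundle.n_clipped_sorted,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh)
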