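"""Synthetic coupled-connectome cohorts.

Generates multi-subject SC/FC pairs, covariates and cognitive scores with the
statistical structure the downstream analysis assumes, so the whole pipeline
can be exercised and calibrated without MRI data.

The generative model works at the edge level.  Structural weights are
log-normal with a within-module location bonus (modular block structure).
For each edge group (one group per module's internal edges plus one for all
between-module edges) the structural weights are rank-normalized to a
standard normal ``z`` and a latent functional value is mixed as

    latent = a * z + sqrt(1 - a^2) * noise_sd * eps,   eps ~ N(0, 1)

then squashed to an absolute-correlation-like weight
``fc = |tanh(scale * (latent + shift [+ within-module bonus]))|``.  Because
proportional thresholding restricts the coupling estimator to the strongest
FC edges, the measured coupling statistic is an attenuated, monotone function
of ``a``; the generator inverts a fixed, pre-computed calibration curve so
that a requested coupling *target* is (approximately) the value the estimator
recovers under the default threshold scheme.  Subject-level heterogeneity is
a shared normal offset on all of a subject's targets, and cognition is a
linear model on the subject's true whole-brain coupling plus covariates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import (
    CohortTable,
    ConnectivityMatrix,
    ModulePartition,
    TimeSeriesMatrix,
    ValidationError,
    default_partition,
    write_cohort,
    write_matrix,
)
from .coupling import WHOLE_BRAIN

__all__ = [
    "CognitionSpec",
    "GroupSpec",
    "SimulationConfig",
    "SyntheticSubject",
    "generate_base_sc",
    "generate_fc_from_sc",
    "generate_time_series",
    "nearest_correlation",
    "generate_cohort",
    "write_cohort_dir",
    "latent_coupling",
    "rank_normal",
]

# Squashing map parameters (see module docstring).
SQUASH_SCALE = 0.35
SQUASH_SHIFT = 1.5
#: within-module bonus on the latent FC value (modular FC structure)
FC_MODULE_BONUS = 0.4
#: log-scale within-module bonus on SC weights
SC_MODULE_BONUS = 0.5
#: log-normal sigma of SC edge weights
SC_SIGMA = 0.4

# Calibration of requested (measured) coupling -> latent mixing weight `a`.
# Frozen from a design-time simulation at the default settings (90 regions,
# five modules, default threshold scheme, noise_sd = 1): mean measured
# coupling AUC over 16 seeds at each latent `a`.  Two curves because the two
# edge-group kinds see different squash offsets and pooling:
#  * within-module groups -> measured modular coupling (baseline 0 at a=0);
#  * the between-module group -> measured whole-brain coupling, whose modular
#    block structure alone yields a nonzero baseline (~0.05) and caps the
#    attainable value (~0.77).
# Monotone, so inversion is 1-D interpolation; targets beyond the attainable
# range clamp to the extreme.
_CAL_MODULE_LATENT = np.array(
    [0.00, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 0.95,
     0.99, 0.9999]
)
_CAL_MODULE_MEASURED = np.array(
    [0.0000, 0.0587, 0.1172, 0.1770, 0.2398, 0.3117, 0.3928, 0.4895,
     0.6023, 0.7429, 0.8303, 0.9136, 0.9365]
)
_CAL_BETWEEN_LATENT = np.array(
    [0.00, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50,
     0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 0.97, 0.99,
     0.995, 0.999, 0.9999]
)
_CAL_BETWEEN_MEASURED = np.array(
    [0.0455, 0.0674, 0.0896, 0.1124, 0.1359, 0.1599, 0.1846, 0.2102,
     0.2368, 0.2649, 0.2947, 0.3264, 0.3600, 0.3961, 0.4350, 0.4768,
     0.5229, 0.5745, 0.6316, 0.6965, 0.7248, 0.7550, 0.7628, 0.7691,
     0.7707]
)


def latent_coupling(target: float, within_module: bool = True) -> float:
    """Latent mixing weight whose measured coupling is ``target``.

    ``within_module`` selects the curve for a module's internal edge group;
    otherwise the between-module (whole-brain) curve is used.  Within-module
    inversion is odd-symmetric for negative targets; both clamp to the
    attainable range.
    """
    if not (-1.0 < target < 1.0):
        raise ValidationError(f"coupling target must lie in (-1, 1), got {target}")
    if within_module:
        mag = min(abs(target), _CAL_MODULE_MEASURED[-1])
        a = float(np.interp(mag, _CAL_MODULE_MEASURED, _CAL_MODULE_LATENT))
        return a if target >= 0 else -a
    t = float(np.clip(target, _CAL_BETWEEN_MEASURED[0], _CAL_BETWEEN_MEASURED[-1]))
    return float(np.interp(t, _CAL_BETWEEN_MEASURED, _CAL_BETWEEN_LATENT))


def rank_normal(x: np.ndarray) -> np.ndarray:
    """Map values to standard-normal quantiles by rank (ties by order)."""
    x = np.asarray(x, dtype=float)
    r = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    return norm.ppf((r + 0.5) / len(x))


# ---------------------------------------------------------------------------
# config


@dataclasses.dataclass(frozen=True)
class CognitionSpec:
    """Linear model for one cognitive score.

    ``score = mean + slope_coupling * (a_wb - reference_coupling)
            + sum_k slope_k * (cov_k - cov_mean_k) + N(0, resid_sd)``
    """

    mean: float
    slope_coupling: float
    resid_sd: float
    slopes: Mapping[str, float] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass(frozen=True)
class GroupSpec:
    name: str
    n_subjects: int
    coupling_targets: Mapping[str, float]  # whole_brain + per-module
    efficiency_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError(f"group {self.name}: need n >= 2")
        for scope, a in self.coupling_targets.items():
            if not (-1.0 < a < 1.0):
                raise ValidationError(
                    f"group {self.name}: target for {scope} outside (-1, 1)"
                )


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic cohort.

    Defaults emulate a three-group small-vessel-disease study: 54 severe
    (CSVD-s) and 106 mild (CSVD-m) patients plus 79 controls on a 90-region
    parcellation with five functional modules, whole-brain coupling targets
    0.268 / 0.278 / 0.284 and module targets on the same scale.
    """

    n_regions: int = 90
    partition: ModulePartition | None = None
    group_specs: tuple[GroupSpec, ...] = ()
    noise_sd: float = 1.0
    subject_coupling_sd: float = 0.02
    cognition: Mapping[str, CognitionSpec] = dataclasses.field(default_factory=dict)
    covariate_means: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"age": 62.0, "education": 12.0, "head_motion": 0.12}
    )
    covariate_sds: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"age": 8.0, "education": 3.3, "head_motion": 0.04}
    )
    sex_p: float = 0.55
    head_motion_floor: float = 0.01
    with_timeseries: bool = False
    n_timepoints: int = 190
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ValidationError("need at least 3 regions")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.with_timeseries and self.n_timepoints < self.n_regions + 10:
            raise ValidationError("need T >= n_regions + 10 for time series")
        if self.partition is None:
            object.__setattr__(self, "partition", _make_partition(self.n_regions))
        # allow plain mappings (e.g. parsed YAML) for group and score specs
        if self.group_specs:
            coerced = tuple(
                g if isinstance(g, GroupSpec) else GroupSpec(**g)
                for g in self.group_specs
            )
            object.__setattr__(self, "group_specs", coerced)
        if self.cognition:
            object.__setattr__(
                self,
                "cognition",
                {
                    k: (v if isinstance(v, CognitionSpec) else CognitionSpec(**v))
                    for k, v in self.cognition.items()
                },
            )
        self.partition.validate_against(self.partition.region_labels)
        if len(self.partition.region_labels) != self.n_regions:
            raise ValidationError("partition size does not match n_regions")
        if not self.group_specs:
            object.__setattr__(
                self, "group_specs", default_group_specs(self.partition)
            )
        if not self.cognition:
            object.__setattr__(self, "cognition", default_cognition_specs())

    @property
    def reference_coupling(self) -> float:
        """Cohort-average whole-brain target, the cognition model's centre."""
        ns = np.array([g.n_subjects for g in self.group_specs], dtype=float)
        targets = np.array(
            [g.coupling_targets[WHOLE_BRAIN] for g in self.group_specs]
        )
        return float((ns * targets).sum() / ns.sum())


def _make_partition(n_regions: int) -> ModulePartition:
    if n_regions == 90:
        return default_partition()
    # proportional five-way split for other sizes
    fracs = [20 / 90, 14 / 90, 18 / 90, 18 / 90, 20 / 90]
    names = ["auditory_motor", "vision", "attention", "dmn", "limbic_subcortical"]
    sizes = [max(1, int(round(f * n_regions))) for f in fracs]
    while sum(sizes) > n_regions:
        sizes[int(np.argmax(sizes))] -= 1
    while sum(sizes) < n_regions:
        sizes[int(np.argmin(sizes))] += 1
    assignment = {}
    i = 0
    for name, size in zip(names, sizes):
        for _ in range(size):
            i += 1
            assignment[f"R{i:02d}"] = name
    return ModulePartition(assignment, tuple(names))


def default_group_specs(partition: ModulePartition) -> tuple[GroupSpec, ...]:
    """Three-group regime: severe patients lowest coupling, controls highest."""
    mods = partition.module_names
    # per-module targets for (CSVD-s, CSVD-m, HC); falls back to the
    # whole-brain target when the partition uses non-default module names
    module_targets = {
        "auditory_motor": (0.192, 0.214, 0.228),
        "vision": (0.247, 0.250, 0.249),
        "attention": (0.255, 0.281, 0.264),
        "dmn": (0.389, 0.393, 0.395),
        "limbic_subcortical": (0.262, 0.291, 0.297),
    }
    wb = (0.268, 0.278, 0.284)
    names = ("CSVD-s", "CSVD-m", "HC")
    ns = (54, 106, 79)
    eff = (0.0, -0.05, 0.0)
    specs = []
    for gi, name in enumerate(names):
        targets = {WHOLE_BRAIN: wb[gi]}
        for m in mods:
            targets[m] = module_targets.get(m, wb)[gi]
        specs.append(GroupSpec(name, ns[gi], targets, eff[gi]))
    return tuple(specs)


def default_cognition_specs() -> dict[str, CognitionSpec]:
    """Score models yielding coupling-cognition partial correlations ~0.2-0.4.

    Means sit at mild-group levels of the emulated cohort; inhibition (SCWT)
    and set-shifting (TMT) scores worsen (increase) as coupling drops.
    """
    return {
        "MoCA": CognitionSpec(25.4, 88.0, 3.2, {"age": -0.05, "education": 0.2}),
        "AVLT": CognitionSpec(60.8, 330.0, 12.0, {"age": -0.2, "education": 0.5}),
        "SCWT": CognitionSpec(149.0, -1230.0, 45.0, {"age": 0.8}),
        "SDMT": CognitionSpec(33.4, 330.0, 12.0, {"age": -0.3, "education": 0.6}),
        "TMT": CognitionSpec(128.0, -2700.0, 100.0, {"age": 1.5}),
    }


# ---------------------------------------------------------------------------
# generators


@dataclasses.dataclass(frozen=True)
class SyntheticSubject:
    id: str
    group: str
    sc: ConnectivityMatrix
    fc: ConnectivityMatrix
    covariates: dict[str, float]
    scores: dict[str, float]
    true_coupling: dict[str, float]  # requested targets incl. subject offset
    ts: TimeSeriesMatrix | None = None


def _edge_groups(
    partition: ModulePartition, labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Upper-triangle edges and a boolean mask per edge group."""
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    idx = partition.indices(labels)
    masks: dict[str, np.ndarray] = {}
    within_any = np.zeros(len(iu), dtype=bool)
    for m, ix in idx.items():
        flag = np.zeros(n, dtype=bool)
        flag[ix] = True
        mask = flag[iu] & flag[ju]
        masks[m] = mask
        within_any |= mask
    masks[WHOLE_BRAIN] = ~within_any  # between-module edges
    return iu, ju, masks


def generate_base_sc(
    n_regions: int,
    partition: ModulePartition,
    rng: np.random.Generator,
) -> ConnectivityMatrix:
    """Log-normal structural weights with a within-module location bonus."""
    if n_regions < 3:
        raise ValidationError("need at least 3 regions")
    labels = partition.region_labels
    if len(labels) != n_regions:
        raise ValidationError("partition size does not match n_regions")
    iu, ju, masks = _edge_groups(partition, labels)
    log_w = SC_SIGMA * rng.standard_normal(len(iu))
    within = ~masks[WHOLE_BRAIN]
    log_w[within] += SC_MODULE_BONUS
    w_edges = np.exp(log_w)
    w = np.zeros((n_regions, n_regions))
    w[iu, ju] = w_edges
    w[ju, iu] = w_edges
    w /= w.max()  # connection-probability-like scale
    return ConnectivityMatrix(labels, w, "structural")


def generate_fc_from_sc(
    sc: ConnectivityMatrix,
    coupling_targets: Mapping[str, float] | float,
    partition: ModulePartition | None = None,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
    efficiency_shift: float = 0.0,
    module_bonus: float = FC_MODULE_BONUS,
) -> ConnectivityMatrix:
    """Functional matrix whose measured coupling tracks the requested targets.

    ``coupling_targets`` is either a single value for every edge or a mapping
    with per-module values (within-module edges) and a ``"whole_brain"`` value
    (between-module edges).  Targets are passed through the frozen calibration
    so that the coupling estimator under the default threshold scheme
    recovers approximately the requested value.
    """
    rng = rng or np.random.default_rng()
    if partition is None:
        partition = ModulePartition.from_assignment(
            {lab: "all" for lab in sc.region_labels}
        )
    partition.validate_against(sc.region_labels)
    if isinstance(coupling_targets, (int, float)):
        coupling_targets = {
            **{m: float(coupling_targets) for m in partition.module_names},
            WHOLE_BRAIN: float(coupling_targets),
        }
    iu, ju, masks = _edge_groups(partition, sc.region_labels)
    sc_edges = sc.weights[iu, ju]
    latent = np.empty(len(iu))
    group_names = [*partition.module_names, WHOLE_BRAIN]
    for name in group_names:
        mask = masks[name]
        if not mask.any():
            continue
        vals = sc_edges[mask]
        if np.ptp(vals) == 0.0:
            raise ValidationError(
                f"degenerate SC: zero variance within edge group {name!r}"
            )
        target = float(
            coupling_targets.get(name, coupling_targets.get(WHOLE_BRAIN, 0.0))
        )
        a = latent_coupling(target, within_module=(name != WHOLE_BRAIN))
        z = rank_normal(vals)
        eps = rng.standard_normal(mask.sum())
        latent[mask] = a * z + np.sqrt(max(0.0, 1.0 - a * a)) * noise_sd * eps
    within = ~masks[WHOLE_BRAIN]
    shift = SQUASH_SHIFT + efficiency_shift + module_bonus * within
    fc_edges = np.abs(np.tanh(SQUASH_SCALE * (latent + shift)))
    fc = np.zeros_like(sc.weights)
    fc[iu, ju] = fc_edges
    fc[ju, iu] = fc_edges
    return ConnectivityMatrix(sc.region_labels, fc, "functional")


def nearest_correlation(
    m: np.ndarray, tol: float = 1e-10, max_iter: int = 200, floor: float = 1e-8
) -> np.ndarray:
    """Nearest valid correlation matrix by alternating projections.

    Eigenvalue clipping at ``floor`` followed by unit-diagonal renormalization,
    iterated to a Frobenius-change tolerance.  Inputs already valid are fixed
    points (returned unchanged up to the tolerance).
    """
    a = np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("input must be square")
    if np.abs(a - a.T).max() > 1e-8:
        raise ValidationError("input must be symmetric")
    x = (a + a.T) / 2.0
    np.fill_diagonal(x, 1.0)
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(x)
        clipped = np.clip(vals, floor, None)
        y = (vecs * clipped) @ vecs.T
        d = np.sqrt(np.clip(np.diag(y), floor, None))
        y = y / np.outer(d, d)
        np.fill_diagonal(y, 1.0)
        if np.linalg.norm(y - x, "fro") < tol:
            x = y
            break
        x = y
    return (x + x.T) / 2.0


def generate_time_series(
    fc_target: ConnectivityMatrix,
    T: int,
    rng: np.random.Generator | None = None,
    sampling_interval: float = 1.0,
) -> TimeSeriesMatrix:
    """Zero-mean Gaussian series whose correlation matrix approaches the
    target FC (off-diagonal entries taken as target correlations, diagonal 1).

    For ``T < n_regions + 1`` the sample correlation matrix is rank-deficient
    (degraded but usable); ``T < 3`` is an error.
    """
    if T < 3:
        raise ValidationError("need T >= 3")
    rng = rng or np.random.default_rng()
    c = fc_target.weights.copy()
    np.fill_diagonal(c, 1.0)
    c = nearest_correlation(c)
    # Cholesky with a tiny jitter ladder for numerically semidefinite inputs
    jitter = 0.0
    for _ in range(6):
        try:
            L = np.linalg.cholesky(c + jitter * np.eye(c.shape[0]))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10)
    else:  # pragma: no cover
        raise ValidationError("target correlation matrix is numerically singular")
    x = L @ rng.standard_normal((c.shape[0], T))
    return TimeSeriesMatrix(fc_target.region_labels, x, sampling_interval)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, floor: float, size: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = out < floor
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.maximum(out, floor)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[SyntheticSubject], CohortTable]:
    """Draw the full cohort: per-subject SC/FC, covariates and scores.

    A single RNG stream seeded from ``config.seed`` drives everything, so the
    same config yields byte-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    partition = config.partition
    subjects: list[SyntheticSubject] = []
    rows = []
    cm = config.covariate_means
    cs = config.covariate_sds
    sid = 0
    for spec in config.group_specs:
        for _ in range(spec.n_subjects):
            sid += 1
            subj_id = f"sub-{sid:03d}"
            offset = config.subject_coupling_sd * rng.standard_normal()
            targets = {
                scope: float(np.clip(t + offset, -0.94, 0.94))
                for scope, t in spec.coupling_targets.items()
            }
            sc = generate_base_sc(config.n_regions, partition, rng)
            fc = generate_fc_from_sc(
                sc,
                targets,
                partition=partition,
                noise_sd=config.noise_sd,
                rng=rng,
                efficiency_shift=spec.efficiency_shift,
            )
            covs = {
                "age": float(rng.normal(cm["age"], cs["age"])),
                "sex": float(rng.random() < config.sex_p),
                "education": float(
                    max(0.0, rng.normal(cm["education"], cs["education"]))
                ),
                "head_motion": float(
                    _truncated_normal(
                        rng, cm["head_motion"], cs["head_motion"],
                        config.head_motion_floor, 1,
                    )[0]
                ),
            }
            scores = {}
            for name, cg in config.cognition.items():
                val = cg.mean + cg.slope_coupling * (
                    targets[WHOLE_BRAIN] - config.reference_coupling
                )
                for cov_name, slope in cg.slopes.items():
                    val += slope * (covs[cov_name] - cm.get(cov_name, 0.0))
                val += cg.resid_sd * rng.standard_normal()
                scores[name] = float(val)
            ts = None
            if config.with_timeseries:
                ts = generate_time_series(fc, config.n_timepoints, rng)
            subjects.append(
                SyntheticSubject(
                    subj_id, spec.name, sc, fc, covs, scores, targets, ts
                )
            )
            rows.append({"id": subj_id, "group": spec.name, **covs, **scores})
    frame = pd.DataFrame(rows)
    cohort = CohortTable(frame, group_order=[g.name for g in config.group_specs])
    return subjects, cohort


def write_cohort_dir(
    subjects: Sequence[SyntheticSubject],
    cohort: CohortTable,
    out_dir: str | Path,
) -> None:
    """Write per-subject matrices, the cohort table and the ground truth."""
    out = Path(out_dir)
    (out / "sc").mkdir(parents=True, exist_ok=True)
    (out / "fc").mkdir(parents=True, exist_ok=True)
    for s in subjects:
        write_matrix(s.sc, out / "sc" / f"{s.id}.tsv")
        write_matrix(s.fc, out / "fc" / f"{s.id}.tsv")
    write_cohort(cohort, out / "cohort.tsv")
    truth = pd.DataFrame(
        [{"id": s.id, "group": s.group, **{f"true_{k}": v for k, v in s.true_coupling.items()}}
         for s in subjects]
    )
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
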