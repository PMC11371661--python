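"""Study-level model object tying the pipeline together.

:class:`CouplingStudy` is built from per-subject FC/SC matrices plus a cohort
table (or directly from a simulation config); :meth:`CouplingStudy.fit` runs
the threshold series, coupling and topology profiles, the covariate-adjusted
group comparisons and the per-group brain-cognition partial correlations, and
returns a :class:`CouplingStudyResults` carrying the report tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CohortTable,
    ConnectivityMatrix,
    ModulePartition,
    ValidationError,
    read_cohort,
    read_matrix,
    read_partition,
)
from .network import ThresholdScheme
from .coupling import WHOLE_BRAIN, coupling_profile
from .topology import topology_profile
from .simulate import SimulationConfig, SyntheticSubject, generate_cohort
from .stats import (
    ancova_group_test,
    anova_oneway,
    bh_fdr,
    chi_square_independence,
    lsd_posthoc,
    partial_correlation,
)

__all__ = [
    "CouplingStudy",
    "CouplingStudyResults",
    "make_demographics_table",
    "format_p",
    "format_percent",
]

log = logging.getLogger("scfc")

DEFAULT_COVARIATES = ("head_motion", "age", "sex", "education")


def format_p(p: float) -> str:
    """Report-style p formatting: 3 decimals with a '<0.001' floor."""
    if not np.isfinite(p):
        return "NA"
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


def format_percent(count: int, total: int) -> str:
    """Percentage to 1 decimal, rounded half away from zero."""
    frac = 100.0 * count / total
    q = np.floor(abs(frac) * 10 + 0.5) / 10 * np.sign(frac)
    return f"{q:.1f}%"


def make_demographics_table(cohort: CohortTable) -> pd.DataFrame:
    """Per-group descriptive statistics with omnibus and post hoc tests.

    Continuous rows (age, education, head motion, cognitive scores) show
    mean +/- sd per group with a one-way ANOVA p and LSD post hoc p-values
    when the omnibus is significant; binary rows (sex, history markers) show
    counts (%) with a Pearson chi-square p.  Single-group cohorts get
    descriptive columns only.
    """
    groups = cohort.group_order
    df = cohort.frame
    single = len(groups) < 2
    rows = []
    continuous = ["age", "education", "head_motion", *cohort.score_columns]

    def group_vals(col: str) -> list[np.ndarray]:
        return [
            df.loc[df["group"] == g, col].dropna().to_numpy(dtype=float)
            for g in groups
        ]

    # sex row (counts of code 1 vs 0)
    sex_counts = [
        (int((df.loc[df["group"] == g, "sex"] == 1).sum()), int((df["group"] == g).sum()))
        for g in groups
    ]
    row = {"characteristic": "sex (code 1)", "test": "chi2"}
    for g, (k, n) in zip(groups, sex_counts):
        row[g] = f"{k} ({format_percent(k, n)})"
    if not single:
        table = [[k for k, _ in sex_counts], [n - k for k, n in sex_counts]]
        try:
            _, _, p, _ = chi_square_independence(table)
            row["p"] = format_p(p)
        except ValueError:
            row["p"] = "NA"
    rows.append(row)

    for col in continuous:
        vals = group_vals(col)
        row = {"characteristic": col, "test": "anova"}
        for g, v in zip(groups, vals):
            row[g] = f"{v.mean():.2f} ± {v.std(ddof=1):.2f}" if len(v) > 1 else "NA"
        if not single and all(len(v) >= 2 for v in vals):
            _, _, p = anova_oneway(*vals)
            row["p"] = format_p(p)
            if p < 0.05:
                ph = lsd_posthoc(*vals)
                for i in range(len(groups)):
                    for j in range(i + 1, len(groups)):
                        row[f"{groups[i]} vs {groups[j]}"] = format_p(ph[i, j])
        rows.append(row)

    for col in cohort.marker_columns:
        sub = df.dropna(subset=[col])
        present = [g for g in groups if (sub["group"] == g).any()]
        counts = [
            (int((sub.loc[sub["group"] == g, col] == 1).sum()),
             int((sub["group"] == g).sum()))
            for g in present
        ]
        row = {"characteristic": col, "test": "chi2"}
        for g, (k, n) in zip(present, counts):
            row[g] = f"{k} ({format_percent(k, n)})"
        if len(present) >= 2:
            table = [[k for k, _ in counts], [n - k for k, n in counts]]
            try:
                _, _, p, _ = chi_square_independence(table)
                row["p"] = format_p(p)
            except ValueError:
                row["p"] = "NA"
        rows.append(row)
    return pd.DataFrame(rows)


class CouplingStudy:
    """SC-FC coupling study over a cohort of paired connectomes.

    Parameters
    ----------
    fc, sc
        Mappings ``subject id -> ConnectivityMatrix``; ids must appear in
        ``cohort``.
    cohort
        The :class:`CohortTable` with group labels, covariates and scores.
    partition
        Five-module (or any) region partition; region order is canonical.
    scheme
        Sparsity series, default 8%..60% step 2%.
    covariates
        Cohort columns adjusted for in ANCOVA and partial correlations.
    lp_convention
        ``"harmonic"`` (Lp = 1/Eglob) or ``"arithmetic"``.
    correlate_all
        When False (default, mirroring the usual reporting practice) partial
        correlations are computed only for metrics whose omnibus ANCOVA is
        significant at 0.05; when True, for all global metrics.
    """

    def __init__(
        self,
        fc: Mapping[str, ConnectivityMatrix],
        sc: Mapping[str, ConnectivityMatrix],
        cohort: CohortTable,
        partition: ModulePartition,
        scheme: ThresholdScheme | None = None,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        lp_convention: str = "harmonic",
        include_topology: bool = True,
        include_nodal: bool = True,
        correlate_all: bool = False,
        seed: int = 0,
    ):
        ids = list(cohort.ids)
        missing = [i for i in ids if i not in fc or i not in sc]
        if missing:
            raise ValidationError(f"subjects without matrices: {missing}")
        extra = [i for i in fc if i not in set(ids)]
        if extra:
            raise ValidationError(f"matrices without cohort rows: {extra}")
        order = partition.region_labels
        self.fc = {i: fc[i].reorder(order) for i in ids}
        self.sc = {i: sc[i].reorder(order) for i in ids}
        self.cohort = cohort
        self.partition = partition
        self.scheme = scheme or ThresholdScheme.default()
        self.covariates = tuple(covariates)
        self.lp_convention = lp_convention
        self.include_topology = include_topology
        self.include_nodal = include_nodal
        self.correlate_all = correlate_all
        self.seed = seed
        self.subjects: list[SyntheticSubject] | None = None

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_simulation(
        cls, config: SimulationConfig, **kwargs
    ) -> "CouplingStudy":
        subjects, cohort = generate_cohort(config)
        study = cls(
            {s.id: s.fc for s in subjects},
            {s.id: s.sc for s in subjects},
            cohort,
            config.partition,
            seed=config.seed,
            **kwargs,
        )
        study.subjects = subjects
        return study

    @classmethod
    def from_directory(
        cls,
        root: str | Path,
        partition_path: str | Path | None = None,
        group_order: Sequence[str] | None = None,
        **kwargs,
    ) -> "CouplingStudy":
        """Load ``<root>/fc/*.tsv``, ``<root>/sc/*.tsv``, ``<root>/cohort.tsv``
        and an optional partition file (default ``<root>/partition.tsv``)."""
        root = Path(root)
        cohort = read_cohort(root / "cohort.tsv", group_order)
        if partition_path is None:
            partition_path = root / "partition.tsv"
        partition = read_partition(partition_path)
        fc = {
            p.stem: read_matrix(p, "functional", partition)
            for p in sorted((root / "fc").glob("*.tsv"))
        }
        sc = {
            p.stem: read_matrix(p, "structural", partition)
            for p in sorted((root / "sc").glob("*.tsv"))
        }
        return cls(fc, sc, cohort, partition, **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "CouplingStudyResults":
        """Run the full analysis chain and return the results object."""
        ids = list(self.cohort.ids)
        log.info("fitting study: %d subjects, %d thresholds", len(ids), len(self.scheme))
        metric_rows = {}
        curve_rows = []
        for sid in ids:
            prof = coupling_profile(
                self.fc[sid], self.sc[sid], self.partition, self.scheme, sid
            )
            row = {
                f"coupling_{scope}": prof.auc[scope]
                for scope in (WHOLE_BRAIN, *self.partition.module_names)
            }
            for _, r in prof.table.iterrows():
                curve_rows.append(
                    (sid, f"coupling_{r['scope']}", r["sparsity"], r["r"])
                )
            if self.include_topology:
                top = topology_profile(
                    self.fc[sid], self.scheme, sid, self.lp_convention
                )
                row.update({m: top.auc[m] for m in ("Lp", "Eglob", "Eloc")})
                if self.include_nodal:
                    row.update(
                        {f"Enodal_{lab}": v for lab, v in top.nodal_auc.items()}
                    )
                for _, r in top.globals_table.iterrows():
                    for m in ("Lp", "Eglob", "Eloc"):
                        curve_rows.append((sid, m, r["sparsity"], r[m]))
            metric_rows[sid] = row
        metrics = pd.DataFrame.from_dict(metric_rows, orient="index")
        metrics.index.name = "id"
        curves = pd.DataFrame(
            curve_rows, columns=["id", "metric", "sparsity", "value"]
        )
        return self._infer(metrics, curves)

    def _infer(self, metrics: pd.DataFrame, curves: pd.DataFrame) -> "CouplingStudyResults":
        df = self.cohort.frame.set_index("id")
        groups = df.loc[metrics.index, "group"].to_numpy()
        cov = df.loc[metrics.index, list(self.covariates)] if self.covariates else None
        order = list(self.cohort.group_order)

        comp_rows = []
        results_by_metric = {}
        multi_group = len(order) >= 2
        for metric in metrics.columns:
            y = metrics[metric].to_numpy(dtype=float)
            if not multi_group or not np.isfinite(y).any():
                continue
            try:
                res = ancova_group_test(y, groups, cov, order, metric)
            except ValueError as err:
                log.warning("ANCOVA skipped for %s: %s", metric, err)
                continue
            results_by_metric[metric] = res
            row = {
                "metric": metric,
                "F": res.f,
                "df1": res.df[0],
                "df2": res.df[1],
                "p": res.p,
            }
            for g in order:
                row[f"mean_{g}"] = res.group_means[g]
                row[f"sd_{g}"] = res.group_sds[g]
                row[f"adj_mean_{g}"] = res.adjusted_means[g]
            for (a, b), p in res.posthoc_p.items():
                row[f"p_{a}_vs_{b}"] = p
            comp_rows.append(row)
        comparisons = pd.DataFrame(comp_rows)

        # per-group partial correlations with cognition, BH-FDR within group
        global_metrics = [
            m for m in metrics.columns if not m.startswith("Enodal_")
        ]
        if self.correlate_all:
            selected = global_metrics
        else:
            selected = [
                m
                for m in global_metrics
                if m in results_by_metric and results_by_metric[m].p < 0.05
            ]
        corr_rows = []
        scores = self.cohort.score_columns
        for g in order:
            gmask = groups == g
            block = []
            for metric in selected:
                for score in scores:
                    x = metrics.loc[gmask, metric].to_numpy(dtype=float)
                    yv = df.loc[metrics.index[gmask], score].to_numpy(dtype=float)
                    zz = (
                        df.loc[metrics.index[gmask], list(self.covariates)]
                        if self.covariates
                        else None
                    )
                    try:
                        r, dfree, p = partial_correlation(x, yv, zz)
                    except ValueError:
                        continue
                    block.append(
                        {"group": g, "metric": metric, "score": score,
                         "r": r, "df": dfree, "p": p}
                    )
            if block:
                q = bh_fdr([b["p"] for b in block])
                for b, qv in zip(block, q):
                    b["q"] = float(qv)
                corr_rows.extend(block)
        correlations = pd.DataFrame(corr_rows)

        demographics = make_demographics_table(self.cohort)

        curve_summary = (
            curves.merge(df[["group"]], left_on="id", right_index=True)
            .groupby(["metric", "sparsity", "group"])["value"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )

        meta = {
            "version": _pkg_version(),
            "seed": self.seed,
            "n_subjects": len(metrics),
            "groups": order,
            "scheme": list(self.scheme.values),
            "covariates": list(self.covariates),
            "lp_convention": self.lp_convention,
            "absolute_fc": True,
            "fdr": "bh",
        }
        meta["config_hash"] = hashlib.sha256(
            json.dumps(meta, sort_keys=True).encode()
        ).hexdigest()[:16]
        return CouplingStudyResults(
            study=self,
            metrics=metrics,
            demographics=demographics,
            group_comparisons=comparisons,
            correlations=correlations,
            curves=curve_summary,
            metadata=meta,
        )


def _pkg_version() -> str:
    from . import __version__

    return __version__


@dataclasses.dataclass
class CouplingStudyResults:
    """Fitted study: per-subject metrics, report tables, and metadata.

    Attributes
    ----------
    metrics
        Per-subject AUC metrics (coupling per scope, Lp/Eglob/Eloc, nodal
        efficiencies), indexed by subject id.
    demographics
        Table-1-style per-group descriptives with tests.
    group_comparisons
        Per-metric ANCOVA omnibus + LSD-style post hoc p-values, raw and
        adjusted group means.
    correlations
        Per-group partial correlations metric x score with BH-FDR q-values.
    curves
        Per-threshold group mean/sd of every metric (figure-style table).
    """

    study: CouplingStudy
    metrics: pd.DataFrame
    demographics: pd.DataFrame
    group_comparisons: pd.DataFrame
    correlations: pd.DataFrame
    curves: pd.DataFrame
    metadata: dict

    def summary(self) -> str:
        """Human-readable overview of the fitted study."""
        lines = []
        meta = self.metadata
        lines.append("SC-FC coupling study")
        lines.append(
            f"  subjects: {meta['n_subjects']}  groups: {', '.join(meta['groups'])}"
        )
        lines.append(
            f"  thresholds: {len(meta['scheme'])} "
            f"({meta['scheme'][0]:.2f}..{meta['scheme'][-1]:.2f})"
        )
        lines.append(f"  covariates: {', '.join(meta['covariates']) or 'none'}")
        lines.append("")
        if not self.group_comparisons.empty:
            lines.append("Group comparisons (ANCOVA on AUC metrics):")
            show = self.group_comparisons[
                ~self.group_comparisons["metric"].str.startswith("Enodal_")
            ]
            for _, r in show.iterrows():
                means = "  ".join(
                    f"{g}={r[f'mean_{g}']:.3f}" for g in meta["groups"]
                )
                lines.append(
                    f"  {r['metric']:<28s} F={r['F']:.2f} p={format_p(r['p'])}  {means}"
                )
            nsig = int((show["p"] < 0.05).sum())
            lines.append(f"  ({nsig} global metrics significant at 0.05)")
        if not self.correlations.empty:
            lines.append("")
            lines.append("Partial correlations with cognition (significant, FDR q<0.05):")
            sig = self.correlations[self.correlations["q"] < 0.05]
            if sig.empty:
                lines.append("  none")
            for _, r in sig.iterrows():
                lines.append(
                    f"  [{r['group']}] {r['metric']} ~ {r['score']}: "
                    f"r={r['r']:.3f} p={format_p(r['p'])} q={format_p(r['q'])}"
                )
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Write all report tables as TSV plus a JSON metadata file."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# scfc {self.metadata['version']} config={self.metadata['config_hash']} seed={self.metadata['seed']}\n"
        for name, df in (
            ("metrics", self.metrics.reset_index()),
            ("demographics", self.demographics),
            ("group_comparisons", self.group_comparisons),
            ("correlations", self.correlations),
            ("curves", self.curves),
        ):
            path = out / f"{name}.tsv"
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        with open(out / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)
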