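"""Cohort-level HRV analysis as a model / results pair.

:class:`CohortHRV` is built from data (a directory of RR files plus a
metadata table, in-memory series, or a simulation config); :meth:`fit`
runs the full pipeline — segment selection, artifact repair, linear
indices, correlation dimension, HRV grade, cohort statistics — and returns
a :class:`CohortHRVResults` carrying the per-subject table, group
descriptives, the Mann–Whitney group contrast on D2, the (partial)
correlation matrices in the patient group, achieved power, and a
``summary()`` text report.  Plotting and table export hang off the results
object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .dimension import EmbeddingConfig, d2 as compute_d2
from .grade import NormativeTable, default_normative_table, grade as compute_grade
from .io import RRSeries, SubjectMeta, read_metadata, read_rr
from .metrics import compute_profile
from .preprocess import (
    correct_artifacts,
    detect_artifacts,
    resample_tachogram,
    select_segment,
)
from .simulate import CohortSimConfig, attach_clinical, simulate_cohort
from .stats import (
    CorrelationReport,
    Descriptives,
    correlation_matrix,
    descriptives,
    mann_whitney_u,
    posthoc_power,
    shapiro_wilk,
)

__all__ = ["PipelineConfig", "CohortHRV", "CohortHRVResults"]

#: HRV index columns of the per-subject table, in report order
INDEX_COLUMNS = [
    "sdnn", "rmssd", "nn50", "pnn50", "rr_tri",
    "vlf", "lf", "hf", "total_power", "lf_hf",
    "sd1", "sd2", "d2",
]

CLINICAL_COLUMNS = [
    "fiq", "nrs", "sf36_phi", "maf", "sas", "sds", "mos", "wpi", "ss",
    "disease_duration",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the analysis pipeline, echoed into the run manifest."""

    segment_duration_s: float = 300.0
    artifact_threshold: float = 0.20
    artifact_max_fraction: float = 0.05
    tachogram_fs: float = 4.0
    welch_window_s: float = 150.0
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    grade_mode: str = "low_only"
    alpha: float = 0.001
    correlation_group: str = "FM"
    control: tuple[str, ...] = ("age",)


class CohortHRV:
    """HRV pipeline model over a cohort of RR recordings.

    Parameters
    ----------
    series : sequence of RRSeries
        One recording per subject.
    metadata : sequence of SubjectMeta
        Group, age, sex and (optionally pre-existing) clinical scores,
        matched to the series by ``subject_id``.
    config : PipelineConfig, optional
    normative : NormativeTable, optional
        Limits for the HRV grade; defaults to the packaged table.
    """

    def __init__(
        self,
        series: Sequence[RRSeries],
        metadata: Sequence[SubjectMeta],
        config: PipelineConfig | None = None,
        normative: NormativeTable | None = None,
    ) -> None:
        self.series = list(series)
        self.metadata = {m.subject_id: m for m in metadata}
        missing = [s.subject_id for s in self.series
                   if s.subject_id not in self.metadata]
        if missing:
            raise ValueError(f"no metadata for subjects {missing}")
        self.config = config or PipelineConfig()
        self.normative = normative or default_normative_table()
        self.sim_config: CohortSimConfig | None = None
        self.load_errors: list[tuple[str, str]] = []

    # ------------------------------------------------------------------ #
    @classmethod
    def from_directory(
        cls,
        rr_dir: str | Path,
        metadata_path: str | Path,
        config: PipelineConfig | None = None,
        normative: NormativeTable | None = None,
        unit: str = "auto",
    ) -> "CohortHRV":
        """Build from one RR file per subject (``<subject_id>.txt``) plus a
        metadata CSV.  Unreadable files are recorded as excluded subjects,
        never silently dropped."""
        rr_dir = Path(rr_dir)
        metadata = read_metadata(metadata_path)
        series: list[RRSeries] = []
        errors: list[tuple[str, str]] = []
        for meta in metadata:
            candidates = [rr_dir / f"{meta.subject_id}{ext}"
                          for ext in (".txt", ".csv", ".rr")]
            path = next((p for p in candidates if p.exists()), None)
            if path is None:
                errors.append((meta.subject_id, "RR file not found"))
                continue
            try:
                series.append(read_rr(path, unit=unit,
                                      subject_id=meta.subject_id))
            except Exception as exc:  # corrupt file → excluded, not fatal
                errors.append((meta.subject_id, f"read error: {exc}"))
        model = cls(series, metadata, config=config, normative=normative)
        model.load_errors = errors
        return model

    @classmethod
    def from_simulation(
        cls,
        sim_config: CohortSimConfig | None = None,
        config: PipelineConfig | None = None,
        normative: NormativeTable | None = None,
    ) -> "CohortHRV":
        """Build from a synthetic cohort (see :mod:`kardia.simulate`)."""
        sim_config = sim_config or CohortSimConfig()
        series, metadata = simulate_cohort(sim_config)
        model = cls(series, metadata, config=config, normative=normative)
        model.sim_config = sim_config
        return model

    # ------------------------------------------------------------------ #
    def _analyze_subject(self, series: RRSeries) -> dict[str, float]:
        cfg = self.config
        segment = select_segment(series, duration_s=cfg.segment_duration_s)
        mask = detect_artifacts(segment, threshold=cfg.artifact_threshold)
        segment = correct_artifacts(segment, mask,
                                    max_fraction=cfg.artifact_max_fraction)
        tacho = resample_tachogram(segment, fs=cfg.tachogram_fs)
        profile = compute_profile(segment, tacho, window_s=cfg.welch_window_s)
        result = compute_d2(segment, cfg.embedding)
        profile.d2 = result.d2
        row = profile.as_dict()
        row["d2_flag"] = result.quality_flag
        row["n_beats"] = len(segment)
        row["artifact_fraction"] = mask.fraction
        return row

    def fit(self) -> "CohortHRVResults":
        """Run the pipeline on every subject and compute cohort statistics."""
        cfg = self.config
        rows: list[dict] = []
        excluded: list[tuple[str, str]] = list(self.load_errors)
        for series in self.series:
            meta = self.metadata[series.subject_id]
            try:
                row = self._analyze_subject(series)
            except Exception as exc:
                excluded.append((series.subject_id, f"{type(exc).__name__}: {exc}"))
                continue
            g = compute_grade(
                {k: row[k] for k in ("sdnn", "rmssd", "total_power")},
                self.normative, mode=cfg.grade_mode,
            )
            row.update(
                subject_id=series.subject_id,
                group=meta.group,
                age=meta.age,
                sex=meta.sex,
                grade=g.grade,
            )
            for name in CLINICAL_COLUMNS:
                if name in meta.clinical:
                    row[name] = meta.clinical[name]
            rows.append(row)
        if not rows:
            raise ValueError("no subject passed the pipeline quality gates")
        table = pd.DataFrame(rows).set_index("subject_id")

        # clinical covariates: attach by copula when simulated and absent
        if self.sim_config is not None and "fiq" not in table.columns:
            fm = table[table["group"] == "FM"]
            attached = attach_clinical(
                fm, self.sim_config.copula_targets,
                seed=self.sim_config.seed + 1,
            )
            for col in attached.columns.difference(table.columns):
                table[col] = attached[col]

        return CohortHRVResults(model=self, table=table, excluded=excluded)


class CohortHRVResults:
    """Fitted cohort results: tables, tests, correlations and export."""

    def __init__(self, model: CohortHRV, table: pd.DataFrame,
                 excluded: list[tuple[str, str]]) -> None:
        self.model = model
        self.table = table
        self.excluded = excluded
        cfg = model.config

        hc = table.loc[table["group"] == "HC", "d2"].to_numpy(dtype=float)
        fm = table.loc[table["group"] == "FM", "d2"].to_numpy(dtype=float)
        self.d2_descriptives: dict[str, Descriptives] = {}
        if hc.size >= 2:
            self.d2_descriptives["HC"] = descriptives(hc)
        if fm.size >= 2:
            self.d2_descriptives["FM"] = descriptives(fm)

        self.shapiro: tuple[float, float] | None = None
        self.mannwhitney: tuple[float, float] | None = None
        self.power: float | None = None
        if hc.size >= 3 and fm.size >= 3:
            pooled = np.concatenate([hc, fm])
            try:
                self.shapiro = shapiro_wilk(pooled)
            except ValueError:
                self.shapiro = None
            self.mannwhitney = mann_whitney_u(hc, fm)
            dh, df_ = self.d2_descriptives["HC"], self.d2_descriptives["FM"]
            if dh.sd > 0 and df_.sd > 0:
                self.power = posthoc_power(
                    dh.mean, dh.sd, dh.n, df_.mean, df_.sd, df_.n,
                    alpha=0.05, method="t_noncentral",
                )

        corr_rows = table[table["group"] == cfg.correlation_group]
        variables = [c for c in INDEX_COLUMNS + ["grade"] + CLINICAL_COLUMNS
                     if c in corr_rows.columns
                     and corr_rows[c].notna().sum() >= 4]
        control = [c for c in cfg.control if c in corr_rows.columns]
        self.spearman: CorrelationReport | None = None
        self.pearson: CorrelationReport | None = None
        if len(corr_rows) >= 4 + len(control) and len(variables) >= 2:
            self.spearman = correlation_matrix(
                corr_rows, variables, method="spearman",
                control=control, alpha=cfg.alpha)
            self.pearson = correlation_matrix(
                corr_rows, variables, method="pearson",
                control=control, alpha=cfg.alpha)

    # ------------------------------------------------------------------ #
    @property
    def grade_distribution(self) -> pd.DataFrame:
        """Counts of grades 0–3 per group."""
        counts = (self.table.groupby(["group", "grade"]).size()
                  .unstack(fill_value=0))
        return counts.reindex(columns=range(4), fill_value=0)

    def manifest(self) -> dict:
        """Everything needed to reproduce this run exactly."""
        cfg = asdict(self.model.config)
        cfg["embedding"] = asdict(self.model.config.embedding)
        out = {
            "package_version": _pkg_version,
            "config": cfg,
            "normative_source": self.model.normative.source,
            "n_subjects": int(len(self.table)),
            "n_excluded": len(self.excluded),
            "excluded": [list(e) for e in self.excluded],
        }
        if self.model.sim_config is not None:
            sc = self.model.sim_config
            out["simulation"] = {
                "n_hc": sc.n_hc, "n_fm": sc.n_fm, "seed": sc.seed,
                "copula_targets": [list(t) for t in sc.copula_targets],
            }
        return out

    def summary(self) -> str:
        """Human-readable report of the cohort analysis."""
        lines = ["Cohort HRV analysis", "=" * 60]
        lines.append(f"subjects analysed: {len(self.table)}"
                     f" (excluded: {len(self.excluded)})")
        for sid, reason in self.excluded:
            lines.append(f"  excluded {sid}: {reason}")
        lines.append("")
        lines.append("D2 descriptives by group")
        header = f"{'group':>6} {'n':>4} {'mean':>7} {'median':>7} {'sd':>7} " \
                 f"{'se':>7} {'var':>7} {'min':>7} {'max':>7} {'skew':>7}"
        lines.append(header)
        for name, d in self.d2_descriptives.items():
            lines.append(
                f"{name:>6} {d.n:>4d} {d.mean:>7.2f} {d.median:>7.2f} "
                f"{d.sd:>7.2f} {d.se:>7.3f} {d.variance:>7.2f} "
                f"{d.min:>7.2f} {d.max:>7.2f} {d.skewness:>7.2f}"
            )
        if self.shapiro is not None:
            w, p = self.shapiro
            lines.append(f"\nShapiro-Wilk on pooled D2: W = {w:.3f}, p = {p:.4g}")
        if self.mannwhitney is not None:
            u, p = self.mannwhitney
            lines.append(f"Mann-Whitney U (D2, HC vs FM): U = {u:.0f}, "
                         f"p = {p:.4g}")
        if self.power is not None:
            lines.append(f"achieved power (alpha = 0.05, two-tailed, "
                         f"noncentral t): {100 * self.power:.2f}%")
        lines.append("\ngrade distribution (rows: group, cols: grade 0-3)")
        lines.append(self.grade_distribution.to_string())
        if self.spearman is not None:
            cfg = self.model.config
            lines.append(
                f"\nSpearman correlations ({cfg.correlation_group} group, "
                f"control: {', '.join(self.spearman.covariates) or 'none'}; "
                f"significance threshold p < {cfg.alpha:g})"
            )
            if "d2" in self.spearman.coefficients.columns:
                row = self.spearman.coefficients["d2"].drop("d2")
                prow = self.spearman.p_values["d2"].drop("d2")
                shown = row.dropna().sort_values(key=np.abs, ascending=False)
                for var in shown.index[:12]:
                    star = " *" if prow[var] < cfg.alpha else ""
                    lines.append(f"  d2 ~ {var:<16s} rho = {row[var]:+.4f}{star}")
        return "\n".join(lines)

    # ------------------------------------------------------------------ #
    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write all report tables + manifest as delimited text files.

        Deterministic: identical fitted results produce byte-identical
        files.  Returns the mapping of artifact name to path.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def _write(name: str, text: str) -> None:
            p = outdir / name
            p.write_text(text)
            paths[name.split(".")[0]] = p

        _write("profiles.csv", self.table.sort_index().to_csv(
            float_format="%.6f", lineterminator="\n"))
        desc = pd.DataFrame({g: d.as_dict()
                             for g, d in self.d2_descriptives.items()}).T
        _write("d2_descriptives.csv", desc.to_csv(
            float_format="%.6f", lineterminator="\n"))
        tests: dict[str, float | str] = {}
        if self.shapiro:
            tests["shapiro_W"], tests["shapiro_p"] = self.shapiro
        if self.mannwhitney:
            tests["mannwhitney_U"], tests["mannwhitney_p"] = self.mannwhitney
        if self.power is not None:
            tests["posthoc_power"] = self.power
        _write("tests.csv", pd.Series(tests, dtype=object).to_csv(
            header=False, lineterminator="\n"))
        _write("grade_distribution.csv",
               self.grade_distribution.to_csv(lineterminator="\n"))
        for name, report in (("spearman", self.spearman),
                             ("pearson", self.pearson)):
            if report is None:
                continue
            _write(f"{name}_rho.csv", report.coefficients.to_csv(
                float_format="%.6f", lineterminator="\n"))
            _write(f"{name}_p.csv", report.p_values.to_csv(
                float_format="%.6g", lineterminator="\n"))
            _write(f"{name}_significant.csv",
                   report.significant.to_csv(lineterminator="\n"))
        _write("manifest.json",
               json.dumps(self.manifest(), indent=2, sort_keys=True) + "\n")
        _write("summary.txt", self.summary() + "\n")
        return paths

    def plot_d2_by_group(self, ax=None):
        """Strip-and-mean plot of D2 per group (mean ± 95% CI, median)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        for pos, group in enumerate(("HC", "FM")):
            vals = self.table.loc[self.table["group"] == group, "d2"]
            jitter = (np.arange(len(vals)) % 7 - 3) * 0.02
            ax.plot(pos + jitter, vals, ".", alpha=0.4, color="C0")
            d = self.d2_descriptives.get(group)
            if d:
                ci = 1.96 * d.se
                ax.errorbar([pos], [d.mean], yerr=[ci], fmt="o", color="C1",
                            capsize=4, label="mean ± 95% CI" if pos == 0 else None)
                ax.plot([pos], [d.median], "s", color="C2",
                        label="median" if pos == 0 else None)
        ax.set_xticks([0, 1], ["HC", "FM"])
        ax.set_ylabel("correlation dimension D2")
        ax.legend(loc="best", fontsize=8)
        return ax
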