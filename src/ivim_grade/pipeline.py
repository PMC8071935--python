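"""End-to-end orchestration: simulate -> fit -> compare -> ROC -> report.

A run is fully determined by a :class:`RunConfig` (cohort design, fitting
settings, analysis options, master seed). ``run_reproduction`` executes the
whole workflow once and writes paper-shaped report tables; ``replicate_study``
repeats it with derived seeds and summarizes the across-replicate spread of
every reported statistic.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BValueScheme, ValidationError
from .fitting import FitConfig
from .group_stats import (
    DEFAULT_GRADE_CODING,
    compare_parameter,
    correlations_frame,
    spearman_grade,
    table1_frame,
)
from .roc_analysis import pairwise_roc_table, table2_frame
from .simulate import (
    BI_GRADE_SPECS,
    Cohort,
    CohortConfig,
    GradeSpec,
    simulate_cohort,
)

__all__ = ["RunConfig", "RunReport", "run_reproduction", "replicate_study"]

SCHEMA_VERSION = 1

PARAMETERS = ("D", "D_star", "f")
MODEL_TAGS = ("mono", "bi")


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one reproducible analysis run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    grade_coding: dict = field(default_factory=lambda: dict(DEFAULT_GRADE_CODING))
    alpha: float = 0.05
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed, cohort=replace(self.cohort, seed=seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["scheme"] = {
            "b_values": list(self.cohort.scheme.b_values),
            "nex": list(self.cohort.scheme.nex),
        }
        d["cohort"]["grade_specs"] = [asdict(s) for s in self.cohort.grade_specs]
        d["cohort"]["snr0"] = (
            "inf" if np.isinf(self.cohort.snr0) else self.cohort.snr0
        )
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cdict = dict(d.get("cohort", {}))
        if "scheme" in cdict:
            s = cdict["scheme"]
            cdict["scheme"] = BValueScheme(tuple(s["b_values"]), tuple(s["nex"]))
        if "grade_specs" in cdict:
            specs = []
            for g in cdict["grade_specs"]:
                specs.append(
                    GradeSpec(
                        g["grade"],
                        int(g["n"]),
                        tuple(g["param_means"]),
                        tuple(g["param_sds"]),
                    )
                )
            cdict["grade_specs"] = tuple(specs)
        elif cdict.get("param_source") == "bi":
            cdict["grade_specs"] = BI_GRADE_SPECS
        if cdict.get("snr0") in ("inf", ".inf"):
            cdict["snr0"] = np.inf
        d["cohort"] = CohortConfig(**cdict)
        fdict = dict(d.get("fit", {}))
        if "bounds" in fdict:
            fdict["bounds"] = {k: tuple(v) for k, v in fdict["bounds"].items()}
        d["fit"] = FitConfig(**fdict)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunReport:
    """All report tables plus a provenance block for one run."""

    cohort: Cohort
    comparisons: list
    correlations: list
    roc_results: list
    table1: pd.DataFrame
    table2: pd.DataFrame
    correlations_table: pd.DataFrame
    provenance: dict


def _df_hash(df: pd.DataFrame) -> str:
    return hashlib.md5(df.to_csv(index=False).encode()).hexdigest()[:12]


def run_reproduction(config: RunConfig, outdir=None) -> RunReport:
    """Execute the full pipeline deterministically for one seed.

    When ``outdir`` is given, writes ``cohort.csv``, ``truth.csv``,
    ``params.csv`` (per-ROI fits), ``table1.csv``, ``table2.csv``,
    ``correlations.csv``, ``config.yaml`` and ``run.log`` into it.
    """
    log: list[str] = []
    t0 = time.perf_counter()
    cohort = simulate_cohort(config.cohort, config.fit)
    cohort_df = cohort.to_frame()
    log.append(
        f"stage=simulate patients={len(cohort.patients)} "
        f"hash={_df_hash(cohort_df)} secs={time.perf_counter() - t0:.2f}"
    )

    t1 = time.perf_counter()
    comparisons = [
        compare_parameter(cohort, p, tag, config.alpha)
        for tag in MODEL_TAGS
        for p in PARAMETERS
    ]
    correlations = [
        spearman_grade(cohort, p, tag, config.grade_coding)
        for tag in MODEL_TAGS
        for p in PARAMETERS
    ]
    table1 = table1_frame(comparisons)
    corr_table = correlations_frame(correlations)
    log.append(
        f"stage=compare rows={len(table1)} hash={_df_hash(table1)} "
        f"secs={time.perf_counter() - t1:.2f}"
    )

    t2 = time.perf_counter()
    roc_results = pairwise_roc_table(cohort, comparisons)
    table2 = table2_frame(roc_results)
    log.append(
        f"stage=roc rows={len(table2)} hash={_df_hash(table2)} "
        f"secs={time.perf_counter() - t2:.2f}"
    )

    provenance = {
        "seed": config.seed,
        "schema_version": config.schema_version,
        "config_hash": hashlib.md5(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12],
    }
    report = RunReport(
        cohort=cohort,
        comparisons=comparisons,
        correlations=correlations,
        roc_results=roc_results,
        table1=table1,
        table2=table2,
        correlations_table=corr_table,
        provenance=provenance,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort_df.to_csv(outdir / "cohort.csv", index=False)
        cohort.truth_frame().to_csv(outdir / "truth.csv", index=False)
        _params_frame(cohort).to_csv(outdir / "params.csv", index=False)
        table1.to_csv(outdir / "table1.csv", index=False)
        table2.to_csv(outdir / "table2.csv", index=False)
        corr_table.to_csv(outdir / "correlations.csv", index=False)
        config.to_yaml(outdir / "config.yaml")
        (outdir / "run.log").write_text("\n".join(log) + "\n")
    return report


def _params_frame(cohort: Cohort) -> pd.DataFrame:
    """Per-ROI fit table: ``roi_id,model,D,D_star,f,rss,converged,flags``."""
    rows = []
    for p in cohort.patients:
        if p.excluded:
            continue
        n_roi = len(p.roi_curves) or 1
        for i, fit in enumerate(p.roi_fits):
            rows.append(
                {
                    "roi_id": f"{p.patient_id}-roi{i % n_roi + 1}",
                    "model": fit.model_tag,
                    "D": fit.params.D,
                    "D_star": fit.params.D_star,
                    "f": fit.params.f,
                    "rss": fit.rss,
                    "converged": fit.converged,
                    "flags": ";".join(fit.flags),
                }
            )
    return pd.DataFrame(rows)


def derive_seed(master_seed: int, index: int) -> int:
    """Reproducible sub-seed for replicate ``index`` (kept below 2**31)."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0]
               % 2**31)


def replicate_study(
    config: RunConfig, n_replicates: int, outdir=None
) -> pd.DataFrame:
    """Repeat ``run_reproduction`` with derived seeds; summarize statistics.

    Returns a tidy frame with across-replicate mean and SD of every group
    comparison p-value and every ROC statistic, plus the failure count.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    records = []
    failures = 0
    for i in range(n_replicates):
        sub = config.with_seed(derive_seed(config.seed, i))
        try:
            rep = run_reproduction(sub)
        except ValidationError:
            failures += 1
            continue
        for c in rep.comparisons:
            records.append(
                {
                    "replicate": i,
                    "statistic": f"omnibus_p[{c.parameter}_{c.model_tag}]",
                    "value": c.omnibus_p,
                }
            )
        for r in rep.roc_results:
            key = f"{r.parameter}_{r.model_tag}|{r.positive_group}v{r.negative_group}"
            records.append(
                {"replicate": i, "statistic": f"auc[{key}]", "value": r.auc}
            )
            records.append(
                {"replicate": i, "statistic": f"cutoff[{key}]", "value": r.cutoff}
            )
        for corr in rep.correlations:
            records.append(
                {
                    "replicate": i,
                    "statistic": f"rho[{corr.parameter}_{corr.model_tag}]",
                    "value": corr.rho,
                }
            )
    long = pd.DataFrame(records)
    summary = (
        long.groupby("statistic")["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    summary.attrs["failures"] = failures
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "replicates_summary.csv", index=False)
    return summary
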