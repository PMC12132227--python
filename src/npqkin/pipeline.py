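"""End-to-end orchestration: simulate/load -> NPQ -> fit -> QC -> compare.

Every run writes a deterministic artifact set (NPQ series, trait table, QC
report, statistics tables, run log with config hash and seed) to the output
directory; re-running with the same config and inputs reproduces identical
numeric CSV content.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import _write_csv, read_traces, write_npq_series, write_traces
from .kinetics import QCThresholds, qc_assess, traits_for_sample, traits_table
from .npq import FluorescenceTrace, npq_series
from .protocol import FlashSchedule, get_schedule
from .simulate import GroundTruth, StudyDesign, simulate_study
from .stats import anova_factorial, assumption_check, dunnett_vs_control, maybe_log_transform


@dataclass
class RunConfig:
    """Configuration for a pipeline run; round-trips through YAML."""

    schedule: str = "crop_default"
    seed: int = 0
    alpha: float = 0.05
    ss_type: int = 2
    qc: QCThresholds = field(default_factory=QCThresholds)
    design: StudyDesign | None = None
    out_dir: str = "npqkin_out"

    def to_dict(self) -> dict:
        d = {
            "schedule": self.schedule,
            "seed": self.seed,
            "alpha": self.alpha,
            "ss_type": self.ss_type,
            "qc": dataclasses.asdict(self.qc),
            "out_dir": self.out_dir,
        }
        if self.design is not None:
            d["design"] = dataclasses.asdict(self.design)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        qc = QCThresholds(**d.get("qc", {}))
        design = None
        if "design" in d and d["design"] is not None:
            dd = dict(d["design"])
            base = GroundTruth(**dd.pop("base", {}))
            design = StudyDesign(base=base, **dd)
        return cls(
            schedule=d.get("schedule", "crop_default"),
            seed=int(d.get("seed", 0)),
            alpha=float(d.get("alpha", 0.05)),
            ss_type=int(d.get("ss_type", 2)),
            qc=qc,
            design=design,
            out_dir=d.get("out_dir", "npqkin_out"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # the artifact location is not run identity
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(
    config: RunConfig,
    traces: list[FluorescenceTrace] | None = None,
    metadata: pd.DataFrame | None = None,
    trace_errors: list[str] | None = None,
) -> dict:
    """Run simulate/load -> NPQ -> fit -> QC -> compare and write artifacts.

    When ``traces`` is None a study is simulated from ``config.design``
    (metadata then comes from the simulation).  Per-sample failures are
    logged and skipped; the pipeline continues for the remaining samples.
    Returns a dict of in-memory results keyed by artifact name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schedule = get_schedule(config.schedule)
    errors: list[str] = list(trace_errors or [])
    header = (
        f"npqkin {__version__} schedule={schedule.name} "
        f"seed={config.seed} config={config.config_hash()}"
    )

    if traces is None:
        design = config.design or StudyDesign(seed=config.seed)
        if design.seed != config.seed:
            design = dataclasses.replace(design, seed=config.seed)
        traces, truth = simulate_study(design, schedule)
        metadata = truth[["sample_id", "genotype", "treatment", "replicate"]]
        _write_csv(truth, out / "truth.csv", header)
        write_traces(traces, out / "flashes.csv", out / "samples.csv", header)

    series_list, all_traits = [], []
    for trace in traces:
        try:
            s = npq_series(trace)
            series_list.append(s)
            all_traits.append(traits_for_sample(s))
        except (ValueError, KeyError) as exc:
            errors.append(f"{trace.sample_id}: {exc}")
    write_npq_series(series_list, out / "npq_series.csv", header)

    traits_df = traits_table(all_traits)
    _write_csv(traits_df, out / "traits.csv", header)

    groups = None
    if metadata is not None and {"genotype", "treatment"} <= set(metadata.columns):
        groups = {
            r.sample_id: (r.genotype, r.treatment) for r in metadata.itertuples()
        }
    report = qc_assess(
        all_traits,
        series_by_sample={s.sample_id: s for s in series_list},
        groups=groups,
        thresholds=config.qc,
    )
    _write_csv(report.records, out / "qc_report.csv", header)

    results: dict = {
        "schedule": schedule,
        "traces": traces,
        "series": series_list,
        "traits": traits_df,
        "qc": report,
        "errors": errors,
    }

    if metadata is not None:
        merged = traits_df.merge(metadata, on="sample_id", how="inner")
        if "cycle" in merged.columns:
            merged = merged[merged["cycle"].isna()] if merged["cycle"].isna().any() else merged
        results["anova"], results["dunnett"] = _compare(merged, config, out, header)

    log = {
        "version": __version__,
        "schedule": schedule.name,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_traces": len(traces),
        "n_fit": len(all_traits),
        "errors": errors,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return results


def _compare(merged: pd.DataFrame, config: RunConfig, out: Path, header: str):
    """Genotype x treatment ANOVA and Dunnett-vs-control per trait."""
    anova_rows, dunnett_rows = [], []
    factors = [f for f in ("genotype", "treatment") if merged[f].nunique() > 1]
    for trait in ("NPQasymptote_lightH", "NPQslope_lightH", "NPQamplitude_darkH"):
        sub = merged.dropna(subset=[trait])
        if sub.empty:
            continue
        values = sub[trait].to_numpy()
        cell = sub[factors].astype(str).agg(":".join, axis=1) if factors else None
        transformed = False
        if factors and cell.nunique() >= 2 and (sub.groupby(cell.values)[trait].count() >= 3).all():
            verdict = assumption_check(values, cell.to_numpy(), alpha=config.alpha)
            values, transformed = maybe_log_transform(values, verdict)
        work = sub.assign(_y=values)
        if factors:
            try:
                aov = anova_factorial(work, "_y", factors, ss_type=config.ss_type)
                aov.insert(0, "trait", trait)
                aov["log_transformed"] = transformed
                anova_rows.append(aov)
            except ValueError:
                pass
        if "treatment" in factors and "control" in set(work["treatment"]):
            samples = {
                t: grp["_y"].to_numpy() for t, grp in work.groupby("treatment")
            }
            if all(len(v) >= 2 for v in samples.values()) and len(samples) >= 2:
                for rec in dunnett_vs_control(samples, "control", seed=config.seed):
                    dunnett_rows.append(
                        {
                            "trait": trait,
                            "group": rec.group,
                            "estimate": rec.estimate,
                            "statistic": rec.statistic,
                            "p_adjusted": rec.p_adjusted,
                            "log_transformed": transformed,
                        }
                    )
    anova_df = (
        pd.concat(anova_rows, ignore_index=True) if anova_rows else pd.DataFrame()
    )
    dunnett_df = pd.DataFrame(dunnett_rows)
    if not anova_df.empty:
        _write_csv(anova_df, out / "anova.csv", header)
    if not dunnett_df.empty:
        _write_csv(dunnett_df, out / "dunnett.csv", header)
    return anova_df, dunnett_df
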