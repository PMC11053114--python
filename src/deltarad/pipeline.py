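"""End-to-end orchestration: cohort -> QA -> features -> DRF/BED -> models.

``run_pipeline`` executes the full analysis on either a generated
synthetic cohort or a manifest-described cohort on disk, and writes a
report bundle (CSV tables + a summary JSON echoing the seed and config
hash).  Reruns with the same config reproduce every stochastic output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contours, io, modeling, synthetic
from .longitudinal import FractionationSchedule, assemble_matrix
from .modeling import AnalysisConfig, EndpointAnalysis
from .preprocessing import QuantizationConfig
from .synthetic import CohortConfig, PatientCourse
from .texture import extract_all

log = logging.getLogger("deltarad")

ENDPOINTS = ("acute_gu", "subacute_gu", "delta_ipss")
CONTOUR_TYPES = ("manual", "automated")


@dataclass
class RunConfig:
    cohort: CohortConfig | None = None
    manifest: str | None = None
    quantization: QuantizationConfig = field(default_factory=QuantizationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    endpoints: tuple[str, ...] = ENDPOINTS
    delta_ipss_threshold: int = 0
    use_stored_fiducial_mask: bool = True
    output_dir: str = "deltarad_out"

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.manifest is None):
            raise ValueError("exactly one of cohort config or manifest must be given")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""

        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        payload = asdict(self)
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def extract_cohort_features(
    cohort: list[PatientCourse],
    qc: QuantizationConfig | None = None,
    contour_types: tuple[str, ...] = CONTOUR_TYPES,
) -> pd.DataFrame:
    """Long-format feature table: (patient, fraction, contour_type, feature, value).

    The stored fiducial mask of each fraction is excluded from the
    effective ROI before discretization.
    """
    qc = qc or QuantizationConfig()
    records = []
    for p in cohort:
        for i, fx in enumerate(p.fractions, start=1):
            for ct in contour_types:
                roi = getattr(fx, ct)
                fv = extract_all(
                    fx.image,
                    roi,
                    fiducial_excl=fx.fiducial,
                    qc=qc,
                    meta={"patient": p.patient_id, "fraction": i, "contour_type": ct},
                )
                for name, val in fv.values.items():
                    records.append((p.patient_id, i, ct, name, val))
    return pd.DataFrame(
        records, columns=["patient", "fraction", "contour_type", "feature", "value"]
    )


def qa_contours(cohort: list[PatientCourse]) -> tuple[pd.DataFrame, dict]:
    """Per-fraction TG-132 agreement metrics and the cohort DSC summary."""
    rows = []
    for p in cohort:
        for i, fx in enumerate(p.fractions, start=1):
            ag = contours.agreement(fx.manual, fx.automated)
            rows.append(
                (p.patient_id, i, ag.dsc, ag.mda_mm, ag.delta_com_mm, ag.delta_vol_pct)
            )
    df = pd.DataFrame(
        rows, columns=["patient", "fraction", "dsc", "mda_mm", "delta_com_mm", "delta_vol_pct"]
    )
    summary = {
        "n_fractions": int(len(df)),
        "dsc_mean": float(df["dsc"].mean()),
        "dsc_sd": float(df["dsc"].std(ddof=1)) if len(df) > 1 else 0.0,
        "mda_mean_mm": float(df["mda_mm"].mean()),
        "delta_com_mean_mm": float(df["delta_com_mm"].mean()),
        "delta_vol_mean_pct": float(df["delta_vol_pct"].mean()),
    }
    return df, summary


def fraction1_feature_table(features_long: pd.DataFrame, contour_type: str) -> pd.DataFrame:
    """Patients x features table of raw fraction-1 values for one contour arm."""
    sub = features_long[
        (features_long["fraction"] == 1) & (features_long["contour_type"] == contour_type)
    ]
    return sub.pivot_table(index="patient", columns="feature", values="value", aggfunc="first")


def analyze_endpoint(
    features_long: pd.DataFrame,
    schedules: dict[str, FractionationSchedule],
    outcomes: pd.DataFrame,
    endpoint: str,
    config: AnalysisConfig,
    bin_width_gy: float = 20.0,
    with_snapshot: bool = True,
) -> EndpointAnalysis:
    """Assemble both contour arms' matrices and run the paired analysis."""
    Xm, y, _ = assemble_matrix(features_long, schedules, outcomes, "manual", endpoint, bin_width_gy)
    Xa, _, _ = assemble_matrix(features_long, schedules, outcomes, "automated", endpoint, bin_width_gy)
    Xa = Xa.loc[Xm.index]
    snapshot = None
    if with_snapshot:
        snapshot = {
            ct: fraction1_feature_table(features_long, ct).loc[Xm.index].assign(
                IPSS_Baseline=outcomes.loc[Xm.index, "ipss_baseline"].astype(float)
            )
            for ct in CONTOUR_TYPES
        }
    return modeling.run_endpoint_analysis(Xm, Xa, y, endpoint, config, snapshot)


def _endpoint_summary(res: EndpointAnalysis) -> dict:
    bins = sorted(res.delong)
    return {
        "selected_features": res.selected_features,
        "skipped_bins": res.skipped_bins,
        "bins": {
            str(b): {
                "auc_median_manual": res.models[("manual", b)].auc_median,
                "auc_ci_manual": list(res.models[("manual", b)].auc_ci),
                "auc_median_automated": res.models[("automated", b)].auc_median,
                "auc_ci_automated": list(res.models[("automated", b)].auc_ci),
                "delong_p": res.delong[b].p_two_sided,
            }
            for b in bins
        },
        "snapshot": {
            arm: {"auc_median": r.auc_median, "auc_ci": list(r.auc_ci)}
            for arm, r in res.snapshot.items()
        },
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns the summary dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage: cohort")
    if config.cohort is not None:
        cohort = synthetic.generate_cohort(config.cohort)
    else:
        problems = io.validate_manifest(config.manifest)
        if problems:
            raise RuntimeError("manifest validation failed: " + "; ".join(problems))
        cohort = io.read_cohort(config.manifest)

    log.info("stage: contour QA")
    qa_df, qa_summary = qa_contours(cohort)
    qa_df.to_csv(out / "contour_agreement.csv", index=False)

    log.info("stage: feature extraction")
    features_long = extract_cohort_features(cohort, config.quantization)
    features_long.to_csv(out / "features_long.csv", index=False)

    log.info("stage: feature consistency QA")
    f1_manual = fraction1_feature_table(features_long, "manual")
    f1_auto = fraction1_feature_table(features_long, "automated")
    consistency = modeling.spearman_bh_consistency(
        f1_manual, f1_auto, alpha=config.analysis.alpha
    )
    consistency.to_csv(out / "feature_consistency.csv")

    log.info("stage: modeling")
    schedules = {p.patient_id: p.schedule for p in cohort}
    outcomes = synthetic.cohort_outcomes(cohort, config.delta_ipss_threshold)
    endpoint_summaries = {}
    for ep in config.endpoints:
        try:
            res = analyze_endpoint(features_long, schedules, outcomes, ep, config.analysis)
        except ValueError as e:
            log.warning("endpoint %s skipped: %s", ep, e)
            endpoint_summaries[ep] = {"skipped": str(e)}
            continue
        endpoint_summaries[ep] = _endpoint_summary(res)
        rows = [
            {"contour_type": ct, "bed_bin": b, "auc": a}
            for (ct, b), r in sorted(res.models.items())
            for a in r.auc_distribution
        ]
        pd.DataFrame(rows).to_csv(out / f"auc_distribution_{ep}.csv", index=False)

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.cohort.seed if config.cohort else None,
        "n_patients": len(cohort),
        "contour_qa": qa_summary,
        "n_consistency_significant": int(consistency["significant"].sum()),
        "n_consistency_tested": int(consistency["p_adjusted"].notna().sum()),
        "endpoints": endpoint_summaries,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
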