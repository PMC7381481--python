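"""Study-replication driver: simulate -> compute -> validate -> report.

Chains the cohort simulator, the index computations, and the diagnostic
statistics into one deterministic run, and renders a JSON report whose
structure mirrors the validation study: per-stratum summaries and agreement
blocks (all lesions / IRA pre-PCI / IRA post-PCI / non-IRA), ROC blocks for
IMR_angio predicting an abnormal reference IMR (>= 40 U) and predicting
significant MVO, the responder table, and the MVO-by-stratum frequency
analysis.  Report keys never depend on the data: empty strata produce
explicit empty blocks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortParams,
    cohort_angiography,
    cohort_patients,
    cohort_physiology,
    cohort_truth,
    generate_cohort,
)
from .diagnostics import (
    bland_altman,
    chi2_2x2,
    classify_responders,
    confusion_at_cutoff,
    correlations,
    fisher_exact_2x2,
    icc_absolute_agreement,
    roc_and_youden,
)
from .exceptions import ImrAngioError
from .indices import compute_panels, panels_to_frame, read_angiography, read_physiology

logger = logging.getLogger("imrangio")

#: adverse resistance threshold (U) — post-PCI IMR >= 40U is prognostically adverse
DEFAULT_RESISTANCE_THRESHOLD = 40.0

STRATA = ("all", "ira_pre", "ira_post", "non_ira")


@dataclass(frozen=True)
class StudyConfig:
    cohort: CohortParams = field(default_factory=CohortParams)
    threshold: float = DEFAULT_RESISTANCE_THRESHOLD
    mvo_threshold: float = 1.55
    out_dir: Optional[str] = None
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.threshold <= 0 or self.mvo_threshold <= 0:
            raise ImrAngioError("thresholds must be positive")


def _stratum_mask(df: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=df.index)
    if stratum == "ira_pre":
        return (df["vessel_role"] == "IRA") & (df["timepoint"] == "pre_pci")
    if stratum == "ira_post":
        return (df["vessel_role"] == "IRA") & (df["timepoint"] == "post_pci")
    if stratum == "non_ira":
        return df["vessel_role"] == "non_IRA"
    raise ImrAngioError(f"unknown stratum {stratum!r}")


def summarize_stratum(values) -> Optional[dict]:
    """Median and (q1-q3) with linear interpolation of the empirical CDF."""
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size == 0:
        return None
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return {"median": float(med), "q1": float(q1), "q3": float(q3), "n": int(arr.size)}


def _stratum_block(sub: pd.DataFrame) -> dict:
    """Summary + correlation/agreement block for one lesion stratum."""
    block: dict = {
        "n": int(len(sub)),
        "summary": {
            name: summarize_stratum(sub[name]) if name in sub else None
            for name in ("IMR", "IMR_angio", "IMR_wedge", "CFR", "PdPa_hyp")
        },
        "correlations": None,
        "agreement": None,
    }
    if len(sub) >= 3:
        x = sub["IMR_angio"].to_numpy(dtype=float)
        y = sub["IMR"].to_numpy(dtype=float)
        r, rho = correlations(x, y)
        ba = bland_altman(x, y)
        icc, (lo, hi), f_stat = icc_absolute_agreement(np.column_stack([x, y]))
        block["correlations"] = {"pearson_r": r, "spearman_rho": rho}
        block["agreement"] = {
            "bias": ba.bias,
            "loa_low": ba.loa_low,
            "loa_high": ba.loa_high,
            "icc": icc,
            "icc_ci_low": lo,
            "icc_ci_high": hi,
            "icc_f": f_stat,
        }
    return block


def _roc_block(scores, labels, cutoff: float) -> Optional[dict]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size == 0 or labels.all() or not labels.any():
        return None
    roc = roc_and_youden(scores, labels)
    conf = confusion_at_cutoff(scores, labels, cutoff)
    return {
        "n": int(scores.size),
        "n_positive": int(labels.sum()),
        "auc": roc.auc,
        "youden_cutoff": roc.youden_cutoff,
        "youden_j": roc.youden_j,
        "at_cutoff": {
            "cutoff": cutoff,
            "tp": conf.tp, "fp": conf.fp, "fn": conf.fn, "tn": conf.tn,
            "sensitivity": conf.sensitivity,
            "specificity": conf.specificity,
            "ppv": conf.ppv,
            "npv": conf.npv,
            "accuracy": conf.accuracy,
        },
    }


def _patient_id_of(lesion_id: str) -> str:
    return str(lesion_id).rsplit("-", 1)[0]


def build_report(
    indices: pd.DataFrame,
    patients: pd.DataFrame,
    truth: Optional[pd.DataFrame],
    threshold: float = DEFAULT_RESISTANCE_THRESHOLD,
    provenance: Optional[dict] = None,
) -> dict:
    """Assemble the full diagnostic-validation report from tables.

    ``indices`` is the per-lesion panel table (indices.csv schema),
    ``patients`` the per-patient MVO table, ``truth`` the optional latent
    resistance table used for the ground-truth recovery block.
    """
    required = {"lesion_id", "timepoint", "vessel_role", "IMR", "IMR_angio"}
    missing = required - set(indices.columns)
    if missing:
        raise ImrAngioError(f"indices table lacks columns: {sorted(missing)}")
    if "patient_id" not in patients.columns or "mvo_significant" not in patients.columns:
        raise ImrAngioError("patients table needs patient_id and mvo_significant columns")
    df = indices.copy()
    report: dict = {
        "provenance": provenance or {},
        "threshold": threshold,
        "strata": {},
    }
    for stratum in STRATA:
        sub = df[_stratum_mask(df, stratum)]
        report["strata"][stratum] = _stratum_block(sub)

    # ROC: IMR_angio predicting an abnormal reference IMR, all lesions
    report["roc_imr"] = _roc_block(
        df["IMR_angio"], df["IMR"] >= threshold, threshold
    )

    # post-PCI IRA panels joined to patient outcomes
    post = df[_stratum_mask(df, "ira_post")].copy()
    post["patient_id"] = post["lesion_id"].map(_patient_id_of)
    merged = post.merge(patients, on="patient_id", how="inner")

    mvo_block = None
    roc_mvo = None
    if len(merged) and merged["mvo_significant"].notna().all():
        mvo = merged["mvo_significant"].astype(bool).to_numpy()
        below = merged["IMR_angio"].to_numpy() < threshold
        n_below, n_above = int(below.sum()), int((~below).sum())
        mvo_below, mvo_above = int(mvo[below].sum()), int(mvo[~below].sum())
        table = [[mvo_below, n_below - mvo_below], [mvo_above, n_above - mvo_above]]
        mvo_block = {
            "below_cutoff": {
                "n": n_below,
                "n_mvo": mvo_below,
                "prevalence": mvo_below / n_below if n_below else None,
            },
            "at_or_above_cutoff": {
                "n": n_above,
                "n_mvo": mvo_above,
                "prevalence": mvo_above / n_above if n_above else None,
            },
            "fisher_p": fisher_exact_2x2(table) if n_below and n_above else None,
            "chi2_p": chi2_2x2(table) if n_below and n_above else None,
        }
        roc_mvo = _roc_block(merged["IMR_angio"], mvo, threshold)
    report["mvo_by_stratum"] = mvo_block
    report["roc_mvo"] = roc_mvo

    # responder classification needs paired pre/post IRA panels
    pre = df[_stratum_mask(df, "ira_pre")]
    paired_ids = set(pre["lesion_id"]) & set(post["lesion_id"])
    responder_block = None
    if paired_ids:
        from .indices import IndexPanel

        def rows_to_panels(sub: pd.DataFrame) -> list:
            return [
                IndexPanel(
                    lesion_id=row.lesion_id,
                    timepoint=row.timepoint,
                    IMR=row.IMR,
                    IMR_angio=row.IMR_angio,
                    PdPa_hyp=row.PdPa_hyp,
                    vessel_role=row.vessel_role,
                )
                for row in sub.itertuples(index=False)
            ]

        res = classify_responders(
            rows_to_panels(pre[pre["lesion_id"].isin(paired_ids)]),
            rows_to_panels(post[post["lesion_id"].isin(paired_ids)]),
            threshold=threshold,
        )
        n = len(res.patient_ids)
        responder_block = {
            "n": n,
            "good_by_imr": res.labels_imr.count("good"),
            "good_by_imr_angio": res.labels_imr_angio.count("good"),
            "frac_good_by_imr": res.labels_imr.count("good") / n,
            "frac_good_by_imr_angio": res.labels_imr_angio.count("good") / n,
            "n_discordant": res.n_discordant,
            "misclassification_rate": res.misclassification_rate,
        }
    report["responders"] = responder_block

    # ground-truth recovery: Youden cutoff of IMR_angio against latent R >= 40U
    truth_block = None
    if truth is not None and len(truth):
        t = truth.set_index("patient_id")
        latent, scores = [], []
        for row in df.itertuples(index=False):
            pid = _patient_id_of(row.lesion_id)
            if pid not in t.index:
                continue
            if row.vessel_role == "non_IRA":
                value = t.loc[pid, "true_R_nonira"]
            elif row.timepoint == "pre_pci":
                value = t.loc[pid, "true_R_pre"]
            else:
                value = t.loc[pid, "true_R_post"]
            if pd.notna(value):
                latent.append(float(value))
                scores.append(float(row.IMR_angio))
        truth_block = _roc_block(scores, np.asarray(latent) >= threshold, threshold)
    report["truth_recovery"] = truth_block
    return report


def run_study(config: StudyConfig) -> dict:
    """Simulate a cohort, compute all indices, and validate — one process.

    Deterministic given ``config.cohort.seed``; equals the CSV round trip
    (simulate -> compute -> validate on the written files) field-for-field.
    """
    try:
        cohort = generate_cohort(config.cohort)
        logger.info("simulate: %d patients, seed %d", len(cohort), config.cohort.seed)
    except ImrAngioError as exc:
        raise ImrAngioError(f"simulate stage failed: {exc}") from exc
    try:
        physio = [r for p in cohort for r in p.physio]
        angio = [r for p in cohort for r in p.angio]
        panels = compute_panels(physio, angio)
        logger.info("compute: %d lesion panels", len(panels))
    except ImrAngioError as exc:
        raise ImrAngioError(f"compute stage failed: {exc}") from exc
    try:
        report = build_report(
            panels_to_frame(panels),
            cohort_patients(cohort),
            cohort_truth(cohort),
            threshold=config.threshold,
            provenance={
                "package": "imrangio",
                "version": __version__,
                "seed": config.cohort.seed,
                "config": {
                    "cohort": config.cohort.to_dict(),
                    "threshold": config.threshold,
                    "mvo_threshold": config.mvo_threshold,
                },
            },
        )
        logger.info("validate: report assembled")
    except ImrAngioError as exc:
        raise ImrAngioError(f"validate stage failed: {exc}") from exc
    return report


def write_cohort_csvs(cohort, params: CohortParams, out_dir) -> dict:
    """Write physiology/angiography/patients/truth CSVs plus provenance JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_physiology(cohort).to_csv(out / "physiology.csv", index=False)
    cohort_angiography(cohort).to_csv(out / "angiography.csv", index=False)
    cohort_patients(cohort).to_csv(out / "patients.csv", index=False)
    cohort_truth(cohort).to_csv(out / "truth.csv", index=False)
    provenance = {
        "package": "imrangio",
        "version": __version__,
        "seed": params.seed,
        "params": params.to_dict(),
        "assumptions": {
            "prepost_copula": "Gaussian copula on log-resistance; rho is an explicit "
            "assumption (the joint pre/post distribution is not published)",
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return provenance


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, allow_nan=False)


def load_config(path) -> StudyConfig:
    """Load a StudyConfig from a YAML (or JSON subset) file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort = CohortParams.from_dict(raw.get("cohort", {}))
    kwargs = {k: v for k, v in raw.items() if k != "cohort"}
    allowed = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(kwargs) - allowed
    if unknown:
        raise ImrAngioError(f"unknown config keys: {sorted(unknown)}")
    return StudyConfig(cohort=cohort, **kwargs)
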