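"""End-to-end orchestration: per-case biomarker extraction and cohort analysis.

``run_case`` composes SUV conversion -> lung segmentation -> biomarker panel
-> dose metrics for one PET/CT case and returns a single CSV-ready row plus a
provenance log.  ``run_study`` runs the full outcome-statistics battery on a
cohort table and writes publication-style tables, figures and a run manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dosimetry, lung_segmentation as seg, rp_statistics as rps
from .core import BinaryMask, ImageVolume, Modality, resample_like
from .suv_conversion import AcquisitionMeta, activity_to_suv
from .uptake_biomarkers import summarize_roi

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Run-wide options; round-trips through JSON unchanged."""

    alpha: float = 0.05
    z: float = 1.96
    paper_compat_terciles: bool = False
    percentile_method: str = "linear"
    segmentation_threshold_hu: float | None = None
    dose_thresholds: tuple[float, float, float, float] = (5.0, 10.0, 20.0, 30.0)
    rbe: float = 1.1
    dose_is_proton: bool = False
    assume_suv: bool = False
    activity_unit: str = "Bq/mL"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        if data.get("dose_thresholds") is not None:
            data["dose_thresholds"] = tuple(data["dose_thresholds"])
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]


@dataclass
class CaseResult:
    row: dict
    roi: BinaryMask
    provenance: dict


def extract_case(ct: ImageVolume, pet: ImageVolume | None = None,
                 dose: ImageVolume | None = None,
                 meta: AcquisitionMeta | None = None,
                 exclusions: list[seg.ExclusionROI] | None = None,
                 config: PipelineConfig | None = None,
                 case_id: str = "case") -> CaseResult:
    """Run the imaging half of the pipeline for one case, in memory.

    PET and dose grids are resampled to the CT grid when they differ (the ROI
    is CT-derived).  A missing dose volume yields empty dose fields plus a
    warning, not an error.
    """
    config = config or PipelineConfig()
    provenance: dict = {"case_id": case_id, "config_hash": config.config_hash,
                        "seed": config.seed, "steps": []}
    parenchyma = seg.segment_lung_parenchyma(ct, threshold=config.segmentation_threshold_hu)
    airway = seg.extract_central_airway(ct, parenchyma)
    roi = seg.finalize_lung_roi(parenchyma, airway, exclusions or [])
    provenance["steps"].extend(roi.provenance)

    row: dict = {"case_id": case_id}
    hu = summarize_roi(ct, roi, method=config.percentile_method)
    row.update(hu.as_row())

    if pet is not None:
        if pet.modality is Modality.PET_ACTIVITY and not config.assume_suv:
            if meta is None:
                raise ValueError("PET is an activity volume but no acquisition metadata given")
            pet = activity_to_suv(pet, meta, input_unit=config.activity_unit)
            provenance["steps"].append("converted PET activity to SUV")
        pet = resample_like(pet, ct)
        suv = summarize_roi(pet, roi, method=config.percentile_method)
        row.update(suv.as_row())

    if dose is not None:
        dose = resample_like(dose, ct)
        if config.dose_is_proton and dose.unit != "CGE":
            dose = dosimetry.to_cge(dose, rbe=config.rbe)
            provenance["steps"].append(f"converted proton Gy to CGE (RBE {config.rbe})")
        metrics = dosimetry.dose_metrics(dose, roi, thresholds=config.dose_thresholds)
        row.update(metrics.as_row())
    else:
        warnings.warn(f"case {case_id}: no dose volume; dose fields left empty", stacklevel=2)
        row.update({"mld": None, "v5": None, "v10": None, "v20": None, "v30": None,
                    "dose_unit": None})
    row["config_hash"] = config.config_hash
    return CaseResult(row=row, roi=roi, provenance=provenance)


def run_case(case_dir: str | Path, case_id: str,
             config: PipelineConfig | None = None,
             outdir: str | Path | None = None) -> dict:
    """File-based wrapper around :func:`extract_case`.

    Expects ``<case_id>_ct.nii.gz`` and optionally ``<case_id>_pet.nii.gz``
    (+ ``<case_id>_meta.json`` for activity input), ``<case_id>_dose.nii.gz``
    and exclusion masks named ``<case_id>_excl_<label>.nii.gz``.
    """
    case_dir = Path(case_dir)
    config = config or PipelineConfig()

    def _find(stem):
        for suffix in (".nii.gz", ".nii"):
            p = case_dir / f"{case_id}_{stem}{suffix}"
            if p.exists():
                return p
        return None

    ct_path = _find("ct")
    if ct_path is None:
        raise FileNotFoundError(f"no CT volume for case {case_id!r} in {case_dir}")
    ct = ImageVolume.from_nifti(ct_path, modality=Modality.CT_HU)
    pet_path, dose_path = _find("pet"), _find("dose")
    pet = ImageVolume.from_nifti(pet_path) if pet_path else None
    dose = ImageVolume.from_nifti(dose_path, modality=Modality.DOSE) if dose_path else None
    meta_path = case_dir / f"{case_id}_meta.json"
    meta = AcquisitionMeta.from_json(meta_path) if meta_path.exists() else None
    exclusions = []
    for label in seg.EXCLUSION_LABELS:
        p = _find(f"excl_{label}")
        if p is not None:
            exclusions.append(seg.ExclusionROI(BinaryMask.from_nifti(p), label))
    result = extract_case(ct, pet, dose, meta, exclusions, config, case_id)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"{case_id}_provenance.json").write_text(
            json.dumps(result.provenance, indent=2))
    return result.row


# --------------------------------------------------------------------------
# Cohort-level statistics
# --------------------------------------------------------------------------

# predictor column -> (units per coefficient step, human-readable scale note)
UNIVARIATE_SCALES = {
    "suv_max": (0.1, "per 0.1 SUV"), "suv_mean": (0.1, "per 0.1 SUV"),
    "suv_sd": (0.1, "per 0.1 SUV"), "suv_80": (0.1, "per 0.1 SUV"),
    "suv_90": (0.1, "per 0.1 SUV"), "suv_95": (0.1, "per 0.1 SUV"),
    "hu_max": (100.0, "per 100 HU"), "hu_mean": (100.0, "per 100 HU"),
    "hu_sd": (100.0, "per 100 HU"), "hu_80": (100.0, "per 100 HU"),
    "hu_90": (100.0, "per 100 HU"), "hu_95": (100.0, "per 100 HU"),
    "mld": (10.0, "per 10 Gy/CGE"), "v5": (10.0, "per 10%"), "v10": (10.0, "per 10%"),
    "v20": (10.0, "per 10%"), "v30": (10.0, "per 10%"),
    "fev1_pct": (10.0, "per 10%"), "dlco_pct": (10.0, "per 10%"),
}
SUV_FAMILY = ("suv_mean", "suv_sd", "suv_max", "suv_80", "suv_90", "suv_95")
MULTIVARIATE_CANDIDATES = {
    "suv_95": 0.1, "age": 5.0, "v30": 1.0, "mld": 10.0, "v20": 10.0,
    "fev1_pct": 10.0, "dlco_pct": 10.0, "hu_95": 100.0,
}
CATEGORICAL_COVARIATES = ("sex", "stage", "tumor_location", "histology",
                          "treatment_type", "chemo_status", "smoking")
CONTINUOUS_COVARIATES = ("age", "interval_days")


@dataclass
class StudyResults:
    associations: pd.DataFrame
    univariate: pd.DataFrame
    holm: rps.HolmResult | None
    multiple_logistic: rps.SelectionResult
    roc: rps.RocResult
    partition: rps.PartitionTree
    km: rps.KMResult | None
    cox: rps.SelectionResult | None
    agreement: rps.AgreementResult | None
    notes: list[str]
    manifest: dict


def _scaled(df: pd.DataFrame, col: str, step: float) -> pd.Series:
    return df[col].astype(float) / step


def run_study(cohort: pd.DataFrame, config: PipelineConfig | None = None,
              outdir: str | Path | None = None,
              readings: pd.DataFrame | None = None) -> StudyResults:
    """Run the complete outcome analysis on a cohort table.

    The table needs a binary ``symptomatic`` column (grade >= 2) or an
    ``rp_grade`` column from which it is derived, plus ``time_days``/``event``
    for the survival analyses.  Cohorts without events skip the survival part
    with an explicit notice.
    """
    config = config or PipelineConfig()
    df = cohort.copy()
    notes: list[str] = []
    if "symptomatic" not in df.columns:
        if "rp_grade" not in df.columns:
            raise ValueError("cohort needs a 'symptomatic' or 'rp_grade' column")
        df["symptomatic"] = (df["rp_grade"] >= 2).astype(int)
    if "rp_grade" in df.columns:
        mismatch = int(((df["rp_grade"] >= 2).astype(int) != df["symptomatic"]).sum())
        if mismatch:
            notes.append(f"{mismatch} records have symptomatic inconsistent with rp_grade")
    if df["symptomatic"].nunique() < 2:
        raise ValueError("outcome column is constant; nothing to analyse")

    # 1. marginal association tests
    assoc_rows = []
    for cov in CATEGORICAL_COVARIATES:
        if cov in df.columns:
            r = rps.association_tests(df, cov, kind="categorical")
            assoc_rows.append(dataclasses.asdict(r))
    for cov in CONTINUOUS_COVARIATES:
        if cov in df.columns:
            r = rps.association_tests(df, cov, kind="continuous")
            assoc_rows.append(dataclasses.asdict(r))
    associations = pd.DataFrame(assoc_rows)

    # 2. univariate logistic panel + Holm over the SUV family
    uni_rows = []
    for col, (step, note) in UNIVARIATE_SCALES.items():
        if col not in df.columns or df[col].isna().all():
            continue
        work = df[["symptomatic"]].copy()
        work["x"] = _scaled(df, col, step)
        try:
            fit = rps.fit_logistic(work, ["x"])
        except (rps.ModelFitError, ValueError) as exc:
            notes.append(f"univariate fit for {col} failed: {exc}")
            continue
        uni_rows.append({
            "predictor": col, "scale": note,
            "coefficient": fit.coef["x"], "se": fit.se["x"],
            "odds_ratio": fit.odds_ratios.loc["x", "or"],
            "or_ci_low": fit.odds_ratios.loc["x", "ci_low"],
            "or_ci_high": fit.odds_ratios.loc["x", "ci_high"],
            "p_value": fit.p_values["x"],
        })
    univariate = pd.DataFrame(uni_rows).set_index("predictor") if uni_rows \
        else pd.DataFrame()
    holm = None
    suv_present = [c for c in SUV_FAMILY if c in univariate.index]
    if suv_present:
        holm = rps.holm_adjust(univariate.loc[suv_present, "p_value"].to_numpy(),
                               alpha=config.alpha)
        univariate.loc[suv_present, "holm_adjusted_p"] = holm.adjusted
        univariate.loc[suv_present, "holm_significant"] = holm.rejected

    # 3. multiple logistic via backward AIC
    scaled = df[["symptomatic"]].copy()
    candidates = []
    for col, step in MULTIVARIATE_CANDIDATES.items():
        if col in df.columns and not df[col].isna().any():
            x = _scaled(df, col, step)
            scaled[col] = x - x.mean()   # centring aids conditioning, leaves ORs unchanged
            candidates.append(col)
    selection = rps.backward_aic_select(scaled, candidates, model_family="logistic")
    if selection.fit is None:
        raise rps.ModelFitError("backward selection eliminated every logistic term")
    fit = selection.fit

    # 4. ROC / Youden on the selected model's predicted probabilities
    scores = fit.predict(scaled)
    roc = rps.roc_delong_youden(scores, df["symptomatic"].to_numpy())

    # 5. recursive partitioning on the raw biomarker/dose pair
    partition = rps.recursive_partition(df, predictors=("suv_95", "v30"))

    # 6. survival: KM terciles + Cox backward selection
    km = cox = None
    if {"time_days", "event"}.issubset(df.columns) and df["event"].sum() > 0:
        km = rps.km_fit(df, value_col="suv_95",
                        paper_compat=config.paper_compat_terciles)
        surv = df[["time_days", "event"]].copy()
        for col in candidates:
            surv[col] = scaled[col]
        try:
            cox = rps.backward_aic_select(surv, candidates, model_family="cox")
        except (rps.ModelFitError, ValueError) as exc:
            notes.append(f"Cox selection failed: {exc}")
    else:
        notes.append("no events (or no time/event columns): survival analyses skipped")

    agreement = rps.bland_altman_loa(readings) if readings is not None else None

    manifest = {"config_hash": config.config_hash, "seed": config.seed,
                "n_patients": len(df), "n_symptomatic": int(df["symptomatic"].sum()),
                "selected_terms": list(selection.selected_terms), "notes": notes}
    results = StudyResults(associations, univariate, holm, selection, roc,
                           partition, km, cox, agreement, notes, manifest)
    if outdir is not None:
        _write_outputs(results, df, Path(outdir))
    return results


def _write_outputs(results: StudyResults, df: pd.DataFrame, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    results.associations.to_csv(outdir / "associations.csv", index=False)
    results.univariate.to_csv(outdir / "univariate_logistic.csv")
    if results.multiple_logistic.fit is not None:
        results.multiple_logistic.fit.summary_frame().to_csv(
            outdir / "multiple_logistic.csv")
    if results.cox is not None and results.cox.fit is not None:
        results.cox.fit.summary_frame().to_csv(outdir / "cox_regression.csv")
    (outdir / "manifest.json").write_text(json.dumps(results.manifest, indent=2))

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(1 - results.roc.specificity, results.roc.sensitivity, lw=2)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {results.roc.auc:.2f} "
                 f"(95% CI {results.roc.auc_ci_95[0]:.2f}-{results.roc.auc_ci_95[1]:.2f})")
    fig.savefig(outdir / "roc.png", dpi=120)
    plt.close(fig)

    if results.km is not None:
        fig, ax = plt.subplots(figsize=(6, 4.5))
        for stratum in results.km.strata:
            ax.step(stratum.timeline, stratum.survival, where="post", label=stratum.label)
        ax.set_xlabel("days from start of radiotherapy")
        ax.set_ylabel("fraction symptom-free")
        ax.legend(fontsize=8)
        fig.savefig(outdir / "km_terciles.png", dpi=120)
        plt.close(fig)

    if {"suv_95", "v30"}.issubset(df.columns):
        fig, ax = plt.subplots(figsize=(5.5, 4.5))
        sym = df["symptomatic"].astype(bool)
        ax.scatter(df.loc[~sym, "suv_95"], df.loc[~sym, "v30"], s=18, label="asymptomatic")
        ax.scatter(df.loc[sym, "suv_95"], df.loc[sym, "v30"], s=18, marker="x",
                   label="symptomatic")
        for s in results.partition.splits:
            if s.variable == "suv_95":
                ax.axvline(s.threshold, ls=":", c="k")
            else:
                ax.axhline(s.threshold, ls=":", c="k")
        ax.set_xlabel("SUV95")
        ax.set_ylabel("V30 (%)")
        ax.legend(fontsize=8)
        fig.savefig(outdir / "partition.png", dpi=120)
        plt.close(fig)

    if results.agreement is not None:
        fig, ax = plt.subplots(figsize=(5.5, 4))
        dev = results.agreement.deviations_pct
        for col in dev.columns:
            ax.scatter(range(len(dev)), dev[col], s=16, label=col)
        lo, hi = results.agreement.limits_of_agreement_pct
        ax.axhline(lo, ls="--", c="r")
        ax.axhline(hi, ls="--", c="r")
        ax.axhline(results.agreement.mean_deviation_pct, c="k", lw=0.8)
        ax.set_xlabel("subject")
        ax.set_ylabel("% deviation from subject mean")
        ax.legend(fontsize=7)
        fig.savefig(outdir / "bland_altman.png", dpi=120)
        plt.close(fig)
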