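"""Synthetic thoracic phantoms and simulated patient cohorts.

Every downstream stage of the pipeline (segmentation, biomarkers, dosimetry,
outcome statistics) is exercised against data generated here, so the
generators carry their own ground truth:

* :func:`generate_phantom` builds a CT/PET/dose triplet containing two
  ellipsoidal lungs, a branching central airway, optional cardiac and tumor
  hot spots whose activity spills into the lung after PSF blurring, and an
  optional attenuation cold-spot band at the diaphragm surface.  The returned
  truth object holds the exact lung/airway/artifact masks and the biomarker
  panel of the *unblurred* lung values.
* :func:`simulate_cohort` draws patient covariates and generates the
  grade >= 2 radiation-pneumonitis outcome from a logistic model and the time
  to symptom onset from an exponential proportional-hazards model, so
  regression refits can be checked against the generating coefficients.
* :func:`simulate_reader_readings` emulates repeat SUV95 reads by independent
  reviewers with a multiplicative inter-reader error.

The lung SUV texture is a stationary Gaussian random field rank-mapped to the
requested marginal distribution.  The field's correlation length (default
15 mm) is chosen well above the PET point-spread width so that resolution
blurring perturbs the voxel-value distribution only marginally, mimicking the
spatially smooth character of parenchymal inflammation.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import BinaryMask, ImageVolume, Modality
from .uptake_biomarkers import UptakeSummary, percentile

# --------------------------------------------------------------------------
# Phantom geometry (fractions of the grid shape; see docs/methods.md)
# --------------------------------------------------------------------------
MIN_GRID = 48

_THORAX_CENTER = (0.5, 0.5, 0.5)
_THORAX_SEMI = (0.44, 0.34, 0.47)
_LUNG_DX = 0.235                       # lung centres at x = 0.5 +/- _LUNG_DX
_LUNG_SEMI = (0.133, 0.172, 0.266)
_TRACHEA_XY = (0.5, 0.47)
_TRACHEA_R = 0.030
_TRACHEA_TOP = 0.86
_CARINA_Z = 0.625
_BRONCHUS_R = 0.019
_BRONCHUS_END_DX = 0.065               # medial lung edge is at 0.5 +/- 0.102
_BRONCHUS_END_Z = 0.55
_TUMOR_CENTER = (0.266, 0.5, 0.547)
_TUMOR_R = 0.047
_HEART_CENTER = (0.61, 0.53, 0.39)
_HEART_SEMI = (0.07, 0.07, 0.07)
_COLDSPOT_HEIGHT = 0.035               # band thickness above the lung base

#: CTCAE grade mix per 100 patients used when assigning grades to simulated
#: outcomes (grades 2-5 are the clinically symptomatic ones).
DEFAULT_GRADE_DISTRIBUTION = {0: 10, 1: 31, 2: 27, 3: 23, 4: 1, 5: 8}

# Lognormal SUV95 population whose lower/upper terciles fall at 0.99 and 1.2.
_Z_TERCILE = stats.norm.ppf(2.0 / 3.0)
SUV95_TERCILES = (0.99, 1.2)
SUV95_LOGNORMAL_SIGMA = (np.log(SUV95_TERCILES[1]) - np.log(SUV95_TERCILES[0])) / (2 * _Z_TERCILE)
SUV95_LOGNORMAL_MU = 0.5 * (np.log(SUV95_TERCILES[0]) + np.log(SUV95_TERCILES[1]))
SUV95_POPULATION_MEAN = float(np.exp(SUV95_LOGNORMAL_MU + SUV95_LOGNORMAL_SIGMA ** 2 / 2))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one thoracic phantom.

    ``lung_suv_distribution`` names the marginal distribution of the clean
    lung SUV field: ``{"name": "constant", "value": c}`` or
    ``{"name": "lognormal", "p95": target 95th percentile, "sigma": log-SD}``.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    lung_suv_distribution: dict = field(
        default_factory=lambda: {"name": "lognormal", "p95": 1.2,
                                 "sigma": float(SUV95_LOGNORMAL_SIGMA)})
    include_cardiac_spillover: bool = True
    include_tumor: bool = True
    include_diaphragm_coldspot: bool = True
    include_airway: bool = True
    psf_fwhm_mm: float = 7.0
    seed: int = 0
    # secondary realism knobs
    soft_tissue_suv: float = 0.9
    air_suv: float = 0.05
    heart_suv: float = 3.0
    tumor_suv: float = 6.0
    coldspot_factor: float = 0.55
    correlation_mm: float = 15.0        # GRF kernel sigma
    ct_noise_hu: float = 20.0
    ct_blur_mm: float = 1.2
    dose_peak_gy: float = 66.0
    dose_sigma_x_mm: float = 60.0
    dose_sigma_z_mm: float = 55.0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be three sizes, each >= 16")
        if any(int(n) < MIN_GRID for n in self.grid_shape):
            raise ValueError(
                f"grid too small to contain the thorax structures; minimum shape is "
                f"({MIN_GRID}, {MIN_GRID}, {MIN_GRID})")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        _lung_distribution(self.lung_suv_distribution)  # validate eagerly

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path


@dataclass
class PhantomTruth:
    """Ground truth shipped with every phantom."""

    lung_mask: BinaryMask               # parenchyma, airway and tumor excluded
    airway_mask: BinaryMask
    exclusions: dict                    # label -> BinaryMask (spill_over, tumor, cold_spot)
    suv_summary: UptakeSummary          # panel of the unblurred lung values
    lung_values: np.ndarray             # the clean lung SUV samples
    designed_p95: float | None


@dataclass
class Phantom:
    ct: ImageVolume
    pet: ImageVolume
    dose: ImageVolume
    truth: PhantomTruth
    spec: PhantomSpec


def _lung_distribution(d: dict):
    """Return a quantile function for the named lung-SUV distribution."""
    name = d.get("name")
    if name == "constant":
        value = float(d["value"])
        if value < 0:
            raise ValueError("constant lung SUV must be >= 0")
        return lambda q: np.full_like(np.asarray(q, dtype=float), value), value
    if name == "lognormal":
        sigma = float(d.get("sigma", SUV95_LOGNORMAL_SIGMA))
        if sigma <= 0:
            raise ValueError("lognormal sigma must be > 0")
        p95 = float(d["p95"])
        mu = np.log(p95) - sigma * stats.norm.ppf(0.95)
        return (lambda q: np.exp(mu + sigma * stats.norm.ppf(np.asarray(q, dtype=float))),
                p95)
    raise ValueError(f"unknown lung SUV distribution {name!r}")


def _ellipsoid(shape, center_frac, semi_frac):
    gx, gy, gz = np.ogrid[:shape[0], :shape[1], :shape[2]]
    cx, cy, cz = (c * (n - 1) for c, n in zip(center_frac, shape))
    ax, ay, az = (max(a * n, 1.0) for a, n in zip(semi_frac, shape))
    return (((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2) <= 1.0


def _airway_mask(shape) -> np.ndarray:
    """Trachea plus two main-stem bronchi, stopping short of the lungs."""
    nx, ny, nz = shape
    mask = np.zeros(shape, dtype=bool)
    cx, cy = _TRACHEA_XY[0] * (nx - 1), _TRACHEA_XY[1] * (ny - 1)
    r_tr = max(_TRACHEA_R * nx, 1.0)
    z_top, z_car = int(_TRACHEA_TOP * (nz - 1)), int(_CARINA_Z * (nz - 1))
    gx, gy = np.ogrid[:nx, :ny]
    trachea_disc = ((gx - cx) ** 2 + (gy - cy) ** 2) <= r_tr ** 2
    mask[:, :, z_car:z_top + 1] |= trachea_disc[:, :, None]
    # bronchi: straight tubes from the carina down-and-out toward each lung
    r_br = max(_BRONCHUS_R * nx, 1.0)
    z_end = int(_BRONCHUS_END_Z * (nz - 1))
    for side in (-1.0, 1.0):
        x_end = (0.5 + side * _BRONCHUS_END_DX) * (nx - 1)
        for z in range(z_end, z_car + 1):
            t = (z_car - z) / max(z_car - z_end, 1)
            x_c = cx + t * (x_end - cx)
            disc = ((gx - x_c) ** 2 + (gy - cy) ** 2) <= r_br ** 2
            mask[:, :, z] |= disc
    return mask


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the CT/PET/dose phantom described by ``spec``.

    Deterministic: the same spec (including seed) yields bit-identical
    volumes.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = tuple(float(s) for s in spec.spacing_mm)

    thorax = _ellipsoid(shape, _THORAX_CENTER, _THORAX_SEMI)
    lung_l = _ellipsoid(shape, (0.5 - _LUNG_DX, 0.5, 0.5), _LUNG_SEMI)
    lung_r = _ellipsoid(shape, (0.5 + _LUNG_DX, 0.5, 0.5), _LUNG_SEMI)
    lungs = lung_l | lung_r
    airway = _airway_mask(shape) if spec.include_airway else np.zeros(shape, bool)
    airway &= ~lungs  # the tube stops short of the lungs by construction
    tumor = _ellipsoid(shape, _TUMOR_CENTER, (_TUMOR_R,) * 3) & lungs \
        if spec.include_tumor else np.zeros(shape, bool)
    heart = _ellipsoid(shape, _HEART_CENTER, _HEART_SEMI) & thorax & ~lungs \
        if spec.include_cardiac_spillover else np.zeros(shape, bool)
    truth_lung = lungs & ~tumor & ~airway

    # ---- CT --------------------------------------------------------------
    ct = np.full(shape, -1000.0)
    ct[thorax] = 40.0
    ct[lungs] = -800.0
    ct[tumor] = 40.0
    ct[airway] = -1000.0
    ct += rng.normal(0.0, spec.ct_noise_hu, shape)
    ct = ndimage.gaussian_filter(ct, sigma=[spec.ct_blur_mm / s for s in spacing])

    # ---- PET: rank-mapped Gaussian random field inside the lung ----------
    qf, designed_p95 = _lung_distribution(spec.lung_suv_distribution)
    grf = ndimage.gaussian_filter(rng.standard_normal(shape),
                                  sigma=[spec.correlation_mm / s for s in spacing])
    lung_grf = grf[truth_lung]
    n = lung_grf.size
    order = np.argsort(lung_grf, kind="stable")
    targets = qf((np.arange(n) + 0.5) / n)
    lung_suv = np.empty(n)
    lung_suv[order] = targets

    struct = ndimage.generate_binary_structure(3, 2)
    shell = ndimage.binary_dilation(lungs, structure=struct, iterations=4)
    shell &= thorax & ~truth_lung & ~tumor & ~heart & ~airway
    sorted_grf = lung_grf[order]
    shell_suv = np.interp(grf[shell], sorted_grf, targets)

    pet = np.full(shape, spec.air_suv)
    pet[thorax] = spec.soft_tissue_suv
    pet[airway] = spec.air_suv
    pet[shell] = shell_suv
    pet[truth_lung] = lung_suv
    pet[tumor] = spec.tumor_suv
    pet[heart] = spec.heart_suv
    psf_sigma_mm = spec.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if psf_sigma_mm > 0:
        pet = ndimage.gaussian_filter(pet, sigma=[psf_sigma_mm / s for s in spacing])

    # attenuation cold spot at the diaphragm surface, applied post-blur
    coldspot = np.zeros(shape, bool)
    if spec.include_diaphragm_coldspot:
        z_idx = np.nonzero(truth_lung.any(axis=(0, 1)))[0]
        band_top = z_idx.min() + max(int(round(_COLDSPOT_HEIGHT * shape[2])), 2)
        gz = np.arange(shape[2])
        coldspot = truth_lung & (gz[None, None, :] < band_top)
        pet[coldspot] *= spec.coldspot_factor

    # ---- dose: cranio-caudal x beam-axis Gaussian falloff around the tumor
    gx, gy, gz = np.ogrid[:shape[0], :shape[1], :shape[2]]
    xt = _TUMOR_CENTER[0] * (shape[0] - 1)
    zt = _TUMOR_CENTER[2] * (shape[2] - 1)
    dose = spec.dose_peak_gy \
        * np.exp(-0.5 * ((gx - xt) * spacing[0] / spec.dose_sigma_x_mm) ** 2) \
        * np.exp(-0.5 * ((gz - zt) * spacing[2] / spec.dose_sigma_z_mm) ** 2)
    dose = np.broadcast_to(dose, shape).copy()

    # ---- truth ------------------------------------------------------------
    dilate_vox = int(np.ceil(3.0 * (psf_sigma_mm / min(spacing)))) + 2 if psf_sigma_mm > 0 else 2
    exclusions: dict[str, BinaryMask] = {}
    if spec.include_cardiac_spillover:
        spill = ndimage.binary_dilation(heart, structure=struct, iterations=dilate_vox)
        exclusions["spill_over"] = BinaryMask(spill & truth_lung, ["truth cardiac spill-over"])
    if spec.include_tumor:
        tspill = ndimage.binary_dilation(tumor, structure=struct, iterations=dilate_vox)
        exclusions["tumor"] = BinaryMask(tspill & truth_lung, ["truth tumor spill-over"])
    if spec.include_diaphragm_coldspot:
        exclusions["cold_spot"] = BinaryMask(coldspot, ["truth diaphragm cold spot"])

    sd = float(np.std(lung_suv, ddof=1)) if n > 1 else 0.0
    summary = UptakeSummary("SUV", float(lung_suv.mean()), sd, float(lung_suv.max()),
                            percentile(lung_suv, 80), percentile(lung_suv, 90),
                            percentile(lung_suv, 95), int(n))
    truth = PhantomTruth(
        lung_mask=BinaryMask(truth_lung, ["truth lung (airway and tumor excluded)"]),
        airway_mask=BinaryMask(airway, ["truth airway"]),
        exclusions=exclusions,
        suv_summary=summary,
        lung_values=lung_suv,
        designed_p95=designed_p95 if spec.lung_suv_distribution["name"] == "lognormal" else None,
    )
    return Phantom(
        ct=ImageVolume(ct, spacing, Modality.CT_HU, unit="HU"),
        pet=ImageVolume(pet, spacing, Modality.PET_SUV, unit="SUV"),
        dose=ImageVolume(dose, spacing, Modality.DOSE, unit="Gy"),
        truth=truth,
        spec=spec,
    )


def save_phantom(phantom: Phantom, outdir: str | Path, case_id: str = "phantom") -> Path:
    """Write the phantom as NIfTI volumes + truth masks + a JSON truth summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phantom.ct.to_nifti(outdir / f"{case_id}_ct.nii.gz")
    phantom.pet.to_nifti(outdir / f"{case_id}_pet.nii.gz")
    phantom.dose.to_nifti(outdir / f"{case_id}_dose.nii.gz")
    phantom.truth.lung_mask.to_nifti(outdir / f"{case_id}_truth_lung.nii.gz", phantom.ct)
    phantom.truth.airway_mask.to_nifti(outdir / f"{case_id}_truth_airway.nii.gz", phantom.ct)
    for label, mask in phantom.truth.exclusions.items():
        mask.to_nifti(outdir / f"{case_id}_excl_{label}.nii.gz", phantom.ct)
    s = phantom.truth.suv_summary
    (outdir / f"{case_id}_truth.json").write_text(json.dumps({
        "seed": phantom.spec.seed,
        "designed_p95": phantom.truth.designed_p95,
        "suv_summary": {k: getattr(s, k) for k in
                        ("modality", "mean", "sd", "max", "p80", "p90", "p95", "n_voxels")},
    }, indent=2))
    phantom.spec.to_json(outdir / f"{case_id}_spec.json")
    return outdir


# ==========================================================================
# Cohort simulation
# ==========================================================================

def _default_logistic():
    # slopes on centred scales: SUV95 per 0.1, age per 5 years, V30 per percent;
    # intercept set to logit(0.59) so the simulated symptomatic fraction matches
    # the reported incidence.
    return {"intercept": float(np.log(0.59 / 0.41)),
            "suv_95": 0.40, "age": 0.79, "v30": 0.09}


def _default_cox():
    return {"suv_95": 0.18, "age": 0.34, "v30": 0.05}


def _default_covariates():
    return {
        "age": {"dist": "truncnorm", "mean": 64.0, "sd": 8.0, "lo": 35.0, "hi": 90.0},
        "v30": {"dist": "truncnorm", "mean": 23.8, "sd": 8.0, "lo": 0.0, "hi": 60.0},
        "suv_95": {"dist": "lognormal", "mu": float(SUV95_LOGNORMAL_MU),
                   "sigma": float(SUV95_LOGNORMAL_SIGMA)},
    }


def _default_scales():
    # covariate -> (centre, units-per-coefficient-step)
    return {"suv_95": (SUV95_POPULATION_MEAN, 0.1),
            "age": (64.0, 5.0),
            "v30": (23.8, 1.0)}


#: Baseline hazard (events/day) calibrated so the Kaplan-Meier median time to
#: symptoms in the upper two SUV95 terciles is ~101 days under the default Cox
#: slopes and 183-day administrative censoring.
DEFAULT_BASELINE_HAZARD = 0.00508


@dataclass(frozen=True)
class CohortConfig:
    """Generative model for a simulated patient cohort."""

    n_patients: int = 100
    logistic_coefficients: dict = field(default_factory=_default_logistic)
    cox_coefficients: dict = field(default_factory=_default_cox)
    covariate_distributions: dict = field(default_factory=_default_covariates)
    scales: dict = field(default_factory=_default_scales)
    baseline_hazard: float = DEFAULT_BASELINE_HAZARD
    admin_censor_days: float = 183.0
    grade_distribution: dict = field(default_factory=lambda: dict(DEFAULT_GRADE_DISTRIBUTION))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.admin_censor_days <= 0:
            raise ValueError("admin_censor_days must be > 0")


def _truncnorm(rng, n, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                               random_state=np.random.RandomState(rng.integers(2 ** 31)))


def _draw_covariate(rng, n, spec):
    if spec["dist"] == "truncnorm":
        return _truncnorm(rng, n, spec["mean"], spec["sd"], spec["lo"], spec["hi"])
    if spec["dist"] == "lognormal":
        return rng.lognormal(spec["mu"], spec["sigma"], n)
    raise ValueError(f"unknown covariate distribution {spec['dist']!r}")


def design_columns(df: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Centred/scaled regression columns ``x_<name>`` for the model covariates.

    These are the scales on which the generating coefficients are defined,
    and the scales a refit must use to recover them.
    """
    out = df.copy()
    for name, (center, step) in config.scales.items():
        out[f"x_{name}"] = (df[name] - center) / step
    return out


def linear_predictors(df: pd.DataFrame, config: CohortConfig):
    """(logistic LP, Cox LP) for each row of ``df``; errors on non-finite values."""
    xs = design_columns(df, config)
    lp_log = np.full(len(df), float(config.logistic_coefficients.get("intercept", 0.0)))
    for name, beta in config.logistic_coefficients.items():
        if name != "intercept":
            lp_log = lp_log + beta * xs[f"x_{name}"].to_numpy()
    lp_cox = np.zeros(len(df))
    for name, beta in config.cox_coefficients.items():
        lp_cox = lp_cox + beta * xs[f"x_{name}"].to_numpy()
    if not (np.all(np.isfinite(lp_log)) and np.all(np.isfinite(lp_cox))):
        raise ValueError("non-finite linear predictor; check coefficients and scales")
    return lp_log, lp_cox


_CATEGORICALS = {
    "sex": (["male", "female"], [0.60, 0.40]),
    "stage": (["I", "II", "III", "IV"], [0.06, 0.05, 0.78, 0.11]),
    "tumor_location": (["LLL", "LUL", "RLL", "RML", "RUL"], [0.15, 0.25, 0.09, 0.06, 0.45]),
    "histology": (["adenocarcinoma", "neuroendocrine", "non_small_cell_nos", "squamous"],
                  [0.57, 0.01, 0.18, 0.24]),
    "treatment_type": (["IMRT", "proton", "3DCRT"], [0.64, 0.13, 0.23]),
    "chemo_status": (["concurrent", "rt_alone"], [0.86, 0.14]),
    "smoking": (["current", "former", "never"], [0.28, 0.66, 0.06]),
}


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate one cohort as a tidy table, one row per patient.

    The symptomatic indicator follows the logistic layer exactly and the
    (time, event) pair follows the exponential proportional-hazards layer
    exactly; the two layers share one uniform draw per patient (comonotone
    coupling) so that high-risk patients are both symptomatic and early-onset.
    See docs/methods.md for why the layers are not merged into one outcome.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    df = pd.DataFrame({"patient_id": [f"P{i:05d}" for i in range(n)]})
    for name, spec in config.covariate_distributions.items():
        df[name] = _draw_covariate(rng, n, spec)
    for name, (levels, probs) in _CATEGORICALS.items():
        df[name] = rng.choice(levels, size=n, p=probs)
    df["interval_days"] = np.clip(np.round(rng.lognormal(np.log(18.0), 0.7, n)), 3, 69)
    df["fev1_pct"] = _truncnorm(rng, n, 72.0, 18.0, 30.0, 124.0)
    df["dlco_pct"] = _truncnorm(rng, n, 66.0, 20.0, 23.0, 125.0)
    # companion uptake/dose columns, loosely derived for realism; they carry no
    # outcome signal beyond their correlation with the active covariates
    suv95 = df["suv_95"].to_numpy()
    df["suv_90"] = suv95 * rng.normal(0.95, 0.01, n)
    df["suv_80"] = suv95 * rng.normal(0.88, 0.02, n)
    df["suv_mean"] = suv95 * rng.normal(0.62, 0.03, n)
    df["suv_sd"] = suv95 * np.abs(rng.normal(0.18, 0.02, n))
    df["suv_max"] = suv95 * rng.uniform(1.5, 4.0, n)
    df["hu_mean"] = rng.normal(-770.0, 35.0, n)
    df["hu_sd"] = np.abs(rng.normal(120.0, 15.0, n))
    df["hu_90"] = rng.normal(-630.0, 45.0, n)
    df["hu_80"] = df["hu_90"] - np.abs(rng.normal(50.0, 15.0, n))
    df["hu_95"] = df["hu_90"] + np.abs(rng.normal(25.0, 10.0, n))
    df["hu_max"] = rng.normal(40.0, 30.0, n)
    v30 = df["v30"].to_numpy()
    df["v20"] = np.clip(v30 + np.abs(rng.normal(6.0, 3.0, n)), 0, 100)
    df["v10"] = np.clip(df["v20"] + np.abs(rng.normal(8.0, 4.0, n)), 0, 100)
    df["v5"] = np.clip(df["v10"] + np.abs(rng.normal(7.0, 4.0, n)), 0, 100)
    df["mld"] = _truncnorm(rng, n, 17.9, 5.5, 2.9, 29.4)

    lp_log, lp_cox = linear_predictors(df, config)
    p = 1.0 / (1.0 + np.exp(-lp_log))
    hazard = config.baseline_hazard * np.exp(lp_cox)
    u = rng.uniform(size=n)
    symptomatic = u < p
    t_raw = -np.log1p(-u) / hazard
    event = t_raw <= config.admin_censor_days
    df["time_days"] = np.minimum(t_raw, config.admin_censor_days)
    df["event"] = event.astype(int)
    df["symptomatic"] = symptomatic.astype(int)

    gd = config.grade_distribution
    sym_grades = np.array([g for g in (2, 3, 4, 5) if gd.get(g, 0) > 0])
    sym_p = np.array([gd[g] for g in sym_grades], dtype=float)
    sym_p /= sym_p.sum()
    asym_grades = np.array([g for g in (0, 1) if gd.get(g, 0) > 0])
    asym_p = np.array([gd[g] for g in asym_grades], dtype=float)
    asym_p /= asym_p.sum()
    grades = np.where(symptomatic,
                      rng.choice(sym_grades, size=n, p=sym_p),
                      rng.choice(asym_grades, size=n, p=asym_p))
    df["rp_grade"] = grades
    df.attrs["seed"] = config.seed
    return df


# ==========================================================================
# Inter-reader reading simulation
# ==========================================================================

@dataclass(frozen=True)
class ReaderSimSpec:
    """Repeat-read study design: subjects x readers with multiplicative error."""

    n_subjects: int = 10
    n_readers: int = 3
    between_subject_sd_pct: float = 15.0
    inter_reader_sd_pct: float = 3.0
    base_suv95: float = SUV95_POPULATION_MEAN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_readers < 2:
            raise ValueError("n_readers must be >= 2")
        if self.between_subject_sd_pct < 0 or self.inter_reader_sd_pct < 0:
            raise ValueError("percent SDs must be >= 0")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")


def simulate_reader_readings(spec: ReaderSimSpec) -> pd.DataFrame:
    """Subjects x readers matrix of SUV95 readings.

    ``reading(s, r) = subject_value(s) * (1 + eps_sr)`` with
    ``eps_sr ~ N(0, inter_reader_sd_pct / 100)``.
    """
    rng = np.random.default_rng(spec.seed)
    subj = spec.base_suv95 * (1.0 + rng.normal(0.0, spec.between_subject_sd_pct / 100.0,
                                               spec.n_subjects))
    subj = np.clip(subj, 0.05, None)
    eps = rng.normal(0.0, spec.inter_reader_sd_pct / 100.0,
                     (spec.n_subjects, spec.n_readers))
    readings = subj[:, None] * (1.0 + eps)
    if np.any(readings <= 0):
        warnings.warn("some simulated readings were non-positive and were clipped",
                      stacklevel=2)
        readings = np.clip(readings, 1e-6, None)
    return pd.DataFrame(readings,
                        index=[f"S{i + 1:03d}" for i in range(spec.n_subjects)],
                        columns=[f"reader_{r + 1}" for r in range(spec.n_readers)])
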