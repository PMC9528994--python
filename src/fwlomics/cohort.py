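"""Synthetic phantom cohort generator.

Emulates the statistical structure the analysis assumes, at desk scale:
two-ellipsoid lungs, a spherical tumor (GTV) excluded from the lung, an
anisotropic Gaussian dose bath centred on the tumor and normalised so the
GTV-centre dose equals the prescription, a smooth positive perfusion field
with a deliberately hypo-perfused sub-volume (so the 0.3 threshold always
yields both functional classes), and a pneumonitis label drawn from a
logistic model of dose to the high-functional region plus a texture term
and noise.  Nothing here attempts realistic anatomy or beam physics.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage, optimize, special

from .core import BinaryMask, PatientRecord, ScalarVolume
from .regions import build_region_set

logger = logging.getLogger("fwlomics")


@dataclasses.dataclass
class CohortConfig:
    """Study-condition knobs for the phantom cohort.

    Defaults mirror the reference population: 126 patients, 50.8% RP
    prevalence, prescriptions in 50-70 Gy; the grid is 48^3 at 3 mm.
    """

    n_patients: int = 126
    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    prevalence: float = 0.508
    rx_range: tuple[float, float] = (50.0, 70.0)
    perfusion_corr_mm: float = 15.0
    threshold: float = 0.3
    # logistic RP model: beta0 + b_dose * z(meanDose high) + b_tex * z(doseSD low) + eps
    beta_dose: float = 2.0
    beta_texture: float = 0.5
    noise_sd: float = 0.4
    beta0: float = 0.0
    # nominal centring/scaling of the two planted features (Gy)
    feature_center: tuple[float, float] = (9.5, 13.0)
    feature_scale: tuple[float, float] = (5.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence target must be in (0, 1)")
        if self.n_patients < 8:
            raise ValueError("need at least 8 patients for stratified splitting")
        if min(self.shape) < 24:
            raise ValueError("grid too small to contain lungs and GTV")


@dataclasses.dataclass
class GroundTruth:
    """Per-patient linear predictors and the planted informative features."""

    linear_predictor: np.ndarray
    beta0: float
    planted_features: tuple[str, ...]
    planted_values: np.ndarray  # columns: meanDose(high), doseSD(low)


#: table-column names of the planted mechanism (FWL dose features)
PLANTED_FEATURE_NAMES = (
    "highFWL:D:dosio:firstorder:Mean",
    "lowFWL:D:dosio:firstorder:Variance",
)


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    acc = np.zeros(shape)
    for g, c, s in zip(grids, center, semi):
        acc += ((g - c) / s) ** 2
    return acc <= 1.0


def generate_patient(cfg: CohortConfig, rng: np.random.Generator, pid: str = "P0") -> PatientRecord:
    """One phantom patient (without the RP label)."""
    shape = cfg.shape
    sp = np.asarray(cfg.spacing)
    nx, ny, nz = shape

    jit = lambda lo, hi: float(rng.uniform(lo, hi))
    lung_semi = np.array([0.17 * nx, 0.22 * ny, 0.30 * nz])
    centers = {
        "L": np.array([0.30 * nx + jit(-1, 1), 0.5 * ny + jit(-1, 1), 0.48 * nz + jit(-1, 1)]),
        "R": np.array([0.70 * nx + jit(-1, 1), 0.5 * ny + jit(-1, 1), 0.48 * nz + jit(-1, 1)]),
    }
    lung = np.zeros(shape, dtype=bool)
    for c in centers.values():
        lung |= _ellipsoid(shape, c, lung_semi * rng.uniform(0.92, 1.08, size=3))
    if not lung.any():
        raise ValueError("grid too small: empty lung mask")

    side = "L" if rng.random() < 0.5 else "R"
    gtv_center = centers[side] + rng.uniform(-0.35, 0.35, size=3) * lung_semi
    gtv_center = np.clip(gtv_center, 3, np.array(shape) - 4)
    gtv_r = jit(2.2, 4.0)
    gtv = _ellipsoid(shape, gtv_center, (gtv_r, gtv_r, gtv_r))
    lung_ex = lung & ~gtv  # GTV excluded from the lung volume

    # dose: anisotropic Gaussian, peak (= prescription) at the GTV centre voxel
    rx = float(np.round(rng.uniform(*cfg.rx_range)))
    sig_vox = np.array([jit(4.5, 6.5), jit(4.5, 6.5), jit(6.0, 8.5)])
    grids = np.indices(shape).astype(float)
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, gtv_center, sig_vox))
    cvox = tuple(int(round(c)) for c in gtv_center)
    qc = sum(((cv - c) / s) ** 2 for cv, c, s in zip(cvox, gtv_center, sig_vox))
    dose = rx * np.exp(-0.5 * (q - qc))  # exact rx at the centre voxel

    # perfusion: smooth positive log-normal field + hypo-perfused sub-volume
    corr_vox = cfg.perfusion_corr_mm / sp
    noise = rng.standard_normal(shape)
    g = ndimage.gaussian_filter(noise, sigma=corr_vox, mode="reflect")
    gsd = g.std()
    g = g / gsd if gsd > 0 else g
    perf = 100.0 * np.exp(0.4 * g)
    defect_side = side if rng.random() < 0.7 else ("R" if side == "L" else "L")
    dc = centers[defect_side] + rng.uniform(-0.3, 0.3, size=3) * lung_semi
    dsemi = lung_semi * rng.uniform(0.45, 0.65, size=3)
    qd = sum(((gr - c) / s) ** 2 for gr, c, s in zip(grids, dc, dsemi))
    perf = perf * (1.0 - 0.85 * np.exp(-0.5 * qd))

    # CT: air-filled lung, soft-tissue background, solid tumor, mild noise
    ct = np.full(shape, 40.0)
    ct[lung] = -800.0
    ct[gtv] = 30.0
    ct += rng.standard_normal(shape) * 20.0

    mk = lambda a: ScalarVolume(a, cfg.spacing, (0.0, 0.0, 0.0), unit="normalized")
    return PatientRecord(
        id=pid,
        ct=ScalarVolume(ct, cfg.spacing, unit="HU"),
        dose=ScalarVolume(dose, cfg.spacing, unit="Gy"),
        lung=BinaryMask(lung_ex, cfg.spacing),
        gtv=BinaryMask(gtv, cfg.spacing),
        perfusion=ScalarVolume(perf, cfg.spacing, unit="perfusion-arb"),
        prescription=rx,
        covariates=_draw_covariates(rng),
    )


def _draw_covariates(rng: np.random.Generator) -> dict:
    return {
        "gender": rng.choice(["M", "F"], p=[0.865, 0.135]),
        "age": float(np.clip(np.round(rng.normal(61, 10)), 29, 82)),
        "pathology": rng.choice(["SCC", "ADC", "Other"], p=[0.627, 0.333, 0.04]),
        "smoking": rng.choice(["ever", "never"], p=[0.77, 0.23]),
        "stage": rng.choice(["IIIA", "IIIB", "IIIC"], p=[0.571, 0.294, 0.135]),
        "treatment": rng.choice(["SCRT", "CCRT", "RT"], p=[0.659, 0.333, 0.008]),
    }


def planted_feature_values(p: PatientRecord, cfg: CohortConfig) -> tuple[float, float]:
    """(mean dose in the high-functional region, dose SD in the low one)."""
    regions = build_region_set(p.perfusion, p.lung, p.gtv, cfg.threshold)
    high = regions.high.values if regions.high.values.any() else regions.wl.values
    low = regions.low.values if regions.low.values.any() else regions.wl.values
    return float(p.dose.values[high].mean()), float(p.dose.values[low].std())


def rp_linear_predictor(p: PatientRecord, cfg: CohortConfig) -> float:
    """beta-weighted standardized planted features (no intercept, no noise)."""
    x1, x2 = planted_feature_values(p, cfg)
    c1, c2 = cfg.feature_center
    s1, s2 = cfg.feature_scale
    return cfg.beta_dose * (x1 - c1) / s1 + cfg.beta_texture * (x2 - c2) / s2


def simulate_rp_label(p: PatientRecord, cfg: CohortConfig, rng: np.random.Generator) -> int:
    """RP ~ Bernoulli(sigmoid(beta0 + predictor + eps))."""
    z = cfg.beta0 + rp_linear_predictor(p, cfg) + rng.normal(0.0, cfg.noise_sd)
    return int(rng.random() < special.expit(z))


def _calibrate_beta0(z: np.ndarray, target: float) -> float:
    """Intercept such that mean sigmoid(beta0 + z) hits the prevalence target."""
    fun = lambda b0: special.expit(b0 + z).mean() - target
    bound = float(np.abs(z).max()) + 60.0
    return float(optimize.brentq(fun, -bound, bound))


def generate_cohort(cfg: CohortConfig) -> tuple[list[PatientRecord], GroundTruth]:
    """n_patients phantom records plus the generating ground truth.

    The logistic intercept is calibrated on the realised cohort so the
    expected prevalence matches the target; labels are then Bernoulli draws.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_patients + 1)
    label_rng = np.random.default_rng(seeds[-1])
    records, planted = [], []
    for i in range(cfg.n_patients):
        rng = np.random.default_rng(seeds[i])
        p = generate_patient(cfg, rng, pid=f"P{i:03d}")
        planted.append(planted_feature_values(p, cfg))
        records.append(p)
    planted_arr = np.asarray(planted)
    c = np.asarray(cfg.feature_center)
    s = np.asarray(cfg.feature_scale)
    zs = (planted_arr - c) / s
    z = cfg.beta_dose * zs[:, 0] + cfg.beta_texture * zs[:, 1]
    z = z + label_rng.normal(0.0, cfg.noise_sd, size=len(records))
    beta0 = _calibrate_beta0(z, cfg.prevalence)
    labels = (label_rng.random(len(records)) < special.expit(beta0 + z)).astype(int)
    for p, y in zip(records, labels):
        p.rp = int(y)
    logger.info(
        "cohort seed=%d: n=%d, RP prevalence %.3f (target %.3f)",
        cfg.seed, cfg.n_patients, labels.mean(), cfg.prevalence,
    )
    gt = GroundTruth(
        linear_predictor=beta0 + z,
        beta0=beta0,
        planted_features=PLANTED_FEATURE_NAMES,
        planted_values=planted_arr,
    )
    return records, gt
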