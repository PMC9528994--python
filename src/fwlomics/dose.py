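"""Dose feature catalog: DVH parameters, scale-invariant spatial dose
moments, and dosiomics.

The default catalog has 213 entries: 63 moments + 59 DVH parameters + 91
dosiomics features.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np

from .core import BinaryMask, DegenerateROIError, ScalarVolume
from .radiomics.extract import extract_intensity_features

logger = logging.getLogger("fwlomics")


class ZeroDoseError(ValueError):
    """ROI receives no dose: spatial moments are undefined."""


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DVHSpec:
    """One DVH parameter: Dx (x = % volume) or Vx (x = Gy, or % of the
    prescription dose)."""

    kind: str  # 'D' | 'Vgy' | 'Vpct'
    x: float

    def __post_init__(self) -> None:
        if self.kind not in ("D", "Vgy", "Vpct"):
            raise ValueError(f"bad DVH spec kind {self.kind!r}")
        if self.kind in ("D",) and not 0 < self.x <= 100:
            raise ValueError(f"Dx percentage out of (0, 100]: {self.x}")
        if self.x <= 0:
            raise ValueError("DVH spec x must be positive")

    @property
    def name(self) -> str:
        xs = f"{self.x:g}"
        return {"D": f"D{xs}", "Vgy": f"V{xs}Gy", "Vpct": f"V{xs}pct"}[self.kind]


def default_dvh_catalog() -> tuple[DVHSpec, ...]:
    """59 parameters: D2, D5..D95 (step 5), D98; V5..V70 Gy (step 5);
    V5..V120 % of prescription (step 5)."""
    dx = [2.0] + [float(x) for x in range(5, 100, 5)] + [98.0]
    vgy = [float(x) for x in range(5, 75, 5)]
    vpct = [float(x) for x in range(5, 125, 5)]
    return tuple(
        [DVHSpec("D", x) for x in dx]
        + [DVHSpec("Vgy", x) for x in vgy]
        + [DVHSpec("Vpct", x) for x in vpct]
    )


def dvh_curve(dose: ScalarVolume, roi: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative DVH: (dose levels ascending, fraction of ROI volume
    receiving >= that dose).  Starts at (0, 1.0) and is non-increasing."""
    roi.require_nonempty()
    d = np.sort(dose.values[roi.values])
    n = d.size
    levels = np.concatenate(([0.0], np.unique(d)))
    frac = 1.0 - np.searchsorted(d, levels, side="left") / n
    return levels, frac


def _dx(sorted_desc: np.ndarray, x_pct: float) -> float:
    """Minimum dose received by the hottest x% of the ROI volume, linearly
    interpolated on the cumulative volume grid."""
    n = sorted_desc.size
    f = np.arange(1, n + 1) / n
    q = x_pct / 100.0
    if q <= f[0]:
        return float(sorted_desc[0])
    return float(np.interp(q, f, sorted_desc))


def dvh_parameters(
    dose: ScalarVolume,
    roi: BinaryMask,
    prescription: float,
    catalog: tuple[DVHSpec, ...] | None = None,
) -> dict[str, float]:
    """Dx in Gy; Vx as % of ROI volume receiving >= the dose cut."""
    roi.require_nonempty()
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    catalog = catalog or default_dvh_catalog()
    d = dose.values[roi.values]
    desc = np.sort(d)[::-1]
    n = d.size
    out = {}
    for spec in catalog:
        if spec.kind == "D":
            out[spec.name] = _dx(desc, spec.x)
        else:
            cut = spec.x if spec.kind == "Vgy" else spec.x / 100.0 * prescription
            out[spec.name] = float((d >= cut).sum() / n * 100.0)
    return out


# ---------------------------------------------------------------------------
# Scale-invariant spatial dose moments
# ---------------------------------------------------------------------------

def moment_orders() -> tuple[tuple[int, int, int], ...]:
    """All (p, q, r) with p,q,r in 0..3 except (0,0,0): 63 orders."""
    return tuple(
        o for o in itertools.product(range(4), repeat=3) if o != (0, 0, 0)
    )


def dose_moments(dose: ScalarVolume, roi: BinaryMask) -> dict[str, float]:
    """Normalised central moments of the dose-weighted spatial distribution.

    eta_pqr = mu_pqr / mu_000^(1 + (p+q+r)/3) with
    mu_pqr = sum_roi (x-cx)^p (y-cy)^q (z-cz)^r * D * dV, coordinates in
    world mm and (cx, cy, cz) the dose-weighted centroid.  Including the
    voxel volume dV makes eta invariant to uniform spatial scaling.
    Axis order is (x, y, z) = (ML, AP, CC) of the world frame.
    """
    roi.require_nonempty()
    w = dose.values[roi.values]
    total = w.sum()
    if total <= 0:
        raise ZeroDoseError("ROI receives no dose")
    ijk = np.argwhere(roi.values)
    xyz = ijk * np.asarray(dose.spacing) + np.asarray(dose.origin)
    centroid = (xyz * w[:, None]).sum(axis=0) / total
    rel = xyz - centroid
    dv = dose.voxel_volume
    mu000 = total * dv
    # powers up to 3 per axis, precomputed
    pw = [np.stack([rel[:, ax] ** k for k in range(4)]) for ax in range(3)]
    out = {}
    for p, q, r in moment_orders():
        mu = float((pw[0][p] * pw[1][q] * pw[2][r] * w).sum()) * dv
        eta = mu / mu000 ** (1.0 + (p + q + r) / 3.0)
        out[f"moment:eta_{p}{q}{r}"] = eta
    return out


# ---------------------------------------------------------------------------
# Dosiomics and the full catalog
# ---------------------------------------------------------------------------

DOSIOMICS_BIN_COUNT = 50


def dosiomics_features(
    dose: ScalarVolume, roi: BinaryMask, n_bins: int = DOSIOMICS_BIN_COUNT
) -> dict[str, float]:
    """91 intensity features on the original dose image (one bin count)."""
    roi.require_nonempty()
    feats = extract_intensity_features(dose, roi, n_bins)
    return {f"dosio:{k}": v for k, v in feats.items()}


def extract_dose_catalog(
    dose: ScalarVolume,
    roi: BinaryMask,
    prescription: float,
    dvh_catalog: tuple[DVHSpec, ...] | None = None,
    dosiomics_bins: int = DOSIOMICS_BIN_COUNT,
) -> dict[str, float]:
    """63 moments + 59 DVH parameters + 91 dosiomics = 213 named values."""
    out = dose_moments(dose, roi)
    dvh = dvh_parameters(dose, roi, prescription, dvh_catalog)
    out.update({f"dvh:{k}": v for k, v in dvh.items()})
    out.update(dosiomics_features(dose, roi, dosiomics_bins))
    return out
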