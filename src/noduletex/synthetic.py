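"""Synthetic CT ROI cohorts with the statistical structure of the study data.

The real cohort (6,299 ROI crops from 336 patients, roughly 3.3 malignant
ROIs per benign one) is not publicly deposited, so this module generates a
stand-in with the features the analysis pipeline actually exercises:

* rectangular grayscale crops holding one bright nodule on a darker
  background (muscle/vessel-like clutter), so segmentation has real work;
* two texture classes: benign nodules are smooth discs; malignant nodules
  add oriented band-limited gratings (what directional subbands detect),
  speckle, and an irregular margin, all scaled by ``texture_contrast`` so
  that contrast 0 makes the classes statistically exchangeable;
* per-patient structure: each patient contributes several ROIs that share
  one rendered nodule diameter;
* a 19-variable patient table whose class-conditional distributions default
  to the study's published marginal rates.

No claim of anatomical realism is made; see the methods note for what
passing tests on this cohort does and does not show about real CT data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from noduletex.stats import PATIENT_COLUMNS

__all__ = [
    "CohortSpec",
    "RoiImage",
    "SyntheticCohort",
    "PATIENT_TABLE_RATES",
    "generate_cohort",
    "generate_patient_table",
    "write_cohort",
]

# Class-conditional parameters of the patient table (benign, malignant).
# Binary variables: P(yes); continuous: (mean, sd).  Values default to the
# published cohort marginals (e.g. smoking 24/84 vs 154/252).
PATIENT_TABLE_RATES: Dict[str, Tuple] = {
    "gender": (34 / 84, 102 / 252),          # P(female)
    "smoking": (24 / 84, 154 / 252),
    "tuberculosis_history": (6 / 84, 15 / 252),
    "tumor_history": (3 / 84, 17 / 252),
    "genetic_disease": (0 / 84, 3 / 252),
    "dust_history": (1 / 84, 6 / 252),
    "lymphadenectasis": (11 / 84, 78 / 252),
    "uniform_density": (31 / 84, 96 / 252),
    "substantial_changes": (75 / 84, 227 / 252),
    "ground_glass": (6 / 84, 19 / 252),
    "spiculation": (61 / 84, 186 / 252),
    "lobulation": (64 / 84, 199 / 252),
    "vacuoles": (18 / 84, 36 / 252),
    "calcification": (7 / 84, 28 / 252),
    "cavitation": (6 / 84, 31 / 252),
    "pleural_indentation": (30 / 84, 80 / 252),
    "pleural_fluid": (8 / 84, 25 / 252),
    "age": ((54.10, 13.57), (59.90, 12.68)),        # years
    "diameter": ((1.80, 0.68), (2.22, 0.73)),       # cm
}

# Gray-level scale (arbitrary CT-like units stored as 16-bit on disk)
_BACKGROUND_MEAN = 40.0
_NODULE_MEAN = 100.0
_TEXTURE_AMPLITUDE = 12.0  # per unit texture_contrast


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of a synthetic cohort.

    Defaults mirror the study scale: 84 benign / 252 malignant patients,
    17-20 ROIs per patient, 128-px crops, 7-30 mm nodules.
    """

    n_benign_patients: int = 84
    n_malignant_patients: int = 252
    rois_per_patient: Tuple[int, int] = (17, 20)
    image_size: int = 128
    diameter_range_mm: Tuple[float, float] = (7.0, 30.0)
    pixel_size_mm: float = 0.7
    texture_contrast: float = 0.6
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign_patients <= 0 or self.n_malignant_patients <= 0:
            raise ValueError("patient counts must be positive")
        lo, hi = self.rois_per_patient
        if lo <= 0 or hi < lo:
            raise ValueError("invalid rois_per_patient range")
        n = self.image_size
        if n < 64 or (n & (n - 1)) != 0:
            raise ValueError("image_size must be a power of two >= 64")
        dlo, dhi = self.diameter_range_mm
        if not (7.0 <= dlo <= dhi <= 30.0):
            raise ValueError("diameter range must lie within [7, 30] mm")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel size must be positive")
        if self.texture_contrast < 0:
            raise ValueError("texture_contrast must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class RoiImage:
    """One grayscale ROI crop with its provenance."""

    pixels: np.ndarray
    pixel_size_mm: float
    label: str
    patient_id: str
    diameter_mm: float
    roi_id: str = ""
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.mask is not None and self.mask.shape != self.pixels.shape:
            raise ValueError("mask shape mismatch")
        if not (0 < self.diameter_mm <= 30):
            raise ValueError("diameter_mm out of (0, 30]")


@dataclass
class SyntheticCohort:
    rois: List[RoiImage]
    patients: pd.DataFrame
    spec: CohortSpec

    def __post_init__(self) -> None:
        ids = set(self.patients["patient_id"])
        labels = dict(zip(self.patients["patient_id"], self.patients["label"]))
        for roi in self.rois:
            if roi.patient_id not in ids:
                raise ValueError(f"ROI patient {roi.patient_id} not in table")
            if labels[roi.patient_id] != roi.label:
                raise ValueError("ROI/patient label mismatch")

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": [r.roi_id for r in self.rois],
                "patient_id": [r.patient_id for r in self.rois],
                "label": [r.label for r in self.rois],
                "diameter_mm": [r.diameter_mm for r in self.rois],
            }
        )


def _render_roi(rng: np.random.Generator, spec: CohortSpec, label: str,
                diameter_mm: float) -> np.ndarray:
    """Render one crop: smooth disc base plus contrast-scaled malignant
    components (gratings, speckle, margin irregularity) and noise."""
    n = spec.image_size
    radius_px = diameter_mm / spec.pixel_size_mm / 2.0
    cy, cx = (n / 2 + rng.uniform(-2, 2), n / 2 + rng.uniform(-2, 2))
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    # margin irregularity: low-order radial perturbation, contrast-scaled
    c = spec.texture_contrast if label == "malignant" else 0.0
    boundary = np.full_like(r, radius_px)
    if c > 0:
        n_lobes = rng.integers(3, 7)
        phase = rng.uniform(0, 2 * np.pi)
        amp = 0.15 * c * radius_px
        boundary = radius_px + amp * np.sin(n_lobes * theta + phase)

    # smooth edge profile (2-px transition approximates partial volume)
    disc = 1.0 / (1.0 + np.exp((r - boundary) / 1.2))
    img = _BACKGROUND_MEAN + (_NODULE_MEAN - _BACKGROUND_MEAN) * disc

    # background clutter: a few soft elongated streaks (vessel-like)
    n_streaks = rng.integers(2, 5)
    for _ in range(n_streaks):
        ang = rng.uniform(0, np.pi)
        off = rng.uniform(-n / 2, n / 2)
        dist = np.abs((xx - n / 2) * np.sin(ang) - (yy - n / 2) * np.cos(ang)
                      - off)
        streak = 12.0 * np.exp(-(dist ** 2) / (2 * 2.0 ** 2))
        img += streak * (1.0 - disc)

    if c > 0:
        # oriented band-limited texture inside the nodule
        n_gratings = rng.integers(2, 5)
        tex = np.zeros_like(img)
        for _ in range(n_gratings):
            ang = rng.uniform(0, np.pi)
            wavelength = rng.uniform(4.0, 12.0)  # px
            phase = rng.uniform(0, 2 * np.pi)
            k = 2 * np.pi / wavelength
            tex += np.sin(k * (np.cos(ang) * yy + np.sin(ang) * xx) + phase)
        tex *= _TEXTURE_AMPLITUDE * c / np.sqrt(n_gratings)
        # speckle: white noise smoothed is avoided (keep high-frequency)
        speckle = rng.normal(0.0, 0.35 * _TEXTURE_AMPLITUDE * c, size=img.shape)
        img += (tex + speckle) * disc

    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return img


def generate_patient_table(spec: CohortSpec,
                           rates: Dict[str, Tuple] | None = None
                           ) -> pd.DataFrame:
    """Patient table with class-conditional marginals.

    ``rates`` overrides the default class-conditional parameters (binary:
    (p_benign, p_malignant); continuous: ((mean, sd), (mean, sd))).
    """
    rates = dict(PATIENT_TABLE_RATES, **(rates or {}))
    for var, val in rates.items():
        if var not in ("age", "diameter"):
            pb, pm = val
            if not (0 <= pb <= 1 and 0 <= pm <= 1):
                raise ValueError(f"probability out of [0,1] for {var}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    rows = []
    counts = (("benign", spec.n_benign_patients),
              ("malignant", spec.n_malignant_patients))
    for label, n_pat in counts:
        sel = 0 if label == "benign" else 1
        for i in range(n_pat):
            pid = f"{label[0].upper()}{i:04d}"
            row = {"patient_id": pid, "label": label}
            for var, val in rates.items():
                if var in ("age", "diameter"):
                    mean, sd = val[sel]
                    x = rng.normal(mean, sd)
                    if var == "age":
                        row[var] = float(np.clip(x, 18, 95))
                    else:
                        row[var] = float(np.clip(x, 0.7, 3.0))
                else:
                    row[var] = int(rng.random() < val[sel])
            rows.append(row)
    return pd.DataFrame(rows, columns=list(PATIENT_COLUMNS))


def generate_cohort(spec: CohortSpec,
                    rates: Dict[str, Tuple] | None = None) -> SyntheticCohort:
    """Generate the full cohort: patient table plus rendered ROI stack.

    Rendered nodule diameters are drawn uniformly from ``diameter_range_mm``
    independently of class (one diameter per patient, shared by all of the
    patient's ROIs) so that image-channel class signal is controlled solely
    by ``texture_contrast``.  The tabulated ``diameter`` variable instead
    follows its class-conditional distribution, mirroring how the reported
    clinical measurement would.
    """
    patients = generate_patient_table(spec, rates)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    lo, hi = spec.rois_per_patient
    dlo, dhi = spec.diameter_range_mm
    rois: List[RoiImage] = []
    for _, prow in patients.iterrows():
        n_rois = int(rng.integers(lo, hi + 1))
        diameter = float(rng.uniform(dlo, dhi))
        for k in range(n_rois):
            pixels = _render_roi(rng, spec, prow["label"], diameter)
            rois.append(RoiImage(
                pixels=pixels,
                pixel_size_mm=spec.pixel_size_mm,
                label=prow["label"],
                patient_id=prow["patient_id"],
                diameter_mm=diameter,
                roi_id=f"{prow['patient_id']}_R{k:03d}",
            ))
    return SyntheticCohort(rois=rois, patients=patients, spec=spec)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write ROIs as 16-bit PNG plus manifest and patient CSVs."""
    from noduletex.io import write_png16

    outdir = Path(outdir)
    (outdir / "rois").mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest()
    paths = []
    for roi in cohort.rois:
        p = outdir / "rois" / f"{roi.roi_id}.png"
        write_png16(p, roi.pixels)
        paths.append(str(p.relative_to(outdir)))
    manifest["path"] = paths
    manifest.to_csv(outdir / "manifest.csv", index=False)
    cohort.patients.to_csv(outdir / "patients.csv", index=False)
    with open(outdir / "cohort.spec", "w") as fh:
        for k, v in vars(cohort.spec).items():
            fh.write(f"{k}={v}\n")
    return outdir
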