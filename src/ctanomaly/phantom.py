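"""Synthetic abdominal CT phantoms with paired template reports.

Each exam is a 3D attenuation volume (HU) holding six ellipsoidal organs
(liver, gallbladder, pancreas, spleen, left/right kidneys) inside a
soft-tissue body cylinder on an air background, plus a matching integer
label mask. Focal spherical lesions are inserted per (organ, disease
category) by independent Bernoulli draws; hypodense categories (cyst,
fatty change, hydronephrosis) subtract the configured contrast, the rest
add it. A template report states each organ's findings with a graded
certainty phrase; a configurable organ-level noise rate corrupts report
statements (dropping true findings or adding spurious ones) to emulate
imperfect automatic label extraction. Everything is reproducible
byte-for-byte under a fixed seed.

The phantom emulates the statistical structure the pipeline assumes —
organ-localised contrast anomalies with report-derived weak labels — not
realistic anatomy.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from pydantic import BaseModel, Field, model_validator

from .report_ie import Lexicon, load_lexicon
from .schema import MASK_LABELS, ORGAN_CATEGORIES, TARGET_ORGANS

__all__ = [
    "OrganSpec",
    "PhantomConfig",
    "PhantomExam",
    "generate_exam",
    "corrupt_labels",
    "render_report",
    "generate_cohort",
    "desk_scale_config",
]

#: Categories rendered hypodense (negative contrast); the rest are hyperdense.
HYPODENSE_CATEGORIES = frozenset({"cyst", "fatty_change", "hydronephrosis"})

BODY_HU = 20.0
AIR_HU = -1000.0


class PhantomError(ValueError):
    """Invalid phantom configuration (overlapping or out-of-grid organs)."""


class TemplateError(KeyError):
    """Missing report template for a requested (organ, category, grade)."""


class OrganSpec(BaseModel):
    """One ellipsoidal organ: centre/radii in voxels, mean attenuation in HU."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    mean_hu: float

    @model_validator(mode="after")
    def _positive_radii(self):
        if min(self.radii) < 1.0:
            raise ValueError("organ radii must be >= 1 voxel")
        return self


def _default_organ_specs(grid: tuple[int, int, int]) -> dict[str, OrganSpec]:
    gx, gy, gz = grid

    def spec(cx, cy, cz, rx, ry, rz, hu):
        return OrganSpec(
            center=(cx * gx, cy * gy, cz * gz),
            radii=(max(rx * gx, 2.0), max(ry * gy, 2.0), max(rz * gz, 2.0)),
            mean_hu=hu,
        )

    return {
        "liver": spec(0.32, 0.32, 0.62, 0.21, 0.16, 0.24, 60.0),
        "gallbladder": spec(0.38, 0.62, 0.28, 0.06, 0.06, 0.09, 10.0),
        "pancreas": spec(0.55, 0.58, 0.62, 0.15, 0.05, 0.06, 40.0),
        "spleen": spec(0.78, 0.34, 0.62, 0.09, 0.08, 0.13, 50.0),
        "kidney_L": spec(0.72, 0.70, 0.28, 0.08, 0.08, 0.13, 30.0),
        "kidney_R": spec(0.25, 0.76, 0.28, 0.08, 0.08, 0.13, 30.0),
    }


def _default_prevalence(p: float = 0.15) -> dict[str, dict[str, float]]:
    return {
        organ: {cat: p for cat in ORGAN_CATEGORIES[organ]} for organ in TARGET_ORGANS
    }


class PhantomConfig(BaseModel):
    """Full description of the synthetic cohort's generating process."""

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)
    organ_specs: dict[str, OrganSpec] = Field(default_factory=dict)
    lesion_prevalence: dict[str, dict[str, float]] = Field(
        default_factory=_default_prevalence
    )
    lesion_contrast_hu: float = 40.0
    lesion_radius_vox: tuple[int, int] = (2, 5)
    noise_sigma_hu: float = 10.0
    report_noise_rate: float = 0.0
    exams_per_patient: float = 1.7
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self):
        if not self.organ_specs:
            self.organ_specs = _default_organ_specs(self.grid_shape)
        for organ, spec in self.organ_specs.items():
            for c, r, g in zip(spec.center, spec.radii, self.grid_shape):
                if c - r < 0 or c + r > g:
                    raise PhantomError(f"organ {organ} extends outside the grid")
        for table in self.lesion_prevalence.values():
            for p in table.values():
                if not 0.0 <= p <= 1.0:
                    raise PhantomError("lesion prevalence must lie in [0, 1]")
        if self.lesion_radius_vox[0] < 1:
            raise PhantomError("lesion radius must be >= 1 voxel")
        if not 0.0 <= self.report_noise_rate <= 1.0:
            raise PhantomError("report noise rate must lie in [0, 1]")
        return self

    def geometry_key(self) -> tuple:
        return (
            self.grid_shape,
            tuple(
                (o, s.center, s.radii, s.mean_hu)
                for o, s in sorted(self.organ_specs.items())
            ),
        )


def desk_scale_config(**overrides) -> PhantomConfig:
    """Small phantom (32x32x24 grid) for CPU-scale end-to-end runs."""
    defaults = dict(
        grid_shape=(32, 32, 24),
        spacing_mm=(4.0, 4.0, 6.0),
        lesion_radius_vox=(2, 3),
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@dataclass
class PhantomExam:
    exam_id: str
    patient_id: str
    volume: np.ndarray  # HU, float32
    mask: np.ndarray  # labels per schema, uint8
    truth_labels: dict[str, set[str]]
    report_text: str
    report_labels: dict[str, set[str]]


_BASE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _ellipsoid_mask(
    grid: tuple[int, int, int],
    center: Sequence[float],
    radii: Sequence[float],
) -> np.ndarray:
    coords = np.ogrid[: grid[0], : grid[1], : grid[2]]
    d2 = sum(((c - mu) / r) ** 2 for c, mu, r in zip(coords, center, radii))
    return d2 <= 1.0


def base_arrays(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free attenuation map and organ label mask (cached per geometry)."""
    key = config.geometry_key()
    if key in _BASE_CACHE:
        return _BASE_CACHE[key]
    grid = config.grid_shape
    gx, gy, _ = grid
    x, y = np.ogrid[:gx, :gy]
    body = ((x - gx / 2) / (0.46 * gx)) ** 2 + ((y - gy / 2) / (0.44 * gy)) ** 2 <= 1.0
    hu = np.where(body[:, :, None], BODY_HU, AIR_HU).astype(np.float64)
    hu = np.broadcast_to(hu, grid).copy()
    mask = np.zeros(grid, dtype=np.uint8)
    for organ, spec in config.organ_specs.items():
        ell = _ellipsoid_mask(grid, spec.center, spec.radii)
        if (mask[ell] != 0).any():
            raise PhantomError(f"organ {organ} overlaps another organ")
        mask[ell] = MASK_LABELS[organ]
        hu[ell] = spec.mean_hu
    _BASE_CACHE[key] = (hu, mask)
    return hu, mask


def _sphere_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def _insert_lesion(
    volume: np.ndarray,
    organ_mask: np.ndarray,
    contrast: float,
    radius_range: tuple[int, int],
    rng: np.random.Generator,
) -> bool:
    """Add one spherical lesion wholly inside the organ; False if none fits."""
    idx = np.argwhere(organ_mask)
    for radius in range(
        int(rng.integers(radius_range[0], radius_range[1] + 1)),
        0,
        -1,
    ):
        offsets = _sphere_offsets(radius)
        for _ in range(30):
            center = idx[rng.integers(len(idx))]
            vox = center + offsets
            if (vox < 0).any() or (vox >= np.array(volume.shape)).any():
                continue
            if organ_mask[vox[:, 0], vox[:, 1], vox[:, 2]].all():
                volume[vox[:, 0], vox[:, 1], vox[:, 2]] += contrast
                return True
    return False


def generate_exam(
    config: PhantomConfig,
    rng: np.random.Generator,
    exam_id: str = "exam_0000",
    patient_id: str = "pat_0000",
    lexicon: Lexicon | None = None,
) -> PhantomExam:
    """Draw one synthetic exam: volume, mask, truth labels and paired report."""
    base_hu, mask = base_arrays(config)
    volume = base_hu.copy()
    if config.noise_sigma_hu > 0:
        volume += rng.normal(0.0, config.noise_sigma_hu, size=volume.shape)
    truth: dict[str, set[str]] = {organ: set() for organ in TARGET_ORGANS}
    for organ in TARGET_ORGANS:
        if organ not in config.organ_specs:
            continue
        organ_mask = mask == MASK_LABELS[organ]
        prevalences = config.lesion_prevalence.get(organ, {})
        for category in ORGAN_CATEGORIES[organ]:
            p = prevalences.get(category, 0.0)
            if rng.random() >= p:
                continue
            sign = -1.0 if category in HYPODENSE_CATEGORIES else 1.0
            if _insert_lesion(
                volume,
                organ_mask,
                sign * config.lesion_contrast_hu,
                config.lesion_radius_vox,
                rng,
            ):
                truth[organ].add(category)
    text, report_labels = render_report(
        truth, config.report_noise_rate, lexicon, rng
    )
    return PhantomExam(
        exam_id=exam_id,
        patient_id=patient_id,
        volume=volume.astype(np.float32),
        mask=mask.copy(),
        truth_labels=truth,
        report_text=text,
        report_labels=report_labels,
    )


def corrupt_labels(
    truth_labels: Mapping[str, set[str]],
    noise_rate: float,
    rng: np.random.Generator,
) -> dict[str, set[str]]:
    """Corrupt each organ's statement independently with the given probability.

    Abnormal organs lose all findings (dropped / certainty flipped to
    absence); normal organs gain one spurious category. A corrupted
    statement therefore always differs from the truth, so the empirical
    corruption rate is directly the Bernoulli rate.
    """
    out: dict[str, set[str]] = {}
    for organ in truth_labels:
        cats = set(truth_labels[organ])
        if rng.random() < noise_rate:
            if cats:
                cats = set()
            else:
                pool = ORGAN_CATEGORIES[organ]
                cats = {pool[rng.integers(len(pool))]}
        out[organ] = cats
    return out


def render_report(
    truth_labels: Mapping[str, set[str]],
    report_noise_rate: float = 0.0,
    lexicon: Lexicon | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, dict[str, set[str]]]:
    """Render one template report; returns (text, labels as stated).

    Findings are stated with the grade-4 (definite presence) phrase; organs
    with nothing to report get the grade-0 "no evidence of" sentence. With a
    non-zero noise rate the stated labels are first corrupted organ-wise.
    """
    if lexicon is None:
        lexicon = load_lexicon()
    if rng is None:
        rng = np.random.default_rng(0)
    for grade in range(5):
        if grade not in lexicon.templates:
            raise TemplateError(f"no sentence template for certainty grade {grade}")
    stated = corrupt_labels(truth_labels, report_noise_rate, rng)
    sentences = []
    for organ in truth_labels:
        phrase = lexicon.organ_phrases.get(organ, organ)
        cats = sorted(stated[organ])
        if not cats:
            sentences.append(
                lexicon.templates[0].format(finding="abnormality", organ=phrase)
            )
            continue
        for category in cats:
            word = lexicon.finding_words.get(category)
            if word is None:
                raise TemplateError(f"no finding word for category {category}")
            sentences.append(lexicon.templates[4].format(finding=word, organ=phrase))
    text = " ".join(s[0].upper() + s[1:] for s in sentences)
    return text, stated


def _write_nifti(path: Path, array: np.ndarray, spacing: Sequence[float]) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(array, affine)
    # write through gzip with fixed mtime so identical arrays give identical bytes
    with gzip.GzipFile(path, "wb", mtime=0) as fh:
        fh.write(img.to_bytes())


def generate_cohort(
    config: PhantomConfig,
    n_exams: int,
    out_dir: str | Path,
    lexicon: Lexicon | None = None,
) -> dict:
    """Write a cohort to disk: NIfTI pairs, reports JSONL, label CSV, manifest.

    Exams are assigned to patients at the configured exams-per-patient ratio
    so patient-grouped splits are exercised. Each exam draws from a child
    seed spawned from the master seed; the manifest records them all.
    """
    out_dir = Path(out_dir)
    (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    if lexicon is None:
        lexicon = load_lexicon()
    n_patients = max(1, int(round(n_exams / config.exams_per_patient)))
    seeds = np.random.SeedSequence(config.seed).generate_state(max(n_exams, 1))
    rows = []
    manifest_exams = []
    with open(out_dir / "reports.jsonl", "w") as reports_fh:
        for i in range(n_exams):
            exam_id = f"exam_{i:05d}"
            patient_id = f"pat_{i % n_patients:05d}"
            child_seed = int(seeds[i] % (2**31))
            rng = np.random.default_rng(child_seed)
            exam = generate_exam(config, rng, exam_id, patient_id, lexicon)
            vol_path = out_dir / "volumes" / f"{exam_id}.nii.gz"
            mask_path = out_dir / "masks" / f"{exam_id}_mask.nii.gz"
            _write_nifti(vol_path, exam.volume, config.spacing_mm)
            _write_nifti(mask_path, exam.mask, config.spacing_mm)
            reports_fh.write(
                json.dumps(
                    {
                        "exam_id": exam_id,
                        "patient_id": patient_id,
                        "text": exam.report_text,
                    }
                )
                + "\n"
            )
            for organ in TARGET_ORGANS:
                for category in ORGAN_CATEGORIES[organ]:
                    rows.append(
                        {
                            "exam_id": exam_id,
                            "patient_id": patient_id,
                            "organ": organ,
                            "category": category,
                            "truth": int(category in exam.truth_labels[organ]),
                            "report_stated": int(
                                category in exam.report_labels[organ]
                            ),
                        }
                    )
            manifest_exams.append(
                {
                    "exam_id": exam_id,
                    "patient_id": patient_id,
                    "seed": child_seed,
                    "volume": str(vol_path.relative_to(out_dir)),
                    "mask": str(mask_path.relative_to(out_dir)),
                }
            )
    import pandas as pd

    labels = pd.DataFrame(
        rows,
        columns=["exam_id", "patient_id", "organ", "category", "truth", "report_stated"],
    )
    labels.to_csv(out_dir / "labels.csv", index=False)
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "n_exams": n_exams,
        "n_patients": min(n_patients, n_exams),
        "exams": manifest_exams,
        "labels_sha256": hashlib.sha256(
            (out_dir / "labels.csv").read_bytes()
        ).hexdigest(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
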