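"""Synthetic frontal-sinus phantom generator.

Real cone-beam CT of the head cannot be redistributed, so every stage of the
pipeline is exercised on simple volumetric phantoms: a bright spherical
"skull" shell filled with mid-intensity soft tissue, containing a dark
two-lobed air cavity that stands in for the frontal sinus.  The cavity's
volume (and with it its axis lengths) is drawn from a class-conditional
distribution — the male-class mean is ``dimorphism_factor`` times the
female-class mean — mirroring the sexual dimorphism in sinus volume and
major/minor axis length seen in real cohorts.  Optional distractor blobs
below the cavity imitate ethmoid air cells (a known source of segmentation
false positives), and optional blurring imitates mucosal thickening.

Intensities are a normalized [0, 1] surrogate (cone-beam CT is not
calibrated to Hounsfield units): air is dark, bone bright, soft tissue
intermediate.  All randomness flows from explicit integer seeds, and
identical (spec, sex, seed) triples give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask, Volume
from .io import save_mask, save_volume

AIR = 0.05
SOFT_TISSUE = 0.55
BONE = 0.95


@dataclass
class PhantomSpec:
    """Generative parameters for one phantom family.

    Sizes are in voxels; ``voxel_spacing`` in mm; ``dimorphism_factor`` is
    the ratio of male to female mean cavity volume (1.0 = no dimorphism).
    ``axis_ratio_range`` bounds the two minor/major semi-axis ratios sampled
    independently per lobe.
    """

    grid_size: int = 64
    voxel_spacing: float = 0.3
    shell_radius: float = 28.0
    shell_thickness: float = 3.0
    cavity_base_volume: float = 2200.0
    dimorphism_factor: float = 1.5
    axis_ratio_range: tuple[float, float] = (0.55, 0.85)
    lobe_separation: float = 11.0
    confounder_count: int = 3
    confounder_volume: float = 120.0
    blur_sigma: float = 0.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16 per axis")
        if self.dimorphism_factor <= 0:
            raise ValueError("dimorphism_factor must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.axis_ratio_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("axis_ratio_range must satisfy 0 < lo <= hi <= 1")
        if self.shell_radius + 1 > self.grid_size / 2:
            raise ValueError("shell does not fit inside the grid")

    @classmethod
    def tiny(cls, **overrides) -> "PhantomSpec":
        """Desk-scale 32-cubed profile used throughout the test suite."""
        kw = dict(
            grid_size=32,
            shell_radius=14.0,
            shell_thickness=2.0,
            cavity_base_volume=240.0,
            lobe_separation=6.0,
            confounder_count=2,
            confounder_volume=30.0,
        )
        kw.update(overrides)
        return cls(**kw)

    @property
    def interior_radius(self) -> float:
        return self.shell_radius - self.shell_thickness


@dataclass
class SampledCavity:
    """The per-subject latent geometry actually drawn from the spec."""

    lobe_centers: list[np.ndarray]
    lobe_semiaxes: list[np.ndarray]  # (axial, row, col) semi-axes per lobe
    target_volume: float

    @property
    def major_axis(self) -> float:
        return 2.0 * max(float(s.max()) for s in self.lobe_semiaxes)

    @property
    def minor_axis(self) -> float:
        return 2.0 * min(float(s.min()) for s in self.lobe_semiaxes)


def _sample_cavity(spec: PhantomSpec, sex: int,
                   rng: np.random.Generator) -> SampledCavity:
    mean_v = spec.cavity_base_volume * (spec.dimorphism_factor if sex == 1 else 1.0)
    # volume draw truncated at +/- 2 sigma: keeps the class mean (symmetric)
    # while bounding the worst-case lobe reach against the shell
    sd = 0.12 * mean_v
    v = float(np.clip(rng.normal(mean_v, sd), mean_v - 2 * sd, mean_v + 2 * sd))
    frac = rng.uniform(0.42, 0.58)
    lobe_volumes = [v * frac, v * (1.0 - frac)]

    c = spec.grid_size / 2.0 - 0.5
    # cavity sits superior (low axial index) of center, lobes split left/right
    axial_off = -spec.grid_size / 10.0
    centers, semiaxes = [], []
    for k, lv in enumerate(lobe_volumes):
        side = -1.0 if k == 0 else 1.0
        center = np.array([c + axial_off, c, c + side * spec.lobe_separation / 2.0])
        center += rng.uniform(-0.75, 0.75, size=3)
        r1 = rng.uniform(*spec.axis_ratio_range)  # row / col ratio
        r2 = rng.uniform(*spec.axis_ratio_range)  # axial / col ratio
        a = (3.0 * lv / (4.0 * np.pi * r1 * r2)) ** (1.0 / 3.0)  # major semi-axis
        semi = np.array([a * r2, a * r1, a])  # (axial, row, col)
        centers.append(center)
        semiaxes.append(semi)
    return SampledCavity(centers, semiaxes, v)


def _check_inside_shell(spec: PhantomSpec, cavity: SampledCavity) -> None:
    c = spec.grid_size / 2.0 - 0.5
    shell_center = np.array([c, c, c])
    for center, semi in zip(cavity.lobe_centers, cavity.lobe_semiaxes):
        reach = float(np.linalg.norm(center - shell_center)) + float(semi.max())
        if reach >= spec.interior_radius:
            raise ValueError(
                "cavity lobe does not fit inside the shell interior: "
                f"lobe reach {reach:.1f} vx >= interior radius "
                f"{spec.interior_radius:.1f} vx (cavity_base_volume="
                f"{spec.cavity_base_volume}, dimorphism_factor="
                f"{spec.dimorphism_factor}, shell_radius={spec.shell_radius}, "
                f"shell_thickness={spec.shell_thickness}, "
                f"lobe_separation={spec.lobe_separation})"
            )


def _ellipsoid_mask(grid: tuple[np.ndarray, ...], center: np.ndarray,
                    semi: np.ndarray) -> np.ndarray:
    q = sum(((g - mu) / s) ** 2 for g, mu, s in zip(grid, center, semi))
    return q <= 1.0


def generate_phantom(spec: PhantomSpec, sex: int,
                     instance_seed: int) -> tuple[Volume, BinaryMask]:
    """Draw one phantom of the given sex (0 = female, 1 = male).

    Returns the intensity volume and the ground-truth sinus mask (the union
    of the two sampled ellipsoidal lobes; distractor blobs are visible in
    the image but never in the mask).
    """
    if sex not in (0, 1):
        raise ValueError("sex must be 0 (female) or 1 (male)")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, sex, instance_seed]))
    cavity = _sample_cavity(spec, sex, rng)
    _check_inside_shell(spec, cavity)

    n = spec.grid_size
    grid = np.meshgrid(*(np.arange(n, dtype=np.float64),) * 3, indexing="ij")
    c = n / 2.0 - 0.5
    r = np.sqrt(sum((g - c) ** 2 for g in grid))

    img = np.full((n, n, n), AIR, dtype=np.float64)
    img[r <= spec.shell_radius] = BONE
    img[r <= spec.interior_radius] = SOFT_TISSUE

    mask = np.zeros((n, n, n), dtype=bool)
    for center, semi in zip(cavity.lobe_centers, cavity.lobe_semiaxes):
        mask |= _ellipsoid_mask(grid, center, semi)
    img[mask] = AIR

    # ethmoid-like distractors: air pockets inferior-adjacent to the cavity
    if spec.confounder_count > 0:
        rconf = (3.0 * spec.confounder_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
        cav_bottom = max(
            ctr[0] + semi[0] for ctr, semi in
            zip(cavity.lobe_centers, cavity.lobe_semiaxes)
        )
        for _ in range(spec.confounder_count):
            center = np.array([
                cav_bottom + rconf + 1.0 + rng.uniform(0.0, 2.0),
                c + rng.uniform(-3.0, 3.0),
                c + rng.uniform(-spec.lobe_separation, spec.lobe_separation),
            ])
            shell_c = np.array([c, c, c])
            if np.linalg.norm(center - shell_c) + rconf >= spec.interior_radius:
                continue  # skip distractors that would breach the shell
            blob = _ellipsoid_mask(grid, center, np.full(3, rconf))
            img[blob & ~mask] = AIR

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    sp = (spec.voxel_spacing,) * 3
    vol = Volume(img.astype(np.float32), sp)
    bmask = BinaryMask(mask.astype(np.uint8), sp)
    vol.cavity = cavity  # latent geometry, recorded in cohort manifests
    return vol, bmask


def stratified_split(sexes: list[int], ratios: tuple[float, float, float]
                     ) -> list[str]:
    """Assign train/val/test labels with equal sex composition per split.

    Within each sex, subjects are allocated in index order; rounding favors
    train, then val.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    out = [""] * len(sexes)
    for sex in (0, 1):
        idx = [i for i, s in enumerate(sexes) if s == sex]
        n = len(idx)
        n_train = int(round(ratios[0] * n))
        n_val = int(round(ratios[1] * n))
        n_val = min(n_val, n - n_train)
        for j, i in enumerate(idx):
            out[i] = "train" if j < n_train else ("val" if j < n_train + n_val
                                                  else "test")
    return out


def generate_cohort(spec: PhantomSpec, n_male: int, n_female: int,
                    out_dir: str | Path,
                    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                    ) -> pd.DataFrame:
    """Generate a labeled cohort on disk and return its manifest.

    Writes one NIfTI volume and mask per subject plus ``manifest.csv`` with
    columns (subject_id, sex, volume_path, mask_path, cavity_voxels,
    major_axis, minor_axis, split).  Per-subject randomness derives from the
    spec seed and the subject index, so reruns are bit-identical.
    """
    if n_male < 1 or n_female < 1:
        raise ValueError("need at least one subject of each sex")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sexes = [1] * n_male + [0] * n_female
    splits = stratified_split(sexes, split_ratios)
    rows = []
    for i, (sex, split) in enumerate(zip(sexes, splits)):
        vol, mask = generate_phantom(spec, sex, instance_seed=i)
        sid = f"S{i:04d}"
        vpath = out_dir / f"{sid}_vol.nii.gz"
        mpath = out_dir / f"{sid}_mask.nii.gz"
        save_volume(vol, vpath)
        save_mask(mask, mpath)
        rows.append({
            "subject_id": sid,
            "sex": sex,
            "volume_path": str(vpath),
            "mask_path": str(mpath),
            "cavity_voxels": mask.volume_voxels(),
            "major_axis": vol.cavity.major_axis,
            "minor_axis": vol.cavity.minor_axis,
            "split": split,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
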