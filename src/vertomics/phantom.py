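"""Synthetic thoracolumbar vertebral-body phantoms.

Generates CT-like volumes of a single vertebral body (elliptic cylinder with a
bright cortical shell and textured trabecular interior) in three fracture
classes:

* ``benign_chronic`` — healed compression: height loss only;
* ``benign_acute``   — recent osteoporotic/traumatic compression: height loss
  plus a dense sclerotic band under the superior endplate (impacted bone);
* ``malignant``      — tumour infiltration: a low-attenuation lytic sphere
  breaching the cortical shell.

Each case carries a ground-truth mask plus observer re-segmentations produced
by displacing the mask boundary with a smooth random field, emulating the
inter-reader variability that the concordance-based stability filter is
designed to absorb.  Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .utils import derive_seed
from .volume import MaskVolume, VolumeGrid, write_mask, write_volume

LABELS = ("benign_acute", "benign_chronic", "malignant")


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters of one vertebral-body phantom.

    Distances in mm, intensities in HU.  ``body_semi_axes_mm`` is
    (anterior-posterior semi-axis is the second entry): (a_x, a_y, height).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    voxel_spacing_mm: tuple[float, float, float] = (0.5, 0.5, 1.0)
    body_semi_axes_mm: tuple[float, float, float] = (16.0, 12.0, 26.0)
    cortical_thickness_mm: float = 1.5
    trabecular_mean_hu: float = 150.0
    trabecular_sd_hu: float = 30.0
    cortical_mean_hu: float = 800.0
    background_hu: float = -50.0
    fracture_compression_frac: float = 0.25
    lesion_radius_mm: float = 6.0
    lesion_mean_hu: float = -20.0
    sclerosis_band_hu: float = 250.0
    noise_sd_hu: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if not (0.0 <= self.fracture_compression_frac < 1.0):
            raise ValueError("compression fraction must lie in [0, 1)")
        if any(a <= 0 for a in self.body_semi_axes_mm):
            raise ValueError("body semi-axes must be positive")
        if self.cortical_thickness_mm <= 0 or self.lesion_radius_mm <= 0:
            raise ValueError("thickness and lesion radius must be positive")


@dataclass(frozen=True)
class PhantomCase:
    volume: VolumeGrid
    truth_mask: MaskVolume
    observer_masks: tuple
    label: str
    patient_id: str
    vertebra_id: str


def _mm_grids(params: PhantomParams):
    """Voxel-centre coordinates in mm, centred on the grid midpoint."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(params.grid_shape, params.voxel_spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _correlated_field(shape, spacing, sigma_mm, rng):
    """Zero-mean unit-SD smooth Gaussian random field."""
    white = rng.standard_normal(shape)
    sig_vox = [sigma_mm / s for s in spacing]
    f = ndimage.gaussian_filter(white, sig_vox)
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def make_vertebra_phantom(params: PhantomParams, label: str) -> PhantomCase:
    """Build one phantom case of the requested fracture class."""
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    ax, ay, height = params.body_semi_axes_mm
    if label == "malignant" and params.lesion_radius_mm >= min(ax, ay, height / 2.0):
        raise ValueError("lesion exceeds body")

    x, y, z = _mm_grids(params)
    rng = np.random.default_rng(params.seed)

    # compressed, anteriorly wedged body: height loss strongest at the
    # anterior margin (negative y), milder posteriorly
    frac = params.fracture_compression_frac
    wedge = frac * (0.75 + 0.25 * np.clip(-y / ay, -1.0, 1.0))
    half_h = (height / 2.0) * (1.0 - wedge)
    in_ellipse = (x / ax) ** 2 + (y / ay) ** 2 <= 1.0
    body = in_ellipse & (np.abs(z) <= half_h)
    if not body.any():
        raise ValueError("degenerate phantom: empty body")

    spacing = params.voxel_spacing_mm
    depth_mm = ndimage.distance_transform_edt(body, sampling=spacing)
    shell = body & (depth_mm <= params.cortical_thickness_mm)
    interior = body & ~shell

    vol = np.full(params.grid_shape, params.background_hu, dtype=float)
    vol[interior] = params.trabecular_mean_hu
    if params.trabecular_sd_hu > 0:
        texture = _correlated_field(params.grid_shape, spacing, 1.2, rng)
        vol[interior] += params.trabecular_sd_hu * texture[interior]
    vol[shell] = params.cortical_mean_hu

    if label == "benign_acute" and params.sclerosis_band_hu != 0:
        # impacted-bone band just below the (compressed) superior endplate
        band = interior & (z >= half_h - 6.0) & (z <= half_h)
        vol[band] += params.sclerosis_band_hu
    elif label == "malignant":
        # lytic sphere centred on the anterior cortex so it breaches the shell
        r = params.lesion_radius_mm
        cy = -(ay - 0.5 * r)
        lesion = x**2 + (y - cy) ** 2 + z**2 <= r**2
        destroyed = lesion & body
        vol[destroyed] = params.lesion_mean_hu

    if params.noise_sd_hu > 0:
        vol += params.noise_sd_hu * rng.standard_normal(params.grid_shape)

    volume = VolumeGrid(vol, spacing)
    truth = MaskVolume(body, spacing)
    return PhantomCase(volume, truth, (), label, "P0", "V0")


def simulate_observer_mask(mask: MaskVolume, displacement_mm: float, seed: int) -> MaskVolume:
    """Perturb a mask boundary by a smooth random field of bounded amplitude.

    The field is applied as a level-set offset of the signed Euclidean
    distance function; since the distance function has unit gradient, the
    boundary moves along its normal by at most ``displacement_mm``.  The
    largest connected component is kept and holes filled, preserving the
    single-body topology.
    """
    if mask.count() == 0:
        raise ValueError("cannot perturb an empty mask")
    if displacement_mm < 0:
        raise ValueError("displacement must be nonnegative")
    if displacement_mm == 0:
        return MaskVolume(mask.labels.copy(), mask.spacing_mm, mask.origin_mm)
    spacing = mask.spacing_mm
    inside = ndimage.distance_transform_edt(mask.labels, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask.labels, sampling=spacing)
    signed = outside - inside  # negative inside the mask
    rng = np.random.default_rng(seed)
    # unit-SD smooth field, scaled so ~1.5 sigma reaches the bound, then
    # clipped: |f| <= displacement_mm everywhere, hence the displacement bound
    f = _correlated_field(mask.shape, spacing, 4.0, rng)
    f = np.clip(f * (displacement_mm / 1.5), -displacement_mm, displacement_mm)
    new = signed <= f
    # keep the largest component, fill internal holes
    lab, n = ndimage.label(new)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        new = lab == (1 + int(np.argmax(sizes)))
    new = ndimage.binary_fill_holes(new)
    return MaskVolume(new, spacing, mask.origin_mm)


def _jittered(base: PhantomParams, rng: np.random.Generator, case_seed: int) -> PhantomParams:
    """Per-case biological variation around the cohort base parameters.

    Lesion density, sclerosis degree and trabecular density vary widely in
    practice (osteoporosis, healing stage, tumour type), which keeps cohort
    discrimination realistic rather than saturated.
    """
    ax, ay, h = base.body_semi_axes_mm
    scale = rng.uniform(0.9, 1.1, size=3)
    return replace(
        base,
        body_semi_axes_mm=(ax * scale[0], ay * scale[1], h * scale[2]),
        trabecular_mean_hu=base.trabecular_mean_hu + rng.normal(0, 35),
        fracture_compression_frac=float(rng.uniform(0.10, 0.35)),
        lesion_radius_mm=base.lesion_radius_mm * float(rng.uniform(0.5, 1.15)),
        lesion_mean_hu=base.lesion_mean_hu + rng.normal(0, 60),
        sclerosis_band_hu=base.sclerosis_band_hu * float(rng.uniform(0.0, 1.0)),
        seed=case_seed,
    )


def make_cohort(
    n_benign: int,
    n_malignant: int,
    base_params: PhantomParams = PhantomParams(),
    seed: int = 0,
    n_observers: int = 3,
    observer_displacement_mm: float = 0.5,
    benign_chronic_frac: float = 0.0,
    min_observer_dsc: float = 0.8,
) -> list[PhantomCase]:
    """Generate a labelled cohort of phantom cases with observer masks.

    Patients own one to three vertebrae (all of the same class) so that
    per-patient random selection is exercised downstream.  Benign cases are
    acute by default; ``benign_chronic_frac`` mixes in healed fractures.
    """
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("cohort counts must be nonnegative")
    rng = np.random.default_rng(derive_seed(seed, "cohort"))
    todo: list[str] = []
    for i in range(n_benign):
        chronic = rng.random() < benign_chronic_frac
        todo.append("benign_chronic" if chronic else "benign_acute")
    todo += ["malignant"] * n_malignant

    cases: list[PhantomCase] = []
    patient = 0
    idx = 0
    while idx < len(todo):
        patient += 1
        k = int(rng.integers(1, 4))  # 1-3 vertebrae per patient
        k = min(k, len(todo) - idx)
        pid = f"P{patient:04d}"
        for v in range(k):
            label = todo[idx]
            case_seed = derive_seed(seed, "case", idx)
            params = _jittered(base_params, rng, case_seed)
            case = make_vertebra_phantom(params, label)
            observers = []
            for o in range(n_observers):
                om = simulate_observer_mask(
                    case.truth_mask,
                    observer_displacement_mm,
                    derive_seed(seed, "observer", idx, o),
                )
                observers.append(om)
            case = PhantomCase(
                case.volume,
                case.truth_mask,
                tuple(observers),
                label,
                pid,
                f"V{v + 1}",
            )
            cases.append(case)
            idx += 1
    return cases


def select_one_vertebra_per_patient(cases, seed: int) -> list[PhantomCase]:
    """Pick exactly one vertebra per patient, uniformly at random.

    Output is ordered by patient id, so the result is deterministic in
    (cases, seed).
    """
    by_patient: dict[str, list[PhantomCase]] = {}
    for c in cases:
        by_patient.setdefault(c.patient_id, []).append(c)
    out = []
    for pid in sorted(by_patient):
        group = by_patient[pid]
        rng = np.random.default_rng(derive_seed(seed, "select", pid))
        out.append(group[int(rng.integers(len(group)))])
    return out


def write_cohort(cases, outdir) -> Path:
    """Write volumes/masks as NIfTI plus a CSV manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "vertebra_id", "label", "volume", "truth_mask", "observer_masks"])
        for c in cases:
            stem = f"{c.patient_id}_{c.vertebra_id}"
            vpath = outdir / f"{stem}_ct.nii.gz"
            mpath = outdir / f"{stem}_mask.nii.gz"
            write_volume(c.volume, vpath)
            write_mask(c.truth_mask, mpath)
            opaths = []
            for i, om in enumerate(c.observer_masks):
                op = outdir / f"{stem}_obs{i + 1}.nii.gz"
                write_mask(om, op)
                opaths.append(op.name)
            writer.writerow([c.patient_id, c.vertebra_id, c.label, vpath.name, mpath.name, ";".join(opaths)])
    return manifest
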