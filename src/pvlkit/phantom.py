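"""Synthetic aortic-root CT phantoms and clinical cohorts.

The phantom is a bent tube with three longitudinal segments (outflow-tract /
sinus bulge / ascending segment) of elliptical cross-section, rendered into a
contrast-CT-like intensity grid with co-registered binary masks for the root
and for calcification deposits seeded on the annular ring. The clinical table
mimics the marginal distributions of a TAVI cohort, and the binary outcome
follows a logistic model on a small set of standardized latent drivers so
that downstream learning and evaluation have a known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PhantomParams", "VolumeSample", "CohortSpec",
    "generate_phantom", "compute_calcification_volume", "generate_cohort",
    "save_sample", "load_sample", "CLINICAL_COLUMNS", "OUTCOME_COLUMN",
    "DEFAULT_DRIVERS", "InfeasibleCalcVolume",
]

OUTCOME_COLUMN = "pvl_ge_moderate"

#: Continuous covariates: (name, generating median-ish location, scale, kind)
_CONTINUOUS_SPECS = [
    ("age_yr", 72.0, 7.0, "normal"),
    ("bmi_kg_m2", 22.6, 3.3, "normal"),
    ("sts_score_pct", 2.75, 0.55, "lognormal"),
    ("lvef_pct", 57.0, 12.0, "normal"),
    ("lvedd_mm", 50.0, 8.0, "normal"),
    ("ivs_mm", 14.0, 2.0, "normal"),
    ("mean_av_gradient_mmhg", 59.0, 20.0, "normal"),
    ("peak_av_velocity_m_s", 4.9, 0.9, "normal"),
    ("annular_angle_deg", 53.9, 8.5, "normal"),
    ("annular_perimeter_mm", 78.6, 9.5, "normal"),
    ("sov_perimeter_mm", 108.5, 13.0, "normal"),
    ("stj_diameter_mm", 30.8, 4.0, "normal"),
    ("lvot_perimeter_mm", 83.6, 13.0, "normal"),
    ("lca_ostium_height_mm", 14.1, 3.0, "normal"),
    ("rca_ostium_height_mm", 15.0, 3.3, "normal"),
    ("max_ascending_ao_mm", 42.0, 5.0, "normal"),
    ("calc_volume_mm3", 578.0, 0.85, "lognormal"),
    ("post_dilatation_balloon_mm", 21.0, 1.8, "normal"),
]

#: Binary covariates: (name, prevalence)
_BINARY_SPECS = [
    ("sex_male", 0.567),
    ("hypertension", 0.306),
    ("diabetes", 0.179),
    ("copd", 0.154),
    ("cad", 0.236),
    ("ckd", 0.052),
    ("af", 0.087),
    ("pvd", 0.184),
    ("prior_stroke", 0.107),
    ("ar_ge_moderate", 0.129),
    ("new_generation_thv", 0.386),
    ("thv_lt_26mm", 0.338),
    ("transfemoral", 0.990),
    ("pre_dilatation", 0.948),
]

CLINICAL_COLUMNS = ([n for n, *_ in _CONTINUOUS_SPECS]
                    + [n for n, _ in _BINARY_SPECS])

#: Default outcome drivers and their log-odds per standardized unit.
#: Calcification burden, annular size, sinotubular dilation, age and sex.
DEFAULT_DRIVERS = {
    "calc_volume_mm3": 1.1,
    "annular_perimeter_mm": 0.9,
    "stj_diameter_mm": 0.9,
    "age_yr": 0.45,
    "sex_male": 0.5,
}


class InfeasibleCalcVolume(ValueError):
    """Requested calcification volume exceeds the annular-region capacity."""


@dataclasses.dataclass(frozen=True)
class PhantomParams:
    """Geometry, intensity palette, and calcification target for one phantom."""

    grid_shape: tuple[int, int, int] = (96, 96, 56)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    root_radius: float = 12.5           # mm, nominal lumen radius
    root_length: float = 90.0           # mm along z
    wall_thickness: float = 2.5         # mm
    background_hu: float = 40.0
    lumen_hu: float = 300.0
    wall_hu: float = 80.0
    calc_hu: float = 800.0
    target_calc_volume: float = 600.0   # mm^3
    n_calc_blobs: int = 4
    noise_sd: float = 20.0
    bend_mm: float = 6.0
    ellipticity: float = 1.1
    seed: int = 0

    @classmethod
    def desk_scale(cls, **overrides) -> "PhantomParams":
        """Reduced grid matched to the desk-scale preprocessing shape, so the
        chain introduces no extra resampling distortion at small n."""
        defaults = dict(grid_shape=(64, 48, 32), root_radius=11.0,
                        root_length=58.0, bend_mm=4.0)
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def max_root_radius(self) -> float:
        """Largest nominal radius the grid can contain (sinus bulge included)."""
        extent = min(self.grid_shape[0] * self.spacing[0],
                     self.grid_shape[1] * self.spacing[1])
        return ((extent / 2 - abs(self.bend_mm)) / self.ellipticity
                - self.wall_thickness) / 1.22

    def __post_init__(self):
        if self.target_calc_volume < 0:
            raise ValueError("target_calc_volume must be >= 0")
        if not (self.background_hu < self.lumen_hu < self.calc_hu):
            raise ValueError("HU palette must satisfy background < lumen < calc")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")


@dataclasses.dataclass
class VolumeSample:
    """Co-registered CT + root mask + calcification mask for one patient."""

    patient_id: str
    ct: np.ndarray
    root_mask: np.ndarray
    calc_mask: np.ndarray
    spacing: tuple[float, float, float]

    def validate(self) -> None:
        if not (self.ct.shape == self.root_mask.shape == self.calc_mask.shape):
            raise ValueError(f"{self.patient_id}: grids are not co-registered")
        for name, m in (("root_mask", self.root_mask),
                        ("calc_mask", self.calc_mask)):
            vals = np.unique(m)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError(f"{self.patient_id}: {name} is not binary")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"{self.patient_id}: non-positive spacing")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Size, prevalence, and outcome-generating coefficients for a cohort."""

    n_total: int = 210
    event_rate: float = 35.0 / 210.0
    drivers: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_DRIVERS))
    intercept: float | None = None      # None -> solved to hit event_rate
    exact_event_count: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.event_rate <= 1.0:
            raise ValueError("event_rate must be in [0, 1]")
        if self.n_total < 10:
            raise ValueError("n_total must be >= 10")


# --------------------------------------------------------------------- phantom

def _radius_profile(zf: np.ndarray, r0: float) -> np.ndarray:
    """Lumen radius vs. normalized axial position (0 = LVOT, 1 = ascending)."""
    r = np.full_like(zf, r0)
    lvot = zf < 0.22
    r[lvot] = r0 * 0.88
    sinus = (zf >= 0.22) & (zf < 0.55)
    # smooth bulge peaking mid-sinus
    t = (zf[sinus] - 0.22) / 0.33
    r[sinus] = r0 * (0.88 + 0.34 * np.sin(np.pi * t))
    asc = zf >= 0.55
    r[asc] = r0 * 1.02
    return r


ANNULUS_ZFRAC = 0.22  # axial position of the annular ring (LVOT/sinus junction)


def generate_phantom(params: PhantomParams) -> VolumeSample:
    """Render one phantom deterministically from its parameters.

    Raises
    ------
    InfeasibleCalcVolume
        If the requested calcification volume exceeds what fits in the
        annular neighborhood band; the message reports the capacity in mm^3.
    ValueError
        If the grid cannot contain the root at the given spacing.
    """
    rng = np.random.default_rng(params.seed)
    nx, ny, nz = params.grid_shape
    sx, sy, sz = params.spacing

    # physical coordinates of voxel centers
    x = (np.arange(nx) - nx / 2) * sx
    y = (np.arange(ny) - ny / 2) * sy
    z = np.arange(nz) * sz
    zf = np.clip(z / params.root_length, 0, 1)

    r_prof = _radius_profile(zf, params.root_radius)
    r_outer_max = (r_prof.max() + params.wall_thickness) * params.ellipticity
    if (r_outer_max + abs(params.bend_mm)) * 2 > min(nx * sx, ny * sy):
        raise ValueError("grid too small to contain the root at this spacing")

    # bent centerline: quadratic offset in x
    cx = params.bend_mm * zf ** 2
    cy = np.zeros_like(cx)

    X = x[:, None, None]
    Y = y[None, :, None]
    dx = (X - cx[None, None, :]) / params.ellipticity
    dy = Y - cy[None, None, :]
    dist = np.sqrt(dx * dx + dy * dy)

    in_length = z <= params.root_length
    lumen = (dist <= r_prof[None, None, :]) & in_length[None, None, :]
    root = (dist <= (r_prof + params.wall_thickness)[None, None, :]) \
        & in_length[None, None, :]
    wall = root & ~lumen

    ct = np.full(params.grid_shape, params.background_hu, dtype=np.float32)
    ct[wall] = params.wall_hu
    ct[lumen] = params.lumen_hu

    calc = np.zeros(params.grid_shape, dtype=np.uint8)
    if params.target_calc_volume > 0:
        calc = _place_calcification(params, rng, dist, r_prof, z)
        ct[calc > 0] = params.calc_hu

    if params.noise_sd > 0:
        ct += rng.normal(0.0, params.noise_sd,
                         size=params.grid_shape).astype(np.float32)

    sample = VolumeSample(
        patient_id=f"phantom-{params.seed:05d}",
        ct=ct,
        root_mask=root.astype(np.uint8),
        calc_mask=calc,
        spacing=params.spacing,
    )
    sample.validate()
    return sample


def _place_calcification(params: PhantomParams, rng: np.random.Generator,
                         dist: np.ndarray, r_prof: np.ndarray,
                         z: np.ndarray) -> np.ndarray:
    """Seed ellipsoidal blobs on the annular ring and bisect a global scale
    factor so the realized voxel count matches the target volume."""
    sx, sy, sz = params.spacing
    voxvol = sx * sy * sz
    n_target = params.target_calc_volume / voxvol

    z_ann = ANNULUS_ZFRAC * params.root_length
    k_ann = int(np.argmin(np.abs(z - z_ann)))
    r_ann = r_prof[k_ann] + params.wall_thickness * 0.5

    # capacity: voxels within 4 mm of the root surface in the annular band
    band = (np.abs(z - z_ann) <= 12.0)[None, None, :]
    near_wall = np.abs(dist - (r_prof + params.wall_thickness * 0.5)
                       [None, None, :]) <= 4.0
    capacity = int(np.count_nonzero(band & near_wall))
    if n_target > capacity:
        raise InfeasibleCalcVolume(
            f"target calcification volume {params.target_calc_volume:.1f} mm^3 "
            f"exceeds annular-region capacity {capacity * voxvol:.1f} mm^3")

    nx, ny, nz = params.grid_shape
    xs = (np.arange(nx) - nx / 2) * sx
    ys = (np.arange(ny) - ny / 2) * sy

    centers, axes = [], []
    for _ in range(max(1, params.n_calc_blobs)):
        theta = rng.uniform(0, 2 * np.pi)
        cx0 = params.bend_mm * ANNULUS_ZFRAC ** 2
        c = (cx0 + r_ann * params.ellipticity * np.cos(theta),
             r_ann * np.sin(theta),
             z_ann + rng.uniform(-4.0, 4.0))
        a = rng.uniform(0.6, 1.4, size=3)  # relative semi-axes
        centers.append(c)
        axes.append(a)

    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = z[None, None, :]

    def realized(scale: float) -> np.ndarray:
        mask = np.zeros(params.grid_shape, dtype=bool)
        for c, a in zip(centers, axes):
            sa = scale * a
            q = (((X - c[0]) / sa[0]) ** 2 + ((Y - c[1]) / sa[1]) ** 2
                 + ((Z - c[2]) / sa[2]) ** 2)
            mask |= q <= 1.0
        # keep deposits in the root neighborhood (wall +/- 4 mm)
        mask &= near_wall
        return mask

    lo, hi = 0.1, 30.0
    best = realized(hi)
    if best.sum() < n_target * 0.9:
        raise InfeasibleCalcVolume(
            f"target calcification volume {params.target_calc_volume:.1f} mm^3 "
            f"exceeds blob capacity {best.sum() * voxvol:.1f} mm^3 "
            f"for {params.n_calc_blobs} blobs")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        m = realized(mid)
        cnt = m.sum()
        if abs(cnt - n_target) <= max(1.0, 0.05 * n_target):
            return m.astype(np.uint8)
        if cnt < n_target:
            lo = mid
        else:
            hi = mid
    return realized(hi).astype(np.uint8)


def compute_calcification_volume(mask: np.ndarray,
                                 spacing: tuple[float, float, float]) -> float:
    """Total physical volume (mm^3) of a binary calcification mask."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, [0, 1])):
        raise ValueError("mask must be binary {0,1}")
    return float(np.count_nonzero(mask) * float(np.prod(spacing)))


# ---------------------------------------------------------------------- cohort

def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name, loc, scale, kind in _CONTINUOUS_SPECS:
        if kind == "lognormal":
            cols[name] = np.exp(rng.normal(np.log(loc), scale, size=n))
        else:
            cols[name] = rng.normal(loc, scale, size=n)
    for name, prev in _BINARY_SPECS:
        cols[name] = (rng.uniform(size=n) < prev).astype(int)
    df = pd.DataFrame(cols)
    # loose anatomical coherence between root levels
    df["annular_area_mm2"] = df["annular_perimeter_mm"] ** 2 / (4 * np.pi) \
        * rng.normal(0.97, 0.03, size=n)
    df["sov_perimeter_mm"] = df["annular_perimeter_mm"] * 1.38 \
        + rng.normal(0, 5.0, size=n)
    df["lvot_perimeter_mm"] = df["annular_perimeter_mm"] * 1.06 \
        + rng.normal(0, 6.0, size=n)
    df["lvef_pct"] = df["lvef_pct"].clip(15, 80)
    df["bmi_kg_m2"] = df["bmi_kg_m2"].clip(14, 45)
    return df


def _solve_intercept(eta: np.ndarray, target_rate: float) -> float:
    """Bisect the intercept so the mean predicted probability hits the rate."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        rate = float(np.mean(1.0 / (1.0 + np.exp(-(eta + mid)))))
        if rate < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(spec: CohortSpec,
                    phantom_defaults: PhantomParams | None = None,
                    with_volumes: bool = True,
                    ) -> tuple[list[VolumeSample], pd.DataFrame]:
    """Generate a full synthetic cohort: clinical table and (optionally) one
    phantom per patient whose calcification volume matches the table entry.

    The outcome is Bernoulli under a logistic model on population-standardized
    driver covariates (log scale for calcification volume); the intercept is
    solved numerically so the expected event rate equals ``spec.event_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    df = _draw_covariates(spec.n_total, rng)
    df.insert(0, "patient_id",
              [f"P{spec.seed:04d}-{i:04d}" for i in range(spec.n_total)])

    eta = np.zeros(spec.n_total)
    for name, beta in spec.drivers.items():
        v = df[name].to_numpy(dtype=float)
        if name == "calc_volume_mm3":
            v = np.log1p(v)
        sd = v.std()
        zv = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        eta += beta * zv

    if spec.intercept is None:
        b0 = _solve_intercept(eta, spec.event_rate)
    else:
        b0 = spec.intercept
    p = 1.0 / (1.0 + np.exp(-(eta + b0)))

    expected_events = spec.n_total * spec.event_rate
    if 0 < expected_events < 1:
        warnings.warn(
            f"event_rate {spec.event_rate:.4f} yields <1 expected event at "
            f"n={spec.n_total}; downstream cross-validation may fail",
            stacklevel=2)

    if spec.exact_event_count:
        k = int(round(spec.n_total * spec.event_rate))
        y = np.zeros(spec.n_total, dtype=int)
        if k > 0:
            # weighted sampling without replacement by model probability
            keys = rng.gumbel(size=spec.n_total) + np.log(p + 1e-12) \
                - np.log1p(-p + 1e-12)
            y[np.argsort(keys)[-k:]] = 1
    else:
        y = (rng.uniform(size=spec.n_total) < p).astype(int)
    df[OUTCOME_COLUMN] = y

    samples: list[VolumeSample] = []
    if with_volumes:
        base = phantom_defaults or PhantomParams()
        r_hi = min(16.0, 0.98 * base.max_root_radius)
        for i, row in df.iterrows():
            radius = float(np.clip(row["annular_perimeter_mm"] / (2 * np.pi),
                                   min(9.0, r_hi), r_hi))
            params = dataclasses.replace(
                base,
                root_radius=radius,
                target_calc_volume=float(min(row["calc_volume_mm3"], 4000.0)),
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            s = generate_phantom(params)
            s.patient_id = row["patient_id"]
            # keep the table consistent with the rendered phantom
            df.loc[i, "calc_volume_mm3"] = compute_calcification_volume(
                s.calc_mask, s.spacing)
            samples.append(s)
    return samples, df


# -------------------------------------------------------------------------- IO

def save_sample(sample: VolumeSample, out_dir: str | Path) -> dict[str, Path]:
    """Write one sample as three NIfTI-1 files (RAS, spacing in the affine)."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(sample.spacing) + [1.0])
    paths = {}
    for tag, arr, dtype in (("ct", sample.ct, np.float32),
                            ("root_mask", sample.root_mask, np.uint8),
                            ("calc_mask", sample.calc_mask, np.uint8)):
        img = nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine)
        path = out_dir / f"{sample.patient_id}_{tag}.nii.gz"
        nib.save(img, path)
        paths[tag] = path
    return paths


def load_sample(patient_id: str, in_dir: str | Path) -> VolumeSample:
    import nibabel as nib

    in_dir = Path(in_dir)
    arrays = {}
    spacing = None
    for tag in ("ct", "root_mask", "calc_mask"):
        img = nib.load(in_dir / f"{patient_id}_{tag}.nii.gz")
        arrays[tag] = np.asarray(img.dataobj)
        spacing = tuple(float(v) for v in img.header.get_zooms()[:3])
    sample = VolumeSample(
        patient_id=patient_id,
        ct=arrays["ct"].astype(np.float32),
        root_mask=arrays["root_mask"].astype(np.uint8),
        calc_mask=arrays["calc_mask"].astype(np.uint8),
        spacing=spacing,
    )
    sample.validate()
    return sample


def save_cohort(samples: list[VolumeSample], table: pd.DataFrame,
                out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / "clinical.csv", index=False)
    vol_dir = out_dir / "volumes"
    for s in samples:
        save_sample(s, vol_dir)
    meta = {"n": len(table), "columns": list(table.columns)}
    (out_dir / "cohort.json").write_text(json.dumps(meta, indent=2))
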