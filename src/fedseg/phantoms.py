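"""Synthetic multi-site CT-phantom cohorts for segmentation training.

Real federated segmentation studies run on horizontally partitioned
clinical data: every hospital holds CT slices and tumour delineations for
its *own* patients, with site-specific scanner characteristics.  This
module emulates that landscape at desk scale.  Each site is described by a
:class:`SiteProfile` whose knobs (additive intensity offset, noise level,
tumour size range, lung-ellipse geometry) play the role of inter-hospital
heterogeneity; each generated :class:`PhantomCase` is one synthetic
patient: a 2D grey-level image containing a bright elliptical "lung"
region with a single quasi-elliptical tumour blob, and the matching
binary tumour mask.

Generation is deterministic: case ``i`` of a profile is a pure function
of ``(profile.seed, i)`` with an independent RNG stream per case, so
enlarging a site never perturbs its existing patients, and regenerating a
cohort from the same profiles is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DataError

GRID_SHAPE: tuple[int, int] = (64, 64)

# grey levels, arbitrary units
_BACKGROUND_LEVEL = 20.0
_LUNG_LEVEL = 110.0
_TUMOR_CONTRAST = 90.0
_AXIS_JITTER = 0.10  # +/- fractional jitter on tumour ellipse axes
_BOUNDARY_NOISE_SD = 0.25  # pixels, radial perturbation of the tumour rim


@dataclass(frozen=True)
class SiteProfile:
    """Generation recipe for one synthetic hospital site."""

    site_id: str
    n_patients: int
    seed: int
    intensity_offset: float = 0.0
    noise_sd: float = 5.0
    tumor_radius_range: tuple[float, float] = (4.0, 9.0)
    lung_ellipse_params: tuple[float, float] = (24.0, 18.0)

    def __post_init__(self):
        if not self.site_id:
            raise ConfigurationError("site_id must be a non-empty string")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.seed < 0:
            raise ConfigurationError("seed must be non-negative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        rmin, rmax = self.tumor_radius_range
        if not (0 < rmin <= rmax):
            raise ConfigurationError("tumor_radius_range must satisfy 0 < min <= max")
        a, b = self.lung_ellipse_params
        if rmax * (1 + _AXIS_JITTER) >= min(a, b):
            raise ConfigurationError(
                "tumor radius bounds must fit inside the lung ellipse"
            )
        h, w = GRID_SHAPE
        if a >= w / 2 or b >= h / 2:
            raise ConfigurationError("lung ellipse must fit inside the image grid")


@dataclass
class PhantomCase:
    """One synthetic patient: image + binary tumour mask + identifiers."""

    patient_id: str
    site_id: str
    image: np.ndarray  # 2D float32, GRID_SHAPE
    mask: np.ndarray  # 2D uint8 {0,1}, same shape

    def validate(self) -> "PhantomCase":
        if self.image.shape != self.mask.shape:
            raise DataError(
                f"{self.patient_id}: image shape {self.image.shape} != "
                f"mask shape {self.mask.shape}"
            )
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise DataError(f"{self.patient_id}: mask is not binary")
        if int(self.mask.sum()) < 1:
            raise DataError(f"{self.patient_id}: mask has no foreground pixel")
        return self


@dataclass
class PartitionedCohort:
    """Horizontally partitioned cohort: disjoint patients per site, each
    case assigned to exactly one of its site's train/validation splits."""

    train: dict[str, list[PhantomCase]] = field(default_factory=dict)
    validation: dict[str, list[PhantomCase]] = field(default_factory=dict)
    split_fraction: float = 0.8

    @property
    def sites(self) -> list[str]:
        return list(self.train.keys())

    def all_cases(self, site_id: str) -> list[PhantomCase]:
        return list(self.train[site_id]) + list(self.validation[site_id])

    def n_cases(self) -> int:
        return sum(
            len(v) for v in self.train.values()
        ) + sum(len(v) for v in self.validation.values())


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _lung_region(profile: SiteProfile) -> np.ndarray:
    h, w = GRID_SHAPE
    a, b = profile.lung_ellipse_params  # semi-axes: a along x (cols), b along y
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _tumor_mask(profile: SiteProfile, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one quasi-elliptical tumour blob fully inside the lung."""
    h, w = GRID_SHAPE
    a_lung, b_lung = profile.lung_ellipse_params
    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    rmin, rmax = profile.tumor_radius_range
    radius = float(rng.uniform(rmin, rmax))
    ax = radius * float(rng.uniform(1 - _AXIS_JITTER, 1 + _AXIS_JITTER))
    ay = radius * float(rng.uniform(1 - _AXIS_JITTER, 1 + _AXIS_JITTER))
    theta = float(rng.uniform(0, np.pi))
    # place the centre so the jittered ellipse stays inside the lung ellipse
    margin = max(ax, ay) + 1.0
    fx = np.sqrt(max(0.0, 1.0 - (margin / a_lung) ** 2))
    fy = np.sqrt(max(0.0, 1.0 - (margin / b_lung) ** 2))
    while True:
        u, v = rng.uniform(-1, 1, size=2)
        if u * u + v * v <= 1.0:
            break
    cx = cx0 + u * a_lung * fx
    cy = cy0 + v * b_lung * fy

    yy, xx = np.mgrid[0:h, 0:w]
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    rho = np.sqrt((xr / ax) ** 2 + (yr / ay) ** 2)
    if _BOUNDARY_NOISE_SD > 0:
        # smooth radial perturbation of the rim, parametrised by polar angle
        n_harm = 3
        amps = rng.normal(0.0, _BOUNDARY_NOISE_SD, size=n_harm)
        phases = rng.uniform(0, 2 * np.pi, size=n_harm)
        ang = np.arctan2(yr, xr)
        pert = sum(
            amps[k] * np.cos((k + 1) * ang + phases[k]) for k in range(n_harm)
        )
        rho = rho * (1.0 + pert / max(ax, ay))
    blob = rho <= 1.0
    blob &= _lung_region(profile)  # containment is an invariant, enforce it
    return blob.astype(np.uint8)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _case_rng(profile: SiteProfile, case_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([profile.seed, case_index]))


def patient_id_for(profile: SiteProfile, case_index: int) -> str:
    # embedding the site id makes cross-site id collisions impossible
    return f"{profile.site_id}_p{case_index:04d}"


def generate_case(profile: SiteProfile, case_index: int) -> PhantomCase:
    """Deterministically synthesise patient ``case_index`` of a site."""
    if not 0 <= case_index < profile.n_patients:
        raise ConfigurationError(
            f"case_index {case_index} out of range for site {profile.site_id!r} "
            f"with {profile.n_patients} patients"
        )
    rng = _case_rng(profile, case_index)
    lung = _lung_region(profile)
    mask = _tumor_mask(profile, rng)
    image = np.full(GRID_SHAPE, _BACKGROUND_LEVEL, dtype=np.float64)
    image[lung] = _LUNG_LEVEL + profile.intensity_offset
    image[mask.astype(bool)] += _TUMOR_CONTRAST
    if profile.noise_sd > 0:
        image += rng.normal(0.0, profile.noise_sd, size=GRID_SHAPE)
    case = PhantomCase(
        patient_id=patient_id_for(profile, case_index),
        site_id=profile.site_id,
        image=image.astype(np.float32),
        mask=mask,
    )
    return case.validate()


def split_counts(n: int, split_fraction: float) -> tuple[int, int]:
    """(n_train, n_validation) under the documented degenerate-split policy:
    every station must keep at least one validation case, and a single-case
    site cannot satisfy that, so it is a configuration error."""
    if not (0.0 < split_fraction < 1.0):
        raise ConfigurationError("split_fraction must lie strictly in (0, 1)")
    if n == 1:
        raise ConfigurationError(
            "a site with a single patient cannot hold out a validation case"
        )
    n_val = max(1, round((1.0 - split_fraction) * n))
    if n_val >= n:
        n_val = n - 1
    return n - n_val, n_val


def generate_partitioned_cohort(
    profiles: list[SiteProfile], split_fraction: float = 0.8
) -> PartitionedCohort:
    """Generate all sites and split each deterministically into train and
    validation subsets (shuffle driven by the site seed)."""
    seen: set[str] = set()
    for p in profiles:
        if p.site_id in seen:
            raise ConfigurationError(f"duplicate site_id {p.site_id!r}")
        seen.add(p.site_id)
    cohort = PartitionedCohort(split_fraction=split_fraction)
    for profile in profiles:
        cases = [generate_case(profile, i) for i in range(profile.n_patients)]
        n_train, n_val = split_counts(profile.n_patients, split_fraction)
        rng = np.random.default_rng(
            np.random.SeedSequence([profile.seed, 0x5B11F])  # split stream
        )
        order = rng.permutation(profile.n_patients)
        train_idx = sorted(order[:n_train].tolist())
        val_idx = sorted(order[n_train:].tolist())
        cohort.train[profile.site_id] = [cases[i] for i in train_idx]
        cohort.validation[profile.site_id] = [cases[i] for i in val_idx]
    return cohort


# ---------------------------------------------------------------------------
# profile (de)serialization
# ---------------------------------------------------------------------------

def profile_to_dict(p: SiteProfile) -> dict:
    return {
        "site_id": p.site_id,
        "n_patients": p.n_patients,
        "seed": p.seed,
        "intensity_offset": p.intensity_offset,
        "noise_sd": p.noise_sd,
        "tumor_radius_range": list(p.tumor_radius_range),
        "lung_ellipse_params": list(p.lung_ellipse_params),
    }


def profile_from_dict(d: dict) -> SiteProfile:
    try:
        return SiteProfile(
            site_id=d["site_id"],
            n_patients=int(d["n_patients"]),
            seed=int(d["seed"]),
            intensity_offset=float(d.get("intensity_offset", 0.0)),
            noise_sd=float(d.get("noise_sd", 5.0)),
            tumor_radius_range=tuple(d.get("tumor_radius_range", (4.0, 9.0))),
            lung_ellipse_params=tuple(d.get("lung_ellipse_params", (24.0, 18.0))),
        )
    except KeyError as exc:
        raise ConfigurationError(f"site profile missing required key {exc}") from exc


def load_profiles(path) -> list[SiteProfile]:
    """Read a JSON list of site-profile objects."""
    data = json.loads(Path(path).read_text())
    if not isinstance(data, list):
        raise ConfigurationError("profile file must contain a JSON list")
    return [profile_from_dict(d) for d in data]
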