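"""Synthetic top-view pig scenes: biometry sampling and binary-mask rendering.

The generator stands in for a real data-collection campaign: a herd of
fattening pigs (~100-150 kg) walks one at a time under a fixed downward
camera, and each frame yields a clean top-view mask of the animal's back.
Every scene carries its ground truth (biometry, bend curvature, camera
distance, pixel scale), so downstream feature extraction, correction and
regression stages can be validated quantitatively.

Body model: the back is a capsule (stadium) of length ``BL`` and width
``HW`` whose long axis is swept along a circular arc — curvature zero is a
straight spine, positive curvature models the animal bending while walking.
The camera is a pinhole: an object at distance ``hdep`` from the lens maps
to ``focal_scale / hdep`` pixels per centimetre.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage


class ConfigurationError(ValueError):
    """Raised when population or camera parameters are inconsistent."""


class RenderError(ValueError):
    """Raised when a body cannot be rasterized inside the image frame."""


@dataclass(frozen=True)
class BiometryRecord:
    """One pig's measured traits (the manual tape-and-scale ground truth)."""

    pig_id: str
    weight: float        # kg
    body_length: float   # cm (BL)
    hip_width: float     # cm (HW)
    body_height: float   # cm (Hb)
    hip_height: float    # cm (Hh)

    def __post_init__(self) -> None:
        for name in ("weight", "body_length", "hip_width", "body_height", "hip_height"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.body_length <= self.hip_width:
            raise ConfigurationError("body_length must exceed hip_width")


@dataclass(frozen=True)
class TraitSpec:
    """Marginal distribution of one trait: truncated normal."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("trait SD must be non-negative")
        if not (self.min < self.mean < self.max):
            raise ConfigurationError(
                f"trait bounds must satisfy min < mean < max, got "
                f"({self.min}, {self.mean}, {self.max})"
            )


def _default_traits() -> dict[str, TraitSpec]:
    # Herd statistics of the 39-pig study population (means, SDs and ranges
    # of weight and the four linear body measurements, in kg / cm).
    return {
        "weight": TraitSpec(122.81, 7.86, 104.0, 138.0),
        "body_length": TraitSpec(126.0, 5.79, 108.0, 137.0),
        "hip_width": TraitSpec(34.28, 1.72, 30.0, 38.0),
        "body_height": TraitSpec(69.4, 2.00, 65.0, 74.0),
        "hip_height": TraitSpec(75.13, 2.55, 70.0, 82.0),
    }


@dataclass(frozen=True)
class PopulationParams:
    """Trait marginals plus the allometric law linking size to mass.

    Weight is generated as ``scale * BL**a * HW**b * Hb**c * exp(eps)`` with
    ``eps ~ N(0, noise_sd)``, then truncated (clipped) to the weight trait's
    bounds.  The default exponents (1, 2, 1) follow the classical heart-girth
    allometry (mass grows with length times girth squared), which also makes
    slender animals lighter at equal size — the documented behaviour of the
    eccentricity feature.  ``scale`` defaults to a deterministic internal
    calibration that maps the mean *generated* weight onto the population
    mean weight, correcting for the truncation/rejection bias of the trait
    bounds.  Linear traits share a latent size factor so that every pair has
    correlation ``trait_correlation``.
    """

    traits: dict[str, TraitSpec] = field(default_factory=_default_traits)
    allometric_exponents: tuple[float, float, float] = (1.0, 2.0, 1.0)
    allometric_scale: float | None = None   # None -> internal calibration
    noise_sd: float = 0.02                  # SD of log-weight residual
    trait_correlation: float = 0.6

    def __post_init__(self) -> None:
        required = {"weight", "body_length", "hip_width", "body_height", "hip_height"}
        missing = required - set(self.traits)
        if missing:
            raise ConfigurationError(f"missing trait specs: {sorted(missing)}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not (0.0 <= self.trait_correlation < 1.0):
            raise ConfigurationError("trait_correlation must lie in [0, 1)")

    @property
    def calibrated_scale(self) -> float:
        if self.allometric_scale is not None:
            return self.allometric_scale
        cached = getattr(self, "_scale_cache", None)
        if cached is None:
            cached = _calibrate_scale(self)
            object.__setattr__(self, "_scale_cache", cached)
        return cached

    def allometric_weight(self, bl: float, hw: float, hb: float) -> float:
        """Noise-free weight implied by the allometric law (kg)."""
        a, b, c = self.allometric_exponents
        return self.calibrated_scale * bl**a * hw**b * hb**c


@dataclass(frozen=True)
class CameraConfig:
    """Fixed downward-looking camera over the weighing channel."""

    height_above_ground: float = 145.0   # cm (Hg)
    focal_scale: float = 400.0           # pixel*cm: pixels-per-cm at 1 cm distance
    image_width: int = 1920
    image_height: int = 1080

    def __post_init__(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if self.height_above_ground <= 0 or self.focal_scale <= 0:
            raise ConfigurationError("camera height and focal scale must be positive")

    def pixels_per_cm(self, hdep: float) -> float:
        """Pinhole scale at camera-to-back distance ``hdep`` (cm)."""
        if hdep <= 0:
            raise ConfigurationError("camera-to-back distance must be positive")
        return self.focal_scale / hdep


@dataclass(frozen=True)
class SyntheticScene:
    """One rendered frame plus its full ground truth."""

    mask: np.ndarray             # 2-D bool, True = pig back
    biometry: BiometryRecord
    bend_curvature: float        # 1/cm, 0 = straight spine
    hdep_true: float             # cm, camera to back
    pixels_per_cm: float
    pose_angle: float = 0.0      # radians
    frame_id: str = ""


_LINEAR_TRAITS = ("body_length", "hip_width", "body_height", "hip_height")

# Fixed internal stream for the scale calibration; independent of user seeds.
_CALIBRATION_SEED = 987654321
_CALIBRATION_N = 2000


def _sample_trait_vector(
    params: "PopulationParams", rng: np.random.Generator
) -> dict[str, float]:
    """One pig's linear traits: shared latent factor + rejection on bounds."""
    r = params.trait_correlation
    w_shared, w_indep = np.sqrt(r), np.sqrt(1.0 - r)
    while True:
        latent = rng.standard_normal()
        z = w_shared * latent + w_indep * rng.standard_normal(len(_LINEAR_TRAITS))
        vals = {}
        ok = True
        for name, zi in zip(_LINEAR_TRAITS, z):
            spec = params.traits[name]
            v = spec.mean + spec.sd * zi
            if not (spec.min <= v <= spec.max):
                ok = False
                break
            vals[name] = v
        if ok and vals["body_length"] > vals["hip_width"]:
            return vals


def _calibrate_scale(params: "PopulationParams") -> float:
    """Scale factor making the mean generated weight hit the nominal mean.

    Joint rejection on the trait bounds and the final weight clipping both
    bias the naive trait-means calibration; a deterministic Monte-Carlo
    fixed point (internal seed, 2000 pigs) removes the bias.  Degenerate
    populations (all SDs zero) recover the exact trait-means calibration.
    """
    a, b, c = params.allometric_exponents
    wspec = params.traits["weight"]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    base = np.empty(_CALIBRATION_N)
    for i in range(_CALIBRATION_N):
        v = _sample_trait_vector(params, rng)
        eps = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
        base[i] = (
            v["body_length"] ** a * v["hip_width"] ** b * v["body_height"] ** c
        ) * np.exp(eps)
    s = wspec.mean / base.mean()
    for _ in range(12):
        realized = np.clip(s * base, wspec.min, wspec.max).mean()
        s *= wspec.mean / realized
    return float(s)


def sample_biometry(
    n_pigs: int,
    params: PopulationParams | None = None,
    seed: int = 0,
) -> list[BiometryRecord]:
    """Draw a herd of ``n_pigs`` with correlated, truncated-normal traits.

    The four linear traits load on a shared latent size factor (pairwise
    correlation ``params.trait_correlation``); out-of-bound draws are
    rejected and redrawn per pig.  Weight follows the allometric law with
    multiplicative log-normal noise and is clipped to its bounds.
    """
    if n_pigs < 1:
        raise ConfigurationError("n_pigs must be >= 1")
    params = params or PopulationParams()
    rng = np.random.default_rng(seed)
    wspec = params.traits["weight"]

    records: list[BiometryRecord] = []
    for i in range(n_pigs):
        vals = _sample_trait_vector(params, rng)
        eps = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
        w = params.allometric_weight(
            vals["body_length"], vals["hip_width"], vals["body_height"]
        ) * np.exp(eps)
        w = float(np.clip(w, wspec.min, wspec.max))
        records.append(BiometryRecord(pig_id=f"pig{i:03d}", weight=w, **vals))
    return records


def _centerline(bl: float, curvature: float, step_cm: float) -> np.ndarray:
    """Sample the spine arc (length ``bl``, given curvature) as (x, y) cm.

    Arc-length parameterised, centred on the arc midpoint.  For curvature
    kappa the chord is (2/kappa)*sin(kappa*bl/2); kappa -> 0 recovers a
    straight segment.
    """
    n = max(int(np.ceil(bl / step_cm)) + 1, 2)
    s = np.linspace(-bl / 2.0, bl / 2.0, n)
    if abs(curvature) < 1e-12:
        return np.column_stack([s, np.zeros_like(s)])
    radius = 1.0 / curvature
    x = radius * np.sin(curvature * s)
    y = radius * (1.0 - np.cos(curvature * s))
    return np.column_stack([x, y])


def render_mask(
    biometry: BiometryRecord,
    bend_curvature: float = 0.0,
    camera: CameraConfig | None = None,
    seed: int = 0,
    edge_noise: float = 0.0,
    max_jitter_px: float = 60.0,
) -> SyntheticScene:
    """Rasterize one pig's back as a filled capsule swept along an arc.

    The capsule (stadium) has overall straight length BL and width HW: a
    spine arc of length BL - HW is swept with radius HW/2, the semicircular
    end caps restoring the full BL extent.  The body is rotated by a seeded
    uniform angle, jittered around the frame centre, and rasterized at the
    pinhole scale ``focal_scale / hdep_true``.  ``edge_noise`` (pixels) adds
    a seeded random modulation of the local capsule radius, mimicking
    segmentation boundary jitter.
    """
    camera = camera or CameraConfig()
    if bend_curvature < 0:
        raise ConfigurationError("bend_curvature must be non-negative")
    hdep = camera.height_above_ground - (biometry.body_height + biometry.hip_height) / 2.0
    if hdep <= 0:
        raise RenderError("camera sits below the pig's back (hdep <= 0)")
    ppcm = camera.pixels_per_cm(hdep)
    rng = np.random.default_rng(seed)
    angle = rng.uniform(0.0, 2.0 * np.pi)

    # Spine in cm, rotated into the frame.  Arc length BL - HW so the end
    # caps bring the straight body to exactly BL overall.
    spine_len = biometry.body_length - biometry.hip_width
    pts = _centerline(spine_len, bend_curvature, step_cm=0.25 / ppcm)
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    pts = pts @ rot.T
    radius_px = biometry.hip_width / 2.0 * ppcm
    pts_px = pts * ppcm

    # Frame-fit check before any allocation.
    half_w = pts_px[:, 0].max() - pts_px[:, 0].min() + 2 * radius_px
    half_h = pts_px[:, 1].max() - pts_px[:, 1].min() + 2 * radius_px
    if half_w > camera.image_width:
        raise RenderError(
            f"rendered body span {half_w:.0f} px exceeds image_width "
            f"{camera.image_width} (body_length {biometry.body_length} cm "
            f"at {ppcm:.2f} px/cm)"
        )
    if half_h > camera.image_height:
        raise RenderError(
            f"rendered body span {half_h:.0f} px exceeds image_height "
            f"{camera.image_height} (body_length {biometry.body_length} cm "
            f"at {ppcm:.2f} px/cm)"
        )

    # Centre plus a seeded jitter that keeps the body inside the frame.
    cx = camera.image_width / 2.0
    cy = camera.image_height / 2.0
    slack_x = (camera.image_width - half_w) / 2.0 - 2.0
    slack_y = (camera.image_height - half_h) / 2.0 - 2.0
    jx = rng.uniform(-1.0, 1.0) * min(max(slack_x, 0.0), max_jitter_px)
    jy = rng.uniform(-1.0, 1.0) * min(max(slack_y, 0.0), max_jitter_px)
    col = pts_px[:, 0] + cx + jx
    row = pts_px[:, 1] + cy + jy

    # Rasterize via an exact Euclidean distance transform from the sampled
    # spine: a pixel belongs to the capsule iff its distance to the spine
    # polyline is <= HW/2 (in px).  Work on a padded bounding box.
    pad = int(np.ceil(radius_px)) + 3
    r0 = max(int(np.floor(row.min())) - pad, 0)
    c0 = max(int(np.floor(col.min())) - pad, 0)
    r1 = min(int(np.ceil(row.max())) + pad, camera.image_height - 1)
    c1 = min(int(np.ceil(col.max())) + pad, camera.image_width - 1)
    box = np.ones((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    rr = np.clip(np.rint(row).astype(int) - r0, 0, box.shape[0] - 1)
    cc = np.clip(np.rint(col).astype(int) - c0, 0, box.shape[1] - 1)
    box[rr, cc] = False
    dist = ndimage.distance_transform_edt(box)
    if edge_noise > 0:
        dist = dist + rng.normal(0.0, edge_noise, size=dist.shape)
    local = dist <= radius_px

    mask = np.zeros((camera.image_height, camera.image_width), dtype=bool)
    mask[r0 : r1 + 1, c0 : c1 + 1] = local
    return SyntheticScene(
        mask=mask,
        biometry=biometry,
        bend_curvature=float(bend_curvature),
        hdep_true=float(hdep),
        pixels_per_cm=float(ppcm),
        pose_angle=float(angle),
    )


@dataclass(frozen=True)
class CurvatureDistribution:
    """Half-normal spine-curvature model (1/cm); sd=0 means always straight."""

    sd: float = 0.004

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd <= 0:
            return 0.0
        return float(abs(rng.normal(0.0, self.sd)))


def generate_dataset(
    n_pigs: int = 39,
    frames_per_pig: int = 39,
    params: PopulationParams | None = None,
    camera: CameraConfig | None = None,
    curvature: CurvatureDistribution | None = None,
    seed: int = 0,
    edge_noise: float = 0.0,
) -> tuple[list[SyntheticScene], pd.DataFrame]:
    """Simulate a full recording campaign.

    Each pig's biometry is sampled once; every frame re-draws curvature and
    pose.  Returns the scenes (with ``frame_id`` assigned) and the biometry
    table.  Fully reproducible from ``seed``.
    """
    if n_pigs < 1 or frames_per_pig < 1:
        raise ConfigurationError("n_pigs and frames_per_pig must be >= 1")
    params = params or PopulationParams()
    camera = camera or CameraConfig()
    curvature = curvature or CurvatureDistribution()

    herd = sample_biometry(n_pigs, params, seed=seed)
    root = np.random.SeedSequence(seed)
    frame_seeds = root.spawn(n_pigs * frames_per_pig)

    scenes: list[SyntheticScene] = []
    k = 0
    for pig in herd:
        for j in range(frames_per_pig):
            rng = np.random.default_rng(frame_seeds[k])
            kappa = curvature.sample(rng)
            render_seed = int(rng.integers(0, 2**31 - 1))
            scene = render_mask(
                pig, kappa, camera, seed=render_seed, edge_noise=edge_noise
            )
            scenes.append(
                replace(scene, frame_id=f"{pig.pig_id}_f{j:03d}")
            )
            k += 1
    table = biometry_table(herd)
    return scenes, table


def biometry_table(herd: list[BiometryRecord]) -> pd.DataFrame:
    """Biometry records as the canonical CSV-ready table."""
    return pd.DataFrame(
        {
            "pig_id": [p.pig_id for p in herd],
            "weight_kg": [p.weight for p in herd],
            "body_length_cm": [p.body_length for p in herd],
            "hip_width_cm": [p.hip_width for p in herd],
            "body_height_cm": [p.body_height for p in herd],
            "hip_height_cm": [p.hip_height for p in herd],
        }
    )


def scene_table(scenes: list[SyntheticScene]) -> pd.DataFrame:
    """Per-frame ground-truth sidecar (curvature, camera distance, scale)."""
    return pd.DataFrame(
        {
            "frame_id": [s.frame_id for s in scenes],
            "pig_id": [s.biometry.pig_id for s in scenes],
            "bend_curvature_per_cm": [s.bend_curvature for s in scenes],
            "hdep_cm": [s.hdep_true for s in scenes],
            "pixels_per_cm": [s.pixels_per_cm for s in scenes],
            "pose_angle_rad": [s.pose_angle for s in scenes],
        }
    )
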