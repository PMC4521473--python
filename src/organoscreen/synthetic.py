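"""Synthetic 3-D microtissue generator.

Renders seeded, ground-truthed two-channel (filamentous-actin / nuclei)
image stacks that emulate organoids grown in a gel matrix and imaged as
multi-section z-stacks in a multi-well plate, and — at the other end of the
pipeline — well × feature tables with planted statistical structure.

The rendering model is deliberately minimal: an organoid is an extruded
(cylindrical in z) elliptical body with optional thin radial arms
(protrusions, the invasive phenotype) and an optional dimmed concentric
lumen; nuclei are Gaussian blobs placed inside the body at a controllable
depth from the boundary.  Each morphological "dial" of the generator maps
onto one of the canonical morphology features measured downstream, so every
stage of the analysis can be validated against exact ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "OrganoidSpec",
    "EffectTemplate",
    "TreatmentSpec",
    "PlateSpec",
    "ImageStack",
    "GroundTruth",
    "NucleusRecord",
    "render_well_stack",
    "generate_plate",
    "iterate_plate_wells",
    "simulate_feature_table",
    "invasive_template",
    "polarized_template",
    "null_template",
    "default_plate_spec",
    "two_group_plate_spec",
    "default_class_templates",
]

# intensity scale of the 16-bit rendering
_BACKGROUND = 400.0
_ACTIN_AMP = 12000.0
_NUCLEI_AMP = 15000.0
_LUMEN_DIM = 0.55  # lumen intensity relative to body; stays above half-max


# ---------------------------------------------------------------------------
# specs


@dataclass
class OrganoidSpec:
    """Geometry of one rendered organoid.

    ``center`` is (x, y, z) in voxel coordinates (x = column, y = row,
    z = section index).  ``elongation`` >= 1 is the major/minor axis ratio of
    the elliptical footprint.  Arms are thin radial protrusions; ``hollow``
    dims a concentric lumen in the actin channel without breaking the mask.
    ``boundary_fraction`` is the fraction of nuclei drawn toward the
    boundary (polarised placement); the ``nuclei_placement`` enum is a
    shorthand for the two extremes.
    """

    center: tuple[float, float, float]
    radius: float = 10.0
    elongation: float = 1.0
    orientation: float = 0.0
    n_branches: int = 0
    branch_length: float = 8.0
    branch_width: float = 2.0
    hollow: bool = False
    lumen_radius: float | None = None
    texture_sd: float = 0.0  # speckle contrast of the actin body (0 = flat)
    nuclei_count: int = 8
    nuclei_placement: Literal["boundary", "uniform"] = "uniform"
    boundary_fraction: float | None = None
    nuclei_depth: float | None = None  # target depth (px) from the boundary
    nuclei_depth_sd: float = 2.0
    z_halfspan: float = 2.0
    intensity_scale: float = 1.0
    branch_angles: tuple[float, ...] | None = None
    branch_lengths: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.radius < 2:
            raise ValueError(f"organoid radius must be >= 2 px, got {self.radius}")
        if self.elongation < 1:
            raise ValueError("elongation is major/minor and must be >= 1")
        if self.n_branches < 0:
            raise ValueError("n_branches must be >= 0")
        if self.nuclei_count < 1:
            raise ValueError("nuclei_count must be >= 1")
        if self.hollow:
            if self.lumen_radius is None:
                self.lumen_radius = 0.45 * self.radius
            if not self.lumen_radius < self.radius:
                raise ValueError("lumen radius must be smaller than the organoid radius")
        if self.boundary_fraction is None:
            self.boundary_fraction = 1.0 if self.nuclei_placement == "boundary" else 0.0

    @property
    def footprint_reach(self) -> float:
        """Largest in-plane distance from the center covered by the footprint."""
        reach = self.radius * math.sqrt(self.elongation)
        if self.n_branches > 0:
            lengths = self.branch_lengths or (self.branch_length,) * self.n_branches
            reach = max(reach, self.radius + max(lengths) + self.branch_width)
        return reach


@dataclass(frozen=True)
class EffectTemplate:
    """Maximal (top-of-curve) additive shifts of the phenotype dials.

    Each field is the shift applied to the corresponding well-recipe
    baseline at full effect; intermediate doses are scaled by a Hill curve.
    The six dials map onto the six canonical morphology features: arms drive
    organoid branching and (via the max-diameter term) roundness, radius
    drives per-organoid size, organoid count and z span drive the per-well
    count and accumulated-area measures, and boundary placement of nuclei
    drives cell polarity.
    """

    name: str
    arm_length: float = 0.0
    arm_count: float = 0.0
    radius: float = 0.0
    n_organoids: float = 0.0
    z_halfspan: float = 0.0
    nuclei_depth: float = 0.0
    hill_ec50: float = 3.3
    hill_slope: float = 2.5

    def effect_fraction(self, dose: float) -> float:
        """Fractional effect in [0, 1) at a given dose (Hill curve)."""
        if dose <= 0:
            return 0.0
        r = (dose / self.hill_ec50) ** self.hill_slope
        return r / (1.0 + r)


def null_template() -> EffectTemplate:
    """A template with zero slopes: treated wells match buffer wells."""
    return EffectTemplate(name="null")


def invasive_template() -> EffectTemplate:
    """Invasion-promoting reference template (the default screen effect).

    At full effect: long and more numerous protrusions, smaller and more
    numerous organoid bodies spanning more sections, nuclei dispersed away
    from the boundary.
    """
    return EffectTemplate(
        name="invasive",
        arm_length=4.5,
        arm_count=1.5,
        radius=2.0,
        n_organoids=4.0,
        nuclei_depth=2.0,
    )


def polarized_template() -> EffectTemplate:
    """Invasion-suppressing template: compact rounded bodies, polarised nuclei."""
    return EffectTemplate(
        name="polarized",
        arm_length=-5.0,
        arm_count=-1.6,
        radius=-1.5,
        n_organoids=-3.0,
        nuclei_depth=-2.5,
    )


@dataclass(frozen=True)
class TreatmentSpec:
    name: str
    template: EffectTemplate
    doses: tuple[float, ...] = (0.5, 1.5, 3.0, 6.0, 12.0, 30.0)
    replicates: int = 4
    potency: float = 1.0  # multiplies the dose before the Hill curve

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")


# baseline (buffer) values of the phenotype dials
_BASELINE = {
    "arm_length": 11.0,
    "arm_count": 2.0,
    "radius": 10.0,
    "n_organoids": 7.0,
    "z_halfspan": 2.2,
    "nuclei_depth": 4.0,
}


@dataclass(frozen=True)
class PlateSpec:
    """Layout and rendering conditions for one synthetic screen plate."""

    treatments: tuple[TreatmentSpec, ...]
    buffer_fraction: float = 0.25
    seed: int = 0
    geometry: tuple[int, int, int] = (8, 320, 320)  # (sections, height, width)
    noise_sd: float = 150.0
    defocus_sections: tuple[int, ...] = (0,)
    defocus_sigma: float = 4.0
    baseline: dict = field(default_factory=lambda: dict(_BASELINE))

    def __post_init__(self) -> None:
        n_treat = sum(len(t.doses) * t.replicates for t in self.treatments)
        if n_treat == 0:
            raise ValueError("plate needs at least one treatment well")
        if not 0 < self.buffer_fraction < 1:
            raise ValueError("buffer_fraction must be in (0, 1)")
        n_wells = n_treat / (1.0 - self.buffer_fraction)
        if abs(n_wells - round(n_wells)) > 1e-9:
            raise ValueError(
                "buffer_fraction * n_wells must be an integer; got "
                f"{n_treat} treatment wells with buffer fraction {self.buffer_fraction}"
            )
        if round(n_wells) - n_treat < 2:
            raise ValueError("plate needs at least 2 buffer wells")

    @property
    def n_treatment_wells(self) -> int:
        return sum(len(t.doses) * t.replicates for t in self.treatments)

    @property
    def n_wells(self) -> int:
        return round(self.n_treatment_wells / (1.0 - self.buffer_fraction))

    @property
    def n_buffer_wells(self) -> int:
        return self.n_wells - self.n_treatment_wells


def default_plate_spec(seed: int = 1) -> PlateSpec:
    """The default screen plate: a twelve-treatment panel, six doses in
    quadruplicate, 25 % buffer-control wells (384 wells).

    The treatments share the invasion-promoting template at staggered
    potencies, emulating an antibody panel with a common mechanism and a
    range of affinities."""
    treatments = tuple(
        TreatmentSpec(name=f"ab{i + 1:02d}", template=invasive_template(), potency=p)
        for i, p in enumerate(
            (1.0, 0.8, 1.25, 0.6, 1.0, 0.9, 1.1, 0.7, 1.3, 0.85, 1.05, 0.95))
    )
    return PlateSpec(treatments=treatments, seed=seed)


def two_group_plate_spec(seed: int = 1) -> PlateSpec:
    """A two-treatment plate with opposing templates (invasion-promoting vs
    invasion-suppressing), for end-to-end class-separation scenarios."""
    treatments = (
        TreatmentSpec(name="suppressor", template=polarized_template()),
        TreatmentSpec(name="promoter", template=invasive_template()),
    )
    return PlateSpec(treatments=treatments, seed=seed)


# ---------------------------------------------------------------------------
# rendering


@dataclass
class NucleusRecord:
    object_id: int
    section: int
    x: float
    y: float


@dataclass
class ImageStack:
    """One well's two-channel multi-section image data."""

    well: str
    actin: np.ndarray  # (sections, H, W) uint16
    nuclei: np.ndarray  # (sections, H, W) uint16

    @property
    def geometry(self) -> tuple[int, int, int]:
        return self.actin.shape


@dataclass
class GroundTruth:
    """Exact rendering ground truth for one well.

    ``labels`` holds, per section, an integer label image where voxel value
    ``i`` marks membership of organoid ``i`` (0 = background); every rendered
    voxel belongs to exactly one object.  Nuclei mass centers are recorded
    with their parent organoid id.
    """

    well: str
    specs: list[OrganoidSpec]
    labels: np.ndarray  # (sections, H, W) int32
    nuclei: list[NucleusRecord]
    class_label: str | None = None

    def mask(self, object_id: int, section: int) -> np.ndarray:
        return self.labels[section] == object_id

    @property
    def n_objects(self) -> int:
        return len(self.specs)


def _footprint(spec: OrganoidSpec, height: int, width: int, rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean footprint (and lumen region) of one organoid on the canvas."""
    cx, cy, _ = spec.center
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    dx, dy = xx - cx, yy - cy
    ct, st = math.cos(spec.orientation), math.sin(spec.orientation)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    a = spec.radius * math.sqrt(spec.elongation)
    b = spec.radius / math.sqrt(spec.elongation)
    body = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = body
    if spec.n_branches > 0:
        angles = spec.branch_angles
        if angles is None:
            angles = tuple(rng.uniform(0, 2 * math.pi, size=spec.n_branches))
        lengths = spec.branch_lengths or (spec.branch_length,) * spec.n_branches
        for ang, length in zip(angles, lengths):
            # capsule from just inside the boundary to radius + length
            ex, ey = math.cos(ang), math.sin(ang)
            t0, t1 = 0.6 * spec.radius, spec.radius + max(length, 0.0)
            proj = dx * ex + dy * ey
            t = np.clip(proj, t0, t1)
            dist2 = (dx - t * ex) ** 2 + (dy - t * ey) ** 2
            mask = mask | (dist2 <= spec.branch_width**2)
    lumen = np.zeros_like(mask)
    if spec.hollow and spec.lumen_radius:
        s = spec.lumen_radius / spec.radius
        lumen = (u / (a * s)) ** 2 + (v / (b * s)) ** 2 <= 1.0
    return mask, lumen


def _sample_nucleus_xy(spec: OrganoidSpec, rng: np.random.Generator
                       ) -> tuple[float, float]:
    """Sample one nucleus mass center inside the elliptical body.

    With probability ``boundary_fraction`` the nucleus sits at a small depth
    from the boundary (polarised placement, additive depth jitter); otherwise
    it is placed area-uniformly in the body.
    """
    cx, cy, _ = spec.center
    a = spec.radius * math.sqrt(spec.elongation)
    b = spec.radius / math.sqrt(spec.elongation)
    ang = rng.uniform(0, 2 * math.pi)
    if spec.nuclei_depth is not None:
        # depth-targeted placement: distance from the boundary with a fixed
        # spread, independent of the organoid radius
        d = float(np.clip(rng.normal(spec.nuclei_depth, spec.nuclei_depth_sd),
                          0.5, 0.92 * spec.radius))
        rho = 1.0 - d / spec.radius
    elif rng.uniform() < (spec.boundary_fraction or 0.0):
        depth = min(0.9, abs(rng.normal(0.0, 2.5)) / spec.radius + 0.12)
        rho = 1.0 - depth
    else:
        rho = math.sqrt(rng.uniform(0.05, 0.9))
    u = rho * a * math.cos(ang)
    v = rho * b * math.sin(ang)
    ct, st = math.cos(spec.orientation), math.sin(spec.orientation)
    return cx + u * ct - v * st, cy + u * st + v * ct


def render_well_stack(
    specs: Sequence[OrganoidSpec],
    geometry: tuple[int, int, int] = (8, 256, 256),
    noise_sd: float = 0.0,
    defocus_sections: Sequence[int] = (),
    seed: int = 0,
    *,
    well: str = "W00",
    psf_sigma: float = 0.0,
    defocus_sigma: float = 4.0,
    illumination: tuple[float, float] = (1.0, 1.0),
    background: float = _BACKGROUND,
    nucleus_sigma: float = 2.2,
    nucleus_amp_sd: float = 0.2,
) -> tuple[ImageStack, GroundTruth]:
    """Render one well's two-channel stack plus exact ground truth.

    The rendering is a pure function of ``(specs, geometry, seed, ...)``:
    identical inputs reproduce bit-identical stacks.  With ``noise_sd=0``
    and ``psf_sigma=0`` the actin channel thresholded at half-maximum
    recovers the ground-truth voxel set exactly.

    Raises ``ValueError`` naming the offending spec when a footprint does
    not fit the canvas.
    """
    sections, height, width = geometry
    if sections < 1 or height < 1 or width < 1:
        raise ValueError("geometry must be positive")
    for idx, spec in enumerate(specs):
        cx, cy, cz = spec.center
        reach = spec.footprint_reach
        if not (reach <= cx <= width - 1 - reach and reach <= cy <= height - 1 - reach):
            raise ValueError(
                f"organoid spec #{idx} (center={spec.center}, reach={reach:.1f}) "
                "does not fit the canvas"
            )
        if not 0 <= cz <= sections - 1:
            raise ValueError(f"organoid spec #{idx} center section {cz} outside stack")

    rng = np.random.default_rng(seed)
    actin = np.zeros((sections, height, width), dtype=float)
    nucl = np.zeros((sections, height, width), dtype=float)
    labels = np.zeros((sections, height, width), dtype=np.int32)
    nuclei_records: list[NucleusRecord] = []

    for idx, spec in enumerate(specs, start=1):
        mask, lumen = _footprint(spec, height, width, rng)
        cz = spec.center[2]
        lo = max(0, int(math.ceil(cz - spec.z_halfspan)))
        hi = min(sections - 1, int(math.floor(cz + spec.z_halfspan)))
        spanned = list(range(lo, hi + 1))
        amp = _ACTIN_AMP * spec.intensity_scale * illumination[0]
        body_int = np.where(lumen & mask, amp * _LUMEN_DIM, amp)
        if spec.texture_sd > 0:
            # extruded speckle texture: filamentous staining is not uniform
            speckle = ndimage.gaussian_filter(
                rng.normal(0.0, 1.0, size=mask.shape), 2.0)
            speckle /= max(speckle.std(), 1e-9)
            body_int = body_int * np.exp(spec.texture_sd * speckle
                                         - 0.5 * spec.texture_sd**2)
        for s in spanned:
            free = labels[s] == 0
            put = mask & free
            actin[s][put] = body_int[put]
            labels[s][put] = idx
        # nuclei: blobs of ~2 px sigma placed inside the body
        n_sigma = nucleus_sigma
        for _ in range(spec.nuclei_count):
            x, y = _sample_nucleus_xy(spec, rng)
            s = int(rng.choice(spanned)) if spanned else int(round(cz))
            # render the Gaussian blob only on a local +-4 sigma window
            x0, x1 = max(0, int(x - 4 * n_sigma)), min(width, int(x + 4 * n_sigma) + 1)
            y0, y1 = max(0, int(y - 4 * n_sigma)), min(height, int(y + 4 * n_sigma) + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
            blob = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * n_sigma**2))
            nucl[s, y0:y1, x0:x1] += (
                _NUCLEI_AMP * illumination[1] * spec.intensity_scale
                * float(max(0.2, rng.normal(1.0, nucleus_amp_sd))) * blob
            )
            nuclei_records.append(NucleusRecord(object_id=idx, section=s, x=x, y=y))

    for channel in (actin, nucl):
        channel += background
        for s in range(sections):
            sigma = psf_sigma
            if s in set(defocus_sections):
                sigma = max(sigma, defocus_sigma)
            if sigma > 0:
                channel[s] = ndimage.gaussian_filter(channel[s], sigma)
        if noise_sd > 0:
            channel += rng.normal(0.0, noise_sd, size=channel.shape)

    stack = ImageStack(
        well=well,
        actin=np.clip(actin, 0, 65535).astype(np.uint16),
        nuclei=np.clip(nucl, 0, 65535).astype(np.uint16),
    )
    truth = GroundTruth(well=well, specs=list(specs), labels=labels, nuclei=nuclei_records)
    return stack, truth


# ---------------------------------------------------------------------------
# plate generation


def _sample_well_specs(
    dials: dict, geometry: tuple[int, int, int], rng: np.random.Generator
) -> list[OrganoidSpec]:
    """Sample organoid specs for one well from its dial settings."""
    sections, height, width = geometry
    n = max(3, int(round(rng.normal(dials["n_organoids"], 0.8))))
    nuclei_rate = dials["nuclei_rate"]
    specs: list[OrganoidSpec] = []
    centers: list[tuple[float, float, float]] = []
    attempts = 0
    while len(specs) < n and attempts < 400:
        attempts += 1
        radius = max(4.0, rng.normal(dials["radius"], dials["radius_sd"]))
        lam = max(1.0, dials["arm_count"] + dials.get("arm_count_jitter", 0.0))
        arm_count = max(1, int(round(rng.normal(lam, 0.3))))
        arm_len = max(2.0, rng.normal(dials["arm_length"], dials["arm_len_sd"]))
        arm_lengths = tuple(
            max(2.0, rng.normal(arm_len, 1.2)) for _ in range(arm_count))
        reach = radius + ((max(arm_lengths) + 3.6) if arm_count else 0.0)
        # one placement margin for every well (sized for the largest
        # renderable organoid) so spatial statistics cannot encode size
        margin = min(40.0, max(32.0, 0.12 * min(height, width)))
        if reach >= margin or 2 * margin >= min(height, width):
            continue
        cx = rng.uniform(margin, width - 1 - margin)
        cy = rng.uniform(margin, height - 1 - margin)
        # full footprints stay disjoint
        if any(
            math.hypot(cx - ox, cy - oy) < reach + orr + 2.0
            for ox, oy, orr in centers
        ):
            continue
        z_half = max(0.6, rng.normal(dials["z_halfspan"], 0.35))
        cz = rng.uniform(z_half, sections - 1 - z_half) if sections - 1 > 2 * z_half \
            else (sections - 1) / 2.0
        depth = max(0.8, rng.normal(dials["nuclei_depth"], 0.6))
        arm_width = float(rng.uniform(2.1, 2.7))
        n_nuclei = max(1, int(rng.poisson(nuclei_rate)))
        specs.append(
            OrganoidSpec(
                center=(cx, cy, cz),
                radius=radius,
                elongation=1.0 + abs(rng.normal(0.0, 0.05)),
                orientation=rng.uniform(0, math.pi),
                n_branches=arm_count,
                branch_length=arm_len,
                branch_width=arm_width,
                branch_lengths=arm_lengths,
                nuclei_count=n_nuclei,
                nuclei_depth=depth,
                nuclei_depth_sd=dials["nuclei_depth_sd"],
                z_halfspan=z_half,
                intensity_scale=float(rng.uniform(0.9, 1.1)),
                texture_sd=dials.get("texture_sd", 0.28),
            )
        )
        centers.append((cx, cy, reach))
    return specs


def _well_dials(spec: PlateSpec, template: EffectTemplate, dose: float,
                potency: float, rng: np.random.Generator) -> dict:
    frac = template.effect_fraction(dose * potency)
    base = spec.baseline
    dials = {
        "arm_length": max(0.5, base["arm_length"] + frac * template.arm_length),
        "arm_count": max(0.0, base["arm_count"] + frac * template.arm_count),
        "radius": max(4.5, base["radius"] + frac * template.radius),
        "n_organoids": max(3.0, base["n_organoids"] + frac * template.n_organoids),
        "z_halfspan": max(0.6, base["z_halfspan"] + frac * template.z_halfspan),
        "nuclei_depth": max(1.0, base["nuclei_depth"] + frac * template.nuclei_depth),
        # per-well nuisance jitters: nuclei seeding density, growth
        # heterogeneity and optics vary well to well, giving all aggregate
        # descriptors a realistic buffer variance
        "nuclei_rate": float(np.exp(rng.normal(math.log(7.0), 0.9))),
        "nuclei_depth_sd": float(rng.uniform(1.4, 2.8)),
        "texture_sd": float(rng.uniform(0.18, 0.38)),
        "arm_count_jitter": float(rng.normal(0.0, 0.4)),
        "nucleus_amp_sd": float(rng.uniform(0.1, 0.4)),

        "radius_sd": float(rng.uniform(0.5, 2.4)),
        "arm_len_sd": float(rng.uniform(0.8, 2.2)),
    }
    return dials


def build_plate_map(spec: PlateSpec) -> pd.DataFrame:
    """Deterministic plate map: wells with role / treatment / dose / replicate.

    Buffer wells are interleaved across the plate (every fourth well),
    mirroring controls distributed across assay plates at 25 % of wells.
    """
    rows = []
    for t in spec.treatments:
        for dose in t.doses:
            for rep in range(1, t.replicates + 1):
                rows.append(("treatment", t.name, dose, rep))
    rng = np.random.default_rng(spec.seed + 1_000_003)
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    records = []
    treat_iter = iter(rows)
    n_buffer = spec.n_buffer_wells
    buffer_every = max(1, spec.n_wells // n_buffer)
    buffer_left = n_buffer
    for i in range(spec.n_wells):
        well = f"W{i + 1:03d}"
        remaining = spec.n_wells - i
        if buffer_left and (i % buffer_every == 0 or remaining <= buffer_left):
            records.append((well, "buffer", "", np.nan, buffer_left))
            buffer_left -= 1
        else:
            role, name, dose, rep = next(treat_iter)
            records.append((well, role, name, dose, rep))
    return pd.DataFrame(
        records, columns=["well", "role", "treatment", "dose", "replicate"]
    )


def iterate_plate_wells(spec: PlateSpec) -> Iterator[tuple[pd.Series, ImageStack, GroundTruth]]:
    """Render the plate one well at a time (constant memory).

    Yields ``(plate-map row, ImageStack, GroundTruth)`` in plate order.
    Buffer wells are rendered from the null template; treatment wells have
    their dials moved along the treatment's effect template by dose.
    """
    plate_map = build_plate_map(spec)
    by_name = {t.name: t for t in spec.treatments}
    seeds = np.random.SeedSequence(spec.seed).spawn(len(plate_map))
    for (_, row), ss in zip(plate_map.iterrows(), seeds):
        rng = np.random.default_rng(ss)
        if row.role == "buffer":
            template, dose, potency = null_template(), 0.0, 1.0
        else:
            t = by_name[row.treatment]
            template, dose, potency = t.template, float(row.dose), t.potency
        dials = _well_dials(spec, template, dose, potency, rng)
        specs = _sample_well_specs(dials, spec.geometry, rng)
        stack, truth = render_well_stack(
            specs,
            geometry=spec.geometry,
            noise_sd=spec.noise_sd * float(rng.uniform(0.7, 1.4)),
            defocus_sections=spec.defocus_sections,
            seed=int(rng.integers(2**31 - 1)),
            well=row.well,
            psf_sigma=float(rng.uniform(0.5, 1.6)),
            defocus_sigma=spec.defocus_sigma,
            illumination=(float(rng.uniform(0.75, 1.25)), float(rng.uniform(0.75, 1.25))),
            background=_BACKGROUND * float(rng.uniform(0.7, 1.3)),
            nucleus_sigma=float(rng.uniform(1.9, 2.5)),
            nucleus_amp_sd=dials.get("nucleus_amp_sd", 0.2),
        )
        truth.class_label = template.name if row.role == "treatment" else "buffer"
        yield row, stack, truth


def generate_plate(spec: PlateSpec) -> tuple[dict[str, ImageStack], dict[str, GroundTruth], pd.DataFrame]:
    """Render a whole plate into memory.

    Returns ``(stacks by well, ground truth by well, plate map)``.  For large
    plates prefer :func:`iterate_plate_wells`, which renders one well at a
    time.
    """
    plate_map = build_plate_map(spec)
    stacks: dict[str, ImageStack] = {}
    truths: dict[str, GroundTruth] = {}
    for row, stack, truth in iterate_plate_wells(spec):
        stacks[row.well] = stack
        truths[row.well] = truth
    return stacks, truths, plate_map


# ---------------------------------------------------------------------------
# feature-table simulation (direct well-level data with planted structure)


def default_class_templates(scale: float = 4.5) -> dict[str, np.ndarray]:
    """Five named 6-vector class centroids, mutually equidistant at
    scale·√2 (> 6 SD at the default scale, unit-variance noise)."""
    patterns = np.array([
        (-1.0, -0.6, -0.8, 0.4, 0.0, -0.6),
        (0.9, -0.3, 0.2, -0.8, -0.4, 0.3),
        (0.0, 1.0, -0.5, 0.0, 0.8, -0.2),
        (-0.4, 0.2, 0.9, 0.9, -0.6, 0.5),
        (0.5, 0.5, 0.4, -0.2, 0.9, -0.9),
    ])
    # orthonormalise so every pair of centroids is equally separated
    q, _ = np.linalg.qr(patterns.T)
    basis = q.T[:5]
    return {name: scale * basis[i] for i, name in enumerate("ABCDE")}


def simulate_feature_table(
    class_templates: dict[str, np.ndarray] | Sequence[np.ndarray],
    n_per_class: int = 20,
    n_noise_features: int = 288,
    effect_sd: float = 1.0,
    seed: int = 0,
    informative_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a well × feature table with planted class structure.

    Informative columns are drawn from the class centroid plus noise of
    standard deviation ``effect_sd``; the remaining columns are pure
    standard-normal noise.  Column count defaults to 294 (6 informative +
    288 noise).  Returns the table and the true class labels.
    """
    if isinstance(class_templates, dict):
        names = list(class_templates)
        centroids = [np.asarray(class_templates[k], dtype=float) for k in names]
    else:
        centroids = [np.asarray(c, dtype=float) for c in class_templates]
        names = [f"class{i + 1}" for i in range(len(centroids))]
    if len(centroids) < 2:
        raise ValueError("clustering is undefined for fewer than 2 class templates")
    if n_per_class < 2:
        raise ValueError("need at least 2 observations per class")
    dim = len(centroids[0])
    if any(len(c) != dim for c in centroids):
        raise ValueError("all class centroids must have the same dimension")

    rng = np.random.default_rng(seed)
    if informative_names is None:
        informative_names = [f"signal_{i + 1}" for i in range(dim)]
    noise_names = [f"noise_{i + 1}" for i in range(n_noise_features)]

    blocks, labels = [], []
    for name, c in zip(names, centroids):
        info = c[None, :] + rng.normal(0.0, effect_sd, size=(n_per_class, dim))
        noise = rng.normal(0.0, 1.0, size=(n_per_class, n_noise_features))
        blocks.append(np.hstack([info, noise]))
        labels.extend([name] * n_per_class)
    data = np.vstack(blocks)
    index = [f"well{i + 1:03d}" for i in range(len(data))]
    table = pd.DataFrame(data, index=index, columns=list(informative_names) + noise_names)
    return table, pd.Series(labels, index=index, name="class")
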