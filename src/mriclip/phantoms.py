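"""Synthetic multi-sequence MRI phantom studies with known ground truth.

Each study is a small set of 3D volumes ("sequences") sharing one patient's
anatomy: an ellipsoidal head whose size shrinks linearly with age (an
"atrophy" signal), low-frequency texture, and Rician-style magnitude noise.
Diagnosis classes plant distinct geometric lesions (bright sphere, ring,
paired ellipsoids, wedge) at recorded voxel locations, visible only in
class-appropriate sequence types, and each planted class emits one templated
finding string.  Cohorts add subgroup metadata (region, scheduling, sex,
age band, insurer, scanner) and turnaround times with optionally planted
odds-ratio bias, so the fairness suite can audit a known effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

PLANES = ("axial", "coronal", "sagittal")
ORIENTATIONS = ("LPS", "RPS", "LAS", "RAS", "LPI", "RPI", "LAI", "RAI")
ACUITY_LEVELS = ("normal", "medium", "high")


class ConfigurationError(ValueError):
    """Raised for unknown lesion classes or malformed generator settings."""


@dataclass
class MRIVolume:
    voxels: np.ndarray            # 3D float array
    spacing: tuple                # (mm, mm, mm)
    plane: str
    orientation: str
    sequence_name: str

    def __post_init__(self):
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("volume must be 3D with all dims >= 1")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume intensities must be finite")
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class MRIStudy:
    study_name: str
    sequences: list               # of MRIVolume
    patient_id: str
    abnormal: bool
    # ground truth retained for explainability validation:
    # class name -> {sequence index -> boolean voxel mask}
    lesion_masks: dict = field(default_factory=dict)


@dataclass
class ReportRecord:
    findings: list                # of short strings, ordered
    labels: np.ndarray            # L-dim multi-hot
    acuity: str                   # in ACUITY_LEVELS
    age: float                    # years
    referrals: np.ndarray         # R-dim multi-hot


@dataclass
class SubgroupMetadata:
    attributes: dict              # name -> categorical value
    turnaround_days: float


# ---------------------------------------------------------------------------
# configuration

LESION_SHAPES = ("sphere", "ring", "paired", "wedge")

DEFAULT_CATALOG = ("tumor", "abscess", "ventriculomegaly", "infarct")

DEFAULT_LESION_SHAPE = {
    "tumor": "sphere",
    "abscess": "ring",
    "ventriculomegaly": "paired",
    "infarct": "wedge",
}

SEQUENCE_TYPES = ("T1", "T2", "FLAIR", "DWI")

# class -> extra amplitude multiplier per sequence type (1.0 elsewhere)
DEFAULT_TYPE_BOOST = {
    "abscess": {"DWI": 1.6},
    "infarct": {"DWI": 1.8},
}

# class -> sequence types in which its lesion is visible
DEFAULT_VISIBILITY = {
    "tumor": ("T1", "T2", "FLAIR"),
    "abscess": ("T2", "FLAIR", "DWI"),
    "ventriculomegaly": ("T1", "T2", "FLAIR", "DWI"),
    "infarct": ("DWI", "FLAIR"),
}

DEFAULT_ACUITY_MAP = {
    "tumor": "high",
    "infarct": "high",
    "abscess": "medium",
    "ventriculomegaly": "medium",
}

DEFAULT_REFERRALS = ("neurosurgery", "neurology", "infectious_disease")

DEFAULT_REFERRAL_MAP = {
    "tumor": ("neurosurgery",),
    "abscess": ("neurosurgery", "infectious_disease"),
    "ventriculomegaly": ("neurosurgery",),
    "infarct": ("neurology",),
}

DESK_SHAPES = ((32, 32, 16), (32, 32, 12), (24, 24, 16))
PAPER_SHAPES = ((256, 256, 32), (256, 256, 24))

PLANE_PREFIX = {"axial": "AX", "coronal": "COR", "sagittal": "SAG"}

STUDY_NAMES = (
    "MRI BRAIN WITHOUT CONTRAST",
    "MRI BRAIN WITH AND WITHOUT CONTRAST",
    "MRI BRAIN STEALTH PROTOCOL",
)

NORMAL_FINDING = "no acute intracranial abnormality"


@dataclass
class GeneratorConfig:
    catalog: tuple = DEFAULT_CATALOG
    lesion_shape: dict = field(default_factory=lambda: dict(DEFAULT_LESION_SHAPE))
    visibility: dict = field(default_factory=lambda: dict(DEFAULT_VISIBILITY))
    acuity_map: dict = field(default_factory=lambda: dict(DEFAULT_ACUITY_MAP))
    referrals: tuple = DEFAULT_REFERRALS
    referral_map: dict = field(default_factory=lambda: dict(DEFAULT_REFERRAL_MAP))
    shapes: tuple = DESK_SHAPES
    n_sequences: tuple = (2, 4)     # inclusive range
    snr: float = 20.0               # head intensity over noise sigma
    head_intensity: float = 0.6
    lesion_intensity: float = 0.9
    lesion_radius_frac: tuple = (0.35, 0.5)    # of half the head radius span
    age_range: tuple = (20.0, 90.0)
    # head scale = scale_at_20 - atrophy_per_year * (age - 20) + noise;
    # noise sigma expressed in equivalent years of age
    scale_at_20: float = 1.0
    atrophy_per_year: float = 0.004
    age_noise_years: float = 5.0
    base_long_turnaround_prob: float = 0.2
    long_turnaround_days: float = 7.0

    def __post_init__(self):
        if len(self.catalog) < 2:
            raise ConfigurationError("label catalog needs >= 2 classes")
        for c in self.catalog:
            if self.lesion_shape.get(c) not in LESION_SHAPES:
                raise ConfigurationError(f"class {c!r} has no valid lesion shape")


DEFAULT_ATTRIBUTES = {
    "region": (("urban", "suburban", "rural"), (0.5, 0.3, 0.2)),
    "schedule": (("routine", "stat"), (0.8, 0.2)),
    "sex": (("F", "M"), (0.5, 0.5)),
    "insurer": (("insurer_a", "insurer_b", "insurer_c"), (0.4, 0.4, 0.2)),
    "scanner": (("scanner_1", "scanner_2", "scanner_3"), (0.4, 0.3, 0.3)),
}


# ---------------------------------------------------------------------------
# geometry helpers

def _normalized_grid(shape):
    """Coordinate grids in [-1, 1] per axis."""
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    return np.meshgrid(*axes, indexing="ij")


def _head_mask(shape, scale):
    gx, gy, gz = _normalized_grid(shape)
    r2 = (gx / (0.85 * scale)) ** 2 + (gy / (0.85 * scale)) ** 2 + (gz / (0.9 * scale)) ** 2
    return r2 <= 1.0


def _lesion_pattern(shape, kind, center, radius, wedge_dirs=None):
    """(mask, relative intensity map) for one lesion.

    Shapes carry distinct intensity signatures as well as geometry so the
    classes remain separable after aggressive latent compression: bright
    solid sphere; very bright rim around a dark core (ring); brightest
    striped paired ellipsoids; moderate wedge sector.  Lesions are larger
    than a patch, so interior tokens must carry the class signature
    themselves.
    """
    gx, gy, gz = _normalized_grid(shape)
    dx, dy, dz = gx - center[0], gy - center[1], gz - center[2]
    r = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    ix, iy, iz = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    amp = np.zeros(shape)
    if kind == "sphere":
        mask = r <= radius
        amp[mask] = 1.0                              # homogeneous bright
    elif kind == "ring":
        mask = r <= radius
        rim = mask & (r >= 0.55 * radius)
        core = r < 0.55 * radius
        amp[rim] = 1.8                               # very bright capsule
        amp[core] = -0.6                             # dark necrotic core
    elif kind == "paired":
        off = 0.6 * radius
        m1 = ((gx - (center[0] - off)) ** 2 + dy ** 2 + dz ** 2) <= (0.8 * radius) ** 2
        m2 = ((gx - (center[0] + off)) ** 2 + dy ** 2 + dz ** 2) <= (0.8 * radius) ** 2
        mask = m1 | m2
        stripes = 1.0 + 0.25 * np.sin(2 * np.pi * iz / 4.0)  # axial striping
        amp[mask] = (2.6 * stripes)[mask]            # brightest class
    elif kind == "wedge":
        u1, u2 = wedge_dirs
        d = np.stack([dx, dy, dz], axis=-1)
        mask = (r <= 1.5 * radius) & (d @ u1 > 0) & (d @ u2 > 0)
        amp[mask] = 0.75                             # moderate sector
    else:
        raise ConfigurationError(f"unknown lesion kind {kind!r}")
    return mask, amp


def _region_descriptor(center):
    lr = "left" if center[0] < 0 else "right"
    ap = "frontal" if center[1] < 0 else "occipital"
    si = "superior" if center[2] >= 0 else "inferior"
    return f"{lr} {ap} {si} region"


def finding_text(class_name, descriptor):
    """Fixed report grammar: '<class name> in <region descriptor>'."""
    return f"{class_name} in {descriptor}"


def render_report(record: ReportRecord) -> str:
    """Render findings as the numbered itemized report used for alignment."""
    if not record.findings:
        return f"1. {NORMAL_FINDING}"
    return "\n".join(f"{i + 1}. {f}" for i, f in enumerate(record.findings))


# ---------------------------------------------------------------------------
# study generation

def _draw_sequence_types(rng, required_types, n_range):
    lo, hi = n_range
    m = int(rng.integers(lo, hi + 1))
    types = list(required_types)
    while len(types) < max(m, 2, len(required_types)):
        t = SEQUENCE_TYPES[rng.integers(len(SEQUENCE_TYPES))]
        if t not in types:
            types.append(t)
        elif len(set(SEQUENCE_TYPES) - set(types)) == 0:
            break
    rng.shuffle(types)
    return types


def generate_study(seed, lesion_classes=(), size_preset="desk",
                   config: GeneratorConfig | None = None, age=None,
                   patient_id=None):
    """Generate one phantom (MRIStudy, ReportRecord) pair.

    Deterministic in `seed`.  Every requested lesion class plants its
    geometric signature at a recorded location visible in a class-specific
    subset of sequences; the findings list holds one templated string per
    planted class.
    """
    config = config or GeneratorConfig(
        shapes=DESK_SHAPES if size_preset == "desk" else PAPER_SHAPES)
    catalog = config.catalog
    lesion_classes = list(lesion_classes)
    for c in lesion_classes:
        if c not in catalog:
            raise ConfigurationError(f"unknown lesion class {c!r}")

    rng = np.random.default_rng(seed)
    if age is None:
        age = float(rng.uniform(*config.age_range))
    scale = (config.scale_at_20
             - config.atrophy_per_year * (age - config.age_range[0])
             + rng.normal(0.0, config.atrophy_per_year * config.age_noise_years))
    scale = float(np.clip(scale, 0.55, 1.05))

    # one sequence type able to show each planted class
    required = []
    for c in lesion_classes:
        vis = config.visibility[c]
        pick = vis[rng.integers(len(vis))]
        if pick not in required:
            required.append(pick)
    seq_types = _draw_sequence_types(rng, required, config.n_sequences)

    # shared anatomy: lesion centers/sizes in normalized coordinates
    lesion_geom = {}
    for c in lesion_classes:
        center = rng.uniform(-0.45, 0.45, size=3) * scale
        radius = float(rng.uniform(*config.lesion_radius_frac))
        wedge_dirs = None
        if config.lesion_shape[c] == "wedge":
            u1 = rng.normal(size=3)
            u1 /= np.linalg.norm(u1)
            u2 = rng.normal(size=3)
            u2 -= (u2 @ u1) * u1
            u2 /= np.linalg.norm(u2)
            wedge_dirs = (u1, u2)
        lesion_geom[c] = (center, radius, wedge_dirs)

    sigma = config.head_intensity / config.snr
    sequences, lesion_masks = [], {c: {} for c in lesion_classes}
    for si, stype in enumerate(seq_types):
        shape = config.shapes[rng.integers(len(config.shapes))]
        plane = PLANES[rng.integers(len(PLANES))]
        orientation = ORIENTATIONS[rng.integers(len(ORIENTATIONS))]
        # per-type contrast so sequence names carry information
        contrast = {"T1": 1.0, "T2": 0.8, "FLAIR": 0.9, "DWI": 0.7}[stype]
        head = _head_mask(shape, scale)
        texture = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
        img = np.zeros(shape, dtype=np.float64)
        img[head] = config.head_intensity * contrast * (1.0 + 0.3 * texture[head])
        for c in lesion_classes:
            center, radius, wdirs = lesion_geom[c]
            mask, amp = _lesion_pattern(shape, config.lesion_shape[c], center,
                                        radius, wdirs)
            mask &= head
            if stype in config.visibility[c]:
                boost = DEFAULT_TYPE_BOOST.get(c, {}).get(stype, 1.0)
                img[mask] += config.lesion_intensity * boost * amp[mask]
                lesion_masks[c][si] = mask
        # Rician-style magnitude noise: |signal + complex Gaussian|
        img = np.abs(img + rng.normal(0, sigma, shape)
                     + 1j * rng.normal(0, sigma, shape))
        name = f"{PLANE_PREFIX[plane]}_{stype}"
        if rng.random() < 0.3:
            name = name.lower()
        sequences.append(MRIVolume(
            voxels=img.astype(np.float32),
            spacing=(1.0, 1.0, 4.0), plane=plane, orientation=orientation,
            sequence_name=name))

    labels = np.array([1 if c in lesion_classes else 0 for c in catalog],
                      dtype=np.int64)
    findings = [finding_text(c, _region_descriptor(lesion_geom[c][0]))
                for c in catalog if c in lesion_classes]
    acuity = "normal"
    if lesion_classes:
        levels = [config.acuity_map[c] for c in lesion_classes]
        acuity = "high" if "high" in levels else "medium"
    referrals = np.zeros(len(config.referrals), dtype=np.int64)
    for c in lesion_classes:
        for ref in config.referral_map.get(c, ()):
            referrals[config.referrals.index(ref)] = 1

    study = MRIStudy(
        study_name=STUDY_NAMES[rng.integers(len(STUDY_NAMES))],
        sequences=sequences,
        patient_id=patient_id or f"P{seed % 10 ** 8:08d}",
        abnormal=bool(labels.any()),
        lesion_masks=lesion_masks,
    )
    record = ReportRecord(findings=findings, labels=labels, acuity=acuity,
                          age=age, referrals=referrals)
    return study, record


# ---------------------------------------------------------------------------
# cohort generation

def _draw_turnaround(rng, attrs, bias_spec, config):
    p = config.base_long_turnaround_prob
    odds = p / (1.0 - p)
    for (attr, value), mult in (bias_spec or {}).items():
        if attrs.get(attr) == value:
            odds *= mult
    p_long = odds / (1.0 + odds)
    if rng.random() < p_long:
        return config.long_turnaround_days + float(rng.exponential(5.0))
    return float(rng.uniform(0.25, config.long_turnaround_days))


def generate_cohort(n, class_prevalences, bias_spec=None, seed=0,
                    config: GeneratorConfig | None = None, size_preset="desk"):
    """Generate n (MRIStudy, ReportRecord, SubgroupMetadata) triples.

    `class_prevalences` gives an independent Bernoulli rate per catalog
    class; `bias_spec` maps (attribute, value) pairs to odds multipliers on
    the probability that report turnaround exceeds the configured long
    threshold (default 7 days).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    config = config or GeneratorConfig(
        shapes=DESK_SHAPES if size_preset == "desk" else PAPER_SHAPES)
    prev = np.asarray(class_prevalences, dtype=float)
    if prev.shape != (len(config.catalog),):
        raise ValueError("one prevalence per catalog class required")
    if np.any(prev < 0) or np.any(prev > 1):
        raise ValueError("prevalences must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        classes = [c for c, p in zip(config.catalog, prev) if rng.random() < p]
        study_seed = int(rng.integers(2 ** 31))
        study, record = generate_study(
            study_seed, classes, config=config, patient_id=f"P{seed}_{i:05d}")
        attrs = {}
        for name, (values, probs) in DEFAULT_ATTRIBUTES.items():
            attrs[name] = values[rng.choice(len(values), p=probs)]
        attrs["age_band"] = ("under_40" if record.age < 40
                             else "40_to_65" if record.age < 65 else "over_65")
        meta = SubgroupMetadata(
            attributes=attrs,
            turnaround_days=_draw_turnaround(rng, attrs, bias_spec, config))
        out.append((study, record, meta))
    return out
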