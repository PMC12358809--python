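"""Synthetic multi-site cohorts: phenotypes, diagnosis trajectories, volumes.

The generator emulates the structure of multi-dataset AD neuroimaging
studies: several datasets, each with one or more scanner models; CN, AD and
MCI groups with sex labels and baseline ages; longitudinal diagnosis
trajectories for MCI subjects; and registered 3D volumes rendered as

    clip(template
         + age_amplitude * (brain_age - age_ref) * P_age
         + disease_amplitude * severity * P_dis
         + site_offset + site_gain * template
         + noise, 0, 255)

where ``brain_age = age + brain_age_offset`` adds a per-subject normal
deviation (``aging_variability_sd`` years) capturing individual variation
in brain aging — the biological component of brain-age-gap variance.

quantized to 8-bit integers.  ``P_age`` and ``P_dis`` are smooth unit-norm
spatial patterns built from smoothed Gaussian random fields; their cosine
similarity is controlled exactly by ``overlap_rho`` via
``P_dis = rho * P_age + sqrt(1 - rho^2) * P_perp``.  With ``overlap_rho = 1``
disease is pure accelerated aging; with ``overlap_rho = 0`` the disease
pattern is orthogonal to the aging pattern.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, UsageError, ValidationError

GROUPS = ("CN", "AD", "sMCI", "pMCI")
PMCI_WINDOW_MONTHS = 36


@dataclass
class GeneratorConfig:
    volume_shape: tuple[int, int, int] = (32, 40, 32)
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"CN": 20, "AD": 20, "sMCI": 10, "pMCI": 10})
    datasets: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("DSA", ("scA1", "scA2")), ("DSB", ("scB1",)))
    age_range: tuple[float, float] = (55.0, 90.0)
    age_amplitude: float = 60.0
    aging_variability_sd: float = 5.0   # per-subject brain-age offset, years
    disease_amplitude: float = 100.0
    disease_pattern_scale: float = 3.0  # P_dis is this much finer-grained than P_age
    overlap_rho: float = 0.0
    noise_sd: float = 4.0
    site_offset_sd: float = 3.0
    site_gain_sd: float = 0.05
    progression_hazard: float = 1.0
    visit_months: tuple[int, ...] = (0, 12, 24, 36, 48)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.volume_shape = tuple(int(s) for s in self.volume_shape)
        if any(s <= 0 for s in self.volume_shape):
            raise ConfigurationError(f"volume_shape: must be strictly positive, got {self.volume_shape}")
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ConfigurationError(f"n_per_group: unknown group {g!r}")
            if n < 0:
                raise ConfigurationError(f"n_per_group: count for {g} must be >= 0, got {n}")
        if not 0.0 <= self.overlap_rho <= 1.0:
            raise ConfigurationError(f"overlap_rho: must be in [0, 1], got {self.overlap_rho}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError(f"age_range: low must be < high, got {self.age_range}")
        if self.noise_sd < 0 or self.site_offset_sd < 0 or self.site_gain_sd < 0:
            raise ConfigurationError("noise_sd/site_offset_sd/site_gain_sd: must be >= 0")
        if self.aging_variability_sd < 0:
            raise ConfigurationError(
                f"aging_variability_sd: must be >= 0, got {self.aging_variability_sd}")
        if self.disease_pattern_scale < 1.0:
            raise ConfigurationError(
                f"disease_pattern_scale: must be >= 1, got {self.disease_pattern_scale}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError(f"missing_rate: must be in [0, 1), got {self.missing_rate}")
        if list(self.visit_months) != sorted(set(self.visit_months)) or self.visit_months[0] != 0:
            raise ConfigurationError("visit_months: must start at 0 and be strictly increasing")

    @property
    def age_ref(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])


@dataclass
class SubjectRecord:
    subject_id: str
    dataset_id: str
    scanner_id: str
    sex: str
    age: float
    group: str              # clinical group at baseline: CN, AD or MCI
    severity: float         # latent disease burden; 0 for CN
    brain_age_offset: float = 0.0   # individual deviation of brain age, years
    visits: list[tuple[int, str]] = field(default_factory=list)
    intended_label: str = ""  # generator-side CN/AD/sMCI/pMCI designation


@dataclass
class Volume:
    voxels: np.ndarray      # integer intensities in [0, 255]
    subject_id: str = ""
    intensity_range: tuple[int, int] = (0, 255)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        lo, hi = self.intensity_range
        if self.voxels.min() < lo or self.voxels.max() > hi:
            raise ValidationError(
                f"intensities outside [{lo}, {hi}]: "
                f"range [{self.voxels.min()}, {self.voxels.max()}]")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.voxels.shape)


# ---------------------------------------------------------------------------
# Spatial patterns and site effects (deterministic in config.seed)
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return f / np.linalg.norm(f)


def make_patterns(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(template, P_age, P_dis): template plus two unit-norm smooth patterns
    with <P_age, P_dis> = overlap_rho exactly."""
    shape = config.volume_shape
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9A77]))
    sigma = max(min(shape) / 8.0, 1.0)
    # brain-like template: bright ellipsoid interior on a dark background
    grids = np.meshgrid(*[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij")
    r2 = sum(g**2 for g in grids)
    template = 20.0 + 140.0 * np.exp(-2.5 * r2)
    p_age = _smooth_field(rng, shape, sigma)
    # the disease component is more focal than diffuse aging: its random
    # field is smoothed at a finer scale before orthogonalization
    raw = _smooth_field(rng, shape, sigma / config.disease_pattern_scale)
    perp = raw - np.vdot(raw, p_age) * p_age
    perp /= np.linalg.norm(perp)
    rho = config.overlap_rho
    p_dis = rho * p_age + np.sqrt(max(1.0 - rho**2, 0.0)) * perp
    return template.astype(np.float64), p_age, p_dis


def site_effects(config: GeneratorConfig) -> dict[str, tuple[float, float]]:
    """Per-scanner (additive offset, multiplicative gain), drawn once."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x517E]))
    effects = {}
    for _, scanners in config.datasets:
        for sc in scanners:
            offset = rng.normal(0.0, config.site_offset_sd)
            gain = rng.normal(0.0, config.site_gain_sd)
            effects[sc] = (float(offset), float(gain))
    return effects


def _subject_rng(config: GeneratorConfig, subject_id: str, salt: int) -> np.random.Generator:
    h = zlib.crc32(subject_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt, h]))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_volume(subject: SubjectRecord, config: GeneratorConfig,
                  _cache: dict | None = None) -> Volume:
    """Render one subject's 8-bit volume from the generative formula."""
    if _cache is not None and "patterns" in _cache:
        template, p_age, p_dis = _cache["patterns"]
        sites = _cache["sites"]
    else:
        template, p_age, p_dis = make_patterns(config)
        sites = site_effects(config)
        if _cache is not None:
            _cache["patterns"] = (template, p_age, p_dis)
            _cache["sites"] = sites
    offset, gain = sites.get(subject.scanner_id, (0.0, 0.0))
    rng = _subject_rng(config, subject.subject_id, 0xF00D)
    noise = rng.normal(0.0, config.noise_sd, size=config.volume_shape) \
        if config.noise_sd > 0 else 0.0
    brain_age = subject.age + subject.brain_age_offset
    vox = (template
           + config.age_amplitude * (brain_age - config.age_ref) * p_age
           + config.disease_amplitude * subject.severity * p_dis
           + offset + gain * template
           + noise)
    vox = np.clip(np.rint(vox), 0, 255).astype(np.uint8)
    return Volume(voxels=vox, subject_id=subject.subject_id)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def _hazard(config: GeneratorConfig, severity: float) -> float:
    from scipy.special import expit

    return float(expit(config.progression_hazard * severity))


def generate_trajectory(subject: SubjectRecord, config: GeneratorConfig
                        ) -> SubjectRecord:
    """Fill an MCI subject's visits by a per-visit conversion hazard.

    At each follow-up visit conversion to AD occurs with probability
    ``h = logistic(progression_hazard * severity)``; once converted, every
    later visit is AD.  Optional missingness replaces follow-up diagnoses
    with "missing" at ``missing_rate``.
    """
    if subject.group != "MCI":
        raise UsageError(f"generate_trajectory requires an MCI subject, got group {subject.group!r}")
    h = _hazard(config, subject.severity)
    rng = _subject_rng(config, subject.subject_id, 0x7A47)
    visits: list[tuple[int, str]] = [(0, "MCI")]
    converted = False
    for month in config.visit_months[1:]:
        if not converted and rng.random() < h:
            converted = True
        dx = "AD" if converted else "MCI"
        if config.missing_rate > 0 and rng.random() < config.missing_rate:
            dx = "missing"
        visits.append((month, dx))
    return replace(subject, visits=visits)


def _conditional_trajectory(subject: SubjectRecord, config: GeneratorConfig,
                            progressor: bool) -> list[tuple[int, str]]:
    """Trajectory conditioned on the designated stable/progressive label.

    Progressors draw their conversion visit from the per-visit hazard
    restricted to follow-ups within the 36-month window; stable subjects
    remain MCI at every visit.  This lets the cohort hit requested
    sMCI/pMCI counts exactly while preserving the hazard's shape.
    """
    follow_ups = list(config.visit_months[1:])
    if not progressor:
        return [(0, "MCI")] + [(m, "MCI") for m in follow_ups]
    window = [m for m in follow_ups if m <= PMCI_WINDOW_MONTHS]
    if not window:
        raise ConfigurationError("visit_months: no follow-up within 36 months for pMCI subjects")
    h = _hazard(config, subject.severity)
    h = min(max(h, 1e-9), 1.0)
    # geometric conversion-time pmf truncated to the window
    pmf = np.array([(1.0 - h) ** j * h for j in range(len(window))])
    pmf /= pmf.sum()
    rng = _subject_rng(config, subject.subject_id, 0x7A47)
    conv_idx = int(rng.choice(len(window), p=pmf))
    conv_month = window[conv_idx]
    return [(0, "MCI")] + [(m, "AD" if m >= conv_month else "MCI") for m in follow_ups]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_SEVERITY = {  # (mean, sd) of truncated-normal latent burden per label
    "CN": (0.0, 0.0),
    "AD": (2.0, 0.3),
    "pMCI": (1.5, 0.3),
    "sMCI": (0.7, 0.25),
}


def generate_cohort(config: GeneratorConfig, render: bool = True
                    ) -> tuple[list[SubjectRecord], dict[str, Volume]]:
    """Generate the full cohort: records (with visits) and rendered volumes.

    Deterministic given the config (including its seed).  Per-scanner group
    counts match ``n_per_group`` exactly; MCI subjects carry trajectories
    consistent with their designated stable/progressive label.
    """
    records: list[SubjectRecord] = []
    for ds_id, scanners in config.datasets:
        for sc_id in scanners:
            for label in GROUPS:
                n = config.n_per_group.get(label, 0)
                for i in range(n):
                    sid = f"{ds_id}-{sc_id}-{label}-{i:04d}"
                    rng = _subject_rng(config, sid, 0x5EED)
                    age = float(rng.uniform(*config.age_range))
                    sex = "F" if rng.random() < 0.5 else "M"
                    mu, sd = _SEVERITY[label]
                    severity = float(abs(rng.normal(mu, sd))) if mu > 0 else 0.0
                    offset = float(rng.normal(0.0, config.aging_variability_sd)) \
                        if config.aging_variability_sd > 0 else 0.0
                    group = "MCI" if label in ("sMCI", "pMCI") else label
                    rec = SubjectRecord(subject_id=sid, dataset_id=ds_id,
                                        scanner_id=sc_id, sex=sex, age=age,
                                        group=group, severity=severity,
                                        brain_age_offset=offset,
                                        intended_label=label)
                    if group == "MCI":
                        rec.visits = _conditional_trajectory(
                            rec, config, progressor=(label == "pMCI"))
                    else:
                        rec.visits = [(m, group) for m in config.visit_months]
                    records.append(rec)
    volumes: dict[str, Volume] = {}
    if render:
        cache: dict = {}
        for rec in records:
            volumes[rec.subject_id] = render_volume(rec, config, _cache=cache)
    return records, volumes


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def phenotype_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Long-format phenotype table (one row per subject-visit)."""
    rows = []
    for r in records:
        for month, dx in r.visits:
            rows.append({"subject_id": r.subject_id, "dataset_id": r.dataset_id,
                         "scanner_id": r.scanner_id, "sex": r.sex,
                         "age": r.age, "group": r.group, "severity": r.severity,
                         "visit_month": month, "diagnosis": dx})
    return pd.DataFrame(rows)


def write_phenotypes(records: list[SubjectRecord], path) -> None:
    phenotype_table(records).to_csv(path, sep="\t", index=False)


def write_volumes(volumes: dict[str, Volume], out_dir) -> None:
    """One NIfTI (.nii.gz) file per subject, identity affine."""
    import nibabel as nib
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, vol in volumes.items():
        img = nib.Nifti1Image(vol.voxels.astype(np.uint8), affine=np.eye(4))
        nib.save(img, out / f"{sid}.nii.gz")


def read_volume(path) -> Volume:
    import nibabel as nib
    from pathlib import Path

    p = Path(path)
    arr = np.asarray(nib.load(p).dataobj)
    return Volume(voxels=arr, subject_id=p.name.split(".")[0])
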