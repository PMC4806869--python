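"""Synthetic EIT phantom cohort for a low-flow inflation maneuver.

The clinical recordings behind the ROI-comparison study are not publicly
deposited, so this module generates 32×32 frame sequences with the
statistical structure the analysis assumes:

* two elliptical lungs, left–right symmetric in expectation, with a
  smooth positive ventilation-amplitude field driven by a monotonic
  raised-cosine inflation ramp (a quasi-static pressure–volume maneuver
  at constant flow, not a mechanics model — the analysis only consumes
  per-pixel extrema and cardiac-band content);
* per-subject anatomical variability in both groups — lung size and
  position jitter, a mild left/right amplitude imbalance, a random
  dorsoventral ventilation gradient and a smooth multiplicative
  amplitude texture — so that inhomogeneity indices spread realistically
  within each group instead of being pinned by a fixed geometry;
* a Gaussian reconstruction point-spread blur, emulating the heavy
  spatial smoothing of EIT difference reconstructions;
* a global compliance scale per subject drawn from the respective group's
  respiratory-system compliance distribution (ARDS stiffer than control);
  the inhomogeneity indices are scale-invariant, so this carries no
  group information by itself;
* for ARDS subjects only, a disease pattern with two components: a
  diffuse one-sided aeration-loss texture (patchy injury) and one to
  three focal hypoventilated/atelectatic patches, biased to one side
  and dorsally, each attenuating the local amplitude by a factor drawn
  from U(0, 0.4);
* a small ventral-central cardiac patch oscillating at the subject's
  heart rate (drawn from 60–100/min), peak-to-peak 20% of the mean lung
  ventilation amplitude;
* a fraction of lung-boundary pixels given inverted-sign ventilation so
  every subject's ΔZ image contains negative (out-of-phase) pixels;
* additive white per-frame noise, SD 1% of the subject's peak
  ventilation amplitude (per-pixel max-min over a 750-frame maneuver
  amplifies a white noise floor roughly sevenfold, so this corresponds
  to an image-domain noise floor near 7% of peak ΔZ).

All randomness flows from a single seed via numpy ``SeedSequence``
spawning, so cohorts are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .errors import InvalidGeometryError, InvalidParametersError
from .frames import DEFAULT_SAMPLE_RATE, FrameSequence, Group, default_pixel_mask


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and noise model of the synthetic cohort (defaults = study conditions)."""

    rows: int = 32
    cols: int = 32
    maneuver_duration: float = 30.0      # s; slow constant-flow inflation
    sample_rate: float = DEFAULT_SAMPLE_RATE
    # lung geometry: two ellipses mirrored about the vertical midline
    lung_center_row: float = 16.0
    lung_center_col_offset: float = 7.2  # distance of each lung center from midline
    lung_semi_row: float = 14.0
    lung_semi_col: float = 8.2
    amplitude_profile: str = "plateau"   # "plateau" (1-rho^8), "smooth" (cos^2) or "uniform"
    # per-subject anatomical variability (both groups)
    lung_size_jitter: tuple[float, float] = (0.85, 1.1)   # semi-axis multiplier
    lung_center_row_jitter: float = 1.5                   # ± pixels
    lateral_imbalance: tuple[float, float] = (0.75, 1.0)  # weaker-lung peak factor
    dorsoventral_gradient: tuple[float, float] = (-0.3, 0.3)
    texture_strength: float = 0.15       # log-amplitude SD of smooth texture
    texture_sigma: float = 2.0           # texture correlation length, pixels
    psf_sigma: float = 2.0               # reconstruction point-spread, pixels
    # group compliance (ml/mbar): relative amplitude scale, control as reference
    compliance_ards: tuple[float, float] = (57.0, 20.0)     # mean, SD
    compliance_control: tuple[float, float] = (88.0, 17.0)  # mean, SD
    # ARDS disease model: diffuse heterogeneity plus focal defect patches
    defects_enabled: bool = True
    diffuse_severity: float = 0.40       # extra log-amplitude SD (ARDS only)
    n_defects_range: tuple[int, int] = (1, 3)
    defect_radius_range: tuple[float, float] = (3.5, 7.0)       # pixels
    defect_attenuation_range: tuple[float, float] = (0.0, 0.4)  # amplitude multiplier
    defect_side_bias: float = 0.85       # P(defect lands on the affected side)
    defect_dorsal_bias: tuple[float, float] = (-0.2, 0.8)  # row offset, lung semi-rows
    # cardiac model
    heart_center: tuple[float, float] = (10.0, 18.0)  # ventral-central, subject-left
    heart_radius: float = 2.8
    cardiac_amplitude_fraction: float = 0.20  # sine amplitude / mean lung amplitude
    heart_rate_range: tuple[float, float] = (60.0, 100.0)  # beats/min
    # out-of-phase (negative ΔZ) boundary pixels
    out_of_phase_fraction: float = 0.10
    out_of_phase_amplitude: float = 0.15  # relative to peak ventilation amplitude
    out_of_phase_shell: tuple[float, float] = (1.0, 1.25)  # elliptical radii
    noise_sd: float = 0.01  # per-frame white noise, relative to peak amplitude

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise InvalidGeometryError(f"grid must be >= 2x2, got {self.rows}x{self.cols}")
        if self.lung_semi_row <= 0 or self.lung_semi_col <= 0:
            raise InvalidGeometryError("lung semi-axes must be positive")
        lo, hi = self.defect_attenuation_range
        if not (0.0 <= lo <= hi < 1.0 or (lo == hi == 0.0)):
            raise InvalidParametersError(
                f"defect attenuation must lie in [0, 1), got {self.defect_attenuation_range}"
            )
        if self.amplitude_profile not in ("plateau", "smooth", "uniform"):
            raise InvalidParametersError(
                "amplitude_profile must be 'plateau', 'smooth' or 'uniform', "
                f"got {self.amplitude_profile!r}"
            )
        if self.maneuver_duration * self.sample_rate < 2:
            raise InvalidParametersError("maneuver must span at least 2 frames")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomParams":
        fields = {f: tuple(v) if isinstance(v, list) else v for f, v in data.items()}
        return cls(**fields)

    @classmethod
    def idealized(cls, **overrides) -> "PhantomParams":
        """A noiseless, variability-free phantom: uniform lung amplitude, no
        cardiac signal, no defects, no out-of-phase pixels, no blur.
        Useful as an analytically checkable base case."""
        base = dict(
            amplitude_profile="uniform",
            defects_enabled=False,
            cardiac_amplitude_fraction=0.0,
            out_of_phase_fraction=0.0,
            noise_sd=0.0,
            lung_size_jitter=(1.0, 1.0),
            lung_center_row_jitter=0.0,
            lateral_imbalance=(1.0, 1.0),
            dorsoventral_gradient=(0.0, 0.0),
            texture_strength=0.0,
            psf_sigma=0.0,
        )
        base.update(overrides)
        return cls(**base)


def _elliptical_radius(
    rows: int, cols: int, center_row: float, center_col: float,
    semi_row: float, semi_col: float,
) -> np.ndarray:
    r = np.arange(rows)[:, None] + 0.5
    c = np.arange(cols)[None, :] + 0.5
    return np.hypot((r - center_row) / semi_row, (c - center_col) / semi_col)


def _smooth(field: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0.0:
        return field
    return ndimage.gaussian_filter(field, sigma)


def _subject_anatomy(
    params: PhantomParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Draw one subject's lung geometry and ventilation-amplitude field.

    Returns (amplitude field, elliptical radius field, geometry dict); the
    radius field is the minimum over both lungs and defines lung interior
    (rho < 1) and the boundary shell.
    """
    semi_row = params.lung_semi_row * rng.uniform(*params.lung_size_jitter)
    semi_col = params.lung_semi_col * rng.uniform(*params.lung_size_jitter)
    center_row = params.lung_center_row + rng.uniform(
        -params.lung_center_row_jitter, params.lung_center_row_jitter
    )
    weak_side = rng.choice([-1.0, 1.0])
    imbalance = rng.uniform(*params.lateral_imbalance)
    gradient = rng.uniform(*params.dorsoventral_gradient)
    texture = rng.normal(0.0, 1.0, size=(params.rows, params.cols))

    mid = params.cols / 2.0
    rho_by_side = {
        side: _elliptical_radius(
            params.rows, params.cols, center_row,
            mid + side * params.lung_center_col_offset, semi_row, semi_col,
        )
        for side in (-1.0, 1.0)
    }
    rho = np.minimum(rho_by_side[-1.0], rho_by_side[1.0])

    amp = np.zeros((params.rows, params.cols))
    for side, rho_s in rho_by_side.items():
        inside = rho_s < 1.0
        if params.amplitude_profile == "uniform":
            bump = inside.astype(float)
        elif params.amplitude_profile == "smooth":
            bump = np.where(
                inside, np.cos(np.pi * np.clip(rho_s, 0.0, 1.0) / 2.0) ** 2, 0.0
            )
        else:  # plateau: near-flat ventilation with a steep margin
            bump = np.where(inside, 1.0 - np.clip(rho_s, 0.0, 1.0) ** 8, 0.0)
        if side == weak_side:
            bump = bump * imbalance
        amp = np.maximum(amp, bump)

    if gradient != 0.0:
        rows_rel = (np.arange(params.rows)[:, None] + 0.5 - center_row) / max(semi_row, 1.0)
        amp = amp * np.clip(1.0 + gradient * rows_rel, 0.1, None)
    if params.texture_strength > 0.0:
        tex = _smooth(texture, params.texture_sigma)
        sd = tex.std()
        if sd > 0:
            amp = amp * np.exp(params.texture_strength * tex / sd)

    geometry = dict(
        semi_row=semi_row, semi_col=semi_col, center_row=center_row,
    )
    return amp, rho, geometry


def _heart_field(params: PhantomParams) -> np.ndarray:
    r = np.arange(params.rows)[:, None] + 0.5
    c = np.arange(params.cols)[None, :] + 0.5
    hr, hc = params.heart_center
    rho = np.hypot(r - hr, c - hc) / params.heart_radius
    return np.where(rho < 1.0, np.cos(np.pi * np.clip(rho, 0.0, 1.0) / 2.0) ** 2, 0.0)


def _apply_defects(
    amp: np.ndarray, params: PhantomParams, rng: np.random.Generator,
    geometry: dict,
) -> np.ndarray:
    """Impose the ARDS disease pattern on the amplitude field.

    Two components, emulating the patchy aeration of the injured lung:
    a diffuse multiplicative heterogeneity (extra smooth log-normal
    texture of SD ``diffuse_severity``) and focal hypoventilated /
    atelectatic patches, biased to one side and dorsally, each
    attenuating the local amplitude by a factor from the configured
    range (0 = fully atelectatic).
    """
    if params.diffuse_severity > 0.0:
        tex = _smooth(
            rng.normal(0.0, 1.0, size=amp.shape), params.texture_sigma
        )
        sd = tex.std()
        if sd > 0:
            # one-sided: disease only removes aeration, never adds it
            amp = amp * np.minimum(
                1.0, np.exp(params.diffuse_severity * tex / sd)
            )
    mid = params.cols / 2.0
    affected = rng.choice([-1.0, 1.0])  # -1 = subject-right (low cols)
    n_lo, n_hi = params.n_defects_range
    n_defects = int(rng.integers(n_lo, n_hi + 1))
    r = np.arange(params.rows)[:, None] + 0.5
    c = np.arange(params.cols)[None, :] + 0.5
    attenuation = np.ones_like(amp)
    for _ in range(n_defects):
        side = affected if rng.random() < params.defect_side_bias else -affected
        col_center = mid + side * params.lung_center_col_offset
        dc = rng.uniform(-0.6, 0.6) * geometry["semi_col"]
        dr = rng.uniform(*params.defect_dorsal_bias) * geometry["semi_row"]
        radius = rng.uniform(*params.defect_radius_range)
        factor = rng.uniform(*params.defect_attenuation_range)
        patch = np.hypot(r - (geometry["center_row"] + dr), c - (col_center + dc)) <= radius
        attenuation[patch] = np.minimum(attenuation[patch], factor)
    return amp * attenuation


def generate_subject(
    group: Group | str,
    params: PhantomParams = PhantomParams(),
    seed: int | np.random.SeedSequence = 0,
    subject_id: str | None = None,
) -> FrameSequence:
    """Generate one subject's frame sequence; deterministic in (group, params, seed)."""
    group = Group.parse(group)
    rng = np.random.default_rng(seed)

    mean, sd = (
        params.compliance_ards if group is Group.ARDS else params.compliance_control
    )
    compliance = max(float(rng.normal(mean, sd)), 10.0)
    scale = compliance / params.compliance_control[0]
    heart_rate = float(rng.uniform(*params.heart_rate_range))
    phase = float(rng.uniform(0.0, 2.0 * np.pi))
    baseline = float(rng.uniform(0.0, 10.0))

    amp, rho, geometry = _subject_anatomy(params, rng)
    if group is Group.ARDS and params.defects_enabled:
        amp = _apply_defects(amp, params, rng, geometry)
    amp = _smooth(amp, params.psf_sigma)

    peak_amp = float(amp.max()) if amp.max() > 0 else 1.0

    # inverted-sign ventilation on a random subset of boundary-shell pixels
    if params.out_of_phase_fraction > 0.0 and params.out_of_phase_amplitude > 0.0:
        shell = (rho > params.out_of_phase_shell[0]) & (rho <= params.out_of_phase_shell[1])
        # stay inside the device's reconstructed region so negative pixels
        # are visible to the analysis
        shell &= default_pixel_mask(params.rows, params.cols)
        chosen = shell & (rng.random(amp.shape) < params.out_of_phase_fraction)
        if shell.any() and not chosen.any():
            # guarantee at least one out-of-phase pixel per subject
            idx = np.argwhere(shell)[0]
            chosen[idx[0], idx[1]] = True
        amp = np.where(chosen, -params.out_of_phase_amplitude * peak_amp, amp)

    n_frames = int(round(params.maneuver_duration * params.sample_rate))
    t = np.arange(n_frames) / params.sample_rate
    ramp = 0.5 * (1.0 - np.cos(np.pi * t / params.maneuver_duration))

    lung_mask = (rho < 1.0) & (amp > 0)
    mean_amp = float(amp[lung_mask].mean()) if lung_mask.any() else 1.0
    cardiac_peak = params.cardiac_amplitude_fraction * mean_amp  # sine amplitude
    cardiac = (
        cardiac_peak
        * _smooth(_heart_field(params), params.psf_sigma)[None, :, :]
        * np.sin(2.0 * np.pi * heart_rate / 60.0 * t + phase)[:, None, None]
    )

    frames = scale * (amp[None, :, :] * ramp[:, None, None] + cardiac) + baseline
    if params.noise_sd > 0.0:
        noise = rng.normal(0.0, 1.0, size=frames.shape)
        if params.psf_sigma > 0.0:
            # temporally white, spatially correlated (reconstruction smoothing)
            noise = ndimage.gaussian_filter(
                noise, (0.0, params.psf_sigma, params.psf_sigma)
            )
            noise = noise / noise.std()
        frames = frames + params.noise_sd * scale * peak_amp * noise

    if subject_id is None:
        subject_id = f"{group.value.lower()}-{int(np.random.default_rng(seed).integers(1 << 30)):08x}"
    return FrameSequence(
        frames=frames,
        sample_rate=params.sample_rate,
        heart_rate=heart_rate,
        subject_id=subject_id,
        group=group,
    )


def generate_cohort(
    n_ards: int = 24,
    n_control: int = 12,
    params: PhantomParams = PhantomParams(),
    seed: int | np.random.SeedSequence = 0,
) -> list[FrameSequence]:
    """Generate a labelled cohort (default 24 ARDS / 12 control) with spawned per-subject seeds."""
    if n_ards < 1 or n_control < 1:
        raise InvalidParametersError("need at least one subject per group")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_ards + n_control)
    cohort = []
    for i in range(n_ards):
        cohort.append(
            generate_subject(Group.ARDS, params, children[i], subject_id=f"ards-{i + 1:02d}")
        )
    for j in range(n_control):
        cohort.append(
            generate_subject(
                Group.CONTROL, params, children[n_ards + j], subject_id=f"ctrl-{j + 1:02d}"
            )
        )
    return cohort
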