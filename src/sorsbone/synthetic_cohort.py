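"""Synthetic paired transcutaneous / exposed-bone Raman cohorts.

Real paired SORS measurements on cadaveric fingers are not publicly
deposited, so this module generates spectral cohorts with known ground
truth that reproduce the structure the modelling pipeline relies on:

* Bone spectra are sums of Gaussian bands at the standard bone assignments
  (phosphate ~960, carbonate ~1070, Amide III ~1250, CH2 ~1450, Amide I
  ~1665 cm⁻¹).  Mineral-band amplitudes scale down linearly as the DXA
  T-score falls, and matrix-band widths inflate, so every mineral-to-matrix
  ratio decreases — and CH2 FWHM increases — from Normal through
  Osteopenia to Osteoporosis.
* Transcutaneous spectra mix the bone spectrum with an overlying
  soft-tissue spectrum (CH2, Amide I, lipid and broad collagen features),
  with a bone fraction that grows with the lateral collection offset
  (larger offsets sample deeper tissue), plus a smooth polynomial
  fluorescence baseline and additive Gaussian noise.
* Per-class T-scores are drawn from class-specific normals truncated to
  the WHO interval of that class, anchored to the cadaveric cohort's
  demographics (Normal 0.05 ± 0.45, Osteopenia −1.63 ± 0.38, Osteoporosis
  −4.19 ± 0.90).

One global seed fans out to independent per-subject substreams, so growing
a cohort never perturbs earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from ._exceptions import ConfigError
from .clinical_eval import SubjectRecord, WHORule, classify_who
from .spectra_io import AcquisitionMeta, PairedDataset, Spectrum, WavenumberAxis


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian band: center and width in cm⁻¹, amplitude in a.u."""

    center: float
    width_sigma: float
    amplitude: float
    assignment: str

    def __post_init__(self) -> None:
        if self.width_sigma <= 0:
            raise ConfigError(f"{self.assignment}: width_sigma must be > 0")
        if self.amplitude < 0:
            raise ConfigError(f"{self.assignment}: amplitude must be >= 0")


#: Bone band table: amplitudes at T-score 0; mineral amplitudes shrink and
#: matrix widths grow as the T-score falls.
BONE_PEAKS = (
    PeakSpec(960.0, 8.0, 1.00, "PO4"),
    PeakSpec(1070.0, 10.0, 0.25, "CO3"),
    PeakSpec(1250.0, 25.0, 0.35, "AmideIII"),
    PeakSpec(1450.0, 15.0, 0.45, "CH2"),
    PeakSpec(1665.0, 30.0, 0.60, "AmideI"),
)

#: Overlying soft tissue: strong CH2/Amide I, lipid and broad collagen.
SOFT_PEAKS = (
    PeakSpec(1450.0, 18.0, 0.85, "CH2_soft"),
    PeakSpec(1660.0, 32.0, 0.90, "AmideI_soft"),
    PeakSpec(1300.0, 20.0, 0.50, "lipid"),
    PeakSpec(1245.0, 45.0, 0.30, "collagen_broad"),
    PeakSpec(935.0, 25.0, 0.15, "collagen_CC"),
)

MINERAL_BANDS = frozenset({"PO4", "CO3"})
MATRIX_BANDS = frozenset({"AmideIII", "CH2", "AmideI"})

#: WHO T-score intervals used for truncated sampling.
WHO_INTERVALS = {
    "Normal": (-1.0, np.inf),
    "Osteopenia": (-2.5, -1.0),
    "Osteoporosis": (-np.inf, -2.5),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    ``tscore_slopes`` multiplies each mineral band's amplitude by
    ``max(floor, 1 + slope * t)``; the phosphate band shrinks faster than
    carbonate so PO4/CO3 also falls toward osteoporosis.  ``width_slope``
    inflates matrix-band sigmas by ``1 − width_slope * t`` for t < 0, so
    CH2 FWHM grows as bone quality degrades.  ``bone_fraction_by_offset``
    gives the fraction f of bone signal in a transcutaneous spectrum at
    each lateral offset; only the ordering matters for the method and the
    6-mm channel stays soft-tissue-dominated.
    """

    class_tscore_params: dict = field(
        default_factory=lambda: {
            "Normal": (0.05, 0.45),
            "Osteopenia": (-1.63, 0.38),
            "Osteoporosis": (-4.19, 0.90),
        }
    )
    tscore_slopes: dict = field(
        default_factory=lambda: {"PO4": 0.085, "CO3": 0.045}
    )
    amplitude_floor: float = 0.05
    width_slope: float = 0.03
    bone_fraction_by_offset: dict = field(
        default_factory=lambda: {0: 0.05, 3: 0.20, 6: 0.40}
    )
    baseline_scale: float = 0.30
    noise_sd: float = 0.01
    subject_jitter_sigma: float = 0.08   # lognormal sigma on peak amplitudes
    site_jitter_sigma: float = 0.02      # per-site lognormal amplitude jitter

    def __post_init__(self) -> None:
        offs = sorted(self.bone_fraction_by_offset)
        fracs = [self.bone_fraction_by_offset[o] for o in offs]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ConfigError("bone fractions must lie in [0, 1]")
        if any(b < a for a, b in zip(fracs, fracs[1:])):
            raise ConfigError("bone fractions must be non-decreasing in offset")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Noise-free truth recorded alongside a generated cohort."""

    tscores: dict[str, float]
    who_classes: dict[str, str]
    bone_spectra: dict[tuple[str, str, float], Spectrum]
    # per-subject noiseless bone spectrum at the reference site
    reference_bone: dict[str, Spectrum]


def _gaussian_sum(axis: WavenumberAxis, peaks) -> np.ndarray:
    x = axis.values
    y = np.zeros_like(x)
    for p in peaks:
        y += p.amplitude * np.exp(-0.5 * ((x - p.center) / p.width_sigma) ** 2)
    return y


def _bone_peaks_for_tscore(
    tscore: float, cfg: GeneratorConfig, jitter: dict[str, float] | None = None
) -> list[PeakSpec]:
    out = []
    for p in BONE_PEAKS:
        amp = p.amplitude
        sigma = p.width_sigma
        if p.assignment in MINERAL_BANDS:
            slope = cfg.tscore_slopes[p.assignment]
            amp *= max(cfg.amplitude_floor, 1.0 + slope * min(tscore, 0.0))
            if tscore > 0:  # mild gain above the reference: keep monotone
                amp *= 1.0 + slope * tscore
        elif p.assignment in MATRIX_BANDS and tscore < 0:
            sigma *= 1.0 - cfg.width_slope * tscore
        if jitter is not None:
            amp *= jitter.get(p.assignment, 1.0)
        out.append(replace(p, amplitude=amp, width_sigma=sigma))
    return out


def generate_bone_spectrum(
    tscore: float,
    cfg: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
    axis: WavenumberAxis | None = None,
    meta: AcquisitionMeta | None = None,
    jitter: bool = True,
) -> Spectrum:
    """Noise-free bone spectrum whose composition tracks the T-score.

    Mineral bands (PO4, CO3) scale monotonically with the T-score and the
    phosphate band shrinks fastest, so all four mineral-to-matrix ratios —
    and PO4/CO3 — decrease from Normal toward Osteoporosis.  With
    ``jitter`` a small per-call lognormal factor perturbs each amplitude
    (requires ``rng``).
    """
    cfg = cfg or GeneratorConfig()
    axis = axis or WavenumberAxis.default()
    jit = None
    if jitter:
        if rng is None:
            raise ConfigError("jitter requires an rng")
        jit = {
            p.assignment: float(
                np.exp(rng.normal(0.0, cfg.subject_jitter_sigma))
            )
            for p in BONE_PEAKS
        }
    peaks = _bone_peaks_for_tscore(tscore, cfg, jit)
    meta = meta or AcquisitionMeta(
        subject_id="synthetic", offset_mm=3, tissue="exposed_bone"
    )
    return Spectrum(axis, _gaussian_sum(axis, peaks), meta)


def generate_soft_tissue(
    cfg: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
    axis: WavenumberAxis | None = None,
) -> Spectrum:
    """Soft-tissue spectrum overlying the bone (subject-level jitter)."""
    cfg = cfg or GeneratorConfig()
    axis = axis or WavenumberAxis.default()
    peaks = []
    for p in SOFT_PEAKS:
        amp = p.amplitude
        if rng is not None:
            amp *= float(np.exp(rng.normal(0.0, cfg.subject_jitter_sigma)))
        peaks.append(replace(p, amplitude=amp))
    meta = AcquisitionMeta(
        subject_id="synthetic", offset_mm=0, tissue="transcutaneous"
    )
    return Spectrum(axis, _gaussian_sum(axis, peaks), meta)


def generate_transcutaneous(
    bone: Spectrum,
    soft: Spectrum,
    offset_mm: int,
    cfg: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Mix bone and soft tissue at the offset's bone fraction.

    Output is ``f·bone + (1−f)·soft`` plus a random smooth polynomial
    fluorescence baseline and additive Gaussian noise (both omitted when
    ``rng`` is None or their scales are zero).
    """
    cfg = cfg or GeneratorConfig()
    if bone.axis != soft.axis:
        raise ValueError("bone and soft spectra must share an axis")
    if offset_mm not in cfg.bone_fraction_by_offset:
        raise ConfigError(f"no bone fraction configured for offset {offset_mm} mm")
    f = cfg.bone_fraction_by_offset[offset_mm]
    y = f * bone.intensities + (1.0 - f) * soft.intensities
    if rng is not None and cfg.baseline_scale > 0:
        x = bone.axis.values
        xs = (x - x.mean()) / (np.ptp(x) / 2)
        coeffs = rng.normal(0.0, cfg.baseline_scale, size=3)
        baseline = coeffs[0] + coeffs[1] * xs + coeffs[2] * xs**2
        y = y + (baseline - baseline.min())  # fluorescence is non-negative
    if rng is not None and cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=y.size)
    meta = AcquisitionMeta(
        subject_id=bone.meta.subject_id,
        digit_phalanx=bone.meta.digit_phalanx,
        position_mm=bone.meta.position_mm,
        offset_mm=offset_mm,
        tissue="transcutaneous",
    )
    return Spectrum(bone.axis, y, meta)


def _sample_truncated_tscore(
    who_class: str, cfg: GeneratorConfig, rng: np.random.Generator
) -> float:
    mu, sd = cfg.class_tscore_params[who_class]
    lo, hi = WHO_INTERVALS[who_class]
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def generate_cohort(
    n_per_class: tuple[int, int, int] = (6, 4, 11),
    cfg: GeneratorConfig | None = None,
    seed: int = 0,
    positions_mm: tuple[float, ...] = (-5.0, 0.0, 5.0),
    digit_phalanx: str = "D2P1",
) -> tuple[PairedDataset, GroundTruth, list[SubjectRecord]]:
    """Generate a full paired cohort with ground truth.

    Per subject: a T-score drawn from its class's truncated normal, a
    jittered bone composition, and for each site (default MP05, MM00,
    MD05 on one phalanx) a paired 6-mm transcutaneous spectrum (X) and a
    3-mm exposed-bone spectrum (Y, bone plus measurement noise).  The
    default class sizes (6, 4, 11) mirror the cadaveric cohort.
    Reproducible bit-for-bit from the seed.
    """
    cfg = cfg or GeneratorConfig()
    if all(n == 0 for n in n_per_class):
        raise ConfigError("empty cohort: all class counts are zero")
    if any(n < 0 for n in n_per_class):
        raise ConfigError("class counts must be non-negative")
    axis = WavenumberAxis.default()
    class_names = ("Normal", "Osteopenia", "Osteoporosis")

    X_rows, Y_rows, subjects, sites = [], [], [], []
    gt = GroundTruth({}, {}, {}, {})
    records: list[SubjectRecord] = []
    rule = WHORule()

    ss = np.random.SeedSequence(seed)
    # one substream per subject, extensible without perturbing earlier ones
    n_total = sum(n_per_class)
    child_seeds = ss.spawn(n_total)
    idx = 0
    for who_class, n in zip(class_names, n_per_class):
        for k in range(n):
            rng = np.random.default_rng(child_seeds[idx])
            sid = f"S{idx + 1:02d}"
            idx += 1
            tscore = _sample_truncated_tscore(who_class, cfg, rng)
            # subject-level composition jitter shared across that subject's sites
            subj_jit = {
                p.assignment: float(
                    np.exp(rng.normal(0.0, cfg.subject_jitter_sigma))
                )
                for p in BONE_PEAKS
            }
            soft = generate_soft_tissue(cfg, rng, axis)
            records.append(
                SubjectRecord(subject_id=sid, tscore=tscore,
                              who_class=classify_who(tscore, rule))
            )
            gt.tscores[sid] = tscore
            gt.who_classes[sid] = who_class
            for pos in positions_mm:
                site_jit = {
                    a: j * float(np.exp(rng.normal(0.0, cfg.site_jitter_sigma)))
                    for a, j in subj_jit.items()
                }
                peaks = _bone_peaks_for_tscore(tscore, cfg, site_jit)
                meta_bone = AcquisitionMeta(
                    subject_id=sid, digit_phalanx=digit_phalanx,
                    position_mm=pos, offset_mm=3, tissue="exposed_bone",
                )
                bone_true = Spectrum(axis, _gaussian_sum(axis, peaks), meta_bone)
                gt.bone_spectra[(sid, digit_phalanx, pos)] = bone_true
                if pos == 0.0:
                    gt.reference_bone[sid] = bone_true
                trans = generate_transcutaneous(bone_true, soft, 6, cfg, rng)
                y_meas = bone_true.intensities
                if cfg.noise_sd > 0:
                    y_meas = y_meas + rng.normal(0.0, cfg.noise_sd, size=y_meas.size)
                X_rows.append(trans.intensities)
                Y_rows.append(y_meas)
                subjects.append(sid)
                sites.append((digit_phalanx, pos))

    data = PairedDataset(
        axis, np.vstack(X_rows), np.vstack(Y_rows), subjects, sites
    )
    return data, gt, records
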