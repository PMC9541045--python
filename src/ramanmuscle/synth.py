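"""Synthetic Raman muscle cohorts with known ground truth.

The generator emulates in vivo fiber-optic Raman spectra of dystrophic
(mdx) mouse gastrocnemius and ex vivo human dystrophic quadriceps:

* fingerprint-region muscle bands (alpha-helical protein at 938, 1300 and
  the amide I band near 1654 cm^-1; phenylalanine at 1000 cm^-1;
  protein/phospholipid CH2 deformation at 1444 cm^-1);
* exercise-dependent features — bands enhanced in exercised animals (904,
  930, 1025, 1045, 1057/1062, 1095, 1220, 1610, 1641 cm^-1), bands reduced
  (951, 961 cm^-1), and the amide I position moving from 1657 cm^-1
  (unexercised) to 1653 cm^-1 (exercised), reflecting an alpha-helix to
  beta-sheet transition in necrotic muscle;
* a broad fluorescence baseline (smooth polynomial, several times the peak
  heights) plus the optical fiber's silica contribution below 900 cm^-1;
* hierarchical structure: four spectra per mouse (medial/lateral
  gastrocnemius, both hindlimbs) with a per-mouse random effect, and a
  per-mouse voluntary running distance (mean about 6.5 km over 48 h,
  clipped to 0.4–21.2 km) that scales the exercise effects.

The "human" group reuses the exercised effect set (exercise drives mdx
pathology toward the human phenotype) with its own subject count and no
distance covariate.

Every draw is deterministic given ``GeneratorConfig.seed``, and a
:class:`TruthRecord` carries the noiseless per-subject signals so that
downstream stages can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import Cohort, RamanSpectrum, SpectrumMetadata

__all__ = [
    "PeakSpec",
    "GroupEffect",
    "GeneratorConfig",
    "SubjectTruth",
    "TruthRecord",
    "peak_profile",
    "default_config",
    "generate_cohort",
    "REFERENCE_GROUP",
]

#: Group receiving no effects; every other group gets the effect set.
REFERENCE_GROUP = "unexercised"

_SITES = (
    "gastrocnemius-medial-left",
    "gastrocnemius-lateral-left",
    "gastrocnemius-medial-right",
    "gastrocnemius-lateral-right",
)

_FWHM_TO_SIGMA2 = 4.0 * np.log(2.0)  # gaussian: exp(-4 ln2 (x-c)^2 / fwhm^2)


@dataclass(frozen=True)
class PeakSpec:
    """One spectral band: center (cm^-1), FWHM (cm^-1), amplitude, lineshape."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")


@dataclass(frozen=True)
class GroupEffect:
    """A modification of one library peak in the non-reference groups.

    ``amplitude_delta`` multiplies the peak amplitude (at unit effect
    magnitude); ``center_shift`` moves the band center (cm^-1).  When
    ``scales_with_covariate`` is true the effect magnitude for a subject is
    ``u_s * (1 + beta * d_s / d_ref)`` where ``u_s`` is the subject's
    log-normal scatter and ``d_s`` its running distance; otherwise the
    effect is applied at fixed unit magnitude (structural changes such as
    the amide I shift).
    """

    peak_index: int
    amplitude_delta: float = 1.0
    center_shift: float = 0.0
    scales_with_covariate: bool = True

    def __post_init__(self) -> None:
        if self.amplitude_delta <= 0:
            raise ValueError("amplitude_delta must be > 0")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    ``baseline`` holds polynomial coefficients (low order first) evaluated
    on the normalised coordinate t = (nu - start) / (stop - start), so the
    fluorescence background is grid-independent.  ``covariate_model`` is
    (mean km, sd of log, min km, max km) for the log-normal running
    distance.  ``covariate_beta`` is the linear link between distance and
    effect magnitude.
    """

    n_subjects_per_group: int = 15
    spectra_per_subject: int = 4
    grid: tuple[float, float, float] = (800.0, 1900.0, 1.0)
    peak_library: list[PeakSpec] = field(default_factory=list)
    effects: list[GroupEffect] = field(default_factory=list)
    baseline: tuple[float, ...] = (5.0, 3.0, -4.0, 2.0)
    silica_bump: PeakSpec = field(
        default_factory=lambda: PeakSpec(850.0, 80.0, 3.0)
    )
    noise_sd: float = 0.02
    subject_sd: float = 0.2
    covariate_beta: float = 0.5
    covariate_model: tuple[float, float, float, float] = (6.5, 0.9, 0.4, 21.2)
    n_human_subjects: int = 3
    human_spectra_per_subject: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spectra_per_subject < 1:
            raise ValueError("spectra_per_subject must be >= 1")
        if self.grid[2] <= 0:
            raise ValueError("grid step must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for eff in self.effects:
            if not 0 <= eff.peak_index < len(self.peak_library):
                raise ValueError(f"effect peak_index {eff.peak_index} out of range")

    def wavenumbers(self) -> np.ndarray:
        start, stop, step = self.grid
        n = int(round((stop - start) / step)) + 1
        return start + step * np.arange(n)


@dataclass
class SubjectTruth:
    """Ground truth for one subject: covariate, effect magnitude, clean signal."""

    subject_id: str
    group: str
    covariate: float | None
    effect_scale: float
    clean_spectrum: np.ndarray


@dataclass
class TruthRecord:
    """Per-subject ground truth plus noiseless group means on the grid."""

    grid: np.ndarray
    subjects: dict[str, SubjectTruth]
    group_means: dict[str, np.ndarray]


def peak_profile(spec: PeakSpec, grid: np.ndarray) -> np.ndarray:
    """Evaluate a single band on a wavenumber grid.

    Gaussian: ``A exp(-4 ln2 (nu-c)^2 / fwhm^2)``; Lorentzian:
    ``A (fwhm/2)^2 / ((nu-c)^2 + (fwhm/2)^2)``.  Either way the profile
    attains ``A`` at the band center.
    """
    grid = np.asarray(grid, dtype=float)
    d = grid - spec.center
    if spec.shape == "gaussian":
        return spec.amplitude * np.exp(-_FWHM_TO_SIGMA2 * d**2 / spec.fwhm**2)
    half = spec.fwhm / 2.0
    return spec.amplitude * half**2 / (d**2 + half**2)


# Base muscle bands: (center, fwhm, amplitude).  Amide I dominates; the
# narrow exercise-responsive bands in the 1600-1700 cm^-1 shoulder are kept
# weak so that the group-mean amide I maximum sits exactly at 1657
# (unexercised) / 1653 cm^-1 (exercised) on a 1 cm^-1 grid.
_BASE_PEAKS = [
    (938.0, 14.0, 0.55),   # alpha-helix C-C stretch
    (1000.0, 10.0, 0.60),  # phenylalanine ring breathing
    (1300.0, 18.0, 0.60),  # alpha-helix CH deformation / amide III region
    (1444.0, 18.0, 0.80),  # protein/phospholipid CH2
    (1657.0, 25.0, 1.00),  # amide I (alpha-helix position, unexercised)
]
_UP_PEAKS = [
    (904.0, 12.0, 0.20),   # C-C skeletal stretch, protein
    (930.0, 12.0, 0.20),   # collagen
    (1025.0, 12.0, 0.20),  # phenylalanine C-H
    (1045.0, 12.0, 0.20),  # collagen
    (1057.0, 10.0, 0.25),  # lipid
    (1062.0, 10.0, 0.25),  # nucleic acid
    (1095.0, 12.0, 0.20),  # DNA backbone
    (1220.0, 14.0, 0.25),  # beta-sheet amide III
    (1610.0, 10.0, 0.12),  # DNA bases
    (1641.0, 10.0, 0.08),  # protein
]
_DOWN_PEAKS = [
    (951.0, 12.0, 0.35),   # alpha-helix protein
    (961.0, 12.0, 0.35),   # C-C stretch, protein
]

AMIDE_I_CENTER = 1657.0
AMIDE_I_SHIFT = -4.0
UP_CENTERS = tuple(c for c, _, _ in _UP_PEAKS)
DOWN_CENTERS = tuple(c for c, _, _ in _DOWN_PEAKS)


def default_config(seed: int = 0) -> GeneratorConfig:
    """Default generator: mdx running-wheel study conditions.

    15 subjects per group, 4 spectra per mouse, 800–1900 cm^-1 grid at
    1 cm^-1; the effect set enhances the exercise-associated bands (×1.6),
    suppresses the alpha-helix 951/961 cm^-1 bands (×0.5), and shifts
    amide I from 1657 to 1653 cm^-1; running distances are log-normal with
    mean 6.5 km clipped to [0.4, 21.2] km.
    """
    library = [PeakSpec(c, w, a) for c, w, a in _BASE_PEAKS + _UP_PEAKS + _DOWN_PEAKS]
    centers = [p.center for p in library]
    effects = [
        GroupEffect(centers.index(AMIDE_I_CENTER), center_shift=AMIDE_I_SHIFT,
                    scales_with_covariate=False)
    ]
    effects += [
        GroupEffect(centers.index(c), amplitude_delta=1.6) for c in UP_CENTERS
    ]
    effects += [
        GroupEffect(centers.index(c), amplitude_delta=0.5) for c in DOWN_CENTERS
    ]
    return GeneratorConfig(peak_library=library, effects=effects, seed=seed)


def _baseline_signal(config: GeneratorConfig, grid: np.ndarray) -> np.ndarray:
    start, stop, _ = config.grid
    t = (grid - start) / (stop - start)
    poly = np.polynomial.polynomial.polyval(t, np.asarray(config.baseline, dtype=float))
    return poly + peak_profile(config.silica_bump, grid)


def _subject_clean_signal(
    config: GeneratorConfig, grid: np.ndarray, affected: bool, magnitude: float
) -> np.ndarray:
    """Noiseless spectrum for one subject (baseline + silica + peaks)."""
    peaks = list(config.peak_library)
    if affected:
        for eff in config.effects:
            p = peaks[eff.peak_index]
            m = magnitude if eff.scales_with_covariate else 1.0
            amp = max(p.amplitude * (1.0 + (eff.amplitude_delta - 1.0) * m), 0.0)
            peaks[eff.peak_index] = replace(
                p, amplitude=amp, center=p.center + eff.center_shift
            )
    signal = _baseline_signal(config, grid)
    for p in peaks:
        signal = signal + peak_profile(p, grid)
    return signal


def _clipped_lognormal_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    from scipy.stats import norm

    a, b = (np.log(lo) - mu) / sd, (np.log(hi) - mu) / sd
    return (
        lo * norm.cdf(a)
        + hi * norm.sf(b)
        + np.exp(mu + 0.5 * sd**2) * (norm.cdf(b - sd) - norm.cdf(a - sd))
    )


def _covariate_mu(config: GeneratorConfig) -> float:
    """Log-normal location giving the requested mean *after* clipping."""
    mean, sd_log, lo, hi = config.covariate_model
    if not lo < mean < hi:
        raise ValueError("covariate mean must lie inside the clip range")
    from scipy.optimize import brentq

    return brentq(
        lambda m: _clipped_lognormal_mean(m, sd_log, lo, hi) - mean,
        np.log(lo), np.log(hi), xtol=1e-10,
    )


def _draw_covariate(
    config: GeneratorConfig, rng: np.random.Generator, mu: float
) -> float:
    _, sd_log, lo, hi = config.covariate_model
    return float(np.clip(rng.lognormal(mu, sd_log), lo, hi))


def generate_cohort(
    config: GeneratorConfig,
    groups: Sequence[str] = (REFERENCE_GROUP, "exercised"),
) -> tuple[Cohort, TruthRecord]:
    """Draw a full hierarchical cohort.

    Each subject receives a running distance (exercised mice only), a
    log-normal effect-magnitude scatter, and a noiseless signal; each of
    its spectra adds i.i.d. Gaussian noise.  Deterministic given
    ``config.seed``.
    """
    known = {REFERENCE_GROUP, "exercised", "human"}
    for g in groups:
        if g not in known:
            raise ValueError(f"unknown group name {g!r}")
    rng = np.random.default_rng(config.seed)
    grid = config.wavenumbers()
    mean_dist = config.covariate_model[0]
    cov_mu = _covariate_mu(config)
    spectra: list[RamanSpectrum] = []
    subjects: dict[str, SubjectTruth] = {}
    clean_by_group: dict[str, list[np.ndarray]] = {g: [] for g in groups}
    acq = 0
    for group in groups:
        affected = group != REFERENCE_GROUP
        if group == "human":
            n_subj = config.n_human_subjects
            n_spec = config.human_spectra_per_subject
        else:
            n_subj = config.n_subjects_per_group
            n_spec = config.spectra_per_subject
        for i in range(1, n_subj + 1):
            subject_id = f"{group[:2]}{i:02d}"
            covariate = (
                _draw_covariate(config, rng, cov_mu) if group == "exercised" else None
            )
            u = float(rng.lognormal(0.0, config.subject_sd)) if affected else 1.0
            c = 1.0
            if covariate is not None:
                c = 1.0 + config.covariate_beta * covariate / mean_dist
            magnitude = u * c
            clean = _subject_clean_signal(config, grid, affected, magnitude)
            subjects[subject_id] = SubjectTruth(
                subject_id, group, covariate, magnitude if affected else 0.0, clean
            )
            clean_by_group[group].append(clean)
            for j in range(n_spec):
                acq += 1
                noise = rng.normal(0.0, config.noise_sd, grid.size) if config.noise_sd else 0.0
                meta = SpectrumMetadata(
                    subject_id=subject_id,
                    group=group,
                    site=_SITES[j % len(_SITES)] if group != "human" else f"biopsy-site-{j + 1}",
                    covariate=covariate,
                    acquisition_id=f"a{acq:04d}",
                )
                spectra.append(RamanSpectrum(grid.copy(), clean + noise, meta))
    truth = TruthRecord(
        grid=grid,
        subjects=subjects,
        group_means={g: np.mean(v, axis=0) for g, v in clean_by_group.items() if v},
    )
    return Cohort(spectra, name="synthetic"), truth
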