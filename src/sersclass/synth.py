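"""Synthetic SERS serum cohorts.

Generates two-class patient cohorts of surface-enhanced Raman spectra with
the statistical structure the downstream analysis assumes: sharp Lorentzian
bands riding on a smooth fluorescence-like background, a multiplicative
patient-level random effect (so replicate spectra of one patient are
correlated), a per-spectrum detector gain, and additive Gaussian noise.
Class membership acts through per-band multiplicative intensity factors.

All randomness flows from a single integer seed through per-patient child
streams, so a cohort is bit-reproducible and stable under patient reordering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "WavenumberAxis",
    "PeakSpec",
    "SyntheticConfig",
    "Spectrum",
    "SpectraDataset",
    "default_peak_library",
    "generate_cohort",
    "null_cohort",
]


@dataclass(frozen=True)
class WavenumberAxis:
    """Uniform Raman-shift grid in cm^-1, endpoints inclusive.

    The default (517-1913 cm^-1, 1950 points) is the fingerprint window on
    which serum SERS spectra are recorded and classified.
    """

    start: float = 517.0
    end: float = 1913.0
    n_points: int = 1950

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"WavenumberAxis.start must be < end, got {self.start} >= {self.end}")
        if self.n_points < 2:
            raise ValueError(f"WavenumberAxis.n_points must be >= 2, got {self.n_points}")

    def grid(self) -> np.ndarray:
        """The wavenumber values as a float array of length ``n_points``."""
        return np.linspace(self.start, self.end, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.end - self.start) / (self.n_points - 1)


@dataclass(frozen=True)
class PeakSpec:
    """One Raman band: a unit-height Lorentzian line scaled per class.

    ``group_effect`` maps a class label to a multiplicative intensity factor;
    labels absent from the map get factor 1 (band not affected by class).
    """

    center: float
    width: float = 8.0  # half-width at half-maximum, cm^-1
    base_amplitude: float = 1.0
    assignment: str = ""
    group_effect: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"PeakSpec.width must be > 0, got {self.width}")
        if self.base_amplitude < 0:
            raise ValueError(f"PeakSpec.base_amplitude must be >= 0, got {self.base_amplitude}")
        for label, f in self.group_effect.items():
            if f <= 0:
                raise ValueError(f"PeakSpec.group_effect[{label!r}] must be > 0, got {f}")

    def factor(self, class_label: str) -> float:
        return float(self.group_effect.get(class_label, 1.0))

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Unit-height Lorentzian evaluated on ``grid``."""
        return 1.0 / (1.0 + ((grid - self.center) / self.width) ** 2)


# The 15 serum bands used throughout, with their literature assignments.
# Class labels used by the default two-group setup.
RESPIRATORY = "respiratory"
REFERENT = "referent"

_BANDS: tuple[tuple[float, float, str], ...] = (
    # (center cm^-1, base amplitude, assignment)
    (587.0, 0.35, "Phosphatidylinositol in lipids"),
    (638.0, 0.90, "uric acid"),
    (724.0, 0.85, "delta(C-H) of adenine, coenzyme A, DNA/RNA"),
    (805.0, 0.30, "nu(C-C-O) of L-Serine, glutathione"),
    (890.0, 0.35, "delta(C-O-H) or ring bending of tryptophan, glutathione, D-galactosamine"),
    (947.0, 0.40, "C-C stretching of proteins"),
    (1008.0, 0.60, "Phenylalanine"),
    (1051.0, 0.50, "Glycogen in Carbohydrates"),
    (1132.0, 0.45, "nu(C-N) in D-Mannose"),
    (1207.0, 0.35, "ring vibrations in L-Tryptophan, phenylalanine"),
    (1329.0, 0.50, "Torsion mode CH2 in lipids"),
    (1390.0, 0.55, "C-N, C-H group, omega(CH3), CH2 wagging in lipids"),
    (1442.0, 0.45, "CH2/CH3 deformations in proteins and lipids"),
    (1568.0, 0.40, "DNA/RNA bases"),
    (1657.0, 0.60, "nu(C-O), Amide I"),
)

# Respiratory-group intensity shifts relative to the pathological referent:
# higher at 724/947/1051/1390, lower at 638/1657, all other bands neutral.
_RESPIRATORY_FACTOR: dict[float, float] = {
    724.0: 1.25,
    947.0: 1.25,
    1051.0: 1.25,
    1390.0: 1.25,
    638.0: 0.75,
    1657.0: 0.80,
}


def default_peak_library() -> list[PeakSpec]:
    """The 15-band serum SERS library with two-group intensity effects.

    Group effects encode the observed respiratory-vs-referent direction:
    respiratory spectra higher at 724, 947, 1051 and 1390 cm^-1, lower at
    638 (uric acid) and 1657 cm^-1 (amide I); remaining bands carry no class
    signal. Factors apply to the ``"respiratory"`` label; any other label
    (e.g. ``"referent"``) gets factor 1.
    """
    peaks = []
    for center, amp, assignment in _BANDS:
        effect = {}
        if center in _RESPIRATORY_FACTOR:
            effect[RESPIRATORY] = _RESPIRATORY_FACTOR[center]
        peaks.append(
            PeakSpec(center=center, width=8.0, base_amplitude=amp, assignment=assignment, group_effect=effect)
        )
    return peaks


@dataclass(frozen=True)
class SyntheticConfig:
    """Full recipe for one synthetic cohort.

    ``classes`` is a sequence of (label, n_patients, spectra_per_patient).
    ``patient_sd``/``gain_sd`` are log-scale standard deviations of the
    multiplicative patient amplitude effect and per-spectrum gain;
    ``noise_sd`` is the additive Gaussian noise scale in the same arbitrary
    units as the peak amplitudes. ``baseline_coeffs`` are power-series
    coefficients of the smooth background in wavenumber rescaled to [-1, 1].
    ``spectra_jitter`` (optional) makes per-patient replicate counts uneven:
    each patient gets spectra_per_patient +/- U{-j..j}, floored at 1.
    """

    axis: WavenumberAxis = WavenumberAxis()
    peaks: Sequence[PeakSpec] = field(default_factory=default_peak_library)
    classes: Sequence[tuple[str, int, int]] = ((RESPIRATORY, 41, 3), (REFERENT, 103, 3))
    patient_sd: float = 0.15
    noise_sd: float = 0.02
    baseline_coeffs: Sequence[float] = (0.6, -0.25, 0.12, 0.05, -0.04, 0.02)
    gain_sd: float = 0.10
    spectra_jitter: int = 0
    seed: int = 0

    def validate(self) -> None:
        if len(self.classes) == 0:
            raise ValueError("SyntheticConfig.classes must list at least one class")
        labels = [c[0] for c in self.classes]
        if len(set(labels)) != len(labels):
            raise ValueError("SyntheticConfig.classes has duplicate labels")
        for label, n_pat, spp in self.classes:
            if n_pat < 1:
                raise ValueError(f"SyntheticConfig.classes[{label!r}].n_patients must be >= 1, got {n_pat}")
            if spp < 1:
                raise ValueError(
                    f"SyntheticConfig.classes[{label!r}].spectra_per_patient must be >= 1, got {spp}"
                )
        for name in ("patient_sd", "noise_sd", "gain_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"SyntheticConfig.{name} must be >= 0, got {getattr(self, name)}")
        if self.spectra_jitter < 0:
            raise ValueError(f"SyntheticConfig.spectra_jitter must be >= 0, got {self.spectra_jitter}")
        if len(self.peaks) == 0:
            raise ValueError("SyntheticConfig.peaks must not be empty")


@dataclass(frozen=True, eq=False)
class Spectrum:
    """One recorded spectrum with its provenance metadata."""

    spectrum_id: str
    patient_id: str
    class_label: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float))
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"Spectrum {self.spectrum_id!r} has non-finite intensities")


@dataclass(eq=False)
class SpectraDataset:
    """A collection of spectra on one shared axis plus the patient->class map."""

    axis: WavenumberAxis
    spectra: list[Spectrum]
    class_of_patient: dict[str, str]

    def validate(self) -> None:
        for s in self.spectra:
            if len(s.intensities) != self.axis.n_points:
                raise ValueError(
                    f"Spectrum {s.spectrum_id!r} has {len(s.intensities)} points, axis has {self.axis.n_points}"
                )
            if s.patient_id not in self.class_of_patient:
                raise ValueError(f"Spectrum {s.spectrum_id!r}: patient {s.patient_id!r} missing from class map")
            if self.class_of_patient[s.patient_id] != s.class_label:
                raise ValueError(
                    f"Spectrum {s.spectrum_id!r}: class {s.class_label!r} disagrees with patient map"
                )
        covered = {s.patient_id for s in self.spectra}
        missing = set(self.class_of_patient) - covered
        if missing:
            raise ValueError(f"Patients with no spectra: {sorted(missing)}")

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)

    @property
    def class_labels(self) -> list[str]:
        return sorted(set(self.class_of_patient.values()))

    def patients_of_class(self, label: str) -> list[str]:
        return sorted(p for p, c in self.class_of_patient.items() if c == label)

    def spectra_of_patient(self, patient_id: str) -> list[Spectrum]:
        return [s for s in self.spectra if s.patient_id == patient_id]

    def intensity_matrix(self) -> np.ndarray:
        """Spectra-by-wavenumber matrix, row order = ``self.spectra`` order."""
        if not self.spectra:
            return np.empty((0, self.axis.n_points))
        return np.vstack([s.intensities for s in self.spectra])

    def label_array(self) -> np.ndarray:
        return np.array([s.class_label for s in self.spectra], dtype=object)

    def patient_array(self) -> np.ndarray:
        return np.array([s.patient_id for s in self.spectra], dtype=object)


def _baseline_curve(axis: WavenumberAxis, coeffs: Sequence[float]) -> np.ndarray:
    grid = axis.grid()
    x = 2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0
    return np.polynomial.polynomial.polyval(x, np.asarray(coeffs, dtype=float))


def generate_cohort(config: SyntheticConfig) -> SpectraDataset:
    """Draw one synthetic cohort; the seed fully determines the output.

    Per patient one multiplicative amplitude effect is drawn; each spectrum
    is gain x sum_peaks(base_amplitude x class factor x patient effect x
    Lorentzian) + baseline + noise.
    """
    config.validate()
    axis = config.axis
    grid = axis.grid()
    baseline = _baseline_curve(axis, config.baseline_coeffs)
    profiles = np.vstack([p.profile(grid) for p in config.peaks])  # peaks x points
    base_amps = np.array([p.base_amplitude for p in config.peaks])

    total_patients = sum(n for _, n, _ in config.classes)
    children = np.random.SeedSequence(config.seed).spawn(total_patients)

    spectra: list[Spectrum] = []
    class_of_patient: dict[str, str] = {}
    child_idx = 0
    for label, n_pat, spp in config.classes:
        factors = np.array([p.factor(label) for p in config.peaks])
        class_amps = base_amps * factors
        for k in range(n_pat):
            rng = np.random.default_rng(children[child_idx])
            child_idx += 1
            pid = f"{label}_p{k + 1:03d}"
            class_of_patient[pid] = label
            patient_eff = float(np.exp(rng.normal(0.0, config.patient_sd)))
            if config.spectra_jitter:
                n_spec = max(1, spp + int(rng.integers(-config.spectra_jitter, config.spectra_jitter + 1)))
            else:
                n_spec = spp
            signal = (class_amps * patient_eff) @ profiles
            for j in range(n_spec):
                gain = float(np.exp(rng.normal(0.0, config.gain_sd)))
                noise = rng.normal(0.0, config.noise_sd, axis.n_points)
                spectra.append(
                    Spectrum(
                        spectrum_id=f"{pid}_s{j + 1}",
                        patient_id=pid,
                        class_label=label,
                        intensities=gain * signal + baseline + noise,
                    )
                )
    ds = SpectraDataset(axis=axis, spectra=spectra, class_of_patient=class_of_patient)
    ds.validate()
    return ds


def null_cohort(config: SyntheticConfig) -> SpectraDataset:
    """As :func:`generate_cohort` but with every class effect removed.

    Class labels then carry no signal: the two groups' spectra come from the
    identical generating distribution, which makes this the type-I-error
    harness for the classification protocol.
    """
    neutral = [replace(p, group_effect={}) for p in config.peaks]
    return generate_cohort(dataclasses.replace(config, peaks=neutral))
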