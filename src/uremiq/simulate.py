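"""Synthetic-data generator: ground-truthed cohorts and 1H spectra.

The simulator emulates 500 MHz one-dimensional proton spectra of
deproteinized plasma the way the quantification pipeline expects to see
them: every visible multiplet is a sum of Lorentzian lines whose total area
is proportional to (proton count x in-tube concentration), a TSP singlet at
0.00 ppm provides the internal reference, and Gaussian point noise plus a
smooth low-order baseline stand in for instrument imperfections.

Three sample preparations are modelled as concentration transforms:

* ultrafiltration passes only the protein-unbound fraction of each solute
  (hippuric acid and p-cresyl sulphate vanish entirely),
* acetonitrile extraction recovers the bound solutes but loses citric acid,
* perchloric acid (PCA) extraction keeps everything in solution yet
  degrades the spectrum: noise is inflated and the whole axis picks up a
  random global shift, which is why the analysis never quantifies from it.

Patient cohorts are drawn per metabolite from a normal distribution
truncated at zero with the configured mean/SD of the uremic population;
controls are drawn at literature-normal levels.  eGFR is uniform on the
configured stage 3-4 range and independent of the concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PreparationError
from .library import (
    PREPARATIONS,
    TSP_NAME,
    MetaboliteLibrary,
    ResonanceGroup,
    default_library,
)
from .lineshapes import multiplet_profile
from .spectrum import Spectrum

__all__ = [
    "AcquisitionParams",
    "PatientSample",
    "PreparedSample",
    "Cohort",
    "DILUTION_FACTORS",
    "apply_preparation",
    "simulate_multiplet",
    "simulate_spectrum",
    "simulate_cohort",
]

#: Tube-to-plasma back-conversion factors per preparation.  Ultrafiltrate is
#: measured neat; 0.5 ml plasma resuspended in 700 ul after acetonitrile
#: drying gives 700/500; 100 ul acid into 500 ul plasma gives 600/500.
DILUTION_FACTORS = {"ultrafiltration": 1.0, "acetonitrile": 1.4, "PCA": 1.2}

#: PCA quality degradation: noise inflation and the half-width of the
#: uniform random global shift (ppm).
PCA_NOISE_FACTOR = 3.0
PCA_SHIFT_HALFWIDTH = 0.02


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition and instrument-response settings of the simulator.

    Defaults mirror a routine 500 MHz 1-D acquisition: 6002 Hz spectral
    width digitized in 32K points.  ``fwhm_hz`` (1.2 Hz) is a typical
    solution-state linewidth; ``response`` is the global area-per-proton-uM
    constant ``k``; ``noise_sd`` and ``baseline_amplitude`` are in the same
    arbitrary intensity units as the simulated traces.
    """

    spectrometer_freq: float = 500.0  # MHz
    spectral_width: float = 6002.0  # Hz
    n_points: int = 32768
    noise_sd: float = 200.0
    baseline_amplitude: float = 100.0
    fwhm_hz: float = 1.2
    carrier_ppm: float = 4.7  # axis centre (water position)
    response: float = 1.0  # intensity*ppm per (proton * uM)

    def __post_init__(self) -> None:
        if self.n_points < 1024:
            raise ValueError("n_points must be >= 1024")
        if self.spectrometer_freq <= 0 or self.spectral_width <= 0:
            raise ValueError("frequencies must be positive")
        if self.fwhm_hz <= 0:
            raise ValueError("fwhm_hz must be positive")

    @property
    def fwhm_ppm(self) -> float:
        return self.fwhm_hz / self.spectrometer_freq

    @property
    def ppm_span(self) -> float:
        return self.spectral_width / self.spectrometer_freq

    def ppm_axis(self) -> np.ndarray:
        """Descending ppm axis centred on the carrier."""
        half = 0.5 * self.ppm_span
        return np.linspace(self.carrier_ppm + half, self.carrier_ppm - half, self.n_points)


@dataclass(frozen=True)
class PatientSample:
    """One subject's ground truth: plasma concentrations and kidney function."""

    patient_id: str
    true_conc: dict  # metabolite name -> plasma uM
    egfr: float | None = None  # ml/min/1.73 m^2 (None for controls)
    group: str = "patient"  # "patient" | "control"

    def __post_init__(self) -> None:
        bad = [m for m, c in self.true_conc.items() if c < 0]
        if bad:
            raise ValueError(f"negative concentrations for {bad}")


@dataclass(frozen=True)
class PreparedSample:
    """Result of pushing a plasma sample through one deproteinization."""

    preparation: str
    effective_conc: dict  # metabolite -> plasma-equivalent uM after the prep
    tube_conc: dict  # metabolite -> in-tube uM (effective / dilution)
    dilution_factor: float
    noise_sd: float
    shift_offset: float  # global ppm offset (PCA only)


def apply_preparation(
    sample: PatientSample,
    preparation: str,
    library: MetaboliteLibrary | None = None,
    params: AcquisitionParams | None = None,
    rng: np.random.Generator | None = None,
) -> PreparedSample:
    """Transform true plasma concentrations into what one prep makes visible."""
    if preparation not in PREPARATIONS:
        raise PreparationError(f"unknown preparation {preparation!r}")
    library = library or default_library()
    params = params or AcquisitionParams()
    effective = {}
    for name, conc in sample.true_conc.items():
        spec = library[name]
        effective[name] = conc * spec.preparation_factor(preparation)
    dilution = DILUTION_FACTORS[preparation]
    tube = {name: c / dilution for name, c in effective.items()}
    noise_sd = params.noise_sd
    shift = 0.0
    if preparation == "PCA":
        noise_sd *= PCA_NOISE_FACTOR
        rng = rng if rng is not None else np.random.default_rng()
        shift = float(rng.uniform(-PCA_SHIFT_HALFWIDTH, PCA_SHIFT_HALFWIDTH))
    return PreparedSample(
        preparation=preparation,
        effective_conc=effective,
        tube_conc=tube,
        dilution_factor=dilution,
        noise_sd=noise_sd,
        shift_offset=shift,
    )


def simulate_multiplet(
    group: ResonanceGroup,
    conc: float,
    params: AcquisitionParams | None = None,
    axis: np.ndarray | None = None,
    center: float | None = None,
) -> Spectrum:
    """Noise-free trace of a single multiplet at an in-tube concentration.

    Total area is ``response * n_protons * conc`` regardless of splitting,
    so the integral carries the concentration information.
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    params = params or AcquisitionParams()
    if axis is None:
        axis = params.ppm_axis()
    area = params.response * group.n_protons * conc
    if area == 0.0:
        trace = np.zeros_like(np.asarray(axis, dtype=float))
    else:
        trace = multiplet_profile(
            axis, group, area, params.spectrometer_freq, params.fwhm_ppm, center=center
        )
    return Spectrum(axis.copy(), trace, {"metabolite": group.metabolite_id})


def _baseline(axis: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth quadratic baseline with randomized, seeded coefficients."""
    if amplitude <= 0:
        return np.zeros_like(axis)
    u = np.linspace(-1.0, 1.0, axis.size)
    c0, c1, c2 = rng.uniform(-1.0, 1.0, size=3)
    return amplitude * (c0 + c1 * u + c2 * u**2)


def simulate_spectrum(
    sample: PatientSample,
    preparation: str,
    library: MetaboliteLibrary | None = None,
    params: AcquisitionParams | None = None,
    seed: int | np.random.Generator | None = None,
) -> Spectrum:
    """Full synthetic spectrum of one prepared sample.

    Sum of all preparation-visible multiplets at their in-tube
    concentrations, plus the TSP reference singlet at its spike
    concentration, plus seeded Gaussian noise and a smooth baseline.
    Identical seeds give identical traces.
    """
    library = library or default_library()
    params = params or AcquisitionParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prepared = apply_preparation(sample, preparation, library, params, rng)
    axis = params.ppm_axis()
    trace = np.zeros_like(axis)
    for name, tube_conc in prepared.tube_conc.items():
        if tube_conc <= 0.0:
            continue
        for group in library[name].resonances:
            trace += simulate_multiplet(
                group,
                tube_conc,
                params,
                axis=axis,
                center=group.center_shift + prepared.shift_offset,
            ).intensity
    tsp_group = library[TSP_NAME].quantifiable_group
    trace += simulate_multiplet(
        tsp_group,
        library.tsp.tube_conc,
        params,
        axis=axis,
        center=tsp_group.center_shift + prepared.shift_offset,
    ).intensity
    trace += _baseline(axis, params.baseline_amplitude, rng)
    if prepared.noise_sd > 0:
        trace += rng.normal(0.0, prepared.noise_sd, size=axis.size)
    meta = {
        "patient_id": sample.patient_id,
        "group": sample.group,
        "preparation": preparation,
        "spectrometer_freq_mhz": params.spectrometer_freq,
        "n_points": params.n_points,
        "noise_sd": prepared.noise_sd,
        "shift_offset_ppm": prepared.shift_offset,
        "dilution_factor": prepared.dilution_factor,
    }
    if sample.egfr is not None:
        meta["egfr"] = sample.egfr
    return Spectrum(axis, trace, meta)


_TRUNCNORM_LOC_CACHE: dict = {}


def _truncnorm_loc(mean: float, sd: float) -> float:
    """Location parameter of a zero-truncated normal whose mean equals ``mean``.

    Truncation at zero inflates the mean of a normal with ``loc = mean``
    whenever ``mean``/``sd`` is small, so the reported cohort mean would be
    overshot; solving for the location keeps the generated population mean
    at the configured value (the SD shrinks slightly under truncation,
    which is tolerated).
    """
    key = (mean, sd)
    if key in _TRUNCNORM_LOC_CACHE:
        return _TRUNCNORM_LOC_CACHE[key]

    def truncated_mean(loc: float) -> float:
        return float(stats.truncnorm.mean((0.0 - loc) / sd, np.inf, loc=loc, scale=sd))

    from scipy.optimize import brentq

    lo, hi = mean - 8.0 * sd, mean + sd
    loc = float(brentq(lambda L: truncated_mean(L) - mean, lo, hi, xtol=1e-10 * max(sd, 1.0)))
    _TRUNCNORM_LOC_CACHE[key] = loc
    return loc


def _draw_concentration(
    mean: float, sd: float, rng: np.random.Generator
) -> float:
    """Zero-truncated normal concentration draw with mean-matched location."""
    if sd <= 0:
        return float(mean)
    loc = _truncnorm_loc(mean, sd)
    a = (0.0 - loc) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=loc, scale=sd, random_state=rng))


@dataclass
class Cohort:
    """Simulated study: samples, their spectra and the retained ground truth."""

    patients: list[PatientSample]
    controls: list[PatientSample]
    spectra: dict  # (patient_id, preparation) -> Spectrum
    seed: int
    params: AcquisitionParams
    preparations: tuple[str, ...]

    @property
    def samples(self) -> list[PatientSample]:
        return self.patients + self.controls

    def truth_frame(self) -> pd.DataFrame:
        """Long-form ground truth: one row per (subject, metabolite)."""
        rows = []
        for sample in self.samples:
            for name, conc in sample.true_conc.items():
                rows.append(
                    {
                        "patient_id": sample.patient_id,
                        "group": sample.group,
                        "metabolite": name,
                        "true_uM": conc,
                        "egfr": sample.egfr if sample.egfr is not None else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def draw_cohort_samples(
    n_patients: int,
    n_controls: int,
    rng: np.random.Generator,
    library: MetaboliteLibrary,
    egfr_range: tuple[float, float] = (14.0, 36.0),
) -> tuple[list[PatientSample], list[PatientSample]]:
    """Draw ground-truth concentrations and eGFR for patients and controls."""
    if n_patients < 2:
        raise ValueError("need at least 2 patients (cohort SD is undefined below that)")
    if n_controls < 0:
        raise ValueError("n_controls must be >= 0")
    specs = library.simulated()
    patients = []
    for i in range(n_patients):
        conc = {
            m.name: _draw_concentration(m.cohort_mean, m.cohort_sd or 0.0, rng)
            for m in specs
        }
        egfr = float(rng.uniform(*egfr_range))
        patients.append(
            PatientSample(patient_id=f"P{i + 1:02d}", true_conc=conc, egfr=egfr)
        )
    controls = []
    for i in range(n_controls):
        conc = {
            m.name: _draw_concentration(m.control_mean or 0.0, m.control_sd or 0.0, rng)
            for m in specs
        }
        controls.append(
            PatientSample(patient_id=f"C{i + 1:02d}", true_conc=conc, group="control")
        )
    return patients, controls


def simulate_cohort(
    n_patients: int = 10,
    n_controls: int = 4,
    seed: int = 0,
    library: MetaboliteLibrary | None = None,
    params: AcquisitionParams | None = None,
    preparations: tuple[str, ...] = ("ultrafiltration", "acetonitrile"),
    egfr_range: tuple[float, float] = (14.0, 36.0),
    with_spectra: bool = True,
) -> Cohort:
    """Simulate the full study: cohort truth plus one spectrum per preparation.

    Defaults reproduce the study conditions: 10 patients, 4 controls, eGFR
    uniform on 14-36 ml/min/1.73 m^2, patient concentrations at the uremic
    panel's configured mean +/- SD, and the two quantifiable preparations.
    """
    library = library or default_library()
    params = params or AcquisitionParams()
    for prep in preparations:
        if prep not in PREPARATIONS:
            raise PreparationError(f"unknown preparation {prep!r}")
    rng = np.random.default_rng(seed)
    patients, controls = draw_cohort_samples(
        n_patients, n_controls, rng, library, egfr_range
    )
    spectra: dict = {}
    if with_spectra:
        seeds = np.random.SeedSequence(seed).spawn(len(patients + controls))
        for sample, child in zip(patients + controls, seeds):
            child_rng = np.random.default_rng(child)
            for prep in preparations:
                spectra[(sample.patient_id, prep)] = simulate_spectrum(
                    sample, prep, library, params, seed=child_rng
                )
    return Cohort(
        patients=patients,
        controls=controls,
        spectra=spectra,
        seed=seed,
        params=params,
        preparations=tuple(preparations),
    )
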