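"""Concentration calibration against the TSP internal standard.

With a single-pulse acquisition the integrated area of a multiplet is
proportional to (number of contributing protons) x (concentration), so a
metabolite's in-tube molar concentration follows from the area ratio to the
9-proton TSP singlet of known concentration:

    c_m = (A_m / A_TSP) * (9 / n_m) * c_TSP * dilution_factor

where the dilution factor converts from the measurement tube back to
plasma (1.0 for neat ultrafiltrate, 700/500 for the acetonitrile extract
resuspension, 600/500 for the perchloric-acid extract).

Detection follows the reporting convention of the cohort table: a value is
"detected" only above max(control reporting limit, 3.3 x the concentration
equivalent of the spectral noise); undetected values are excluded from
cohort means rather than zero-imputed.  The complementary preparations are
merged per patient: strongly protein-bound solutes are taken from the
acetonitrile extract, everything else from the ultrafiltrate, and the PCA
extract is never used for quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import QuantificationError
from .fitting import SpectrumFit
from .library import TSP_NAME, MetaboliteLibrary, MetaboliteSpec, ReferenceStandard, default_library
from .lineshapes import multiplet_pattern
from .simulate import DILUTION_FACTORS

__all__ = [
    "QuantRecord",
    "concentration_from_areas",
    "noise_equivalent_area",
    "detection_threshold",
    "apply_detection",
    "quantify_spectrum",
    "merge_preparations",
    "records_frame",
]

#: Signal-to-noise multiple defining the limit of detection.
LOD_FACTOR = 3.3


@dataclass(frozen=True)
class QuantRecord:
    """One (patient, metabolite, preparation) concentration measurement."""

    patient_id: str
    metabolite_id: str
    preparation: str
    conc: float  # plasma-referenced uM (nan when the solute left no signal)
    detected: bool
    source_area: float  # fitted quantifiable-multiplet area (intensity*ppm)
    threshold: float  # detection/reporting threshold applied (uM)
    lod: float  # noise-derived limit of detection alone (uM)

    def reported(self) -> str:
        """Human-readable value: '<threshold' when not detected."""
        if self.detected:
            return f"{self.conc:.1f}"
        return f"<{self.threshold:.1f}"


def concentration_from_areas(
    area_m: float,
    area_tsp: float,
    n_protons_m: int,
    tsp: ReferenceStandard,
    dilution_factor: float = 1.0,
) -> float:
    """Molar concentration (uM) from the area ratio to the TSP singlet."""
    if area_tsp <= 0:
        raise QuantificationError("TSP reference area must be positive")
    if n_protons_m < 1:
        raise QuantificationError("metabolite proton count must be >= 1")
    if area_m < 0:
        raise QuantificationError("metabolite area must be non-negative")
    return (
        (area_m / area_tsp)
        * (tsp.n_protons / n_protons_m)
        * tsp.tube_conc
        * dilution_factor
    )


def noise_equivalent_area(noise_sd: float, fwhm_ppm: float, n_lines: int) -> float:
    """Area of a multiplet whose every line has peak height equal to the noise.

    A Lorentzian of height h and width w has area h * pi * w / 2; summing
    over the multiplet's lines gives the smallest area plausibly
    distinguishable from baseline noise.
    """
    return noise_sd * (math.pi / 2.0) * fwhm_ppm * n_lines


def detection_threshold(
    spec: MetaboliteSpec,
    noise_sd: float,
    fwhm_ppm: float,
    tsp_area: float,
    tsp: ReferenceStandard,
    dilution_factor: float,
) -> tuple[float, float]:
    """(applied threshold, noise-only LOD), both in plasma uM.

    The applied threshold is the larger of the library's control reporting
    limit (when present) and ``LOD_FACTOR`` times the noise-equivalent
    concentration of the quantifiable multiplet.
    """
    group = spec.quantifiable_group
    n_lines = len(multiplet_pattern(group))
    lod_area = LOD_FACTOR * noise_equivalent_area(noise_sd, fwhm_ppm, n_lines)
    lod_conc = concentration_from_areas(
        lod_area, tsp_area, group.n_protons, tsp, dilution_factor
    )
    return max(spec.control_threshold or 0.0, lod_conc), lod_conc


def apply_detection(record: QuantRecord, threshold: float | None = None) -> QuantRecord:
    """Re-evaluate the detection flag of a record against a threshold."""
    thr = record.threshold if threshold is None else float(threshold)
    detected = bool(np.isfinite(record.conc) and record.conc >= thr)
    return replace(record, detected=detected, threshold=thr)


def quantify_spectrum(
    fit: SpectrumFit,
    library: MetaboliteLibrary | None = None,
    patient_id: str | None = None,
) -> list[QuantRecord]:
    """Turn one spectrum's fitted areas into concentration records.

    Every simulated-panel metabolite yields a record; solutes that leave no
    signal under this preparation (or whose region failed to converge) get
    ``conc = nan`` and ``detected = False`` so downstream merging can
    distinguish "not detectable here" from "measured low".
    """
    library = library or default_library()
    pid = patient_id or fit.meta.get("patient_id", "unknown")
    dilution = DILUTION_FACTORS[fit.preparation]
    default_fwhm = 1.2 / float(fit.meta.get("spectrometer_freq_mhz", 500.0))
    records = []
    for m in library.simulated():
        area = fit.areas.get(m.name)
        fwhm = fit.fwhms.get(m.name, default_fwhm)
        threshold, lod = detection_threshold(
            m, fit.noise_sd, fwhm, fit.tsp_area, library.tsp, dilution
        )
        if area is None:
            record = QuantRecord(
                patient_id=pid,
                metabolite_id=m.name,
                preparation=fit.preparation,
                conc=float("nan"),
                detected=False,
                source_area=float("nan"),
                threshold=threshold,
                lod=lod,
            )
        else:
            conc = concentration_from_areas(
                area, fit.tsp_area, m.quantifiable_group.n_protons, library.tsp, dilution
            )
            record = apply_detection(
                QuantRecord(
                    patient_id=pid,
                    metabolite_id=m.name,
                    preparation=fit.preparation,
                    conc=conc,
                    detected=False,
                    source_area=area,
                    threshold=threshold,
                    lod=lod,
                )
            )
        records.append(record)
    return records


def merge_preparations(
    records: list[QuantRecord],
    library: MetaboliteLibrary | None = None,
) -> dict:
    """Merge one patient's per-preparation records into one value per solute.

    Strongly protein-bound metabolites are read from the acetonitrile
    extract (they are absent from the ultrafiltrate); all others from the
    ultrafiltrate; PCA records are never used for quantification.  A
    metabolite whose source preparation is missing maps to ``None`` (not
    quantified).  Conflicting duplicate records raise.
    """
    library = library or default_library()
    patients = {r.patient_id for r in records}
    if len(patients) > 1:
        raise QuantificationError(f"records from multiple patients: {sorted(patients)}")
    by_key: dict = {}
    for r in records:
        key = (r.metabolite_id, r.preparation)
        if key in by_key:
            prev = by_key[key]
            same = (prev.conc == r.conc) or (
                math.isnan(prev.conc) and math.isnan(r.conc)
            )
            if not same:
                raise QuantificationError(f"conflicting duplicate records for {key}")
        by_key[key] = r
    merged: dict = {}
    names = {r.metabolite_id for r in records}
    for name in sorted(names):
        if name == TSP_NAME:
            continue
        source = "acetonitrile" if library[name].protein_bound else "ultrafiltration"
        merged[name] = by_key.get((name, source))
    return merged


def records_frame(records: list[QuantRecord]) -> pd.DataFrame:
    """Long-form concentration table, the pipeline's central exchange format."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "metabolite": r.metabolite_id,
                "preparation": r.preparation,
                "conc_uM": r.conc,
                "detected": r.detected,
                "source_area": r.source_area,
                "threshold_uM": r.threshold,
                "lod_uM": r.lod,
            }
            for r in records
        ]
    )
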