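"""End-to-end orchestration: simulate -> fit -> quantify -> summarize.

Every output table is delimited text with a provenance header (package
version, seed, configuration hash) so a run can be reproduced exactly from
its artefacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _pkg_version
from .errors import ConfigError
from .fitting import fit_spectrum
from .library import MetaboliteLibrary, default_library
from .quantify import merge_preparations, quantify_spectrum, records_frame
from .retention import band_counts, cohort_summary, egfr_correlation, summarize_cohort
from .simulate import AcquisitionParams, simulate_cohort
from .spectrum import Spectrum

__all__ = ["RunConfig", "run_simulation", "analyse_cohort", "run_analysis", "run_all"]

log = logging.getLogger("uremiq")


@dataclass
class RunConfig:
    """One run's complete configuration (YAML-loadable, CLI-overridable)."""

    seed: int = 0
    n_patients: int = 10
    n_controls: int = 4
    preparations: tuple[str, ...] = ("ultrafiltration", "acetonitrile")
    egfr_range: tuple[float, float] = (14.0, 36.0)
    library_path: str | None = None
    out_dir: str = "uremiq_out"
    acquisition: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        payload.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        cfg.preparations = tuple(cfg.preparations)
        cfg.egfr_range = tuple(cfg.egfr_range)
        return cfg

    def library(self) -> MetaboliteLibrary:
        if self.library_path is None:
            return default_library()
        p = Path(self.library_path)
        if not p.exists():
            raise ConfigError(f"library file not found: {p}")
        return MetaboliteLibrary.from_yaml(p)

    def params(self) -> AcquisitionParams:
        try:
            return AcquisitionParams(**self.acquisition)
        except TypeError as exc:
            raise ConfigError(f"bad acquisition overrides: {exc}") from None

    def config_hash(self) -> str:
        """Hash of the scientifically meaningful settings.

        The output location is excluded: two runs of the same study into
        different directories are the same experiment.
        """
        payload = asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(config: RunConfig) -> list[str]:
    return [
        f"# uremiq v{_pkg_version}",
        f"# seed: {config.seed}",
        f"# config_hash: {config.config_hash()}",
    ]


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = "\n".join(_provenance(config)) + "\n"
    body = df.to_csv(sep="\t", index=False, float_format="%.6g")
    path.write_text(header + body)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def run_simulation(config: RunConfig) -> dict:
    """Simulate the cohort and write spectra plus ground truth to disk."""
    library = config.library()
    params = config.params()
    cohort = simulate_cohort(
        n_patients=config.n_patients,
        n_controls=config.n_controls,
        seed=config.seed,
        library=library,
        params=params,
        preparations=config.preparations,
        egfr_range=config.egfr_range,
    )
    out = Path(config.out_dir)
    spectra_dir = out / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (patient_id, prep), spectrum in sorted(cohort.spectra.items()):
        spectrum.meta["seed"] = config.seed
        spectrum.meta["config_hash"] = config.config_hash()
        p = spectra_dir / f"{patient_id}_{prep}.txt"
        spectrum.write(p)
        paths.append(p)
    truth = cohort.truth_frame()
    truth_path = out / "ground_truth.tsv"
    _write_table(truth, truth_path, config)
    log.info("wrote %d spectra and ground truth to %s", len(paths), out)
    return {"spectra_dir": spectra_dir, "ground_truth": truth_path, "paths": paths}


# ---------------------------------------------------------------------------
# analyse
# ---------------------------------------------------------------------------


def analyse_cohort(
    spectra: list[Spectrum],
    library: MetaboliteLibrary | None = None,
) -> dict:
    """Fit and quantify a set of spectra and build the cohort tables.

    Returns a dict with the per-preparation record table (``records``), the
    per-patient merged concentrations (``merged``), the main summary table
    (``summary``), M/N chart data (``mn``), eGFR correlations
    (``correlations``), per-line fit diagnostics (``fit_report``) and the
    count of panel solutes elevated in at least one patient
    (``n_elevated``).
    """
    library = library or default_library()
    all_records = []
    fit_rows = []
    egfr_by_patient: dict = {}
    group_by_patient: dict = {}
    for spectrum in spectra:
        fit = fit_spectrum(spectrum, library)
        pid = spectrum.meta.get("patient_id", "unknown")
        group_by_patient[pid] = spectrum.meta.get("group", "patient")
        if "egfr" in spectrum.meta:
            egfr_by_patient[pid] = float(spectrum.meta["egfr"])
        for res in fit.results:
            for peak in res.peaks:
                fit_rows.append(
                    {
                        "patient_id": pid,
                        "preparation": fit.preparation,
                        "region_lo": res.region[0],
                        "region_hi": res.region[1],
                        "metabolite": peak.metabolite_id,
                        "line": peak.line_index,
                        "center_ppm": peak.center,
                        "fwhm_ppm": peak.fwhm,
                        "area": peak.area,
                        "rms": res.residual_rms,
                        "converged": res.converged,
                    }
                )
            if not res.converged:
                log.warning(
                    "%s/%s: fit did not converge in region %.2f-%.2f ppm",
                    pid,
                    fit.preparation,
                    *res.region,
                )
        all_records.extend(quantify_spectrum(fit, library, patient_id=pid))

    records = records_frame(all_records)
    merged_rows = []
    for pid in sorted({r.patient_id for r in all_records}):
        patient_records = [r for r in all_records if r.patient_id == pid]
        merged = merge_preparations(patient_records, library)
        for name, record in merged.items():
            merged_rows.append(
                {
                    "patient_id": pid,
                    "group": group_by_patient.get(pid, "patient"),
                    "metabolite": name,
                    "conc_uM": record.conc if record is not None else np.nan,
                    "detected": bool(record.detected) if record is not None else False,
                    "preparation": record.preparation if record is not None else "",
                    "egfr": egfr_by_patient.get(pid, np.nan),
                }
            )
    merged_df = pd.DataFrame(merged_rows)
    patients_df = merged_df[merged_df["group"] == "patient"]

    summary = summarize_cohort(patients_df, library)
    summaries = [cohort_summary(patients_df, m.name, library) for m in library.uremic_panel()]
    bands = band_counts(summaries)
    mn_df = pd.DataFrame(
        [
            {"metabolite": s.metabolite_id, "MN": s.mn, "band": s.band}
            for s in summaries
        ]
    )

    panel_names = [m.name for m in library.uremic_panel()]
    detected_any = (
        patients_df[patients_df["metabolite"].isin(panel_names)]
        .groupby("metabolite")["detected"]
        .any()
    )
    n_elevated = int(detected_any.sum())

    corr_rows = []
    for name in panel_names:
        sub = patients_df[
            (patients_df["metabolite"] == name)
            & patients_df["detected"]
            & np.isfinite(patients_df["egfr"])
        ]
        if len(sub) < 3 or sub["conc_uM"].nunique() < 2:
            continue
        res = egfr_correlation(sub["conc_uM"], sub["egfr"], metabolite_id=name)
        corr_rows.append(
            {
                "metabolite": name,
                "n": res.n,
                "spearman_r": res.spearman_r,
                "spearman_p": res.spearman_p,
                "pearson_r_ln": res.pearson_r_ln,
                "slope_ln": res.slope,
                "intercept_ln": res.intercept,
                "slope_ci_lo": res.slope_ci[0],
                "slope_ci_hi": res.slope_ci[1],
            }
        )
    correlations = pd.DataFrame(corr_rows)

    return {
        "records": records,
        "merged": merged_df,
        "summary": summary,
        "mn": mn_df,
        "bands": bands,
        "correlations": correlations,
        "fit_report": pd.DataFrame(fit_rows),
        "n_elevated": n_elevated,
    }


def _load_spectra(spectra_dir: str | Path) -> list[Spectrum]:
    spectra_dir = Path(spectra_dir)
    if not spectra_dir.is_dir():
        raise ConfigError(f"spectra directory not found: {spectra_dir}")
    spectra = []
    paths = sorted(spectra_dir.glob("*.txt"))
    for p in paths:
        try:
            spectra.append(Spectrum.read(p))
        except (ValueError, OSError) as exc:
            log.warning("skipping unreadable spectrum %s: %s", p, exc)
    if not spectra:
        raise ConfigError(f"no readable spectra in {spectra_dir}")
    return spectra


def run_analysis(
    config: RunConfig,
    spectra_dir: str | Path,
    ground_truth: str | Path | None = None,
) -> dict:
    """Analyse a directory of spectra and write all report tables."""
    library = config.library()
    spectra = _load_spectra(spectra_dir)
    tables = analyse_cohort(spectra, library)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, fname in (
        ("records", "concentrations.tsv"),
        ("merged", "merged_concentrations.tsv"),
        ("summary", "cohort_summary.tsv"),
        ("mn", "mn_index.tsv"),
        ("correlations", "egfr_correlations.tsv"),
        ("fit_report", "fit_report.tsv"),
    ):
        _write_table(tables[key], out / fname, config)
    if ground_truth is not None:
        truth = read_table(ground_truth)
        recovery = recovery_report(tables["merged"], truth)
        _write_table(recovery, out / "recovery.tsv", config)
        tables["recovery"] = recovery
    log.info(
        "analysis complete: %d panel solutes elevated in >=1 patient",
        tables["n_elevated"],
    )
    return tables


def recovery_report(merged: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Join recovered concentrations with simulator ground truth."""
    joined = merged.merge(
        truth[["patient_id", "metabolite", "true_uM"]],
        on=["patient_id", "metabolite"],
        how="inner",
    )
    joined = joined[joined["detected"] & (joined["true_uM"] > 0)].copy()
    joined["rel_error"] = (joined["conc_uM"] - joined["true_uM"]) / joined["true_uM"]
    per_met = (
        joined.groupby("metabolite")
        .agg(
            n=("rel_error", "size"),
            median_abs_rel_error=("rel_error", lambda e: float(np.median(np.abs(e)))),
            mean_rel_error=("rel_error", "mean"),
        )
        .reset_index()
    )
    return per_met


def run_all(config: RunConfig) -> dict:
    """simulate -> analyse with ground-truth comparison, all on disk."""
    sim = run_simulation(config)
    return run_analysis(config, sim["spectra_dir"], ground_truth=sim["ground_truth"])
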