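"""Reference library of the uremic solute panel.

The library is the single source of prior knowledge used across the
pipeline: where each metabolite resonates at pH 2.5 / 500 MHz, how many
protons contribute to the multiplet used for quantification, whether the
solute survives each deproteinization method, the control-group reporting
limits, and the literature normal concentration ``N`` used by the M/N
retention index.

It ships as a human-editable YAML file (``data/metabolite_library.yml``)
and round-trips losslessly through :meth:`MetaboliteLibrary.to_yaml` /
:meth:`MetaboliteLibrary.from_yaml`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import LibraryError, PreparationError, UnknownMetaboliteError

MULTIPLICITIES = ("singlet", "doublet", "triplet", "quartet", "AB_system")

#: The three deproteinization methods the pipeline understands.
PREPARATIONS = ("ultrafiltration", "acetonitrile", "PCA")

TSP_NAME = "TSP"


@dataclass(frozen=True)
class ResonanceGroup:
    """One multiplet: a chemically equivalent proton group of a metabolite."""

    metabolite_id: str
    center_shift: float  # ppm
    multiplicity: str
    j_coupling: float  # Hz; 0 for singlets
    n_protons: int
    quantifiable: bool
    ab_delta_nu: float = 0.0  # Hz chemical-shift difference of an AB pair

    def __post_init__(self) -> None:
        if self.multiplicity not in MULTIPLICITIES:
            raise LibraryError(
                f"{self.metabolite_id}: unknown multiplicity {self.multiplicity!r}"
            )
        if self.n_protons < 1 or int(self.n_protons) != self.n_protons:
            raise LibraryError(f"{self.metabolite_id}: n_protons must be a positive integer")
        if self.j_coupling < 0:
            raise LibraryError(f"{self.metabolite_id}: j_coupling must be >= 0")
        if self.multiplicity == "singlet" and self.j_coupling != 0:
            raise LibraryError(f"{self.metabolite_id}: a singlet has no J coupling")
        if self.multiplicity == "AB_system" and self.ab_delta_nu < 0:
            raise LibraryError(f"{self.metabolite_id}: ab_delta_nu must be >= 0")


@dataclass(frozen=True)
class MetaboliteSpec:
    """Everything the pipeline knows about one metabolite a priori."""

    name: str
    resonances: tuple[ResonanceGroup, ...]
    protein_bound: bool = False
    free_fraction: float = 1.0
    acetonitrile_recovery: float = 1.0
    normal_conc: float | None = None  # literature normal N, uM
    control_threshold: float | None = None  # "<x uM" reporting limit
    uremic_panel: bool = True
    excluded_from_mn: bool = False
    exclusion_reason: str | None = None
    # Simulator ground truth (cohort distribution), uM.
    cohort_mean: float | None = None
    cohort_sd: float | None = None
    control_mean: float | None = None
    control_sd: float | None = None
    peak_numbers: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.free_fraction <= 1.0:
            raise LibraryError(f"{self.name}: free_fraction outside [0, 1]")
        if not 0.0 <= self.acetonitrile_recovery <= 1.0:
            raise LibraryError(f"{self.name}: acetonitrile_recovery outside [0, 1]")
        if self.normal_conc is not None and self.normal_conc <= 0:
            raise LibraryError(f"{self.name}: normal_conc must be > 0 when present")
        if self.protein_bound and self.free_fraction >= 0.5:
            raise LibraryError(
                f"{self.name}: strongly protein-bound solutes must have free_fraction < 0.5"
            )
        quantifiable = [g for g in self.resonances if g.quantifiable]
        if len(quantifiable) != 1:
            raise LibraryError(f"{self.name}: exactly one resonance must be quantifiable")
        if self.excluded_from_mn and not self.exclusion_reason:
            raise LibraryError(f"{self.name}: excluded_from_mn requires an exclusion_reason")

    @property
    def quantifiable_group(self) -> ResonanceGroup:
        return next(g for g in self.resonances if g.quantifiable)

    def preparation_factor(self, preparation: str) -> float:
        """Fraction of the plasma concentration surviving a preparation.

        Ultrafiltration passes only the free fraction; acetonitrile recovers
        what the solvent extraction retains; perchloric acid precipitation is
        treated as fully recovering (its damage is to spectral quality, not
        solute content).
        """
        if preparation == "ultrafiltration":
            return self.free_fraction
        if preparation == "acetonitrile":
            return self.acetonitrile_recovery
        if preparation == "PCA":
            return 1.0
        raise PreparationError(f"unknown preparation {preparation!r}")


@dataclass(frozen=True)
class ReferenceStandard:
    """TSP spike: chemical-shift reference and concentration reference.

    The stock is spiked into the deproteinized sample, so the in-tube
    concentration follows from the spike volume and the total tube volume:
    ``tube_conc = stock_conc * spike_volume / tube_volume``.
    """

    name: str = TSP_NAME
    stock_conc_mM: float = 20.2
    spike_volume_ul: float = 20.0
    tube_volume_ul: float = 670.0
    shift: float = 0.0  # ppm, by definition
    n_protons: int = 9

    def __post_init__(self) -> None:
        if self.n_protons != 9:
            raise LibraryError("the reference standard must have exactly 9 equivalent protons")
        if min(self.stock_conc_mM, self.spike_volume_ul, self.tube_volume_ul) <= 0:
            raise LibraryError("reference-standard volumes and stock must be positive")

    @property
    def tube_conc(self) -> float:
        """In-tube TSP concentration in uM."""
        return self.stock_conc_mM * 1000.0 * self.spike_volume_ul / self.tube_volume_ul


def _packaged_library_path() -> Path:
    return Path(resources.files("uremiq").joinpath("data/metabolite_library.yml"))  # type: ignore[arg-type]


class MetaboliteLibrary:
    """Ordered collection of :class:`MetaboliteSpec` plus the TSP standard."""

    def __init__(self, metabolites: list[MetaboliteSpec], tsp: ReferenceStandard):
        self._by_name = {m.name: m for m in metabolites}
        if len(self._by_name) != len(metabolites):
            raise LibraryError("duplicate metabolite names in library")
        if TSP_NAME not in self._by_name:
            raise LibraryError("library must contain the TSP reference entry")
        self.tsp = tsp

    # -- lookup ---------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> MetaboliteSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise UnknownMetaboliteError(name) from None

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def get_panel(self) -> list[MetaboliteSpec]:
        """All library entries: the 14 uremic solutes plus citric acid and TSP."""
        return list(self._by_name.values())

    def uremic_panel(self) -> list[MetaboliteSpec]:
        """The uremic retention panel (the quantified solutes)."""
        return [m for m in self._by_name.values() if m.uremic_panel]

    def simulated(self) -> list[MetaboliteSpec]:
        """Entries the simulator draws concentrations for (panel + citrate)."""
        return [m for m in self._by_name.values() if m.cohort_mean is not None]

    def resonances_for(self, metabolite_id: str, preparation: str) -> list[ResonanceGroup]:
        """Multiplets expected to be visible under the given preparation.

        Strong protein binders vanish from the ultrafiltrate; citric acid is
        lost on acetonitrile extraction. An empty list means the metabolite
        contributes no signal for this preparation.
        """
        spec = self[metabolite_id]
        if spec.name == TSP_NAME:
            return list(spec.resonances)  # spiked after deproteinization
        if spec.preparation_factor(preparation) <= 0.0:
            return []
        return list(spec.resonances)

    # -- serialisation --------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "MetaboliteLibrary":
        """Load the packaged library, or a user-edited copy of it."""
        p = Path(path) if path is not None else _packaged_library_path()
        try:
            payload = yaml.safe_load(p.read_text())
        except FileNotFoundError:
            raise LibraryError(f"library file not found: {p}") from None
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "MetaboliteLibrary":
        if not isinstance(payload, dict) or "metabolites" not in payload:
            raise LibraryError("library file must contain a 'metabolites' list")
        ref = payload.get("reference_standard", {})
        tsp = ReferenceStandard(
            name=ref.get("name", TSP_NAME),
            stock_conc_mM=float(ref.get("stock_conc_mM", 20.2)),
            spike_volume_ul=float(ref.get("spike_volume_ul", 20.0)),
            tube_volume_ul=float(ref.get("tube_volume_ul", 670.0)),
            shift=float(ref.get("shift_ppm", 0.0)),
            n_protons=int(ref.get("n_protons", 9)),
        )
        metabolites = []
        for entry in payload["metabolites"]:
            name = entry.get("name")
            if not name:
                raise LibraryError("metabolite entry without a name")
            groups = tuple(
                ResonanceGroup(
                    metabolite_id=name,
                    center_shift=float(g["center_ppm"]),
                    multiplicity=str(g["multiplicity"]),
                    j_coupling=float(g.get("j_hz", 0.0)),
                    n_protons=int(g["n_protons"]),
                    quantifiable=bool(g.get("quantifiable", False)),
                    ab_delta_nu=float(g.get("ab_delta_nu_hz", 0.0)),
                )
                for g in entry.get("resonances", [])
            )
            metabolites.append(
                MetaboliteSpec(
                    name=name,
                    resonances=groups,
                    protein_bound=bool(entry.get("protein_bound", False)),
                    free_fraction=float(entry.get("free_fraction", 1.0)),
                    acetonitrile_recovery=float(entry.get("acetonitrile_recovery", 1.0)),
                    normal_conc=_opt_float(entry.get("normal_uM")),
                    control_threshold=_opt_float(entry.get("control_threshold_uM")),
                    uremic_panel=bool(entry.get("uremic_panel", True)),
                    excluded_from_mn=bool(entry.get("excluded_from_mn", False)),
                    exclusion_reason=entry.get("exclusion_reason"),
                    cohort_mean=_opt_float(entry.get("cohort_mean_uM")),
                    cohort_sd=_opt_float(entry.get("cohort_sd_uM")),
                    control_mean=_opt_float(entry.get("control_mean_uM")),
                    control_sd=_opt_float(entry.get("control_sd_uM")),
                    peak_numbers=tuple(entry.get("peak_numbers", ())),
                )
            )
        return cls(metabolites, tsp)

    def to_dict(self) -> dict:
        ref = {
            "name": self.tsp.name,
            "stock_conc_mM": self.tsp.stock_conc_mM,
            "spike_volume_ul": self.tsp.spike_volume_ul,
            "tube_volume_ul": self.tsp.tube_volume_ul,
            "shift_ppm": self.tsp.shift,
            "n_protons": self.tsp.n_protons,
        }
        metabolites = []
        for m in self:
            entry: dict = {
                "name": m.name,
                "uremic_panel": m.uremic_panel,
                "peak_numbers": list(m.peak_numbers),
                "protein_bound": m.protein_bound,
                "free_fraction": m.free_fraction,
                "acetonitrile_recovery": m.acetonitrile_recovery,
                "excluded_from_mn": m.excluded_from_mn,
            }
            for key, value in (
                ("cohort_mean_uM", m.cohort_mean),
                ("cohort_sd_uM", m.cohort_sd),
                ("control_mean_uM", m.control_mean),
                ("control_sd_uM", m.control_sd),
                ("control_threshold_uM", m.control_threshold),
                ("normal_uM", m.normal_conc),
                ("exclusion_reason", m.exclusion_reason),
            ):
                if value is not None:
                    entry[key] = value
            entry["resonances"] = [
                {
                    "center_ppm": g.center_shift,
                    "multiplicity": g.multiplicity,
                    "j_hz": g.j_coupling,
                    "n_protons": g.n_protons,
                    "quantifiable": g.quantifiable,
                    **({"ab_delta_nu_hz": g.ab_delta_nu} if g.multiplicity == "AB_system" else {}),
                }
                for g in m.resonances
            ]
            metabolites.append(entry)
        return {"reference_standard": ref, "metabolites": metabolites}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _opt_float(value) -> float | None:
    return None if value is None else float(value)


def default_library() -> MetaboliteLibrary:
    """The packaged library (panel of 14 uremic solutes + citric acid + TSP)."""
    return MetaboliteLibrary.from_yaml()
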