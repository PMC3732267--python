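"""Exception taxonomy shared across the pipeline stages."""


class UremiqError(Exception):
    """Base class for all package-specific failures."""


class LibraryError(UremiqError):
    """Malformed or inconsistent metabolite library content."""


class UnknownMetaboliteError(LibraryError, KeyError):
    """Lookup of a metabolite that is not in the library."""


class PreparationError(UremiqError):
    """Unknown or unusable deproteinization method."""


class ReferencingError(UremiqError):
    """No chemical-shift reference singlet found near 0 ppm."""


class FitError(UremiqError):
    """Lineshape fit unusable (non-convergence, bad region, missing peak)."""


class QuantificationError(UremiqError):
    """Concentration calibration failed (e.g. non-positive reference area)."""


class ConfigError(UremiqError):
    """Invalid run configuration (missing files, bad values)."""
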