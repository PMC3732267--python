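"""Cohort retention statistics.

For each solute the cohort is summarized by the mean uremic concentration
C_u and sample SD over the detected patients, the hypothetical maximal
concentration C_max = C_u + 2 SD, and the retention index M/N — the ratio
of the mean uremic concentration (M = C_u) to the literature normal
concentration N.  Solutes are banded by M/N: high (> 10), moderate
(4 to 10 inclusive), low (< 4); solutes without a reference value, the
single-patient detection and the conventional filtration marker creatinine
are excluded from the banding.

The association between kidney function (eGFR) and solute level is probed
two ways, mirroring common practice for small cohorts: a nonparametric
Spearman rank correlation with an exact permutation p-value for n <= 10
(the t-approximation otherwise), and an ordinary least-squares regression
of the natural-log concentrations on eGFR with a 95% confidence interval.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import QuantificationError
from .library import MetaboliteLibrary, default_library

__all__ = [
    "CohortSummary",
    "CorrelationResult",
    "cmax",
    "mn_index",
    "retention_band",
    "cohort_summary",
    "band_counts",
    "summarize_cohort",
    "spearman_exact",
    "egfr_correlation",
]

BAND_HIGH = "high"
BAND_MODERATE = "moderate"
BAND_LOW = "low"
BAND_EXCLUDED = "excluded"

#: Largest n for which the Spearman p-value is computed by full enumeration.
EXACT_SPEARMAN_MAX_N = 10


def cmax(c_u: float, sd: float) -> float:
    """Hypothetical maximal uremic concentration, C_max = C_u + 2 SD."""
    if sd < 0:
        raise ValueError("SD must be non-negative")
    return c_u + 2.0 * sd


def mn_index(c_u: float, normal: float) -> float:
    """Retention index M/N: mean uremic concentration over literature normal."""
    if normal is None or normal <= 0:
        raise ValueError("normal concentration N must be positive")
    return c_u / normal


def retention_band(mn: float | None, excluded: bool = False) -> str:
    """Band a solute by its M/N index (boundary 10 belongs to 'moderate')."""
    if excluded or mn is None:
        return BAND_EXCLUDED
    if mn > 10.0:
        return BAND_HIGH
    if mn >= 4.0:
        return BAND_MODERATE
    return BAND_LOW


@dataclass(frozen=True)
class CohortSummary:
    """Per-solute cohort statistics in the style of the study's main table."""

    metabolite_id: str
    n_detected: int
    c_u: float | None  # mean over detected patients, uM
    sd: float | None  # sample SD (ddof=1), None when < 2 detected
    c_max: float | None
    normal: float | None  # literature N, uM
    mn: float | None
    band: str


def cohort_summary(
    conc_table: pd.DataFrame,
    metabolite_id: str,
    library: MetaboliteLibrary | None = None,
) -> CohortSummary:
    """Summarize one solute over the detected patients of a cohort table.

    ``conc_table`` is the merged long-form table with columns
    ``metabolite``, ``conc_uM`` and ``detected``; undetected rows are
    excluded from the mean and SD (they are reporting-limit values, not
    zeros).
    """
    library = library or default_library()
    spec = library[metabolite_id]
    sub = conc_table[(conc_table["metabolite"] == metabolite_id) & conc_table["detected"]]
    values = sub["conc_uM"].to_numpy(dtype=float)
    n = int(values.size)
    if n == 0:
        return CohortSummary(metabolite_id, 0, None, None, None, spec.normal_conc, None,
                             retention_band(None, True))
    c_u = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n >= 2 else None
    c_max_val = cmax(c_u, sd) if sd is not None else None
    mn = None
    if spec.normal_conc is not None:
        mn = mn_index(c_u, spec.normal_conc)
    band = retention_band(mn, excluded=spec.excluded_from_mn or spec.normal_conc is None)
    return CohortSummary(metabolite_id, n, c_u, sd, c_max_val, spec.normal_conc, mn, band)


def band_counts(summaries: list[CohortSummary]) -> dict:
    """Count solutes per retention band; bands partition the input."""
    counts = {BAND_HIGH: 0, BAND_MODERATE: 0, BAND_LOW: 0, BAND_EXCLUDED: 0}
    for s in summaries:
        counts[s.band] += 1
    return counts


def summarize_cohort(
    conc_table: pd.DataFrame,
    library: MetaboliteLibrary | None = None,
) -> pd.DataFrame:
    """Main-table-style report over the uremic panel.

    Concentrations are reported rounded to integer uM and M/N to one
    decimal (matching the presentation convention); internal arithmetic is
    unrounded.
    """
    library = library or default_library()
    rows = []
    for m in library.uremic_panel():
        s = cohort_summary(conc_table, m.name, library)
        rows.append(
            {
                "metabolite": s.metabolite_id,
                "n_detected": s.n_detected,
                "C_u_uM": None if s.c_u is None else round(s.c_u),
                "SD_uM": None if s.sd is None else round(s.sd),
                "C_max_uM": None if s.c_max is None else round(s.c_max),
                "N_uM": s.normal,
                "MN": None if s.mn is None else round(s.mn, 1),
                "band": s.band,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-sample p-value
# ---------------------------------------------------------------------------

_PERM_CHUNK = 200_000
_null_cache: dict = {}


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    if denom == 0.0:
        raise ValueError("zero variance in ranks")
    return float(rxc @ ryc) / denom


def _null_r_values(rx: tuple, ry: tuple) -> np.ndarray:
    """All Spearman r values over every permutation pairing of the ranks.

    The correlation is linear in the dot product of ``rx`` with the
    permuted ``ry``, so the full null distribution follows from enumerating
    the n! pairings (chunked to bound memory).  Cached per rank
    configuration — with untied ranks the distribution depends only on n.
    """
    key = (tuple(sorted(rx)), tuple(sorted(ry)), len(rx))
    cached = _null_cache.get(key)
    if cached is not None:
        return cached
    rx_arr = np.asarray(rx, dtype=float)
    n = rx_arr.size
    rxc = rx_arr - rx_arr.mean()
    ry_arr = np.asarray(ry, dtype=float)
    ryc_norm = math.sqrt(float(np.sum((ry_arr - ry_arr.mean()) ** 2)))
    denom = math.sqrt(float(rxc @ rxc)) * ryc_norm
    if denom == 0.0:
        raise ValueError("zero variance in ranks")
    out = np.empty(math.factorial(n))
    pos = 0
    perms = itertools.permutations(ry_arr)
    while True:
        chunk = list(itertools.islice(perms, _PERM_CHUNK))
        if not chunk:
            break
        arr = np.array(chunk, dtype=float)
        out[pos : pos + arr.shape[0]] = (arr @ rxc) / denom
        pos += arr.shape[0]
    _null_cache[key] = out
    return out


def spearman_exact(x, y) -> tuple[float, float]:
    """Spearman rank correlation with an exact permutation p-value.

    For n <= ``EXACT_SPEARMAN_MAX_N`` the two-sided p-value is the exact
    share of the n! rank pairings whose |r| reaches the observed |r|
    (midranks handle ties); larger samples fall back to the
    t-approximation of :func:`scipy.stats.spearmanr`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = _rank_corr(rx, ry)
    if x.size > EXACT_SPEARMAN_MAX_N:
        return r, float(stats.spearmanr(x, y).pvalue)
    null = _null_r_values(tuple(rx), tuple(ry))
    p = float(np.mean(np.abs(null) >= abs(r) - 1e-12))
    return r, p


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman and log-scale regression association with eGFR."""

    metabolite_id: str
    n: int
    spearman_r: float
    spearman_p: float
    pearson_r_ln: float
    slope: float
    intercept: float
    slope_ci: tuple[float, float]  # 95% CI on the LN-scale slope
    intercept_ci: tuple[float, float]


def egfr_correlation(
    conc: np.ndarray | list,
    egfr: np.ndarray | list,
    metabolite_id: str = "",
) -> CorrelationResult:
    """Associate per-patient solute levels with kidney function.

    Spearman rank correlation (exact p for small n) on the raw pairs, plus
    Pearson r and an OLS line with 95% CI on natural-log concentrations —
    the transform used to display skewed solute levels.
    """
    conc = np.asarray(conc, dtype=float)
    egfr = np.asarray(egfr, dtype=float)
    if conc.size != egfr.size or conc.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive for the log transform")
    if np.ptp(conc) == 0 or np.ptp(egfr) == 0:
        raise QuantificationError("undefined correlation: zero variance")
    r_s, p_s = spearman_exact(conc, egfr)
    ln_c = np.log(conc)
    r_ln = float(stats.pearsonr(ln_c, egfr).statistic)
    X = sm.add_constant(egfr)
    ols = sm.OLS(ln_c, X).fit()
    ci = ols.conf_int(alpha=0.05)
    return CorrelationResult(
        metabolite_id=metabolite_id,
        n=int(conc.size),
        spearman_r=r_s,
        spearman_p=p_s,
        pearson_r_ln=r_ln,
        slope=float(ols.params[1]),
        intercept=float(ols.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
    )
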