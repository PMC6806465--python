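"""Weekly trend aggregation, the one-sample Wilcoxon signed-rank test,
tolerance flagging and running-median drift detection.

The Wilcoxon test is implemented exactly for n <= 25 by dynamic programming
over the conditional distribution of the positive-rank sum given the
observed midranks (equivalent to enumerating all 2^n sign assignments, but
polynomial), which keeps exactness under ties where generic exact modes
fall back to approximations.  Zero differences are dropped before ranking
by default; Pratt handling (rank zeros, then discard their ranks) is
available via ``zero_method="pratt"``.  The two-sided p doubles the smaller
exact tail and is capped at 1.  Above n = 25 a normal approximation with
tie correction and continuity correction is used.

Drift detection flags weeks whose value departs from the running median of
all prior weeks by more than a threshold (default 0.4 mm translations /
0.3 deg rotations — the stable-period single-direction envelope); it needs
at least five prior weeks of baseline.  This is a beyond-eyeball addition:
the weekly trend figures are otherwise judged visually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, ManifestError, UndefinedTestError

__all__ = ["QARecord", "ToleranceSet", "wilcoxon_one_sample",
           "summarize_trend", "tolerance_flags", "drift_report"]

TRANSLATION_AXES = ("VRT", "LNG", "LAT")
ROTATION_AXES = ("pitch", "roll", "Rtn")
MODALITIES = ("MV", "kV", "CBCT", "radiation")
#: The radiation isocenter is a point: it carries no rotation axes.
RADIATION_AXES = TRANSLATION_AXES

EXACT_N_MAX = 25


@dataclass(frozen=True)
class QARecord:
    """One modality-axis shift of one week (mm for translations, deg rotations)."""

    week_index: int
    modality: str
    axis: str
    value: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise DomainError(f"unknown modality {self.modality!r}")
        if self.axis not in TRANSLATION_AXES + ROTATION_AXES:
            raise DomainError(f"unknown axis {self.axis!r}")
        if self.modality == "radiation" and self.axis in ROTATION_AXES:
            raise DomainError("radiation modality carries translation axes only")
        if not self.units:
            object.__setattr__(self, "units",
                               "mm" if self.axis in TRANSLATION_AXES else "deg")


@dataclass(frozen=True)
class ToleranceSet:
    """QA action levels: SRS motion tolerances and the vendor congruence spec."""

    srs_translation_mm: float = 1.0
    srs_rotation_deg: float = 1.0
    vendor_congruence_mm: float = 0.75

    def __post_init__(self) -> None:
        if min(self.srs_translation_mm, self.srs_rotation_deg,
               self.vendor_congruence_mm) <= 0:
            raise DomainError("tolerances must be positive")


def _exact_signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """PMF numerators of the positive-rank sum over doubled (integer) ranks.

    ``counts[s]`` = number of the 2^n sign assignments with doubled
    positive-rank sum s; conditional on the observed midranks, every
    assignment is equally likely under H0 symmetry.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        new = counts.copy()
        new[r:] += counts[:total + 1 - r]
        counts = new
    return counts


def wilcoxon_one_sample(values, mu0: float = 0.0,
                        zero_method: str = "wilcox",
                        method: str = "auto") -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank test of symmetry about ``mu0``.

    Returns ``(W_plus, p_two_sided)`` where ``W_plus`` is the sum of
    midranks of positive differences.

    Raises
    ------
    UndefinedTestError
        If every difference equals zero (no information after zero removal).
    """
    d = np.asarray(values, dtype=float) - mu0
    if zero_method not in ("wilcox", "pratt"):
        raise DomainError("zero_method must be 'wilcox' or 'pratt'")
    if np.all(d == 0):
        raise UndefinedTestError("all differences are zero: test undefined")

    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = sps.rankdata(np.abs(d))
    else:  # pratt: rank including zeros, then drop the zero ranks
        ranks_all = sps.rankdata(np.abs(d))
        keep = d != 0
        ranks = ranks_all[keep]
        d = d[keep]
    n = len(d)
    w_plus = float(ranks[d > 0].sum())

    use_exact = method == "exact" or (method == "auto" and n <= EXACT_N_MAX)
    if use_exact:
        ranks2 = np.round(2 * ranks).astype(int)
        counts = _exact_signed_rank_distribution(ranks2)
        total = 2.0 ** n
        w2 = int(round(2 * w_plus))
        p_low = counts[:w2 + 1].sum() / total
        p_high = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return w_plus, float(p)

    # conditional null moments given the observed midranks: each rank enters
    # W+ independently with probability 1/2, which absorbs ties (and, under
    # pratt, the discarded zero ranks) without a separate correction term
    mean = float(ranks.sum()) / 2.0
    var = float(np.sum(ranks**2)) / 4.0
    if var <= 0:
        raise UndefinedTestError("zero variance: test undefined")
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return w_plus, float(min(1.0, p))


def records_to_frame(records) -> pd.DataFrame:
    rows = [{"week": r.week_index, "modality": r.modality, "axis": r.axis,
             "value": r.value, "units": r.units} for r in records]
    return pd.DataFrame(rows, columns=["week", "modality", "axis", "value", "units"])


def summarize_trend(records) -> pd.DataFrame:
    """Per (modality, axis): sample mean, SD (n-1) and the signed extreme.

    The extreme is the value of largest magnitude with its sign retained.
    Cells with fewer than two weeks are omitted with a warning.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    rows = []
    for (modality, axis), grp in df.groupby(["modality", "axis"], sort=False):
        vals = grp["value"].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(f"cell ({modality}, {axis}) has < 2 weeks; omitted",
                          stacklevel=2)
            continue
        extreme = vals[int(np.argmax(np.abs(vals)))]
        rows.append({"modality": modality, "axis": axis, "n_weeks": len(vals),
                     "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                     "extreme": float(extreme),
                     "units": grp["units"].iloc[0]})
    return pd.DataFrame(rows, columns=["modality", "axis", "n_weeks", "mean",
                                       "sd", "extreme", "units"])


def _tolerance_for(axis: str, tol: ToleranceSet) -> float:
    return (tol.srs_translation_mm if axis in TRANSLATION_AXES
            else tol.srs_rotation_deg)


def tolerance_flags(records, tol: ToleranceSet = ToleranceSet()) -> dict:
    """Pass/fail per modality-axis for one week, plus overall conjunction.

    Boundary equality passes (<= semantics).  Also evaluates the vendor
    isocenter-congruence check: every translational shift of every modality
    within ``vendor_congruence_mm``.

    Raises
    ------
    ManifestError
        If any expected modality-axis cell is missing from the record set.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    flags: dict = {}
    max_translation = 0.0
    for modality in MODALITIES:
        axes = (RADIATION_AXES if modality == "radiation"
                else TRANSLATION_AXES + ROTATION_AXES)
        for axis in axes:
            cell = df[(df["modality"] == modality) & (df["axis"] == axis)]
            if cell.empty:
                raise ManifestError(f"missing record for ({modality}, {axis})")
            v = float(cell["value"].iloc[0])
            flags[(modality, axis)] = abs(v) <= _tolerance_for(axis, tol)
            if axis in TRANSLATION_AXES:
                max_translation = max(max_translation, abs(v))
    overall = all(flags.values())
    return {"per_axis": flags, "overall": overall,
            "congruence": max_translation <= tol.vendor_congruence_mm,
            "max_translation_mm": max_translation}


def drift_report(records, threshold_mm: float = 0.4,
                 threshold_deg: float = 0.3, baseline_weeks: int = 5) -> dict:
    """Flag weeks departing from the running median of all prior weeks.

    For each modality-axis series (ordered by week), a week is evaluable
    once at least ``baseline_weeks`` prior weeks exist; it is flagged when
    ``|value - median(prior)| > threshold`` (mm for translations, deg for
    rotations).  Returns flagged week indices, per-week detail, and the
    weeks that could not be evaluated for lack of baseline.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    flagged: dict[int, list] = {}
    not_evaluable: set[int] = set()
    for (modality, axis), grp in df.groupby(["modality", "axis"], sort=False):
        grp = grp.sort_values("week")
        weeks = grp["week"].to_numpy()
        vals = grp["value"].to_numpy(dtype=float)
        thr = threshold_mm if axis in TRANSLATION_AXES else threshold_deg
        for i in range(len(vals)):
            if i < baseline_weeks:
                not_evaluable.add(int(weeks[i]))
                continue
            med = float(np.median(vals[:i]))
            if abs(vals[i] - med) > thr:
                flagged.setdefault(int(weeks[i]), []).append(
                    {"modality": modality, "axis": axis,
                     "value": float(vals[i]), "baseline_median": med})
    evaluable = sorted(set(df["week"].astype(int)) - not_evaluable)
    return {"flagged_weeks": sorted(flagged), "detail": flagged,
            "not_evaluable_weeks": sorted(not_evaluable - set(flagged)),
            "evaluated_weeks": evaluable}
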