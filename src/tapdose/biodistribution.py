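"""Biodistribution analytics: %ID/g, group summaries, formulation metrics,
tumor-size correlations, and radiochemical purity.

The counting workflow mirrors a standard gamma-counter study: each harvested
organ is counted (background already subtracted upstream), a standard
representing a known fraction of the injected dose is counted alongside, and
both are decay-corrected to the injection time before forming

    %ID   = 100 · counts / (standard_counts / standard_fraction)
    %ID/g = %ID / organ_mass

%ID/g values are therefore decay-corrected to injection; the dosimetry layer
re-applies physical decay when building time–activity curves.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import atom_weights
from scipy import optimize, stats

from .errors import (
    DegenerateInputError,
    EmptyChromatogramError,
    IncompleteTableError,
    InvalidFormulaError,
    InvalidParameterError,
    InvalidSampleError,
    MissingCellError,
)
from .nuclide_chain import decay_correct_counts

__all__ = [
    "STANDARD_ORGAN",
    "BiodistTable",
    "DoseFormulation",
    "Chromatogram",
    "percent_id_per_gram",
    "summarize_biodist",
    "formulation_metrics",
    "compare_uptake_groups",
    "uptake_vs_tumor_size",
    "chromatogram_purity",
]

#: organ label reserved for standard rows in the CSV interchange format
STANDARD_ORGAN = "__standard__"

#: epoch used when serialising relative hours as ISO timestamps
_CSV_EPOCH = datetime(2024, 1, 1, 0, 0, 0)

_SAMPLE_COLUMNS = [
    "animal_id", "group", "organ", "mass_g", "counts",
    "count_time_h", "timepoint_h", "tumor_volume_mm3",
]


@dataclass
class BiodistTable:
    """Per-animal organ counts plus the dose standard used for normalisation.

    ``samples`` columns: animal_id, group, organ, mass_g, counts,
    count_time_h (hours post injection), timepoint_h (nominal euthanasia
    time), tumor_volume_mm3 (NaN where not applicable).  The standard counts
    represent ``standard_fraction`` of the injected dose (1.0 = full dose
    equivalent) and were acquired at ``standard_count_time_h``.
    """

    samples: pd.DataFrame
    standard_counts: float
    standard_fraction: float = 1.0
    standard_count_time_h: float = 0.0
    reference_time_h: float = 0.0

    def __post_init__(self) -> None:
        if not self.standard_counts > 0:
            raise IncompleteTableError("standard_counts must be positive")
        if not 0 < self.standard_fraction <= 1:
            raise InvalidParameterError("standard_fraction must be in (0, 1]")
        df = pd.DataFrame(self.samples)
        for col in _SAMPLE_COLUMNS:
            if col not in df.columns:
                if col == "tumor_volume_mm3":
                    df[col] = np.nan
                else:
                    raise InvalidSampleError(f"samples missing column {col!r}")
        if (df["mass_g"] <= 0).any():
            raise InvalidSampleError("organ masses must be positive")
        if (df["counts"] < 0).any():
            raise InvalidSampleError("counts must be >= 0 after background subtraction")
        if (df["timepoint_h"] < 0).any():
            raise InvalidSampleError("timepoints must be >= 0")
        self.samples = df[_SAMPLE_COLUMNS].reset_index(drop=True)

    # -- CSV interchange ----------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the interchange CSV (standard as an ``__standard__`` row)."""
        df = self.samples.copy()
        df["count_time_iso"] = [
            (_CSV_EPOCH + timedelta(hours=float(h))).isoformat() for h in df["count_time_h"]
        ]
        std = pd.DataFrame(
            {
                "animal_id": ["standard"],
                "group": ["standard"],
                "organ": [STANDARD_ORGAN],
                "mass_g": [1.0],
                "counts": [self.standard_counts],
                "timepoint_h": [0.0],
                "tumor_volume_mm3": [np.nan],
                "count_time_iso": [
                    (_CSV_EPOCH + timedelta(hours=self.standard_count_time_h)).isoformat()
                ],
                "standard_fraction": [self.standard_fraction],
            }
        )
        out = pd.concat([df.drop(columns=["count_time_h"]), std], ignore_index=True)
        cols = ["animal_id", "group", "timepoint_h", "organ", "mass_g", "counts",
                "count_time_iso", "tumor_volume_mm3", "standard_fraction"]
        out[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, reference_time: datetime | None = None) -> "BiodistTable":
        """Read the interchange CSV.

        ``reference_time`` (injection time) defaults to the earliest count
        time in the file.
        """
        df = pd.read_csv(path, comment="#")
        if "count_time_iso" in df.columns:
            times = pd.to_datetime(df["count_time_iso"])
            ref = pd.Timestamp(reference_time) if reference_time else times.min()
            df["count_time_h"] = (times - ref).dt.total_seconds() / 3600.0
        elif "count_time_h" not in df.columns:
            raise InvalidSampleError("CSV needs count_time_iso or count_time_h")
        std_rows = df[df["organ"] == STANDARD_ORGAN]
        if std_rows.empty:
            raise IncompleteTableError(f"no {STANDARD_ORGAN} row in CSV")
        std = std_rows.iloc[0]
        frac = float(std.get("standard_fraction", 1.0)) if "standard_fraction" in df.columns else 1.0
        if np.isnan(frac):
            frac = 1.0
        samples = df[df["organ"] != STANDARD_ORGAN].copy()
        return cls(
            samples=samples,
            standard_counts=float(std["counts"]),
            standard_fraction=frac,
            standard_count_time_h=float(std["count_time_h"]),
            reference_time_h=0.0,
        )

    # -- analytics ----------------------------------------------------------

    def percent_injected_dose(self, half_life_h: float) -> pd.DataFrame:
        """Samples annotated with decay-corrected %ID and %ID/g columns."""
        std_corr = decay_correct_counts(
            self.standard_counts, self.standard_count_time_h, self.reference_time_h, half_life_h
        )
        dose_equiv = std_corr / self.standard_fraction
        df = self.samples.copy()
        corr = np.array(
            [
                decay_correct_counts(c, t, self.reference_time_h, half_life_h)
                for c, t in zip(df["counts"], df["count_time_h"])
            ]
        )
        df["pct_id"] = 100.0 * corr / dose_equiv
        df["pct_id_per_g"] = df["pct_id"] / df["mass_g"]
        return df


def percent_id_per_gram(sample, table: BiodistTable, half_life_h: float) -> float:
    """%ID/g of one sample (a row-like with organ mass, counts, count time)."""
    mass = float(sample["mass_g"])
    if mass <= 0:
        raise InvalidSampleError("organ mass must be positive")
    std_corr = decay_correct_counts(
        table.standard_counts, table.standard_count_time_h, table.reference_time_h, half_life_h
    )
    dose_equiv = std_corr / table.standard_fraction
    corr = decay_correct_counts(
        float(sample["counts"]), sample["count_time_h"], table.reference_time_h, half_life_h
    )
    return 100.0 * corr / dose_equiv / mass


def summarize_biodist(table: BiodistTable, half_life_h: float, by_group: bool = True) -> pd.DataFrame:
    """Per (group,) organ, timepoint mean, sample SD (n−1) and n of %ID/g and %ID.

    Single-sample cells report SD as NaN.
    """
    df = table.percent_injected_dose(half_life_h)
    keys = (["group"] if by_group else []) + ["organ", "timepoint_h"]
    agg = df.groupby(keys, sort=True).agg(
        mean_idg=("pct_id_per_g", "mean"),
        sd_idg=("pct_id_per_g", lambda s: s.std(ddof=1)),
        mean_id=("pct_id", "mean"),
        sd_id=("pct_id", lambda s: s.std(ddof=1)),
        n=("pct_id", "size"),
    )
    return agg.reset_index()


@dataclass(frozen=True)
class DoseFormulation:
    """An administered formulation: activity, peptide mass, molecular formula.

    Default formula is the GRPR-targeting peptide conjugate C77H119N23O17.
    """

    activity_kbq: float
    peptide_mass_ng: float
    molecular_formula: str = "C77H119N23O17"

    def __post_init__(self) -> None:
        if self.activity_kbq <= 0 or self.peptide_mass_ng <= 0:
            raise InvalidParameterError("activity and peptide mass must be positive")


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise InvalidFormulaError(f"cannot parse formula {formula!r} at {pos}")
        pos = match.end()
        symbol, digits = match.groups()
        if symbol not in atom_weights:
            raise InvalidFormulaError(f"unknown element symbol {symbol!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
    if pos != len(formula) or not counts:
        raise InvalidFormulaError(f"cannot parse formula {formula!r}")
    return counts


def formulation_metrics(f: DoseFormulation) -> dict[str, float]:
    """Molar mass, molar amount, and specific/molar activity of a formulation.

    Returns molar_mass (g/mol), amount_nmol, specific_activity_kbq_per_ng,
    molar_activity_gbq_per_umol.
    """
    counts = parse_formula(f.molecular_formula)
    molar_mass = sum(atom_weights[el] * n for el, n in counts.items())
    amount_nmol = f.peptide_mass_ng / molar_mass  # ng / (g/mol) = nmol
    return {
        "molar_mass": molar_mass,
        "amount_nmol": amount_nmol,
        "specific_activity_kbq_per_ng": f.activity_kbq / f.peptide_mass_ng,
        "molar_activity_gbq_per_umol": f.activity_kbq / amount_nmol * 1e-3,
    }


def _cell_values(df: pd.DataFrame, group: str, organ: str, timepoint_h: float) -> np.ndarray:
    sel = df[
        (df["group"] == group)
        & (df["organ"] == organ)
        & np.isclose(df["timepoint_h"], timepoint_h)
    ]
    if sel.empty:
        raise MissingCellError(f"no samples for group={group!r}, organ={organ!r}, t={timepoint_h}")
    return sel["pct_id_per_g"].to_numpy()


def compare_uptake_groups(
    table: BiodistTable,
    group_a: str,
    group_b: str,
    organ: str,
    timepoint_h: float,
    half_life_h: float,
    test: str = "welch",
) -> dict[str, float]:
    """Percent change in mean %ID/g from group_a to group_b, with a t test.

    ``test`` is ``"welch"`` (unequal variance, default) or ``"student"``
    (pooled variance).  Two identical groups return p = 1 exactly.
    """
    df = table.percent_injected_dose(half_life_h)
    a = _cell_values(df, group_a, organ, timepoint_h)
    b = _cell_values(df, group_b, organ, timepoint_h)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("need >= 2 samples per group for a t test")
    percent_change = 100.0 * (b.mean() - a.mean()) / a.mean()
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    else:
        _, p = stats.ttest_ind(b, a, equal_var=(test == "student"))
        p = float(p)
    return {"percent_change": float(percent_change), "p_value": p}


def uptake_vs_tumor_size(
    table: BiodistTable, half_life_h: float, organ: str = "tumor"
) -> dict[str, float]:
    """Pearson correlation of tumor volume against %ID/g and against %ID.

    Necrotic cores grow with tumor size, diluting concentration: uptake per
    gram falls with volume even while absolute uptake (%ID) stays flat.
    """
    df = table.percent_injected_dose(half_life_h)
    sel = df[(df["organ"] == organ) & df["tumor_volume_mm3"].notna()]
    if len(sel) < 3:
        raise DegenerateInputError("need >= 3 tumors with recorded volumes")
    vol = sel["tumor_volume_mm3"].to_numpy(dtype=float)
    idg = sel["pct_id_per_g"].to_numpy(dtype=float)
    pid = sel["pct_id"].to_numpy(dtype=float)
    if np.std(vol) == 0:
        raise DegenerateInputError("zero variance in tumor volumes")

    def _corr(y):
        # an exactly-flat uptake variable is uncorrelated by construction
        if np.std(y) == 0:
            return 0.0, 1.0
        r, p = stats.pearsonr(vol, y)
        return float(r), float(p)

    r_idg, p_idg = _corr(idg)
    r_id, p_id = _corr(pid)
    return {"corr_idg": r_idg, "p_idg": p_idg, "corr_id": r_id, "p_id": p_id}


@dataclass
class Chromatogram:
    """Radio-chromatogram as fraction times (s) and counts per fraction."""

    fraction_times_s: np.ndarray
    fraction_counts: np.ndarray
    main_peak_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.fraction_times_s = np.asarray(self.fraction_times_s, dtype=float)
        self.fraction_counts = np.asarray(self.fraction_counts, dtype=float)
        if self.fraction_times_s.shape != self.fraction_counts.shape:
            raise InvalidParameterError("times and counts must have equal length")
        if np.any(np.diff(self.fraction_times_s) <= 0):
            raise InvalidParameterError("fraction times must be strictly increasing")
        if self.main_peak_window is not None:
            lo, hi = self.main_peak_window
            if not (lo < hi):
                raise InvalidParameterError("main_peak_window must satisfy start < end")

    @classmethod
    def from_csv(cls, path, main_peak_window=None) -> "Chromatogram":
        df = pd.read_csv(path, comment="#")
        return cls(df["time_s"].to_numpy(), df["counts"].to_numpy(), main_peak_window)


def _gaussian(t, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _fit_main_peak_window(times: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    """±3σ window from a Gaussian fit to the tallest peak (FWHM seeded)."""
    i_max = int(np.argmax(counts))
    c_max = counts[i_max]
    half = c_max / 2.0
    left = i_max
    while left > 0 and counts[left - 1] > half:
        left -= 1
    right = i_max
    while right < len(counts) - 1 and counts[right + 1] > half:
        right += 1
    dt = np.median(np.diff(times))
    sigma0 = max((times[right] - times[left]) / 2.355, dt / 2.0)
    lo = max(0, i_max - int(round(3 * sigma0 / dt)) - 1)
    hi = min(len(counts), i_max + int(round(3 * sigma0 / dt)) + 2)
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, times[lo:hi], counts[lo:hi],
            p0=[c_max, times[i_max], sigma0], maxfev=5000,
        )
        mu, sigma = popt[1], abs(popt[2])
    except RuntimeError:
        mu, sigma = times[i_max], sigma0
    return (mu - 3 * sigma, mu + 3 * sigma)


def chromatogram_purity(c: Chromatogram) -> float:
    """Percent of total counts inside the main-peak window.

    Without an explicit window, a Gaussian is fitted to the tallest peak and
    ±3σ is used.
    """
    total = c.fraction_counts.sum()
    if total <= 0:
        raise EmptyChromatogramError("chromatogram has no counts")
    window = c.main_peak_window or _fit_main_peak_window(c.fraction_times_s, c.fraction_counts)
    lo, hi = window
    inside = c.fraction_counts[(c.fraction_times_s >= lo) & (c.fraction_times_s <= hi)].sum()
    return 100.0 * inside / total
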