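"""Concentration-response statistics for MEA units in the 11-segment
multi-neurotransmitter receptor paradigm.

Order of operations: activity filter (spikes in both baselines) ->
percentile inclusion window (2.5th / 97.5th of each baseline over the
active population) -> pharmacological unit classification (agonist
suppression then antagonist rebound) -> per-unit normalization over the
analyzed segments (4-11) -> Friedman test across the 8 conditions with
Conover many-to-one post hoc versus the 0 uM reference and
Benjamini-Hochberg adjustment of the 7 comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nonparametric import TestResult, bh_adjust, conover_many_to_one, friedman_test, sample_quantile
from .protocol import DEFAULT_PARADIGM, RecordingParadigm

__all__ = [
    "InclusionBounds",
    "filter_active_units",
    "compute_inclusion_bounds",
    "apply_inclusion",
    "classify_unit",
    "classify_units",
    "normalize_unit",
    "normalize_units",
    "ConcentrationResponseResult",
    "concentration_response",
    "analyze_mea",
]

SEGMENT_COLUMNS = tuple(f"seg{i}" for i in range(1, 12))


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in ("unit", "antagonist", *SEGMENT_COLUMNS) if c not in table.columns]
    if missing:
        raise ValueError(f"spike-count table missing columns {missing}")


@dataclass(frozen=True)
class InclusionBounds:
    """Percentile inclusion window for the two baseline recordings."""

    baseline1: tuple[float, float]
    baseline2: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (self.baseline1, self.baseline2):
            if lo > hi:
                raise ValueError("lower bound exceeds upper bound")

    def to_dict(self) -> dict:
        return {"baseline1": list(self.baseline1), "baseline2": list(self.baseline2)}


def filter_active_units(
    table: pd.DataFrame, paradigm: RecordingParadigm = DEFAULT_PARADIGM
) -> pd.DataFrame:
    """Retain units with spike counts > 0 in both baselines (segments 1 and 4)."""
    _check_table(table)
    b1 = table[f"seg{paradigm.baseline1}"]
    b2 = table[f"seg{paradigm.baseline2}"]
    return table[(b1 > 0) & (b2 > 0)].copy()


def compute_inclusion_bounds(
    active: pd.DataFrame, paradigm: RecordingParadigm = DEFAULT_PARADIGM
) -> InclusionBounds:
    """2.5th and 97.5th percentiles of each baseline over the active units.

    Linear-interpolation quantiles; computed after the activity filter,
    separately for the two baseline segments.
    """
    if len(active) < 2:
        raise ValueError("need at least 2 active units for percentile bounds")
    b1 = active[f"seg{paradigm.baseline1}"].to_numpy(dtype=float)
    b2 = active[f"seg{paradigm.baseline2}"].to_numpy(dtype=float)
    return InclusionBounds(
        baseline1=(float(sample_quantile(b1, 0.025)), float(sample_quantile(b1, 0.975))),
        baseline2=(float(sample_quantile(b2, 0.025)), float(sample_quantile(b2, 0.975))),
    )


def apply_inclusion(
    table: pd.DataFrame,
    bounds: InclusionBounds,
    paradigm: RecordingParadigm = DEFAULT_PARADIGM,
) -> pd.DataFrame:
    """Retain units whose baseline counts fall inside both windows (inclusive)."""
    _check_table(table)
    b1 = table[f"seg{paradigm.baseline1}"]
    b2 = table[f"seg{paradigm.baseline2}"]
    lo1, hi1 = bounds.baseline1
    lo2, hi2 = bounds.baseline2
    keep = (b1 >= lo1) & (b1 <= hi1) & (b2 >= lo2) & (b2 <= hi2)
    return table[keep].copy()


def classify_unit(counts, antagonist: str) -> str:
    """Pharmacological class from segments 1-3 and the well's antagonist.

    A strict decrease from baseline to the GABA segment followed by a
    strict increase under the antagonist marks the unit as GABA_A (if the
    well received bicuculline) or GABA_B (saclofen); anything else —
    including ties — is unclassified.
    """
    c = np.asarray(counts, dtype=float)
    if c.size < 3:
        raise ValueError("need segments 1-3 to classify")
    if antagonist not in ("bicuculline", "saclofen"):
        raise ValueError(f"unknown antagonist {antagonist!r}")
    if c[1] < c[0] and c[2] > c[1]:
        return "GABA_A" if antagonist == "bicuculline" else "GABA_B"
    return "unclassified"


def classify_units(table: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`classify_unit` to every row; adds a ``unit_class`` column."""
    _check_table(table)
    out = table.copy()
    out["unit_class"] = [
        classify_unit(row[["seg1", "seg2", "seg3"]].to_numpy(), row["antagonist"])
        for _, row in table.iterrows()
    ]
    return out


def normalize_unit(counts, analyzed_segments=None) -> np.ndarray:
    """Per-unit fractions of the total spike count over the analyzed segments.

    ``counts`` holds all 11 segments; the default analyzed window is
    segments 4-11 (the 0 uM reference plus the seven PFOS exposures).
    Raises on a zero total (such units are excluded upstream with a logged
    reason).
    """
    c = np.asarray(counts, dtype=float)
    idx = np.asarray(
        analyzed_segments if analyzed_segments is not None else DEFAULT_PARADIGM.analyzed_segments
    )
    sub = c[idx - 1]
    total = sub.sum()
    if total <= 0:
        raise ValueError("zero total spike count over analyzed segments")
    return sub / total


def normalize_units(
    table: pd.DataFrame, paradigm: RecordingParadigm = DEFAULT_PARADIGM
) -> tuple[pd.DataFrame, list[str]]:
    """Normalized fractions for every unit; returns (fractions, dropped units).

    Fractions are indexed by unit with one column per analyzed segment;
    units with zero analyzed-segment totals are dropped and reported.
    """
    _check_table(table)
    segs = paradigm.analyzed_segments
    rows, dropped = {}, []
    for _, row in table.iterrows():
        counts = row[list(SEGMENT_COLUMNS)].to_numpy(dtype=float)
        try:
            rows[row["unit"]] = normalize_unit(counts, segs)
        except ValueError:
            dropped.append(str(row["unit"]))
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"seg{s}" for s in segs]
    )
    frame.index.name = "unit"
    return frame, dropped


@dataclass
class ConcentrationResponseResult:
    """Friedman + Conover-vs-control + BH outcome for one unit class."""

    unit_class: str
    n_units: int
    friedman: TestResult
    concentrations_um: tuple[float, ...]
    conover: list[TestResult]
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "unit_class": self.unit_class,
            "n_units": self.n_units,
            "friedman": self.friedman.to_dict(),
            "concentrations_um": list(self.concentrations_um),
            "conover_statistics": [t.statistic for t in self.conover],
            "raw_p": [float(p) for p in self.raw_p],
            "adjusted_p": [float(p) for p in self.adjusted_p],
            "metadata": self.metadata,
        }


def concentration_response(
    normalized: pd.DataFrame,
    unit_class: str = "all",
    paradigm: RecordingParadigm = DEFAULT_PARADIGM,
) -> ConcentrationResponseResult:
    """Friedman over units x 8 conditions, Conover many-to-one versus the
    0 uM reference, BH adjustment of the 7 PFOS comparisons.

    ``normalized`` is the per-unit fraction table from
    :func:`normalize_units` (units as rows, analyzed segments as columns).
    """
    segs = [f"seg{s}" for s in paradigm.analyzed_segments]
    missing = [s for s in segs if s not in normalized.columns]
    if missing:
        raise ValueError(f"normalized table missing segments {missing}")
    if len(normalized) < 2:
        raise ValueError("need at least 2 units of the class")
    matrix = normalized[segs].to_numpy(dtype=float)
    if not np.isfinite(matrix).all():
        raise ValueError("incomplete blocks: every unit needs all 8 conditions")
    friedman = friedman_test(matrix)
    conover = conover_many_to_one(matrix, control_index=0, two_sided=True)
    raw = np.array([t.p_value for t in conover])
    adjusted = bh_adjust(raw)
    return ConcentrationResponseResult(
        unit_class=unit_class,
        n_units=len(normalized),
        friedman=friedman,
        concentrations_um=paradigm.pfos_concentrations_um,
        conover=conover,
        raw_p=raw,
        adjusted_p=adjusted,
        metadata={"control": "0 uM (segment 4)", "adjustment": "benjamini-hochberg"},
    )


def analyze_mea(
    table: pd.DataFrame, paradigm: RecordingParadigm = DEFAULT_PARADIGM
) -> dict:
    """Full chain: filter -> bounds -> inclusion -> classify -> normalize ->
    per-class concentration response.

    Returns a dict with the exclusion bookkeeping, per-unit classes, and a
    :class:`ConcentrationResponseResult` per pharmacological class with at
    least two units.
    """
    _check_table(table)
    active = filter_active_units(table, paradigm)
    bounds = compute_inclusion_bounds(active, paradigm)
    included = apply_inclusion(active, bounds, paradigm)
    classified = classify_units(included)
    normalized, dropped = normalize_units(classified, paradigm)
    results: dict[str, ConcentrationResponseResult] = {}
    for cls in ("GABA_A", "GABA_B"):
        units = classified.loc[classified["unit_class"] == cls, "unit"]
        sub = normalized.loc[normalized.index.intersection(units)]
        if len(sub) >= 2:
            results[cls] = concentration_response(sub, cls, paradigm)
    return {
        "n_input": int(len(table)),
        "n_active": int(len(active)),
        "bounds": bounds,
        "n_included": int(len(included)),
        "classes": classified.set_index("unit")["unit_class"].to_dict(),
        "dropped_zero_total": dropped,
        "results": results,
    }
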