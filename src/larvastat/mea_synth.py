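"""Synthetic per-unit MEA spike-count tables for the 11-segment
multi-neurotransmitter receptor paradigm.

Each simulated unit carries a true type: ``gabaA`` and ``gabaB`` units are
suppressed by the GABA application (segment 2) and rebound under their
matching antagonist (segment 3: bicuculline for GABA_A wells, saclofen for
GABA_B wells); ``nonresponsive`` units keep their baseline rate throughout;
``inactive`` units are silent in a baseline to exercise the activity
filter.  Counts are negative-binomial in the NB1 (constant Fano factor)
parameterization: variance = mean * (1 + dispersion), drawn as a
gamma-Poisson mixture.  Under PFOS (segments 5-11), responsive units' rates
are scaled by the per-concentration factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import DEFAULT_PARADIGM, RecordingParadigm

__all__ = ["MeaSimConfig", "simulate_paradigm"]

UNIT_TYPES = ("gabaA", "gabaB", "nonresponsive", "inactive")


@dataclass
class MeaSimConfig:
    """Study conditions for the MEA spike-count simulator.

    Defaults: baseline rate lognormal with median 200 spikes per 15-min
    segment (dispersion 0.5 on the log scale), NB1 overdispersion 5 (Fano
    factor 6), GABA suppressing responsive units to 0.3 x baseline and the
    matching antagonist rebounding them 2.5-fold from the suppressed level.
    PFOS factors default to 1.0 (no exposure effect); set them to simulate
    a concentration response.
    """

    n_units: dict = field(
        default_factory=lambda: {
            "gabaA": 30,
            "gabaB": 30,
            "nonresponsive": 30,
            "inactive": 10,
        }
    )
    baseline_median: float = 200.0
    baseline_log_sd: float = 0.5
    nb_dispersion: float = 5.0
    gaba_effect: float = 0.3
    antagonist_effect: float = 2.5
    pfos_effects: tuple[float, ...] = (1.0,) * 7
    units_per_well: int = 8
    #: "alternate": wells alternate antagonists irrespective of content;
    #: "matched": responsive units sit in wells receiving their own
    #: receptor's antagonist (the identifiable arrangement)
    antagonist_assignment: str = "alternate"
    seed: int = 0
    paradigm: RecordingParadigm = field(default_factory=lambda: DEFAULT_PARADIGM)

    def validate(self) -> None:
        if set(self.n_units) - set(UNIT_TYPES):
            raise ValueError(f"unit types must be among {UNIT_TYPES}")
        if any(v < 0 for v in self.n_units.values()):
            raise ValueError("unit counts must be >= 0")
        if self.baseline_median <= 0 or self.baseline_log_sd < 0:
            raise ValueError("baseline rate distribution parameters invalid")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.gaba_effect <= 0 or self.antagonist_effect <= 0:
            raise ValueError("multiplicative effects must be > 0")
        if len(self.pfos_effects) != len(self.paradigm.pfos_segments):
            raise ValueError("one PFOS factor per PFOS segment required")
        if any(f <= 0 for f in self.pfos_effects):
            raise ValueError("PFOS factors must be > 0")
        if self.units_per_well < 1:
            raise ValueError("units_per_well must be >= 1")
        if self.antagonist_assignment not in ("alternate", "matched"):
            raise ValueError("antagonist_assignment must be 'alternate' or 'matched'")

    def to_dict(self) -> dict:
        return {
            "n_units": dict(self.n_units),
            "baseline_median": self.baseline_median,
            "baseline_log_sd": self.baseline_log_sd,
            "nb_dispersion": self.nb_dispersion,
            "count_model": "NB1 (variance = mean * (1 + dispersion))",
            "gaba_effect": self.gaba_effect,
            "antagonist_effect": self.antagonist_effect,
            "pfos_effects": list(self.pfos_effects),
            "units_per_well": self.units_per_well,
            "seed": self.seed,
        }


def _nb1_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB1 draws: Poisson with gamma-mixed rate, var = mean*(1+dispersion)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = mean / dispersion
    rate = np.where(shape > 0, rng.gamma(np.maximum(shape, 1e-12), dispersion), 0.0)
    return rng.poisson(rate)


def _segment_means(
    unit_type: str, antagonist: str, baseline: float, config: MeaSimConfig
) -> np.ndarray:
    p = config.paradigm
    means = np.full(p.n_segments, baseline, dtype=float)
    responsive = unit_type in ("gabaA", "gabaB")
    if unit_type == "inactive":
        return np.zeros(p.n_segments)
    if responsive:
        suppressed = baseline * config.gaba_effect
        means[p.gaba - 1] = suppressed
        matches = (unit_type == "gabaA" and antagonist == "bicuculline") or (
            unit_type == "gabaB" and antagonist == "saclofen"
        )
        # rebound only under the matching antagonist; otherwise the agonist
        # suppression persists through segment 3
        means[p.antagonist - 1] = (
            suppressed * config.antagonist_effect if matches else suppressed
        )
        for k, seg in enumerate(p.pfos_segments):
            means[seg - 1] = baseline * config.pfos_effects[k]
    return means


def simulate_paradigm(config: MeaSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one spike-count table over the 11-segment paradigm.

    Returns (counts, truth): counts has columns unit, well, antagonist,
    seg1..seg11 (integer spikes per 15-min segment); truth carries each
    unit's true type and realized baseline rate.  Wells alternate between
    the two antagonists; a unit's classification opportunity therefore
    depends on its well, as in the physical assay.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.paradigm
    rows, truth_rows = [], []
    uid = 0
    for unit_type in UNIT_TYPES:
        for _ in range(int(config.n_units.get(unit_type, 0))):
            well_idx = uid // config.units_per_well
            if config.antagonist_assignment == "matched" and unit_type in ("gabaA", "gabaB"):
                antagonist = "bicuculline" if unit_type == "gabaA" else "saclofen"
            else:
                antagonist = p.antagonists[well_idx % 2]
            baseline = float(
                config.baseline_median * np.exp(rng.normal(0.0, config.baseline_log_sd))
            )
            means = _segment_means(unit_type, antagonist, baseline, config)
            counts = _nb1_counts(rng, means, config.nb_dispersion)
            unit = f"u{uid:05d}"
            rows.append(
                {
                    "unit": unit,
                    "well": f"w{well_idx:03d}",
                    "antagonist": antagonist,
                    **{f"seg{k + 1}": int(c) for k, c in enumerate(counts)},
                }
            )
            truth_rows.append(
                {
                    "unit": unit,
                    "true_type": unit_type,
                    "baseline_rate": baseline,
                    "antagonist": antagonist,
                }
            )
            uid += 1
    counts = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return counts, truth
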