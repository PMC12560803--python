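"""Synthetic larval locomotion data with the structure the behavioral
analysis assumes.

Two fidelity levels:

* :func:`simulate_bins` draws 2-min activity sums directly from the
  generative counterpart of the fitted model — beta responses with
  logit-scale smooth time trend, treatment/phase effects and per-larva
  random intercepts.  This is the level the statistical model describes.
* :func:`simulate_trace` emits full 1-s distance traces over the 3720-s
  assay with phase-dependent mean activity, 3-s startle bursts after each
  illumination transition, and viability flags.  Per-second values are
  gamma-distributed; trace-level realism is limited to what the binning and
  startle code needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .protocol import DEFAULT_PROTOCOL, AssayProtocol

__all__ = ["BehaviorSimConfig", "simulate_bins", "simulate_trace"]


def _default_logit_effects() -> dict:
    # dark-phase hyperactivity of the exposed group, on the logit scale
    return {("PFOS", "D1"): 1.0, ("PFOS", "D2"): 1.0}


def _default_phase_effects() -> dict:
    # larvae swim more in the dark; L1 is the reference phase
    return {"L1": 0.0, "L2": -0.1, "D1": 0.8, "D2": 0.6}


@dataclass
class BehaviorSimConfig:
    """Study conditions for the behavioral simulator.

    Defaults mirror a two-arm acute-exposure experiment: 24 larvae per
    group (replicate counts in such assays typically run 21-45), beta
    precision phi = 20, per-larva random-intercept SD 0.5 on the logit
    scale, and a +1.0 logit dark-phase interaction for the exposed group.
    """

    n_per_group: int = 24
    treatment_labels: tuple[str, ...] = ("control", "PFOS")
    logit_intercept: float = -1.0
    phase_effects: dict = field(default_factory=_default_phase_effects)
    treatment_effects: dict = field(default_factory=dict)  # main effects by label
    logit_effects: dict = field(default_factory=_default_logit_effects)
    time_trend_amplitude: float = 0.3  # logit-scale sinusoid over the assay
    random_sd: float = 0.5
    precision: float = 20.0
    startle_magnitude: float = 6.0  # cm summed over the 3-s burst
    baseline_rates: dict = field(
        default_factory=lambda: {"acclimation": 0.10, "light": 0.15, "dark": 0.35}
    )  # mean cm/s by illumination context at trace level
    exclusion_rate: float = 0.02
    seed: int = 0
    protocol: AssayProtocol = field(default_factory=lambda: DEFAULT_PROTOCOL)

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not self.treatment_labels:
            raise ValueError("at least one treatment label required")
        if self.precision <= 0:
            raise ValueError("beta precision phi must be > 0")
        if self.random_sd < 0:
            raise ValueError("random_sd must be >= 0")
        if not (0.0 <= self.exclusion_rate <= 1.0):
            raise ValueError("exclusion_rate must lie in [0, 1]")
        if self.startle_magnitude < 0:
            raise ValueError("startle_magnitude must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_per_group": self.n_per_group,
            "treatment_labels": list(self.treatment_labels),
            "logit_intercept": self.logit_intercept,
            "phase_effects": dict(self.phase_effects),
            "treatment_effects": dict(self.treatment_effects),
            "logit_effects": {f"{t}|{p}": v for (t, p), v in self.logit_effects.items()},
            "time_trend_amplitude": self.time_trend_amplitude,
            "random_sd": self.random_sd,
            "precision": self.precision,
            "startle_magnitude": self.startle_magnitude,
            "exclusion_rate": self.exclusion_rate,
            "seed": self.seed,
        }


def _bin_times(protocol: AssayProtocol) -> list[tuple[str, int, float]]:
    out = []
    for phase, (start, _) in protocol.phase_windows.items():
        for k in range(protocol.bins_per_phase):
            mid = start + protocol.bin_seconds * k + protocol.bin_seconds / 2.0
            out.append((phase, k + 1, mid))
    return out


def true_linear_predictor(
    config: BehaviorSimConfig, treatment: str, phase: str, time_s: float
) -> float:
    """Logit-scale mean for one cell at one time, excluding the random intercept."""
    eta = config.logit_intercept
    eta += config.phase_effects.get(phase, 0.0)
    eta += config.treatment_effects.get(treatment, 0.0)
    eta += config.logit_effects.get((treatment, phase), 0.0)
    eta += config.time_trend_amplitude * np.sin(
        2.0 * np.pi * time_s / config.protocol.total_seconds
    )
    return float(eta)


def simulate_bins(config: BehaviorSimConfig) -> tuple[pd.DataFrame, dict]:
    """Draw scaled 2-min activity bins from the generative beta model.

    Returns (table, truth): the table has columns animal, treatment, phase,
    bin, time_s, value with values strictly in (0, 1); truth records the
    parameters used, including each larva's random intercept.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    intercepts: dict[str, float] = {}
    bins = _bin_times(config.protocol)
    for treatment in config.treatment_labels:
        for i in range(config.n_per_group):
            animal = f"{treatment}_{i + 1:03d}"
            b = rng.normal(0.0, config.random_sd) if config.random_sd > 0 else 0.0
            intercepts[animal] = b
            for phase, bin_idx, mid in bins:
                eta = true_linear_predictor(config, treatment, phase, mid) + b
                mu = float(np.clip(special.expit(eta), 1e-9, 1 - 1e-9))
                y = rng.beta(mu * config.precision, (1.0 - mu) * config.precision)
                y = float(np.clip(y, 1e-9, 1.0 - 1e-9))
                rows.append((animal, treatment, phase, bin_idx, mid, y))
    table = pd.DataFrame(
        rows, columns=["animal", "treatment", "phase", "bin", "time_s", "value"]
    )
    truth = {
        "config": config.to_dict(),
        "random_intercepts": intercepts,
        "interaction_effects": {f"{t}|{p}": v for (t, p), v in config.logit_effects.items()},
    }
    return table, truth


def simulate_trace(config: BehaviorSimConfig) -> tuple[pd.DataFrame, dict]:
    """Per-second locomotion traces for the full 0-3720 s assay.

    Each larva gets gamma-distributed per-second distances whose mean
    follows the illumination context (multiplied by exp(logit effects) for
    its treatment/phase), a startle burst summing to ``startle_magnitude``
    spread over the 3 s after each transition, and Bernoulli viability
    flags at ``exclusion_rate`` (split across dead / malformed / uninflated
    swim bladder).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    proto = config.protocol
    t = np.arange(proto.total_seconds)
    context = np.full(proto.total_seconds, "acclimation", dtype=object)
    context[(t >= proto.light[0]) & (t < proto.light[1])] = "light"
    context[t >= proto.dark[0]] = "dark"
    phase_of_second = np.full(proto.total_seconds, "", dtype=object)
    for ph, (a, b) in proto.phase_windows.items():
        phase_of_second[(t >= a) & (t < b)] = ph

    burst_weights = np.array([0.5, 0.3, 0.2])
    flag_names = ("dead", "malformed", "uninflated")
    rows = []
    truth_flags = {}
    for treatment in config.treatment_labels:
        for i in range(config.n_per_group):
            animal = f"{treatment}_{i + 1:03d}"
            larva_scale = float(np.exp(rng.normal(0.0, config.random_sd)))
            mean = np.array([config.baseline_rates[c] for c in context]) * larva_scale
            for ph, (a, b) in proto.phase_windows.items():
                eff = config.logit_effects.get((treatment, ph), 0.0)
                eff += config.treatment_effects.get(treatment, 0.0)
                mean[a:b] *= np.exp(eff)
            shape = 2.0  # gamma shape: mild per-second burstiness
            dist = rng.gamma(shape, mean / shape)
            for _, (w0, _w1) in proto.vsr_windows.items():
                dist[w0 : w0 + 3] += config.startle_magnitude * burst_weights
            flags = dict.fromkeys(flag_names, False)
            if config.exclusion_rate > 0 and rng.random() < config.exclusion_rate:
                flags[flag_names[rng.integers(0, len(flag_names))]] = True
            truth_flags[animal] = flags
            rows.append(
                pd.DataFrame(
                    {
                        "experiment": "sim",
                        "animal": animal,
                        "treatment": treatment,
                        "time_s": t,
                        "distance_cm": dist,
                        "dead": flags["dead"],
                        "malformed": flags["malformed"],
                        "uninflated": flags["uninflated"],
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    truth = {"config": config.to_dict(), "flags": truth_flags}
    return table, truth
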