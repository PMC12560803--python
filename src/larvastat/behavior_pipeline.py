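"""Light-dark transition analysis pipeline.

Steps: viability exclusions -> 2-min phase binning -> scaling of bins into
the open unit interval (1.001 x the experiment-wide maximum 2-min sum) ->
penalized logit-beta mixed model with EMM / single-step Tukey-style /
compact-letter post hoc at alpha = 0.05 -> the visual startle response
(3-s post-transition sums) with its Gaussian random-intercept model and the
same post hoc chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beta_gamm import BetaGammFit, fit_beta_gamm
from .lmm import LmmFit, fit_gaussian_lmm
from .model_spec import ModelSpec, SmoothTerm
from .posthoc import ContrastResult, EmmEstimate, compact_letters, estimate_emms, tukey_pairwise
from .protocol import DEFAULT_PROTOCOL, AssayProtocol

__all__ = [
    "ExclusionReport",
    "exclude_invalid",
    "bin_distances",
    "compute_scale",
    "scale_bins",
    "compute_vsr",
    "PhaseAnalysisResult",
    "VsrAnalysisResult",
    "analyze_phases",
    "analyze_vsr",
]

FLAG_COLUMNS = ("dead", "malformed", "uninflated")


@dataclass(frozen=True)
class ExclusionReport:
    n_input: int
    n_retained: int
    counts_by_reason: dict

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "counts_by_reason": dict(self.counts_by_reason),
        }


def exclude_invalid(traces: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop larvae flagged dead, malformed, or with an uninflated swim bladder.

    Any true flag excludes the larva.  The report counts excluded larvae per
    reason (a larva with several flags counts under each).
    """
    for col in FLAG_COLUMNS:
        if col not in traces.columns:
            raise ValueError(f"missing viability flag column {col!r}")
    per_animal = traces.groupby("animal")[list(FLAG_COLUMNS)].any()
    bad = per_animal.any(axis=1)
    counts = {c: int(per_animal[c].sum()) for c in FLAG_COLUMNS if per_animal[c].any()}
    keep = per_animal.index[~bad]
    retained = traces[traces["animal"].isin(keep)].copy()
    return retained, ExclusionReport(
        n_input=int(per_animal.shape[0]),
        n_retained=int(keep.size),
        counts_by_reason=counts,
    )


def bin_distances(
    traces: pd.DataFrame, protocol: AssayProtocol = DEFAULT_PROTOCOL
) -> pd.DataFrame:
    """Five consecutive 120-s distance sums per assay phase per larva.

    The acclimation period and the final 120 s of the dark period are not
    binned.  Raises, naming the gap, if any phase second is missing.
    """
    required = {"animal", "treatment", "time_s", "distance_cm"}
    if not required.issubset(traces.columns):
        raise ValueError(f"trace table must have columns {sorted(required)}")
    rows = []
    for (animal, treatment), sub in traces.groupby(["animal", "treatment"], sort=False):
        times = sub["time_s"].to_numpy()
        dist = sub["distance_cm"].to_numpy(dtype=float)
        lookup = pd.Series(dist, index=times)
        if lookup.index.has_duplicates:
            dup = lookup.index[lookup.index.duplicated()][0]
            raise ValueError(f"duplicate time {dup} for animal {animal!r}")
        for phase, (start, end) in protocol.phase_windows.items():
            needed = np.arange(start, end)
            missing = np.setdiff1d(needed, times)
            if missing.size:
                raise ValueError(
                    f"animal {animal!r}: missing seconds in phase {phase} "
                    f"(first gap at t={int(missing[0])} s)"
                )
            vals = lookup.reindex(needed).to_numpy()
            sums = vals.reshape(protocol.bins_per_phase, protocol.bin_seconds).sum(axis=1)
            for k, s in enumerate(sums):
                mid = start + protocol.bin_seconds * k + protocol.bin_seconds / 2.0
                rows.append((animal, treatment, phase, k + 1, mid, float(s)))
    return pd.DataFrame(
        rows, columns=["animal", "treatment", "phase", "bin", "time_s", "distance_cm"]
    )


def compute_scale(bins: pd.DataFrame, factor: float = 1.001) -> float:
    """Scale constant M = 1.001 x the maximum 2-min sum across all larvae
    of the experiment.

    One constant per experiment (the experiment-wide maximum over per-larva
    sums) so that scaled values are comparable across groups.
    """
    if bins.empty:
        raise ValueError("no bins to scale")
    m = float(bins["distance_cm"].max())
    if m <= 0:
        raise ValueError("scale undefined: all bins are zero")
    return factor * m


def scale_bins(bins: pd.DataFrame, m: float, epsilon: float = 1e-6) -> pd.DataFrame:
    """Map bins into (0, 1) by value/M, nudging exact zeros to ``epsilon``."""
    if m <= 0:
        raise ValueError("scale constant must be positive")
    if not (0.0 < epsilon < 1.0):
        raise ValueError("epsilon must lie in (0, 1)")
    vals = bins["distance_cm"].to_numpy(dtype=float)
    if np.any(vals > m):
        raise ValueError("bin value exceeds the scale constant")
    scaled = vals / m
    scaled[scaled == 0.0] = epsilon
    out = bins.copy()
    out["value"] = scaled
    out["scale_constant"] = m
    return out


def compute_vsr(
    traces: pd.DataFrame, protocol: AssayProtocol = DEFAULT_PROTOCOL
) -> pd.DataFrame:
    """Summed distance in the 3 s after each illumination transition.

    VSR1 follows the dark-to-light transition (1200 s), VSR2 the
    light-to-dark transition (2400 s); the window is the first 3 full
    seconds at and after the transition second.
    """
    rows = []
    for (animal, treatment), sub in traces.groupby(["animal", "treatment"], sort=False):
        lookup = pd.Series(
            sub["distance_cm"].to_numpy(dtype=float), index=sub["time_s"].to_numpy()
        )
        for name, (start, end) in protocol.vsr_windows.items():
            needed = np.arange(start, end)
            vals = lookup.reindex(needed)
            if vals.isna().any():
                missing = needed[vals.isna().to_numpy()][0]
                raise ValueError(
                    f"animal {animal!r}: missing second t={int(missing)} in {name} window"
                )
            rows.append((animal, treatment, name, float(vals.sum())))
    return pd.DataFrame(rows, columns=["animal", "treatment", "startle_phase", "vsr_cm"])


@dataclass
class PhaseAnalysisResult:
    fit: BetaGammFit
    emms: list[EmmEstimate]
    contrasts: list[ContrastResult]
    letters: dict
    alpha: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fit": self.fit.to_dict(),
            "emms": [e.to_dict() for e in self.emms],
            "contrasts": [c.to_dict() for c in self.contrasts],
            "letters": dict(self.letters),
            "alpha": self.alpha,
            "metadata": self.metadata,
        }


@dataclass
class VsrAnalysisResult(PhaseAnalysisResult):
    pass


def _posthoc_chain(fit, alpha: float):
    emms = estimate_emms(fit)
    cells = [e.label for e in emms]
    if len(cells) < 2:
        return emms, [], {cells[0]: "a"} if cells else {}
    contrasts = tukey_pairwise(fit, emms, alpha=alpha)
    letters = compact_letters(contrasts, cells, alpha=alpha)
    return emms, contrasts, letters


def analyze_phases(
    scaled_bins: pd.DataFrame,
    spec: ModelSpec | None = None,
    alpha: float = 0.05,
    ar1_rho: float | None = None,
) -> PhaseAnalysisResult:
    """Fit the beta GAMM to scaled bins and run the full post hoc chain.

    Non-convergence raises rather than producing silent post-hoc output.
    """
    if spec is None:
        spec = ModelSpec(
            response="value",
            fixed_factors=("treatment", "phase"),
            interactions=(("treatment", "phase"),),
            smooth_terms=(SmoothTerm("time_s"),),
            random_intercept_factor="animal",
            family="beta-logit",
        )
    fit = fit_beta_gamm(scaled_bins, spec, ar1_rho=ar1_rho)
    if not fit.converged:
        raise RuntimeError("beta GAMM did not converge; post hoc comparisons withheld")
    emms, contrasts, letters = _posthoc_chain(fit, alpha)
    return PhaseAnalysisResult(
        fit=fit,
        emms=emms,
        contrasts=contrasts,
        letters=letters,
        alpha=alpha,
        metadata={"ar1_rho": ar1_rho, "scale": "logit"},
    )


def analyze_vsr(
    vsr: pd.DataFrame, spec: ModelSpec | None = None, alpha: float = 0.05
) -> VsrAnalysisResult:
    """Fit the Gaussian LMM to startle sums and run the post hoc chain.

    Pairwise comparisons are between treatments, marginal to startle phase
    (the model has no treatment-by-phase interaction, so within-phase
    treatment differences equal the marginal ones).
    """
    if spec is None:
        spec = ModelSpec(
            response="vsr_cm",
            fixed_factors=("treatment", "startle_phase"),
            interactions=(),
            smooth_terms=(),
            random_intercept_factor="animal",
            family="gaussian-identity",
        )
    if vsr["startle_phase"].nunique() < 2:
        raise ValueError("both startle phases (VSR1, VSR2) are required")
    fit = fit_gaussian_lmm(vsr, spec)
    if not fit.converged:
        raise RuntimeError("LMM did not converge; post hoc comparisons withheld")
    trt_factor = spec.fixed_factors[0]
    cells = [{trt_factor: lv} for lv in fit.coding.levels[trt_factor]]
    emms = estimate_emms(fit, cells)
    labels = [e.label for e in emms]
    if len(labels) < 2:
        contrasts: list[ContrastResult] = []
        letters = {labels[0]: "a"}
    else:
        contrasts = tukey_pairwise(fit, emms, alpha=alpha)
        letters = compact_letters(contrasts, labels, alpha=alpha)
    return VsrAnalysisResult(
        fit=fit,
        emms=emms,
        contrasts=contrasts,
        letters=letters,
        alpha=alpha,
        metadata={"scale": "cm"},
    )
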