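"""Estimated marginal means, single-step Tukey-style adjustment, and
compact letter displays.

EMMs are the model's linear predictor evaluated on the treatment-by-phase
grid with the time smooth held at its data average and the random intercept
at zero; standard errors come from the coefficient covariance by the delta
method (here the predictor is linear, so exactly L V L').  All pairwise
contrasts are tested on the z scale and adjusted by the single-step
max-|z| familywise method, integrating over the estimated contrast
correlation by Monte Carlo with a fixed internal seed.  Letters follow the
insert-and-absorb algorithm: cells share a letter iff their adjusted p-value
is at or above alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EmmEstimate",
    "ContrastResult",
    "estimate_emms",
    "tukey_pairwise",
    "compact_letters",
]

_MC_SEED = 20240521
_MC_DRAWS = 100_000


@dataclass(frozen=True)
class EmmEstimate:
    """Model-based mean of one factor-level cell (link scale for beta fits)."""

    cell: tuple[tuple[str, str], ...]  # ((factor, level), ...)
    estimate: float
    se: float
    df: float  # inf encodes the normal approximation

    @property
    def label(self) -> str:
        return " ".join(level for _, level in self.cell)

    def to_dict(self) -> dict:
        return {
            "cell": dict(self.cell),
            "estimate": float(self.estimate),
            "se": float(self.se),
            "df": self.df if np.isfinite(self.df) else "inf",
        }


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise difference between cells, with familywise-adjusted p."""

    pair: tuple[str, str]
    estimate: float
    se: float
    z: float
    raw_p: float
    adjusted_p: float

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "estimate": float(self.estimate),
            "se": float(self.se),
            "z": float(self.z),
            "raw_p": float(self.raw_p),
            "adjusted_p": float(self.adjusted_p),
        }


def _design_row(fit, cell: dict[str, str]) -> np.ndarray:
    """Design row for a (possibly partial) cell; unspecified factors are
    averaged over their levels (marginal EMM, emmeans convention)."""
    from itertools import product

    missing = [f for f in fit.coding.factors if f not in cell]
    if not missing:
        return fit.emm_design_row(cell)
    rows = [
        fit.emm_design_row({**cell, **dict(zip(missing, combo))})
        for combo in product(*[fit.coding.levels[f] for f in missing])
    ]
    return np.mean(rows, axis=0)


def estimate_emms(fit, cells: list[dict[str, str]] | None = None) -> list[EmmEstimate]:
    """Estimated marginal means for the given factor cells (default: full grid).

    Cells may omit factors, in which case the mean is marginal (the design
    row averaged over the omitted factor's levels).  ``fit`` is any object
    with ``coding``, ``coef_covariance``, ``emm_design_row`` and
    ``converged`` attributes.
    """
    if not fit.converged:
        raise ValueError("cannot compute EMMs from a non-converged fit")
    if cells is None:
        cells = fit.coding.cells()
    theta = _full_coefficients(fit)
    v = fit.coef_covariance
    out: list[EmmEstimate] = []
    for cell in cells:
        row = _design_row(fit, cell)
        if row.size != theta.size:
            row = row[: theta.size]
        est = float(row @ theta)
        var = float(row @ v[: row.size, : row.size] @ row)
        out.append(
            EmmEstimate(
                cell=tuple((f, str(cell[f])) for f in fit.coding.factors if f in cell),
                estimate=est,
                se=float(np.sqrt(max(var, 0.0))),
                df=np.inf,
            )
        )
    return out


def _full_coefficients(fit) -> np.ndarray:
    parts = [np.asarray(fit.fixed_coefficients, dtype=float)]
    if hasattr(fit, "spline_coefficients"):
        parts.append(np.asarray(fit.spline_coefficients, dtype=float))
    if hasattr(fit, "random_intercepts"):
        parts.append(np.asarray(fit.random_intercepts, dtype=float))
    return np.concatenate(parts)


def tukey_pairwise(
    fit,
    emms: list[EmmEstimate] | None = None,
    alpha: float = 0.05,
    mc_draws: int = _MC_DRAWS,
    cells: list[dict[str, str]] | None = None,
) -> list[ContrastResult]:
    """All pairwise contrasts among the EMM cells with single-step
    familywise adjustment.

    The adjusted p-value of contrast i is P(max_j |Z_j| >= |z_i|) under the
    joint null N(0, R) with R the estimated correlation of the contrasts
    (Monte Carlo, fixed seed, ``mc_draws`` draws).  With a single contrast
    the raw two-sided p is returned unchanged; adjusted_p is never below
    raw_p.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if emms is None:
        emms = estimate_emms(fit, cells)
    if len(emms) < 2:
        raise ValueError("need at least 2 cells for pairwise contrasts")
    rows = np.vstack([_design_row(fit, dict(e.cell)) for e in emms])
    theta = _full_coefficients(fit)
    v = fit.coef_covariance[: rows.shape[1], : rows.shape[1]]
    if np.min(np.linalg.eigvalsh((v + v.T) / 2.0)) < -1e-6 * max(1.0, np.abs(v).max()):
        raise ValueError("coefficient covariance is not positive semi-definite")

    k = len(emms)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    c_mat = np.zeros((len(pairs), rows.shape[1]))
    for idx, (i, j) in enumerate(pairs):
        c_mat[idx] = rows[i] - rows[j]
    est = c_mat @ theta
    cov_c = c_mat @ v @ c_mat.T
    se = np.sqrt(np.maximum(np.diag(cov_c), 1e-300))
    z = est / se
    raw = 2.0 * stats.norm.sf(np.abs(z))

    if len(pairs) == 1:
        adjusted = raw.copy()
    else:
        corr = cov_c / np.outer(se, se)
        corr = (corr + corr.T) / 2.0
        np.fill_diagonal(corr, 1.0)
        # nearest-PSD guard for numerically deficient families
        w, q = np.linalg.eigh(corr)
        w = np.clip(w, 1e-10, None)
        root = q * np.sqrt(w)
        rng = np.random.default_rng(_MC_SEED)
        draws = rng.standard_normal((mc_draws, corr.shape[0])) @ root.T
        scale = np.sqrt((root**2).sum(axis=1))
        maxabs = np.max(np.abs(draws / scale), axis=1)
        adjusted = np.array([(maxabs >= abs(zi)).mean() for zi in z])
        adjusted = np.maximum(adjusted, raw)

    labels = [e.label for e in emms]
    return [
        ContrastResult(
            pair=(labels[i], labels[j]),
            estimate=float(est[idx]),
            se=float(se[idx]),
            z=float(z[idx]),
            raw_p=float(raw[idx]),
            adjusted_p=float(min(adjusted[idx], 1.0)),
        )
        for idx, (i, j) in enumerate(pairs)
    ]


def compact_letters(
    contrasts: list[ContrastResult], cells: list[str], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Two cells share at least one letter iff their adjusted p-value is
    >= alpha.  Raises if any pair of ``cells`` lacks a contrast.
    """
    pmap: dict[frozenset[str], float] = {}
    for c in contrasts:
        pmap[frozenset(c.pair)] = c.adjusted_p
    for i, a in enumerate(cells):
        for b in cells[i + 1 :]:
            if frozenset((a, b)) not in pmap:
                raise ValueError(f"missing contrast for pair ({a}, {b})")

    def differ(a: str, b: str) -> bool:
        return a != b and pmap[frozenset((a, b))] < alpha

    # start with one letter containing every cell; split on each significant pair
    groups: list[set[str]] = [set(cells)]
    for i, a in enumerate(cells):
        for b in cells[i + 1 :]:
            if not differ(a, b):
                continue
            for g in list(groups):
                if a in g and b in g:
                    groups.remove(g)
                    groups.extend([g - {a}, g - {b}])
            # absorb: drop groups contained in another
            groups = [
                g
                for g in groups
                if g and not any(g < h for h in groups if h is not g)
            ]
    # deduplicate while keeping insertion order
    unique: list[set[str]] = []
    for g in groups:
        if g not in unique:
            unique.append(g)
    unique.sort(key=lambda g: min(cells.index(c) for c in g))
    letters = "abcdefghijklmnopqrstuvwxyz"
    if len(unique) > len(letters):
        raise ValueError("too many letter groups")
    out = {c: "" for c in cells}
    for letter, g in zip(letters, unique):
        for c in g:
            out[c] += letter
    for c, s in out.items():
        if not s:
            raise ValueError(f"cell {c!r} received no letter")
    return {c: "".join(sorted(s)) for c, s in out.items()}
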