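"""Model specification and fixed-effect design construction.

Both mixed-model families share one formula shape: categorical fixed factors
(treatment/concentration and assay phase) with optional pairwise
interactions, an optional penalized smooth of time, and a single
random-intercept grouping factor (the animal).  :class:`FactorCoding` builds
the treatment-coded (reference level) fixed-effect design and can produce
the design row of any factor-level cell, which is what estimated marginal
means need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = ["SmoothTerm", "ModelSpec", "FactorCoding"]


@dataclass(frozen=True)
class SmoothTerm:
    """A penalized spline smooth of one covariate.

    basis_size cubic B-spline functions with a difference penalty of the
    given order on adjacent coefficients.
    """

    covariate: str
    basis_size: int = 10
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.basis_size < 4:
            raise ValueError("spline basis size must be >= 4")
        if self.penalty_order < 1:
            raise ValueError("penalty order must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed model.

    Parameters
    ----------
    response
        Column holding the response: strictly inside (0, 1) for the
        beta-logit family, real-valued for gaussian-identity.
    fixed_factors
        Categorical fixed-effect columns, e.g. ``["treatment", "phase"]``.
    interactions
        Pairs of factor names whose interaction enters the model; every
        name must also appear in ``fixed_factors``.
    smooth_terms
        Penalized smooths (typically a single smooth of time).
    random_intercept_factor
        Grouping column for the per-animal random intercept.
    family
        ``"beta-logit"`` or ``"gaussian-identity"``.
    """

    response: str
    fixed_factors: tuple[str, ...]
    random_intercept_factor: str
    family: Literal["beta-logit", "gaussian-identity"] = "beta-logit"
    interactions: tuple[tuple[str, str], ...] = ()
    smooth_terms: tuple[SmoothTerm, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_factors", tuple(self.fixed_factors))
        object.__setattr__(
            self, "interactions", tuple(tuple(i) for i in self.interactions)
        )
        object.__setattr__(self, "smooth_terms", tuple(self.smooth_terms))
        if not self.fixed_factors:
            raise ValueError("at least one fixed factor is required")
        for pair in self.interactions:
            if len(pair) != 2:
                raise ValueError("interactions must be pairs of factor names")
            for name in pair:
                if name not in self.fixed_factors:
                    raise ValueError(
                        f"interaction factor {name!r} is not a main fixed factor"
                    )
        if not self.random_intercept_factor:
            raise ValueError("exactly one random-intercept factor is required")
        if self.family not in ("beta-logit", "gaussian-identity"):
            raise ValueError(f"unknown family {self.family!r}")

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "fixed_factors": list(self.fixed_factors),
            "interactions": [list(p) for p in self.interactions],
            "smooth_terms": [
                {
                    "covariate": s.covariate,
                    "basis_size": s.basis_size,
                    "penalty_order": s.penalty_order,
                }
                for s in self.smooth_terms
            ],
            "random_intercept_factor": self.random_intercept_factor,
            "family": self.family,
        }


@dataclass
class FactorCoding:
    """Treatment (reference-level) coding for the fixed-effect part.

    Levels are recorded in order of first appearance in the data so that a
    fitted model and later EMM grids agree on the reference level.
    """

    factors: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...]
    levels: dict[str, list[str]] = field(default_factory=dict)
    column_names: list[str] = field(default_factory=list)

    @classmethod
    def from_data(
        cls,
        data: pd.DataFrame,
        factors: Sequence[str],
        interactions: Sequence[tuple[str, str]] = (),
    ) -> "FactorCoding":
        coding = cls(tuple(factors), tuple(tuple(i) for i in interactions))
        for f in factors:
            if f not in data.columns:
                raise ValueError(f"factor column {f!r} missing from data")
            lv = [str(v) for v in pd.unique(data[f].astype(str))]
            if len(lv) < 1:
                raise ValueError(f"factor {f!r} has no levels")
            coding.levels[f] = lv
        names = ["(Intercept)"]
        for f in factors:
            names += [f"{f}[{lv}]" for lv in coding.levels[f][1:]]
        for fa, fb in coding.interactions:
            for la in coding.levels[fa][1:]:
                for lb in coding.levels[fb][1:]:
                    names.append(f"{fa}[{la}]:{fb}[{lb}]")
        coding.column_names = names
        return coding

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def row(self, cell: dict[str, str]) -> np.ndarray:
        """Design row for one factor-level combination."""
        parts = [1.0]
        ind: dict[tuple[str, str], float] = {}
        for f in self.factors:
            if f not in cell:
                raise ValueError(f"cell is missing factor {f!r}")
            lv = str(cell[f])
            if lv not in self.levels[f]:
                raise ValueError(f"level {lv!r} of factor {f!r} absent from design")
            for other in self.levels[f][1:]:
                ind[(f, other)] = 1.0 if lv == other else 0.0
                parts.append(ind[(f, other)])
        for fa, fb in self.interactions:
            for la in self.levels[fa][1:]:
                for lb in self.levels[fb][1:]:
                    parts.append(ind[(fa, la)] * ind[(fb, lb)])
        return np.asarray(parts)

    def matrix(self, data: pd.DataFrame) -> np.ndarray:
        """Fixed-effect design matrix for a data frame (rows in data order)."""
        cols = {f: data[f].astype(str).to_numpy() for f in self.factors}
        n = len(data)
        out = np.empty((n, self.n_columns))
        out[:, 0] = 1.0
        j = 1
        ind: dict[tuple[str, str], np.ndarray] = {}
        for f in self.factors:
            vals = cols[f]
            unseen = set(np.unique(vals)) - set(self.levels[f])
            if unseen:
                raise ValueError(f"unknown levels {sorted(unseen)} for factor {f!r}")
            for lv in self.levels[f][1:]:
                ind[(f, lv)] = (vals == lv).astype(float)
                out[:, j] = ind[(f, lv)]
                j += 1
        for fa, fb in self.interactions:
            for la in self.levels[fa][1:]:
                for lb in self.levels[fb][1:]:
                    out[:, j] = ind[(fa, la)] * ind[(fb, lb)]
                    j += 1
        return out

    def cells(self) -> list[dict[str, str]]:
        """The full factor grid, in level order."""
        grid: list[dict[str, str]] = [{}]
        for f in self.factors:
            grid = [{**g, f: lv} for g in grid for lv in self.levels[f]]
        return grid
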