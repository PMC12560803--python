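"""Gaussian random-intercept linear mixed model for startle-response sums.

The visual startle response (summed distance in the 3 s after a light
transition) is modeled as

    vsr ~ treatment + startle_phase + (1 | animal) + e,   e ~ N(0, sigma_e^2)

REML estimation is delegated to :class:`statsmodels.regression.mixed_linear_model.MixedLM`;
this module supplies design construction, aliased-column detection, and the
:class:`LmmFit` container the post-hoc machinery consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

from .model_spec import FactorCoding, ModelSpec

__all__ = ["LmmFit", "fit_gaussian_lmm"]


@dataclass
class LmmFit:
    """A fitted Gaussian random-intercept model (REML)."""

    spec: ModelSpec
    coding: FactorCoding
    fixed_coefficients: pd.Series
    random_sd: float
    residual_sd: float
    coef_covariance: np.ndarray  # fixed-effect covariance
    converged: bool
    n_obs: int
    n_groups: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_coefficients)

    def emm_design_row(self, cell: dict[str, str]) -> np.ndarray:
        return self.coding.row(cell)

    def to_dict(self) -> dict:
        return {
            "family": "gaussian-identity",
            "spec": self.spec.to_dict(),
            "fixed_coefficients": {k: float(v) for k, v in self.fixed_coefficients.items()},
            "random_sd": float(self.random_sd),
            "residual_sd": float(self.residual_sd),
            "converged": bool(self.converged),
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "metadata": self.metadata,
        }


def fit_gaussian_lmm(data: pd.DataFrame, spec: ModelSpec) -> LmmFit:
    """REML fit of the random-intercept model described by ``spec``.

    Raises ``ValueError`` naming the aliased design columns if the
    fixed-effect design is rank deficient.
    """
    if spec.family != "gaussian-identity":
        raise ValueError("fit_gaussian_lmm requires the gaussian-identity family")
    if spec.smooth_terms:
        raise ValueError("smooth terms are not supported in the Gaussian LMM")
    y = data[spec.response].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite responses")

    coding = FactorCoding.from_data(data, spec.fixed_factors, spec.interactions)
    x = coding.matrix(data)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify aliased columns by greedy QR-style scan
        aliased: list[str] = []
        kept: list[int] = []
        for j in range(x.shape[1]):
            trial = x[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(coding.column_names[j])
        raise ValueError(f"singular fixed-effect design; aliased columns: {aliased}")

    groups = data[spec.random_intercept_factor].astype(str).to_numpy()
    model = MixedLM(y, x, groups=groups)
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for methods in (["bfgs"], ["powell"], ["nm"]):
            try:
                result = model.fit(reml=True, method=methods)
                break
            except np.linalg.LinAlgError:
                continue
    if result is None:
        raise RuntimeError("REML optimization failed for every optimizer")

    k = x.shape[1]
    cov = np.asarray(result.cov_params())[:k, :k]
    re_var = float(np.asarray(result.cov_re).ravel()[0])
    return LmmFit(
        spec=spec,
        coding=coding,
        fixed_coefficients=pd.Series(np.asarray(result.fe_params), index=coding.column_names),
        random_sd=float(np.sqrt(max(re_var, 0.0))),
        residual_sd=float(np.sqrt(result.scale)),
        coef_covariance=(cov + cov.T) / 2.0,
        converged=bool(result.converged),
        n_obs=len(y),
        n_groups=int(pd.unique(groups).size),
        metadata={"estimation": "REML", "df_method": "normal (z)"},
    )
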