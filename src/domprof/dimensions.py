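"""Specifications of performance dimensions and of the multilevel model.

A performance *dimension* is one outcome on which providers are judged,
e.g. length of stay, waiting time beyond a target, readmission within 28
days, or a patient-reported health score. Continuous dimensions are modelled
on a (monotone-)transformed scale where a Gaussian error is defensible;
binary dimensions are modelled as probits, i.e. as the sign of a latent
Gaussian variable whose error variance is fixed at 1 for identification.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

FAMILIES = ("gaussian", "probit")
_NAMED_TRANSFORMS: dict[str, tuple[Callable, Callable]] = {
    "identity": (lambda y: y, lambda z: z),
    "log1p": (np.log1p, np.expm1),
}


@dataclass(frozen=True)
class DimensionSpec:
    """One performance dimension.

    Parameters
    ----------
    name : str
        Column name of the outcome in the patient table.
    family : {"gaussian", "probit"}
        Observation model. Probit dimensions must be coded 0/1.
    transform : str or (callable, callable)
        Monotone transform applied to a gaussian outcome before modelling,
        either a named transform ("identity", "log1p") or a pair
        ``(forward, inverse)`` of callables. Probit dimensions take no
        transform.
    orientation : {+1, -1}
        +1 if a higher *observed* value is better (e.g. a health score),
        -1 if lower is better (e.g. length of stay, an adverse event).
    covariates : sequence of str
        Risk-adjustment covariates for this dimension. May be empty
        (e.g. waiting time is deliberately not risk-adjusted).
    """

    name: str
    family: str
    transform: str | tuple[Callable, Callable] = "identity"
    orientation: int = 1
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.orientation not in (1, -1):
            raise ValueError(f"orientation must be +1 or -1, got {self.orientation!r}")
        if self.family == "probit" and self.transform != "identity":
            raise ValueError(f"probit dimension {self.name!r} cannot have a transform")
        if isinstance(self.transform, str) and self.transform not in _NAMED_TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def is_probit(self) -> bool:
        return self.family == "probit"

    def _funcs(self) -> tuple[Callable, Callable]:
        if isinstance(self.transform, str):
            return _NAMED_TRANSFORMS[self.transform]
        fwd, inv = self.transform
        return fwd, inv

    def to_latent(self, y):
        """Observed -> model (latent) scale for gaussian dims."""
        return self._funcs()[0](np.asarray(y, dtype=float))

    def to_observed(self, z):
        """Model (latent) -> observed scale for gaussian dims."""
        return self._funcs()[1](np.asarray(z, dtype=float))


@dataclass(frozen=True)
class ModelSpec:
    """What to estimate: the dimensions and optional extra regressors.

    ``provider_mean_covariates`` adds Mundlak-style contextual terms —
    provider means of the named covariates, computed on the estimation
    sample — to every dimension's design matrix, absorbing correlation
    between patient mix and the provider random effect.

    ``residual_column`` names a per-patient first-stage choice-model
    residual that is entered into every dimension (two-stage residual
    inclusion for endogenous provider choice).
    """

    dimensions: tuple[DimensionSpec, ...]
    provider_mean_covariates: tuple[str, ...] = ()
    residual_column: str | None = None

    def __post_init__(self):
        dims = tuple(self.dimensions)
        if len(dims) < 1:
            raise ValueError("ModelSpec needs at least one dimension")
        names = [d.name for d in dims]
        if len(set(names)) != len(names):
            raise ValueError("dimension names must be unique")
        object.__setattr__(self, "dimensions", dims)
        object.__setattr__(
            self, "provider_mean_covariates", tuple(self.provider_mean_covariates)
        )

    @property
    def K(self) -> int:
        return len(self.dimensions)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dimensions]

    @property
    def orientations(self) -> np.ndarray:
        return np.array([d.orientation for d in self.dimensions], dtype=float)

    def subset(self, name: str) -> "ModelSpec":
        """A K=1 spec for a single named dimension (univariate fits)."""
        (dim,) = [d for d in self.dimensions if d.name == name]
        return ModelSpec(
            dimensions=(dim,),
            provider_mean_covariates=self.provider_mean_covariates,
            residual_column=self.residual_column,
        )

    def validate_against(self, data: pd.DataFrame) -> None:
        """Check that every referenced column exists in ``data``."""
        missing: list[str] = []
        for d in self.dimensions:
            if d.name not in data.columns:
                missing.append(d.name)
            missing += [c for c in d.covariates if c not in data.columns]
        missing += [c for c in self.provider_mean_covariates if c not in data.columns]
        if self.residual_column is not None and self.residual_column not in data.columns:
            missing.append(self.residual_column)
        if missing:
            raise ValueError(f"columns not found in data: {sorted(set(missing))}")
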