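"""Mixing-model mathematics.

A consumer's expected tracer value is a convex combination of the source
signatures plus trophic fractionation,

    u_j = sum_i p_i (m_{j,i} + f_{j,i})

with mixture variance propagated from source and fractionation variances,

    sigma_j^2 = sum_i p_i^2 (s_{j,i}^2 + g_{j,i}^2).

The likelihood treats tracers as independent Gaussians N(u_j, sigma_j^2)
(CLT argument: the mixture is a linear function of approximately normal
source means, and for FA proportions the approximation improves as more
tracers enter the sum).  Priors on the diet vector p live on the simplex:
either a fixed Dirichlet (default alpha = 1, uniform over compositions) or
a Dirichlet whose concentration parameters get independent Uniform(0, upper)
hyperpriors.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import gammaln

from .library import FractionationSpec, SourceLibrary

#: Additive floor on sigma_j^2.  Sensitivity scenarios divide source SDs by
#: 100, and the framework does not allow resources with exactly zero
#: uncertainty; the floor keeps the log-likelihood finite at exact matches.
DEFAULT_VARIANCE_FLOOR = 1e-12

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class DietProportions:
    """A point on the diet simplex: p_i >= 0, sum p_i = 1."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1:
            raise ValueError("diet proportions must be a vector")
        if np.any(self.p < -1e-12):
            raise ValueError(f"negative diet proportion in {self.p}")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError(f"diet proportions sum to {self.p.sum()}, expected 1")
        self.p = np.clip(self.p, 0.0, None)

    def __len__(self) -> int:
        return len(self.p)


class PriorForm(str, Enum):
    DIRICHLET_FIXED = "dirichlet_fixed"
    DIRICHLET_UNIFORM_HYPER = "dirichlet_uniform_hyper"


@dataclass
class PriorSpec:
    """Prior over diet proportions.

    ``DIRICHLET_FIXED`` uses Dirichlet(alpha) with alpha all ones by default
    (uniform over compositions).  ``DIRICHLET_UNIFORM_HYPER`` places
    independent Uniform(0, hyper_upper) hyperpriors on each concentration
    alpha_i and samples (p, alpha) jointly.
    """

    form: PriorForm = PriorForm.DIRICHLET_FIXED
    alpha: np.ndarray | None = None
    hyper_upper: float = 100.0

    def __post_init__(self) -> None:
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)
            if np.any(self.alpha <= 0):
                raise ValueError("Dirichlet alpha must be > 0")
        if self.hyper_upper <= 0:
            raise ValueError("hyper_upper must be > 0")

    def alpha_for(self, n_groups: int) -> np.ndarray:
        if self.alpha is None:
            return np.ones(n_groups)
        if self.alpha.shape != (n_groups,):
            raise ValueError(f"alpha has shape {self.alpha.shape}, expected ({n_groups},)")
        return self.alpha


@dataclass
class MixtureMoments:
    u: np.ndarray
    var: np.ndarray


def model_matrices(
    lib: SourceLibrary, frac: FractionationSpec | None
) -> tuple[np.ndarray, np.ndarray]:
    """(M, V) with M = m + f (tracer × group) and V = s^2 + g^2."""
    if frac is None:
        frac = FractionationSpec.zero(lib.n_tracers)
    f, g = frac.as_matrices(lib.n_groups)
    if f.shape[0] != lib.n_tracers:
        raise ValueError(
            f"fractionation covers {f.shape[0]} tracers, library has {lib.n_tracers}"
        )
    return lib.mean + f, lib.sd**2 + g**2


def mixture_moments(
    p: DietProportions | np.ndarray,
    lib: SourceLibrary,
    frac: FractionationSpec | None = None,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> MixtureMoments:
    pv = p.p if isinstance(p, DietProportions) else DietProportions(np.asarray(p)).p
    if len(pv) != lib.n_groups:
        raise ValueError(f"{len(pv)} proportions for {lib.n_groups} groups")
    M, V = model_matrices(lib, frac)
    return MixtureMoments(u=M @ pv, var=V @ pv**2 + variance_floor)


def mixture_mean(
    p: DietProportions | np.ndarray,
    lib: SourceLibrary,
    frac: FractionationSpec | None = None,
) -> np.ndarray:
    """u_j = sum_i p_i (m_{j,i} + f_{j,i})."""
    pv = p.p if isinstance(p, DietProportions) else DietProportions(np.asarray(p)).p
    if len(pv) != lib.n_groups:
        raise ValueError(f"{len(pv)} proportions for {lib.n_groups} groups")
    M, _ = model_matrices(lib, frac)
    return M @ pv


def mixture_variance(
    p: DietProportions | np.ndarray,
    lib: SourceLibrary,
    frac: FractionationSpec | None = None,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> np.ndarray:
    """sigma_j^2 = sum_i p_i^2 (s_{j,i}^2 + g_{j,i}^2) + floor."""
    return mixture_moments(p, lib, frac, variance_floor).var


def log_likelihood(
    x: np.ndarray,
    p: DietProportions | np.ndarray,
    lib: SourceLibrary,
    frac: FractionationSpec | None = None,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> float:
    """Independent-Gaussian log-likelihood of observation vector ``x``."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("consumer observation contains non-finite values")
    mom = mixture_moments(p, lib, frac, variance_floor)
    if x.shape != mom.u.shape:
        raise ValueError(f"observation has {x.shape[0]} tracers, model expects {mom.u.shape[0]}")
    return float(-0.5 * np.sum((x - mom.u) ** 2 / mom.var + np.log(mom.var) + _LOG_2PI))


def log_dirichlet(p: np.ndarray, alpha: np.ndarray) -> float:
    """Dirichlet log-density at an interior simplex point."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) and np.any(alpha != 1.0):
        return -np.inf
    lognorm = gammaln(alpha.sum()) - gammaln(alpha).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        core = np.where(alpha == 1.0, 0.0, (alpha - 1.0) * np.log(p))
    return float(lognorm + core.sum())


def log_prior(
    p: DietProportions | np.ndarray,
    spec: PriorSpec,
    alpha: np.ndarray | None = None,
) -> float:
    """Log prior density of p; the hyperprior form needs the sampled alpha.

    For ``DIRICHLET_UNIFORM_HYPER`` this is the joint log density of
    (p, alpha) up to the constant Uniform(0, upper) factor.
    """
    pv = p.p if isinstance(p, DietProportions) else DietProportions(np.asarray(p)).p
    if spec.form is PriorForm.DIRICHLET_FIXED:
        return log_dirichlet(pv, spec.alpha_for(len(pv)))
    if alpha is None:
        raise ValueError(
            "the uniform-hyperparameter prior is evaluated jointly with a sampled alpha"
        )
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0) or np.any(alpha >= spec.hyper_upper):
        return -np.inf
    return log_dirichlet(pv, alpha)
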