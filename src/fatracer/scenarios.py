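"""Monte-Carlo pseudo-consumer simulation and sensitivity designs.

Pseudo-consumers are simulated organisms whose true diet proportions are
known, used to measure parameter recovery:

* SI mode draws each source's tracer vector from N(m, s), mixes with the true
  weights, and adds one trophic-fractionation draw N(f, g) per consumer per
  tracer (consumer-level: the whole animal fractionates once, which
  reproduces the composed SD sqrt(s^2 + g^2) of pure-diet simulations).
* FA mode resamples one raw feeding-trial profile per source group (uniform,
  with replacement) and takes the weight-weighted sum, so simulated profiles
  stay inside the convex hull of the library profiles and remain closed.

Two sensitivity designs are provided: the 2x2 resource/consumer uncertainty
matrix (library SDs divided by ~100 vs full; consumers exact vs noisy), and
the fractionation grid, where the consumer's true fractionation is shifted by
±1.96 SD per tracer while the model assumes the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import (
    DietPosterior,
    MCMCConfig,
    PooledPosterior,
    fit_many,
    pool,
    summarize,
)
from .library import (
    FractionationSpec,
    Profile,
    SourceLibrary,
    TracerKind,
)
from .mixing import DietProportions, mixture_mean


@dataclass
class ScenarioSpec:
    """Declarative description of a pseudo-consumer experiment."""

    weights: np.ndarray
    n_consumers: int = 1000
    group_size: int = 100
    seed: int = 0
    resource_sd_scale: float = 1.0
    consumer_noise: bool = True
    fractionation_offset: np.ndarray | None = None  # in SD units, per tracer

    def __post_init__(self) -> None:
        self.weights = DietProportions(np.asarray(self.weights, dtype=float)).p
        if not (0 < self.resource_sd_scale <= 1):
            raise ValueError("resource_sd_scale must be in (0, 1]")
        if self.n_consumers < 1 or self.group_size < 1:
            raise ValueError("n_consumers and group_size must be positive")
        if self.fractionation_offset is not None:
            self.fractionation_offset = np.asarray(self.fractionation_offset, dtype=float)


@dataclass
class ScenarioResult:
    """Fitted scenario: pooled posterior plus per-batch and overall summaries."""

    label: str
    true_weights: np.ndarray
    pooled: PooledPosterior
    summary: pd.DataFrame
    batch_summaries: list[pd.DataFrame] = field(default_factory=list)
    posteriors: list[DietPosterior] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Consumer generators
# ---------------------------------------------------------------------------

def _frac_vectors(frac: FractionationSpec | None, n_tracers: int) -> tuple[np.ndarray, np.ndarray]:
    if frac is None:
        return np.zeros(n_tracers), np.zeros(n_tracers)
    if frac.mean.ndim != 1:
        raise ValueError("simulators use per-tracer (vector) fractionation")
    return frac.mean, frac.sd


def simulate_pure_si(
    group: str,
    lib: SourceLibrary,
    frac: FractionationSpec | None,
    n: int,
    seed: int = 0,
) -> list[Profile]:
    """Consumers on a 100% single-source diet.

    Each consumer's tracer vector is N(m_group, s_group) plus one
    fractionation draw N(f, g), so the expected SD composes as
    sqrt(s^2 + g^2) per tracer.
    """
    if group not in lib.groups:
        raise ValueError(f"unknown group {group!r}; library has {lib.groups}")
    i = lib.group_index(group)
    f, g = _frac_vectors(frac, lib.n_tracers)
    rng = np.random.default_rng(seed)
    base = rng.normal(lib.mean[:, i], lib.sd[:, i], size=(n, lib.n_tracers))
    shift = rng.normal(f, g, size=(n, lib.n_tracers))
    return [
        Profile(lib.tracer_set, v, f"{group}_pure_{k}")
        for k, v in enumerate(base + shift)
    ]


def simulate_mixed_si(
    weights,
    lib: SourceLibrary,
    frac: FractionationSpec | None,
    n: int,
    seed: int = 0,
) -> list[Profile]:
    """Consumers on a mixed diet with full source and fractionation uncertainty.

    Per consumer: draw each source group's tracer vector from N(m, s),
    combine with the true weights, add one N(f, g) fractionation draw per
    tracer.
    """
    w = DietProportions(np.asarray(weights, dtype=float)).p
    if len(w) != lib.n_groups:
        raise ValueError(f"{len(w)} weights for {lib.n_groups} groups")
    f, g = _frac_vectors(frac, lib.n_tracers)
    rng = np.random.default_rng(seed)
    sources = rng.normal(
        lib.mean[None, :, :], lib.sd[None, :, :], size=(n, lib.n_tracers, lib.n_groups)
    )
    mixed = sources @ w
    shift = rng.normal(f, g, size=(n, lib.n_tracers))
    return [
        Profile(lib.tracer_set, v, f"mixed_{k}") for k, v in enumerate(mixed + shift)
    ]


def simulate_mixed_fa(
    weights,
    raw_profiles: Mapping[str, Sequence[Profile]],
    n: int,
    seed: int = 0,
) -> list[Profile]:
    """FA pseudo-consumers by random resampling of library profiles.

    Per consumer, one feeding-trial profile is sampled uniformly with
    replacement from each source group and the profiles are combined as a
    weighted sum (e.g. 0.8 x a diatom-fed profile + 0.1 + 0.1).  Convexity
    keeps the output closed to the same total as the inputs.
    """
    groups = list(raw_profiles)
    w = DietProportions(np.asarray(weights, dtype=float)).p
    if len(w) != len(groups):
        raise ValueError(f"{len(w)} weights for {len(groups)} groups")
    stacks = []
    ts = None
    for gname in groups:
        ps = list(raw_profiles[gname])
        if not ps:
            raise ValueError(f"group {gname!r} has no raw profiles")
        if ts is None:
            ts = ps[0].tracer_set
        if ts.kind is not TracerKind.FA_PROPORTION:
            raise ValueError("FA resampling needs FA-proportion profiles")
        stacks.append(np.array([p.values for p in ps]))
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        mix = np.zeros(len(ts))
        for wi, stack in zip(w, stacks):
            mix += wi * stack[rng.integers(stack.shape[0])]
        out.append(Profile(ts, mix, f"fa_mixed_{k}"))
    return out


def exact_mixture_consumer(
    weights, lib: SourceLibrary, frac: FractionationSpec | None = None
) -> Profile:
    """The perfect-composition consumer: x = mixture mean, zero uncertainty."""
    w = DietProportions(np.asarray(weights, dtype=float)).p
    return Profile(lib.tracer_set, mixture_mean(w, lib, frac), "exact_mixture")


def scale_library_uncertainty(lib: SourceLibrary, factor: float) -> SourceLibrary:
    """Multiply all library SDs by ``factor`` (means unchanged)."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return SourceLibrary(
        lib.tracer_set, lib.groups, lib.mean.copy(), lib.sd * factor,
        raw_profiles=lib.raw_profiles,
    )


# ---------------------------------------------------------------------------
# Scenario execution
# ---------------------------------------------------------------------------

def run_scenario(
    consumers: Sequence[Profile],
    lib: SourceLibrary,
    frac: FractionationSpec | None,
    cfg: MCMCConfig,
    true_weights,
    label: str = "",
    group_size: int = 100,
) -> ScenarioResult:
    """Fit every consumer, pool, and summarize overall and per batch.

    Consumers are processed in batches of ``group_size``; batch summaries are
    retained for dispersion checks across batches.
    """
    posteriors, pooled = fit_many(consumers, lib, frac, cfg)
    batch_summaries = []
    for start in range(0, len(posteriors), group_size):
        chunk = posteriors[start : start + group_size]
        batch_summaries.append(summarize(pool(chunk)))
    return ScenarioResult(
        label=label,
        true_weights=DietProportions(np.asarray(true_weights, dtype=float)).p,
        pooled=pooled,
        summary=summarize(pooled),
        batch_summaries=batch_summaries,
        posteriors=posteriors,
        provenance={"seed": cfg.seed, "n_consumers": len(consumers), "group_size": group_size},
    )


UNCERTAINTY_CASES = (
    "resource 100% / consumer 100%",
    "resource 100% / consumer 0%",
    "resource ~0% / consumer 100%",
    "resource ~0% / consumer 0%",
)


def run_uncertainty_matrix(
    weights,
    lib: SourceLibrary,
    frac: FractionationSpec | None,
    cfg: MCMCConfig,
    n_consumers: int = 1000,
    group_size: int = 100,
    sd_scale: float = 0.01,
    sim_seed: int = 0,
) -> dict[str, ScenarioResult]:
    """The 2x2 resource/consumer uncertainty design.

    Resource uncertainty ~0% divides the model-side library SDs (and the
    fractionation SD, which is likewise model-side uncertainty) by
    ``1/sd_scale``; consumer uncertainty 0% replaces simulated consumers with
    the single exact-mixture consumer.  Noisy consumers are always simulated
    from the *full-uncertainty* library, whatever the model assumes.
    """
    w = DietProportions(np.asarray(weights, dtype=float)).p
    lib_small = scale_library_uncertainty(lib, sd_scale)
    frac_small = None if frac is None else frac.scaled(sd_scale)

    noisy = simulate_mixed_si(w, lib, frac, n_consumers, seed=sim_seed)
    exact = [exact_mixture_consumer(w, lib, frac)]

    design = {
        UNCERTAINTY_CASES[0]: (noisy, lib, frac),
        UNCERTAINTY_CASES[1]: (exact, lib, frac),
        UNCERTAINTY_CASES[2]: (noisy, lib_small, frac_small),
        UNCERTAINTY_CASES[3]: (exact, lib_small, frac_small),
    }
    results = {}
    for offset, (consumers, model_lib, model_frac) in enumerate(design.values()):
        label = UNCERTAINTY_CASES[offset]
        results[label] = run_scenario(
            consumers, model_lib, model_frac, cfg.with_seed(cfg.seed + offset),
            w, label=label, group_size=group_size,
        )
    return results


FRACTIONATION_CELLS = (
    (0.0, 0.0),
    (+1.96, +1.96),
    (+1.96, -1.96),
    (-1.96, +1.96),
    (-1.96, -1.96),
)


def run_fractionation_grid(
    weights,
    lib: SourceLibrary,
    frac: FractionationSpec,
    cfg: MCMCConfig,
    level: float = 1.96,
    sd_scale: float = 0.01,
    shift_model: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[float, float], ScenarioResult]]:
    """Fractionation sensitivity grid (mean cell plus the four ±1.96 SD cells).

    Resource and consumer uncertainty are minimized (library SDs × sd_scale,
    exact-mixture consumer, fractionation variance fixed to zero).  By
    default the *consumer* is generated with fractionation shifted by
    offset × g per tracer while the model assumes the mean fractionation;
    ``shift_model=True`` flips the convention (model shifted, consumer at the
    mean).  Returns a long-form table (cell × group: median, mean, sd) and
    the per-cell results.
    """
    if lib.tracer_set.kind is not TracerKind.SI_DELTA:
        raise ValueError("the fractionation grid is an SI-mode design")
    if frac.mean.ndim != 1:
        raise ValueError("fractionation grid uses per-tracer (vector) fractionation")
    w = DietProportions(np.asarray(weights, dtype=float)).p
    lib_small = scale_library_uncertainty(lib, sd_scale)
    # fixed-shift design: the model sees no fractionation variance
    model_frac_base = FractionationSpec(frac.mean.copy(), np.zeros_like(frac.sd))

    cells = tuple((c * level / 1.96, n * level / 1.96) for c, n in FRACTIONATION_CELLS)
    results: dict[tuple[float, float], ScenarioResult] = {}
    rows = []
    for k, offs in enumerate(cells):
        offset = np.array(offs) * frac.sd
        if shift_model:
            consumer = exact_mixture_consumer(w, lib, model_frac_base)
            model_frac = FractionationSpec(frac.mean + offset, np.zeros_like(frac.sd))
        else:
            shifted = FractionationSpec(frac.mean + offset, np.zeros_like(frac.sd))
            consumer = exact_mixture_consumer(w, lib, shifted)
            model_frac = model_frac_base
        res = run_scenario(
            [consumer], lib_small, model_frac, cfg.with_seed(cfg.seed + k), w,
            label=f"C{offs[0]:+g} SD / N{offs[1]:+g} SD",
        )
        results[offs] = res
        for g in lib.groups:
            s = res.summary.loc[g]
            rows.append((offs[0], offs[1], g, s["median"], s["mean"], s["sd"]))
    table = pd.DataFrame(
        rows, columns=["carbon_offset_sd", "nitrogen_offset_sd", "group", "median", "mean", "sd"]
    )
    return table, results
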