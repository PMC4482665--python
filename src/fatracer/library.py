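"""Consumer-resource libraries: data model, CSV I/O, validation, diagnostics.

A *consumer-resource library* is a table of biomarker signatures -- per source
group and per tracer, a mean and a standard deviation -- compiled from feeding
trials in which consumers were raised on known monoculture diets.  Because the
signatures are measured on the consumers themselves (not on the resources),
trophic modification of the biomarkers is embedded in the library and no
separate correction is needed in fatty-acid mode.  Stable-isotope libraries
carry a separate :class:`FractionationSpec` describing the trophic shift.

Two tracer kinds are supported:

* ``FA_PROPORTION`` -- individual fatty acids as percent of total fatty acids;
  profiles are compositional (non-negative, closed to ~100%).
* ``SI_DELTA`` -- stable-isotope delta values in per mil (e.g. d13C, d15N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class LibraryFormatError(ValueError):
    """A file could not be parsed into the expected layout."""


class LibraryValidationError(ValueError):
    """Parsed data violate a library invariant (e.g. negative SD)."""


class TracerKind(str, Enum):
    FA_PROPORTION = "fa_proportion"
    SI_DELTA = "si_delta"


#: Curated synonym normalisation applied before tracer-name matching.  Library
#: and field data must use the same suite of tracers; chromatography reports
#: mix omega notations ("18:3w3" vs "18:3ω3") and isotope labels ("d13C" vs
#: "δ13C"), so names are canonicalised on ingestion.
def canonical_tracer(name: str) -> str:
    return (
        str(name)
        .strip()
        .replace("ω", "w")
        .replace("Ω", "w")
        .replace("δ", "d")
        .replace("Δ", "d")
        .replace("^", "")
    )


def _infer_kind(names: Sequence[str]) -> TracerKind:
    if all(n.startswith("d") and any(c.isalpha() for c in n[1:]) for n in names):
        return TracerKind.SI_DELTA
    return TracerKind.FA_PROPORTION


@dataclass(frozen=True)
class TracerSet:
    """Ordered, homogeneous set of tracer identifiers."""

    names: tuple[str, ...]
    kind: TracerKind

    def __post_init__(self) -> None:
        names = tuple(canonical_tracer(n) for n in self.names)
        object.__setattr__(self, "names", names)
        if not names:
            raise LibraryValidationError("tracer set must be non-empty")
        if len(set(names)) != len(names):
            raise LibraryValidationError(f"duplicate tracer names in {names}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(canonical_tracer(name))


@dataclass
class Profile:
    """One observation vector (a source-group replicate or a consumer)."""

    tracer_set: TracerSet
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.tracer_set),):
            raise LibraryValidationError(
                f"profile {self.label!r}: {self.values.shape[0] if self.values.ndim else 0} "
                f"values for {len(self.tracer_set)} tracers"
            )
        if not np.all(np.isfinite(self.values)):
            raise LibraryValidationError(f"profile {self.label!r}: non-finite values")

    def check_closure(self, total: float = 100.0, tol: float = 5.0) -> None:
        """FA profiles must be non-negative and sum to ``total`` within ``tol``."""
        if self.tracer_set.kind is not TracerKind.FA_PROPORTION:
            return
        if np.any(self.values < 0):
            raise LibraryValidationError(f"profile {self.label!r}: negative FA proportion")
        s = float(self.values.sum())
        if abs(s - total) > tol:
            raise LibraryValidationError(
                f"profile {self.label!r}: FA proportions sum to {s:.3f}, "
                f"expected {total} ± {tol}"
            )

    def renormalized(self, total: float = 100.0) -> "Profile":
        return Profile(self.tracer_set, self.values * (total / self.values.sum()), self.label)


@dataclass
class SourceLibrary:
    """Per-group, per-tracer mean/SD matrices; the model's resource file.

    ``mean`` and ``sd`` are (n_tracers, n_groups) arrays; ``raw_profiles``
    optionally retains the individual feeding-trial profiles per group.
    """

    tracer_set: TracerSet
    groups: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    raw_profiles: dict[str, tuple[Profile, ...]] | None = None

    def __post_init__(self) -> None:
        self.groups = tuple(str(g) for g in self.groups)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        J, I = len(self.tracer_set), len(self.groups)
        if len(set(self.groups)) != I:
            raise LibraryValidationError(f"duplicate group names in {self.groups}")
        if self.mean.shape != (J, I) or self.sd.shape != (J, I):
            raise LibraryValidationError(
                f"mean/sd shapes {self.mean.shape}/{self.sd.shape} "
                f"inconsistent with {J} tracers × {I} groups"
            )
        if np.any(self.sd < 0):
            j, i = np.argwhere(self.sd < 0)[0]
            raise LibraryValidationError(
                f"negative SD at tracer {self.tracer_set.names[j]!r}, group {self.groups[i]!r}"
            )

    @property
    def n_tracers(self) -> int:
        return len(self.tracer_set)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_index(self, group: str) -> int:
        return self.groups.index(group)

    def mean_of(self, tracer: str, group: str) -> float:
        return float(self.mean[self.tracer_set.index(tracer), self.group_index(group)])

    def sd_of(self, tracer: str, group: str) -> float:
        return float(self.sd[self.tracer_set.index(tracer), self.group_index(group)])

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.groups):
            for j, t in enumerate(self.tracer_set.names):
                rows.append((g, t, self.mean[j, i], self.sd[j, i]))
        return pd.DataFrame(rows, columns=["group", "tracer", "mean", "sd"])


@dataclass
class FractionationSpec:
    """Trophic modification per tracer: mean shift ``f`` and SD ``g``.

    ``mean``/``sd`` are either (n_tracers,) vectors -- one shift per tracer,
    broadcast across source groups -- or (n_tracers, n_groups) matrices for
    group-specific fractionation.  FA-mode libraries embed fractionation and
    use the all-zero spec.
    """

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise LibraryValidationError("fractionation mean/sd shapes differ")
        if np.any(self.sd < 0):
            raise LibraryValidationError("fractionation SD must be >= 0")

    @classmethod
    def zero(cls, n_tracers: int) -> "FractionationSpec":
        return cls(np.zeros(n_tracers), np.zeros(n_tracers))

    def scaled(self, factor: float) -> "FractionationSpec":
        """Same mean shift, SDs multiplied by ``factor``."""
        return FractionationSpec(self.mean.copy(), self.sd * factor)

    def as_matrices(self, n_groups: int) -> tuple[np.ndarray, np.ndarray]:
        """Broadcast to (n_tracers, n_groups) matrices."""
        if self.mean.ndim == 1:
            f = np.repeat(self.mean[:, None], n_groups, axis=1)
            g = np.repeat(self.sd[:, None], n_groups, axis=1)
            return f, g
        if self.mean.shape[1] != n_groups:
            raise LibraryValidationError(
                f"fractionation has {self.mean.shape[1]} groups, library has {n_groups}"
            )
        return self.mean, self.sd


@dataclass
class ZScoreSummary:
    """Pooled within-group z-score diagnostic for dominant FA tracers."""

    pooled_sd: float
    pooled_median: float
    per_tracer_stats: pd.DataFrame
    tracers_included: tuple[str, ...]
    pooled_scores: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# Packaged stable-isotope fixture
# ---------------------------------------------------------------------------

#: Normalised phytoplankton d13C/d15N values (within-lake variation), per
#: group: (d13C mean, d13C sd, d15N mean, d15N sd).
_SI_TABLE = {
    "Diatoms": (-29.8, 2.3, 7.5, 1.5),
    "Chlorophytes": (-23.7, 2.6, 8.7, 2.0),
    "Cyanobacteria": (-25.8, 3.0, 2.8, 2.5),
}

#: Trophic fractionation SDs used with the SI fixture: ±1.3 permil for d13C
#: and ±1.0 permil for d15N, mean shift zero (the library values are already
#: normalised so simulated pure-diet consumers retain the source means).
_SI_FRACTIONATION_SD = (1.3, 1.0)


def builtin_si_table1() -> tuple[SourceLibrary, FractionationSpec]:
    """Packaged 3-group × 2-tracer stable-isotope library and fractionation.

    Returns the phytoplankton d13C/d15N library (Diatoms, Chlorophytes,
    Cyanobacteria) together with a zero-mean fractionation spec whose SDs are
    (1.3, 1.0) permil.
    """
    ts = TracerSet(("d13C", "d15N"), TracerKind.SI_DELTA)
    groups = tuple(_SI_TABLE)
    mean = np.array([[_SI_TABLE[g][0] for g in groups], [_SI_TABLE[g][2] for g in groups]])
    sd = np.array([[_SI_TABLE[g][1] for g in groups], [_SI_TABLE[g][3] for g in groups]])
    frac = FractionationSpec(np.zeros(2), np.array(_SI_FRACTIONATION_SD))
    return SourceLibrary(ts, groups, mean, sd), frac


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_source_library(
    path: str | Path,
    wide: bool = False,
    kind: TracerKind | None = None,
) -> SourceLibrary:
    """Read a source library from CSV.

    Canonical dialect is long form with columns ``group,tracer,mean,sd``.
    With ``wide=True``, rows are ``group,stat`` (stat in {mean, sd}) and one
    column per tracer.  Tracer order is preserved from the file; tracer kind
    is inferred from the names unless given.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if wide:
        required = {"group", "stat"}
        if not required.issubset(df.columns):
            raise LibraryFormatError(f"{path}: wide form needs columns {sorted(required)}")
        tracers = [c for c in df.columns if c not in ("group", "stat")]
        long_rows = df.melt(
            id_vars=["group", "stat"], value_vars=tracers,
            var_name="tracer", value_name="value",
        )
        df = long_rows.pivot_table(
            index=["group", "tracer"], columns="stat", values="value", sort=False
        ).reset_index()
        if "mean" not in df.columns or "sd" not in df.columns:
            raise LibraryFormatError(f"{path}: wide form needs 'mean' and 'sd' rows")
    missing = {"group", "tracer", "mean", "sd"} - set(df.columns)
    if missing:
        raise LibraryFormatError(f"{path}: missing column(s) {sorted(missing)}")

    df = df.copy()
    df["tracer"] = df["tracer"].map(canonical_tracer)
    dup = df.duplicated(subset=["group", "tracer"])
    if dup.any():
        g, t = df.loc[dup.idxmax(), ["group", "tracer"]]
        raise LibraryValidationError(f"{path}: duplicate entry for group {g!r}, tracer {t!r}")
    neg = df["sd"] < 0
    if neg.any():
        g, t = df.loc[neg.idxmax(), ["group", "tracer"]]
        raise LibraryValidationError(f"{path}: negative SD at group {g!r}, tracer {t!r}")

    tracer_names = tuple(dict.fromkeys(df["tracer"]))
    groups = tuple(dict.fromkeys(df["group"]))
    ts = TracerSet(tracer_names, kind or _infer_kind(tracer_names))
    mean = np.full((len(ts), len(groups)), np.nan)
    sd = np.full((len(ts), len(groups)), np.nan)
    jmap = {t: j for j, t in enumerate(ts.names)}
    imap = {g: i for i, g in enumerate(groups)}
    for row in df.itertuples(index=False):
        mean[jmap[row.tracer], imap[row.group]] = row.mean
        sd[jmap[row.tracer], imap[row.group]] = row.sd
    if np.isnan(mean).any():
        j, i = np.argwhere(np.isnan(mean))[0]
        raise LibraryFormatError(
            f"{path}: no entry for group {groups[i]!r}, tracer {ts.names[j]!r}"
        )
    return SourceLibrary(ts, groups, mean, sd)


def write_source_library(lib: SourceLibrary, path: str | Path, wide: bool = False) -> None:
    path = Path(path)
    if not wide:
        lib.to_long_frame().to_csv(path, index=False)
        return
    rows = []
    for i, g in enumerate(lib.groups):
        rows.append([g, "mean", *lib.mean[:, i]])
        rows.append([g, "sd", *lib.sd[:, i]])
    pd.DataFrame(rows, columns=["group", "stat", *lib.tracer_set.names]).to_csv(path, index=False)


def read_consumers(path: str | Path, tracer_set: TracerSet) -> list[Profile]:
    """Read consumer observations: one row per consumer, one column per tracer.

    An optional first column ``id`` labels consumers.  Tracer columns are
    matched by canonical name against ``tracer_set``; a missing tracer is a
    format error naming the tracer.
    """
    path = Path(path)
    df = pd.read_csv(path)
    colmap = {canonical_tracer(c): c for c in df.columns if c != "id"}
    missing = [t for t in tracer_set.names if t not in colmap]
    if missing:
        raise LibraryFormatError(f"{path}: consumer file lacks tracer column(s) {missing}")
    labels = df["id"].astype(str) if "id" in df.columns else [f"consumer_{k}" for k in range(len(df))]
    values = df[[colmap[t] for t in tracer_set.names]].to_numpy(dtype=float)
    return [Profile(tracer_set, v, str(lab)) for v, lab in zip(values, labels)]


def write_consumers(profiles: Sequence[Profile], path: str | Path) -> None:
    ts = profiles[0].tracer_set
    df = pd.DataFrame([p.values for p in profiles], columns=ts.names)
    df.insert(0, "id", [p.label for p in profiles])
    df.to_csv(Path(path), index=False)


def read_fractionation(path: str | Path, tracer_set: TracerSet) -> FractionationSpec:
    """Read per-tracer fractionation from CSV columns ``tracer,mean,sd``."""
    df = pd.read_csv(Path(path))
    missing = {"tracer", "mean", "sd"} - set(df.columns)
    if missing:
        raise LibraryFormatError(f"{path}: missing column(s) {sorted(missing)}")
    df["tracer"] = df["tracer"].map(canonical_tracer)
    table = df.set_index("tracer")
    try:
        sub = table.loc[list(tracer_set.names)]
    except KeyError as e:
        raise LibraryFormatError(f"{path}: fractionation lacks tracer {e.args[0]!r}") from e
    return FractionationSpec(sub["mean"].to_numpy(float), sub["sd"].to_numpy(float))


# ---------------------------------------------------------------------------
# Library construction and diagnostics
# ---------------------------------------------------------------------------

def summarize_profiles(profiles: Iterable[Profile]) -> SourceLibrary:
    """Build a library from raw feeding-trial profiles grouped by their label.

    Group means are arithmetic per-tracer means; SDs use the sample (n-1)
    estimator.  A single-profile group gets SD 0 with a warning.  Raw profiles
    are retained on the returned library.
    """
    by_group: dict[str, list[Profile]] = {}
    ts = None
    for p in profiles:
        if ts is None:
            ts = p.tracer_set
        elif p.tracer_set.names != ts.names or p.tracer_set.kind != ts.kind:
            raise LibraryValidationError(
                f"profile {p.label!r} uses a different tracer set than the first profile"
            )
        by_group.setdefault(p.label, []).append(p)
    if ts is None:
        raise LibraryValidationError("no profiles given")

    groups = tuple(by_group)
    mean = np.empty((len(ts), len(groups)))
    sd = np.empty_like(mean)
    for i, g in enumerate(groups):
        vals = np.array([p.values for p in by_group[g]])
        mean[:, i] = vals.mean(axis=0)
        if vals.shape[0] == 1:
            warnings.warn(f"group {g!r} has a single profile; SD recorded as 0", stacklevel=2)
            sd[:, i] = 0.0
        else:
            sd[:, i] = vals.std(axis=0, ddof=1)
    raw = {g: tuple(ps) for g, ps in by_group.items()}
    return SourceLibrary(ts, groups, mean, sd, raw_profiles=raw)


def zscore_diagnostic(
    profiles: Sequence[Profile], abundance_threshold: float = 5.0
) -> ZScoreSummary:
    """Normality diagnostic for the dominant fatty acids.

    Selects tracers whose grand mean across all profiles exceeds
    ``abundance_threshold`` percent of total FA, z-scores each selected tracer
    within its diet group (group mean 0, group SD 1), pools all scores, and
    reports the pooled SD and median plus per-tracer moments.  Pooled scores
    close to a standard normal support the Gaussian likelihood on raw
    percentage scale.
    """
    ts = profiles[0].tracer_set
    if ts.kind is not TracerKind.FA_PROPORTION:
        raise LibraryValidationError("z-score diagnostic applies to FA-proportion profiles")
    all_vals = np.array([p.values for p in profiles])
    grand_mean = all_vals.mean(axis=0)
    selected = [j for j in range(len(ts)) if grand_mean[j] > abundance_threshold]
    if not selected:
        raise LibraryValidationError(
            f"no tracer has grand mean > {abundance_threshold}% of total FA"
        )

    by_group: dict[str, list[np.ndarray]] = {}
    for p in profiles:
        by_group.setdefault(p.label, []).append(p.values)

    pooled: list[np.ndarray] = []
    per_tracer: dict[str, list[np.ndarray]] = {ts.names[j]: [] for j in selected}
    for vals_list in by_group.values():
        vals = np.array(vals_list)
        if vals.shape[0] < 2:
            continue
        for j in selected:
            col = vals[:, j]
            s = col.std(ddof=1)
            if s == 0:
                continue
            z = (col - col.mean()) / s
            pooled.append(z)
            per_tracer[ts.names[j]].append(z)

    if not pooled:
        raise LibraryValidationError("no group with >= 2 profiles and nonzero spread")
    scores = np.concatenate(pooled)
    stats_rows = []
    for name, zs in per_tracer.items():
        z = np.concatenate(zs) if zs else np.empty(0)
        stats_rows.append(
            (name, z.mean() if z.size else np.nan,
             z.std(ddof=1) if z.size > 1 else np.nan,
             stats.skew(z) if z.size > 2 else np.nan)
        )
    table = pd.DataFrame(stats_rows, columns=["tracer", "mean", "sd", "skew"]).set_index("tracer")
    return ZScoreSummary(
        pooled_sd=float(scores.std(ddof=1)),
        pooled_median=float(np.median(scores)),
        per_tracer_stats=table,
        tracers_included=tuple(ts.names[j] for j in selected),
        pooled_scores=scores,
    )


def validate_library(
    lib: SourceLibrary, closure_total: float = 100.0, closure_tol: float = 5.0
) -> list[str]:
    """Report-based invariant check; returns a list of violation messages.

    For FA libraries, per-group mean vectors must also sum to the declared
    closure total within tolerance.
    """
    violations: list[str] = []
    for (j, i) in np.argwhere(lib.sd < 0):
        violations.append(
            f"negative SD at tracer {lib.tracer_set.names[j]!r}, group {lib.groups[i]!r}"
        )
    if not np.all(np.isfinite(lib.mean)):
        violations.append("non-finite mean value(s)")
    if not np.all(np.isfinite(lib.sd)):
        violations.append("non-finite SD value(s)")
    if lib.tracer_set.kind is TracerKind.FA_PROPORTION:
        for i, g in enumerate(lib.groups):
            total = float(lib.mean[:, i].sum())
            if abs(total - closure_total) > closure_tol:
                violations.append(
                    f"group {g!r}: FA means sum to {total:.2f}, expected "
                    f"{closure_total} ± {closure_tol} (closure violation)"
                )
        if np.any(lib.mean < 0):
            j, i = np.argwhere(lib.mean < 0)[0]
            violations.append(
                f"negative FA mean at tracer {lib.tracer_set.names[j]!r}, "
                f"group {lib.groups[i]!r}"
            )
    return violations
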