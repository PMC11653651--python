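"""Synthetic blood small-RNA count data with known planted truth.

Generates negative-binomial miRNA count matrices that emulate the structure of
a bovine blood miRNAome: a handful of dominant miRNAs carrying most of the
reads (the top 10 carry ~85% of the library by default), log-normal sequencing
depths of ~6.7 million mapped reads per sample, and a long tail of
low-abundance miRNAs in the 1-10 RPM range where phenotype-specific markers
live.

Three cohort generators are provided:

* :func:`simulate_counts` - a pre-treatment (W0) cross-section over the five
  phenotype groups (healthy controls plus four lameness phenotypes), with
  optional planted two-group fold changes and planted phenotype-specific
  miRNAs (expressed in exactly one group).
* :func:`simulate_recovery_cohort` - a three-week longitudinal cohort with
  per-animal gait-score trajectories, recovery labels derived from those
  trajectories (final gait < initial gait => recovered), planted U/N/D
  temporal patterns, and planted time-point-specific miRNAs.
* :func:`simulate_ct_table` - qPCR Ct values for target and reference assays
  with planted per-group fold changes, for exercising ddCt quantification.

Every planted effect is recorded exhaustively in the returned truth tables, so
downstream detection rules can be scored for sensitivity and precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import PHENOTYPES, WEEKS, Study, join_validate

# Nine admissible week-to-week trend patterns (U=up, N=no change, D=down).
PATTERN_CATEGORIES = ("D-D", "D-N", "D-U", "N-D", "N-U", "N-N", "U-D", "U-N", "U-U")

#: W0 cross-section design: group sizes of the pre-treatment study arm.
W0_GROUP_SIZES: dict[str, int] = {"DD": 24, "FR": 40, "TTN": 13, "FRDD": 17, "HC": 12}

#: Longitudinal design: animals per phenotype followed W0->W2.
LONGITUDINAL_GROUP_SIZES: dict[str, int] = {"DD": 59, "TTN": 31, "FRDD": 50}


class PlantedDE(NamedTuple):
    mirna_id: str
    group_a: str       # baseline group of the contrast
    group_b: str       # group whose mean is shifted by 2**log2fc
    log2fc: float


class PlantedSpecific(NamedTuple):
    mirna_id: str
    phenotype: str
    target_rpm: float  # expected RPM in the target group; zero elsewhere


class PlantedTimepointSpecific(NamedTuple):
    mirna_id: str
    phenotype: str
    week: str
    target_rpm: float


class PlantedPattern(NamedTuple):
    mirna_id: str
    phenotype: str
    recovery: str      # "RE" or "UNR"
    pattern: str       # one of PATTERN_CATEGORIES


@dataclass(frozen=True)
class SimulationConfig:
    """Generative conditions for a synthetic study.

    The negative binomial is parameterized as Var = mu + dispersion * mu**2
    with a single global dispersion. Library sizes are log-normal with the
    given mean and coefficient of variation. ``baseline_abundance_profile``
    maps miRNA id -> expected relative abundance (sums to 1); when None a
    profile is built with ``top10_share`` of the mass on the ten dominant
    miRNAs and the remainder spread log-normally over the tail.
    """

    n_mirnas: int = 300
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(W0_GROUP_SIZES))
    weeks: Sequence[str] = ("W0",)
    library_size_mean: float = 6.7e6
    library_size_cv: float = 0.3
    dispersion: float = 0.2
    baseline_abundance_profile: Mapping[str, float] | None = None
    top10_share: float = 0.85
    planted_de: Sequence[PlantedDE] = ()
    planted_specific: Sequence[PlantedSpecific] = ()
    planted_timepoint_specific: Sequence[PlantedTimepointSpecific] = ()
    planted_patterns: Sequence[PlantedPattern] = ()
    pattern_log2fc: float = 2.0
    recovery_fraction: float = 0.5
    ct_reference_ids: tuple[str, str] = ("bta-miR-93", "bta-miR-16b")
    ct_baseline: float = 25.0
    ct_noise_sd: float = 0.2
    ct_replicates: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.n_mirnas < 1:
            raise ConfigurationError("n_mirnas must be positive")
        for g, n in self.group_sizes.items():
            if g not in PHENOTYPES:
                raise ConfigurationError(f"unknown phenotype group {g!r}")
            if n < 2:
                raise ConfigurationError(f"group {g!r} needs >= 2 samples, got {n}")
        if any(w not in WEEKS for w in self.weeks):
            raise ConfigurationError(f"weeks must be drawn from {WEEKS}")
        if self.library_size_mean <= 0:
            raise ConfigurationError("library_size_mean must be positive")
        if self.library_size_cv < 0:
            raise ConfigurationError("library_size_cv must be nonnegative")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be nonnegative")
        if not 0 <= self.recovery_fraction <= 1:
            raise ConfigurationError("recovery_fraction must lie in [0, 1]")
        for p in self.planted_patterns:
            if p.pattern not in PATTERN_CATEGORIES:
                raise ConfigurationError(
                    f"pattern {p.pattern!r} not one of {PATTERN_CATEGORIES}")
            if p.recovery not in ("RE", "UNR"):
                raise ConfigurationError(f"pattern recovery must be RE/UNR, got {p.recovery!r}")
        if self.baseline_abundance_profile is not None:
            total = float(sum(self.baseline_abundance_profile.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"baseline abundance profile sums to {total}, expected 1")


@dataclass(frozen=True)
class SimulatedStudy:
    """Counts + metadata plus exhaustive truth tables of planted effects."""

    counts: pd.DataFrame
    metadata: pd.DataFrame
    truth_de: pd.DataFrame
    truth_specific: pd.DataFrame
    truth_timepoint: pd.DataFrame
    truth_patterns: pd.DataFrame
    truth_recovery: pd.DataFrame
    config: SimulationConfig

    @property
    def study(self) -> Study:
        return join_validate(self.counts, self.metadata)


@dataclass(frozen=True)
class SimulatedCtStudy:
    """Tidy Ct table (sample_id, assay_id, ct) with metadata and truth folds."""

    ct: pd.DataFrame
    metadata: pd.DataFrame
    truth_fold_changes: pd.DataFrame
    config: SimulationConfig


def default_w0_config(**overrides) -> SimulationConfig:
    """Study conditions of the pre-treatment cross-section."""
    return replace(SimulationConfig(), **overrides)


def default_longitudinal_config(**overrides) -> SimulationConfig:
    """Study conditions of the three-week recovery cohort."""
    base = SimulationConfig(
        group_sizes=dict(LONGITUDINAL_GROUP_SIZES), weeks=tuple(WEEKS))
    return replace(base, **overrides)


def _build_profile(config: SimulationConfig, rng: np.random.Generator
                   ) -> pd.Series:
    """Baseline relative-abundance profile (sums to 1).

    Ten dominant miRNAs share ``top10_share`` of the mass (Zipf-like within
    the top), the tail is log-normal. Planted specific/timepoint-specific ids
    absent from an auto-built profile are appended at their target abundance.
    """
    if config.baseline_abundance_profile is not None:
        profile = pd.Series(config.baseline_abundance_profile, dtype=float)
        _check_planted_ids(config, set(profile.index))
        return profile

    n = config.n_mirnas
    ids = [f"bta-mir-s{i:04d}" for i in range(n)]
    k = min(10, n)
    top = 1.0 / np.arange(1, k + 1)          # Zipf weights within the top 10
    top = top / top.sum() * config.top10_share
    tail_mass = 1.0 - config.top10_share
    if n > k:
        tail = rng.lognormal(mean=0.0, sigma=1.2, size=n - k)
        tail = np.sort(tail)[::-1]
        tail = tail / tail.sum() * tail_mass
        # keep the top-10 genuinely dominant
        tail = np.minimum(tail, top.min() * 0.9)
        tail = tail / tail.sum() * tail_mass
        probs = np.concatenate([top, tail])
    else:
        probs = top / top.sum()
    profile = pd.Series(probs, index=ids)

    extra = {}
    for entry in list(config.planted_specific) + list(config.planted_timepoint_specific):
        if entry.mirna_id not in profile.index:
            extra[entry.mirna_id] = entry.target_rpm / 1e6
    if extra:
        extra_s = pd.Series(extra)
        profile = profile * (1.0 - extra_s.sum())
        profile = pd.concat([profile, extra_s])
    profile /= profile.sum()

    missing = [p.mirna_id for p in config.planted_de
               if p.mirna_id not in profile.index]
    missing += [p.mirna_id for p in config.planted_patterns
                if p.mirna_id not in profile.index]
    if missing:
        raise ConfigurationError(
            f"planted miRNA ids absent from baseline profile: {sorted(set(missing))}")
    return profile


def _check_planted_ids(config: SimulationConfig, known: set[str]) -> None:
    planted = (
        [p.mirna_id for p in config.planted_de]
        + [p.mirna_id for p in config.planted_specific]
        + [p.mirna_id for p in config.planted_timepoint_specific]
        + [p.mirna_id for p in config.planted_patterns]
    )
    missing = sorted(set(planted) - known)
    if missing:
        raise ConfigurationError(
            f"planted miRNA ids absent from baseline profile: {missing}")


def _draw_counts(mu: np.ndarray, dispersion: float,
                 rng: np.random.Generator) -> np.ndarray:
    """NB(mu, alpha) draws via the gamma-Poisson mixture; Poisson if alpha=0."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return rng.poisson(mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu[pos])
    out[pos] = rng.poisson(lam)
    return out


def _library_sizes(n: int, config: SimulationConfig,
                   rng: np.random.Generator) -> np.ndarray:
    if config.library_size_cv == 0:
        return np.full(n, config.library_size_mean)
    sigma2 = np.log1p(config.library_size_cv ** 2)
    mu = np.log(config.library_size_mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def simulate_counts(config: SimulationConfig) -> SimulatedStudy:
    """W0 cross-section with planted fold changes and specific miRNAs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    profile = _build_profile(config, rng)
    mirna_ids = list(profile.index)
    groups = list(config.group_sizes)

    # per-group expected relative abundance
    abundance = pd.DataFrame(
        {g: profile.to_numpy(copy=True) for g in groups}, index=mirna_ids)
    for p in config.planted_specific:
        if p.phenotype not in groups:
            raise ConfigurationError(
                f"planted specific miRNA targets unknown group {p.phenotype!r}")
        abundance.loc[p.mirna_id, :] = 0.0
        abundance.loc[p.mirna_id, p.phenotype] = p.target_rpm / 1e6
    for p in config.planted_de:
        if p.group_b not in groups:
            raise ConfigurationError(
                f"planted DE effect targets unknown group {p.group_b!r}")
        abundance.loc[p.mirna_id, p.group_b] *= 2.0 ** p.log2fc

    sample_ids, animal_ids, phenotypes = [], [], []
    columns = []
    for g in groups:
        n_g = config.group_sizes[g]
        lib = _library_sizes(n_g, config, rng)
        mu = np.outer(abundance[g].to_numpy(), lib)
        columns.append(_draw_counts(mu, config.dispersion, rng))
        for i in range(n_g):
            animal = f"{g}{i + 1:03d}"
            animal_ids.append(animal)
            sample_ids.append(f"{animal}_W0")
            phenotypes.append(g)

    counts = pd.DataFrame(
        np.hstack(columns), index=pd.Index(mirna_ids, name="mirna_id"),
        columns=sample_ids)
    metadata = pd.DataFrame({
        "sample_id": sample_ids,
        "animal_id": animal_ids,
        "phenotype": phenotypes,
        "week": "W0",
        "gait_score": [0 if g == "HC" else None for g in phenotypes],
        "recovery": "NA",
    })
    metadata["gait_score"] = metadata["gait_score"].astype("Int64")

    truth_de = pd.DataFrame(
        config.planted_de, columns=["mirna_id", "group_a", "group_b", "log2fc"])
    truth_specific = pd.DataFrame(
        config.planted_specific, columns=["mirna_id", "phenotype", "target_rpm"])
    empty_tp = pd.DataFrame(columns=["mirna_id", "phenotype", "week", "target_rpm"])
    empty_pat = pd.DataFrame(columns=["mirna_id", "phenotype", "recovery", "pattern"])
    empty_rec = pd.DataFrame(columns=["animal_id", "phenotype", "recovery"])
    return SimulatedStudy(counts, metadata, truth_de, truth_specific,
                          empty_tp, empty_pat, empty_rec, config)


def _gait_trajectory(recovered: bool, rng: np.random.Generator) -> tuple[int, int, int]:
    """A 0-3 gait path over W0/W1/W2; decreasing iff recovered."""
    g0 = int(rng.integers(1, 4))                    # lame at diagnosis
    if recovered:
        g2 = int(rng.integers(0, g0))               # strictly below g0
        g1 = int(rng.integers(g2, g0 + 1))
    else:
        g2 = int(rng.integers(g0, 4))               # never below g0
        g1 = int(rng.integers(g0, g2 + 1))
    return g0, g1, g2


def _pattern_multipliers(pattern: str, log2fc: float) -> np.ndarray:
    """Cumulative per-week mean multipliers for a U/N/D pattern string."""
    step = {"U": 2.0 ** log2fc, "N": 1.0, "D": 2.0 ** -log2fc}
    first, second = pattern.split("-")
    m0 = 1.0
    m1 = m0 * step[first]
    m2 = m1 * step[second]
    return np.array([m0, m1, m2])


def simulate_recovery_cohort(config: SimulationConfig) -> SimulatedStudy:
    """Three-week longitudinal cohort with derived recovery labels."""
    config.validate()
    if tuple(config.weeks) != tuple(WEEKS):
        raise ConfigurationError(
            f"recovery cohort requires weeks {WEEKS}, got {tuple(config.weeks)}")
    rng = np.random.default_rng(config.seed)
    profile = _build_profile(config, rng)
    mirna_ids = list(profile.index)
    groups = list(config.group_sizes)
    n_weeks = len(WEEKS)

    # expected relative abundance per (phenotype, recovery, week)
    strata: dict[tuple[str, str], np.ndarray] = {}
    for g in groups:
        for rec in ("RE", "UNR"):
            strata[(g, rec)] = np.tile(
                profile.to_numpy()[:, None], (1, n_weeks)).astype(float)
    idx = {m: i for i, m in enumerate(mirna_ids)}
    for p in config.planted_timepoint_specific:
        if p.phenotype not in groups:
            raise ConfigurationError(
                f"planted timepoint-specific miRNA targets unknown group {p.phenotype!r}")
        w = WEEKS.index(p.week)
        for rec in ("RE", "UNR"):
            strata[(p.phenotype, rec)][idx[p.mirna_id], :] = 0.0
            strata[(p.phenotype, rec)][idx[p.mirna_id], w] = p.target_rpm / 1e6
        # absent from every other phenotype
        for g in groups:
            if g != p.phenotype:
                for rec in ("RE", "UNR"):
                    strata[(g, rec)][idx[p.mirna_id], :] = 0.0
    for p in config.planted_specific:
        for g in groups:
            for rec in ("RE", "UNR"):
                strata[(g, rec)][idx[p.mirna_id], :] = 0.0
        if p.phenotype in groups:
            for rec in ("RE", "UNR"):
                strata[(p.phenotype, rec)][idx[p.mirna_id], :] = p.target_rpm / 1e6
    for p in config.planted_patterns:
        if p.phenotype not in groups:
            raise ConfigurationError(
                f"planted pattern targets unknown group {p.phenotype!r}")
        mult = _pattern_multipliers(p.pattern, config.pattern_log2fc)
        strata[(p.phenotype, p.recovery)][idx[p.mirna_id], :] *= mult

    sample_ids, animal_ids, phenotypes, weeks_col = [], [], [], []
    gait_col, recovery_col = [], []
    columns = []
    recovery_rows = []
    for g in groups:
        n_g = config.group_sizes[g]
        n_re = int(round(config.recovery_fraction * n_g))
        recovered_flags = np.zeros(n_g, dtype=bool)
        recovered_flags[:n_re] = True
        rng.shuffle(recovered_flags)
        for i in range(n_g):
            animal = f"{g}{i + 1:03d}"
            rec = "RE" if recovered_flags[i] else "UNR"
            recovery_rows.append((animal, g, rec))
            gait = _gait_trajectory(recovered_flags[i], rng)
            lib = _library_sizes(n_weeks, config, rng)
            mu = strata[(g, rec)] * lib[None, :]
            columns.append(_draw_counts(mu, config.dispersion, rng))
            for w, wk in enumerate(WEEKS):
                animal_ids.append(animal)
                sample_ids.append(f"{animal}_{wk}")
                phenotypes.append(g)
                weeks_col.append(wk)
                gait_col.append(gait[w])
                recovery_col.append(rec)

    counts = pd.DataFrame(
        np.hstack(columns), index=pd.Index(mirna_ids, name="mirna_id"),
        columns=sample_ids)
    metadata = pd.DataFrame({
        "sample_id": sample_ids,
        "animal_id": animal_ids,
        "phenotype": phenotypes,
        "week": weeks_col,
        "gait_score": pd.array(gait_col, dtype="Int64"),
        "recovery": recovery_col,
    })
    truth_de = pd.DataFrame(
        config.planted_de, columns=["mirna_id", "group_a", "group_b", "log2fc"])
    truth_specific = pd.DataFrame(
        config.planted_specific, columns=["mirna_id", "phenotype", "target_rpm"])
    truth_timepoint = pd.DataFrame(
        config.planted_timepoint_specific,
        columns=["mirna_id", "phenotype", "week", "target_rpm"])
    truth_patterns = pd.DataFrame(
        config.planted_patterns,
        columns=["mirna_id", "phenotype", "recovery", "pattern"])
    truth_recovery = pd.DataFrame(
        recovery_rows, columns=["animal_id", "phenotype", "recovery"])
    return SimulatedStudy(counts, metadata, truth_de, truth_specific,
                          truth_timepoint, truth_patterns, truth_recovery,
                          config)


def derive_recovery(meta: pd.DataFrame) -> pd.Series:
    """RE iff the last observed gait score is below the first; else UNR.

    Returns a per-animal label series indexed by animal_id.
    """
    week_order = {w: i for i, w in enumerate(WEEKS)}
    labels = {}
    for animal, rows in meta.groupby("animal_id"):
        rows = rows.sort_values("week", key=lambda s: s.map(week_order))
        gait = rows["gait_score"].dropna()
        if len(gait) < 2:
            labels[animal] = "NA"
        else:
            labels[animal] = "RE" if gait.iloc[-1] < gait.iloc[0] else "UNR"
    return pd.Series(labels, name="recovery")


def simulate_ct_table(config: SimulationConfig,
                      planted_fold_changes: Mapping[str, Mapping[str, float]],
                      reference_group: str = "HC") -> SimulatedCtStudy:
    """qPCR Ct values with planted per-group fold changes.

    ``planted_fold_changes`` maps target assay id -> {group: fold change
    relative to the reference group}. Ct is generated as a per-assay baseline
    minus log2(fold) plus Gaussian noise of sd ``config.ct_noise_sd``; the two
    reference assays have fold change 1 in every group by construction.
    """
    config.validate()
    refs = config.ct_reference_ids
    if len(refs) != 2 or refs[0] == refs[1]:
        raise ConfigurationError("two distinct reference assay ids are required")
    groups = list(config.group_sizes)
    if reference_group not in groups:
        raise ConfigurationError(
            f"reference group {reference_group!r} not among groups {groups}")
    for target, folds in planted_fold_changes.items():
        if target in refs:
            raise ConfigurationError(
                f"target {target!r} collides with a reference assay")
        for g in folds:
            if g not in groups:
                raise ConfigurationError(
                    f"fold change for {target!r} names unknown group {g!r}")
            if folds[g] <= 0:
                raise ConfigurationError("fold changes must be positive")

    rng = np.random.default_rng(config.seed)
    rows = []
    meta_rows = []
    truth_rows = []
    for g in groups:
        for i in range(config.ct_replicates):
            sample = f"{g}q{i + 1:03d}"
            meta_rows.append((sample, sample, g, "W0", pd.NA, "NA"))
            for ref in refs:
                ct = config.ct_baseline + rng.normal(0.0, config.ct_noise_sd)
                rows.append((sample, ref, ct))
            for target, folds in planted_fold_changes.items():
                fold = float(folds.get(g, 1.0))
                ct = (config.ct_baseline - np.log2(fold)
                      + rng.normal(0.0, config.ct_noise_sd))
                rows.append((sample, target, ct))
    for target, folds in planted_fold_changes.items():
        for g in groups:
            truth_rows.append((target, g, float(folds.get(g, 1.0))))

    ct = pd.DataFrame(rows, columns=["sample_id", "assay_id", "ct"])
    metadata = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "animal_id", "phenotype", "week",
                 "gait_score", "recovery"])
    metadata["gait_score"] = metadata["gait_score"].astype("Int64")
    truth = pd.DataFrame(truth_rows, columns=["target", "phenotype", "fold_change"])
    return SimulatedCtStudy(ct, metadata, truth, config)
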