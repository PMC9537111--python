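"""Synthetic paired-score cohort generation.

Real paired MMSE/MoCA cohorts from memory-clinic populations are rarely
deposited, so the pipeline is exercised on synthetic cohorts that emulate
their statistical structure: integer totals on 0-30, high rank
correlation between the two scales, education strata with distinct score
levels, a MoCA mean below the MMSE mean (so that clamping at zero
produces the MoCA floor effect), and realistic age/sex marginals.

Two mechanisms are provided:

* ``generate_cohort`` — a latent bivariate normal per education stratum,
  discretized by rounding and clamping to [0, 30].  This is the simplest
  mechanism that yields integer scores, floor effects and a tunable
  correlation, given that only means, SDs, ranges and a correlation level
  are available to target.
* ``generate_from_model`` — known-truth generation: source scores are
  sampled, target scores are the circle-arc conversion of the source plus
  Gaussian noise.  Used for parameter-recovery and round-trip tests.

A single root seed spawns independent substreams for stratum assignment,
scores, education, age and sex, so adding a field never perturbs the
draws of another.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .circle_arc import CircleArcModel, convert_score, round_half_away
from .score_data import SCORE_MAX, SCORE_MIN, Cohort, SubjectRecord

#: education-year band sampled uniformly within each stratum
EDUCATION_BANDS = {"low": (0, 6), "medium": (7, 9), "high": (10, 16)}

#: age distribution of the emulated clinic population (years)
AGE_MEAN, AGE_SD, AGE_MIN, AGE_MAX = 69.7, 11.1, 40.0, 95.0
#: proportion of male patients
MALE_PROPORTION = 0.42


@dataclass(frozen=True)
class StratumScores:
    """Target first moments for one stratum's paired scores (score units)."""

    mmse_mean: float
    mmse_sd: float
    moca_mean: float
    moca_sd: float


#: default per-stratum score moments of the emulated clinic cohort
DEFAULT_STRATUM_SCORES: Mapping[str, StratumScores] = {
    "low": StratumScores(11.42, 7.08, 6.82, 5.37),
    "medium": StratumScores(15.54, 6.91, 8.54, 4.92),
    "high": StratumScores(15.48, 6.67, 9.62, 5.49),
}

#: default stratum mix (proportional to 66 : 48 : 84 low/medium/high)
DEFAULT_STRATA_WEIGHTS: Mapping[str, float] = {
    "low": 66 / 198, "medium": 48 / 198, "high": 84 / 198,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to draw one synthetic cohort reproducibly."""

    n: int = 322
    rho: float = 0.9
    strata_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRATA_WEIGHTS))
    stratum_scores: Mapping[str, StratumScores] = field(
        default_factory=lambda: dict(DEFAULT_STRATUM_SCORES))
    noise_sd: float = 2.0
    seed: int = 0
    mode: str = "bivariate"  # "bivariate" | "model_driven"

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if not -1 < self.rho < 1:
            raise ValueError(f"rho={self.rho} must lie strictly in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.mode not in ("bivariate", "model_driven"):
            raise ValueError(f"unknown mode {self.mode!r}")
        w = np.array([self.strata_weights.get(k, 0.0)
                      for k in ("low", "medium", "high")])
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("strata_weights must be nonnegative and sum to 1")
        missing = [k for k in ("low", "medium", "high")
                   if k not in self.stratum_scores]
        if missing:
            raise ValueError(f"stratum_scores missing strata {missing}")


def _clamp_scores(latent: np.ndarray) -> np.ndarray:
    return np.clip(round_half_away(latent), SCORE_MIN, SCORE_MAX)


def _spawn_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _demographics(rngs, n):
    ages = np.clip(rngs["age"].normal(AGE_MEAN, AGE_SD, size=n), AGE_MIN, AGE_MAX)
    sexes = np.where(rngs["sex"].random(n) < MALE_PROPORTION, "male", "female")
    return ages, sexes


def generate_cohort(spec: GeneratorSpec) -> Cohort:
    """Draw a stratified cohort from the latent bivariate-normal mechanism.

    Each subject is assigned a stratum by the mixture weights; the paired
    scores come from a bivariate normal with that stratum's means/SDs and
    the shared correlation ``rho``, rounded half away from zero and
    clamped to [0, 30]; education years are uniform within the stratum's
    band; age is normal (clamped to [40, 95]) and sex Bernoulli.
    Identical spec (including seed) gives an identical cohort.
    """
    rngs = _spawn_rngs(spec.seed, ["strata", "scores", "education", "age", "sex"])
    levels = ("low", "medium", "high")
    weights = np.array([spec.strata_weights[k] for k in levels], dtype=float)
    strata = rngs["strata"].choice(len(levels), size=spec.n, p=weights)

    mmse = np.empty(spec.n, dtype=int)
    moca = np.empty(spec.n, dtype=int)
    education = np.empty(spec.n, dtype=int)
    for idx, level in enumerate(levels):
        mask = strata == idx
        k = int(mask.sum())
        if k == 0:
            continue
        m = spec.stratum_scores[level]
        cov = np.array([
            [m.mmse_sd**2, spec.rho * m.mmse_sd * m.moca_sd],
            [spec.rho * m.mmse_sd * m.moca_sd, m.moca_sd**2],
        ])
        latent = rngs["scores"].multivariate_normal(
            [m.mmse_mean, m.moca_mean], cov, size=k)
        mmse[mask] = _clamp_scores(latent[:, 0])
        moca[mask] = _clamp_scores(latent[:, 1])
        lo, hi = EDUCATION_BANDS[level]
        education[mask] = rngs["education"].integers(lo, hi + 1, size=k)

    ages, sexes = _demographics(rngs, spec.n)
    records = [
        SubjectRecord(subject_id=f"syn{i:05d}", age=float(ages[i]),
                      sex=str(sexes[i]), education_years=int(education[i]),
                      mmse=int(mmse[i]), moca=int(moca[i]))
        for i in range(spec.n)
    ]
    return Cohort(records=records, label="synthetic",
                  metadata={"generator_spec": spec})


MmseSampler = Callable[[np.random.Generator, int], np.ndarray]


def _default_mmse_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    """Discretized normal at the emulated total-group moments (12.11, 6.82)."""
    return _clamp_scores(rng.normal(12.11, 6.82, size=n))


def generate_from_model(model: CircleArcModel, n: int, noise_sd: float,
                        mmse_sampler: "MmseSampler | Sequence[int] | None" = None,
                        seed: int = 0) -> Cohort:
    """Generate a cohort whose target scores follow a known conversion.

    ``moca = clamp(round(convert(mmse) + N(0, noise_sd)), 0, 30)``.  The
    sampler may be a callable ``(rng, n) -> scores``, an explicit sequence
    of length ``n`` used verbatim (handy for full-coverage designs), any
    other sequence sampled uniformly with replacement, or ``None`` for the
    default discretized-normal source distribution.  The generating model
    is recorded in the cohort metadata for recovery tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rngs = _spawn_rngs(seed, ["mmse", "noise", "education", "age", "sex"])
    if mmse_sampler is None:
        mmse = _default_mmse_sampler(rngs["mmse"], n)
    elif callable(mmse_sampler):
        mmse = np.asarray(mmse_sampler(rngs["mmse"], n), dtype=int)
    else:
        pool = np.asarray(list(mmse_sampler), dtype=int)
        mmse = pool if pool.size == n else rngs["mmse"].choice(pool, size=n)
    if mmse.shape != (n,):
        raise ValueError(f"mmse sampler produced shape {mmse.shape}, wanted ({n},)")

    exact = np.array([convert_score(model, float(s)) for s in mmse])
    noise = rngs["noise"].normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    moca = _clamp_scores(exact + noise)

    education = rngs["education"].integers(0, 17, size=n)
    ages, sexes = _demographics(rngs, n)
    records = [
        SubjectRecord(subject_id=f"mod{i:05d}", age=float(ages[i]),
                      sex=str(sexes[i]), education_years=int(education[i]),
                      mmse=int(mmse[i]), moca=int(moca[i]))
        for i in range(n)
    ]
    return Cohort(records=records, label="model-driven",
                  metadata={"generating_model": model, "noise_sd": noise_sd})


def read_generator_spec(path: str | Path) -> GeneratorSpec:
    """Parse a GeneratorSpec from an INI-style ``key = value`` config.

    Sections: ``[generator]`` (n, rho, noise_sd, seed, mode),
    ``[strata]`` (weights), and per-stratum ``[low]/[medium]/[high]``
    sections with mmse_mean/mmse_sd/moca_mean/moca_sd.  Omitted sections
    fall back to the package defaults.
    """
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(path)
    kwargs: dict = {}
    if parser.has_section("generator"):
        gen = parser["generator"]
        for key, cast in (("n", int), ("rho", float), ("noise_sd", float),
                          ("seed", int)):
            if key in gen:
                kwargs[key] = cast(gen[key])
        if "mode" in gen:
            kwargs["mode"] = gen["mode"].strip()
    if parser.has_section("strata"):
        kwargs["strata_weights"] = {
            k: float(v) for k, v in parser["strata"].items()}
    scores = dict(DEFAULT_STRATUM_SCORES)
    for level in ("low", "medium", "high"):
        if parser.has_section(level):
            sec = parser[level]
            scores[level] = StratumScores(
                mmse_mean=float(sec["mmse_mean"]), mmse_sd=float(sec["mmse_sd"]),
                moca_mean=float(sec["moca_mean"]), moca_sd=float(sec["moca_sd"]))
    kwargs["stratum_scores"] = scores
    return GeneratorSpec(**kwargs)
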