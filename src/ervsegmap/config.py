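"""Configuration objects for simulation and pipeline runs.

All coordinates are 0-based, half-open. The three pooled lines are always
ordered (H, L, W): high-growth, low-growth, and the White Leghorn outgroup.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

LINES = ("H", "L", "W")

#: Pooled-library fold coverage of the three lines (H, L, W).
DEFAULT_COVERAGE = (5.53, 5.19, 3.37)


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class AlleleFrequencyModel:
    """Distribution of per-line insertion allele frequencies.

    kind:
      ``beta_shared``      one Beta(a, b) draw per insertion, copied to all
                           three lines (null model: no line differentiation).
      ``beta_independent`` independent Beta(a, b) draws per line.
      ``point``            fixed frequency triple for every insertion.
      ``cycle``            deterministic cycle over a list of frequency
                           triples (e.g. alternate line-private and shared
                           insertions).
    """

    kind: str = "beta_shared"
    a: float = 0.5
    b: float = 0.5
    freqs: tuple[float, float, float] = (0.5, 0.5, 0.5)
    freq_list: tuple = ()

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Return an (n, 3) array of per-line allele frequencies."""
        if self.kind == "beta_shared":
            f = rng.beta(self.a, self.b, size=n)
            return np.repeat(f[:, None], 3, axis=1)
        if self.kind == "beta_independent":
            return rng.beta(self.a, self.b, size=(n, 3))
        if self.kind == "point":
            f = np.asarray(self.freqs, dtype=float)
            if f.shape != (3,) or np.any(f < 0) or np.any(f > 1):
                raise ConfigError("point frequencies must be a triple in [0, 1]")
            return np.repeat(f[None, :], n, axis=0)
        if self.kind == "cycle":
            if not self.freq_list:
                raise ConfigError("cycle model requires a non-empty freq_list")
            arr = np.asarray(self.freq_list, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or np.any((arr < 0) | (arr > 1)):
                raise ConfigError("freq_list must hold frequency triples in [0, 1]")
            idx = np.arange(n) % len(arr)
            return arr[idx]
        raise ConfigError(f"unknown allele_freq_model kind: {self.kind!r}")


@dataclass(frozen=True)
class ScoreModel:
    """Distribution of ERV-library alignment scores.

    Defaults emulate the mapper's observed integer score range 400-493,
    drawn uniformly; junction reads therefore straddle both the strict
    (>=425) and relaxed (>=400) thresholds.
    """

    low: int = 400
    high: int = 493

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.low > self.high:
            raise ConfigError("score model requires low <= high")
        return rng.integers(self.low, self.high + 1, size=n)


@dataclass
class SimulationConfig:
    """Parameters of the pooled mate-pair simulation.

    Defaults reproduce the study conditions the pipeline was built for:
    three pools of 11 individuals sequenced at 5.53x / 5.19x / 3.37x with
    50 nt x 2 mate-pair reads and ~3,500 nt inserts; full-length elements
    of 7-11 kb flanked by LTRs; solo-LTRs about 20x more frequent than
    full-length proviruses.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 1_000_000
    n_erv_families: int = 20
    erv_length_range: tuple[int, int] = (7_000, 11_000)
    ltr_length: int = 300
    n_insertions: int = 100
    solo_ltr_fraction: float = 20.0 / 21.0
    truncated_fraction: float = 0.1
    in_reference_fraction: float = 0.25
    pool_size_per_line: int = 11
    coverage_per_line: tuple[float, float, float] = DEFAULT_COVERAGE
    read_length: int = 50
    insert_mean: int = 3_500
    insert_sd: int = 300
    noise_rate: float = 0.01
    allele_freq_model: AlleleFrequencyModel = field(default_factory=AlleleFrequencyModel)
    score_model: ScoreModel = field(default_factory=ScoreModel)

    def validate(self) -> None:
        counts = (
            self.n_chromosomes,
            self.chromosome_length,
            self.n_erv_families,
            self.ltr_length,
            self.pool_size_per_line,
            self.read_length,
            self.insert_mean,
        )
        if any(c <= 0 for c in counts):
            raise ConfigError("all counts and lengths must be positive")
        if self.n_insertions < 0:
            raise ConfigError("n_insertions must be >= 0")
        if len(self.coverage_per_line) != 3 or any(c < 0 for c in self.coverage_per_line):
            raise ConfigError("coverage_per_line must be a non-negative triple")
        if not (0.0 <= self.solo_ltr_fraction <= 1.0):
            raise ConfigError("solo_ltr_fraction must lie in [0, 1]")
        if not (0.0 <= self.truncated_fraction <= 1.0):
            raise ConfigError("truncated_fraction must lie in [0, 1]")
        if not (0.0 <= self.in_reference_fraction <= 1.0):
            raise ConfigError("in_reference_fraction must lie in [0, 1]")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ConfigError("noise_rate must lie in [0, 1]")
        if self.insert_mean <= 2 * self.read_length:
            raise ConfigError("insert_mean must exceed twice the read length")
        lo, hi = self.erv_length_range
        if not (0 < lo <= hi):
            raise ConfigError("erv_length_range must satisfy 0 < lo <= hi")
        if self.ltr_length * 2 >= lo:
            raise ConfigError("two LTRs must fit inside the shortest full element")

    @property
    def haploids_per_pool(self) -> int:
        return 2 * self.pool_size_per_line


@dataclass
class RunConfig:
    """Flat parameter set for an end-to-end pipeline run.

    Every clustering/testing threshold has a named default matching the
    conditions the pipeline was calibrated for.
    """

    seed: int = 0
    score_min: int = 425
    relaxed_min: int = 400
    window: int = 3_500
    footprint_frac: float = 0.02
    max_sep: int = 20_000
    fisher_cutoff: int = 15
    alpha: float = 0.05
    flank: int = 150_000
    bin_size: int = 10_000
    tune_target: int = 10_000
    require_flank_evidence: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")
        positives = (
            self.score_min,
            self.relaxed_min,
            self.window,
            self.max_sep,
            self.fisher_cutoff,
            self.flank,
            self.bin_size,
            self.tune_target,
        )
        if any(v <= 0 for v in positives):
            raise ConfigError("all thresholds must be positive")
        if not (0.0 < self.footprint_frac <= 1.0):
            raise ConfigError("footprint_frac must lie in (0, 1]")
        if self.relaxed_min > self.score_min:
            raise ConfigError("relaxed_min must not exceed score_min")
        self.simulation.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        afm = sim_raw.pop("allele_freq_model", None)
        sm = sim_raw.pop("score_model", None)
        sim = SimulationConfig(**sim_raw)
        if afm is not None:
            sim.allele_freq_model = AlleleFrequencyModel(**afm)
        if sm is not None:
            sim.score_model = ScoreModel(**sm)
        cfg = cls(**raw, simulation=sim)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
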