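"""Synthetic Hi-C cohorts with planted, ground-truthed chromatin loops.

The generator emulates the statistical structure the union workflow
assumes: a power-law distance-decay background ``E(d) = A (1 + d)^-alpha``,
multiplicative per-bin coverage bias (lognormal), independent Poisson counts
per pixel, and planted focal loops that multiply the local mean by a factor
``f`` through a Gaussian bump of spread ``sigma_bins``.  Loops can be shared
or sample-specific, and are positionally jittered per sample.  Expected
total cis counts per sample are rescaled to the configured depth.  A peak
track (one resolution-sized interval per true anchor) accompanies the truth
table for anchor-overlap evaluation.

Everything is reproducible from the seed: placement, jitter, bias and
counts draw from independent child streams of one root seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contacts import ContactMatrix, merge_samples
from .dotcall import DotCallParams
from .model import BinnedChrom, PeakInterval

__all__ = [
    "PlantedLoop",
    "LoopSpec",
    "SampleOverride",
    "SimConfig",
    "SimCohort",
    "simulate_cohort",
    "standard_scenarios",
    "desk_scale_dot_params",
]


@dataclass(frozen=True)
class PlantedLoop:
    """One planted loop: base pixel, presence set, enrichment, spread, jitter."""

    bin1: int
    bin2: int
    presence: tuple[int, ...]  # sample indices carrying the loop
    factor: float
    sigma_bins: float = 0.0
    jitter_bins: int = 0  # per-axis offsets drawn uniformly from [-j, j]

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError("enrichment factor must be >= 1")
        if not self.presence:
            raise ValueError("presence set must be nonempty")


@dataclass(frozen=True)
class LoopSpec:
    """Recipe for seeded random loop placement."""

    n_loops: int
    min_dist_bins: int
    max_dist_bins: int
    factor: float
    sigma_bins: float = 0.0
    jitter_bins: int = 0
    min_separation_bins: int = 15
    # (presence tuple, weight) choices; None = present in all samples
    presence_weights: tuple[tuple[tuple[int, ...], float], ...] | None = None


@dataclass(frozen=True)
class SampleOverride:
    """Per-sample deviations (e.g. an outlier sample with shifted loops)."""

    factor_mult: float = 1.0
    jitter_bins: int | None = None


@dataclass(frozen=True)
class SimConfig:
    chrom_name: str = "chrSim"
    length_bp: int = 25_000_000
    resolution: int = 5000
    n_samples: int = 3
    depth: float = 1e7  # expected total cis counts per sample
    alpha: float = 1.0  # distance-decay exponent
    bias_sigma: float = 0.2  # lognormal coverage-bias sigma (0 = bias-free)
    overdispersion: float = 0.0  # gamma-Poisson mixing; 0 = pure Poisson
    loops: tuple[PlantedLoop, ...] | None = None
    loop_spec: LoopSpec | None = None
    sample_overrides: dict[int, SampleOverride] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.depth <= 0:
            raise ValueError("alpha and depth must be > 0")
        if self.bias_sigma < 0 or self.overdispersion < 0:
            raise ValueError("bias_sigma and overdispersion must be >= 0")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")

    @property
    def chrom(self) -> BinnedChrom:
        return BinnedChrom(self.chrom_name, self.length_bp, self.resolution)

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]


@dataclass
class SimCohort:
    config: SimConfig
    matrices: dict[str, dict[str, ContactMatrix]]  # sample -> chrom -> matrix
    truth: pd.DataFrame
    peaks: list[PeakInterval]
    bias: dict[str, np.ndarray] = field(default_factory=dict)  # realized coverage bias

    @property
    def sample_ids(self) -> list[str]:
        return self.config.sample_ids

    def mega(self) -> dict[str, ContactMatrix]:
        """Merged (MEGA) map: element-wise sum of all samples' raw counts."""
        chroms = next(iter(self.matrices.values())).keys()
        return {
            c: merge_samples([self.matrices[s][c] for s in self.sample_ids])
            for c in chroms
        }


# --------------------------------------------------------------------------- #


def _place_loops(config: SimConfig, rng: np.random.Generator) -> tuple[PlantedLoop, ...]:
    spec = config.loop_spec
    n = config.chrom.n_bins
    margin = spec.max_dist_bins + spec.jitter_bins + 10
    placed: list[tuple[int, int]] = []
    loops: list[PlantedLoop] = []
    attempts = 0
    while len(loops) < spec.n_loops:
        attempts += 1
        if attempts > 200 * spec.n_loops:
            raise ValueError("cannot place loops: chromosome too crowded")
        b1 = int(rng.integers(margin, n - margin))
        d = int(rng.integers(spec.min_dist_bins, spec.max_dist_bins + 1))
        b2 = b1 + d
        if any(
            max(abs(b1 - p1), abs(b2 - p2)) < spec.min_separation_bins
            for p1, p2 in placed
        ):
            continue
        if spec.presence_weights is None:
            presence = tuple(range(config.n_samples))
        else:
            choices, weights = zip(*spec.presence_weights)
            wsum = sum(weights)
            k = rng.choice(len(choices), p=[w / wsum for w in weights])
            presence = tuple(choices[k])
        placed.append((b1, b2))
        loops.append(
            PlantedLoop(
                b1, b2, presence, spec.factor, spec.sigma_bins, spec.jitter_bins
            )
        )
    return tuple(loops)


def simulate_cohort(config: SimConfig, seed: int | None = None) -> SimCohort:
    """Generate a cohort of contact matrices plus truth and peak track.

    The per-pixel mean in sample ``s`` is
    ``b_i b_j E(|i - j|) L_s(i, j)`` with ``L_s`` the product of Gaussian
    loop bumps present in ``s`` (each jittered per sample), rescaled so the
    expected total equals the configured depth; counts are Poisson.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    root = int(config.seed)
    chrom = config.chrom
    n = chrom.n_bins

    loops = config.loops
    if loops is None:
        if config.loop_spec is None:
            loops = ()
        else:
            loops = _place_loops(config, np.random.default_rng([root, 1]))

    # per-sample, per-loop jitter offsets
    rng_jit = np.random.default_rng([root, 2])
    jitters: dict[tuple[int, int], tuple[int, int]] = {}
    for li, lp in enumerate(loops):
        for s in range(config.n_samples):
            ov = config.sample_overrides.get(s)
            j = lp.jitter_bins if ov is None or ov.jitter_bins is None else ov.jitter_bins
            dx = int(rng_jit.integers(-j, j + 1)) if j > 0 else 0
            dy = int(rng_jit.integers(-j, j + 1)) if j > 0 else 0
            jitters[(li, s)] = (dx, dy)

    idx = np.arange(n)
    decay = (1.0 + np.arange(n, dtype=float)) ** (-config.alpha)
    base = decay[np.abs(idx[:, None] - idx[None, :])]  # shared decay background
    lower = idx[None, :] < idx[:, None]

    matrices: dict[str, dict[str, ContactMatrix]] = {}
    biases: dict[str, np.ndarray] = {}
    for s, sid in enumerate(config.sample_ids):
        rng_bias = np.random.default_rng([root, 3, s])
        if config.bias_sigma > 0:
            b = rng_bias.lognormal(0.0, config.bias_sigma, size=n)
            b /= b.mean()
        else:
            b = np.ones(n)
        biases[sid] = b
        mean = base * b[:, None]
        mean *= b[None, :]
        ov = config.sample_overrides.get(s)
        fmult = 1.0 if ov is None else ov.factor_mult
        for li, lp in enumerate(loops):
            if s not in lp.presence:
                continue
            dx, dy = jitters[(li, s)]
            c1, c2 = lp.bin1 + dx, lp.bin2 + dy
            f = 1.0 + (lp.factor * fmult - 1.0)
            if lp.sigma_bins == 0:
                mean[c1, c2] *= f
                mean[c2, c1] *= f
            else:
                R = int(np.ceil(3 * lp.sigma_bins)) + 1
                u = np.arange(-R, R + 1)
                g = np.exp(-(u[:, None] ** 2 + u[None, :] ** 2) / (2 * lp.sigma_bins**2))
                bump = 1.0 + (f - 1.0) * g
                mean[c1 - R : c1 + R + 1, c2 - R : c2 + R + 1] *= bump
                mean[c2 - R : c2 + R + 1, c1 - R : c1 + R + 1] *= bump.T
        mean[lower] = 0.0
        mean *= config.depth / mean.sum()
        rng_counts = np.random.default_rng([root, 4, s])
        if config.overdispersion > 0:
            shape = 1.0 / config.overdispersion
            mean = mean * rng_counts.gamma(shape, 1.0 / shape, size=mean.shape)
        counts = rng_counts.poisson(mean)
        matrices[sid] = {chrom.name: ContactMatrix(chrom, sp.coo_matrix(counts))}

    truth_rows = []
    for li, lp in enumerate(loops):
        row = {
            "loop_id": li,
            "chrom": chrom.name,
            "bin1": lp.bin1,
            "bin2": lp.bin2,
            "presence": ",".join(config.sample_ids[s] for s in sorted(lp.presence)),
            "factor": lp.factor,
        }
        for s, sid in enumerate(config.sample_ids):
            if s in lp.presence:
                dx, dy = jitters[(li, s)]
                row[f"bin1_{sid}"] = lp.bin1 + dx
                row[f"bin2_{sid}"] = lp.bin2 + dy
            else:
                row[f"bin1_{sid}"] = np.nan
                row[f"bin2_{sid}"] = np.nan
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    res = chrom.resolution
    anchor_bins = sorted(
        {lp.bin1 for lp in loops} | {lp.bin2 for lp in loops}
    )
    peaks = [PeakInterval(chrom.name, b * res, (b + 1) * res) for b in anchor_bins]
    return SimCohort(
        config=config, matrices=matrices, truth=truth, peaks=peaks, bias=biases
    )


# --------------------------------------------------------------------------- #
# named presets


def standard_scenarios() -> dict[str, SimConfig]:
    """Named cohort presets covering the workflow's study conditions.

    * ``shared_jitter`` — 200 strong (f = 6) loops shared by all three
      samples, Gaussian spread 1 bin, per-sample jitter of +/- 1 bin: the
      specificity/fine-tuning scenario.
    * ``weak_rescue`` — 200 weak (f = 4.6 at half depth) sharp loops shared
      by all samples; individually they surface mostly as sub-threshold
      singletons, so recovery requires pooling with the other samples and
      the MEGA map.
    * ``specific_mix`` — a mix of shared and sample-specific loops (gained /
      lost between samples).
    * ``depth_sweep_high/mid/low`` — the shared_jitter truth at decreasing
      sequencing depth.
    * ``outlier_sample`` — shared loops where the third sample is an
      outlier: stronger (f x 4/3) and more jittered (+/- 2 bins) signal,
      the regime separating max-single from summed representative selection.
    """
    shared_spec = LoopSpec(
        n_loops=200,
        min_dist_bins=20,
        max_dist_bins=60,
        factor=6.0,
        sigma_bins=1.0,
        jitter_bins=1,
        min_separation_bins=15,
    )
    base = SimConfig(loop_spec=shared_spec)
    mix_weights = (
        ((0, 1, 2), 0.4),
        ((0,), 0.15),
        ((2,), 0.15),
        ((0, 1), 0.15),
        ((1, 2), 0.15),
    )
    return {
        "shared_jitter": base,
        "weak_rescue": SimConfig(
            depth=5e6,
            loop_spec=LoopSpec(
                n_loops=200,
                min_dist_bins=40,
                max_dist_bins=60,
                factor=4.6,
                sigma_bins=0.0,
                jitter_bins=0,
                min_separation_bins=15,
            ),
        ),
        "specific_mix": SimConfig(
            loop_spec=replace(shared_spec, presence_weights=mix_weights)
        ),
        "depth_sweep_high": base,
        "depth_sweep_mid": replace(base, depth=5e6),
        "depth_sweep_low": replace(base, depth=2.5e6),
        "outlier_sample": replace(
            base,
            sample_overrides={2: SampleOverride(factor_mult=4.0 / 3.0, jitter_bins=2)},
        ),
    }


def desk_scale_dot_params(**overrides) -> DotCallParams:
    """Dot-calling parameters sized for the simulated 25 Mb chromosome.

    Planted loops lie at 100 kb - 1 Mb anchor separation, so the search band
    is capped at 2 Mb and tiles at 2.5 Mb; all other parameters keep the
    package defaults.
    """
    kw = {"max_loci_separation": 2_000_000, "tile_size": 2_500_000}
    kw.update(overrides)
    return DotCallParams(**kw)
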