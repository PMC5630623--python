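"""Bagging nearest-neighbor prediction test (BNNPT) of independence.

BNNPT asks whether a response Y can be predicted from a predictor X better
than chance. A bagged 1-nearest-neighbor regressor is built from X alone:
for every point i and every bag j, ``mtry`` candidate indices are drawn at
random from the other points and the candidate whose X value is closest to
``x[i]`` becomes that bag's neighbor. The out-of-bag prediction

    H_i = mean_j y[Neighborhood(i, j)]

never uses ``y[i]`` itself. The test statistic is the Euclidean prediction
error ``SE = ||H - Y||_2``. Under independence, shuffling Y leaves the
distribution of SE unchanged, so the p-value is the fraction of random
permutations of Y whose SE is less than or equal to the observed SE, the
neighborhood structure being held fixed.

The module is organised in the order the method runs:

1.  configuration and logging
2.  core test (neighborhood, out-of-bag estimator, SE, permutation p-value,
    exhaustive small-n oracle)
3.  classical comparator tests (Pearson, Spearman, Kendall, distance
    correlation, Hoeffding's D)
4.  simulation study (scenario generator, rejection-rate estimation, power
    tables)
5.  file I/O and batch screening with Bonferroni control
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSample",
    "BNNPTConfig",
    "NeighborhoodStructure",
    "TestResult",
    "ComparatorResult",
    "Scenario",
    "PowerEstimate",
    "BatchResult",
    "build_neighborhood",
    "weight_matrix",
    "oob_estimate",
    "se_statistic",
    "bnnpt_test",
    "exhaustive_bnnpt_pvalue",
    "pearson_test",
    "spearman_test",
    "kendall_test",
    "distance_correlation_test",
    "hoeffding_test",
    "hoeffding_d",
    "generate_dataset",
    "estimate_rejection_rate",
    "run_power_table",
    "read_pair_table",
    "run_batch",
    "bonferroni_threshold",
    "write_result_tsv",
    "write_manifest",
    "SCENARIO_FUNCTIONS",
    "COMPARATOR_METHODS",
]

# --------------------------------------------------------------------------
# configuration & logging
# --------------------------------------------------------------------------

logger = logging.getLogger("bnnpt")

#: default number of bags; chosen for computing efficiency, the test is
#: robust to this choice.
DEFAULT_BAGS = 256

#: default Monte-Carlo permutation count.
DEFAULT_PERMUTATIONS = 1000

#: largest n for which exhaustive n! enumeration is allowed.
EXHAUSTIVE_MAX_N = 8

# chunk sizes keeping intermediate arrays small (~tens of MB) while leaving
# RNG consumption a deterministic function of (n, bags, mtry) only
_NEIGHBOR_CHUNK_FLOATS = 4_000_000
_PERMUTATION_CHUNK = 100_000


def default_mtry(n: int) -> int:
    """Default bag size: round(sqrt(N)), at least 1 (N=50 gives 7)."""
    return max(1, int(round(math.sqrt(n))))


@dataclass(frozen=True)
class PairedSample:
    """A paired sample (x, y) of common length n >= 3 without missing values.

    ``x`` is the predictor, ``y`` the response; the test is not symmetric in
    the two roles.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1:
            raise ValueError("x and y must be one-dimensional vectors")
        if x.shape[0] != y.shape[0]:
            raise ValueError(
                f"x and y must have equal length, got {x.shape[0]} and {y.shape[0]}"
            )
        if x.shape[0] < 3:
            raise ValueError(f"need at least 3 paired observations, got {x.shape[0]}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("missing or non-finite values are not allowed; drop them upstream")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.shape[0]


@dataclass(frozen=True)
class BNNPTConfig:
    """Parameters of the BNNPT permutation test.

    Parameters
    ----------
    bags:
        Number of bags b (columns of the neighborhood structure).
    mtry:
        Bag size m, the number of candidate neighbors drawn per bag;
        ``None`` resolves to ``round(sqrt(n))`` at test time.
    permutations:
        Monte-Carlo permutation count B.
    alpha:
        Nominal significance level, only used by callers that threshold
        the p-value.
    seed:
        Master RNG seed; required by :func:`bnnpt_test` for reproducibility.
    p_estimator:
        ``"add_one"`` reports (count+1)/(B+1), which can never be zero;
        ``"raw"`` reports count/B.
    replace:
        Draw bag candidates with replacement (sensitivity checks only);
        the default draws without replacement.
    """

    bags: int = DEFAULT_BAGS
    mtry: int | None = None
    permutations: int = DEFAULT_PERMUTATIONS
    alpha: float = 0.05
    seed: int | None = None
    p_estimator: str = "add_one"
    replace: bool = False

    def resolved_mtry(self, n: int) -> int:
        return self.mtry if self.mtry is not None else default_mtry(n)

    def validate(self, n: int) -> None:
        mtry = self.resolved_mtry(n)
        if not 1 <= mtry <= n - 1:
            raise ValueError(f"mtry must be in [1, n-1] = [1, {n - 1}], got {mtry}")
        if self.bags < 1:
            raise ValueError(f"bags must be >= 1, got {self.bags}")
        if self.permutations < 1:
            raise ValueError(f"permutations must be >= 1, got {self.permutations}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.p_estimator not in ("raw", "add_one"):
            raise ValueError(f"p_estimator must be 'raw' or 'add_one', got {self.p_estimator!r}")


# --------------------------------------------------------------------------
# core test
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NeighborhoodStructure:
    """n x bags matrix of neighbor indices, a function of x (never y).

    ``neighbors[i, j]`` is the 0-based index of the bag-j nearest neighbor
    of point i; it is never i itself.
    """

    neighbors: np.ndarray
    bags: int
    mtry: int
    seed_used: int | None = None

    @property
    def n(self) -> int:
        return self.neighbors.shape[0]


def build_neighborhood(
    x: np.ndarray,
    bags: int,
    mtry: int,
    rng: np.random.Generator,
    replace: bool = False,
    seed_used: int | None = None,
) -> NeighborhoodStructure:
    """Construct the bagged nearest-neighbor index matrix from x alone.

    For each point i and bag j, ``mtry`` candidate indices are drawn
    uniformly from the other n-1 points (without replacement unless
    ``replace``); the candidate minimising ``|x[k] - x[i]|`` wins, distance
    ties broken uniformly at random.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points to build a neighborhood")
    if not 1 <= mtry <= n - 1:
        raise ValueError(f"mtry must be in [1, n-1] = [1, {n - 1}], got {mtry}")
    if bags < 1:
        raise ValueError(f"bags must be >= 1, got {bags}")
    if np.ptp(x) == 0.0:
        logger.warning(
            "x is constant: all candidates tie, neighbors are uniform random "
            "and the test is null-calibrated but powerless"
        )

    neighbors = np.empty((n, bags), dtype=np.int64)
    chunk = max(1, _NEIGHBOR_CHUNK_FLOATS // (bags * max(n - 1, 1)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        rows = np.arange(start, stop)
        if replace:
            pos = rng.integers(0, n - 1, size=(rows.size, bags, mtry))
        else:
            # uniform sample without replacement: keep the mtry smallest
            # of n-1 i.i.d. uniform keys
            keys = rng.random((rows.size, bags, n - 1))
            pos = np.argpartition(keys, mtry - 1, axis=-1)[..., :mtry]
        # map candidate positions over {0..n-2} to indices skipping the row
        cand = pos + (pos >= rows[:, None, None])
        dist = np.abs(x[cand] - x[rows][:, None, None])
        tie_key = rng.random(dist.shape)
        is_min = dist <= dist.min(axis=-1, keepdims=True)
        winner_pos = np.where(is_min, tie_key, -1.0).argmax(axis=-1)
        neighbors[start:stop] = np.take_along_axis(
            cand, winner_pos[..., None], axis=-1
        )[..., 0]
    return NeighborhoodStructure(neighbors=neighbors, bags=bags, mtry=mtry, seed_used=seed_used)


def weight_matrix(neigh: NeighborhoodStructure) -> np.ndarray:
    """Row-stochastic, zero-diagonal weight matrix W with H = W @ y."""
    n = neigh.n
    flat = (np.arange(n)[:, None] * n + neigh.neighbors).ravel()
    counts = np.bincount(flat, minlength=n * n).astype(float)
    return counts.reshape(n, n) / neigh.bags


def oob_estimate(neigh: NeighborhoodStructure, y: np.ndarray) -> np.ndarray:
    """Out-of-bag prediction H: per-point mean of y over the neighbor row."""
    y = np.asarray(y, dtype=float)
    if y.shape != (neigh.n,):
        raise ValueError(f"y must have length {neigh.n}, got {y.shape}")
    return y[neigh.neighbors].mean(axis=1)


def se_statistic(h: np.ndarray, y: np.ndarray) -> float:
    """Euclidean prediction error ||H - Y||_2."""
    h = np.asarray(h, dtype=float)
    y = np.asarray(y, dtype=float)
    if h.shape != y.shape:
        raise ValueError("h and y must have equal length")
    return float(np.linalg.norm(h - y))


@dataclass(frozen=True)
class TestResult:
    """Outcome of one BNNPT run."""

    se_observed: float
    p_value: float
    permutations_used: int
    count_le: int
    config: BNNPTConfig
    mtry_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "se_observed": [self.se_observed],
                "p_value": [self.p_value],
                "permutations": [self.permutations_used],
                "bags": [self.config.bags],
                "mtry": [self.mtry_used],
                "seed": [self.config.seed],
            }
        )


def _spawn_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    # substream 0 builds the structure, substream 1 drives permutations;
    # the split keeps results independent of any later parallelisation
    s_struct, s_perm = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(s_struct), np.random.default_rng(s_perm)


def _pvalue_from_count(count_le: int, permutations: int, estimator: str) -> float:
    if estimator == "raw":
        return count_le / permutations
    return (count_le + 1) / (permutations + 1)


def bnnpt_test(sample: PairedSample, config: BNNPTConfig) -> TestResult:
    """Run the BNNPT permutation test of independence of (x, y).

    The neighborhood structure is built once from x; the observed SE and the
    SE of ``config.permutations`` uniform random permutations of y are
    computed on that fixed structure via the weight-matrix form
    ``SE(y') = ||(W - I) y'||``. The p-value is the (estimator-adjusted)
    fraction of permutations with ``SE_random <= SE_observed``.
    Deterministic given (sample, config.seed).
    """
    config.validate(sample.n)
    if config.seed is None:
        raise ValueError("config.seed is required for a reproducible test")
    n = sample.n
    mtry = config.resolved_mtry(n)
    rng_struct, rng_perm = _spawn_streams(config.seed)
    neigh = build_neighborhood(
        sample.x, config.bags, mtry, rng_struct, replace=config.replace, seed_used=config.seed
    )
    A = weight_matrix(neigh) - np.eye(n)
    se_obs = float(np.linalg.norm(A @ sample.y))

    count_le = 0
    remaining = config.permutations
    while remaining > 0:
        block = min(remaining, _PERMUTATION_CHUNK)
        yp = rng_perm.permuted(np.tile(sample.y, (block, 1)), axis=1)
        se_rand = np.linalg.norm(A @ yp.T, axis=0)
        count_le += int((se_rand <= se_obs).sum())
        remaining -= block

    p = _pvalue_from_count(count_le, config.permutations, config.p_estimator)
    return TestResult(
        se_observed=se_obs,
        p_value=p,
        permutations_used=config.permutations,
        count_le=count_le,
        config=config,
        mtry_used=mtry,
    )


def exhaustive_bnnpt_pvalue(sample: PairedSample, config: BNNPTConfig) -> float:
    """Exact permutation p-value by enumerating all n! permutations of y.

    Uses the same structure-building RNG substream as :func:`bnnpt_test`, so
    for a given seed the two share the neighborhood. The identity permutation
    is included, hence the result is at least 1/n!. Refuses n > 8.
    """
    config.validate(sample.n)
    if config.seed is None:
        raise ValueError("config.seed is required")
    n = sample.n
    if n > EXHAUSTIVE_MAX_N:
        raise ValueError(f"exhaustive enumeration limited to n <= {EXHAUSTIVE_MAX_N}, got {n}")
    rng_struct, _ = _spawn_streams(config.seed)
    neigh = build_neighborhood(
        sample.x, config.bags, config.resolved_mtry(n), rng_struct, replace=config.replace
    )
    A = weight_matrix(neigh) - np.eye(n)
    se_obs = float(np.linalg.norm(A @ sample.y))
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    se_all = np.linalg.norm(A @ sample.y[perms].T, axis=0)
    return float((se_all <= se_obs).sum() / perms.shape[0])


# --------------------------------------------------------------------------
# comparator tests
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparatorResult:
    """Uniform (method, statistic, p-value) contract for benchmark tests."""

    method: str
    statistic: float
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"method": [self.method], "statistic": [self.statistic], "p_value": [self.p_value]}
        )


def _check_variance(sample: PairedSample) -> None:
    if np.ptp(sample.x) == 0.0 or np.ptp(sample.y) == 0.0:
        raise ValueError("correlation undefined: zero variance in x or y")


def pearson_test(sample: PairedSample) -> ComparatorResult:
    """Pearson r with the two-sided t-test p-value on n-2 df."""
    _check_variance(sample)
    r, p = stats.pearsonr(sample.x, sample.y)
    return ComparatorResult("pearson", float(r), float(p))


def spearman_test(sample: PairedSample) -> ComparatorResult:
    """Spearman rho: Pearson on midranks, two-sided t approximation."""
    _check_variance(sample)
    rho, p = stats.spearmanr(sample.x, sample.y)
    return ComparatorResult("spearman", float(rho), float(p))


def kendall_test(sample: PairedSample) -> ComparatorResult:
    """Kendall tau-b with tie correction; exact p for small tie-free n,
    normal approximation otherwise (scipy's 'auto' policy)."""
    _check_variance(sample)
    tau, p = stats.kendalltau(sample.x, sample.y)
    return ComparatorResult("kendall", float(tau), float(p))


def _centered_distance_matrix(v: np.ndarray) -> np.ndarray:
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation_test(
    sample: PairedSample, permutations: int = DEFAULT_PERMUTATIONS, seed: int | None = None
) -> ComparatorResult:
    """Distance correlation with a Monte-Carlo permutation p-value.

    Implements the standard sample distance covariance via double-centered
    pairwise-distance matrices (an external published definition, not part
    of the bagging test itself). dCor is 0 for independent variables and 1
    for y a similarity transform of x; a degenerate margin yields dCor 0.
    Permuting y leaves both marginal distance variances unchanged, so the
    permutation test may rank permutations by dCov^2 alone.
    """
    A = _centered_distance_matrix(sample.x)
    B = _centered_distance_matrix(sample.y)
    dcov2 = float((A * B).mean())
    denom2 = float(np.sqrt((A * A).mean() * (B * B).mean()))
    dcor = float(np.sqrt(max(dcov2, 0.0) / denom2)) if denom2 > 0 else 0.0

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(permutations):
        idx = rng.permutation(sample.n)
        if float((A * B[np.ix_(idx, idx)]).mean()) >= dcov2:
            count_ge += 1
    p = (count_ge + 1) / (permutations + 1)
    return ComparatorResult("distance", dcor, p)


def hoeffding_d(x: np.ndarray, y: np.ndarray) -> float:
    """Hoeffding's D (scaled by 30 so D = 1 for tie-free monotone data).

    Uses the classical rank form with midrank tie corrections: with
    u(t) = 1, 1/2, 0 for t > 0, t = 0, t < 0,

        R_i = rank(x_i), S_i = rank(y_i)  (midranks),
        c_i = sum_{j != i} u(x_i - x_j) u(y_i - y_j),
        D1  = sum c_i (c_i - 1),
        D2  = sum (R_i - 1)(R_i - 2)(S_i - 1)(S_i - 2),
        D3  = sum (R_i - 2)(S_i - 2) c_i,
        D   = 30 [(n-2)(n-3) D1 + D2 - 2(n-2) D3] / [n(n-1)(n-2)(n-3)(n-4)].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 5:
        raise ValueError("Hoeffding's D requires n >= 5")
    R = stats.rankdata(x)
    S = stats.rankdata(y)
    ux = (np.sign(x[:, None] - x[None, :]) + 1.0) / 2.0
    uy = (np.sign(y[:, None] - y[None, :]) + 1.0) / 2.0
    prod = ux * uy
    np.fill_diagonal(prod, 0.0)
    c = prod.sum(axis=1)
    d1 = float(np.sum(c * (c - 1)))
    d2 = float(np.sum((R - 1) * (R - 2) * (S - 1) * (S - 2)))
    d3 = float(np.sum((R - 2) * (S - 2) * c))
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return 30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / denom


def hoeffding_test(
    sample: PairedSample, permutations: int = DEFAULT_PERMUTATIONS, seed: int | None = None
) -> ComparatorResult:
    """Hoeffding's D independence test with a permutation p-value.

    Being rank-based, D is invariant to strictly monotone transforms of
    either margin. Note the statistic targets continuous distributions and
    may behave poorly when either margin is heavily discrete (many ties).
    """
    d_obs = hoeffding_d(sample.x, sample.y)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(permutations):
        if hoeffding_d(sample.x, rng.permutation(sample.y)) >= d_obs:
            count_ge += 1
    p = (count_ge + 1) / (permutations + 1)
    return ComparatorResult("hoeffding", d_obs, p)


# --------------------------------------------------------------------------
# simulation study
# --------------------------------------------------------------------------

#: the simulated mean functions on x ~ Uniform(-1, 1)
SCENARIO_FUNCTIONS: Mapping[str, Callable[[np.ndarray], np.ndarray]] = {
    "const0": lambda x: np.zeros_like(x),
    "linear": lambda x: x,
    "quadratic": lambda x: 0.5 * (x + 1.0) ** 2,
    "sin1": lambda x: np.sin(np.pi * x),
    "sin3": lambda x: np.sin(3.0 * np.pi * x),
    "cos1": lambda x: np.cos(np.pi * x),
    "cos2": lambda x: np.cos(2.0 * np.pi * x),
    "cos3": lambda x: np.cos(3.0 * np.pi * x),
}


@dataclass(frozen=True)
class Scenario:
    """One simulation design: y = f(x) + N(0, sigma^2), x ~ Uniform(-1, 1).

    ``const0`` is the null (the rejection rate is the type-I error); every
    other function id yields a power estimate. ``noise_variance`` is the
    Gaussian variance (not the standard deviation).
    """

    function_id: str
    n: int = 50
    noise_variance: float = 1.0
    n_sims: int = 1000
    alpha: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.function_id not in SCENARIO_FUNCTIONS:
            raise ValueError(
                f"unknown function_id {self.function_id!r}; "
                f"choose one of {sorted(SCENARIO_FUNCTIONS)}"
            )
        if self.n < 3 or self.n_sims < 1 or self.noise_variance < 0:
            raise ValueError("invalid scenario parameters")


@dataclass(frozen=True)
class PowerEstimate:
    """Empirical rejection rate of a test under a scenario."""

    scenario: Scenario
    method: str
    rejections: int
    rejection_rate: float
    mc_std_error: float


def _replicate_rng(master_seed: int, replicate_index: int, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, replicate_index, salt]))


def _replicate_seed(master_seed: int, replicate_index: int, salt: int) -> int:
    ss = np.random.SeedSequence([master_seed, replicate_index, salt])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def generate_dataset(scenario: Scenario, replicate_index: int) -> PairedSample:
    """Generate one simulated dataset, regenerable in isolation.

    The RNG is seeded from (master_seed, replicate_index) only, so datasets
    are identical across methods (paired comparisons) and independent of
    execution order.
    """
    if not 0 <= replicate_index < scenario.n_sims:
        raise ValueError(f"replicate_index must be in [0, {scenario.n_sims}), got {replicate_index}")
    rng = _replicate_rng(scenario.master_seed, replicate_index)
    x = rng.uniform(-1.0, 1.0, scenario.n)
    eps = rng.normal(0.0, math.sqrt(scenario.noise_variance), scenario.n)
    y = SCENARIO_FUNCTIONS[scenario.function_id](x) + eps
    return PairedSample(x=x, y=y)


#: comparator registry used by the simulation and batch drivers;
#: signature: (sample, permutations, seed) -> p-value
COMPARATOR_METHODS: Mapping[str, Callable[[PairedSample, int, int], float]] = {
    "pearson": lambda s, B, seed: pearson_test(s).p_value,
    "spearman": lambda s, B, seed: spearman_test(s).p_value,
    "kendall": lambda s, B, seed: kendall_test(s).p_value,
    "distance": lambda s, B, seed: distance_correlation_test(s, B, seed).p_value,
    "hoeffding": lambda s, B, seed: hoeffding_test(s, B, seed).p_value,
}

# salt values separating the RNG streams of dataset generation (0), the
# BNNPT test (1) and permutation-based comparators (2)
_SALT_BNNPT = 1
_SALT_COMPARATOR = 2


def _method_pvalue(
    method: str,
    sample: PairedSample,
    scenario: Scenario,
    replicate_index: int,
    test_config: BNNPTConfig,
) -> float:
    if method == "bnnpt":
        seed = _replicate_seed(scenario.master_seed, replicate_index, _SALT_BNNPT)
        cfg = dataclasses.replace(test_config, seed=seed)
        return bnnpt_test(sample, cfg).p_value
    if method in COMPARATOR_METHODS:
        seed = _replicate_seed(scenario.master_seed, replicate_index, _SALT_COMPARATOR)
        return COMPARATOR_METHODS[method](sample, test_config.permutations, seed)
    raise ValueError(f"unknown method {method!r}")


def estimate_rejection_rate(
    scenario: Scenario,
    method: str,
    test_config: BNNPTConfig | None = None,
) -> PowerEstimate:
    """Empirical rejection rate of ``method`` at ``scenario.alpha``.

    Runs the test on ``scenario.n_sims`` independently generated datasets and
    counts rejections (p < alpha). For the null scenario ``const0`` this is
    the type-I error estimate; otherwise it is power. The Monte-Carlo
    standard error sqrt(r(1-r)/n_sims) accompanies the rate.
    """
    cfg = test_config if test_config is not None else BNNPTConfig()
    rejections = 0
    for i in range(scenario.n_sims):
        sample = generate_dataset(scenario, i)
        try:
            p = _method_pvalue(method, sample, scenario, i, cfg)
        except Exception:
            logger.error("replicate %d of scenario %s failed", i, scenario.function_id)
            raise
        if p < scenario.alpha:
            rejections += 1
    rate = rejections / scenario.n_sims
    return PowerEstimate(
        scenario=scenario,
        method=method,
        rejections=rejections,
        rejection_rate=rate,
        mc_std_error=math.sqrt(rate * (1.0 - rate) / scenario.n_sims),
    )


def run_power_table(
    scenarios: Sequence[Scenario],
    methods: Sequence[str],
    test_config: BNNPTConfig | None = None,
) -> pd.DataFrame:
    """Long-format power table over the scenarios x methods grid.

    Datasets are shared across methods within a replicate (the generator is
    seeded by scenario and replicate only), so method comparisons are paired.
    """
    if not scenarios or not methods:
        raise ValueError("scenarios and methods must be non-empty")
    rows = []
    for scenario in scenarios:
        for method in methods:
            est = estimate_rejection_rate(scenario, method, test_config)
            logger.info(
                "scenario=%s method=%s rate=%.3f",
                scenario.function_id, method, est.rejection_rate,
            )
            rows.append(
                {
                    "scenario": scenario.function_id,
                    "method": method,
                    "n": scenario.n,
                    "sigma2": scenario.noise_variance,
                    "n_sims": scenario.n_sims,
                    "alpha": scenario.alpha,
                    "rejections": est.rejections,
                    "rate": est.rejection_rate,
                    "mc_se": est.mc_std_error,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# file I/O & batch screening
# --------------------------------------------------------------------------


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_pair_table(
    path: str | Path,
    delimiter: str | None = None,
    has_header: bool | None = None,
) -> PairedSample:
    """Read a two-column (x, y) table from delimited text.

    The delimiter defaults to comma for ``.csv`` and tab otherwise. With
    ``has_header=None`` a header row is auto-detected (a first row that does
    not parse as numbers). Rows with missing or non-numeric values are
    dropped with a logged count; fewer than 3 complete rows is an error.
    """
    path = Path(path)
    sep = _sep_for(path, delimiter)
    if has_header is None:
        first = pd.read_csv(path, sep=sep, header=None, nrows=1)
        has_header = not all(
            pd.api.types.is_number(v) or _parses_as_float(v) for v in first.iloc[0]
        )
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns, found {df.shape[1]}")
    xy = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    complete = xy.dropna()
    dropped = len(xy) - len(complete)
    if dropped:
        logger.info("%s: dropped %d incomplete row(s)", path, dropped)
    if len(complete) < 3:
        raise ValueError(f"{path}: fewer than 3 complete rows after dropping missing values")
    return PairedSample(x=complete.iloc[:, 0].to_numpy(), y=complete.iloc[:, 1].to_numpy())


def _parses_as_float(v: object) -> bool:
    try:
        float(v)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class BatchResult:
    """Per-feature screening outcome under family-wise error control."""

    feature_id: str
    p_value: float
    se_observed: float
    significant: bool
    threshold_used: float


def bonferroni_threshold(alpha: float, n_features: int) -> float:
    """Per-test threshold alpha / m controlling the family-wise error."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return alpha / n_features


def _feature_seed(master_seed: int, feature_id: str) -> int:
    # stable under feature reordering: hash the id, not the position
    h = zlib.crc32(feature_id.encode("utf-8"))
    return int(np.random.SeedSequence([master_seed, h]).generate_state(1, dtype=np.uint32)[0])


def read_feature_matrix(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Features x samples matrix: first column feature ids, optional header."""
    path = Path(path)
    sep = _sep_for(path, delimiter)
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = not all(_parses_as_float(v) for v in first.iloc[0, 1:])
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None, index_col=0)
    df.index = df.index.astype(str)
    return df


def read_phenotype(path: str | Path, delimiter: str | None = None) -> pd.Series:
    """Phenotype vector: one value column, optionally preceded by sample ids."""
    path = Path(path)
    sep = _sep_for(path, delimiter)
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = not _parses_as_float(first.iloc[0, first.shape[1] - 1])
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    if df.shape[1] == 1:
        return pd.Series(pd.to_numeric(df.iloc[:, 0]))
    s = pd.Series(pd.to_numeric(df.iloc[:, 1]).to_numpy(), index=df.iloc[:, 0].astype(str))
    return s


def run_batch(
    matrix: pd.DataFrame,
    phenotype: pd.Series | np.ndarray,
    config: BNNPTConfig,
    correction: str = "bonferroni",
    swap: bool = False,
) -> list[BatchResult]:
    """Screen every feature against the phenotype with BNNPT.

    Each feature row plays the predictor X and the phenotype the response Y
    (``swap=True`` reverses the roles; the test is asymmetric). When both the
    matrix columns and the phenotype carry sample ids the two are aligned by
    id, otherwise by position. Per-feature seeds derive from the master seed
    and a hash of the feature id, so the result set is invariant to feature
    order. ``correction='bonferroni'`` flags p < alpha / n_features.
    """
    if config.seed is None:
        raise ValueError("config.seed is required for batch screening")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"correction must be 'bonferroni' or 'none', got {correction!r}")
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dupes[:5]}")

    if isinstance(phenotype, pd.Series) and not isinstance(phenotype.index, pd.RangeIndex):
        missing = [c for c in matrix.columns.astype(str) if c not in phenotype.index]
        if missing:
            raise ValueError(f"phenotype missing sample ids: {missing[:5]}")
        pheno = phenotype.loc[matrix.columns.astype(str)].to_numpy(dtype=float)
    else:
        pheno = np.asarray(phenotype, dtype=float)
        if pheno.shape[0] != matrix.shape[1]:
            raise ValueError(
                f"phenotype length {pheno.shape[0]} != sample count {matrix.shape[1]}"
            )
    if np.isin(pheno, (0.0, 1.0)).all():
        logger.warning(
            "phenotype is binary 0/1; the test assumes a continuous response "
            "and is applied to the binary coding as-is"
        )

    n_features = matrix.shape[0]
    threshold = (
        bonferroni_threshold(config.alpha, n_features)
        if correction == "bonferroni"
        else config.alpha
    )
    results = []
    for feature_id, row in matrix.iterrows():
        values = row.to_numpy(dtype=float)
        x, y = (pheno, values) if swap else (values, pheno)
        cfg = dataclasses.replace(config, seed=_feature_seed(config.seed, str(feature_id)))
        res = bnnpt_test(PairedSample(x=x, y=y), cfg)
        results.append(
            BatchResult(
                feature_id=str(feature_id),
                p_value=res.p_value,
                se_observed=res.se_observed,
                significant=res.p_value < threshold,
                threshold_used=threshold,
            )
        )
    return results


def batch_to_frame(results: Sequence[BatchResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "p_value": [r.p_value for r in results],
            "se_observed": [r.se_observed for r in results],
            "significant": [r.significant for r in results],
            "threshold_used": [r.threshold_used for r in results],
        }
    )


def write_result_tsv(result: TestResult | ComparatorResult, path: str | Path) -> None:
    """Single-row TSV serialisation of a test result."""
    result.to_frame().to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, config: BNNPTConfig, extra: Mapping[str, object] | None = None) -> None:
    """Run manifest: seed, config and library versions, one key/value per row."""
    import scipy

    from . import __version__

    items: dict[str, object] = {
        "bnnpt_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "bags": config.bags,
        "mtry": config.mtry if config.mtry is not None else "auto",
        "permutations": config.permutations,
        "alpha": config.alpha,
        "seed": config.seed,
        "p_estimator": config.p_estimator,
        "replace": config.replace,
    }
    if extra:
        items.update(extra)
    pd.DataFrame({"key": list(items), "value": [items[k] for k in items]}).to_csv(
        path, sep="\t", index=False
    )
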