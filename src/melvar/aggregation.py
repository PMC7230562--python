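"""Region-based rare-variant aggregation tests: burden, SKAT and SKAT-O.

All three tests are score tests of the region's joint genotype effect on a
binary phenotype under an intercept-only null model: with case fraction
``mu = mean(y)``, residuals ``r = y - mu`` and Bernoulli variance
``v = mu (1 - mu)``, the per-variant scores are ``S_j = sum_i G_ij r_i``.

* **burden** collapses weighted allele counts per individual,
  ``b_i = sum_j w_j G_ij``, and refers ``Q_b = (b' r)^2`` normalized by its
  null variance to a 1-df chi-square (the two-sided score test);
* **SKAT** uses the variance-component statistic
  ``Q_s = sum_j (w_j S_j)^2``, whose null law is a positively weighted sum
  of 1-df chi-squares with weights given by the eigenvalues of the
  projected, weighted genotype cross-product;
* **SKAT-O** evaluates the family ``Q_rho = (1-rho) Q_s + rho Q_b`` over a
  grid of mixing parameters and combines the minimum p-value through the
  one-dimensional integral of the omnibus construction.

Variant weights default to the Beta(1, 25) density evaluated at the
minor-allele fraction, which strongly up-weights the rarest variants. A
label-permutation scheme provides an assumption-free reference p-value for
any of the statistics, and :func:`reconstruct_from_counts` rebuilds an
individual-level genotype matrix from a published carrier-count table so the
tests can run on summary data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from melvar.qform import (
    imhof_tail_grid,
    liu_quantile,
    liu_tail,
    qform_tail,
    truncate_eigenvalues,
)
from melvar.screen import CarrierTable

logger = logging.getLogger(__name__)

#: Default mixing-parameter grid for the omnibus test.
DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

class MonomorphicVariantError(ValueError):
    """A monomorphic column reached a test that requires polymorphic input."""


@dataclass
class GenotypeMatrix:
    """n_samples x m_variants allele-count matrix.

    Entries are 0/1/2 allele counts; ``nan`` marks an untyped sample-variant
    pair (these arise when carrier-count tables with differing denominators
    are reconstructed). ``maf`` is the folded minor-allele fraction estimated
    from the typed entries of each column.
    """

    G: np.ndarray
    sample_ids: Optional[list[str]] = None
    variant_keys: Optional[list] = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2:
            raise ValueError("G must be 2-dimensional")
        n, m = self.G.shape
        if n < 2 or m < 1:
            raise ValueError("G needs at least 2 samples and 1 variant")
        typed = self.G[~np.isnan(self.G)]
        if not np.all(np.isin(typed, (0.0, 1.0, 2.0))):
            raise ValueError("allele counts must be 0, 1 or 2 (nan = untyped)")

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]

    @property
    def n_variants(self) -> int:
        return self.G.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Folded minor-allele fraction per column, from typed entries."""
        with np.errstate(invalid="ignore"):
            af = np.nanmean(self.G, axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def imputed(self) -> np.ndarray:
        """Copy of G with untyped entries replaced by the column mean."""
        X = self.G.copy()
        col_mean = np.nanmean(X, axis=0)
        holes = np.isnan(X)
        if holes.any():
            X[holes] = np.take(col_mean, np.nonzero(holes)[1])
        return X


@dataclass(frozen=True)
class AggregationConfig:
    """Defaults of the aggregation-test family."""

    weight_beta_a: float = 1.0
    weight_beta_b: float = 25.0
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID
    pvalue_method: str = "davies"  # davies | liu | permutation
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if 0.0 not in self.rho_grid or 1.0 not in self.rho_grid:
            raise ValueError("rho_grid must contain both 0 and 1")
        if self.pvalue_method not in {"davies", "liu", "permutation"}:
            raise ValueError(f"unknown pvalue_method {self.pvalue_method!r}")
        if self.pvalue_method == "permutation" and self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


@dataclass
class AggregationResult:
    Q_burden: float
    Q_skat: float
    p_burden: float
    p_skat: float
    p_skato: float
    method_burden: str
    method_skat: str
    method_skato: str
    lambdas: np.ndarray = field(default_factory=lambda: np.array([]))
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID
    p_rho: Optional[np.ndarray] = None

    def as_dict(self) -> dict:
        return {
            "Q_burden": self.Q_burden,
            "Q_skat": self.Q_skat,
            "p_burden": self.p_burden,
            "p_skat": self.p_skat,
            "p_skato": self.p_skato,
            "method_burden": self.method_burden,
            "method_skat": self.method_skat,
            "method_skato": self.method_skato,
            "lambdas": list(map(float, self.lambdas)),
        }


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def beta_maf_weights(maf: Sequence[float], a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta-density weights evaluated at the minor-allele fraction.

    With the default (a=1, b=25) the weight is ``25 (1-maf)^24``: close to 25
    for the rarest variants and decreasing in maf.
    """
    maf = np.asarray(maf, dtype=float)
    if np.any(maf <= 0.0):
        raise MonomorphicVariantError(
            "maf = 0: monomorphic variants must be dropped before weighting"
        )
    if np.any(maf > 0.5):
        raise ValueError("maf must be a folded frequency in (0, 0.5]")
    return beta_dist.pdf(maf, a, b)


@dataclass(frozen=True)
class NullBinaryModel:
    """Intercept-only binomial null: common mean and Bernoulli variance."""

    mu: float
    n: int

    @property
    def variance(self) -> float:
        return self.mu * (1.0 - self.mu)

    def residuals(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) - self.mu


def fit_null_binary(y: Sequence[int]) -> NullBinaryModel:
    """Fit the intercept-only null model for a binary phenotype."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("y must be a 1-d vector with >= 2 samples")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")
    mu = float(y.mean())
    if mu in (0.0, 1.0):
        raise ValueError("both phenotype classes must be present")
    return NullBinaryModel(mu=mu, n=y.size)


def _as_matrix(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    if isinstance(G, GenotypeMatrix):
        return G.imputed()
    X = np.asarray(G, dtype=float)
    if np.isnan(X).any():
        raise ValueError("plain arrays may not contain nan; use GenotypeMatrix")
    return X


def _check_shapes(X: np.ndarray, y: np.ndarray, weights: np.ndarray) -> None:
    if X.shape[0] != y.size:
        raise ValueError(f"G has {X.shape[0]} rows but y has {y.size} entries")
    if X.shape[1] != weights.size:
        raise ValueError(f"G has {X.shape[1]} columns but {weights.size} weights given")
    col_var = X.var(axis=0)
    if np.any(col_var == 0.0):
        bad = np.nonzero(col_var == 0.0)[0]
        raise MonomorphicVariantError(
            f"monomorphic genotype column(s) {bad.tolist()}: drop before testing"
        )


# ---------------------------------------------------------------------------
# the three tests
# ---------------------------------------------------------------------------

@dataclass
class BurdenResult:
    Q: float
    p: float
    score: float
    variance: float
    method: str = "score_chi2"


def burden_test(
    G: GenotypeMatrix | np.ndarray,
    y: Sequence[int],
    weights: Sequence[float],
) -> BurdenResult:
    """Weighted burden (collapsing) score test.

    The per-sample burden ``b_i = sum_j w_j G_ij`` is score-tested against
    the phenotype: ``U = b' (y - mu)``, ``Var(U) = v * b' (I - J/n) b`` and
    ``U^2 / Var(U)`` is referred to the 1-df chi-square (two-sided).
    """
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    X = _as_matrix(G)
    _check_shapes(X, y, weights)
    null = fit_null_binary(y)

    b = X @ weights
    r = null.residuals(y)
    score = float(b @ r)
    centered = b - b.mean()
    variance = float(null.variance * (centered @ centered))
    Q = score ** 2
    if variance <= 0.0:
        logger.warning("burden_test: degenerate burden (all collapsed scores equal); p = 1")
        return BurdenResult(Q=Q, p=1.0, score=score, variance=variance, method="degenerate")
    p = float(chi2.sf(Q / variance, df=1))
    return BurdenResult(Q=Q, p=p, score=score, variance=variance)


@dataclass
class SkatResult:
    Q: float
    p: float
    lambdas: np.ndarray
    method: str


def _skat_kernel_eigenvalues(
    X: np.ndarray, weights: np.ndarray, variance: float
) -> np.ndarray:
    """Eigenvalues of the null kernel v * W G' (I - J/n) G W."""
    Xw = X * weights
    Xc = Xw - Xw.mean(axis=0)
    K = variance * (Xc.T @ Xc)
    lam = np.linalg.eigvalsh(K)
    return truncate_eigenvalues(lam)


def skat_test(
    G: GenotypeMatrix | np.ndarray,
    y: Sequence[int],
    weights: Sequence[float],
    pvalue_method: str = "davies",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> SkatResult:
    """Variance-component (kernel) score test.

    ``Q = sum_j (w_j S_j)^2`` with ``S_j = G_j' (y - mu)``; the p-value comes
    from the weighted chi-square mixture via Davies inversion, the Liu
    moment match, or label permutation.
    """
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    X = _as_matrix(G)
    _check_shapes(X, y, weights)
    null = fit_null_binary(y)

    r = null.residuals(y)
    S = X.T @ r
    Q = float(np.sum((weights * S) ** 2))
    lam = _skat_kernel_eigenvalues(X, weights, null.variance)

    if pvalue_method == "permutation":
        p = permutation_pvalue(
            lambda Gp, yp: float(
                np.sum((weights * (Gp.T @ (yp - yp.mean()))) ** 2)
            ),
            X, y, n_permutations=n_permutations, seed=seed,
        )
        return SkatResult(Q=Q, p=p, lambdas=lam, method="permutation")
    if pvalue_method == "liu":
        return SkatResult(Q=Q, p=liu_tail(Q, lam), lambdas=lam, method="liu")

    p, method = qform_tail(Q, lam)
    if method != "davies":
        logger.info("skat_test: Davies inversion unusable at this tail; Liu moments used")
    return SkatResult(Q=Q, p=p, lambdas=lam, method=method)


@dataclass
class SkatoResult:
    p: float
    rho_grid: tuple[float, ...]
    p_rho: np.ndarray
    q_rho: np.ndarray
    rho_min: float
    method: str


def _rho_half_matrix(rho: float, m: int) -> np.ndarray:
    """Symmetric square root of R_rho = (1-rho) I + rho 11'."""
    off = (np.sqrt(1.0 - rho + m * rho) - np.sqrt(1.0 - rho)) / m
    return np.sqrt(1.0 - rho) * np.eye(m) + off * np.ones((m, m))


def skato_test(
    G: GenotypeMatrix | np.ndarray,
    y: Sequence[int],
    weights: Sequence[float],
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    acc: float = 1e-6,
) -> SkatoResult:
    """Omnibus combination of SKAT and burden over a rho grid.

    For each rho, ``Q_rho = (1-rho) Q_skat + rho Q_burden`` is evaluated
    against its own chi-square mixture; the minimum p over the grid is then
    calibrated through the one-dimensional mixture-decomposition integral
    (the common-factor chi-square is integrated out analytically). With a
    single grid point the corresponding component p-value is returned
    unchanged.
    """
    rho_grid = tuple(sorted(set(float(r) for r in rho_grid)))
    if any(not 0.0 <= r <= 1.0 for r in rho_grid):
        raise ValueError("rho values must lie in [0, 1]")
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    X = _as_matrix(G)
    _check_shapes(X, y, weights)
    null = fit_null_binary(y)
    m = X.shape[1]

    r = null.residuals(y)
    Xw = X * weights
    S_w = Xw.T @ r
    Q_skat = float(np.sum(S_w ** 2))
    Q_burden = float(np.sum(S_w) ** 2)

    Xc = Xw - Xw.mean(axis=0)
    M = null.variance * (Xc.T @ Xc)  # m x m null cross-product

    # per-rho statistics and p-values
    q_rho = np.array([(1.0 - rho) * Q_skat + rho * Q_burden for rho in rho_grid])
    p_rho = np.empty(len(rho_grid))
    lam_rho: list[np.ndarray] = []
    for k, rho in enumerate(rho_grid):
        Rh = _rho_half_matrix(rho, m)
        lam = truncate_eigenvalues(np.linalg.eigvalsh(Rh @ M @ Rh))
        lam_rho.append(lam)
        p_rho[k], _ = qform_tail(q_rho[k], lam, acc=acc)

    rho_min = rho_grid[int(np.argmin(p_rho))]
    T = float(np.min(p_rho))
    if len(rho_grid) == 1:
        return SkatoResult(
            p=T, rho_grid=rho_grid, p_rho=p_rho, q_rho=q_rho,
            rho_min=rho_min, method="single_rho",
        )

    # --- omnibus calibration (mixture decomposition) -------------------
    # Z1 = P0^{1/2} G W; decompose onto the common burden direction.
    Z1 = np.sqrt(null.variance) * Xc
    z_mean = Z1.mean(axis=1)
    denom = float(z_mean @ z_mean)
    if denom <= 0.0:
        logger.warning("skato_test: degenerate burden direction; returning Bonferroni bound")
        return SkatoResult(
            p=min(1.0, T * len(rho_grid)), rho_grid=rho_grid, p_rho=p_rho,
            q_rho=q_rho, rho_min=rho_min, method="bonferroni",
        )
    cof = (z_mean @ Z1) / denom
    Z_item1 = np.outer(z_mean, cof)
    Z_item2 = Z1 - Z_item1
    W22 = Z_item2.T @ Z_item2
    lam_cond = truncate_eigenvalues(np.linalg.eigvalsh(W22))
    mu_q = float(lam_cond.sum())
    var_remain = float(4.0 * np.sum((Z_item1.T @ Z_item1) * W22))
    var_q = float(2.0 * np.sum(lam_cond ** 2) + var_remain)
    tau = np.array(
        [m * m * rho + (1.0 - rho) * float(cof @ cof) for rho in rho_grid]
    ) * denom

    # quantile of each component distribution at the minimum p
    qmin = np.array([liu_quantile(T, lam_rho[k]) for k in range(len(rho_grid))])

    # rho = 1 contributes a pure chi-square; clip for the (1-rho) division
    rho_clip = np.minimum(np.asarray(rho_grid), 0.999)
    sd_ratio = np.sqrt((var_q - var_remain) / var_q) if var_q > 0 else 1.0

    # Conditional on the common burden-direction chi-square x, the remaining
    # statistic must stay below q_cond(x) = min_rho (qmin - tau x)/(1 - rho)
    # for no component to beat the observed minimum p. q_cond is piecewise
    # linear and decreasing in x, so the conditional CDF of the residual
    # mixture is needed along one monotone stretch of arguments: evaluate it
    # with Davies inversion on a grid and interpolate monotonically, then
    # integrate over x = t^2 (which removes the chi-square density
    # singularity at 0) with a fine Simpson rule.
    x_hi = 40.0  # chi-square_1 mass beyond 40 is ~2.5e-10

    def q_cond(x: np.ndarray) -> np.ndarray:
        vals = (qmin[:, None] - tau[:, None] * x[None, :]) / (1.0 - rho_clip[:, None])
        return vals.min(axis=0)

    def q_adjusted(x: np.ndarray) -> np.ndarray:
        return (q_cond(x) - mu_q) * sd_ratio + mu_q

    q_top = float(q_adjusted(np.array([0.0]))[0])
    if q_top <= 0.0:
        p = 1.0
    else:
        from scipy.interpolate import PchipInterpolator

        grid_q = np.linspace(0.0, q_top, 64)
        grid_F = 1.0 - imhof_tail_grid(grid_q, lam_cond, acc=max(acc, 1e-5))
        grid_F[0] = 0.0
        grid_F = np.maximum.accumulate(np.clip(grid_F, 0.0, 1.0))
        cdf = PchipInterpolator(grid_q, grid_F, extrapolate=False)

        t = np.linspace(0.0, np.sqrt(x_hi), 2001)
        qa = q_adjusted(t * t)
        surv = np.where(qa <= 0.0, 0.0, np.nan_to_num(cdf(np.clip(qa, 0.0, q_top))))
        integrand = surv * np.sqrt(2.0 / np.pi) * np.exp(-0.5 * t * t)
        from scipy.integrate import simpson

        non_exceed = float(simpson(integrand, x=t))
        p = 1.0 - non_exceed
    # numerical guards: the omnibus p cannot beat the Bonferroni bound and
    # cannot be smaller than the best component beyond integration error
    p = min(p, T * len(rho_grid), 1.0)
    p = max(p, T, 0.0)
    return SkatoResult(
        p=float(p), rho_grid=rho_grid, p_rho=p_rho, q_rho=q_rho,
        rho_min=rho_min, method="integration",
    )


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def permutation_pvalue(
    statistic_fn: Callable[[np.ndarray, np.ndarray], float],
    G: GenotypeMatrix | np.ndarray,
    y: Sequence[int],
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Label-permutation p-value ``(1 + #{perm >= obs}) / (1 + B)``.

    ``statistic_fn(G, y)`` must return a scalar whose large values are
    evidence against the null. Fully reproducible from ``seed``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    X = _as_matrix(G)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    observed = statistic_fn(X, y)
    exceed = 0
    for _ in range(n_permutations):
        exceed += statistic_fn(X, rng.permutation(y)) >= observed
    return (1 + exceed) / (1 + n_permutations)


def permutation_reference(
    G: GenotypeMatrix | np.ndarray,
    y: Sequence[int],
    weights: Sequence[float],
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    n_permutations: int = 100_000,
    seed: int = 0,
    chunk: int = 20_000,
) -> dict[str, float]:
    """Vectorized permutation p-values for burden, SKAT and a min-p omnibus.

    The omnibus reference converts each permuted ``Q_rho`` into its
    within-permutation upper-tail rank, takes the minimum over the grid and
    compares against the observed minimum — an assumption-free analogue of
    the SKAT-O combination.
    """
    X = _as_matrix(G)
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    _check_shapes(X, y, weights)
    rho = np.asarray(sorted(set(float(r) for r in rho_grid)))
    rng = np.random.default_rng(seed)

    Xw = X * weights
    mu = y.mean()

    def stats_for(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # labels: B x n; returns (Q_skat[B], Q_burden[B])
        S = (labels - mu) @ Xw  # B x m
        return np.sum(S ** 2, axis=1), np.sum(S, axis=1) ** 2

    qs_obs, qb_obs = stats_for(y[None, :])
    qs_parts, qb_parts = [], []
    done = 0
    while done < n_permutations:
        size = min(chunk, n_permutations - done)
        block = rng.permuted(np.broadcast_to(y, (size, y.size)).copy(), axis=1)
        qs, qb = stats_for(block)
        qs_parts.append(qs)
        qb_parts.append(qb)
        done += size
    Qs = np.concatenate(qs_parts)
    Qb = np.concatenate(qb_parts)
    B = n_permutations

    p_burden = float((1 + np.sum(Qb >= qb_obs[0])) / (1 + B))
    p_skat = float((1 + np.sum(Qs >= qs_obs[0])) / (1 + B))

    # min-p omnibus over the rho grid via within-permutation ranks
    Q_all = (1.0 - rho)[:, None] * Qs[None, :] + rho[:, None] * Qb[None, :]
    q_obs = (1.0 - rho) * qs_obs[0] + rho * qb_obs[0]
    T_perm = np.ones(B)
    for k in range(rho.size):
        order = np.argsort(Q_all[k])[::-1]
        ranks = np.empty(B)
        ranks[order] = np.arange(1, B + 1)  # 1 = largest statistic
        # upper-tail probability of each permuted statistic within the null
        p_k = ranks / B
        T_perm = np.minimum(T_perm, p_k)
    T_obs = np.min(
        [(1 + np.sum(Q_all[k] >= q_obs[k])) / (1 + B) for k in range(rho.size)]
    )
    p_skato = float((1 + np.sum(T_perm <= T_obs)) / (1 + B))
    return {"p_burden": p_burden, "p_skat": p_skat, "p_skato": p_skato}


# ---------------------------------------------------------------------------
# carrier-table reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReconstructionPolicy:
    """Assumptions used to rebuild genotypes from a carrier-count table.

    * ``ploidy`` — carriers are heterozygous (the dominant-model default);
    * ``overlap`` — carriers of different variants are disjoint individuals
      within each group, which is exact when the counts sum to the group
      size;
    * ``denominators`` — ``pad_to_max`` places every group member in the
      matrix and marks sample-variant pairs beyond a variant's own
      denominator as untyped (mean-imputed inside the tests);
      ``scale_to_min`` rescales counts to the smallest denominator.
    """

    ploidy: str = "heterozygous"
    overlap: str = "disjoint"
    denominators: str = "pad_to_max"

    def __post_init__(self) -> None:
        if self.ploidy not in {"heterozygous", "homozygous"}:
            raise ValueError("ploidy must be heterozygous or homozygous")
        if self.overlap != "disjoint":
            raise ValueError("only the disjoint carrier policy is implemented")
        if self.denominators not in {"pad_to_max", "scale_to_min"}:
            raise ValueError("denominators must be pad_to_max or scale_to_min")


class ReconstructionError(ValueError):
    """Carrier counts cannot be realized under the stated policy."""


def reconstruct_from_counts(
    table: CarrierTable,
    policy: Optional[ReconstructionPolicy] = None,
    case_group: str = "MPM",
    control_group: str = "CONTROL",
) -> tuple[GenotypeMatrix, np.ndarray, list[str]]:
    """Rebuild (GenotypeMatrix, phenotype vector, log) from carrier counts.

    Cases (``case_group``) are labelled 1 and controls 0; column sums of the
    rebuilt matrix reproduce the printed carrier counts per group. Every
    assumption applied is appended to the returned log.
    """
    policy = policy or ReconstructionPolicy()
    log: list[str] = [f"policy: {policy}"]
    keys = sorted(table.rows)
    if not keys:
        raise ReconstructionError("empty carrier table")
    dose = 1.0 if policy.ploidy == "heterozygous" else 2.0

    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for group, label in ((case_group, 1.0), (control_group, 0.0)):
        cells = {}
        for key in keys:
            cell = table.cell(key, group)
            if cell is None:
                raise ReconstructionError(f"variant {key} has no {group} counts")
            cells[key] = cell
        denominators = {k: c.denominator for k, c in cells.items()}
        counts = {k: c.carriers for k, c in cells.items()}
        for k in keys:
            if counts[k] > denominators[k]:
                raise ReconstructionError(
                    f"group {group}: carriers exceed denominator for {k}"
                )
        if policy.denominators == "scale_to_min":
            n_group = min(denominators.values())
            scaled = {}
            for k in keys:
                scaled[k] = round(counts[k] * n_group / denominators[k])
                if scaled[k] != counts[k]:
                    log.append(
                        f"group {group}: {k} carriers scaled "
                        f"{counts[k]}/{denominators[k]} -> {scaled[k]}/{n_group}"
                    )
            counts = scaled
            denominators = {k: n_group for k in keys}
        else:
            n_group = max(denominators.values())

        total = sum(counts.values())
        if total > n_group:
            raise ReconstructionError(
                f"group {group}: disjoint carriers infeasible "
                f"({total} carriers > {n_group} samples)"
            )
        block = np.zeros((n_group, len(keys)))
        used = np.zeros(n_group, dtype=bool)
        for j, k in enumerate(keys):
            d = denominators[k]
            if d < n_group:
                block[d:, j] = np.nan  # untyped beyond this variant's denominator
                log.append(
                    f"group {group}: {k} typed in {d}/{n_group} samples; "
                    "remainder marked untyped"
                )
            free = np.nonzero(~used[:d])[0]
            if free.size < counts[k]:
                raise ReconstructionError(
                    f"group {group}: cannot place {counts[k]} disjoint carriers "
                    f"of {k} among {d} typed samples"
                )
            chosen = free[: counts[k]]
            block[chosen, j] = dose
            used[chosen] = True
        blocks.append(block)
        labels.append(np.full(n_group, label))
        log.append(
            f"group {group}: {n_group} samples, {total} disjoint "
            f"{policy.ploidy} carriers across {len(keys)} variants"
        )

    G = np.vstack(blocks)
    y = np.concatenate(labels)
    for line in log:
        logger.info("reconstruct_from_counts: %s", line)
    return GenotypeMatrix(G, variant_keys=keys), y, log


# ---------------------------------------------------------------------------
# one-call interface
# ---------------------------------------------------------------------------

def aggregate(
    G: GenotypeMatrix | np.ndarray,
    y: Sequence[int],
    config: Optional[AggregationConfig] = None,
) -> AggregationResult:
    """Run burden, SKAT and SKAT-O on one variant set with shared weights."""
    config = config or AggregationConfig()
    Gm = G if isinstance(G, GenotypeMatrix) else GenotypeMatrix(np.asarray(G, float))
    maf = Gm.maf
    weights = beta_maf_weights(maf, config.weight_beta_a, config.weight_beta_b)

    if config.pvalue_method == "permutation":
        ref = permutation_reference(
            Gm, y, weights, rho_grid=config.rho_grid,
            n_permutations=config.n_permutations, seed=config.seed,
        )
        bur = burden_test(Gm, y, weights)
        ska = skat_test(Gm, y, weights)
        return AggregationResult(
            Q_burden=bur.Q, Q_skat=ska.Q,
            p_burden=ref["p_burden"], p_skat=ref["p_skat"], p_skato=ref["p_skato"],
            method_burden="permutation", method_skat="permutation",
            method_skato="permutation", lambdas=ska.lambdas,
            rho_grid=tuple(config.rho_grid),
        )

    bur = burden_test(Gm, y, weights)
    ska = skat_test(Gm, y, weights, pvalue_method=config.pvalue_method)
    sko = skato_test(Gm, y, weights, rho_grid=config.rho_grid)
    return AggregationResult(
        Q_burden=bur.Q, Q_skat=ska.Q,
        p_burden=bur.p, p_skat=ska.p, p_skato=sko.p,
        method_burden=bur.method, method_skat=ska.method, method_skato=sko.method,
        lambdas=ska.lambdas, rho_grid=sko.rho_grid, p_rho=sko.p_rho,
    )
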