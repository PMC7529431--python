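"""Case-control rare-variant association for a single candidate gene.

The cohort analysis asks whether individuals with the trait are enriched
for carriers of rare, predicted-deleterious variants in one gene.  It
comprises:

* a carrier 2x2 table and a two-tailed Fisher exact test (summed-tail
  rule, computed in log space);
* case subsampling without replacement to match the control group size
  (the carrier count per draw is a hypergeometric variable);
* a negative control repeating the enrichment test on rare synonymous
  variants, which should show no signal;
* SKAT and SKAT-O with the linear weighted kernel (Beta(1, 25) MAF
  weights) and age/sex covariates, the variance-component score tests
  standard for rare-variant sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist
from scipy.stats import chi2, hypergeom

from ._quadform import (
    chi2_mixture_sf,
    chi2_mixture_sf_many,
    filter_eigenvalues,
    liu_quantile,
)
from .datatypes import (
    MAF_DATABASES,
    MISSING,
    NONSYNONYMOUS_CLASSES,
    AnnotationRecord,
    GenotypeMatrix,
    SampleRecord,
    Variant,
)
from .exceptions import (
    ConfigurationError,
    ConvergenceError,
    DegenerateStatisticError,
    SeparationError,
)
from .family_filter import consensus_verdict, maf_filter

logger = logging.getLogger(__name__)

__all__ = [
    "CarrierTable",
    "BurdenConfig",
    "BurdenResult",
    "BootstrapSummary",
    "CohortDataset",
    "carrier_status",
    "fisher_two_tailed",
    "bootstrap_carriers",
    "synonymous_control",
    "fit_null_model",
    "NullModel",
    "beta_maf_weights",
    "skat_statistic",
    "skat_pvalue",
    "skato",
    "run_burden",
]

VariantKey = tuple[str, int, str, str]

#: The canonical 8-point rho grid for SKAT-O.
DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


@dataclass(frozen=True)
class CarrierTable:
    """Carrier / non-carrier counts in cases and controls."""

    case_carriers: int
    case_noncarriers: int
    control_carriers: int
    control_noncarriers: int

    def __post_init__(self) -> None:
        for v in (
            self.case_carriers,
            self.case_noncarriers,
            self.control_carriers,
            self.control_noncarriers,
        ):
            if v < 0:
                raise ValueError("negative cell in carrier table")

    @property
    def n_cases(self) -> int:
        return self.case_carriers + self.case_noncarriers

    @property
    def n_controls(self) -> int:
        return self.control_carriers + self.control_noncarriers

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.case_carriers,
            self.case_noncarriers,
            self.control_carriers,
            self.control_noncarriers,
        )


@dataclass
class BurdenConfig:
    """Configuration of the cohort association analysis."""

    deleterious_only: bool = True
    maf_threshold: float = 0.02
    weights_beta: tuple[float, float] = (1.0, 25.0)
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID
    covariate_names: tuple[str, ...] = ("age", "sex")
    n_resamples: int = 1000
    resample_size: int = 630
    with_replacement: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ConfigurationError("n_resamples must be >= 1")
        grid = tuple(self.rho_grid)
        if any(r < 0 or r > 1 for r in grid):
            raise ConfigurationError("rho values must lie in [0,1]")
        if len(grid) > 1 and (0.0 not in grid or 1.0 not in grid):
            raise ConfigurationError("rho grid must contain 0 and 1")
        self.rho_grid = grid


@dataclass(frozen=True)
class BootstrapSummary:
    minimum: int
    maximum: int
    mean: float
    histogram: dict[int, int]
    n_resamples: int

    def to_dict(self) -> dict:
        return {
            "min": self.minimum,
            "max": self.maximum,
            "mean": self.mean,
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
            "n_resamples": self.n_resamples,
        }


@dataclass
class BurdenResult:
    carrier_table: CarrierTable
    fisher_p: float
    skat_p: float
    skato_p: float
    skato_rho_hat: float
    bootstrap_summary: BootstrapSummary
    synonymous_control_p: float | None
    deleterious_variants: list[VariantKey] = field(default_factory=list)
    excluded_samples: list[str] = field(default_factory=list)
    p_value_methods: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "carrier_table": {
                "case_carriers": self.carrier_table.case_carriers,
                "case_noncarriers": self.carrier_table.case_noncarriers,
                "control_carriers": self.carrier_table.control_carriers,
                "control_noncarriers": self.carrier_table.control_noncarriers,
            },
            "fisher_p": self.fisher_p,
            "skat_p": self.skat_p,
            "skato_p": self.skato_p,
            "skato_rho_hat": self.skato_rho_hat,
            "bootstrap_summary": self.bootstrap_summary.to_dict(),
            "synonymous_control_p": self.synonymous_control_p,
            "deleterious_variants": [
                f"{c}:{p}:{r}:{a}" for c, p, r, a in self.deleterious_variants
            ],
            "excluded_samples": self.excluded_samples,
            "p_value_methods": self.p_value_methods,
        }


@dataclass
class CohortDataset:
    """Everything the cohort analysis needs, keyed consistently."""

    variants: list[Variant]
    annotations: dict[VariantKey, AnnotationRecord]
    genotypes: GenotypeMatrix
    samples: list[SampleRecord]
    covariates: pd.DataFrame  # indexed by sample_id, columns age/sex


# ---------------------------------------------------------------------------
# Carrier table and Fisher exact test
# ---------------------------------------------------------------------------

def carrier_status(
    genotypes: GenotypeMatrix, variant_set: Sequence[VariantKey]
) -> tuple[np.ndarray, list[str]]:
    """Per-sample carrier flag over a variant set (dominant model).

    A sample is a carrier iff it has dosage >= 1 at at least one set
    variant.  Samples missing at *all* set variants cannot be classified;
    they are returned separately for exclusion from downstream counts.
    """
    keys = [tuple(k) for k in variant_set]
    if not keys:
        raise ConfigurationError("empty variant set")
    sub = genotypes.subset_variants(keys)
    carrier = (sub.dosage >= 1).any(axis=1)
    all_missing = (sub.dosage == MISSING).all(axis=1)
    excluded = [s for s, m in zip(sub.samples, all_missing) if m]
    return carrier, excluded


def fisher_two_tailed(table: CarrierTable) -> float:
    """Two-sided Fisher exact p: summed-tail rule, log-space.

    All tables sharing the observed margins whose hypergeometric
    probability does not exceed the observed table's (within 1e-7
    relative, to absorb floating-point ties) contribute to p.  If any
    margin is zero the table carries no information and p = 1.
    """
    a, b, c, d = table.as_tuple()
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        logger.warning("degenerate carrier table %s: p set to 1", table.as_tuple())
        return 1.0
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    logpmf = hypergeom.logpmf(support, n, c1, r1)
    log_obs = hypergeom.logpmf(a, n, c1, r1)
    include = logpmf <= log_obs + np.log1p(1e-7)
    return float(min(np.exp(logsumexp(logpmf[include])), 1.0))


# ---------------------------------------------------------------------------
# Case subsampling
# ---------------------------------------------------------------------------

def bootstrap_carriers(
    n_cases: int,
    case_carriers: int,
    resample_size: int,
    n_resamples: int,
    seed: int,
    with_replacement: bool = False,
) -> BootstrapSummary:
    """Carrier counts across repeated case subsamples.

    Each replicate draws ``resample_size`` cases from the pool of
    ``n_cases`` (of whom ``case_carriers`` are carriers).  Without
    replacement the count per replicate is a hypergeometric draw; with
    replacement it is binomial.  Deterministic given ``seed``.
    """
    if resample_size > n_cases:
        raise ConfigurationError("resample_size exceeds the case pool")
    if case_carriers > n_cases:
        raise ConfigurationError("case_carriers exceeds the case pool")
    rng = np.random.default_rng(seed)
    if with_replacement:
        counts = rng.binomial(resample_size, case_carriers / n_cases, size=n_resamples)
    else:
        counts = rng.hypergeometric(
            case_carriers, n_cases - case_carriers, resample_size, size=n_resamples
        )
    values, freqs = np.unique(counts, return_counts=True)
    return BootstrapSummary(
        minimum=int(counts.min()),
        maximum=int(counts.max()),
        mean=float(counts.mean()),
        histogram={int(v): int(f) for v, f in zip(values, freqs)},
        n_resamples=n_resamples,
    )


# ---------------------------------------------------------------------------
# Synonymous negative control
# ---------------------------------------------------------------------------

def synonymous_control(
    variants: Sequence[Variant],
    annotations: Mapping[VariantKey, AnnotationRecord],
    genotypes: GenotypeMatrix,
    phenotypes: np.ndarray,
    config: BurdenConfig,
) -> float | None:
    """Enrichment test restricted to rare synonymous variants.

    Applies the same MAF filtering as the main analysis but keeps only
    synonymous sites, then runs the carrier Fisher test.  Returns the
    p-value, or None (with a warning) when no synonymous variant passes.
    """
    keys = [v.key for v in variants if v.consequence == "synonymous"]
    for db in MAF_DATABASES:
        keys = maf_filter(keys, annotations, db, config.maf_threshold)
    if not keys:
        logger.warning("synonymous control undefined: no rare synonymous variant")
        return None
    carrier, excluded = carrier_status(genotypes, keys)
    usable = np.ones(len(carrier), dtype=bool)
    if excluded:
        idx = {s: i for i, s in enumerate(genotypes.samples)}
        usable[[idx[s] for s in excluded]] = False
    y = np.asarray(phenotypes, dtype=bool)
    table = CarrierTable(
        case_carriers=int((carrier & y & usable).sum()),
        case_noncarriers=int((~carrier & y & usable).sum()),
        control_carriers=int((carrier & ~y & usable).sum()),
        control_noncarriers=int((~carrier & ~y & usable).sum()),
    )
    return fisher_two_tailed(table)


# ---------------------------------------------------------------------------
# Null model and SKAT / SKAT-O
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    """Fitted logistic null model y ~ covariates."""

    mu: np.ndarray  # fitted probabilities
    residuals: np.ndarray  # y - mu
    X: np.ndarray  # design matrix incl. intercept
    y: np.ndarray
    params: np.ndarray
    converged: bool


def fit_null_model(
    phenotype: np.ndarray, covariates: np.ndarray | None = None
) -> NullModel:
    """Logistic regression of the binary trait on covariates (IRLS).

    Fitted to relative tolerance 1e-8 with at most 100 iterations.
    Raises on a constant phenotype and on complete separation (fitted
    probabilities indistinguishable from the observed 0/1 outcomes).
    """
    y = np.asarray(phenotype, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    if y.min() == y.max():
        raise ConvergenceError("constant phenotype: null model undefined")
    n = y.shape[0]
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[-1] == 0):
        X = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        fit = model.fit(maxiter=100, tol=1e-8)
    except Exception as exc:
        raise ConvergenceError(f"null logistic model failed: {exc}") from exc
    mu = np.asarray(fit.fittedvalues, dtype=float)
    eps = 1e-8
    if np.all((mu > 1 - eps) == (y == 1)) and np.all((mu < eps) == (y == 0)) and (
        np.any(mu > 1 - eps) or np.any(mu < eps)
    ):
        worst = int(np.argmax(np.abs(fit.params[1:]))) if len(fit.params) > 1 else 0
        raise SeparationError(
            f"complete separation detected (covariate column {worst})"
        )
    return NullModel(
        mu=mu,
        residuals=y - mu,
        X=X,
        y=y,
        params=np.asarray(fit.params, dtype=float),
        converged=bool(fit.converged),
    )


def beta_maf_weights(mafs: np.ndarray, a1: float = 1.0, a2: float = 25.0) -> np.ndarray:
    """Linear-weighted-kernel weights: Beta(a1, a2) density at the MAF."""
    return beta_dist.pdf(np.asarray(mafs, dtype=float), a1, a2)


def _weighted_genotypes(
    G: np.ndarray, weights: np.ndarray | None, weights_beta: tuple[float, float]
) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    G = np.where(G == MISSING, 0.0, G)  # missing treated as reference; logged upstream
    if weights is None:
        maf = G.mean(axis=0) / 2.0
        weights = beta_maf_weights(maf, *weights_beta)
    return G * np.asarray(weights, dtype=float)


def _kernel_matrix(Z: np.ndarray, null: NullModel) -> np.ndarray:
    """Sigma = Z' P0 Z, the null covariance of the variant score vector."""
    v = null.mu * (1 - null.mu)
    VZ = Z * v[:, None]
    VX = null.X * v[:, None]
    XtVX = null.X.T @ VX
    B = np.linalg.solve(XtVX, VX.T @ Z)
    return Z.T @ VZ - (VX.T @ Z).T @ B


def _adjusted_genotypes(Z: np.ndarray, null: NullModel) -> np.ndarray:
    """Z1 = V^{1/2}(Z - X (X'VX)^{-1} X'VZ); satisfies Z1'Z1 = Z'P0Z."""
    v = null.mu * (1 - null.mu)
    sv = np.sqrt(v)
    VX = null.X * v[:, None]
    XtVX = null.X.T @ VX
    B = np.linalg.solve(XtVX, VX.T @ Z)
    return sv[:, None] * (Z - null.X @ B)


def skat_statistic(
    genotypes: GenotypeMatrix | np.ndarray,
    weights: np.ndarray | None,
    null: NullModel,
    weights_beta: tuple[float, float] = (1.0, 25.0),
) -> tuple[float, np.ndarray]:
    """SKAT statistic Q = sum_j w_j^2 score_j^2 and its kernel eigenvalues.

    ``score_j`` is the covariate-adjusted score for variant j, i.e. the
    j-th entry of Z'(y - mu) with Z the weighted dosage matrix.  The
    eigenvalues are those of Z'P0Z, the null covariance of the scores;
    Q is distributed as their chi-square mixture under the null.
    """
    G = genotypes.dosage if isinstance(genotypes, GenotypeMatrix) else genotypes
    Z = _weighted_genotypes(G, weights, weights_beta)
    if not np.any(Z.std(axis=0) > 0):
        raise DegenerateStatisticError("all variants monomorphic")
    score = Z.T @ null.residuals
    q = float(score @ score)
    lam = np.linalg.eigvalsh(_kernel_matrix(Z, null))
    return q, filter_eigenvalues(lam)


def skat_pvalue(
    genotypes: GenotypeMatrix | np.ndarray,
    null: NullModel,
    weights: np.ndarray | None = None,
    weights_beta: tuple[float, float] = (1.0, 25.0),
) -> tuple[float, str]:
    q, lam = skat_statistic(genotypes, weights, null, weights_beta)
    res = chi2_mixture_sf(q, lam)
    return res.p, res.method


def _rho_kernel_eigs(sigma: np.ndarray, rho: float) -> np.ndarray:
    """Eigenvalues of R_rho^{1/2} Sigma R_rho^{1/2}, R_rho=(1-rho)I+rho*11'."""
    m = sigma.shape[0]
    a = np.sqrt(1 - rho)
    b = (np.sqrt((1 - rho) + m * rho) - a) / m
    r_half = a * np.eye(m) + b * np.ones((m, m))
    return np.linalg.eigvalsh(r_half @ sigma @ r_half)


def skato(
    genotypes: GenotypeMatrix | np.ndarray,
    phenotype: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    config: BurdenConfig | None = None,
    null: NullModel | None = None,
    weights: np.ndarray | None = None,
) -> dict:
    """SKAT-O: optimal combination of SKAT and the weighted burden test.

    For each rho on the grid, Q_rho = (1-rho) Q_SKAT + rho Q_burden is
    referred to its chi-square-mixture null; the grid is then combined
    through the minimum-p statistic, whose null distribution is evaluated
    by one-dimensional integration over the shared burden component
    (the construction of the optimal unified test).  Returns the omnibus
    p-value, the minimizing rho, and the per-rho p-values.
    """
    config = config or BurdenConfig()
    if null is None:
        if phenotype is None:
            raise ValueError("either a fitted null model or a phenotype is required")
        null = fit_null_model(phenotype, covariates)
    G = genotypes.dosage if isinstance(genotypes, GenotypeMatrix) else genotypes
    Z = _weighted_genotypes(G, weights, config.weights_beta)
    if not np.any(Z.std(axis=0) > 0):
        raise DegenerateStatisticError("all variants monomorphic")
    m = Z.shape[1]
    score = Z.T @ null.residuals

    # single variant: every rho gives the same 1-df score test
    if m == 1:
        sigma = _kernel_matrix(Z, null)
        q = float(score[0] ** 2)
        p = float(chi2.sf(q / sigma[0, 0], 1))
        return {
            "p": p,
            "rho_hat": float(config.rho_grid[0]),
            "rho_grid": list(config.rho_grid),
            "p_per_rho": [p] * len(config.rho_grid),
            "method": "exact",
        }

    # per-rho p-values use the exact rho (the rho=1 kernel is rank one and
    # well defined); the omnibus decomposition divides by 1-rho, so there
    # rho is capped at 0.999 as is conventional
    grid_in = list(config.rho_grid)
    grid = grid_in

    sigma = _kernel_matrix(Z, null)
    q_skat = float(score @ score)
    q_burden = float(score.sum() ** 2)

    p_per_rho: list[float] = []
    lambdas_per_rho: list[np.ndarray] = []
    q_per_rho: list[float] = []
    methods: set[str] = set()
    for rho in grid:
        q_rho = (1 - rho) * q_skat + rho * q_burden
        lam = filter_eigenvalues(_rho_kernel_eigs(sigma, rho))
        res = chi2_mixture_sf(q_rho, lam)
        p_per_rho.append(res.p)
        lambdas_per_rho.append(lam)
        q_per_rho.append(q_rho)
        methods.add(res.method)

    i_min = int(np.argmin(p_per_rho))
    p_min = p_per_rho[i_min]
    rho_hat = float(grid_in[i_min])
    if len(grid) == 1:
        return {
            "p": p_min,
            "rho_hat": rho_hat,
            "rho_grid": grid_in,
            "p_per_rho": p_per_rho,
            "method": ",".join(sorted(methods)),
        }

    # decomposition of Q_rho into a shared burden axis and its complement
    Z1 = _adjusted_genotypes(Z, null)
    z_bar = Z1.mean(axis=1)
    z_bar_sq = float(z_bar @ z_bar)
    if z_bar_sq <= 0:
        raise DegenerateStatisticError("burden direction degenerate")
    cof = (z_bar @ Z1) / z_bar_sq
    Z_item2 = Z1 - np.outer(z_bar, cof)
    kappa_kernel = Z_item2.T @ Z_item2
    lam_kappa = filter_eigenvalues(np.linalg.eigvalsh(kappa_kernel))
    item1_gram = np.outer(cof, cof) * z_bar_sq  # (Z_item1)'(Z_item1)
    var_remain = 4.0 * float(np.sum(item1_gram * kappa_kernel))
    mu_q = lam_kappa.sum()
    var_q = 2.0 * (lam_kappa**2).sum() + var_remain
    grid_omni = np.array([min(r, 0.999) for r in grid])
    tau = (m**2 * grid_omni + (1 - grid_omni) * float(cof @ cof)) * z_bar_sq

    # per-rho quantiles of Q_rho at upper tail p_min (Liu approximation)
    qmin = np.array(
        [liu_quantile(p_min, lam) for lam in lambdas_per_rho]
    )

    one_minus_rho = 1.0 - grid_omni
    sd_adjust = np.sqrt(max(var_q - var_remain, 0.0)) / np.sqrt(var_q)

    # integrate P(all Q_rho below their p_min-quantiles | burden component)
    # over the shared 1-df burden chi-square; substituting x = s^2 removes
    # the density singularity at zero so Gauss-Legendre converges fast
    nodes, weights = np.polynomial.legendre.leggauss(196)
    s_hi = np.sqrt(40.0)
    s = 0.5 * s_hi * (nodes + 1.0)
    w_gl = 0.5 * s_hi * weights * np.sqrt(2.0 / np.pi) * np.exp(-0.5 * s**2)
    x = s**2
    t_min = ((qmin[:, None] - tau[:, None] * x[None, :]) / one_minus_rho[:, None]).min(axis=0)
    t_std = (t_min - mu_q) * sd_adjust + mu_q
    survive = np.zeros_like(t_std)
    ok = t_std > 0
    survive[ok] = 1.0 - chi2_mixture_sf_many(t_std[ok], lam_kappa)
    survive[t_min > lam_kappa.sum() * 1e4] = 1.0
    p_omnibus = 1.0 - float(np.sum(survive * w_gl))
    # guard against integration undershoot: never below the Bonferroni floor
    p_omnibus = max(min(p_omnibus, 1.0), 0.0)
    if p_min * len(grid) < p_omnibus:
        p_omnibus = p_min * len(grid)
    p_omnibus = min(p_omnibus, 1.0)

    return {
        "p": float(p_omnibus),
        "rho_hat": rho_hat,
        "rho_grid": grid_in,
        "p_per_rho": p_per_rho,
        "method": ",".join(sorted(methods)),
    }


# ---------------------------------------------------------------------------
# Full cohort analysis
# ---------------------------------------------------------------------------

def _covariate_matrix(
    samples: Sequence[SampleRecord],
    covariates: pd.DataFrame,
    names: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (standardized age, 0/1 sex) design; flag incomplete rows."""
    cols = []
    complete = np.ones(len(samples), dtype=bool)
    for name in names:
        vals = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            if s.sample_id in covariates.index:
                row = covariates.loc[s.sample_id]
                if name == "sex":
                    vals[i] = {"male": 0.0, "female": 1.0}.get(row["sex"], np.nan)
                else:
                    vals[i] = row[name]
        complete &= np.isfinite(vals)
        cols.append(vals)
    if not cols:
        return np.empty((len(samples), 0)), complete
    M = np.column_stack(cols)
    # standardize continuous columns (helps IRLS); 0/1 columns left as-is
    for j, name in enumerate(names):
        col = M[:, j]
        finite = np.isfinite(col)
        if name != "sex" and col[finite].std() > 0:
            M[:, j] = (col - col[finite].mean()) / col[finite].std()
    return M, complete


def select_deleterious(
    variants: Sequence[Variant],
    annotations: Mapping[VariantKey, AnnotationRecord],
    config: BurdenConfig,
) -> list[VariantKey]:
    """Rare nonsynonymous variants with a deleterious consensus verdict.

    Applies the five-database MAF filter at ``config.maf_threshold``,
    keeps protein-altering classes, and (unless ``deleterious_only`` is
    off) requires the predictor majority vote to call the variant
    deleterious.  A tied or all-missing vote never qualifies.
    """
    keys = [v.key for v in variants if v.consequence in NONSYNONYMOUS_CLASSES]
    for db in MAF_DATABASES:
        keys = maf_filter(keys, annotations, db, config.maf_threshold)
    if not config.deleterious_only:
        return keys
    out = []
    for key in keys:
        rec = annotations.get(key)
        if rec is not None and consensus_verdict(rec.predictor_calls) == "deleterious":
            out.append(key)
    return out


def run_burden(dataset: CohortDataset, config: BurdenConfig | None = None) -> BurdenResult:
    """Run the full single-gene case-control analysis.

    Selects the deleterious variant set, builds the carrier table,
    computes the Fisher, SKAT and SKAT-O p-values (age and sex as
    covariates), subsamples cases to the control group size, and runs
    the synonymous negative control.  Reproducible given ``config.seed``.
    """
    config = config or BurdenConfig()
    seeds = derive_seeds(config.seed, ("bootstrap",))

    deleterious = select_deleterious(dataset.variants, dataset.annotations, config)
    if not deleterious:
        raise ConfigurationError("no deleterious variant passes the filters")

    samples = dataset.samples
    y = np.array([1.0 if s.group == "cohort_case" else 0.0 for s in samples])

    carrier, excluded = carrier_status(dataset.genotypes, deleterious)
    usable = np.ones(len(samples), dtype=bool)
    if excluded:
        idx = {s: i for i, s in enumerate(dataset.genotypes.samples)}
        usable[[idx[s] for s in excluded]] = False
        logger.info("excluding %d samples missing at all set variants", len(excluded))
    table = CarrierTable(
        case_carriers=int((carrier & (y == 1) & usable).sum()),
        case_noncarriers=int((~carrier & (y == 1) & usable).sum()),
        control_carriers=int((carrier & (y == 0) & usable).sum()),
        control_noncarriers=int((~carrier & (y == 0) & usable).sum()),
    )
    fisher_p = fisher_two_tailed(table)

    covs, complete = _covariate_matrix(samples, dataset.covariates, config.covariate_names)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropping %d samples with missing covariates from SKAT", n_dropped)
    keep = complete & usable
    geno = dataset.genotypes.subset_variants(deleterious)
    G = geno.dosage[keep]
    null = fit_null_model(y[keep], covs[keep] if covs.shape[1] else None)
    skat_p, skat_method = skat_pvalue(G, null, weights_beta=config.weights_beta)
    sk = skato(G, config=config, null=null)

    boot = bootstrap_carriers(
        n_cases=table.n_cases,
        case_carriers=table.case_carriers,
        resample_size=min(config.resample_size, table.n_cases),
        n_resamples=config.n_resamples,
        seed=seeds["bootstrap"],
        with_replacement=config.with_replacement,
    )

    syn_p = synonymous_control(
        dataset.variants, dataset.annotations, dataset.genotypes, y == 1, config
    )

    return BurdenResult(
        carrier_table=table,
        fisher_p=fisher_p,
        skat_p=skat_p,
        skato_p=sk["p"],
        skato_rho_hat=sk["rho_hat"],
        bootstrap_summary=boot,
        synonymous_control_p=syn_p,
        deleterious_variants=deleterious,
        excluded_samples=excluded,
        p_value_methods={"skat": skat_method, "skato": sk["method"]},
    )


def derive_seeds(seed: int, names: Sequence[str]) -> dict[str, int]:
    """Derive one 31-bit child seed per named component from a root seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }
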