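"""Bayesian mixture-model GWAS: BayesR and annotation-informed BayesRC.

Model: y = X b + Z beta + e, with y the case indicator (or a quantitative
liability), X the fixed-effect design (intercept, sex, age, weight, neuter
status, top GRM principal components) and Z the centered, variance-scaled SNP
design. Each SNP effect beta_j is drawn from a four-component normal mixture
N(0, gamma_k * sigma_g2) with gamma = (0, 1e-4, 1e-3, 1e-2): a zero-effect
spike plus three effect-size tiers as fractions of the additive genetic
variance sigma_g2. In BayesRC every SNP carries a biological prior-class
label and each class c keeps its own mixing proportions pi^(c) with a
Dirichlet(alpha) prior, alpha = (1,1,1,1); with a single class the model is
exactly BayesR.

Inference is single-site Gibbs sampling: fixed effects from their joint
Gaussian full conditional; per SNP, the component indicator from its discrete
full conditional (marginalizing beta) followed by the effect's Gaussian full
conditional with incremental residual updates; per class, pi^(c) ~
Dirichlet(alpha + component counts); sigma_g2 and sigma_e2 from scaled
inverse-chi-squared full conditionals (df nu0 = 4, scale set from an initial
heritability guess of 0.5). The hot loop is numba-compiled; posterior storage
is streaming running means so memory stays O(m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin

from .config import GAMMA
from .datatypes import GenotypeMatrix, PosteriorSummary, PriorClassAssignment


@dataclass
class MixtureSpec:
    """Effect-size mixture: relative variances and Dirichlet concentration."""

    gamma: tuple[float, ...] = GAMMA
    alpha: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma)
        if len(self.gamma) != len(self.alpha):
            raise ValueError("gamma and alpha must have equal length")
        if np.any(np.diff(g) < 0):
            raise ValueError("gamma must be non-decreasing")
        if np.any(np.asarray(self.alpha) <= 0):
            raise ValueError("alpha must be strictly positive")


@dataclass
class ModelData:
    """Assembled design matrices for the sampler (no missing values)."""

    y: np.ndarray
    X_fixed: np.ndarray          # includes intercept column
    Z: np.ndarray                # centered/scaled SNP design
    classes: np.ndarray          # (m,) int32 class codes
    class_labels: list[str]
    snp_scale: np.ndarray        # per-SNP divisor used in standardization
    variants: pd.DataFrame | None = None
    fixed_names: list[str] = field(default_factory=list)


def standardize_snps(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center dosages by 2*p and scale by sqrt(2*p*(1-p)); returns (Z, scale)."""
    d = np.asarray(dosage, dtype=np.float64)
    p = d.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    if np.any(scale == 0):
        raise ValueError("zero-variance SNP present; run QC first")
    return (d - 2.0 * p) / scale, scale


def build_model_data(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    pcs: np.ndarray | None = None,
    assignment: PriorClassAssignment | None = None,
    response: str = "case",
    covariate_names: tuple[str, ...] = ("sex", "age", "weight", "neuter"),
) -> ModelData:
    """Assemble response, fixed-effect and SNP designs from cohort artifacts."""
    cov = covariates.set_index("sample_id").loc[genotypes.samples]
    for name in covariate_names:
        bad = cov.index[cov[name].isna()]
        if len(bad):
            raise ValueError(f"missing covariate {name!r} for sample {bad[0]}")
    y = cov[response].to_numpy(dtype=np.float64)
    if np.var(y) == 0:
        raise ValueError("response has no variance (all-case or all-control cohort)")

    cols = [np.ones(len(y))]
    names = ["intercept"]
    for name in covariate_names:
        x = cov[name].to_numpy(dtype=np.float64)
        sd = x.std()
        cols.append((x - x.mean()) / (sd if sd > 0 else 1.0))
        names.append(name)
    if pcs is not None:
        for k in range(pcs.shape[1]):
            cols.append(pcs[:, k])
            names.append(f"PC{k + 1}")
    X = np.column_stack(cols)

    Z, scale = standardize_snps(genotypes.dosage)
    if assignment is None:
        classes = np.zeros(genotypes.n_variants, dtype=np.int32)
        labels = ["NA"]
    else:
        classes, labels = assignment.class_index()
    return ModelData(y, X, Z, classes, labels, scale, genotypes.variants, names)


# ------------------------------------------------------------ numba kernel
@njit(cache=True)
def _chol_solve(L, b):
    p = L.shape[0]
    y = np.empty(p)
    for i in range(p):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * y[k]
        y[i] = s / L[i, i]
    x = np.empty(p)
    for i in range(p - 1, -1, -1):
        s = y[i]
        for k in range(i + 1, p):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _solve_lt(L, e):
    p = L.shape[0]
    u = np.empty(p)
    for i in range(p - 1, -1, -1):
        s = e[i]
        for k in range(i + 1, p):
            s -= L[k, i] * u[k]
        u[i] = s / L[i, i]
    return u


@njit(cache=True)
def _chain_kernel(
    Zt, y, X, classes, n_classes, gamma, alpha,
    n_iter, burn_in, seed, nu0, sg2_scale, se2_scale,
    update_sg2, update_se2, sg2_init, se2_init,
    check_every, store_trace,
):
    np.random.seed(seed)
    m, n = Zt.shape[0], y.shape[0]
    p = X.shape[1]
    K = gamma.shape[0]

    XtX = X.T @ X
    L = np.linalg.cholesky(XtX)
    zz = np.empty(m)
    for j in range(m):
        zz[j] = np.dot(Zt[j], Zt[j])

    b = np.zeros(p)
    beta = np.zeros(m)
    comp = np.zeros(m, dtype=np.int64)
    pi = np.empty((n_classes, K))
    asum = alpha.sum()
    for c in range(n_classes):
        for k in range(K):
            pi[c, k] = alpha[k] / asum
    sg2 = sg2_init
    se2 = se2_init
    r = y.copy()

    n_keep = n_iter - burn_in
    beta_sum = np.zeros(m)
    b_sum = np.zeros(p)
    occ = np.zeros((m, K))
    pi_sum = np.zeros((n_classes, K))
    comp_tot = np.zeros(K)
    sg2_sum = 0.0
    se2_sum = 0.0
    vg_sum = 0.0
    trace = np.zeros((n_keep if store_trace else 1, m))
    max_err = 0.0
    logp = np.empty(K)
    cnt = np.zeros((n_classes, K))

    for it in range(n_iter):
        # ---- fixed effects: joint Gaussian full conditional
        t = r + X @ b
        v = X.T @ t
        bhat = _chol_solve(L, v)
        eps = np.empty(p)
        for i in range(p):
            eps[i] = np.random.normal()
        u = _solve_lt(L, eps)
        b_new = bhat + np.sqrt(se2) * u
        r += X @ (b - b_new)
        b = b_new

        # ---- SNP sweep
        for c in range(n_classes):
            for k in range(K):
                cnt[c, k] = 0.0
        for j in range(m):
            zj = Zt[j]
            bj = beta[j]
            rhs = np.dot(zj, r) + zz[j] * bj
            c = classes[j]
            mx = -1.0e300
            for k in range(K):
                if pi[c, k] <= 0.0:
                    logp[k] = -1.0e300
                elif gamma[k] == 0.0:
                    logp[k] = np.log(pi[c, k])
                else:
                    vk = gamma[k] * sg2
                    lam = zz[j] + se2 / vk
                    logp[k] = (
                        np.log(pi[c, k])
                        - 0.5 * np.log(vk * zz[j] / se2 + 1.0)
                        + 0.5 * rhs * rhs / (se2 * lam)
                    )
                if logp[k] > mx:
                    mx = logp[k]
            tot = 0.0
            for k in range(K):
                logp[k] = np.exp(logp[k] - mx)
                tot += logp[k]
            uu = np.random.random() * tot
            k_new = K - 1
            acc = 0.0
            for k in range(K):
                acc += logp[k]
                if uu <= acc:
                    k_new = k
                    break
            if gamma[k_new] == 0.0:
                beta_new = 0.0
            else:
                vk = gamma[k_new] * sg2
                lam = zz[j] + se2 / vk
                beta_new = rhs / lam + np.sqrt(se2 / lam) * np.random.normal()
            if beta_new != bj:
                diff = bj - beta_new
                for i in range(n):
                    r[i] += zj[i] * diff
            beta[j] = beta_new
            comp[j] = k_new
            cnt[c, k_new] += 1.0

        # ---- mixing proportions per class
        for c in range(n_classes):
            s = 0.0
            for k in range(K):
                g = np.random.gamma(alpha[k] + cnt[c, k], 1.0)
                pi[c, k] = g
                s += g
            for k in range(K):
                pi[c, k] /= s

        # ---- variance components
        if update_sg2:
            ss = 0.0
            nnz = 0
            for j in range(m):
                if gamma[comp[j]] > 0.0:
                    ss += beta[j] * beta[j] / gamma[comp[j]]
                    nnz += 1
            df = nu0 + nnz
            sg2 = (nu0 * sg2_scale + ss) / (2.0 * np.random.gamma(df / 2.0, 1.0))
        if update_se2:
            ss_e = np.dot(r, r)
            df = nu0 + n
            se2 = (nu0 * se2_scale + ss_e) / (2.0 * np.random.gamma(df / 2.0, 1.0))

        # ---- residual conservation check
        if check_every > 0 and (it + 1) % check_every == 0:
            acc_v = X @ b
            for j in range(m):
                if beta[j] != 0.0:
                    for i in range(n):
                        acc_v[i] += Zt[j, i] * beta[j]
            for i in range(n):
                err = abs(r[i] - (y[i] - acc_v[i]))
                if err > max_err:
                    max_err = err

        # ---- streaming posterior accumulation
        if it >= burn_in:
            for j in range(m):
                beta_sum[j] += beta[j]
                occ[j, comp[j]] += 1.0
            for i in range(p):
                b_sum[i] += b[i]
            for c in range(n_classes):
                for k in range(K):
                    pi_sum[c, k] += pi[c, k]
                    comp_tot[k] += cnt[c, k]
            sg2_sum += sg2
            se2_sum += se2
            # genomic variance from the maintained identity Z beta = y - X b - r
            xb = X @ b
            s1 = 0.0
            s2 = 0.0
            for i in range(n):
                gi = y[i] - xb[i] - r[i]
                s1 += gi
                s2 += gi * gi
            vg_sum += s2 / n - (s1 / n) ** 2
            if store_trace:
                trace[it - burn_in] = beta

    inv = 1.0 / n_keep
    return (
        beta_sum * inv, occ * inv, pi_sum * inv, sg2_sum * inv, se2_sum * inv,
        comp_tot * inv, b_sum * inv, vg_sum * inv, max_err, trace,
    )


# --------------------------------------------------------------- estimator
class BayesRC(BaseEstimator, RegressorMixin):
    """Annotation-informed Bayesian mixture-model GWAS estimator.

    Parameters
    ----------
    n_iter, burn_in : MCMC schedule (defaults 200,000 / 100,000).
    n_chains : replicate chains averaged into the final posterior summary
        (default 5); between-chain effect correlations are retained as a
        convergence diagnostic.
    gamma, alpha : mixture relative variances and Dirichlet concentration.
    h2_init : initial heritability guess setting the inverse-chi-squared
        prior scales for sigma_g2 / sigma_e2 (df ``nu0``).
    seed : base seed; chain seeds are derived deterministically.

    Fitted attributes: ``effects_`` (per-SNP posterior-mean effect on the
    standardized-genotype scale), ``occupancy_`` (m x 4 component
    probabilities), ``pi_``, ``sigma_g2_``, ``sigma_e2_``, ``h2_``,
    ``component_counts_``, ``fixed_effects_``, ``summary_``.
    """

    def __init__(
        self,
        n_iter: int = 200_000,
        burn_in: int = 100_000,
        n_chains: int = 5,
        gamma: tuple[float, ...] = GAMMA,
        alpha: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0),
        h2_init: float = 0.5,
        nu0: float = 4.0,
        seed: int = 0,
        fixed_variances: tuple[float, float] | None = None,
        check_residual_every: int = 0,
        store_trace: bool = False,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.n_chains = n_chains
        self.gamma = gamma
        self.alpha = alpha
        self.h2_init = h2_init
        self.nu0 = nu0
        self.seed = seed
        self.fixed_variances = fixed_variances
        self.check_residual_every = check_residual_every
        self.store_trace = store_trace

    # -- internals --------------------------------------------------------
    def _chain_seeds(self) -> np.ndarray:
        ss = np.random.SeedSequence(self.seed)
        return (ss.generate_state(self.n_chains) % np.uint32(2**31)).astype(np.int64)

    def _run_single(self, data: ModelData, seed: int) -> PosteriorSummary:
        MixtureSpec(self.gamma, self.alpha)  # validate
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        vy = float(np.var(data.y))
        if self.fixed_variances is not None:
            sg2_init, se2_init = self.fixed_variances
            upd_g = upd_e = False
        else:
            sg2_init = self.h2_init * vy
            se2_init = (1.0 - self.h2_init) * vy
            upd_g = upd_e = True
        n_classes = max(1, int(data.classes.max()) + 1 if data.classes.size else 1)
        Zt = np.ascontiguousarray(data.Z.T)
        out = _chain_kernel(
            Zt, data.y.astype(np.float64), np.ascontiguousarray(data.X_fixed),
            data.classes.astype(np.int64), n_classes,
            np.asarray(self.gamma, dtype=np.float64), np.asarray(self.alpha, dtype=np.float64),
            int(self.n_iter), int(self.burn_in), int(seed), float(self.nu0),
            float(sg2_init), float(se2_init), upd_g, upd_e,
            float(sg2_init), float(se2_init),
            int(self.check_residual_every), bool(self.store_trace),
        )
        beta, occ, pi, sg2, se2, comp_tot, b_mean, var_g, max_err, trace = out
        if not np.isfinite(beta).all():
            raise FloatingPointError("non-finite SNP effects in sampler output")
        return PosteriorSummary(
            effects=beta, occupancy=occ, pi=pi, sigma_g2=sg2, sigma_e2=se2,
            component_counts=comp_tot, fixed_effects=b_mean, var_genetic=var_g,
            class_labels=list(data.class_labels), max_residual_error=max_err,
            beta_trace=trace if self.store_trace else None,
        )

    # -- API ---------------------------------------------------------------
    def fit(self, X, y=None, *, classes=None, fixed=None, data: ModelData | None = None):
        """Fit on a ModelData (preferred) or on raw (X, y[, classes, fixed])."""
        if data is None:
            X = np.asarray(X, dtype=np.float64)
            y = np.asarray(y, dtype=np.float64)
            Xf = np.ones((len(y), 1)) if fixed is None else np.column_stack(
                [np.ones(len(y)), np.asarray(fixed, dtype=np.float64)]
            )
            if classes is None:
                cls = np.zeros(X.shape[1], dtype=np.int32)
                labels = ["NA"]
            else:
                classes = np.asarray(classes)
                labels = [str(u) for u in np.unique(classes)]
                code = {u: i for i, u in enumerate(np.unique(classes))}
                cls = np.array([code[c] for c in classes], dtype=np.int32)
            data = ModelData(y, Xf, X, cls, labels, np.ones(X.shape[1]))
        self.data_ = data
        chains = [self._run_single(data, s) for s in self._chain_seeds()]
        n_c = len(chains)
        avg = PosteriorSummary(
            effects=np.mean([c.effects for c in chains], axis=0),
            occupancy=np.mean([c.occupancy for c in chains], axis=0),
            pi=np.mean([c.pi for c in chains], axis=0),
            sigma_g2=float(np.mean([c.sigma_g2 for c in chains])),
            sigma_e2=float(np.mean([c.sigma_e2 for c in chains])),
            component_counts=np.mean([c.component_counts for c in chains], axis=0),
            fixed_effects=np.mean([c.fixed_effects for c in chains], axis=0),
            var_genetic=float(np.mean([c.var_genetic for c in chains])),
            class_labels=list(data.class_labels),
            per_chain=chains if n_c > 1 else [],
            max_residual_error=max(c.max_residual_error for c in chains),
            beta_trace=chains[0].beta_trace,
        )
        self.summary_ = avg
        self.effects_ = avg.effects
        self.occupancy_ = avg.occupancy
        self.pi_ = avg.pi
        self.sigma_g2_ = avg.sigma_g2
        self.sigma_e2_ = avg.sigma_e2
        self.h2_ = avg.h2
        self.component_counts_ = avg.component_counts
        self.fixed_effects_ = avg.fixed_effects
        if n_c > 1:
            cors = [
                np.corrcoef(chains[a].effects, chains[b].effects)[0, 1]
                for a in range(n_c) for b in range(a + 1, n_c)
            ]
            self.between_chain_corr_ = float(np.mean(cors))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        return X @ self.effects_ + self.fixed_effects_[0]


# ------------------------------------------------------- functional wrappers
def run_chain(data: ModelData, n_iter=200_000, burn_in=100_000, seed=0, **kw) -> PosteriorSummary:
    est = BayesRC(n_iter=n_iter, burn_in=burn_in, n_chains=1, seed=seed, **kw)
    est.fit(None, data=data)
    return est.summary_


def run_replicates(
    data: ModelData, n_chains=5, n_iter=200_000, burn_in=100_000, seed=0, **kw
) -> PosteriorSummary:
    est = BayesRC(n_iter=n_iter, burn_in=burn_in, n_chains=n_chains, seed=seed, **kw)
    est.fit(None, data=data)
    return est.summary_


def run_bayesr_mode(data: ModelData, **kw) -> PosteriorSummary:
    """Single-class analysis: identical machinery with all SNPs in one class."""
    single = ModelData(
        data.y, data.X_fixed, data.Z,
        np.zeros(data.Z.shape[1], dtype=np.int32), ["NA"],
        data.snp_scale, data.variants, data.fixed_names,
    )
    return run_replicates(single, **kw)
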