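"""Independent oracles for the regression tests.

These deliberately avoid the package's own fitting code: the MLE oracle
maximises the Poisson log-likelihood with a generic Newton optimizer from
scipy, and the covariance oracle is statsmodels' clustered sandwich.
"""

import numpy as np
import pandas as pd
from scipy import optimize


def poisson_mle(mat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Generic-optimizer Poisson MLE under the log link."""

    def nll(beta):
        eta = mat @ beta
        return float(np.sum(np.exp(eta)) - y @ eta)

    def grad(beta):
        return mat.T @ (np.exp(mat @ beta) - y)

    def hess(beta):
        mu = np.exp(mat @ beta)
        return mat.T @ (mat * mu[:, None])

    res = optimize.minimize(
        nll, np.zeros(mat.shape[1]), jac=grad, hess=hess,
        method="trust-ncg", options={"gtol": 1e-12, "maxiter": 500},
    )
    # polish to machine precision with Newton steps on the score equations
    beta = res.x
    for _ in range(50):
        g = grad(beta)
        if np.linalg.norm(g) < 1e-10:
            break
        beta = beta - np.linalg.solve(hess(beta), g)
    return beta


def statsmodels_cluster_cov(mat: np.ndarray, y: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    """Clustered sandwich from statsmodels GLM, without small-sample scaling."""
    import statsmodels.api as sm

    codes = pd.factorize(clusters)[0]
    fit = sm.GLM(y, mat, family=sm.families.Poisson()).fit(
        cov_type="cluster", cov_kwds={"groups": codes, "use_correction": False}
    )
    return np.asarray(fit.cov_params())


def random_design(rng: np.random.Generator, max_subjects: int = 30, max_snps: int = 12):
    """A random small per-gene dataset of phased allele-count rows."""
    from asepofo.pofo import build_design
    from asepofo.simulate import SimConfig, simulate_gene_sites

    while True:
        cfg = SimConfig(
            n_subjects=int(rng.integers(3, max_subjects + 1)),
            snps_per_gene=int(rng.integers(1, max_snps + 1)),
            het_prob=0.7,
            po_true=float(rng.normal(0, 0.8)),
            genetic_sd=0.5,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        frame, _ = simulate_gene_sites(cfg, np.random.default_rng(cfg.seed))
        if len(frame) and frame["sample_id"].nunique() >= 3:
            return build_design(frame)
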