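"""Per-gene parent-of-origin (PofO) testing.

For a gene with N allele-count observations over m heterozygous SNPs, each
(subject, SNP) contributes a ref row and an alt row.  The mean model is a
log-link quasi-Poisson regression

    log E[Y] = b0 + po*Z + b1*X + sum_l g_l V_l + sum_l d_l (V_l * X)

where Z = +1/2 for the paternal and -1/2 for the maternal allele count,
X = +1/2 for ref and -1/2 for alt, and V holds the left singular vectors of
the SNP indicator matrix U whose singular values reach at least 1% of the
largest.  The X and V*X terms absorb genetic (sequence-driven) allelic
imbalance; clustering on subjects absorbs within-individual correlation.
The coefficient of Z is the PofO score `po`; its ratio to the clustered
sandwich standard error is `po_z`.  Positive po means paternal bias.

Point estimates are the Poisson maximum-likelihood estimates (quasi-Poisson
shares them), computed by iteratively reweighted least squares.  The full V
block is structurally collinear with the intercept whenever every singular
vector is retained (rows of U sum to one), so rank reduction scans columns
left to right, keeping intercept, Z and X with priority and dropping
redundant V / V*X columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_REL_THRESHOLD = 0.01
DEFAULT_MIN_SUBJECTS = 3
DEFAULT_PO_CUT = 3.0
DEFAULT_Z_CUT = 3.0
IRLS_TOL = 1e-10
IRLS_MAX_ITER = 100

UNTESTABLE_REASONS = (
    "too_few_subjects",
    "no_phased_snps",
    "po_unidentifiable",
    "no_convergence",
    "none",
)

RESULT_COLUMNS = (
    "gene_id",
    "po",
    "po_se",
    "po_z",
    "n_subjects",
    "n_snps",
    "n_obs",
    "testable",
    "untestable_reason",
    "direction",
    "classification",
    "pearson_dispersion",
)


class DesignError(ValueError):
    pass


@dataclass
class PofoDesign:
    """Regression design for one gene."""

    gene_id: str
    y: np.ndarray  # (N,) counts
    z: np.ndarray  # (N,) +-1/2 paternal/maternal
    x: np.ndarray  # (N,) +-1/2 ref/alt
    u: np.ndarray  # (N, m) SNP indicators
    v: np.ndarray  # (N, q) reduced indicators
    clusters: np.ndarray  # (N,) subject ids
    snp_ids: list = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def m(self) -> int:
        return self.u.shape[1]

    @property
    def q(self) -> int:
        return self.v.shape[1]

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.clusters))

    def matrix(self) -> tuple[np.ndarray, list[str]]:
        """Assemble the model matrix [1, z, x, V, V*x] with column names."""
        cols = [np.ones(self.n_obs), self.z, self.x]
        names = ["intercept", "z", "x"]
        for l in range(self.q):
            cols.append(self.v[:, l])
            names.append(f"v{l + 1}")
        for l in range(self.q):
            cols.append(self.v[:, l] * self.x)
            names.append(f"vx{l + 1}")
        return np.column_stack(cols), names


@dataclass
class PofoFit:
    gene_id: str
    params: dict[str, float]
    cov: np.ndarray  # clustered sandwich over retained columns
    names: list[str]  # retained column names, ordered as cov
    n_subjects: int
    n_snps: int
    n_obs: int
    converged: bool
    dropped_columns: list[str]
    pearson_dispersion: float

    @property
    def po(self) -> float | None:
        return self.params.get("z")

    @property
    def po_se(self) -> float | None:
        if "z" not in self.names:
            return None
        i = self.names.index("z")
        return float(np.sqrt(self.cov[i, i]))


@dataclass
class PofoResult:
    gene_id: str
    po: float
    po_se: float
    po_z: float
    n_subjects: int
    n_snps: int
    n_obs: int
    testable: bool
    untestable_reason: str = "none"
    pearson_dispersion: float = float("nan")

    @property
    def direction(self) -> str:
        if not self.testable or self.po == 0 or np.isnan(self.po):
            return "balanced"
        return "paternal" if self.po > 0 else "maternal"


def reduce_indicators(
    u: np.ndarray, rel_threshold: float = DEFAULT_REL_THRESHOLD
) -> tuple[np.ndarray, int]:
    """Left singular vectors of U with singular value >= rel_threshold * max.

    "At least" is inclusive, so a singular value exactly at the threshold is
    kept.  For the disjoint indicator columns produced here the singular
    values equal sqrt(observations per SNP).
    """
    if u.size == 0 or not np.any(u):
        raise DesignError("indicator matrix is empty")
    left, sv, _ = np.linalg.svd(u, full_matrices=False)
    keep = sv >= rel_threshold * sv[0] - 1e-12 * sv[0]
    return left[:, keep], int(keep.sum())


def build_design(
    gene_sites: pd.DataFrame,
    combine_strands: bool = True,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
) -> PofoDesign:
    """Build the per-gene design from filtered phased annotated rows.

    Each (subject, SNP) pair yields two rows: k=0 (ref, X=+1/2) then k=1
    (alt, X=-1/2), with Y the respective allele counts and Z assigned so the
    paternal count carries +1/2.  With ``combine_strands`` the ref/alt
    counts are summed over strand records per (subject, SNP) first.
    """
    gene_ids = gene_sites["gene_id"].unique()
    if len(gene_ids) != 1:
        raise DesignError(f"expected rows for one gene, got {list(gene_ids)}")
    gene_id = str(gene_ids[0])
    rows = gene_sites[gene_sites["paternal_allele"].isin(["ref", "alt"])]
    if rows.empty:
        raise DesignError("no phased heterozygous SNPs")

    if combine_strands:
        rows = rows.groupby(
            ["sample_id", "contig", "position", "paternal_allele"], as_index=False
        )[["ref_count", "alt_count"]].sum()

    snp_ids = sorted(set(zip(rows["contig"], rows["position"])))
    snp_index = {s: j for j, s in enumerate(snp_ids)}
    m = len(snp_ids)

    y, z, x, clusters, u_col = [], [], [], [], []
    for rec in rows.itertuples(index=False):
        j = snp_index[(rec.contig, rec.position)]
        z_ref = 0.5 if rec.paternal_allele == "ref" else -0.5
        for allele_x, count, z_val in ((0.5, rec.ref_count, z_ref), (-0.5, rec.alt_count, -z_ref)):
            y.append(count)
            x.append(allele_x)
            z.append(z_val)
            clusters.append(rec.sample_id)
            u_col.append(j)

    n = len(y)
    u = np.zeros((n, m))
    u[np.arange(n), u_col] = 1.0
    v, _ = reduce_indicators(u, rel_threshold)
    return PofoDesign(
        gene_id=gene_id,
        y=np.asarray(y, dtype=float),
        z=np.asarray(z),
        x=np.asarray(x),
        u=u,
        v=v,
        clusters=np.asarray(clusters, dtype=object),
        snp_ids=snp_ids,
    )


def _independent_columns(mat: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Greedy left-to-right scan keeping linearly independent columns.

    Scanning order makes later (V, V*X) columns the ones dropped when the
    block is collinear with intercept/Z/X, so po keeps its meaning.
    """
    n = mat.shape[0]
    basis = np.empty((n, 0))
    keep: list[int] = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        resid = col - basis @ (basis.T @ col) if basis.shape[1] else col.copy()
        # re-orthogonalise once for numerical safety
        if basis.shape[1]:
            resid = resid - basis @ (basis.T @ resid)
        norm = np.linalg.norm(resid)
        if norm > tol * max(1.0, np.linalg.norm(col)):
            basis = np.column_stack([basis, resid / norm])
            keep.append(j)
    return keep


def _clustered_sandwich(
    mat: np.ndarray,
    y: np.ndarray,
    mu: np.ndarray,
    clusters: np.ndarray,
    small_sample_correction: str = "cr1",
) -> np.ndarray:
    """Cluster-robust sandwich covariance for the Poisson-score estimator."""
    bread = np.linalg.inv(mat.T @ (mat * mu[:, None]))
    resid = y - mu
    p = mat.shape[1]
    meat = np.zeros((p, p))
    groups = np.unique(clusters)
    for g in groups:
        idx = clusters == g
        s = mat[idx].T @ resid[idx]
        meat += np.outer(s, s)
    cov = bread @ meat @ bread
    n_g = len(groups)
    if small_sample_correction == "cr1" and n_g > 1:
        cov = cov * n_g / (n_g - 1)
    elif small_sample_correction not in ("cr1", "none"):
        raise ValueError("small_sample_correction must be 'cr1' or 'none'")
    return cov


def fit_quasipoisson(
    design: PofoDesign,
    small_sample_correction: str = "cr1",
    tol: float = IRLS_TOL,
    max_iter: int = IRLS_MAX_ITER,
) -> PofoFit:
    """Fit the log-link model by IRLS with a clustered sandwich covariance.

    Rank deficiency is resolved before fitting; if that removes the Z
    column the gene's PofO effect is unidentifiable and the caller marks it
    untestable.  Quasi-Poisson dispersion is reported as a diagnostic only —
    the clustered sandwich already accounts for extra-Poisson variation.
    """
    full, names = design.matrix()
    keep = _independent_columns(full)
    dropped = [names[j] for j in range(full.shape[1]) if j not in keep]
    mat = full[:, keep]
    kept_names = [names[j] for j in keep]

    y = design.y
    eta = np.log(y + 0.5)
    beta = np.zeros(mat.shape[1])
    converged = False
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu
        work = eta + (y - mu) / mu
        mw = mat * w[:, None]
        try:
            beta_new = np.linalg.solve(mat.T @ mw, mw.T @ work)
        except np.linalg.LinAlgError:
            break
        delta = np.max(np.abs(beta_new - beta) / np.maximum(1.0, np.abs(beta)))
        beta = beta_new
        eta = mat @ beta
        if delta < tol:
            converged = True
            break

    mu = np.exp(np.clip(mat @ beta, -30.0, 30.0))
    cov = _clustered_sandwich(mat, y, mu, design.clusters, small_sample_correction)
    dof = max(design.n_obs - mat.shape[1], 1)
    dispersion = float(np.sum((y - mu) ** 2 / mu) / dof)
    return PofoFit(
        gene_id=design.gene_id,
        params=dict(zip(kept_names, beta)),
        cov=cov,
        names=kept_names,
        n_subjects=design.n_subjects,
        n_snps=design.m,
        n_obs=design.n_obs,
        converged=converged,
        dropped_columns=dropped,
        pearson_dispersion=dispersion,
    )


def pofo_score(fit: PofoFit, min_subjects: int = DEFAULT_MIN_SUBJECTS) -> PofoResult:
    """Extract po, its sandwich standard error, and po_z = po / se."""
    reason = "none"
    if "z" not in fit.names:
        reason = "po_unidentifiable"
    elif not fit.converged:
        reason = "no_convergence"
    elif fit.n_subjects < min_subjects:
        reason = "too_few_subjects"
    testable = reason == "none"
    po = fit.po if fit.po is not None else float("nan")
    po_se = fit.po_se if fit.po_se is not None else float("nan")
    po_z = po / po_se if testable and po_se > 0 else float("nan")
    return PofoResult(
        gene_id=fit.gene_id,
        po=po,
        po_se=po_se,
        po_z=po_z,
        n_subjects=fit.n_subjects,
        n_snps=fit.n_snps,
        n_obs=fit.n_obs,
        testable=testable,
        untestable_reason=reason,
        pearson_dispersion=fit.pearson_dispersion,
    )


def classify(
    result: PofoResult, po_cut: float = DEFAULT_PO_CUT, z_cut: float = DEFAULT_Z_CUT
) -> str:
    """Classify a gene: |po_z| gates significance, |po| gates "strong"."""
    if not result.testable:
        return "untestable"
    if abs(result.po_z) <= z_cut or np.isnan(result.po_z):
        return "not_significant"
    side = "paternal" if result.po > 0 else "maternal"
    strength = "strong" if abs(result.po) > po_cut else "significant"
    return f"{strength}_{side}"


def fold_change(po: float) -> float:
    """Implied expected-count ratio between the two parental alleles.

    Z differs by exactly 1 between the paternal (+1/2) and maternal (-1/2)
    rows under the log link, so the ratio is exp(|po|); |po| > 3 implies at
    least a 20-fold difference.
    """
    return float(np.exp(abs(po)))


def score_gene(
    gene_sites: pd.DataFrame,
    combine_strands: bool = True,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    min_subjects: int = DEFAULT_MIN_SUBJECTS,
    small_sample_correction: str = "cr1",
) -> PofoResult:
    """Design, fit, and score one gene; untestable genes never raise."""
    gene_id = str(gene_sites["gene_id"].iloc[0]) if len(gene_sites) else "NA"
    try:
        design = build_design(gene_sites, combine_strands, rel_threshold)
    except DesignError:
        return PofoResult(
            gene_id=gene_id,
            po=float("nan"),
            po_se=float("nan"),
            po_z=float("nan"),
            n_subjects=0,
            n_snps=0,
            n_obs=0,
            testable=False,
            untestable_reason="no_phased_snps",
        )
    fit = fit_quasipoisson(design, small_sample_correction)
    return pofo_score(fit, min_subjects)


def run_pofo(
    sites: pd.DataFrame,
    combine_strands: bool = True,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    min_subjects: int = DEFAULT_MIN_SUBJECTS,
    po_cut: float = DEFAULT_PO_CUT,
    z_cut: float = DEFAULT_Z_CUT,
    small_sample_correction: str = "cr1",
) -> pd.DataFrame:
    """Run the PofO test on every gene in a filtered phased site table."""
    rows = []
    for gene_id, sub in sites.groupby("gene_id", sort=True):
        res = score_gene(
            sub,
            combine_strands=combine_strands,
            rel_threshold=rel_threshold,
            min_subjects=min_subjects,
            small_sample_correction=small_sample_correction,
        )
        rows.append(
            {
                "gene_id": res.gene_id,
                "po": res.po,
                "po_se": res.po_se,
                "po_z": res.po_z,
                "n_subjects": res.n_subjects,
                "n_snps": res.n_snps,
                "n_obs": res.n_obs,
                "testable": res.testable,
                "untestable_reason": res.untestable_reason,
                "direction": res.direction,
                "classification": classify(res, po_cut, z_cut),
                "pearson_dispersion": res.pearson_dispersion,
            }
        )
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
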