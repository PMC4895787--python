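"""Per-SNP association scoring with nested-model selection.

Each SNP ``x_j`` is scored under the Gaussian fixed-effects model

    y = W_j alpha + x_j beta + eps,    eps ~ MVN_n(0, tau^-1 I_n),

fit by maximum likelihood (with i.i.d. Gaussian errors this is ordinary
least squares; tau-hat = n / RSS).  The reported score ``p_j`` is a
likelihood-ratio test of the SNP effect against the no-SNP null.  Two
covariate sets compete: the global PCs alone, or global plus local PCs
("glocal").  Under the default ``minp`` rule both LRTs are computed and
``p_j`` is the smaller; under ``forward`` the local block is adopted only
if it improves the no-SNP model at P < 0.05 and the SNP is then tested in
the adopted design.

An EIGENSTRAT-style baseline is also provided: residualize phenotype and
genotype on the top principal components of the full alignment and refer
``(n - K - 1) r^2`` of the residual correlation to chi-square with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .alignment import HaploidAlignment
from .covariates import CovariateBundle, CovariateBuilder, full_alignment_pcs
from .partition import PartitionSet

__all__ = [
    "ModelFit",
    "AssociationResult",
    "fit_ml",
    "lrt_pvalue",
    "coalmap_score",
    "eigenstrat_score",
    "score_alignment",
    "eigenstrat_scores",
]

_RANK_TOL = 1e-10
_RSS_FLOOR_REL = 1e-12  # RSS floored at this multiple of n*Var(y)
FORWARD_ALPHA = 0.05  # significance threshold for adopting the local block


@dataclass
class ModelFit:
    """Maximum-likelihood fit of one Gaussian linear model."""

    coef: np.ndarray  # coefficients of the retained design columns
    beta_hat: float | None  # SNP effect (None when the model has no SNP)
    tau_hat: float  # inverse error variance, n / RSS
    loglik: float
    rss: float
    df: int  # number of retained mean parameters (matrix rank)
    n: int
    design: str  # label: none | global | glocal | custom
    includes_snp: bool
    dropped: list[int] = field(default_factory=list)  # collinear columns
    rss_floored: bool = False

    @property
    def alpha_hat(self) -> np.ndarray:
        """Covariate coefficients (intercept included, SNP excluded)."""
        return self.coef[:-1] if self.includes_snp else self.coef


def _rss_floor(y: np.ndarray) -> float:
    n = y.size
    return _RSS_FLOOR_REL * max(float(np.var(y)), np.finfo(float).tiny) * n


def fit_ml(
    y: np.ndarray,
    W: np.ndarray | None,
    x: np.ndarray | None = None,
    design: str = "custom",
) -> ModelFit:
    """ML fit of ``y = [1 | W | x] theta + eps`` with Gaussian errors.

    Collinear design columns are dropped by pivoted-QR rank detection
    (tolerance 1e-10 relative to the largest diagonal of R).  A perfect
    fit is handled by flooring the RSS at ``1e-12 * n * Var(y)`` so the
    log-likelihood stays finite; such fits are flagged.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    cols = [np.ones((n, 1))]
    if W is not None and np.size(W):
        W = np.asarray(W, dtype=float)
        if W.ndim == 1:
            W = W[:, None]
        if W.shape[0] != n:
            raise ValueError("W row count does not match y")
        cols.append(W)
    if x is not None:
        x = np.asarray(x, dtype=float).ravel()
        if x.size != n:
            raise ValueError("x length does not match y")
        cols.append(x[:, None])
    D = np.column_stack(cols)

    q, r, piv = scipy.linalg.qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > _RANK_TOL * diag[0])) if diag.size else 0
    keep = np.sort(piv[:rank])
    dropped = sorted(set(range(D.shape[1])) - set(int(i) for i in keep))
    Dk = D[:, keep]
    coef_k, _, _, _ = np.linalg.lstsq(Dk, y, rcond=None)
    resid = y - Dk @ coef_k
    rss = float(resid @ resid)
    floor = _rss_floor(y)
    floored = rss < floor
    rss_eff = max(rss, floor)

    coef = np.zeros(D.shape[1])
    coef[keep] = coef_k
    includes_snp = x is not None
    snp_col = D.shape[1] - 1
    beta = float(coef[snp_col]) if includes_snp else None
    if includes_snp and snp_col in dropped:
        beta = 0.0
    loglik = -0.5 * n * (np.log(2.0 * np.pi * rss_eff / n) + 1.0)
    return ModelFit(
        coef=coef,
        beta_hat=beta,
        tau_hat=n / rss_eff,
        loglik=loglik,
        rss=rss_eff,
        df=rank,
        n=n,
        design=design,
        includes_snp=includes_snp,
        dropped=dropped,
        rss_floored=floored,
    )


def lrt_pvalue(fit_alt: ModelFit, fit_null: ModelFit) -> float:
    """Likelihood-ratio p-value of nested Gaussian fits.

    ``Lambda = 2 (ll_alt - ll_null)`` clipped at zero, referred to
    chi-square with ``df = df_alt - df_null``.  Zero df (the SNP was
    collinear with the null design) yields p = 1.
    """
    if fit_alt.n != fit_null.n:
        raise ValueError("fits are not on the same data")
    if fit_alt.df < fit_null.df:
        raise ValueError("null model is not nested in the alternative")
    df = fit_alt.df - fit_null.df
    if df == 0:
        return 1.0
    lam = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    return float(stats.chi2.sf(lam, df))


@dataclass
class AssociationResult:
    """Per-SNP score with the two nested-model p-values behind it."""

    site: int
    partition_id: int
    p_global: float
    p_glocal: float
    p_value: float
    selected_model: str  # "global" | "glocal"
    beta_hat: float
    selection_rule: str  # "minp" | "forward"


def coalmap_score(
    y: np.ndarray,
    x_j: np.ndarray,
    bundle: CovariateBundle,
    rule: str = "minp",
    site: int = -1,
    local_pcs_override: np.ndarray | None = None,
) -> AssociationResult:
    """Score one SNP against the covariate bundle of its partition.

    ``local_pcs_override`` substitutes the bundle's local PC block (used
    e.g. to drop the test SNP itself from the local PCA).
    """
    if rule not in ("minp", "forward"):
        raise ValueError("rule must be 'minp' or 'forward'")
    Wg = bundle.W_global
    if local_pcs_override is not None:
        Wgl = np.column_stack([Wg, local_pcs_override])
    else:
        Wgl = bundle.W_glocal
    null_g = fit_ml(y, Wg, design="global")
    alt_g = fit_ml(y, Wg, x_j, design="global")
    p_global = lrt_pvalue(alt_g, null_g)
    null_gl = fit_ml(y, Wgl, design="glocal")
    alt_gl = fit_ml(y, Wgl, x_j, design="glocal")
    p_glocal = lrt_pvalue(alt_gl, null_gl)

    if rule == "minp":
        if p_global <= p_glocal:
            selected, p_j, beta = "global", p_global, alt_g.beta_hat
        else:
            selected, p_j, beta = "glocal", p_glocal, alt_gl.beta_hat
    else:  # forward selection on the local covariate block (no SNP)
        p_block = lrt_pvalue(null_gl, null_g)
        if p_block < FORWARD_ALPHA:
            selected, p_j, beta = "glocal", p_glocal, alt_gl.beta_hat
        else:
            selected, p_j, beta = "global", p_global, alt_g.beta_hat
    return AssociationResult(
        site=site,
        partition_id=bundle.partition_id,
        p_global=p_global,
        p_glocal=p_glocal,
        p_value=p_j,
        selected_model=selected,
        beta_hat=float(beta if beta is not None else 0.0),
        selection_rule=rule,
    )


def eigenstrat_score(
    y: np.ndarray, x_j: np.ndarray, pcs: np.ndarray | None
) -> float:
    """EIGENSTRAT-style p-value for one SNP.

    Residualize phenotype and genotype on an intercept plus the supplied
    principal components, then refer ``(n - K - 1) r^2`` (``r`` the
    correlation of the residuals, ``K`` the PC count) to chi-square, 1 df.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x_j, dtype=float).ravel()
    n = y.size
    K = 0 if pcs is None or np.size(pcs) == 0 else np.atleast_2d(pcs).shape[1]
    D = np.ones((n, 1)) if K == 0 else np.column_stack([np.ones(n), pcs])
    q, _ = np.linalg.qr(D)
    ry = y - q @ (q.T @ y)
    rx = x - q @ (q.T @ x)
    denom = np.linalg.norm(ry) * np.linalg.norm(rx)
    if denom <= _RANK_TOL * max(np.linalg.norm(y), np.linalg.norm(x), 1.0):
        return 1.0
    r = float(ry @ rx) / denom
    stat = (n - K - 1) * r * r
    return float(stats.chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# Vectorized whole-alignment scans (exact OLS identities; used by the
# study runner so each replicate takes a few matrix products rather than
# thousands of individual solver calls)
# ---------------------------------------------------------------------------


def _added_column_pvalues(
    y: np.ndarray, W: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """LRT p-values and effect sizes for adding each column of X to [1|W].

    Uses the rank-one update RSS_alt = RSS_null - (r_y.r_x)^2 / |r_x|^2
    on residuals against an orthonormal basis of the null design, which is
    algebraically identical to refitting the augmented model.
    """
    n = y.size
    D = np.column_stack([np.ones(n), W]) if np.size(W) else np.ones((n, 1))
    q, _ = np.linalg.qr(D)
    ry = y - q @ (q.T @ y)
    RX = X - q @ (q.T @ X)
    rss0 = float(ry @ ry)
    floor = _rss_floor(y)
    rss0_eff = max(rss0, floor)
    xnorm2 = np.einsum("ij,ij->j", RX, RX)
    proj = ry @ RX
    # columns collinear with the design add no parameter -> p = 1
    degenerate = xnorm2 <= (_RANK_TOL * max(np.abs(X).max(initial=1.0), 1.0)) ** 2 * n
    safe = np.where(degenerate, 1.0, xnorm2)
    rss1 = rss0 - proj**2 / safe
    rss1 = np.maximum(rss1, floor)
    lam = n * np.log(rss0_eff / rss1)
    lam = np.maximum(lam, 0.0)
    p = stats.chi2.sf(lam, 1)
    beta = proj / safe
    p = np.where(degenerate, 1.0, p)
    beta = np.where(degenerate, 0.0, beta)
    return p, beta


def score_alignment(
    aln: HaploidAlignment,
    parts: PartitionSet,
    y: np.ndarray,
    rule: str = "minp",
    n_global_pcs: int = 5,
    n_local_pcs: int = 5,
    builder: CovariateBuilder | None = None,
    design: str = "coalmap",
    drop_test_snp_from_local: bool = False,
) -> pd.DataFrame:
    """Coal-Map scores for every SNP of an alignment.

    Returns a DataFrame with one row per site: the two nested-model
    p-values, the reported ``p_value`` under the selection rule, the
    selected model and the fitted SNP effect.  ``design="local-only"``
    is an ablation that corrects for local sample structure alone (the
    SNP is tested against its partition's local PCs only; no model
    selection).
    """
    if rule not in ("minp", "forward"):
        raise ValueError("rule must be 'minp' or 'forward'")
    if design not in ("coalmap", "local-only"):
        raise ValueError("design must be 'coalmap' or 'local-only'")
    y = np.asarray(y, dtype=float).ravel()
    if y.size != aln.n_samples:
        raise ValueError("phenotype length does not match sample count")
    if builder is None:
        builder = CovariateBuilder(aln, parts, n_global_pcs, n_local_pcs)
    if drop_test_snp_from_local:
        if design != "coalmap":
            raise ValueError("drop_test_snp_from_local requires the "
                             "default design")
        # per-SNP local PCA: necessarily the slow path
        rows = []
        for j in range(aln.n_sites):
            ell = parts.partition_of_site(j)
            res = coalmap_score(
                y, aln.genotypes[:, j], builder.bundle(ell), rule=rule,
                site=j,
                local_pcs_override=builder.local_pcs_excluding(ell, j),
            )
            rows.append({
                "site": j, "site_id": aln.site_ids[j],
                "partition_id": ell, "p_global": res.p_global,
                "p_glocal": res.p_glocal, "p_value": res.p_value,
                "selected_model": res.selected_model,
                "beta_hat": res.beta_hat, "selection_rule": rule,
            })
        return pd.DataFrame(rows)
    X = aln.genotypes.astype(float)
    k = aln.n_sites
    p_global = np.empty(k)
    p_glocal = np.empty(k)
    beta_g = np.empty(k)
    beta_gl = np.empty(k)
    part_of = np.empty(k, dtype=np.int64)
    adopt_local = np.zeros(parts.n_partitions, dtype=bool)
    for ell in range(parts.n_partitions):
        idx = parts.site_indices(ell)
        part_of[idx] = ell
        bundle = builder.bundle(ell)
        Xl = X[:, idx]
        if design == "local-only":
            p_loc, b_loc = _added_column_pvalues(y, bundle.W_local, Xl)
            p_global[idx] = p_glocal[idx] = p_loc
            beta_g[idx] = beta_gl[idx] = b_loc
            continue
        pg, bg = _added_column_pvalues(y, bundle.W_global, Xl)
        pgl, bgl = _added_column_pvalues(y, bundle.W_glocal, Xl)
        p_global[idx], beta_g[idx] = pg, bg
        p_glocal[idx], beta_gl[idx] = pgl, bgl
        if rule == "forward":
            null_g = fit_ml(y, bundle.W_global, design="global")
            null_gl = fit_ml(y, bundle.W_glocal, design="glocal")
            adopt_local[ell] = lrt_pvalue(null_gl, null_g) < FORWARD_ALPHA

    if rule == "minp":
        use_glocal = p_glocal < p_global
    else:
        use_glocal = adopt_local[part_of]
    p_value = np.where(use_glocal, p_glocal, p_global)
    beta = np.where(use_glocal, beta_gl, beta_g)
    selected = np.where(use_glocal, "glocal", "global")
    if design == "local-only":
        selected = np.full(k, "local")
    return pd.DataFrame(
        {
            "site": np.arange(k),
            "site_id": aln.site_ids,
            "partition_id": part_of,
            "p_global": p_global,
            "p_glocal": p_glocal,
            "p_value": p_value,
            "selected_model": selected,
            "beta_hat": beta,
            "selection_rule": rule,
        }
    )


def eigenstrat_scores(
    aln: HaploidAlignment, y: np.ndarray, n_pcs: int = 10,
    lambda_gc: bool = False,
) -> np.ndarray:
    """EIGENSTRAT-style p-values for every SNP (vectorized).

    ``lambda_gc=True`` additionally applies genomic control: the
    chi-square statistics are divided by the inflation factor
    ``lambda = median(stat) / 0.4549`` (the chi-square-1 median) before
    the p-values are computed.  Off by default; note that per-dataset
    rescaling makes p-values incomparable across pooled replicates.
    """
    y = np.asarray(y, dtype=float).ravel()
    pcs = full_alignment_pcs(aln, n_pcs)
    n = y.size
    K = pcs.shape[1]
    D = np.column_stack([np.ones(n), pcs])
    q, _ = np.linalg.qr(D)
    ry = y - q @ (q.T @ y)
    X = aln.genotypes.astype(float)
    RX = X - q @ (q.T @ X)
    ry_norm = np.linalg.norm(ry)
    rx_norm = np.sqrt(np.einsum("ij,ij->j", RX, RX))
    denom = ry_norm * rx_norm
    tiny = denom <= _RANK_TOL
    denom = np.where(tiny, 1.0, denom)
    r = (ry @ RX) / denom
    stat = (n - K - 1) * r * r
    if lambda_gc:
        lam = max(float(np.median(stat)) / stats.chi2.median(1), 1.0)
        stat = stat / lam
    p = stats.chi2.sf(stat, 1)
    return np.where(tiny, 1.0, p)
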