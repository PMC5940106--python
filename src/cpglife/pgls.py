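"""Phylogenetic generalized least squares with Pagel's λ estimated by ML.

The regression model for one locus is

    y = α + β x + ε,    ε ~ N(0, σ² V(λ)),

where y is log maximum lifespan, x is promoter CpG density, and V(λ) is the
phylogenetic covariance matrix: V_ii is the root-to-tip path length of
species i, V_ij the root-to-MRCA path length of i and j, with off-diagonals
multiplied by Pagel's λ ∈ [0, 1].  λ = 0 recovers ordinary least squares
(phylogenetic independence); λ = 1 is pure Brownian motion.

λ is estimated by profiling the ML log-likelihood over [0, 1] (coarse grid
then Brent refinement).  σ² uses the ML (divide-by-n) scale inside the
profile; the slope standard error uses the df-corrected (n−2) scale so the
t-test keeps its classical degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.stats

from .io_formats import Phylogeny

logger = logging.getLogger(__name__)

#: condition-number limit beyond which a one-shot diagonal jitter is applied
COND_LIMIT = 1e12
JITTER_SCALE = 1e-10
#: a λ profile flatter than this (max − min log-likelihood) is reported flat
FLAT_PROFILE_TOL = 1e-6

LAMBDA_GRID = np.linspace(0.0, 1.0, 21)


class UnfitLocusError(ValueError):
    """The locus cannot be fit (singular covariance or degenerate predictor)."""


@dataclass
class PhyloCov:
    """Tip covariance matrix for an ordered species list.

    ``C[i, j]`` is the shared root-to-MRCA path length of species i and j;
    the diagonal holds root-to-tip path lengths.
    """

    species: list[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.species)
        if self.C.shape != (n, n):
            raise ValueError("covariance shape does not match species list")


@dataclass
class PGLSFit:
    """Slope inference for one locus at the profiled λ."""

    slope: float
    intercept: float
    se_slope: float
    t: float
    p: float
    df: int
    lam: float
    sigma2: float          # ML-scale residual variance
    loglik: float
    n: int
    boundary_flag: str     # interior | at0 | at1 | flat
    degenerate: bool = False
    pearson_r: float = float("nan")   # naive (non-phylogenetic) diagnostic
    pearson_p: float = float("nan")


def phylo_cov(phylo: Phylogeny, species: Sequence[str]) -> PhyloCov:
    """Tip covariance matrix for ``species``, restricted from the full tree.

    C_ii is the root-to-tip path length of species i in the source tree and
    C_ij the root-to-MRCA(i, j) path length, so the matrix for a subset of
    tips is simply the corresponding submatrix of the full-tree covariance.
    Species absent from the tree are reported together in one error; fewer
    than two species leaves no covariance to define.
    """
    species = list(species)
    if len(species) < 2:
        raise ValueError("need at least 2 species for a phylogenetic covariance")
    if len(set(species)) != len(species):
        raise ValueError("duplicate species in requested order")
    tip_set = set(phylo.tip_labels)
    missing = [sp for sp in species if sp not in tip_set]
    if missing:
        raise ValueError(f"species absent from tree: {missing}")

    tree = phylo.tree
    index = {sp: i for i, sp in enumerate(species)}
    n = len(species)
    C = np.zeros((n, n))

    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    # leaf index sets per node, postorder; C_ij = depth of MRCA(i, j)
    leafsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label in index:
                i = index[label]
                C[i, i] = depth[id(node)]
                leafsets[id(node)] = [i]
            else:
                leafsets[id(node)] = []
            continue
        children = [leafsets[id(ch)] for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        C[i, j] = d
                        C[j, i] = d
        leafsets[id(node)] = [i for ch in children for i in ch]
    return PhyloCov(species=species, C=C)


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Multiply off-diagonal entries of C by λ, leaving the diagonal alone."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda {lam} outside [0, 1]")
    C = np.asarray(C, dtype=float)
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _cholesky_with_jitter(V: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of V, with a single diagonal jitter retry.

    Conditioning is judged from the Cholesky diagonal (cond(V) is at least
    the squared ratio of its extreme entries — cheap, no SVD); a factor
    failing that bound, or a failed factorization, triggers one jitter of
    1e-10·mean(diag) before the locus is declared unfit.
    """
    try:
        L = scipy.linalg.cholesky(V, lower=True)
        d = np.diag(L)
        if (d.max() / d.min()) ** 2 <= COND_LIMIT:
            return L
    except scipy.linalg.LinAlgError:
        pass
    Vj = V + JITTER_SCALE * np.mean(np.diag(V)) * np.eye(V.shape[0])
    try:
        return scipy.linalg.cholesky(Vj, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise UnfitLocusError("covariance matrix singular even after jitter") from exc


def gls_fit(
    y: np.ndarray, x: np.ndarray, V: np.ndarray
) -> PGLSFit:
    """Exact GLS of y on [1, x] with error covariance σ²V.

    Solved by whitening with the Cholesky factor of V (numerically stable;
    agrees with the explicit-inverse estimator β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y).
    σ̂² is ML-scale (divide by n); the slope SE uses the n−2 scale.  The
    log-likelihood is −½(n·log(2πσ̂²) + log|V| + n).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if x.size != n or V.shape != (n, n):
        raise ValueError("y, x and V dimensions disagree")
    if n < 3:
        raise ValueError("need at least 3 observations for a slope test")
    if np.ptp(x) == 0.0:
        raise UnfitLocusError("zero variance in predictor: slope undefined")

    L = _cholesky_with_jitter(V)
    X = np.column_stack([np.ones(n), x])
    Xw = scipy.linalg.solve_triangular(L, X, lower=True)
    yw = scipy.linalg.solve_triangular(L, y, lower=True)

    XtX = Xw.T @ Xw
    beta = scipy.linalg.solve(XtX, Xw.T @ yw, assume_a="pos")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)

    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    sigma2_ml = rss / n
    degenerate = sigma2_ml <= 0.0 or not np.isfinite(sigma2_ml)
    if degenerate or sigma2_ml < 1e-300:
        # perfect fit: slope is exact, no sampling error to report
        loglik = math.inf
        se = 0.0
        t_stat = math.inf if beta[1] != 0 else 0.0
        p = 0.0 if beta[1] != 0 else 1.0
        sigma2_ml = max(sigma2_ml, 0.0)
        degenerate = True
    else:
        loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2_ml) + logdetV + n)
        sigma2_df = rss / (n - 2)
        cov_beta = sigma2_df * scipy.linalg.inv(XtX)
        se = math.sqrt(cov_beta[1, 1])
        t_stat = beta[1] / se
        p = 2.0 * scipy.stats.t.sf(abs(t_stat), df=n - 2)
        p = min(max(p, np.finfo(float).tiny), 1.0)

    return PGLSFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        se_slope=float(se),
        t=float(t_stat),
        p=float(p),
        df=n - 2,
        lam=float("nan"),
        sigma2=float(sigma2_ml),
        loglik=float(loglik),
        n=n,
        boundary_flag="interior",
        degenerate=degenerate,
    )


def profile_lambda_ml(
    y: np.ndarray, x: np.ndarray, C: np.ndarray
) -> PGLSFit:
    """Maximize the GLS log-likelihood over λ ∈ [0, 1].

    A 21-point grid locates the best cell, then bounded Brent refines within
    the neighbouring cells.  A profile flatter than ``FLAT_PROFILE_TOL``
    (e.g. a star phylogeny, where λ has no effect) reports λ̂ = 1 with
    flag ``flat``; maxima within 1e-6 of the bounds flag ``at0``/``at1``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    C = np.asarray(C, dtype=float)

    def loglik_at(lam: float) -> float:
        return gls_fit(y, x, lambda_transform(C, lam)).loglik

    grid_ll = np.array([loglik_at(lam) for lam in LAMBDA_GRID])
    if np.any(np.isinf(grid_ll)):
        # degenerate (perfect) fit somewhere: report at the first such λ
        lam_hat = float(LAMBDA_GRID[int(np.argmax(np.isinf(grid_ll)))])
        fit = gls_fit(y, x, lambda_transform(C, lam_hat))
        fit.lam = lam_hat
        fit.boundary_flag = "flat"
        return fit

    if float(grid_ll.max() - grid_ll.min()) < FLAT_PROFILE_TOL:
        lam_hat = 1.0
        flag = "flat"
    else:
        k = int(np.argmax(grid_ll))
        lo = LAMBDA_GRID[max(k - 1, 0)]
        hi = LAMBDA_GRID[min(k + 1, len(LAMBDA_GRID) - 1)]
        if lo == hi:
            lam_hat = float(lo)
        else:
            res = scipy.optimize.minimize_scalar(
                lambda lam: -loglik_at(lam),
                bounds=(float(lo), float(hi)),
                method="bounded",
                options={"xatol": 1e-8},
            )
            lam_hat = float(res.x)
            # Brent can return a hair worse than the grid point; keep the best
            if loglik_at(lam_hat) < grid_ll[k]:
                lam_hat = float(LAMBDA_GRID[k])
        if lam_hat < 1e-6:
            lam_hat, flag = 0.0, "at0"
        elif lam_hat > 1.0 - 1e-6:
            lam_hat, flag = 1.0, "at1"
        else:
            flag = "interior"

    fit = gls_fit(y, x, lambda_transform(C, lam_hat))
    fit.lam = lam_hat
    fit.boundary_flag = flag
    return fit


@dataclass
class SkippedLocus:
    """Placeholder for a locus that could not be fit, with the reason."""

    n: int
    reason: str


def pgls(
    pairs: Mapping[str, tuple[float, float]],
    phylo: Phylogeny,
    min_n: int = 5,
    lam: float | None = None,
) -> PGLSFit | SkippedLocus:
    """Fit log(lifespan) ~ CpG density for one locus under PGLS.

    ``pairs`` maps species → (cpg_density, lifespan_yrs); only species that
    are also tips of the tree are used (complete cases).  ``lam=None``
    profiles λ by ML; a fixed value skips the profile.  Loci with fewer than
    ``min_n`` complete cases, a constant predictor, or a singular covariance
    come back as :class:`SkippedLocus` rather than raising.
    """
    tips = set(phylo.tip_labels)
    species = sorted(sp for sp in pairs if sp in tips)
    n = len(species)
    if n < min_n or n < 3:
        return SkippedLocus(n=n, reason="too-few-species")

    x = np.array([pairs[sp][0] for sp in species])
    y = np.log(np.array([pairs[sp][1] for sp in species]))
    if np.any(~np.isfinite(y)):
        return SkippedLocus(n=n, reason="nonpositive-lifespan")

    cov = phylo_cov(phylo, species)
    try:
        if lam is None:
            fit = profile_lambda_ml(y, x, cov.C)
        else:
            fit = gls_fit(y, x, lambda_transform(cov.C, lam))
            fit.lam = lam
    except UnfitLocusError as exc:
        return SkippedLocus(n=n, reason=str(exc))

    if n >= 3 and np.ptp(x) > 0:
        r, rp = scipy.stats.pearsonr(x, y)
        fit.pearson_r = float(r)
        fit.pearson_p = float(rp)
    return fit
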