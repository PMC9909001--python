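"""Phylogenetic generalized least squares with Pagel's lambda.

Shared ancestry makes species non-independent: under Brownian motion a
trait's covariance between two tips equals the branch length they share
from the root to their most recent common ancestor.  PGLS puts that matrix
C in the regression error term, scaled by Pagel's lambda, which multiplies
the off-diagonal entries and interpolates between independence (lambda = 0)
and the full Brownian expectation (lambda = 1).  Models are fit by maximum
likelihood: sigma^2 and the coefficients are profiled out analytically, and
lambda is optimized by a one-dimensional grid-plus-refinement search.

Trees are read with dendropy; everything downstream of the Newick text
(covariances, the lambda transform, the GLS machinery, likelihoods, AICc,
R^2 and the phylogenetic-signal test) is implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from scipy import optimize, stats
from scipy.linalg import solve_triangular

__all__ = [
    "Phylogeny",
    "PGLSFit",
    "parse_newick",
    "phylo_covariance",
    "lambda_transform",
    "gls_fit",
    "pgls_ml",
    "aicc",
    "pgls_r2",
    "phylo_signal_lambda",
]

#: tolerance on the lambda line search
_LAMBDA_TOL = 1e-6
#: grid resolution for the initial lambda profile scan
_LAMBDA_GRID = 101
#: relative root-to-tip depth spread above which a tree is flagged non-ultrametric
_ULTRAMETRIC_TOL = 0.01


def normalize_taxon(name: str) -> str:
    """Unify tree and table taxon spellings: spaces -> underscores, trimmed."""
    return name.strip().replace(" ", "_")


class Phylogeny:
    """A rooted, time-calibrated tree wrapping a dendropy ``Tree``.

    Tip labels are normalized on construction and must be unique.  Branch
    lengths are in time units; a warning is emitted if root-to-tip depths
    spread by more than 1% (the covariance construction still works, but an
    ultrametric tree is the intended input).
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None:
                raise ValueError("tree has an unlabeled tip")
            label = normalize_taxon(leaf.taxon.label)
            leaf.taxon.label = label
            labels.append(label)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("tree has edges without branch lengths")
            if edge.length < 0:
                raise ValueError("negative branch length")
        self.taxa: list[str] = sorted(labels)
        depths = np.array(list(self.tip_depths().values()))
        span = depths.max() - depths.min()
        if depths.max() > 0 and span / depths.max() > _ULTRAMETRIC_TOL:
            warnings.warn(
                f"tree is not ultrametric: root-to-tip depths span "
                f"[{depths.min():.6g}, {depths.max():.6g}]",
                stacklevel=3,
            )

    def __len__(self) -> int:
        return len(self.taxa)

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per taxon."""
        out = {}
        for leaf in self._tree.leaf_node_iter():
            out[leaf.taxon.label] = leaf.distance_from_root()
        return out

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (or file-like content) into a :class:`Phylogeny`."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def check_taxa_match(tree: Phylogeny, table_taxa: Sequence[str]) -> list[str]:
    """Validate tree/table taxon agreement; returns the normalized table order.

    Raises with the two set differences spelled out on any mismatch.
    """
    table_norm = [normalize_taxon(t) for t in table_taxa]
    tree_set, table_set = set(tree.taxa), set(table_norm)
    if tree_set != table_set:
        raise ValueError(
            "tree/table taxon mismatch: "
            f"only in tree: {sorted(tree_set - table_set)}; "
            f"only in table: {sorted(table_set - tree_set)}"
        )
    return table_norm


def phylo_covariance(
    tree: Phylogeny, order: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix from shared branch lengths.

    ``C[i, j]`` is the summed branch length from the root to the most recent
    common ancestor of tips i and j; the diagonal holds tip depths.  Computed
    in one preorder sweep: each internal node at depth d is the MRCA of every
    tip pair split across its children.
    """
    taxa = list(order) if order is not None else tree.taxa
    taxa = [normalize_taxon(t) for t in taxa]
    check_taxa_match(tree, taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))

    dtree = tree.dendropy_tree
    # leaf index sets and node depths, bottom-up
    leafsets: dict = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = [idx[node.taxon.label]]
        else:
            leafsets[node] = [i for ch in node.child_nodes() for i in leafsets[ch]]

    for node in dtree.preorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            C[i, i] = node.distance_from_root()
            continue
        d = node.distance_from_root()
        children = node.child_nodes()
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in leafsets[children[a]]:
                    for j in leafsets[children[b]]:
                        C[i, j] = C[j, i] = d
    return C, taxa


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal covariances by Pagel's lambda; diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


# ---------------------------------------------------------------------------
# GLS machinery


@dataclass(frozen=True)
class GLSResult:
    beta: np.ndarray       # coefficient estimates
    se: np.ndarray         # standard errors (unbiased sigma^2, df = n - p)
    sigma2_ml: float       # ML residual variance (n denominator)
    loglik: float          # maximized log-likelihood (beta, sigma2 profiled)
    rss: float             # whitened residual sum of squares
    df_resid: int


def gls_fit(X: np.ndarray, y: np.ndarray, V: np.ndarray) -> GLSResult:
    """Generalized least squares with error covariance proportional to V.

    beta-hat = (X' V^-1 X)^-1 X' V^-1 y, computed on the Cholesky-whitened
    scale; sigma^2 is the ML estimate RSS/n, and the log-likelihood is that
    of the multivariate normal N(X beta-hat, sigma^2 V).  Standard errors
    use the unbiased variance RSS/(n - p) so that t-tests have their usual
    small-sample behavior.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"X has {n} rows but y has {len(y)}")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than coefficients ({p})")

    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)

    rank = np.linalg.matrix_rank(Xw)
    if rank < p:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {p} columns)"
        )

    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2_ml <= 0:
        sigma2_ml = np.finfo(float).tiny
    loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2_ml) + n + logdetV)

    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    sigma2_unbiased = rss / (n - p) if n > p else np.nan
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2_unbiased, 0.0))
    return GLSResult(
        beta=beta, se=se, sigma2_ml=sigma2_ml, loglik=loglik, rss=rss,
        df_resid=n - p,
    )


@dataclass
class PGLSFit:
    """One fitted PGLS model."""

    terms: tuple[str, ...]          # design column names, intercept first
    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray            # two-sided t-tests, df = n - p
    lambda_: float
    sigma2: float                   # ML residual variance
    loglik: float
    k: int                          # parameters counted for AICc
    n: int
    aicc: float
    rss: float                      # whitened residual sum of squares
    r2: float = np.nan
    formula: str = ""

    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.terms, self.beta))


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _profile_loglik(lam: float, X: np.ndarray, y: np.ndarray, C: np.ndarray) -> float:
    return gls_fit(X, y, lambda_transform(C, lam)).loglik


def optimize_lambda(
    X: np.ndarray, y: np.ndarray, C: np.ndarray
) -> tuple[float, float]:
    """Maximize the profile log-likelihood over lambda in [0, 1].

    Grid scan (101 points) followed by bounded scalar refinement around the
    best grid point; deterministic for fixed inputs.  Returns (lambda-hat,
    profile log-likelihood at lambda-hat).  Boundary optima are legitimate
    results, not errors.
    """
    grid = np.linspace(0.0, 1.0, _LAMBDA_GRID)
    lls = np.array([_profile_loglik(g, X, y, C) for g in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    best_lam, best_ll = grid[i], lls[i]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda lam: -_profile_loglik(lam, X, y, C),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": _LAMBDA_TOL},
        )
        if -res.fun >= best_ll:
            best_lam, best_ll = float(res.x), float(-res.fun)
    return best_lam, best_ll


def pgls_ml(
    X: np.ndarray,
    y: np.ndarray,
    C: np.ndarray,
    terms: Sequence[str] | None = None,
    count_lambda: bool = True,
) -> PGLSFit:
    """Fit a PGLS model by maximum likelihood, estimating lambda.

    ``k`` for AICc counts the regression coefficients plus sigma^2 plus
    (when ``count_lambda``) the fitted lambda; counting lambda keeps model
    comparison honest when every candidate re-estimates it.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError(
            f"lambda is unidentifiable with n={n} taxa; need at least 3"
        )
    lam, _ = optimize_lambda(X, y, C)
    res = gls_fit(X, y, lambda_transform(C, lam))
    k = p + 1 + (1 if count_lambda else 0)
    tvals = np.divide(
        res.beta, res.se, out=np.full_like(res.beta, np.nan), where=res.se > 0
    )
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=res.df_resid)
    if terms is None:
        terms = tuple(f"x{i}" for i in range(p))
    fit = PGLSFit(
        terms=tuple(terms),
        beta=res.beta,
        se=res.se,
        p_values=pvals,
        lambda_=lam,
        sigma2=res.sigma2_ml,
        loglik=res.loglik,
        k=k,
        n=n,
        aicc=aicc(res.loglik, k, n),
        rss=res.rss,
    )
    fit.r2 = pgls_r2(fit, y, C)
    fit.formula = " + ".join(t for t in fit.terms if t != "Intercept") or "1"
    return fit


def pgls_r2(fit: PGLSFit, y: np.ndarray, C: np.ndarray) -> float:
    """R^2 = 1 - RSS_model / SS_null.

    SS_null is the whitened residual sum of squares of an intercept-only
    GLS sharing the model's fitted lambda (the same correlation structure),
    so an intercept-only model scores exactly zero.
    """
    y = np.asarray(y, dtype=float).ravel()
    V = lambda_transform(C, fit.lambda_)
    null = gls_fit(np.ones((len(y), 1)), y, V)
    if null.rss == 0.0:
        return np.nan
    return 1.0 - fit.rss / null.rss


def phylo_signal_lambda(
    y: np.ndarray, C: np.ndarray
) -> tuple[float, float, float, float]:
    """Phylogenetic signal in a trait via Pagel's lambda.

    Fits an intercept-only PGLS by ML and compares against the lambda = 0
    (independence) fit with a likelihood-ratio test.  Because lambda = 0 sits
    on the boundary of its range, the null distribution is the 50:50 mixture
    of a point mass at zero and chi-square with 1 df.

    Returns ``(lambda_hat, loglik_at_hat, LR, p_value)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 10:
        warnings.warn(f"phylogenetic signal with n={n} < 10 is poorly powered",
                      stacklevel=2)
    X = np.ones((n, 1))
    lam, ll = optimize_lambda(X, y, C)
    ll0 = gls_fit(X, y, lambda_transform(C, 0.0)).loglik
    lr = max(0.0, 2.0 * (ll - ll0))
    p = 1.0 if lr == 0.0 else 0.5 * float(stats.chi2.sf(lr, df=1))
    return lam, ll, lr, p
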