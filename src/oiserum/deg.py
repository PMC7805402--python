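"""Vote-based paired differential expression and its companions.

The selection rule is a per-cell-line ballot run separately for the two
directions of change. For every gene and every cell line the paired
log2-scale difference d = post - basal is computed on quantile-normalized,
log2(x+1)-transformed expression. In the *up* direction a line votes "for"
when d > +theta_vote and "against" when d < -theta_vote (lines inside the
dead band abstain); the *down* direction mirrors this. A gene is selected in
a direction when it collects at least ``min_votes`` "for" votes and its
one-tailed paired t-test (in that direction, across lines) gives p < alpha.
Selected genes are ranked by ascending p.

The module also carries the standard companions of that analysis: quantile
normalization, the log2(x+1) stabilization, highly-variable gene selection,
UPGMA/Euclidean sample clustering and a centered sample PCA.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionMatrix

__all__ = [
    "VoteConfig",
    "QuantileNormalizer",
    "DemocraticVoteSelector",
    "quantile_normalize",
    "log2p1",
    "democratic_vote",
    "paired_t",
    "select_highly_variable",
    "upgma_cluster",
    "Dendrogram",
    "pca_scores",
    "PCAResult",
]

UP, DOWN, NONE = "up", "down", "none"


@dataclass
class VoteConfig:
    """Parameters of the vote selector.

    theta_vote : dead-band half width in log2 units (default 0.1); a line
        only casts a vote when |post - basal| exceeds it.
    min_votes : "for" votes required for selection (default 9, of 10 lines).
    alpha : one-tailed paired-t significance threshold (default 0.05).
    """

    theta_vote: float = 0.1
    min_votes: int = 9
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.theta_vote > 0:
            raise ValueError("theta_vote must be > 0")
        if not self.min_votes > 0:
            raise ValueError("min_votes must be a positive integer")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


# ---------------------------------------------------------------------------
# quantile normalization / log transform
# ---------------------------------------------------------------------------

class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalization: every sample shares the mean empirical distribution.

    sklearn layout: X is (n_samples, n_genes); ``fit`` stores the per-rank
    cross-sample mean of the sorted rows, ``transform`` replaces each row's
    values by the reference value of their within-row rank. Tied values
    receive the mean of the reference values of their tied ranks, which keeps
    the map deterministic.
    """

    def fit(self, X, y=None):
        X = self._check(X)
        if X.shape[0] < 1:
            raise ValueError("need at least one sample")
        self.n_features_in_ = X.shape[1]
        self.reference_distribution_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_distribution_")
        X = self._check(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        ref = self.reference_distribution_
        out = np.empty_like(X)
        for i, row in enumerate(X):
            order = np.argsort(row, kind="stable")
            assigned = np.empty_like(ref)
            assigned[order] = ref
            # ties: mean of the reference values mapped to the tied positions
            uniq, inverse, counts = np.unique(row, return_inverse=True, return_counts=True)
            if len(uniq) < len(row):
                sums = np.bincount(inverse, weights=assigned)
                assigned = (sums / counts)[inverse]
            out[i] = assigned
        return out

    @staticmethod
    def _check(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.size == 0:
            raise ValueError("X must be a non-empty 2-D array")
        if np.isnan(X).any():
            raise ValueError("X contains NaN")
        return X


def _frame(m) -> tuple[pd.DataFrame, ExpressionMatrix | None]:
    if isinstance(m, ExpressionMatrix):
        return m.values, m
    if isinstance(m, pd.DataFrame):
        return m, None
    raise TypeError("expected an ExpressionMatrix or DataFrame")


def _rewrap(values: pd.DataFrame, src: ExpressionMatrix | None):
    return src.with_values(values) if src is not None else values


def quantile_normalize(m):
    """Quantile-normalize sample columns of a genes x samples matrix.

    Accepts an :class:`ExpressionMatrix` or a plain DataFrame and returns the
    same kind. A single-sample matrix is returned unchanged.
    """
    values, src = _frame(m)
    if values.shape[1] == 1:
        return _rewrap(values.copy(), src)
    qn = QuantileNormalizer().fit(values.to_numpy().T)
    out = pd.DataFrame(qn.transform(values.to_numpy().T).T,
                       index=values.index, columns=values.columns)
    return _rewrap(out, src)


def log2p1(m):
    """Variance-stabilize expression as log2(x + 1); rejects negative input."""
    values, src = _frame(m)
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("log2p1 requires non-negative values")
    out = pd.DataFrame(np.log2(arr + 1.0), index=values.index, columns=values.columns)
    return _rewrap(out, src)


# ---------------------------------------------------------------------------
# paired t statistics
# ---------------------------------------------------------------------------

def _paired_t_rows(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise paired t on difference rows; returns (t, p_up, p_down).

    Zero-variance rows: all-zero differences give the symmetric null
    (t=0, p=0.5 both tails); a constant non-zero difference has no defined t
    and is flagged for exclusion with p=1 in both tails.
    """
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n = diffs.shape[1]
    if n < 2:
        raise ValueError("paired t needs at least two pairs")
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    t = np.full(len(diffs), np.nan)
    p_up = np.ones(len(diffs))
    p_down = np.ones(len(diffs))
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p_up[ok] = stats.t.sf(t[ok], df=n - 1)
    p_down[ok] = stats.t.cdf(t[ok], df=n - 1)
    zero_null = (~ok) & (mean == 0)
    t[zero_null] = 0.0
    p_up[zero_null] = 0.5
    p_down[zero_null] = 0.5
    return t, p_up, p_down


def paired_t(values_basal, values_post, alternative: str = "greater") -> tuple[float, float]:
    """One-tailed paired t-test on post - basal differences.

    ``alternative="greater"`` tests upregulation after treatment,
    ``"less"`` downregulation. Returns (t_statistic, p_value).
    """
    basal = np.asarray(values_basal, dtype=float)
    post = np.asarray(values_post, dtype=float)
    if basal.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    t, p_up, p_down = _paired_t_rows((post - basal)[None, :])
    if alternative == "greater":
        return float(t[0]), float(p_up[0])
    if alternative == "less":
        return float(t[0]), float(p_down[0])
    raise ValueError("alternative must be 'greater' or 'less'")


# ---------------------------------------------------------------------------
# the vote selector
# ---------------------------------------------------------------------------

class DemocraticVoteSelector(SelectorMixin, BaseEstimator):
    """Per-line vote selection of differentially expressed genes.

    sklearn layout: X is (n_samples, n_genes) of already quantile-normalized,
    log2(x+1)-transformed expression; ``y`` gives each sample's condition
    ("basal"/"post") and ``groups`` its cell line. Genes are the features;
    after ``fit`` the selector exposes per-gene ballots and supports
    ``transform``/``get_support`` like any sklearn feature selector.

    Attributes (per gene): ``votes_for_up_``, ``votes_against_up_``,
    ``votes_for_down_``, ``votes_against_down_``, ``t_statistic_``,
    ``p_value_up_``, ``p_value_down_``, ``selected_direction_``,
    ``p_value_`` (tested direction), ``rank_`` (1..n_selected by ascending p,
    NaN when unselected).
    """

    def __init__(self, theta_vote: float = 0.1, min_votes: int = 9, alpha: float = 0.05):
        self.theta_vote = theta_vote
        self.min_votes = min_votes
        self.alpha = alpha

    def fit(self, X, y, groups=None):
        cfg = VoteConfig(self.theta_vote, self.min_votes, self.alpha)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x genes)")
        y = np.asarray(y)
        if groups is None:
            raise ValueError("groups (cell-line ids) are required")
        groups = np.asarray(groups)
        if len(y) != X.shape[0] or len(groups) != X.shape[0]:
            raise ValueError("y and groups must match the number of samples")

        basal_idx, post_idx = {}, {}
        for i, (cond, line) in enumerate(zip(y, groups)):
            if cond == "basal":
                if line in basal_idx:
                    raise ValueError(f"line {line!r} has more than one basal sample")
                basal_idx[line] = i
            elif cond == "post":
                if line in post_idx:
                    raise ValueError(f"line {line!r} has more than one post sample")
                post_idx[line] = i
            else:
                raise ValueError(f"unknown condition {cond!r}")
        lines = sorted(set(groups), key=str)
        missing = [str(l) for l in lines if l not in basal_idx or l not in post_idx]
        if missing:
            raise ValueError(f"lines missing a pair member: {missing}")
        n_lines = len(lines)
        if cfg.min_votes > n_lines:
            raise ValueError(f"min_votes={cfg.min_votes} exceeds the {n_lines} available lines")

        # genes x lines matrix of paired log2 differences
        D = np.stack([X[post_idx[l]] - X[basal_idx[l]] for l in lines], axis=1)

        up_for = (D > cfg.theta_vote).sum(axis=1)
        up_against = (D < -cfg.theta_vote).sum(axis=1)
        t, p_up, p_down = _paired_t_rows(D)

        sel_up = (up_for >= cfg.min_votes) & (p_up < cfg.alpha)
        sel_down = (up_against >= cfg.min_votes) & (p_down < cfg.alpha)

        n_genes = X.shape[1]
        direction = np.array([NONE] * n_genes, dtype=object)
        direction[sel_up] = UP
        direction[sel_down] = DOWN
        both = sel_up & sel_down  # possible only when min_votes <= n_lines / 2
        for g in np.nonzero(both)[0]:
            if up_for[g] != up_against[g]:
                direction[g] = UP if up_for[g] > up_against[g] else DOWN
            else:
                direction[g] = UP if p_up[g] <= p_down[g] else DOWN

        # p in the direction under test: the better-voted one (ties: smaller p)
        p_tested = np.where(
            up_for > up_against, p_up,
            np.where(up_against > up_for, p_down, np.minimum(p_up, p_down)),
        )
        p_tested = np.where(direction == UP, p_up, p_tested)
        p_tested = np.where(direction == DOWN, p_down, p_tested)

        support = direction != NONE
        rank = np.full(n_genes, np.nan)
        sel = np.nonzero(support)[0]
        order = sel[np.lexsort((sel, p_tested[sel]))]
        rank[order] = np.arange(1, len(order) + 1)

        self.n_features_in_ = n_genes
        self.n_lines_ = n_lines
        self.line_ids_ = lines
        self.differences_ = D
        self.votes_for_up_ = up_for
        self.votes_against_up_ = up_against
        self.votes_for_down_ = up_against.copy()
        self.votes_against_down_ = up_for.copy()
        self.t_statistic_ = t
        self.p_value_up_ = p_up
        self.p_value_down_ = p_down
        self.selected_direction_ = direction
        self.p_value_ = p_tested
        self.rank_ = rank
        self.support_ = support
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


def democratic_vote(m: ExpressionMatrix, cfg: VoteConfig | None = None) -> pd.DataFrame:
    """Run the vote selector on a paired matrix; returns the per-gene ballot.

    ``m`` must already be quantile-normalized and log2(x+1)-transformed and
    must carry full pairing metadata. Columns of the result: votes_for_up,
    votes_against_up, votes_for_down, votes_against_down, direction, t, p,
    rank (rank is NaN for unselected genes).
    """
    cfg = cfg or VoteConfig()
    if not isinstance(m, ExpressionMatrix) or m.pairing is None:
        raise ValueError("democratic_vote needs an ExpressionMatrix with pairing")
    y = m.pairing.loc[m.sample_ids, "condition"].to_numpy()
    groups = m.pairing.loc[m.sample_ids, "line_id"].to_numpy()
    sel = DemocraticVoteSelector(cfg.theta_vote, cfg.min_votes, cfg.alpha)
    sel.fit(m.values.to_numpy().T, y, groups=groups)
    return pd.DataFrame(
        {
            "votes_for_up": sel.votes_for_up_,
            "votes_against_up": sel.votes_against_up_,
            "votes_for_down": sel.votes_for_down_,
            "votes_against_down": sel.votes_against_down_,
            "direction": sel.selected_direction_,
            "t": sel.t_statistic_,
            "p": sel.p_value_,
            "rank": sel.rank_,
        },
        index=m.values.index,
    )


# ---------------------------------------------------------------------------
# companions: highly variable genes, UPGMA, PCA
# ---------------------------------------------------------------------------

def select_highly_variable(m, k: int) -> list[str]:
    """The k genes of largest cross-sample variance, ties broken by gene id."""
    values, _ = _frame(m)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > values.shape[0]:
        raise ValueError("k exceeds the number of genes")
    var = values.var(axis=1, ddof=1) if values.shape[1] > 1 else values.var(axis=1, ddof=0)
    tab = pd.DataFrame({"var": var, "gene": values.index.astype(str)})
    tab = tab.sort_values(["var", "gene"], ascending=[False, True], kind="stable")
    return tab.index[:k].tolist()


@dataclass
class Dendrogram:
    """UPGMA tree over samples: a scipy linkage matrix plus the leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.left), walk(node.right)
            bl = node.dist - node.left.dist
            br = node.dist - node.right.dist
            return f"({left}:{bl:g},{right}:{br:g})"

        return walk(tree) + ";"


def upgma_cluster(m) -> Dendrogram:
    """UPGMA (average-linkage) clustering of sample columns, Euclidean distance."""
    values, _ = _frame(m)
    if values.shape[1] < 2:
        raise ValueError("clustering needs at least two samples")
    Z = linkage(values.to_numpy().T, method="average", metric="euclidean")
    return Dendrogram(linkage=Z, labels=[str(c) for c in values.columns])


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # genes x components
    explained_variance: np.ndarray  # descending


def pca_scores(m, n_components: int | None = None) -> PCAResult:
    """Centered PCA of the sample columns.

    Samples are the observations (centered across samples); component
    variances come out descending and each component's sign is fixed so its
    largest-magnitude gene loading is positive.
    """
    values, _ = _frame(m)
    if values.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    A = values.to_numpy().T  # samples x genes
    A = A - A.mean(axis=0, keepdims=True)
    if not (A != 0).any():
        raise ValueError("constant matrix has no principal components")
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    k = min(n_components or len(S), len(S))
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    comp = [f"PC{j + 1}" for j in range(k)]
    scores = pd.DataFrame(U * S, index=values.columns, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=values.index, columns=comp)
    explained = S**2 / max(A.shape[0] - 1, 1)
    return PCAResult(scores=scores, loadings=loadings, explained_variance=explained)
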