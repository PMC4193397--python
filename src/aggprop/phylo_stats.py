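"""Comparative statistics: Kendall correlation, Felsenstein independent
contrasts, through-origin contrast correlation, ANCOVA with habitat
interaction, and the Mann-Whitney test.

All tests here are implemented directly (not wrapped) so they can be checked
against independent oracles; scipy/statsmodels are used in the test suite as
the second route, never here.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Kendall tau-b
# --------------------------------------------------------------------------


def _tau_b_statistic(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    prod = dx[iu] * dy[iu]
    concordant_minus_discordant = prod.sum()
    tie_x = int((dx[iu] == 0).sum())
    tie_y = int((dy[iu] == 0).sum())
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - tie_x) * (n0 - tie_y))
    if denom == 0:
        raise ValueError("tau undefined: a vector is completely tied")
    return float(concordant_minus_discordant / denom)


def kendall_tau(
    x: Sequence[float], y: Sequence[float], exact_n: int = 8
) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b with a two-sided p-value.

    For n <= ``exact_n`` the p-value enumerates all permutations of y against
    x (exact even with ties); otherwise the normal approximation with tie
    correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    tau = _tau_b_statistic(x, y)

    if n <= exact_n:
        observed = abs(tau)
        count = total = 0
        for perm in itertools.permutations(range(n)):
            t = _tau_b_statistic(x, y[list(perm)])
            total += 1
            if abs(t) >= observed - 1e-12:
                count += 1
        return tau, count / total

    # normal approximation with tie correction (standard tau-b variance)
    def tie_groups(v: np.ndarray) -> np.ndarray:
        _, counts = np.unique(v, return_counts=True)
        return counts[counts > 1].astype(float)

    tx = tie_groups(x)
    ty = tie_groups(y)
    n0 = n * (n - 1) / 2

    def v_terms(t: np.ndarray) -> tuple[float, float, float]:
        return (
            float((t * (t - 1) * (2 * t + 5)).sum()),
            float((t * (t - 1) * (t - 2)).sum()),
            float((t * (t - 1)).sum()),
        )

    vtx, v1x, v2x = v_terms(tx)
    vty, v1y, v2y = v_terms(ty)
    var_s = (
        (n * (n - 1) * (2 * n + 5) - vtx - vty) / 18
        + v1x * v1y / (9 * n * (n - 1) * (n - 2))
        + v2x * v2y / (2 * n * (n - 1))
    )
    s = tau * math.sqrt((n0 - (v2x / 2)) * (n0 - (v2y / 2)))
    if var_s <= 0:
        return tau, 1.0
    z = (abs(s) - 1.0) / math.sqrt(var_s)  # continuity correction
    z = max(z, 0.0)
    p = math.erfc(z / math.sqrt(2))
    return tau, min(p, 1.0)


# --------------------------------------------------------------------------
# phylogenetic independent contrasts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Contrast:
    node_id: str
    value: float
    sum_branch: float  # v1 + v2 at the node (standardization variance)


@dataclass(frozen=True)
class ContrastSet:
    contrasts: tuple[Contrast, ...]

    @property
    def values(self) -> np.ndarray:
        return np.array([c.value for c in self.contrasts])

    @property
    def standard_deviations(self) -> np.ndarray:
        return np.sqrt(np.array([c.sum_branch for c in self.contrasts]))

    def __len__(self) -> int:
        return len(self.contrasts)


def _resolve_polytomies(tree: dendropy.Tree, epsilon: float) -> dendropy.Tree:
    tree = tree.clone(depth=1)
    tree.resolve_polytomies(limit=2, update_bipartitions=False)
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is None:
            continue
        if edge.length is None or edge.length == 0:
            edge.length = epsilon
    return tree


def independent_contrasts(
    tree: dendropy.Tree, trait: Mapping[str, float]
) -> ContrastSet:
    """Felsenstein pruning: standardized contrasts for one trait.

    At each internal node joining children with values x1, x2 and adjusted
    branch lengths v1, v2: contrast = (x1 - x2) / sqrt(v1 + v2); the node gets
    the 1/v-weighted average value and its parent branch is extended by
    v1*v2/(v1+v2). Polytomies are resolved arbitrarily with near-zero
    branches (epsilon = 1e-8 x tree height).
    """
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = sorted(set(tips) - set(trait))
    if missing:
        raise ValueError(f"missing trait values for tips: {missing}")
    height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    epsilon = 1e-8 * (height if height > 0 else 1.0)
    work = _resolve_polytomies(tree, epsilon)

    values: dict[int, float] = {}
    lengths: dict[int, float] = {}
    contrasts: list[Contrast] = []
    counter = itertools.count()
    for node in work.postorder_node_iter():
        if node.is_leaf():
            values[id(node)] = float(trait[node.taxon.label])
            lengths[id(node)] = float(node.edge.length or 0.0)
            continue
        children = node.child_nodes()
        # binary after polytomy resolution (root may keep 2 children too)
        while len(children) > 2:  # defensive; resolve_polytomies handles this
            raise RuntimeError("unresolved polytomy")
        c1, c2 = children
        x1, x2 = values[id(c1)], values[id(c2)]
        v1, v2 = lengths[id(c1)], lengths[id(c2)]
        total = v1 + v2
        if total <= 0:
            raise ValueError("zero total branch variance at an internal node")
        node_id = node.label or f"node{next(counter)}"
        contrasts.append(
            Contrast(node_id=node_id, value=(x1 - x2) / math.sqrt(total), sum_branch=total)
        )
        values[id(node)] = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
        own = float(node.edge.length or 0.0) if node.parent_node is not None else 0.0
        lengths[id(node)] = own + v1 * v2 / total
    return ContrastSet(tuple(contrasts))


def contrast_correlation(cx: ContrastSet, cy: ContrastSet) -> tuple[float, float]:
    """Through-origin correlation of two contrast sets with a t-based p-value.

    r = sum(cx*cy) / sqrt(sum(cx^2) * sum(cy^2)); t = r sqrt((n-1)/(1-r^2))
    on n-1 degrees of freedom (through-origin regression), two-sided.
    """
    if len(cx) != len(cy):
        raise ValueError("contrast sets must come from the same tree")
    n = len(cx)
    if n < 3:
        raise ValueError("need at least 3 contrasts")
    a = cx.values
    b = cy.values
    denom = math.sqrt(float((a**2).sum() * (b**2).sum()))
    if denom == 0:
        raise ValueError("zero-variance contrasts")
    r = float((a * b).sum() / denom)
    df = n - 1
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt(df / (1 - r * r))
    p = 2 * _t_sf(abs(t), df)
    return r, p


def _t_sf(t: float, df: int) -> float:
    """Student-t survival function via the regularized incomplete beta."""
    from scipy.special import betainc  # closed-form special function, not a test

    x = df / (df + t * t)
    return 0.5 * float(betainc(df / 2.0, 0.5, x))


# --------------------------------------------------------------------------
# ANCOVA
# --------------------------------------------------------------------------


def _f_sf(f: float, d1: int, d2: int) -> float:
    from scipy.special import betainc

    if f <= 0:
        return 1.0
    x = d2 / (d2 + d1 * f)
    return float(betainc(d2 / 2.0, d1 / 2.0, x))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def ancova(
    y: Sequence[float], gc: Sequence[float], habitat: Sequence[str]
) -> dict[str, object]:
    """Linear model y ~ gc + habitat + gc:habitat with Type-II F-tests.

    Returns the habitat main-effect p-value (habitat | gc), the interaction
    p-value (gc:habitat | gc + habitat) and the full-model coefficients.
    """
    y = np.asarray(y, dtype=float)
    gc = np.asarray(gc, dtype=float)
    habitat = np.asarray(habitat)
    levels, codes = np.unique(habitat, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("habitat must have >= 2 levels")
    counts = np.bincount(codes)
    if counts.min() < 3:
        raise ValueError("each habitat level needs >= 3 observations")
    n = len(y)
    # treatment-coded dummies, first level as reference
    dummies = np.zeros((n, len(levels) - 1))
    for j in range(1, len(levels)):
        dummies[:, j - 1] = codes == j
    ones = np.ones((n, 1))
    X_gc = np.hstack([ones, gc[:, None]])
    X_main = np.hstack([ones, gc[:, None], dummies])
    X_full = np.hstack([ones, gc[:, None], dummies, gc[:, None] * dummies])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design (confounded gc/habitat)")

    q = len(levels) - 1
    df_resid = n - X_full.shape[1]
    rss_full = _rss(X_full, y)
    rss_main = _rss(X_main, y)
    rss_gc = _rss(X_gc, y)
    sigma2 = rss_full / df_resid

    f_habitat = ((rss_gc - rss_main) / q) / sigma2
    f_inter = ((rss_main - rss_full) / q) / sigma2
    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    names = (
        ["intercept", "gc"]
        + [f"habitat[{lv}]" for lv in levels[1:]]
        + [f"gc:habitat[{lv}]" for lv in levels[1:]]
    )
    return {
        "habitat_p": _f_sf(f_habitat, q, df_resid),
        "interaction_p": _f_sf(f_inter, q, df_resid),
        "habitat_F": f_habitat,
        "interaction_F": f_inter,
        "df": (q, df_resid),
        "coefficients": dict(zip(names, beta.tolist())),
    }


# --------------------------------------------------------------------------
# Mann-Whitney
# --------------------------------------------------------------------------

_EXACT_PRODUCT_LIMIT = 400
_ENUMERATION_LIMIT = 200_000


def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements with each U value (tie-free), exact.

    Standard recurrence c(a,b,u) = c(a-1,b,u-b) + c(a,b-1,u); the counts sum
    to C(n1+n2, n1).
    """
    max_u = n1 * n2
    # prev[a] holds counts for (a, b-1); cur[a] for (a, b)
    prev = [np.zeros(max_u + 1) for _ in range(n1 + 1)]
    for a in range(n1 + 1):
        prev[a][0] = 1.0  # b = 0: single arrangement with U = 0
    for b in range(1, n2 + 1):
        cur = [np.zeros(max_u + 1) for _ in range(n1 + 1)]
        cur[0][0] = 1.0
        for a in range(1, n1 + 1):
            cur[a][:] = prev[a]
            cur[a][b:] += cur[a - 1][: max_u + 1 - b]
        prev = cur
    return prev[n1]


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U test (U for sample ``a``).

    With ``method='auto'``: exact null enumeration when n_a * n_b <= 400
    (count recurrence for tie-free data; full combination enumeration when
    ties are present and feasible); tie-corrected normal approximation with
    continuity correction otherwise. ``method='exact'``/``'approx'`` force a
    path. Identical zero-variance data returns p = 1.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    from scipy.stats import rankdata  # ranking primitive only

    ranks = rankdata(combined)
    u_a = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    has_ties = len(np.unique(combined)) < n1 + n2

    if method == "exact" or (method == "auto" and n1 * n2 <= _EXACT_PRODUCT_LIMIT):
        if not has_ties:
            counts = _u_counts(n1, n2)
            total = counts.sum()
            u_int = int(round(u_a))
            p_less = counts[: u_int + 1].sum() / total
            p_greater = counts[u_int:].sum() / total
            return u_a, _combine_p(p_less, p_greater, alternative)
        if math.comb(n1 + n2, n1) <= _ENUMERATION_LIMIT:
            return u_a, _exact_with_ties(combined, n1, n2, u_a, alternative)

    # tie-corrected normal approximation
    mu = n1 * n2 / 2
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u_a, 1.0
    sd = math.sqrt(var)
    if alternative == "two-sided":
        z = max((abs(u_a - mu) - 0.5) / sd, 0.0)
        p = math.erfc(z / math.sqrt(2))
    elif alternative == "greater":
        z = (u_a - mu - 0.5) / sd
        p = 0.5 * math.erfc(z / math.sqrt(2))
    else:
        z = (u_a - mu + 0.5) / sd
        p = 0.5 * math.erfc(-z / math.sqrt(2))
    return u_a, min(p, 1.0)


def _combine_p(p_less: float, p_greater: float, alternative: str) -> float:
    if alternative == "less":
        return min(p_less, 1.0)
    if alternative == "greater":
        return min(p_greater, 1.0)
    return min(2 * min(p_less, p_greater), 1.0)


def _exact_with_ties(
    combined: np.ndarray, n1: int, n2: int, u_obs: float, alternative: str
) -> float:
    from scipy.stats import rankdata

    ranks = rankdata(combined)
    idx = range(n1 + n2)
    less = greater = total = 0
    for subset in itertools.combinations(idx, n1):
        u = sum(ranks[i] for i in subset) - n1 * (n1 + 1) / 2
        total += 1
        if u <= u_obs + 1e-9:
            less += 1
        if u >= u_obs - 1e-9:
            greater += 1
    return _combine_p(less / total, greater / total, alternative)
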