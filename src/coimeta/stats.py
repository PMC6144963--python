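"""Community-ecology statistics for samples × species count tables.

Implements the survey's analysis battery: Hellinger transformation,
Bray–Curtis and Hellinger (Euclidean-on-transformed) distances, principal
coordinates analysis, PERMANOVA with label permutations, SIMPER
decomposition of between-group Bray–Curtis dissimilarity, Shannon
diversity, sample- and read-based species accumulation (exact
hypergeometric expectations with resampled envelopes), abundance-based
Chao–Sørensen/Jaccard similarity, and randomized-block ANOVA / Student's
t group comparisons.

PERMANOVA and PCoA default to Euclidean distances on Hellinger-transformed
counts (the Hellinger distance); SIMPER is defined on Bray–Curtis.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# transforms and distances
# ---------------------------------------------------------------------------

def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    m = np.asarray(matrix, dtype=float)
    return pd.DataFrame(m)


def hellinger_transform(matrix, on_zero_rows: str = "drop") -> pd.DataFrame:
    """y'ij = sqrt(yij / Σj yij); every nonzero row gets unit Euclidean norm.

    All-zero rows are dropped with a warning (``on_zero_rows='error'``
    raises instead).
    """
    df = _as_frame(matrix).astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    sums = df.sum(axis=1)
    zero = sums == 0
    if zero.any():
        if on_zero_rows == "error":
            raise ValueError(f"all-zero rows: {list(df.index[zero])}")
        warnings.warn(f"dropping all-zero rows: {list(df.index[zero])}")
        df, sums = df.loc[~zero], sums[~zero]
    return np.sqrt(df.div(sums, axis=0))


@dataclass
class DistanceMatrix:
    values: np.ndarray
    ids: list
    metric: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def bray_curtis(matrix) -> DistanceMatrix:
    """d(i,j) = Σk |yik − yjk| / Σk (yik + yjk); 0 for two all-zero rows."""
    df = _as_frame(matrix).astype(float)
    y = df.to_numpy()
    if y.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    num = np.abs(y[:, None, :] - y[None, :, :]).sum(axis=2)
    den = (y[:, None, :] + y[None, :, :]).sum(axis=2)
    zero = den == 0
    if zero.sum() > y.shape[0]:  # off-diagonal zeros = pairs of empty rows
        warnings.warn("all-zero row pair: Bray-Curtis defined as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(df.index), "braycurtis")


def hellinger_distance(matrix) -> DistanceMatrix:
    """Euclidean distance between Hellinger-transformed rows."""
    hdf = hellinger_transform(matrix)
    h = hdf.to_numpy()
    diff = h[:, None, :] - h[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(hdf.index), "hellinger")


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(dist: DistanceMatrix) -> PCoAResult:
    """Classical (metric) multidimensional scaling via Gower centering.

    B = −½ J D² J is eigendecomposed; coordinates are eigenvectors scaled
    by sqrt of the positive eigenvalues, ordered by decreasing eigenvalue.
    Negative eigenvalues (non-Euclidean D) are reported and their axes
    dropped.
    """
    n = dist.n
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    D2 = dist.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = np.abs(evals).max() * 1e-10 if evals.size else 0.0
    pos = evals > tol
    neg = evals[evals < -tol]
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    total = evals[pos].sum()
    prop = evals[pos] / total if total > 0 else evals[pos]
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        pd.DataFrame(coords, index=dist.ids, columns=cols),
        evals[pos], prop, neg,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    R_squared: float
    p_value: float
    n_permutations: int
    seed: int | None
    perm_F: np.ndarray | None = None


def _ss_parts(D2: np.ndarray, codes: np.ndarray, n_groups: int):
    N = D2.shape[0]
    ss_t = D2.sum() / (2 * N)
    ss_w = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_w += D2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    return ss_t, ss_w


def _batch_F(D2: np.ndarray, perm_codes: np.ndarray, n_groups: int,
             sizes: np.ndarray) -> np.ndarray:
    """Pseudo-F for each row of label codes in ``perm_codes`` (P, N)."""
    N = D2.shape[0]
    ss_t = D2.sum() / (2 * N)
    ss_w = np.zeros(perm_codes.shape[0])
    for g in range(n_groups):
        M = (perm_codes == g).astype(float)
        ss_w += ((M @ D2) * M).sum(axis=1) / (2 * sizes[g])
    ss_a = ss_t - ss_w
    a = n_groups
    return (ss_a / (a - 1)) / (ss_w / (N - a))


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = 0,
    exhaustive: bool = False,
    return_perm_F: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_T = Σ_{i<j} d²ij / N; SS_W sums within-group pair terms scaled by
    group size; pseudo-F = (SS_A/(a−1)) / (SS_W/(N−a)).  Significance is
    by permutation of raw sample labels: p = (#{F_perm ≥ F_obs} + 1) /
    (n_perm + 1).  ``exhaustive=True`` enumerates all N! label orders
    (p is then the exact fraction ≥ observed).
    """
    labels = np.asarray(groups)
    if labels.size != dist.n:
        raise ValueError("groups length must match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = uniq.size
    if a < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("degenerate group (size 1)")

    D2 = dist.values ** 2
    ss_t, ss_w = _ss_parts(D2, codes, a)
    ss_a = ss_t - ss_w
    N = dist.n
    F_obs = (ss_a / (a - 1)) / (ss_w / (N - a))
    r2 = ss_a / ss_t

    if exhaustive:
        perms = np.array(list(itertools.permutations(range(N))))
        perm_codes = codes[perms]
        F_perm = _batch_F(D2, perm_codes, a, sizes)
        p = float(np.mean(F_perm >= F_obs - 1e-12))
        n_used = perms.shape[0]
    else:
        rng = np.random.default_rng(seed)
        perm_codes = np.tile(codes, (n_perm, 1))
        perm_codes = rng.permuted(perm_codes, axis=1)
        F_perm = _batch_F(D2, perm_codes, a, sizes)
        p = (np.count_nonzero(F_perm >= F_obs - 1e-12) + 1) / (n_perm + 1)
        n_used = n_perm
    return PermanovaResult(
        float(F_obs), float(r2), float(p), n_used, seed,
        F_perm if return_perm_F else None,
    )


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

def simper(matrix, groups) -> pd.DataFrame:
    """Species contributions to between-group Bray–Curtis dissimilarity.

    For each between-group sample pair (i, j) species k contributes
    |yik − yjk| / Σs (yis + yjs); the table reports the average over all
    between-group pairs, sorted descending (name breaks ties), with
    percent and cumulative percent of the mean between-group
    dissimilarity.  Contributions sum exactly to the mean between-group
    Bray–Curtis distance.
    """
    df = _as_frame(matrix).astype(float)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("SIMPER requires exactly 2 groups")
    y1 = df.to_numpy()[labels == uniq[0]]
    y2 = df.to_numpy()[labels == uniq[1]]
    if y1.shape[0] < 1 or y2.shape[0] < 1:
        raise ValueError("empty group")
    num = np.abs(y1[:, None, :] - y2[None, :, :])            # (n1, n2, S)
    den = (y1[:, None, :] + y2[None, :, :]).sum(axis=2)      # (n1, n2)
    contrib = (num / den[:, :, None]).mean(axis=(0, 1))
    total = contrib.sum()
    out = pd.DataFrame({
        "species": list(df.columns),
        "average_contribution": contrib,
    }).sort_values(
        ["average_contribution", "species"], ascending=[False, True],
        kind="stable",
    ).reset_index(drop=True)
    out["percent"] = 100 * out["average_contribution"] / total
    out["cumulative_percent"] = out["percent"].cumsum()
    out.attrs["mean_between_group_dissimilarity"] = float(total)
    return out


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_stats(matrix, log_base: float = math.e) -> pd.DataFrame:
    """Per-sample Shannon H (natural log by default), richness S, reads N.

    Zero-read samples get H = NaN.
    """
    df = _as_frame(matrix).astype(float)
    y = df.to_numpy()
    N = y.sum(axis=1)
    S = (y > 0).sum(axis=1)
    H = np.full(y.shape[0], np.nan)
    for i in range(y.shape[0]):
        if N[i] > 0:
            p = y[i][y[i] > 0] / N[i]
            H[i] = float(-(p * np.log(p)).sum() / np.log(log_base))
    return pd.DataFrame(
        {"shannon": H, "richness": S.astype(int), "reads": N}, index=df.index
    )


# ---------------------------------------------------------------------------
# accumulation / rarefaction
# ---------------------------------------------------------------------------

def expected_richness_samples(matrix, t: int) -> float:
    """Sample-based rarefaction: E[S_t] = Σi [1 − C(T−Oi, t)/C(T, t)]."""
    df = _as_frame(matrix)
    T = df.shape[0]
    if not 1 <= t <= T:
        raise ValueError(f"t must be in [1, {T}]")
    O = (df.to_numpy() > 0).sum(axis=0)
    O = O[O > 0]
    return float(np.sum(1.0 - _choose_ratio(T - O, T, t)))


def expected_richness_reads(pooled_counts, n: int) -> float:
    """Read-based rarefaction on pooled counts: E[S_n] = Σi [1 − C(N−Ni, n)/C(N, n)]."""
    Ni = np.asarray(pooled_counts, dtype=np.int64)
    Ni = Ni[Ni > 0]
    N = int(Ni.sum())
    if not 1 <= n <= N:
        raise ValueError(f"n must be in [1, {N}]")
    return float(np.sum(1.0 - _choose_ratio(N - Ni, N, n)))


def _choose_ratio(tops, total: int, k: int) -> np.ndarray:
    """C(tops, k)/C(total, k) elementwise, 0 where tops < k (log-gamma)."""
    tops = np.asarray(tops, dtype=np.int64)
    out = np.zeros(tops.shape, dtype=float)
    ok = tops >= k
    t = tops[ok]
    out[ok] = np.exp(
        gammaln(t + 1) - gammaln(t - k + 1) - gammaln(total + 1)
        + gammaln(total - k + 1)
    )
    return out


def accumulation_curves(
    matrix,
    n_boot: int = 100,
    n_read_points: int = 25,
    seed: int = 0,
    ci: float = 95.0,
) -> dict:
    """Sample- and read-based expected-richness curves with envelopes.

    Expectations are exact (hypergeometric); 95% envelopes come from
    resampling: random sample orderings for the sample-based curve and
    multivariate-hypergeometric subsamples of the pooled reads for the
    read-based curve.  Both curves are monotone and end at the observed
    pooled richness.
    """
    df = _as_frame(matrix)
    T = df.shape[0]
    if T < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2

    ts = np.arange(1, T + 1)
    exp_s = np.array([expected_richness_samples(df, int(t)) for t in ts])
    pres = df.to_numpy() > 0
    acc = np.zeros((n_boot, T))
    for b in range(n_boot):
        order = rng.permutation(T)
        seen = np.logical_or.accumulate(pres[order], axis=0)
        acc[b] = seen.sum(axis=1)
    sample_df = pd.DataFrame({
        "t": ts, "expected_richness": exp_s,
        "lo": np.percentile(acc, lo_q, axis=0),
        "hi": np.percentile(acc, hi_q, axis=0),
    })

    pooled = df.sum(axis=0).to_numpy().astype(np.int64)
    N = int(pooled.sum())
    grid = np.unique(np.linspace(1, N, min(n_read_points, N)).astype(np.int64))
    exp_r = np.array([expected_richness_reads(pooled, int(n)) for n in grid])
    boot = np.zeros((n_boot, grid.size))
    nz = pooled[pooled > 0]
    for b in range(n_boot):
        for j, n in enumerate(grid):
            sub = rng.multivariate_hypergeometric(nz, int(n))
            boot[b, j] = (sub > 0).sum()
    read_df = pd.DataFrame({
        "n_reads": grid, "expected_richness": exp_r,
        "lo": np.percentile(boot, lo_q, axis=0),
        "hi": np.percentile(boot, hi_q, axis=0),
    })
    return {"sample_based": sample_df, "read_based": read_df}


# ---------------------------------------------------------------------------
# Chao abundance-based similarity
# ---------------------------------------------------------------------------

@dataclass
class SimilarityEstimate:
    U: float
    V: float
    chao_jaccard: float
    chao_sorensen: float
    jaccard: float
    sorensen: float


def chao_similarity(x_counts, y_counts) -> SimilarityEstimate:
    """Abundance-based Chao–Jaccard/Sørensen estimates plus raw incidence indices.

    U estimates the total relative abundance in assemblage X of the
    species shared with Y, corrected for unseen shared species via the
    species that are singletons/doubletons in Y (f+1, f+2; f+2 = 0 is
    replaced by 1).  V is symmetric.  Chao–Jaccard = UV/(U+V−UV),
    Chao–Sørensen = 2UV/(U+V); no shared species gives all zeros.
    """
    x = np.asarray(x_counts, dtype=np.int64)
    y = np.asarray(y_counts, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("count vectors must share a species index")
    shared = (x > 0) & (y > 0)
    if not shared.any():
        return SimilarityEstimate(0, 0, 0, 0, 0, 0)
    n, m = int(x.sum()), int(y.sum())

    def one_side(a, b, na, nb):
        # estimated share of assemblage A belonging to species shared with B
        f1 = int(np.count_nonzero(shared & (b == 1)))
        f2 = int(np.count_nonzero(shared & (b == 2)))
        obs = a[shared].sum() / na
        rare = a[shared & (b == 1)].sum() / na
        corr = ((nb - 1) / nb) * (f1 / (2 * (f2 if f2 > 0 else 1))) * rare
        return min(1.0, obs + corr)

    U = one_side(x, y, n, m)
    V = one_side(y, x, m, n)
    cj = U * V / (U + V - U * V) if U + V - U * V > 0 else 0.0
    cs = 2 * U * V / (U + V) if U + V > 0 else 0.0
    a_ = int(shared.sum())
    b_ = int(np.count_nonzero((x > 0) & (y == 0)))
    c_ = int(np.count_nonzero((x == 0) & (y > 0)))
    return SimilarityEstimate(
        U, V, cj, cs, a_ / (a_ + b_ + c_), 2 * a_ / (2 * a_ + b_ + c_)
    )


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    method: str
    statistic: float
    df: tuple
    p_value: float
    table: pd.DataFrame | None = None


def ttest_two_groups(values, groups, log10: bool = False) -> GroupComparison:
    """Two-sample Student's t with pooled variance (e.g. summer vs fall)."""
    v = np.asarray(values, dtype=float)
    if log10:
        v = np.log10(v)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("t test requires exactly 2 groups")
    a, b = v[labels == uniq[0]], v[labels == uniq[1]]
    res = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison("student_t", float(res.statistic),
                           (a.size + b.size - 2,), float(res.pvalue))


def anova_blocked(values, groups, blocks=None, log10: bool = False) -> GroupComparison:
    """One-factor ANOVA with an optional additive block term (site).

    The block term stands in for a random site effect: the factor F is
    tested against the residual after removing additive block
    differences.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    v = np.asarray(values, dtype=float)
    if log10:
        v = np.log10(v)
    labels = np.asarray(groups).astype(str)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 groups")
    data = pd.DataFrame({"y": v, "g": labels})
    formula = "y ~ C(g)"
    if blocks is not None:
        data["b"] = np.asarray(blocks).astype(str)
        formula += " + C(b)"
    fit = smf.ols(formula, data=data).fit()
    table = anova_lm(fit, typ=2)
    F = float(table.loc["C(g)", "F"])
    p = float(table.loc["C(g)", "PR(>F)"])
    df = (float(table.loc["C(g)", "df"]), float(table.loc["Residual", "df"]))
    return GroupComparison("anova_blocked" if blocks is not None else "anova",
                           F, df, p, table)


def group_comparison(values, groups, blocks=None, log10: bool = False) -> GroupComparison:
    """Dispatch: 2 groups without blocks → pooled t; otherwise blocked ANOVA."""
    labels = np.asarray(groups)
    if blocks is None and np.unique(labels).size == 2:
        return ttest_two_groups(values, labels, log10=log10)
    return anova_blocked(values, labels, blocks=blocks, log10=log10)
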