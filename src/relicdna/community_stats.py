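"""Community statistics implemented from first principles.

Distances (Bray-Curtis, Jaccard), the centered log-ratio transform,
permutational multivariate ANOVA on a distance matrix (McArdle-Anderson
sequential sums of squares with free label permutation), redundancy-style
variance partitioning, Procrustes superimposition with a PROTEST
permutation test, principal coordinates analysis, bias-corrected Chao1
richness, and a Holm-corrected compositional differential-abundance test.

Permutation p-values use the plus-one convention
``p = (1 + exceedances) / (1 + n_perm)`` and are therefore never zero;
tiny designs can instead be enumerated exhaustively, in which case the
identity permutation is part of the reference set and
``p = exceedances / n!``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import AsvCountTable, ParameterError, SampleMetadata, logger


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """Symmetric sample x sample dissimilarities with a metric tag."""

    sample_ids: list[str]
    matrix: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(m)).max() > 1e-12:
            raise ValueError("distance matrix must have a zero diagonal")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids,
                            columns=self.sample_ids)


def _pairwise(X: np.ndarray, fn) -> np.ndarray:
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(X[i], X[j])
    return out


def bray_curtis(table: AsvCountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on raw counts:
    ``BC(x, y) = sum |x - y| / sum (x + y)``."""
    X = table.counts.to_numpy(float).T  # samples x ASVs

    def bc(x, y):
        denom = (x + y).sum()
        if denom == 0:
            logger.warning("Bray-Curtis between two all-zero samples set to 0")
            return 0.0
        return float(np.abs(x - y).sum() / denom)

    return DistanceMatrix(table.sample_ids, _pairwise(X, bc), "bray_curtis")


def jaccard(table: AsvCountTable) -> DistanceMatrix:
    """Jaccard distance on presence/absence:
    ``1 - |A intersect B| / |A union B|``."""
    P = (table.counts.to_numpy() > 0).T

    def jc(a, b):
        union = np.logical_or(a, b).sum()
        if union == 0:
            logger.warning("Jaccard between two all-zero samples set to 0")
            return 0.0
        return float(1.0 - np.logical_and(a, b).sum() / union)

    return DistanceMatrix(table.sample_ids, _pairwise(P, jc), "jaccard")


def euclidean_clr(table: AsvCountTable, pseudocount: float = 0.5) -> DistanceMatrix:
    """Aitchison-style distance: Euclidean distance between CLR-transformed
    samples (rotation-equivalent to distances on ilr coordinates)."""
    Z = clr_transform(table, pseudocount).to_numpy().T  # samples x ASVs
    d = _pairwise(Z, lambda x, y: float(np.linalg.norm(x - y)))
    return DistanceMatrix(table.sample_ids, d, "euclidean_clr")


# ---------------------------------------------------------------------------
# compositional transform


def clr_transform(table: AsvCountTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform, per sample.

    ``z = log(x + c) - mean(log(x + c))`` over the sample's ASVs, so each
    sample's CLR values sum to zero.  ``c = 0`` is admissible only when the
    table has no zero counts.
    """
    if pseudocount < 0:
        raise ParameterError("pseudocount must be >= 0")
    x = table.counts.to_numpy(float)
    if pseudocount == 0 and (x == 0).any():
        raise ParameterError("pseudocount 0 requires strictly positive counts")
    logx = np.log(x + pseudocount)
    z = logx - logx.mean(axis=0, keepdims=True)
    return pd.DataFrame(z, index=table.counts.index, columns=table.counts.columns)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # per term: SS, df, pseudo_F, R2, p
    ss_total: float
    ss_residual: float
    df_residual: int
    n_perm: int
    seed: int | None


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def _dummies(values) -> np.ndarray:
    levels = pd.unique(np.asarray(values))
    return (np.asarray(values)[:, None] == levels[None, :]).astype(float)


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto the column span of X, and its rank."""
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def permanova(
    dist: DistanceMatrix,
    factors: dict[str, "pd.Series | list"],
    interaction: bool = False,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational MANOVA on a distance matrix.

    Sequential (Type-I) sums of squares are obtained by projecting the
    Gower-centered inner-product matrix onto nested design matrices built
    from one or two categorical factors (plus an optional interaction), in
    the order the ``factors`` mapping lists them.  Each term's pseudo-F is
    ``(SS_term / df_term) / (SS_res / df_res)``; p-values come from free
    permutation of sample labels.
    """
    if not 1 <= len(factors) <= 2:
        raise ValueError("permanova supports one or two factors")
    n = len(dist.sample_ids)
    fvals = {}
    for name, vals in factors.items():
        v = vals.reindex(dist.sample_ids).to_numpy() if isinstance(vals, pd.Series) else np.asarray(vals)
        if len(v) != n:
            raise ValueError(f"factor {name!r} length mismatch")
        counts = pd.Series(v).value_counts()
        if len(counts) < 2:
            raise ValueError(f"factor {name!r} has a single level")
        if (counts < 2).any():
            raise ValueError(f"factor {name!r} has levels with <2 samples")
        fvals[name] = v

    names = list(fvals)
    blocks: list[tuple[str, np.ndarray]] = [
        (name, _dummies(fvals[name])) for name in names
    ]
    if interaction:
        if len(names) != 2:
            raise ValueError("interaction requires exactly two factors")
        a, b = fvals[names[0]], fvals[names[1]]
        ab = np.char.add(np.char.add(a.astype(str), "\x1f"), b.astype(str))
        blocks.append((f"{names[0]}:{names[1]}", _dummies(ab)))

    G = _gower_center(dist.matrix)
    ss_total = float(np.trace(G))

    # nested projectors; intercept contributes nothing on centered G
    X = np.ones((n, 1))
    hats, dfs, term_names = [], [], []
    prev_rank = 1
    for name, block in blocks:
        X = np.hstack([X, block])
        H, rank = _hat(X)
        df = rank - prev_rank
        if df == 0:
            raise ValueError(f"term {name!r} is aliased with preceding terms")
        hats.append(H)
        dfs.append(df)
        term_names.append(name)
        prev_rank = rank

    H_full, rank_full = _hat(X)
    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_stats(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        traces = np.array([float(np.sum(H * Gm)) for H in hats])
        ss = np.diff(np.concatenate([[0.0], traces]))
        ss_res = float(np.trace(Gm)) - traces[-1]
        F = (ss / np.array(dfs)) / (ss_res / df_res)
        return ss, ss_res, F

    ss, ss_res, F_obs = term_stats(G)

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        count = np.zeros(len(hats))
        total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            _, _, Fp = term_stats(G[np.ix_(idx, idx)])
            count += Fp >= F_obs - 1e-12
            total += 1
        p = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(hats))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            _, _, Fp = term_stats(G[np.ix_(idx, idx)])
            count += Fp >= F_obs - 1e-12
        p = (1.0 + count) / (1.0 + n_perm)
        n_used = n_perm

    tbl = pd.DataFrame(
        {
            "SS": ss,
            "df": dfs,
            "pseudo_F": F_obs,
            "R2": ss / ss_total,
            "p": p,
        },
        index=pd.Index(term_names, name="term"),
    )
    return PermanovaResult(
        table=tbl, ss_total=ss_total, ss_residual=ss_res,
        df_residual=df_res, n_perm=n_used, seed=seed,
    )


# ---------------------------------------------------------------------------
# variance partitioning (redundancy-analysis R2 on CLR coordinates)


@dataclass
class VariancePartition:
    table: pd.DataFrame  # per component: R2, adjusted R2


def _rda_r2(Yc: np.ndarray, X: np.ndarray) -> tuple[float, float, int]:
    n = Yc.shape[0]
    H, rank = _hat(np.hstack([np.ones((n, 1)), X]))
    fit = H @ Yc
    r2 = float((fit**2).sum() / (Yc**2).sum())
    p = rank - 1
    adj = np.nan if n - p - 1 <= 0 else 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return r2, adj, p


def variance_partition(
    clr_matrix: pd.DataFrame, factor_a, factor_b,
    names: tuple[str, str] = ("A", "B"),
) -> VariancePartition:
    """Partition multivariate CLR variance between two categorical factors.

    Unadjusted R2 is the fraction of total sum of squares captured by the
    least-squares fit on dummy predictors; Ezekiel's formula gives adjusted
    R2, and unique fractions come from differences of nested models
    (``unique_A = adjR2_{A+B} - adjR2_B``), so
    ``R2_{A+B} = unique_A + unique_B + shared`` holds identically.
    """
    Y = clr_matrix.to_numpy(float).T  # samples x features
    Yc = Y - Y.mean(axis=0, keepdims=True)
    Xa, Xb = _dummies(np.asarray(factor_a)), _dummies(np.asarray(factor_b))
    r2_a, adj_a, _ = _rda_r2(Yc, Xa)
    r2_b, adj_b, _ = _rda_r2(Yc, Xb)
    r2_ab, adj_ab, _ = _rda_r2(Yc, np.hstack([Xa, Xb]))
    na, nb = names
    rows = {
        na: (r2_a, adj_a),
        nb: (r2_b, adj_b),
        f"{na}+{nb}": (r2_ab, adj_ab),
        f"unique_{na}": (r2_ab - r2_b, adj_ab - adj_b),
        f"unique_{nb}": (r2_ab - r2_a, adj_ab - adj_a),
        "shared": (r2_a + r2_b - r2_ab, adj_a + adj_b - adj_ab),
    }
    tbl = pd.DataFrame(rows, index=["R2", "adjusted_R2"]).T
    tbl.index.name = "component"
    return VariancePartition(tbl)


# ---------------------------------------------------------------------------
# Procrustes / PROTEST


@dataclass
class ProcrustesResult:
    m2: float
    correlation: float
    p: float
    n_perm: int


def _standardise(M: np.ndarray) -> np.ndarray:
    C = M - M.mean(axis=0, keepdims=True)
    norm = np.sqrt((C**2).sum())
    if norm == 0:
        raise ValueError("degenerate configuration (all points identical)")
    return C / norm


def _m2(Xs: np.ndarray, Ys: np.ndarray) -> float:
    s = np.linalg.svd(Xs.T @ Ys, compute_uv=False).sum()
    return float(max(0.0, 1.0 - s**2))


def procrustes(
    X: np.ndarray, Y: np.ndarray, n_perm: int = 999, seed: int | None = None
) -> ProcrustesResult:
    """Symmetric Procrustes concordance of two ordination configurations.

    Both configurations are centered and scaled to unit sum of squares;
    the residual ``m2 = 1 - (sum of singular values of X'Y)^2`` after the
    optimal rotation/scaling, and ``correlation = sqrt(1 - m2)``.  The
    PROTEST p-value permutes the row order of Y.
    """
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points")
    width = max(X.shape[1], Y.shape[1])
    X = np.pad(X, ((0, 0), (0, width - X.shape[1])))
    Y = np.pad(Y, ((0, 0), (0, width - Y.shape[1])))
    Xs, Ys = _standardise(X), _standardise(Y)
    m2 = _m2(Xs, Ys)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _m2(Xs, Ys[rng.permutation(Y.shape[0])]) <= m2 + 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return ProcrustesResult(
        m2=m2, correlation=math.sqrt(max(0.0, 1.0 - m2)), p=p, n_perm=n_perm
    )


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives kept)


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Principal coordinates: eigendecomposition of the Gower-centered
    matrix.  Axes are ordered by eigenvalue; negative eigenvalues are
    reported, never silently dropped — only non-positive axes are excluded
    from the coordinate matrix."""
    G = _gower_center(dist.matrix)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-10 * max(vals.max(), 1.0), 0.0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    df = pd.DataFrame(
        coords, index=dist.sample_ids,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return PcoaResult(coordinates=df, eigenvalues=vals)


# ---------------------------------------------------------------------------
# richness


def chao1(pooled_counts) -> tuple[float, float]:
    """Bias-corrected Chao1 estimate and its standard error.

    ``chao1 = S_obs + f1 (f1 - 1) / (2 (f2 + 1))`` with f1, f2 the numbers
    of singleton and doubleton ASVs in the pooled counts; the variance is
    the classic bias-corrected formula.
    """
    c = np.asarray(pooled_counts)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    add = f1 * (f1 - 1) / (2.0 * (f2 + 1))
    est = s_obs + add
    var = (
        add
        + f1 * (2 * f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 2)
        + f1**2 * f2 * (f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 4)
    )
    return float(est), float(math.sqrt(max(var, 0.0)))


def richness(table: AsvCountTable, meta: SampleMetadata) -> pd.DataFrame:
    """Observed and Chao1-estimated ASV richness per sample group."""
    rows = []
    for gid, samples in meta.groups.items():
        pooled = table.counts[samples].sum(axis=1).to_numpy()
        est, se = chao1(pooled)
        rows.append(
            {
                "group_id": gid,
                "s_obs": int((pooled > 0).sum()),
                "f1": int((pooled == 1).sum()),
                "f2": int((pooled == 2).sum()),
                "chao1": est,
                "chao1_se": se,
            }
        )
    return pd.DataFrame(rows).set_index("group_id")


# ---------------------------------------------------------------------------
# differential abundance (CLR + per-ASV linear model + Holm)


@dataclass
class DifferentialAbundanceResult:
    effects: pd.DataFrame  # per (asv, coefficient): estimate, p_raw, p_holm, significant
    significant_asvs: list[str]
    alpha: float


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment (family-wise error control)."""
    return multipletests(np.asarray(pvalues, float), method="holm")[1]


def differential_abundance(
    clr_matrix: pd.DataFrame,
    stage_factor,
    alpha: float = 0.05,
) -> DifferentialAbundanceResult:
    """Stage effects on CLR abundances, Holm-corrected family-wise.

    Every ASV's CLR values are regressed on stage dummy variables
    (first stage level is the reference); per-coefficient two-sided
    t-tests are Holm-adjusted across the full ASV x coefficient family.
    An ASV with zero residual-model variance gets p = 1 by convention.
    """
    f = np.asarray(stage_factor)
    samples = list(clr_matrix.columns)
    if len(f) != len(samples):
        raise ValueError("stage factor length must match sample count")
    levels = list(pd.unique(f))
    if len(levels) < 2:
        raise ValueError("need at least two stages")
    if (pd.Series(f).value_counts() < 2).any():
        raise ValueError("each stage needs at least two samples")

    n = len(samples)
    X = np.ones((n, len(levels)))
    coef_names = []
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (f == lev).astype(float)
        coef_names.append(f"{lev}_vs_{levels[0]}")
    k = X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    Y = clr_matrix.to_numpy(float)  # asv x sample
    B = Y @ X @ xtx_inv  # asv x k
    resid = Y - B @ X.T
    df = n - k
    sigma2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(np.maximum(sigma2[:, None], 0.0) * np.diag(xtx_inv)[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[se == 0] = 1.0  # zero-variance ASVs carry no evidence

    rows = []
    for i, asv in enumerate(clr_matrix.index):
        for j, cname in enumerate(coef_names, start=1):
            rows.append(
                {
                    "asv_id": asv,
                    "coefficient": cname,
                    "estimate": B[i, j],
                    "p_raw": p[i, j],
                }
            )
    eff = pd.DataFrame(rows).set_index(["asv_id", "coefficient"])
    eff["p_holm"] = holm_adjust(eff["p_raw"].to_numpy())
    eff["significant"] = eff["p_holm"] < alpha
    sig = sorted(
        {asv for (asv, _), s in eff["significant"].items() if s},
        key=list(clr_matrix.index).index,
    )
    return DifferentialAbundanceResult(effects=eff, significant_asvs=sig, alpha=alpha)
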