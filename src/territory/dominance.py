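"""Dominance-hierarchy inference and the surrounding statistics.

The central object is :class:`DominanceModel`: given a matrix of seven
behavioral measures per mouse (attacks, chases, flights, upright postures,
locomotion in cm, exploration fraction, hiding fraction) for a cohort of
paired animals, ``fit()`` z-scores each behavior across the pooled cohort,
performs a PCA, and labels the member of each pair with the higher first
principal-component score as dominant. PC1 separates an
aggressive/exploratory strategy from a defensive/hiding one and serves as
a one-dimensional dominance score; PC2 captures overall social engagement.

The module also provides the cohort re-pairing permutation test (a null
distribution for the mean absolute within-pair difference built by
randomly re-matching the cohort into artificial pairs), behavior
correlation matrices with significance masks, thin wrappers around the
standard nonparametric tests (Wilcoxon signed-rank; Kruskal–Wallis with a
hand-rolled Dunn post hoc), and the two validation indices used for dye
safety checks (center/corner anxiety index and odor-preference index).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "BEHAVIOR_COLUMNS",
    "DominanceModel",
    "DominanceResults",
    "dominance_pca",
    "assign_ranks",
    "PermutationResult",
    "repairing_permutation_test",
    "behavior_correlations",
    "wilcoxon_paired",
    "kruskal_dunn",
    "preference_index",
    "zscore_across_cohort",
]

#: canonical behavior columns of the analysis matrix
BEHAVIOR_COLUMNS = (
    "attacks",
    "chases",
    "flights",
    "uprights",
    "locomotion_cm",
    "exploration_frac",
    "hiding_frac",
)


def zscore_across_cohort(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardise each column across ALL mice pooled (mean 0, SD 1).

    Normalisation pools every animal regardless of strain so that scores
    are comparable across groups. Sample SD (ddof=1) by default;
    ``ddof=0`` selects the population convention.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 mice to z-score")
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=ddof)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(
            f"zero-variance behavior column(s): {', '.join(map(str, zero.index))}"
        )
    if matrix.isna().any().any():
        raise ValueError("behavior matrix contains missing cells")
    return (matrix - mu) / sd


class DominanceModel:
    """PCA-based dominance ranking of a paired-mouse cohort.

    Parameters
    ----------
    data : DataFrame
        One row per mouse. Must contain the seven behavior columns
        (:data:`BEHAVIOR_COLUMNS`) plus ``mouse_id`` and ``pair_id``;
        ``strain`` is optional metadata carried through to results.
    ddof : int
        0 or 1; delta degrees of freedom of the z-scoring SD.
    """

    def __init__(self, data: pd.DataFrame, ddof: int = 1):
        required = {"mouse_id", "pair_id", *BEHAVIOR_COLUMNS}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"behavior matrix missing columns: {sorted(missing)}")
        if data["mouse_id"].duplicated().any():
            raise ValueError("each mouse must appear exactly once")
        sizes = data.groupby("pair_id").size()
        bad = sizes[sizes != 2]
        if len(bad):
            raise ValueError(f"pair ids must partition mice into pairs; offending: {list(bad.index)}")
        self.data = data.reset_index(drop=True)
        self.ddof = ddof
        self.endog = self.data[list(BEHAVIOR_COLUMNS)].astype(float)

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, ddof: int = 1) -> "DominanceModel":
        """Build from long format (mouse_id, pair_id[, strain], behavior, value)."""
        idx = ["mouse_id", "pair_id"] + (["strain"] if "strain" in tidy.columns else [])
        wide = tidy.pivot_table(index=idx, columns="behavior", values="value").reset_index()
        wide.columns.name = None
        return cls(wide, ddof=ddof)

    def fit(self) -> "DominanceResults":
        """Z-score, run the PCA, orient the components, assign ranks."""
        z = zscore_across_cohort(self.endog, ddof=self.ddof)
        load_df, evr, score_df = dominance_pca(z, orient_on="attacks")
        score_df.insert(0, "mouse_id", self.data["mouse_id"].to_numpy())
        score_df.insert(1, "pair_id", self.data["pair_id"].to_numpy())
        if "strain" in self.data.columns:
            score_df.insert(2, "strain", self.data["strain"].to_numpy())
        return DominanceResults(
            model=self,
            loadings=load_df,
            explained_variance_ratio=evr,
            scores=score_df,
        )


def dominance_pca(
    z: pd.DataFrame, orient_on: str = "attacks"
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """PCA of a standardised matrix with a deterministic sign convention.

    Full-SVD eigen-decomposition of the covariance; components ordered by
    explained variance. Each component is oriented so its loading on
    ``orient_on`` (falling back to the first nonzero loading if that
    behavior loads exactly zero, or is absent) is positive — so higher PC1
    means more aggressive and the dominance axis points up. Returns
    (loadings behaviors x PCs, explained variance fractions, scores).
    """
    if z.isna().any().any():
        raise ValueError("matrix contains missing cells")
    cols = list(z.columns)
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(z.to_numpy(dtype=float))
    loadings = pca.components_.T.copy()  # behaviors x components
    i_ref = cols.index(orient_on) if orient_on in cols else 0
    for k in range(loadings.shape[1]):
        ref = loadings[i_ref, k]
        if ref == 0:
            nz = np.flatnonzero(loadings[:, k])
            ref = loadings[nz[0], k] if len(nz) else 1.0
        if ref < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    pcs = [f"PC{k + 1}" for k in range(loadings.shape[1])]
    return (
        pd.DataFrame(loadings, index=cols, columns=pcs),
        pca.explained_variance_ratio_.copy(),
        pd.DataFrame(scores, columns=pcs),
    )


@dataclass
class DominanceResults:
    """Fitted dominance PCA: loadings, scores, variance fractions, ranks."""

    model: DominanceModel
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame
    _ranks: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def ranks(self) -> pd.DataFrame:
        """Per-pair labels: dominant, subordinate, PC1 difference (dom - sub).

        An exact PC1 tie flags the pair ``tied`` with a null dominant.
        """
        if self._ranks is None:
            self._ranks = assign_ranks(self.scores)
        return self._ranks

    @property
    def dominant_by_pair(self) -> dict[str, str]:
        """pair key 'a|b' (in score order) -> dominant mouse id."""
        out = {}
        for r in self.ranks.itertuples(index=False):
            out[f"{r.member_1}|{r.member_2}"] = r.dominant
        return out

    def plot_scores(self, ax=None):
        """Scatter of PC1 (dominance) vs PC2 (engagement) per mouse.

        Pair members are joined by a line; dominants are filled,
        subordinates open, ties grey.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        sc = self.scores.set_index("mouse_id")
        for r in self.ranks.itertuples(index=False):
            a, b = sc.loc[r.member_1], sc.loc[r.member_2]
            ax.plot([a["PC1"], b["PC1"]], [a["PC2"], b["PC2"]], "-", c="0.8", lw=1, zorder=1)
            if r.tied:
                ax.scatter([a["PC1"], b["PC1"]], [a["PC2"], b["PC2"]], c="0.5", zorder=2)
            else:
                d, s = (a, b) if r.dominant == r.member_1 else (b, a)
                ax.scatter(d["PC1"], d["PC2"], c="tab:red", zorder=2, label="dominant")
                ax.scatter(
                    s["PC1"], s["PC2"], facecolors="none", edgecolors="tab:blue",
                    zorder=2, label="subordinate",
                )
        handles, labels = ax.get_legend_handles_labels()
        uniq = dict(zip(labels, handles))
        ax.legend(uniq.values(), uniq.keys(), frameon=False)
        ev = self.explained_variance_ratio
        ax.set_xlabel(f"PC1 ({100 * ev[0]:.1f}% var)")
        ax.set_ylabel(f"PC2 ({100 * ev[1]:.1f}% var)")
        return ax

    def summary(self) -> str:
        lines = ["Dominance PCA (7 behaviors, cohort-pooled z-scores)"]
        lines.append("=" * 56)
        ev = self.explained_variance_ratio
        lines.append(
            "Variance explained: "
            + ", ".join(f"PC{k + 1} {100 * v:.1f}%" for k, v in enumerate(ev[:3]))
        )
        lines.append("")
        lines.append("Loadings (PC1 oriented with attacks > 0):")
        lines.append(self.loadings[["PC1", "PC2"]].round(3).to_string())
        lines.append("")
        rk = self.ranks
        lines.append(f"Pairs ranked: {len(rk)} ({int((rk['tied']).sum())} tied)")
        lines.append(
            rk[["pair_id", "dominant", "subordinate", "pc1_difference"]]
            .round(3)
            .to_string(index=False)
        )
        return "\n".join(lines)


def assign_ranks(scores: pd.DataFrame) -> pd.DataFrame:
    """Label the higher-PC1 member of each pair dominant.

    Input needs columns ``mouse_id``, ``pair_id``, ``PC1``. The PC1
    difference is reported dominant-minus-subordinate (>= 0). Exact ties
    are flagged and get no dominant label.
    """
    rows = []
    for pid, grp in scores.groupby("pair_id", sort=False):
        if len(grp) != 2:
            raise ValueError(f"pair {pid!r} does not have exactly 2 scored members")
        (m1, s1), (m2, s2) = grp[["mouse_id", "PC1"]].itertuples(index=False, name=None)
        if np.isnan(s1) or np.isnan(s2):
            raise ValueError(f"pair {pid!r} has an unscored member")
        tied = s1 == s2
        if tied:
            dom, sub = None, None
        elif s1 > s2:
            dom, sub = m1, m2
        else:
            dom, sub = m2, m1
        rows.append(
            {
                "pair_id": pid,
                "member_1": m1,
                "member_2": m2,
                "dominant": dom,
                "subordinate": sub,
                "tied": tied,
                "pc1_difference": abs(s1 - s2),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# re-pairing permutation test

@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, its re-pairing null, and the resulting p-value."""

    behavior: str
    observed: float
    null: np.ndarray
    n_permutations: int
    seed: int | None
    exhaustive: bool

    @property
    def p_value(self) -> float:
        # fraction of null draws at least as large as the observation;
        # equal to the strict 'larger than' rule almost surely for
        # continuous statistics, and well-defined on ties
        return float(np.sum(self.null >= self.observed)) / len(self.null)


def _n_perfect_matchings(n: int) -> int:
    return math.prod(range(n - 1, 0, -2))  # (n-1)!!


def _all_matchings(idx: tuple[int, ...]):
    """Yield every perfect matching of idx as tuples of index pairs."""
    if not idx:
        yield ()
        return
    a, rest = idx[0], idx[1:]
    for j, b in enumerate(rest):
        rem = rest[:j] + rest[j + 1 :]
        for sub in _all_matchings(rem):
            yield ((a, b),) + sub


def mean_abs_pair_difference(
    values: np.ndarray, pairs: Sequence[tuple[int, int]]
) -> float:
    return float(np.mean([abs(values[a] - values[b]) for a, b in pairs]))


def repairing_permutation_test(
    values: Mapping[str, float] | pd.Series,
    pairs: Sequence[tuple[str, str]],
    behavior: str = "",
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive_limit: int = 10_005,
) -> PermutationResult:
    """Test whether the within-pair divergence exceeds random re-pairing.

    The observed statistic is the mean over true pairs of the absolute
    within-pair difference. Each permutation draws a uniformly random
    perfect matching of the whole cohort into artificial pairs and
    recomputes the statistic; when the number of distinct matchings is at
    most ``exhaustive_limit`` the full set is enumerated instead (the
    result is then exact and deterministic).
    """
    values = pd.Series(values)
    ids = [m for p in pairs for m in p]
    if len(set(ids)) != len(ids):
        raise ValueError("pairs must be disjoint")
    missing = set(ids) - set(values.index)
    if missing:
        raise ValueError(f"no values for: {sorted(missing)}")
    n = len(ids)
    if n < 4 or n % 2:
        raise ValueError("need an even cohort of at least 4 mice")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    v = values.loc[ids].to_numpy(dtype=float)
    true_pairs = [(2 * i, 2 * i + 1) for i in range(len(pairs))]
    observed = mean_abs_pair_difference(v, true_pairs)

    n_match = _n_perfect_matchings(n)
    if n_match <= exhaustive_limit:
        null = np.array(
            [
                mean_abs_pair_difference(v, m)
                for m in _all_matchings(tuple(range(n)))
            ]
        )
        exhaustive = True
    else:
        # uniform random matchings: shuffle, pair consecutive (vectorised)
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_perm, n)), axis=1)
        pv = v[idx]
        null = np.mean(np.abs(pv[:, 0::2] - pv[:, 1::2]), axis=1)
        exhaustive = False
    return PermutationResult(
        behavior=behavior,
        observed=observed,
        null=null,
        n_permutations=len(null),
        seed=seed,
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# correlations and standard tests

def behavior_correlations(
    matrix: pd.DataFrame, method: str = "pearson", alpha: float = 0.05
) -> dict:
    """Pairwise behavior correlations with a significance mask.

    Returns ``corr`` and ``p`` DataFrames, a boolean ``significant`` mask
    (p < alpha, diagonal False), a list of ``constant`` columns whose
    correlations are undefined (masked NaN), and run metadata. No
    multiple-testing correction is applied; the metadata records that.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 mice for correlations")
    cols = list(matrix.columns)
    k = len(cols)
    corr = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    constant = [c for c in cols if matrix[c].nunique() <= 1]
    fn = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}[method]
    for i, j in itertools.combinations(range(k), 2):
        a, b = matrix[cols[i]], matrix[cols[j]]
        if cols[i] in constant or cols[j] in constant:
            r, p = np.nan, np.nan
        else:
            r, p = fn(a, b)
        corr.iloc[i, j] = corr.iloc[j, i] = r
        pval.iloc[i, j] = pval.iloc[j, i] = p
    sig = (pval < alpha) & np.isfinite(corr)
    np.fill_diagonal(sig.values, False)
    return {
        "corr": corr,
        "p": pval,
        "significant": sig,
        "constant": constant,
        "meta": {"method": method, "alpha": alpha, "mt_correction": "none", "n": len(matrix)},
    }


def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> dict:
    """Wilcoxon matched-pairs signed-rank test (two-sided).

    All-zero differences are a degenerate case where the test carries no
    information; by convention statistic 0, p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two paired samples of equal length >= 2")
    if np.all(x == y):
        return {"statistic": 0.0, "p_value": 1.0, "n": len(x), "degenerate": True}
    res = stats.wilcoxon(x, y)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n": len(x),
        "degenerate": False,
    }


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]], p_adjust: str = "holm"
) -> dict:
    """Kruskal–Wallis across groups with Dunn's pairwise post hoc.

    Dunn's test compares mean ranks of each group pair on the pooled
    ranking, z = (R̄_i - R̄_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    with tie correction T = Σ(t³ - t) / (12(N - 1)); two-sided p-values
    are adjusted by Holm (default) or Bonferroni.
    """
    names = list(groups)
    data = [np.asarray(groups[g], float) for g in names]
    if len(names) < 2 or any(len(d) < 2 for d in data):
        raise ValueError("need >= 2 groups with >= 2 values each")
    H, p = stats.kruskal(*data)
    pooled = np.concatenate(data)
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts) / (12.0 * (N - 1))
    splits = np.cumsum([len(d) for d in data])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_rank = {g: r.mean() for g, r in zip(names, group_ranks)}
    nsize = {g: len(groups[g]) for g in names}
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt((N * (N + 1) / 12.0 - tie) * (1.0 / nsize[a] + 1.0 / nsize[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        rows.append({"group_1": a, "group_2": b, "z": z, "p_raw": 2 * stats.norm.sf(abs(z))})
    posthoc = pd.DataFrame(rows)
    praw = posthoc["p_raw"].to_numpy()
    if p_adjust == "bonferroni":
        padj = np.minimum(praw * len(praw), 1.0)
    elif p_adjust == "holm":
        order = np.argsort(praw)
        padj = np.empty_like(praw)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (len(praw) - rank_i) * praw[idx])
            padj[idx] = min(running, 1.0)
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    posthoc["p_adjusted"] = padj
    return {"H": float(H), "p_value": float(p), "posthoc": posthoc, "p_adjust": p_adjust}


def preference_index(t_a: float, t_b: float) -> float:
    """Normalised time-preference index (T_a - T_b)/(T_a + T_b) in [-1, 1].

    Used both as the open-field anxiety index (center vs corners) and as
    the odor-preference index (dye vs saline). Undefined when both times
    are zero (returns NaN).
    """
    if t_a < 0 or t_b < 0:
        raise ValueError("times must be nonnegative")
    if t_a + t_b == 0:
        return float("nan")
    return (t_a - t_b) / (t_a + t_b)
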