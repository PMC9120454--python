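"""Statistical battery for composition comparisons.

Covers the analyses used to attribute composition differences to
protocol factors:

* gram-positive/gram-negative abundance ratios against the expected
  ratio of the mock community;
* Pearson correlation of observed vs manufacturer-reported abundances,
  split by gram status;
* ordinary least squares with top-down (backward) term elimination, to
  test whether gram status, genome length or GC content predicts median
  species abundance;
* pairwise Wilcoxon rank-sum tests per clade with Benjamini–Hochberg
  FDR adjustment;
* distance-based PERMANOVA with sequential (Type I) sums of squares and
  a seeded label-permutation test, the machinery behind factorial
  "does kit / homogenisation time matter" tables.

The PERMANOVA follows McArdle & Anderson: the squared dissimilarity
matrix is Gower-centred into an inner-product matrix G; for a sequence
of model terms the explained sum of squares is tr(H G) of the
cumulative hat matrices, and the permutation p-value uses the add-one
convention (1 + #{F* >= F}) / (1 + n_permutations).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import OLS, add_constant
from statsmodels.stats.multitest import multipletests

from .community_metrics import DissimilarityMatrix
from .profile_io import ReferenceCommunity, Taxon, TaxonProfile

__all__ = [
    "GramRatioResult",
    "CorrelationResult",
    "LinearModelFit",
    "PairwiseTestTable",
    "PermanovaResult",
    "gram_ratio",
    "correlate_with_reference",
    "fit_ols",
    "top_down_select",
    "wilcoxon_rank_sum",
    "pairwise_clade_tests",
    "fdr_adjust",
    "permanova",
]


# ---------------------------------------------------------------------------
# gram ratios & correlation


@dataclass
class GramRatioResult:
    sample_id: str
    observed_ratio: Optional[float]  # None when gram-negative sum is 0
    expected_ratio: Optional[float]
    gram_positive_sum: float
    gram_negative_sum: float


def gram_ratio(profile: TaxonProfile, annotations: ReferenceCommunity) -> GramRatioResult:
    """Ratio of summed gram-positive to gram-negative abundance.

    Computed on abundance sums (not species counts), observed and
    expected alike.  Taxa without a gram label are excluded.  A zero
    gram-negative sum flags the ratio as undefined (``None``).
    """
    gram_of = {t: annotations.annotation(t).gram for t in annotations.taxa}
    pos = neg = 0.0
    for t, a in profile.entries.items():
        g = gram_of.get(t)
        if g == "positive":
            pos += a
        elif g == "negative":
            neg += a
    epos = sum(a for t, a in annotations.entries.items() if gram_of[t] == "positive")
    eneg = sum(a for t, a in annotations.entries.items() if gram_of[t] == "negative")
    return GramRatioResult(
        sample_id=profile.sample_id,
        observed_ratio=pos / neg if neg > 0 else None,
        expected_ratio=epos / eneg if eneg > 0 else None,
        gram_positive_sum=pos,
        gram_negative_sum=neg,
    )


@dataclass
class CorrelationResult:
    group: str  # gram_positive | gram_negative | all
    r: float
    n: int


def correlate_with_reference(
    observed: TaxonProfile,
    reference: ReferenceCommunity,
    gram_split: bool = True,
) -> list[CorrelationResult]:
    """Pearson r of observed vs reference abundance, per gram group.

    Groups with fewer than two shared taxa are omitted (with so few
    points — e.g. only 4 gram-positive species in a 12-strain mix — the
    coefficient may be computable but never significant, and with <2 it
    is undefined).
    """
    pairs: dict[str, list[tuple[float, float]]] = {}
    for t, exp_a in reference.entries.items():
        if t not in observed.entries:
            continue
        if gram_split:
            g = reference.annotation(t).gram
            if g not in ("positive", "negative"):
                continue
            group = f"gram_{g}"
        else:
            group = "all"
        pairs.setdefault(group, []).append((exp_a, observed.entries[t]))
    out = []
    for group in sorted(pairs):
        pts = pairs[group]
        if len(pts) < 2:
            continue
        x, y = zip(*pts)
        if np.std(x) == 0 or np.std(y) == 0:
            continue  # r undefined for a constant group (e.g. even mixes)
        r = float(sps.pearsonr(x, y).statistic)
        out.append(CorrelationResult(group=group, r=r, n=len(pts)))
    return out


# ---------------------------------------------------------------------------
# OLS + top-down selection


@dataclass
class LinearModelFit:
    response: str
    retained_terms: list[str]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    alpha: float
    elimination_trace: list[str] = field(default_factory=list)


def fit_ols(
    y: Sequence[float],
    design: pd.DataFrame,
    response_name: str = "y",
    alpha: float = 0.05,
) -> LinearModelFit:
    """Ordinary least squares of ``y`` on the design columns.

    Coefficient p-values are two-sided t-tests.  An exactly
    rank-deficient design is rejected with the offending terms named.
    """
    y = np.asarray(y, dtype=float)
    if len(y) <= design.shape[1] + 1:
        raise ValueError(
            f"under-determined fit: n={len(y)} with {design.shape[1]} terms + intercept"
        )
    x = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), x])) < design.shape[1] + 1:
        raise ValueError(f"rank-deficient design among terms {list(design.columns)}")
    model = OLS(y, add_constant(design.astype(float), prepend=True)).fit()
    coeffs = {name: float(model.params[name]) for name in model.params.index}
    pvals = {name: float(model.pvalues[name]) for name in model.pvalues.index}
    return LinearModelFit(
        response=response_name,
        retained_terms=list(design.columns),
        coefficients=coeffs,
        p_values=pvals,
        alpha=alpha,
    )


def top_down_select(
    y: Sequence[float],
    design: pd.DataFrame,
    alpha: float = 0.05,
    response_name: str = "y",
) -> LinearModelFit:
    """Backward elimination: drop the least significant term until all
    retained terms have p < alpha (or only the intercept remains).

    The intercept is never dropped.  ``elimination_trace`` records the
    dropped terms in order.
    """
    current = design.copy()
    trace: list[str] = []
    while True:
        if current.shape[1] == 0:
            fit = LinearModelFit(
                response=response_name,
                retained_terms=[],
                coefficients={},
                p_values={},
                alpha=alpha,
                elimination_trace=trace,
            )
            return fit
        fit = fit_ols(y, current, response_name=response_name, alpha=alpha)
        term_p = {t: fit.p_values[t] for t in current.columns}
        term_p = {t: (1.0 if math.isnan(p) else p) for t, p in term_p.items()}
        worst = max(term_p, key=lambda t: term_p[t])
        if term_p[worst] < alpha:
            fit.elimination_trace = trace
            return fit
        trace.append(worst)
        current = current.drop(columns=[worst])


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum + FDR


def _rank_sum_exact_ties(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # midrank enumeration over all C(n, nx) group assignments
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx, n = len(x), len(pooled)
    w_obs = float(ranks[:nx].sum())
    mean_w = nx * (n + 1) / 2.0
    dev_obs = abs(w_obs - mean_w)
    count = total = 0
    for combo in itertools.combinations(range(n), nx):
        w = float(ranks[list(combo)].sum())
        total += 1
        if abs(w - mean_w) >= dev_obs - 1e-12:
            count += 1
    return w_obs, count / total


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the rank sum of ``x`` in the pooled
    sample.  ``mode='exact'`` enumerates the permutation distribution
    (midranks under ties); ``'normal_approx'`` uses the tie-corrected
    normal approximation with continuity correction; ``'auto'`` picks
    exact for combined n <= 20 without ties, else the approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in {"exact", "normal_approx", "auto"}:
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    n = len(pooled)
    if mode == "auto":
        mode = "exact" if (n <= 20 and not has_ties) else "normal_approx"
    w = float(sps.rankdata(pooled)[: len(x)].sum())
    if mode == "exact":
        if has_ties:
            return _rank_sum_exact_ties(x, y)
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return w, float(res.pvalue)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return w, float(res.pvalue)


def fdr_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


@dataclass
class PairwiseTestTable:
    rows: pd.DataFrame  # clade, group_a, group_b, statistic, p_raw, p_adjusted

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.rows[self.rows["p_adjusted"] < alpha]


def pairwise_clade_tests(
    profiles: Sequence[TaxonProfile],
    groups: dict[str, str],
    clades: Optional[Sequence[Taxon]] = None,
    mode: str = "auto",
) -> PairwiseTestTable:
    """Per-clade pairwise Wilcoxon tests between sample groups.

    For every clade and unordered pair of groups, the clade's
    abundances across each group's samples are compared; a profile that
    lacks the clade contributes abundance 0.  All raw p-values in the
    table are jointly FDR-adjusted.  Clades absent from every profile
    are skipped.
    """
    group_names = sorted(set(groups.values()))
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    by_group: dict[str, list[TaxonProfile]] = {g: [] for g in group_names}
    for p in profiles:
        if p.sample_id not in groups:
            raise ValueError(f"sample {p.sample_id} has no group label")
        by_group[groups[p.sample_id]].append(p)
    if clades is None:
        clades = sorted({t for p in profiles for t in p.entries}, key=lambda t: t.key)
    rows = []
    for clade in clades:
        if all(p.entries.get(clade, 0.0) == 0.0 for p in profiles):
            continue
        for ga, gb in itertools.combinations(group_names, 2):
            xa = [p.entries.get(clade, 0.0) for p in by_group[ga]]
            xb = [p.entries.get(clade, 0.0) for p in by_group[gb]]
            stat, p_raw = wilcoxon_rank_sum(xa, xb, mode=mode)
            rows.append(
                {
                    "clade": clade.name,
                    "group_a": ga,
                    "group_b": gb,
                    "statistic": stat,
                    "p_raw": p_raw,
                }
            )
    df = pd.DataFrame(rows, columns=["clade", "group_a", "group_b", "statistic", "p_raw"])
    df["p_adjusted"] = fdr_adjust(df["p_raw"]) if len(df) else []
    return PairwiseTestTable(rows=df)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaTerm:
    name: str
    df: int
    ss: float
    f: float
    r2: float
    p: float


@dataclass
class PermanovaResult:
    terms: list[PermanovaTerm]
    residual_df: int
    residual_ss: float
    residual_r2: float
    total_ss: float
    n_permutations: int
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"term": t.name, "df": t.df, "SS": t.ss, "F": t.f, "R2": t.r2, "p": t.p}
            for t in self.terms
        ]
        rows.append(
            {
                "term": "Residuals",
                "df": self.residual_df,
                "SS": self.residual_ss,
                "F": float("nan"),
                "R2": self.residual_r2,
                "p": float("nan"),
            }
        )
        return pd.DataFrame(rows)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _dummies(col: pd.Series) -> np.ndarray:
    levels = sorted(col.unique())
    if len(levels) < 2:
        raise ValueError(f"factor {col.name!r} has a single level")
    return np.column_stack([(col == lv).to_numpy(float) for lv in levels[1:]])


def parse_formula(formula: str | Sequence[str]) -> list[str]:
    if isinstance(formula, str):
        terms = [t.strip() for t in formula.split("+") if t.strip()]
    else:
        terms = list(formula)
    if not terms:
        raise ValueError("empty formula")
    return terms


def _term_design(term: str, factors: pd.DataFrame) -> np.ndarray:
    if ":" in term:
        parts = term.split(":")
        if len(parts) != 2:
            raise ValueError(f"only two-way interactions supported, got {term!r}")
        da, db = _dummies(factors[parts[0]]), _dummies(factors[parts[1]])
        cols = [da[:, i] * db[:, j] for i in range(da.shape[1]) for j in range(db.shape[1])]
        return np.column_stack(cols)
    if term not in factors.columns:
        raise ValueError(f"unknown factor {term!r}")
    return _dummies(factors[term])


def permanova(
    matrix: DissimilarityMatrix,
    factors: pd.DataFrame,
    formula: str | Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Distance-based PERMANOVA with sequential (Type I) sums of squares.

    ``factors`` must be indexed by (or contain a ``sample_id`` column
    matching) the matrix's sample ids; ``formula`` is an ordered list of
    terms such as ``"time + kit + time:kit"`` — order matters, as each
    term is adjusted only for the terms before it.  Significance is
    assessed by free whole-row permutation of the factor labels, with
    the add-one p-value convention, so the smallest attainable p is
    1/(n_permutations + 1).
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    if "sample_id" in factors.columns:
        factors = factors.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in factors.index]
    if missing:
        raise ValueError(f"factor table missing samples {missing}")
    factors = factors.loc[matrix.sample_ids]
    terms = parse_formula(formula)

    n = len(matrix.sample_ids)
    g = _gower_center(matrix.values)
    ss_total = float(np.trace(g))

    # cumulative hat matrices: intercept, then + each term in order
    ones = np.ones((n, 1))
    blocks = [ones]
    hats: list[np.ndarray] = []
    ranks: list[int] = []
    for term in terms:
        blocks.append(_term_design(term, factors))
        x = np.column_stack(blocks)
        hats.append(x @ np.linalg.pinv(x))
        ranks.append(int(np.linalg.matrix_rank(x)))
    h0 = ones @ np.linalg.pinv(ones)
    cum_ranks = [1] + ranks
    dfs = [cum_ranks[i + 1] - cum_ranks[i] for i in range(len(terms))]
    df_res = n - cum_ranks[-1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom for this formula")
    if any(df == 0 for df in dfs):
        raise ValueError("a term adds no rank to the design (collinear with earlier terms)")

    def term_stats(gm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # tr(H G) for symmetric H, G via elementwise sums
        tr_prev = float(np.sum(h0 * gm))  # = 0 for centred G, kept for clarity
        ss = np.empty(len(terms))
        for i, h in enumerate(hats):
            tr_i = float(np.sum(h * gm))
            ss[i] = tr_i - tr_prev
            tr_prev = tr_i
        ss_res = float(np.trace(gm)) - tr_prev
        f = (ss / np.asarray(dfs)) / (ss_res / df_res)
        return ss, f

    ss_obs, f_obs = term_stats(g)
    ss_res = ss_total - float(ss_obs.sum())

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        _, f_perm = term_stats(gp)
        exceed += f_perm >= f_obs - 1e-12
    p_vals = (1.0 + exceed) / (1.0 + n_permutations)

    result_terms = [
        PermanovaTerm(
            name=terms[i],
            df=dfs[i],
            ss=float(ss_obs[i]),
            f=float(f_obs[i]),
            r2=float(ss_obs[i] / ss_total),
            p=float(p_vals[i]),
        )
        for i in range(len(terms))
    ]
    return PermanovaResult(
        terms=result_terms,
        residual_df=df_res,
        residual_ss=ss_res,
        residual_r2=ss_res / ss_total,
        total_ss=ss_total,
        n_permutations=n_permutations,
        seed=seed,
    )
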