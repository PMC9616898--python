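"""Regulator-conditioned isoform-switch discovery statistics.

Two rankings over two-isoform genes:

* ``correlation_switch_scores`` — the correlation-difference statistic
  ``delta_r = r1 - r2``, where ``r1``/``r2`` are the Pearson correlations of
  regulator expression with the two isoforms' relative frequencies.  Genes
  whose mean isoform fractions sum below a floor (default 0.5) are filtered
  out before ranking; the top-K (default 20) are flagged.
* ``ktsp_switch_scores`` — a rank-based top-scoring-pairs statistic on a
  low/high dichotomy: the absolute difference between the two groups in the
  empirical probability that isoform 1 outweighs isoform 2, ties counted as
  one half.  Top-K default 100.

Isoform orientation convention: within each gene, ``isoform1`` is the
isoform with the higher mean relative frequency among regulator-high
samples, so a strongly positive ``delta_r`` reads "this isoform tracks the
regulator" and true switches rank at the top of the descending list.  Both
statistics depend on relative frequencies only, so they are invariant to
per-sample scaling of total gene expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, ValidationError


@dataclass
class SwitchScore:
    """Per-gene correlation-difference record.

    ``scorable`` is False when fewer than 3 samples have defined fractions
    or a fraction series is constant (Pearson correlation undefined).
    ``rank`` is assigned only to scorable, filter-passing genes.
    """

    gene_id: str
    isoform1: str
    isoform2: str
    r1: float | None
    r2: float | None
    delta_r: float | None
    mean_f1: float
    mean_f2: float
    passes_filter: bool
    scorable: bool
    rank: int | None = None
    in_top_k: bool = False
    perm_p: float | None = None
    perm_p_adj: float | None = None


@dataclass
class KtspScore:
    """Per-gene two-group rank-pair score."""

    gene_id: str
    isoform1: str
    isoform2: str
    p_low: float
    p_high: float
    score: float
    direction: str
    rank: int | None = None
    in_top_k: bool = False


def split_by_regulator(
    regulator_expr: pd.Series,
    method: str = "median",
    threshold: float | None = None,
    preset: dict[str, str] | None = None,
) -> pd.Series:
    """Dichotomize samples into regulator-low/-high groups.

    ``median`` puts samples at or below the median in the low group;
    ``threshold`` compares against an explicit cut; ``preset`` accepts an
    explicit sample -> {low, high} mapping verbatim.  Each resulting group
    must contain at least 2 samples.
    """
    if method == "median":
        cut = float(regulator_expr.median())
        labels = pd.Series(
            np.where(regulator_expr <= cut, "low", "high"), index=regulator_expr.index
        )
    elif method == "threshold":
        if threshold is None:
            raise ValidationError("threshold method requires a threshold value")
        labels = pd.Series(
            np.where(regulator_expr < threshold, "low", "high"),
            index=regulator_expr.index,
        )
    elif method == "preset":
        if preset is None:
            raise ValidationError("preset method requires a sample->group mapping")
        missing = [s for s in regulator_expr.index if s not in preset]
        if missing:
            raise ValidationError(f"preset mapping missing samples {missing}")
        bad = sorted(set(preset.values()) - {"low", "high"})
        if bad:
            raise ValidationError(f"preset labels must be low/high, got {bad}")
        labels = pd.Series([preset[s] for s in regulator_expr.index], index=regulator_expr.index)
    else:
        raise ValidationError(f"unknown split method {method!r}")
    counts = labels.value_counts()
    if counts.get("low", 0) < 2 or counts.get("high", 0) < 2:
        raise ValidationError(
            f"each group needs >= 2 samples (got low={counts.get('low', 0)}, "
            f"high={counts.get('high', 0)})"
        )
    return labels


def _two_isoform_genes(fractions: ExpressionMatrix) -> dict[str, tuple[str, str]]:
    """Genes with exactly two isoforms, mapped to their transcript pair."""
    pairs: dict[str, tuple[str, str]] = {}
    for gene, members in fractions.gene_of.groupby(fractions.gene_of):
        tids = sorted(members.index)
        if len(tids) == 2:
            pairs[str(gene)] = (tids[0], tids[1])
    return pairs


def _orient_pair(
    t1: str, t2: str, fractions: pd.DataFrame, high_samples: pd.Index
) -> tuple[str, str]:
    """Order the pair so isoform1 has higher mean fraction in high samples."""
    m1 = fractions.loc[t1, high_samples].mean()
    m2 = fractions.loc[t2, high_samples].mean()
    if np.isnan(m1) or np.isnan(m2) or math.isclose(m1, m2) or m1 > m2:
        return t1, t2
    return t2, t1


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson r, or None when undefined (constant input or n < 3)."""
    if len(x) < 3:
        return None
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def correlation_switch_scores(
    regulator_expr: pd.Series,
    fractions: ExpressionMatrix,
    min_total_fraction: float = 0.5,
    top_k: int = 20,
) -> list[SwitchScore]:
    """Score and rank two-isoform genes by the correlation difference.

    For each gene, ``r1``/``r2`` correlate the regulator with the two
    isoform fractions over the samples where fractions are defined;
    ``delta_r = r1 - r2``.  Genes whose mean fractions sum below
    ``min_total_fraction`` fail the expression filter; unscorable or
    filtered genes are excluded from the descending-``delta_r`` ranking
    (ties broken by gene id).  All genes are returned, ranked first.
    """
    common = [s for s in fractions.sample_ids if s in regulator_expr.index]
    if len(common) < 3:
        raise ValidationError("need >= 3 samples shared by regulator and fractions")
    reg = regulator_expr.loc[common].astype(float)
    frac = fractions.values[common]
    groups = split_by_regulator(reg, "median")
    high_samples = groups.index[groups == "high"]

    scores: list[SwitchScore] = []
    reg_arr = reg.to_numpy()
    for gene, (ta, tb) in _two_isoform_genes(fractions).items():
        t1, t2 = _orient_pair(ta, tb, frac, high_samples)
        f1 = frac.loc[t1].to_numpy(dtype=float)
        f2 = frac.loc[t2].to_numpy(dtype=float)
        defined = ~(np.isnan(f1) | np.isnan(f2))
        mean_f1 = float(np.nanmean(f1)) if defined.any() else math.nan
        mean_f2 = float(np.nanmean(f2)) if defined.any() else math.nan
        passes = bool(defined.any() and mean_f1 + mean_f2 >= min_total_fraction)
        r1 = _pearson(reg_arr[defined], f1[defined]) if defined.sum() >= 3 else None
        r2 = _pearson(reg_arr[defined], f2[defined]) if defined.sum() >= 3 else None
        scorable = r1 is not None and r2 is not None
        delta = (r1 - r2) if scorable else None
        scores.append(
            SwitchScore(
                gene_id=gene,
                isoform1=t1,
                isoform2=t2,
                r1=r1,
                r2=r2,
                delta_r=delta,
                mean_f1=mean_f1,
                mean_f2=mean_f2,
                passes_filter=passes,
                scorable=scorable,
            )
        )

    ranked = [s for s in scores if s.scorable and s.passes_filter]
    ranked.sort(key=lambda s: (-s.delta_r, s.gene_id))
    for i, s in enumerate(ranked, start=1):
        s.rank = i
        s.in_top_k = i <= top_k
    rest = sorted((s for s in scores if s.rank is None), key=lambda s: s.gene_id)
    return ranked + rest


def ktsp_switch_scores(
    fractions: ExpressionMatrix,
    groups: pd.Series,
    top_k: int = 100,
) -> list[KtspScore]:
    """Two-group rank-pair scores for two-isoform genes.

    ``p_g`` is the empirical probability, within group ``g``, that
    isoform 1's fraction exceeds isoform 2's (ties count 0.5); the score is
    ``|p_low - p_high|``.  Isoform 1 is the lexicographically smaller
    transcript id; ``direction`` names the group favoring it.
    """
    counts = groups.value_counts()
    for g in ("low", "high"):
        if counts.get(g, 0) < 1:
            raise ValidationError(f"empty {g} group")
    if counts.get("low", 0) < 2 or counts.get("high", 0) < 2:
        raise ValidationError("need >= 2 samples per group")
    low = [s for s in fractions.sample_ids if groups.get(s) == "low"]
    high = [s for s in fractions.sample_ids if groups.get(s) == "high"]

    scores: list[KtspScore] = []
    for gene, (t1, t2) in _two_isoform_genes(fractions).items():
        def prob(samples: list[str]) -> float:
            f1 = fractions.values.loc[t1, samples].to_numpy(dtype=float)
            f2 = fractions.values.loc[t2, samples].to_numpy(dtype=float)
            ok = ~(np.isnan(f1) | np.isnan(f2))
            if not ok.any():
                return math.nan
            wins = (f1[ok] > f2[ok]).sum() + 0.5 * (f1[ok] == f2[ok]).sum()
            return float(wins / ok.sum())

        p_low, p_high = prob(low), prob(high)
        if math.isnan(p_low) or math.isnan(p_high):
            continue
        scores.append(
            KtspScore(
                gene_id=gene,
                isoform1=t1,
                isoform2=t2,
                p_low=p_low,
                p_high=p_high,
                score=abs(p_low - p_high),
                direction="low" if p_low >= p_high else "high",
            )
        )
    scores.sort(key=lambda s: (-s.score, s.gene_id))
    for i, s in enumerate(scores, start=1):
        s.rank = i
        s.in_top_k = i <= top_k
    return scores


@dataclass
class PsiComparison:
    """Two-group PSI comparison by pooled-variance Student's t test."""

    mean_low: float
    mean_high: float
    sd_low: float
    sd_high: float
    t: float
    p: float
    degenerate: bool = False


def compare_group_psi(psi: pd.Series, groups: pd.Series) -> PsiComparison:
    """Compare one event's PSI between low and high groups.

    Classical unpaired two-tailed Student's t test (pooled variance).  At
    least 2 defined PSI values are required per group.  With zero pooled
    variance and different means the statistic is infinite; the comparison
    is flagged degenerate and p reported as 0.
    """
    vals = psi.astype(float)
    low = vals[[s for s in vals.index if groups.get(s) == "low"]].dropna()
    high = vals[[s for s in vals.index if groups.get(s) == "high"]].dropna()
    if len(low) < 2 or len(high) < 2:
        raise ValidationError("need >= 2 defined PSI values per group")
    n1, n2 = len(low), len(high)
    m1, m2 = float(low.mean()), float(high.mean())
    s1, s2 = float(low.std(ddof=1)), float(high.std(ddof=1))
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    # treat a pooled sd at floating-point noise level as exactly zero
    if math.sqrt(sp2) <= 1e-12 * max(1.0, abs(m1), abs(m2)):
        if math.isclose(m1, m2, abs_tol=1e-12):
            return PsiComparison(m1, m2, s1, s2, 0.0, 1.0)
        t = math.inf if m1 > m2 else -math.inf
        return PsiComparison(m1, m2, s1, s2, t, 0.0, degenerate=True)
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return PsiComparison(m1, m2, s1, s2, float(t), float(p))


# ---------------------------------------------------------------------------
# permutation null (artifact extension: optional p-values for delta_r)
# ---------------------------------------------------------------------------


def _delta_r_matrix(reg: np.ndarray, F1: np.ndarray, F2: np.ndarray) -> np.ndarray:
    """Vectorized delta_r for rows of F1/F2 against one regulator vector."""

    def zscore(M: np.ndarray) -> np.ndarray:
        sd = M.std(axis=-1, keepdims=True)
        sd = np.where(sd == 0, np.nan, sd)
        return (M - M.mean(axis=-1, keepdims=True)) / sd

    zr = zscore(reg[None, :])[0]
    n = reg.shape[0]
    r1 = zscore(F1) @ zr / n
    r2 = zscore(F2) @ zr / n
    return r1 - r2


def permutation_null_delta(
    regulator_expr: pd.Series,
    fractions: ExpressionMatrix,
    n_permutations: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Observed |delta_r| per gene and a pooled permutation null.

    The regulator vector is permuted across samples ``n_permutations``
    times and delta_r recomputed for every two-isoform gene with complete
    fractions.  Returns (observed |delta_r|, null |delta_r| of shape
    (n_permutations, n_genes), gene ids).
    """
    common = [s for s in fractions.sample_ids if s in regulator_expr.index]
    reg = regulator_expr.loc[common].to_numpy(dtype=float)
    pairs = _two_isoform_genes(fractions)
    frac = fractions.values[common]
    genes, rows1, rows2 = [], [], []
    for gene, (t1, t2) in pairs.items():
        f1 = frac.loc[t1].to_numpy(dtype=float)
        f2 = frac.loc[t2].to_numpy(dtype=float)
        if np.isnan(f1).any() or np.isnan(f2).any():
            continue
        if f1.std() == 0 or f2.std() == 0:
            continue
        genes.append(gene)
        rows1.append(f1)
        rows2.append(f2)
    F1, F2 = np.asarray(rows1), np.asarray(rows2)
    observed = np.abs(_delta_r_matrix(reg, F1, F2))
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, len(genes)))
    for k in range(n_permutations):
        null[k] = np.abs(_delta_r_matrix(rng.permutation(reg), F1, F2))
    return observed, null, genes


def attach_permutation_pvalues(
    scores: list[SwitchScore],
    regulator_expr: pd.Series,
    fractions: ExpressionMatrix,
    n_permutations: int = 200,
    seed: int = 0,
) -> list[SwitchScore]:
    """Add pooled-null permutation p-values (BH-adjusted) to switch scores.

    An extension beyond the score-based discovery ranking: the p-value is
    the fraction of pooled permuted |delta_r| values at least as large as a
    gene's observed |delta_r| (add-one estimator), BH-adjusted across genes.
    """
    from statsmodels.stats.multitest import multipletests

    observed, null, genes = permutation_null_delta(
        regulator_expr, fractions, n_permutations, seed
    )
    pooled = np.sort(null.ravel())
    m = pooled.size
    pvals = {}
    for gene, obs in zip(genes, observed):
        exceed = m - np.searchsorted(pooled, obs, side="left")
        pvals[gene] = (exceed + 1) / (m + 1)
    with_p = [s for s in scores if s.gene_id in pvals]
    raw = [pvals[s.gene_id] for s in with_p]
    if raw:
        adj = multipletests(raw, method="fdr_bh")[1]
        for s, p, pa in zip(with_p, raw, adj):
            s.perm_p = float(p)
            s.perm_p_adj = float(pa)
    return scores


def switch_score_table(scores: list[SwitchScore]) -> pd.DataFrame:
    """Tabulate switch scores (isoform1 = regulator-high-favored isoform)."""
    rows = [
        {
            "gene_id": s.gene_id,
            "isoform1": s.isoform1,
            "isoform2": s.isoform2,
            "r1": s.r1,
            "r2": s.r2,
            "delta_r": s.delta_r,
            "mean_f1": s.mean_f1,
            "mean_f2": s.mean_f2,
            "passes_filter": s.passes_filter,
            "scorable": s.scorable,
            "rank": s.rank,
            "in_top_k": s.in_top_k,
            "perm_p": s.perm_p,
            "perm_p_adj": s.perm_p_adj,
        }
        for s in scores
    ]
    return pd.DataFrame(rows)


def heatmap_fractions(
    scores: list[SwitchScore],
    fractions: ExpressionMatrix,
    regulator_expr: pd.Series,
    top_k: int = 20,
) -> pd.DataFrame:
    """Relative fractions of top-K genes, samples in ascending regulator order."""
    order = list(regulator_expr.sort_values().index)
    tids = [t for s in scores if s.in_top_k and s.rank is not None and s.rank <= top_k for t in (s.isoform1, s.isoform2)]
    out = fractions.values.loc[tids, order].copy()
    out.insert(0, "gene_id", fractions.gene_of.loc[tids])
    out.index.name = "transcript_id"
    return out.reset_index()
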