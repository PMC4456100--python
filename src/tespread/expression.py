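"""With-TE vs without-TE allele expression tests within a strain panel.

For each gene, strains are split by whether any TE insertion site in a
window around the gene is called present ("with TE") or all are absent
("without TE"); a strain with a no-call and no present site is missing data.
Expression is compared on within-strain ranks (rank 1 = highest expression)
to sidestep between-array scale differences, and significance comes from the
exhaustive permutation distribution of the mean-rank difference over all
label reassignments.  A positive observed difference means the with-TE
alleles rank lower in expression.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: window labels (bp from the gene; "in_gene" = intronic sites only)
WINDOWS = {"in_gene": 0, "1kb": 1_000, "2kb": 2_000, "5kb": 5_000, "10kb": 10_000}

MIN_GROUP = 2
MIN_COMBINATIONS = 20  # strictly more than this many label assignments required
DEFAULT_ENUMERATION_CAP = 2_000_000


@dataclass
class StrainPanel:
    """TE site states and expression for a population strain panel.

    ``sites``: DataFrame with columns site_id, chrom, start, end.
    ``states``: DataFrame sites x strains with values present/absent/no_call.
    ``expression``: mapping sex -> DataFrame genes x strains.
    """

    sites: pd.DataFrame
    states: pd.DataFrame
    expression: dict[str, pd.DataFrame]

    @property
    def strains(self) -> list[str]:
        return list(self.states.columns)

    def __post_init__(self) -> None:
        valid = {"present", "absent", "no_call"}
        seen = set(np.unique(self.states.to_numpy().astype(str)))
        if not seen <= valid:
            raise ValueError(f"invalid TE site states: {seen - valid}")


@dataclass(frozen=True)
class AlleleGrouping:
    gene_id: str
    window: str
    state: pd.Series  # per strain: with_te / without_te / missing
    n_sites: int

    @property
    def with_strains(self) -> list[str]:
        return list(self.state.index[self.state == "with_te"])

    @property
    def without_strains(self) -> list[str]:
        return list(self.state.index[self.state == "without_te"])


@dataclass(frozen=True)
class PermTestResult:
    gene_id: str
    window: str
    sex: str
    n_with: int
    n_without: int
    observed_diff: float
    n_combinations: int
    p_one_tail: float
    testable: bool


def expression_rank(values: Sequence[float]) -> np.ndarray:
    """Within-sample expression ranks, rank 1 = highest; ties get average ranks."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or not np.isfinite(v).all():
        raise ValueError("expression_rank requires finite values")
    return stats.rankdata(-v, method="average")


def rank_expression_panel(expr: pd.DataFrame, drop_zero: bool = True) -> pd.DataFrame:
    """Rank each sample (column) across genes; zero-expression genes are
    excluded per sample (their rank is NaN) since absence of signal cannot be
    distinguished from absence of expression."""
    ranked = {}
    for col in expr.columns:
        v = expr[col]
        mask = v.notna() & ((v != 0) if drop_zero else True)
        r = pd.Series(np.nan, index=expr.index)
        r[mask] = stats.rankdata(-v[mask].to_numpy(), method="average")
        ranked[col] = r
    return pd.DataFrame(ranked)


def sites_near_gene(
    panel: StrainPanel, gene_span: tuple[str, int, int], window: str,
    intronic_site_ids: Iterable[str] = (),
) -> list[str]:
    """Site ids within the window around a gene span (chrom, start, end).

    ``in_gene`` selects only the supplied intronic sites; other windows take
    sites whose span overlaps the gene extended by the window size on both
    sides (intronic sites included, since they are at distance 0).
    """
    chrom, start, end = gene_span
    if window == "in_gene":
        return [s for s in intronic_site_ids if s in set(panel.sites["site_id"])]
    w = WINDOWS[window]
    sub = panel.sites[
        (panel.sites["chrom"] == chrom)
        & (panel.sites["start"] < end + w)
        & (panel.sites["end"] > start - w)
    ]
    return list(sub["site_id"])


def allele_state(
    panel: StrainPanel, gene_id: str, site_ids: Sequence[str], window: str
) -> AlleleGrouping:
    """Classify each strain's allele at a gene by the TE sites in its window.

    with_te when >= 1 site is present; without_te when every site is absent;
    missing when some site is no_call and none is present.  With zero sites
    every strain is without_te — such "no-TE genes" are usable only for
    false-positive-rate calibration.
    """
    if len(site_ids) == 0:
        state = pd.Series("without_te", index=panel.states.columns)
        return AlleleGrouping(gene_id=gene_id, window=window, state=state, n_sites=0)
    sub = panel.states.loc[list(site_ids)]
    present = (sub == "present").any(axis=0)
    all_absent = (sub == "absent").all(axis=0)
    state = pd.Series("missing", index=panel.states.columns)
    state[all_absent] = "without_te"
    state[present] = "with_te"
    return AlleleGrouping(gene_id=gene_id, window=window, state=state, n_sites=len(site_ids))


_COMBO_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _combination_table(n: int, k: int) -> np.ndarray:
    """All C(n, k) index combinations as an (C, k) array, memoised.

    Panels reuse the same (n, k) shapes across thousands of genes, so the
    table is built once; int16 indices keep the cache small.
    """
    key = (n, k)
    if key not in _COMBO_CACHE:
        flat = np.fromiter(
            (i for combo in combinations(range(n), k) for i in combo),
            dtype=np.int16,
            count=math.comb(n, k) * k,
        )
        _COMBO_CACHE[key] = flat.reshape(-1, k)
    return _COMBO_CACHE[key]


def rank_diff_stat(with_ranks: Sequence[float], without_ranks: Sequence[float]) -> float:
    """mean rank(with TE) - mean rank(without TE); positive = lower expression
    of the with-TE alleles."""
    if len(with_ranks) == 0 or len(without_ranks) == 0:
        raise ValueError("both groups must be non-empty")
    return float(np.mean(with_ranks) - np.mean(without_ranks))


def exhaustive_permutation_test(
    ranks: Sequence[float],
    with_mask: Sequence[bool],
    gene_id: str = "",
    window: str = "",
    sex: str = "",
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
) -> PermTestResult:
    """Exact one-tailed permutation test of the mean-rank difference.

    All C(n, n_with) assignments of the with/without labels to the observed
    ranks are enumerated; p is the proportion of assignments whose difference
    is greater than or equal to the observed one.  The observed assignment is
    itself enumerated, so p >= 1/C(n, n_with) > 0.  Genes with fewer than two
    alleles per group or at most 20 possible assignments are flagged
    untestable (their p cannot reach 0.05).  No Monte-Carlo fallback: sizes
    beyond ``enumeration_cap`` raise instead of silently approximating.
    """
    r = np.asarray(ranks, dtype=float)
    mask = np.asarray(with_mask, dtype=bool)
    if r.shape != mask.shape:
        raise ValueError("ranks and with_mask must align")
    n = r.size
    k = int(mask.sum())
    m = n - k
    n_comb = math.comb(n, k)
    observed = rank_diff_stat(r[mask], r[~mask]) if (k and m) else np.nan
    testable = k >= MIN_GROUP and m >= MIN_GROUP and n_comb > MIN_COMBINATIONS
    if not (k and m):
        return PermTestResult(gene_id, window, sex, k, m, float("nan"), n_comb, float("nan"), False)
    if n_comb > enumeration_cap:
        raise ValueError(
            f"{n_comb} label assignments exceed the exact-enumeration cap "
            f"({enumeration_cap}); refusing to approximate"
        )
    idx = _combination_table(n, k)
    total = r.sum()
    with_sums = r[idx].sum(axis=1)
    diffs = with_sums / k - (total - with_sums) / m
    p = float(np.count_nonzero(diffs >= observed - 1e-9) / n_comb)
    return PermTestResult(gene_id, window, sex, k, m, observed, n_comb, p, testable)


def gene_permutation_test(
    ranked_expr: pd.DataFrame,
    grouping: AlleleGrouping,
    gene_id: str,
    sex: str,
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
) -> PermTestResult:
    """Run the exhaustive test for one gene against a ranked expression matrix."""
    row = ranked_expr.loc[gene_id]
    strains = [
        s
        for s in grouping.state.index
        if grouping.state[s] in ("with_te", "without_te")
        and s in row.index
        and np.isfinite(row[s])
    ]
    ranks = row[strains].to_numpy(dtype=float)
    mask = np.array([grouping.state[s] == "with_te" for s in strains])
    return exhaustive_permutation_test(
        ranks, mask, gene_id=gene_id, window=grouping.window, sex=sex,
        enumeration_cap=enumeration_cap,
    )


@dataclass(frozen=True)
class ExcessSignificance:
    window: str
    sex: str
    n_sig: int
    n_insig: int
    expected_sig: int
    proportion_sig: float
    odds_ratio: float
    fet_p: float


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def excess_significance(
    results: Sequence[PermTestResult] | Sequence[float],
    alpha: float = 0.05,
    window: str = "",
    sex: str = "",
) -> ExcessSignificance:
    """Is the number of significant genes in excess of the alpha*N expected?

    Builds the 2x2 table [[observed sig, observed insig], [expected sig,
    expected insig]] with the expected count rounded half away from zero, and
    reports the one-sided (greater) Fisher exact p and the sample
    cross-product odds ratio.
    """
    ps = np.asarray(
        [r.p_one_tail if isinstance(r, PermTestResult) else float(r) for r in results]
    )
    n_total = ps.size
    if n_total == 0:
        raise ValueError("excess_significance needs at least one result")
    n_sig = int(np.count_nonzero(ps < alpha))
    n_insig = n_total - n_sig
    expected = _round_half_away(alpha * n_total)
    table = [[n_sig, n_insig], [expected, n_total - expected]]
    _, fet_p = stats.fisher_exact(table, alternative="greater")
    if n_sig == 0:
        oratio = 0.0
    elif n_insig == 0 or expected == 0:
        oratio = float("inf")
    else:
        oratio = (n_sig * (n_total - expected)) / (n_insig * expected)
    return ExcessSignificance(
        window=window,
        sex=sex,
        n_sig=n_sig,
        n_insig=n_insig,
        expected_sig=expected,
        proportion_sig=n_sig / n_total,
        odds_ratio=float(oratio),
        fet_p=float(fet_p),
    )


def sex_concordance(
    results_female: Mapping[str, float], results_male: Mapping[str, float],
    alpha: float = 0.05,
) -> tuple[np.ndarray, float, float]:
    """Concordance of significance calls between sexes over shared genes.

    Same strains carry the same alleles in both sexes, so a real expression
    effect should replicate.  Returns the 2x2 table (rows: female sig/insig,
    cols: male sig/insig), the one-sided Fisher p for joint-significance
    enrichment, and the sample odds ratio.
    """
    genes = sorted(set(results_female) & set(results_male))
    f = np.array([results_female[g] < alpha for g in genes])
    m = np.array([results_male[g] < alpha for g in genes])
    table = np.array(
        [
            [int((f & m).sum()), int((f & ~m).sum())],
            [int((~f & m).sum()), int((~f & ~m).sum())],
        ]
    )
    oratio_num = table[0, 0] * table[1, 1]
    oratio_den = table[0, 1] * table[1, 0]
    oratio = float("inf") if oratio_den == 0 and oratio_num > 0 else (
        oratio_num / oratio_den if oratio_den else 1.0
    )
    _, p = stats.fisher_exact(table, alternative="greater")
    return table, float(p), float(oratio)


def fpr_calibration(
    ranked_expr: pd.DataFrame,
    no_te_genes: Sequence[str],
    group_size_spectrum: Sequence[tuple[int, int]],
    n_genes: int,
    n_reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
) -> tuple[float, np.ndarray]:
    """Empirical false-positive rate of the permutation procedure.

    Per replicate, ``n_genes`` genes with no TE alleles are sampled; for each,
    a (n_with, n_without) pair is drawn from the observed group-size spectrum
    of the real tested genes and the strains are randomly partitioned
    accordingly, so the null mimics the real tests in everything but the TE
    labels.  Returns (mean proportion significant, per-replicate proportions).
    """
    if len(no_te_genes) < n_genes:
        raise ValueError("insufficient pool of no-TE genes")
    spectrum = [
        (kw, kn)
        for kw, kn in group_size_spectrum
        if kw >= MIN_GROUP and kn >= MIN_GROUP and math.comb(kw + kn, kw) > MIN_COMBINATIONS
    ]
    if not spectrum:
        raise ValueError("group-size spectrum contains no testable configurations")
    rng = np.random.default_rng(seed)
    strains = list(ranked_expr.columns)
    props = np.empty(n_reps)
    pool = list(no_te_genes)
    for rep in range(n_reps):
        genes = rng.choice(pool, size=n_genes, replace=False)
        n_sig = 0
        n_done = 0
        for g in genes:
            kw, kn = spectrum[rng.integers(len(spectrum))]
            chosen = rng.choice(strains, size=kw + kn, replace=False)
            row = ranked_expr.loc[g, chosen]
            if not np.isfinite(row.to_numpy(dtype=float)).all():
                continue
            mask = np.zeros(kw + kn, dtype=bool)
            mask[:kw] = True  # strains are already in random order
            res = exhaustive_permutation_test(
                row.to_numpy(dtype=float), mask, gene_id=str(g),
                enumeration_cap=enumeration_cap,
            )
            n_done += 1
            if res.p_one_tail < alpha:
                n_sig += 1
        props[rep] = n_sig / n_done if n_done else np.nan
    return float(np.nanmean(props)), props
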