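"""Haplotype blocks from D' confidence intervals, candidate prioritisation,
and enrichment scores.

Pairs of variants within a fixed span (default 5 Mb) are classified from the
90% confidence interval of |D'|: *strong LD* when the lower bound exceeds
0.7 and the upper bound reaches at least 0.9, *strong recombination* when
the upper bound stays below 0.7, and *uninformative* otherwise.  Intervals
in which at least 90% of the informative pairs show strong LD are haplotype
blocks; overlaps are resolved longest-first.  Within each block the most
severe significant variant (lowest p-value on ties) represents the block as
its candidate variant.

The |D'| confidence interval is a normalised-likelihood interval: haplotype
frequencies are estimated by EM from unphased two-locus genotype counts
(read off directly for phased input), the likelihood of the data is
evaluated on a 101-point grid of |D'| in [0, 1] with allele frequencies held
at their sample values, and the interval spans the 5th to 95th percentile of
the normalised likelihood mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .consequence import severity_rank

logger = logging.getLogger(__name__)

_GRID = np.linspace(0.0, 1.0, 101)


class LdClass(str, Enum):
    STRONG_LD = "strong_ld"
    STRONG_RECOMBINATION = "strong_recombination"
    UNINFORMATIVE = "uninformative"


def genotype_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 two-locus genotype count table from hard-call allele counts."""
    g1 = np.rint(np.asarray(g1)).astype(int)
    g2 = np.rint(np.asarray(g2)).astype(int)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors differ in length")
    table = np.zeros((3, 3), dtype=float)
    np.add.at(table, (g1, g2), 1.0)
    return table


def em_haplotype_freqs(table: np.ndarray, max_iter: int = 1000, tol: float = 1e-12) -> np.ndarray:
    """EM haplotype frequencies (f00, f01, f10, f11) from a 3x3 genotype table.

    Only the double heterozygote is phase-ambiguous; its haplotype pairs are
    split according to the current frequency estimates each iteration.
    Raises RuntimeError on non-convergence.
    """
    n = table.sum()
    if n == 0:
        raise ValueError("empty genotype table")
    # known haplotype contributions (all cells except the double het)
    base = np.zeros(4)  # 00, 01, 10, 11
    base[0] = 2 * table[0, 0] + table[0, 1] + table[1, 0]
    base[1] = 2 * table[0, 2] + table[0, 1] + table[1, 2]
    base[2] = 2 * table[2, 0] + table[2, 1] + table[1, 0]
    base[3] = 2 * table[2, 2] + table[2, 1] + table[1, 2]
    ndh = table[1, 1]
    f = np.full(4, 0.25)
    for _ in range(max_iter):
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        tot = coupling + repulsion
        w = 0.5 if tot == 0 else coupling / tot
        counts = base.copy()
        counts[0] += ndh * w
        counts[3] += ndh * w
        counts[1] += ndh * (1 - w)
        counts[2] += ndh * (1 - w)
        new = counts / (2 * n)
        if np.abs(new - f).max() < tol:
            return new
        f = new
    raise RuntimeError("EM did not converge in %d iterations" % max_iter)


def _hap_freqs_at(pa: float, pb: float, d: float) -> np.ndarray:
    f11 = pa * pb + d
    f10 = pa * (1 - pb) - d
    f01 = (1 - pa) * pb - d
    f00 = (1 - pa) * (1 - pb) + d
    return np.clip(np.array([f00, f01, f10, f11]), 1e-12, None)


def _geno_cell_probs(f: np.ndarray) -> np.ndarray:
    """Unphased genotype cell probabilities (3x3) from haplotype frequencies."""
    f00, f01, f10, f11 = f
    return np.array(
        [
            [f00**2, 2 * f00 * f01, f01**2],
            [2 * f00 * f10, 2 * f00 * f11 + 2 * f01 * f10, 2 * f01 * f11],
            [f10**2, 2 * f10 * f11, f11**2],
        ]
    )


def dprime_ci(
    g1: np.ndarray | None = None,
    g2: np.ndarray | None = None,
    *,
    haplotype_counts: np.ndarray | None = None,
    config: AnalysisConfig | None = None,
) -> tuple[float, float, float]:
    """(|D'| estimate, CI low, CI high) for one variant pair.

    Either unphased hard-call genotype vectors ``g1, g2`` or phased
    ``haplotype_counts`` (f00, f01, f10, f11 order) must be given.
    """
    if haplotype_counts is not None:
        hap_counts = np.asarray(haplotype_counts, dtype=float)
        if hap_counts.shape != (4,) or hap_counts.sum() == 0:
            raise ValueError("haplotype_counts must be 4 non-negative counts")
        f = hap_counts / hap_counts.sum()
        table = None
    else:
        table = genotype_table(g1, g2)
        f = em_haplotype_freqs(table)
    pa = f[2] + f[3]  # alt-allele frequency at locus A
    pb = f[1] + f[3]
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("both variants must be polymorphic")
    d = f[3] - pa * pb
    dmax = min(pa * (1 - pb), (1 - pa) * pb) if d >= 0 else min(pa * pb, (1 - pa) * (1 - pb))
    sign = 1.0 if d >= 0 else -1.0
    dprime = abs(d) / dmax if dmax > 0 else 0.0

    loglik = np.empty_like(_GRID)
    for i, dp in enumerate(_GRID):
        fg = _hap_freqs_at(pa, pb, sign * dp * dmax)
        if table is not None:
            probs = _geno_cell_probs(fg)
            loglik[i] = float(np.sum(table * np.log(probs)))
        else:
            loglik[i] = float(np.sum(hap_counts * np.log(fg)))
    mass = np.exp(loglik - loglik.max())
    cum = np.cumsum(mass) / mass.sum()
    low = float(_GRID[int(np.argmax(cum >= 0.05))])
    high = float(_GRID[int(np.argmax(cum >= 0.95))])
    return float(min(dprime, 1.0)), low, high


def classify_pair(low: float, high: float, config: AnalysisConfig | None = None) -> LdClass:
    """Classify a pair from its |D'| confidence interval."""
    cfg = config or AnalysisConfig()
    if not (0 <= low <= high <= 1):
        raise ValueError(f"invalid CI ({low}, {high})")
    if low > cfg.ci_strong_low and high >= cfg.ci_strong_high:
        return LdClass.STRONG_LD
    if high < cfg.ci_strong_low:
        return LdClass.STRONG_RECOMBINATION
    return LdClass.UNINFORMATIVE


def pairwise_classes(
    dosage: np.ndarray,
    positions: np.ndarray,
    config: AnalysisConfig | None = None,
) -> np.ndarray:
    """Pair-class matrix for all variant pairs within the configured span.

    Codes: +1 strong LD, -1 strong recombination, 0 uninformative or not
    evaluated (monomorphic member, beyond span, or EM failure).
    """
    cfg = config or AnalysisConfig()
    m = dosage.shape[0]
    classes = np.zeros((m, m), dtype=np.int8)
    hard = np.rint(dosage)
    af = hard.mean(axis=1) / 2.0
    poly = (af > 0) & (af < 1)
    for i in range(m):
        if not poly[i]:
            continue
        for j in range(i + 1, m):
            if not poly[j] or positions[j] - positions[i] > cfg.pair_span:
                continue
            try:
                _, low, high = dprime_ci(hard[i], hard[j], config=cfg)
            except (RuntimeError, ValueError):
                logger.info("pair (%d, %d) uninformative: CI unavailable", i, j)
                continue
            c = classify_pair(low, high, cfg)
            code = 1 if c is LdClass.STRONG_LD else (-1 if c is LdClass.STRONG_RECOMBINATION else 0)
            classes[i, j] = classes[j, i] = code
    return classes


@dataclass
class HaplotypeBlock:
    chrom: str
    start: int
    end: int
    member_indices: list[int]
    n_informative_pairs: int
    fraction_strong_ld: float


def _interval_ok(
    classes: np.ndarray,
    positions: np.ndarray,
    a: int,
    b: int,
    cfg: AnalysisConfig,
) -> tuple[bool, int, float]:
    n_inf = 0
    n_strong = 0
    for i in range(a, b):
        for j in range(i + 1, b + 1):
            if positions[j] - positions[i] > cfg.pair_span:
                continue
            c = classes[i, j]
            if c != 0:
                n_inf += 1
                n_strong += c == 1
    frac = n_strong / n_inf if n_inf else 0.0
    return (n_inf > 0 and frac >= cfg.informative_fraction), n_inf, frac


def find_blocks(
    classes: np.ndarray,
    positions: np.ndarray,
    chrom: str = "1",
    config: AnalysisConfig | None = None,
) -> list[HaplotypeBlock]:
    """Haplotype blocks for one chromosome.

    Every interval of >= 2 variants whose informative pairs (within the span)
    are at least 90% strong-LD is a candidate; the maximal non-overlapping
    set is chosen greedily, longest genomic span first, ties by leftmost
    start.  Deterministic given the input.
    """
    cfg = config or AnalysisConfig()
    positions = np.asarray(positions)
    m = len(positions)
    if m < 2:
        return []
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    candidates = []
    for a in range(m - 1):
        n_inf = 0
        n_strong = 0
        for b in range(a + 1, m):
            # incrementally add pairs (i, b) for i in [a, b)
            for i in range(a, b):
                if positions[b] - positions[i] > cfg.pair_span:
                    continue
                c = classes[i, b]
                if c != 0:
                    n_inf += 1
                    n_strong += c == 1
            if n_inf > 0 and n_strong / n_inf >= cfg.informative_fraction:
                candidates.append(
                    (int(positions[b] - positions[a]), a, b, n_inf, n_strong / n_inf)
                )
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for span, a, b, n_inf, frac in candidates:
        if taken[a : b + 1].any():
            continue
        taken[a : b + 1] = True
        blocks.append(
            HaplotypeBlock(
                chrom=chrom,
                start=int(positions[a]),
                end=int(positions[b]),
                member_indices=list(range(a, b + 1)),
                n_informative_pairs=n_inf,
                fraction_strong_ld=frac,
            )
        )
    blocks.sort(key=lambda blk: blk.start)
    return blocks


@dataclass
class CandidateVariant:
    block_start: int
    block_end: int
    variant_id: str
    category: str
    p_value: float
    selection_reason: str  # "severity" or "p-value tie-break"


def select_candidate(
    block: HaplotypeBlock,
    members: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> CandidateVariant | None:
    """Pick the block's candidate: most severe category among significant
    members, lowest p-value on ties, then lowest position.

    ``members`` needs columns variant_id, category, p_value, significant, pos.
    Returns None when the block holds no significant variant.
    """
    cfg = config or AnalysisConfig()
    pool = members if cfg.candidates_from_all_members else members[members["significant"]]
    if pool.empty:
        return None
    ranks = pool["category"].map(severity_rank)
    pool = pool.assign(_rank=ranks).sort_values(["_rank", "p_value", "pos"])
    top = pool.iloc[0]
    ties = (pool["_rank"] == top["_rank"]).sum()
    return CandidateVariant(
        block_start=block.start,
        block_end=block.end,
        variant_id=str(top["variant_id"]),
        category=str(top["category"]),
        p_value=float(top["p_value"]),
        selection_reason="severity" if ties == 1 else "p-value tie-break",
    )


def enrichment_score(
    n_sign_category: int,
    n_not_sign_category: int,
    n_sign_total: int,
    n_not_sign_total: int,
) -> float:
    """Natural-log ratio of category significant/non-significant odds to the
    overall odds.  Zero-count categories yield signed-infinity sentinels."""
    for v in (n_sign_category, n_not_sign_category, n_sign_total, n_not_sign_total):
        if v < 0:
            raise ValueError("negative count")
    if n_sign_total == 0 or n_not_sign_total == 0:
        raise ValueError("total significant and non-significant counts must be positive")
    if n_sign_category == 0:
        return -np.inf
    if n_not_sign_category == 0:
        return np.inf
    return float(
        np.log((n_sign_category / n_not_sign_category) / (n_sign_total / n_not_sign_total))
    )


def enrichment_table(categories: pd.Series, significant: pd.Series) -> pd.DataFrame:
    """Per-category enrichment scores over a full partition of variants."""
    categories = categories.astype(str)
    significant = significant.astype(bool).reindex(categories.index)
    n_sign_total = int(significant.sum())
    n_not_total = int((~significant).sum())
    rows = []
    for cat, idx in categories.groupby(categories).groups.items():
        s = int(significant.loc[idx].sum())
        ns = len(idx) - s
        try:
            score = enrichment_score(s, ns, n_sign_total, n_not_total)
        except ValueError:
            score = np.nan
        rows.append({"category": cat, "n_sign": s, "n_not_sign": ns, "enrichment_score": score})
    return pd.DataFrame(rows)


def fst_enrichment(candidate_fst: np.ndarray, category_fst: np.ndarray) -> float | None:
    """ln(median F_ST of candidates / median F_ST of their category)."""
    cand = np.asarray(candidate_fst, dtype=float)
    cat = np.asarray(category_fst, dtype=float)
    cand = cand[np.isfinite(cand)]
    cat = cat[np.isfinite(cat)]
    if cand.size == 0:
        return None
    if cat.size == 0:
        raise ValueError("empty category F_ST set")
    med_cand = float(np.median(cand))
    med_cat = float(np.median(cat))
    if med_cand <= 0 or med_cat <= 0:
        logger.warning("non-positive median F_ST; enrichment undefined")
        return None
    return float(np.log(med_cand / med_cat))
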