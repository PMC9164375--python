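"""Per-individual load of alleles by consequence category.

For each (consequence category x prevalence level) cell, the load of an
individual is the number and the percentage of the cell's variants carried in
the heterozygous state and in the homozygous state for the alternative
allele.  Large categories are down-sampled to a fixed number of variants
(default 50,000) so that percentages are comparable across categories; for
tolerated missense variants the sample is the variants with the highest SIFT
scores instead of a random draw.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .model import LineGenotypes

logger = logging.getLogger(__name__)


def sample_category(
    variant_ids: pd.Index | np.ndarray,
    rng: np.random.Generator,
    n_max: int = 50_000,
    sift_scores: np.ndarray | None = None,
) -> np.ndarray:
    """Subset of a category's variants used for load accounting.

    Categories at or below ``n_max`` are kept whole.  Otherwise a uniform
    sample without replacement is drawn, reproducible under the generator's
    seed.  When ``sift_scores`` is given (tolerated-missense mode), the
    ``n_max`` variants with the highest SIFT scores are taken instead, ties
    broken by variant key order.
    """
    ids = np.asarray(variant_ids)
    if ids.size == 0:
        raise ValueError("empty category")
    if sift_scores is not None:
        scores = np.asarray(sift_scores, dtype=float)
        order = np.lexsort((ids, -scores))  # descending score, then key order
        return np.sort(ids[order[:n_max]])
    if ids.size <= n_max:
        return ids
    return np.sort(rng.choice(ids, size=n_max, replace=False))


def genotype_state(dosage: np.ndarray) -> np.ndarray:
    """Hard-call states from dosages: 0 hom_ref [0,0.5), 1 het [0.5,1.5], 2 hom_alt (1.5,2]."""
    d = np.asarray(dosage, dtype=float)
    return np.where(d < 0.5, 0, np.where(d <= 1.5, 1, 2))


def individual_load(
    line: LineGenotypes,
    variant_rows: np.ndarray,
    category: str = "",
) -> pd.DataFrame:
    """Per-individual counts and percentages for one category's sampled variants.

    ``variant_rows`` indexes rows of the line's dosage matrix.  Variants not
    called in the line are dropped from the denominator (they cannot be
    carried).  Returns one row per individual with count_het / count_hom_alt
    and the matching percentages of the category size.
    """
    if len(variant_rows) == 0:
        raise ValueError("empty sampled variant set")
    d = line.dosage[variant_rows]
    called = np.isfinite(d).all(axis=1)
    if not called.all():
        logger.info(
            "line %s: %d of %d sampled variants not called; dropped from category",
            line.line_id,
            int((~called).sum()),
            len(variant_rows),
        )
        d = d[called]
    n_cat = d.shape[0]
    if n_cat == 0:
        raise ValueError(f"line {line.line_id}: no sampled variant is called")
    states = genotype_state(d)
    het = (states == 1).sum(axis=0)
    hom_alt = (states == 2).sum(axis=0)
    return pd.DataFrame(
        {
            "individual": line.individuals,
            "category": category,
            "n_variants_in_category": n_cat,
            "count_het": het,
            "count_hom_alt": hom_alt,
            "pct_het": 100.0 * het / n_cat,
            "pct_hom_alt": 100.0 * hom_alt / n_cat,
        }
    )


def cohort_load_summary(per_individual: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of counts and percentages across individuals, per category."""
    g = per_individual.groupby("category")
    out = g.agg(
        n_variants_in_category=("n_variants_in_category", "first"),
        mean_count_het=("count_het", "mean"),
        sd_count_het=("count_het", "std"),
        mean_count_hom_alt=("count_hom_alt", "mean"),
        sd_count_hom_alt=("count_hom_alt", "std"),
        mean_pct_het=("pct_het", "mean"),
        mean_pct_hom_alt=("pct_hom_alt", "mean"),
    )
    return out.reset_index()


def load_by_category(
    line: LineGenotypes,
    variant_index: pd.Index,
    categories: pd.Series,
    rng: np.random.Generator,
    config: AnalysisConfig | None = None,
    sift_scores: pd.Series | None = None,
) -> pd.DataFrame:
    """Run the load accounting for every category over one line.

    ``categories`` maps variant_id -> category label (e.g. consequence x
    prevalence cell); ``sift_scores`` triggers highest-SIFT sampling for the
    ``missense_tolerated`` category.
    """
    config = config or AnalysisConfig()
    pos_of = pd.Series(np.arange(len(variant_index)), index=variant_index)
    frames = []
    for cat, ids in categories.groupby(categories):
        ids = ids.index
        scores = None
        if sift_scores is not None and str(cat).startswith("missense_tolerated") and len(ids) > config.load_sample_size:
            scores = sift_scores.reindex(ids).to_numpy()
        chosen = sample_category(ids, rng, config.load_sample_size, sift_scores=scores)
        rows = pos_of[chosen].to_numpy()
        try:
            frames.append(individual_load(line, rows, category=str(cat)))
        except ValueError:
            logger.info("category %s has no called variants in line %s", cat, line.line_id)
    return pd.concat(frames, ignore_index=True)
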