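"""Predicted-consequence classification of variants.

Variants annotated with Sequence Ontology (SO) terms (e.g. from a VEP-style
annotation export) are resolved to a single most-severe category on a fixed
severity scale, upstream variants close to a transcription start site are
reclassified as promoter variants, missense variants are split by SIFT score
into deleterious / tolerated / unclassified, and a strand-aware relative
position within the transcript is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .config import AnalysisConfig

logger = logging.getLogger(__name__)

#: Categories from most to least severe.  Loss-of-function covers splice
#: acceptor/donor, stop-gain, stop-loss and start-loss; frameshift indels are
#: deliberately kept out of the LOF group because they behave differently in
#: population data and are reported separately.
SEVERITY_ORDER: tuple[str, ...] = (
    "splice_acceptor",
    "splice_donor",
    "stop_gain",
    "stop_loss",
    "start_loss",
    "frameshift_indel",
    "inframe_indel",
    "missense",
    "splice_region",
    "synonymous",
    "promoter_5utr",
    "3utr",
    "non_coding_transcript_exon",
    "intronic",
    "upstream_of_gene",
    "downstream_of_gene",
    "intergenic",
)

LOF_CATEGORIES = frozenset(
    {"splice_acceptor", "splice_donor", "stop_gain", "stop_loss", "start_loss"}
)

_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

#: SO term -> internal category.
SO_TERM_MAP: dict[str, str] = {
    "splice_acceptor_variant": "splice_acceptor",
    "splice_donor_variant": "splice_donor",
    "stop_gained": "stop_gain",
    "stop_lost": "stop_loss",
    "start_lost": "start_loss",
    "frameshift_variant": "frameshift_indel",
    "inframe_insertion": "inframe_indel",
    "inframe_deletion": "inframe_indel",
    "missense_variant": "missense",
    "protein_altering_variant": "missense",
    "splice_region_variant": "splice_region",
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
    "start_retained_variant": "synonymous",
    "5_prime_UTR_variant": "promoter_5utr",
    "3_prime_UTR_variant": "3utr",
    "non_coding_transcript_exon_variant": "non_coding_transcript_exon",
    "intron_variant": "intronic",
    "non_coding_transcript_variant": "intronic",
    "upstream_gene_variant": "upstream_of_gene",
    "downstream_gene_variant": "downstream_of_gene",
    "intergenic_variant": "intergenic",
    # already-internal names are accepted as-is, so our own simulator output
    # round-trips without a second vocabulary
    **{c: c for c in SEVERITY_ORDER},
}


def severity_rank(category: str) -> int:
    """Rank on the severity scale; 0 is most severe."""
    try:
        return _SEVERITY_RANK[category]
    except KeyError:
        raise KeyError(f"unknown consequence category: {category!r}") from None


def resolve_most_severe(terms: Iterable[str]) -> str:
    """Resolve a set of SO terms (multiple transcripts) to the most severe category."""
    terms = list(terms)
    if not terms:
        raise ValueError("empty SO term set")
    cats = []
    for t in terms:
        t = t.strip()
        if t not in SO_TERM_MAP:
            raise KeyError(f"unknown SO term: {t!r}")
        cats.append(SO_TERM_MAP[t])
    return min(cats, key=severity_rank)


def is_lof(category: str) -> bool:
    return category in LOF_CATEGORIES


def report_group(category: str) -> str:
    """Reporting-level grouping: LOF merged, promoter+5'UTR joined with 3'UTR."""
    if category in LOF_CATEGORIES:
        return "LOF"
    if category in ("promoter_5utr", "3utr"):
        return "promoter_utr"
    return category


def reclassify_promoter(
    category: str,
    variant_pos: int,
    strand: str,
    tss_pos: int | None,
    config: AnalysisConfig | None = None,
) -> str:
    """Move an upstream-of-gene variant into the promoter/5'UTR category when it
    lies within the promoter window upstream of the TSS on the transcribed strand.

    The distance is inclusive (a variant exactly at the window edge, or at the
    TSS itself, is reclassified).  A missing TSS leaves the category unchanged.
    """
    if category != "upstream_of_gene":
        raise ValueError("reclassify_promoter applies to upstream_of_gene variants only")
    window = (config or AnalysisConfig()).promoter_window
    if tss_pos is None or (isinstance(tss_pos, float) and np.isnan(tss_pos)):
        logger.warning("upstream variant at pos %d lacks a TSS; left unchanged", variant_pos)
        return category
    if strand not in ("+", "-"):
        raise ValueError(f"unknown strand {strand!r}")
    upstream_dist = tss_pos - variant_pos if strand == "+" else variant_pos - tss_pos
    if 0 <= upstream_dist <= window:
        return "promoter_5utr"
    return category


def classify_missense(sift_score: float | None, config: AnalysisConfig | None = None) -> str:
    """Split missense variants by SIFT: < cutoff deleterious, >= cutoff tolerated,
    absent score unclassified."""
    cutoff = (config or AnalysisConfig()).sift_cutoff
    if sift_score is None or (isinstance(sift_score, float) and np.isnan(sift_score)):
        return "unclassified"
    if not (0.0 <= sift_score <= 1.0):
        raise ValueError(f"SIFT score outside [0, 1]: {sift_score}")
    return "deleterious" if sift_score < cutoff else "tolerated"


def relative_position(variant_pos: int, tx_start: int, tx_end: int, strand: str) -> float:
    """Position within the transcript as a fraction of its length.

    0 at the transcription start, 1 at the transcript end, linear in between;
    for a minus-strand transcript the transcription start is the high
    reference coordinate.
    """
    if tx_end <= tx_start:
        raise ValueError("transcript span must satisfy tx_end > tx_start")
    if not (tx_start <= variant_pos <= tx_end):
        raise ValueError(
            f"variant at {variant_pos} outside transcript span [{tx_start}, {tx_end}]"
        )
    length = tx_end - tx_start
    if strand == "+":
        return (variant_pos - tx_start) / length
    if strand == "-":
        return (tx_end - variant_pos) / length
    raise ValueError(f"unknown strand {strand!r}")


@dataclass
class AnnotationResult:
    """Resolved annotation table plus bookkeeping counts."""

    table: pd.DataFrame
    n_promoter_reclassified: int
    n_upstream_initial: int


def read_annotation(path: str) -> pd.DataFrame:
    """Read an annotation TSV (variant_id, so_terms, sift_score, transcript_id,
    strand, tss_pos, tx_start, tx_end)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"variant_id": str, "so_terms": str})
    req = {"variant_id", "so_terms"}
    if not req.issubset(df.columns):
        raise ValueError(f"annotation table needs at least columns {sorted(req)}")
    return df


def annotate(annotation: pd.DataFrame, config: AnalysisConfig | None = None) -> AnnotationResult:
    """Resolve each variant's category (most-severe rule, promoter
    reclassification, missense SIFT split).

    Returns one row per variant with columns ``category`` (fine-grained),
    ``missense_class``, ``sift_score``, ``relative_position`` and
    ``severity_rank``.
    """
    config = config or AnalysisConfig()
    rows = []
    n_upstream = 0
    n_reclass = 0
    for rec in annotation.itertuples(index=False):
        terms = str(rec.so_terms).split(",")
        cat = resolve_most_severe(terms)
        sift = getattr(rec, "sift_score", None)
        sift = None if sift is None or pd.isna(sift) else float(sift)
        if sift is not None and cat != "missense":
            # a SIFT score only makes sense for missense annotations
            raise ValueError(
                f"{rec.variant_id}: SIFT score present but resolved category is {cat}"
            )
        pos = int(rec.variant_id.split(":")[1])
        strand = getattr(rec, "strand", None)
        if cat == "upstream_of_gene":
            n_upstream += 1
            tss = getattr(rec, "tss_pos", None)
            tss = None if tss is None or pd.isna(tss) else int(tss)
            if strand is not None and not pd.isna(strand):
                newcat = reclassify_promoter(cat, pos, str(strand), tss, config)
                if newcat != cat:
                    n_reclass += 1
                    cat = newcat
        missense_class = classify_missense(sift, config) if cat == "missense" else ""
        tx_start = getattr(rec, "tx_start", None)
        tx_end = getattr(rec, "tx_end", None)
        relpos = np.nan
        if (
            tx_start is not None
            and tx_end is not None
            and not (pd.isna(tx_start) or pd.isna(tx_end) or pd.isna(strand))
            and int(tx_start) <= pos <= int(tx_end)
        ):
            relpos = relative_position(pos, int(tx_start), int(tx_end), str(strand))
        rows.append(
            (
                rec.variant_id,
                cat,
                missense_class,
                np.nan if sift is None else sift,
                relpos,
                severity_rank(cat),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "category",
            "missense_class",
            "sift_score",
            "relative_position",
            "severity_rank",
        ],
    )
    return AnnotationResult(table, n_reclass, n_upstream)


def load_category(table: pd.DataFrame) -> pd.Series:
    """Category label used by the load/enrichment analyses: missense split into
    its SIFT subclasses, everything else at the fine-grained category."""
    cat = table["category"].copy()
    m = cat == "missense"
    cat[m] = "missense_" + table.loc[m, "missense_class"]
    return cat
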