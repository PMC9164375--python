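"""Per-site population statistics across lines.

For every variant we compute the per-line alternative-allele frequency, the
segregation flag (0 < p < 1), the prevalence level k (number of lines in
which the variant segregates; k=1 "private", k=L "widespread") and Wright's
fixation index among the lines in which the variant segregates,

    F_ST = (H_T - H_S) / H_T,

where H_T = 2 p̄ (1 - p̄) is the expected heterozygosity of the mean
frequency across those lines and H_S is the mean of the within-line expected
heterozygosities 2 p_l (1 - p_l), both under Hardy-Weinberg equilibrium.
Lines enter the means unweighted (a Hudson-style sample-size weighting is
available as a config option).  F_ST is undefined (reported absent) when the
variant segregates in fewer than two lines.

Windowed variant-density statistics against a recombination map round out
the module.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .model import MultiLineCohort, RecombinationMap

logger = logging.getLogger(__name__)


def allele_frequency(dosage: np.ndarray) -> float:
    """Alternative-allele frequency of one line at one site: mean(dosage)/2.

    All-absent input (variant not called in the line) yields NaN.
    """
    d = np.asarray(dosage, dtype=float)
    if not np.isfinite(d).any():
        return np.nan
    return float(np.nanmean(d) / 2.0)


def line_frequencies(cohort: MultiLineCohort) -> pd.DataFrame:
    """Per-variant, per-line alternative-allele frequencies (NaN = not called)."""
    cols = {}
    for lid, lg in cohort.lines.items():
        finite = np.isfinite(lg.dosage)
        n = finite.sum(axis=1)
        s = np.where(finite, lg.dosage, 0.0).sum(axis=1)
        cols[lid] = np.where(n > 0, s / np.maximum(n, 1) / 2.0, np.nan)
    return pd.DataFrame(cols, index=cohort.variant_ids)


def prevalence_level(freqs: np.ndarray) -> np.ndarray:
    """Number of lines with 0 < p < 1, per variant (rows = variants)."""
    f = np.asarray(freqs, dtype=float)
    seg = (f > 0) & (f < 1)
    return seg.sum(axis=-1)


def site_fst(freqs: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, float, float]:
    """(F_ST, H_T, H_S) for one variant from the frequencies of the lines
    included in the comparison (the caller restricts to segregating lines).

    Requires at least two frequencies.  With unweighted means H_T >= H_S by
    Jensen's inequality, so F_ST lands in [0, 1] without clamping; this is
    asserted rather than clipped.
    """
    p = np.asarray(freqs, dtype=float)
    if p.size < 2:
        raise ValueError("F_ST needs at least two lines")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies outside [0, 1]")
    if weights is None:
        pbar = p.mean()
        hs = float(np.mean(2 * p * (1 - p)))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        pbar = float(np.sum(w * p))
        hs = float(np.sum(w * 2 * p * (1 - p)))
    ht = float(2 * pbar * (1 - pbar))
    if ht == 0.0:
        # cannot occur for segregating lines (0 < p < 1 forces 0 < pbar < 1)
        return np.nan, ht, hs
    fst = (ht - hs) / ht
    if weights is None:
        assert fst >= -1e-12, f"negative F_ST {fst} under unweighted means"
        fst = max(fst, 0.0)
    if abs(fst) < 1e-15:  # snap rounding residue so equal frequencies give exactly 0
        fst = 0.0
    return float(fst), ht, hs


def compute_site_stats(
    cohort: MultiLineCohort, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Vectorised per-variant statistics table.

    Columns: ``af_<line>`` per line, ``k`` (prevalence level), ``n_called``,
    ``prevalence_class`` (private / intermediate / widespread /
    non_segregating), ``HT``, ``HS``, ``FST`` (NaN when k < 2).
    """
    config = config or AnalysisConfig()
    af = line_frequencies(cohort)
    fmat = af.to_numpy()
    L = cohort.n_lines
    called = np.isfinite(fmat)
    seg = (fmat > 0) & (fmat < 1)
    include = called if config.fst_mode == "called" else seg
    k = seg.sum(axis=1)

    inc = np.where(include, np.nan_to_num(fmat), 0.0)
    n_inc = include.sum(axis=1)
    enough = n_inc >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        if config.fst_weighted:
            sizes = np.array([cohort.lines[l].n_individuals for l in af.columns], dtype=float)
            wsum = np.where(include, sizes, 0.0).sum(axis=1)
            pbar = (inc * sizes).sum(axis=1) / wsum
            hs = (2 * inc * (1 - inc) * sizes * include).sum(axis=1) / wsum
        else:
            denom = np.maximum(n_inc, 1)
            pbar = inc.sum(axis=1) / denom
            hs = (2 * inc * (1 - inc) * include).sum(axis=1) / denom
    ht = 2 * pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(enough & (ht > 0), (ht - hs) / ht, np.nan)
    if not config.fst_weighted:
        bad = fst[np.isfinite(fst)]
        assert bad.size == 0 or bad.min() >= -1e-12, "negative F_ST under unweighted means"
        fst = np.where(np.isfinite(fst), np.maximum(fst, 0.0), np.nan)
    fst = np.where(np.abs(fst) < 1e-15, 0.0, fst)

    cls = np.where(
        k == 0, "non_segregating", np.where(k == 1, "private", np.where(k == L, "widespread", "intermediate"))
    )
    out = af.add_prefix("af_")
    out["k"] = k
    out["n_called"] = called.sum(axis=1)
    out["prevalence_class"] = cls
    out["HT"] = np.where(enough, ht, np.nan)
    out["HS"] = np.where(enough, hs, np.nan)
    out["FST"] = fst
    return out


def mean_segregating_af(site_stats: pd.DataFrame) -> pd.Series:
    """Per-variant mean alternative-allele frequency over segregating lines."""
    af = site_stats.filter(like="af_").to_numpy()
    seg = (af > 0) & (af < 1)
    with np.errstate(invalid="ignore"):
        vals = np.nansum(np.where(seg, af, 0.0), axis=1) / np.maximum(seg.sum(axis=1), 1)
    vals[seg.sum(axis=1) == 0] = np.nan
    return pd.Series(vals, index=site_stats.index, name="mean_af")


def window_stats(
    cohort: MultiLineCohort,
    site_stats: pd.DataFrame,
    recomb_map: RecombinationMap,
) -> pd.DataFrame:
    """Per-window variant counts by prevalence class and density (variants/bp).

    Windows come from the recombination map (half-open).  Variants falling
    outside every window are counted in a diagnostic bin logged at INFO level.
    """
    w = recomb_map.windows
    chroms = np.array([v.chrom for v in cohort.variants])
    pos = np.array([v.pos for v in cohort.variants])
    cls = site_stats["prevalence_class"].to_numpy()

    rows = []
    assigned = np.zeros(len(pos), dtype=bool)
    for rec in w.itertuples(index=False):
        in_w = (chroms == rec.chrom) & (pos - 1 >= rec.start) & (pos - 1 < rec.end)
        assigned |= in_w
        cw = cls[in_w]
        n = int(in_w.sum())
        length = rec.end - rec.start
        rows.append(
            {
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "rate": rec.rate,
                "n_variants": n,
                "n_private": int((cw == "private").sum()),
                "n_widespread": int((cw == "widespread").sum()),
                "n_intermediate": int((cw == "intermediate").sum()),
                "density": n / length,
                "density_private": (cw == "private").sum() / length,
                "density_widespread": (cw == "widespread").sum() / length,
            }
        )
    n_out = int((~assigned).sum())
    if n_out:
        logger.info("%d variants fall outside every map window", n_out)
    return pd.DataFrame(rows)


def density_recombination_correlation(
    window_df: pd.DataFrame, which: str = "all"
) -> tuple[float, float] | None:
    """Pearson correlation (r, two-sided p) between per-window variant density
    and recombination rate; ``which`` selects all/private/widespread density.

    Returns None when either series is degenerate (zero variance) or there are
    fewer than three windows.
    """
    col = {"all": "density", "private": "density_private", "widespread": "density_widespread"}[which]
    x = window_df["rate"].to_numpy(float)
    y = window_df[col].to_numpy(float)
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("degenerate density/rate series; correlation undefined")
        return None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
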