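"""Synthetic multi-line cohort generator.

The generator emulates the statistical structure that the analysis assumes:

* **Line divergence.**  Shared variants follow the Balding-Nichols model:
  given an ancestral alternative-allele frequency ``p`` and a line
  differentiation parameter ``F``, each line's frequency is drawn from
  ``Beta(p (1-F)/F, (1-p)(1-F)/F)``, so that ``E[p_l] = p`` and
  ``Var(p_l) = F p (1-p)``.
* **Prevalence structure.**  A configurable fraction of variants is private:
  called in a single line only, with a low-frequency spectrum.  Together with
  the rare-skewed ancestral spectrum this yields the characteristic pattern
  that low-prevalence variants are rare and high-prevalence variants common.
* **Purifying selection.**  Frequencies of deleterious categories (LOF and
  deleterious missense by default) are down-shifted by a per-category
  multiplier, depleting their allele frequencies and homozygous-alternative
  load.
* **Genome structure.**  Variant positions are placed with intensity
  proportional to ``1 + coupling * recombination rate`` over 1-Mb windows,
  producing a positive density-recombination correlation.
* **Phenotypes.**  Trait values are a sum of sparse causal-variant effects
  (each solved to hit a target share of phenotypic variance), a polygenic
  background built from random marker effects, and white noise.

Genotypes are drawn ``Binomial(2, p_l)`` per individual by default (linkage
equilibrium); the haplotype-copying mode samples individuals as pairs of
haplotypes from a finite per-line pool of size ``hap_pool_size``, which
induces LD whose strength grows as the pool shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import write_table, write_vcf
from .model import DepthTable, LineGenotypes, MultiLineCohort, RecombinationMap, VariantKey

#: Genome-wide consequence composition (fractions) patterned on the
#: composition of a commercial pig sequencing panel; realistic but leaves
#: coding categories nearly empty at desk-scale variant counts.
DEFAULT_CATEGORY_MIXTURE: dict[str, float] = {
    "splice_acceptor": 0.00009,
    "splice_donor": 0.00009,
    "stop_gain": 0.00009,
    "stop_loss": 0.00003,
    "start_loss": 0.00002,
    "frameshift_indel": 0.00027,
    "inframe_indel": 0.00006,
    "missense": 0.00393,
    "splice_region": 0.00090,
    "synonymous": 0.00316,
    "promoter_5utr": 0.00810,
    "3utr": 0.01370,
    "non_coding_transcript_exon": 0.00111,
    "intronic": 0.46981,
    "upstream_of_gene": 0.03015,
    "downstream_of_gene": 0.02692,
    "intergenic": 0.44157,
}


def coding_enriched_mixture() -> dict[str, float]:
    """Mixture with inflated coding fractions so that per-category analyses
    (load, enrichment) have usable counts at desk-scale variant numbers."""
    return {
        "splice_acceptor": 0.005,
        "splice_donor": 0.005,
        "stop_gain": 0.01,
        "stop_loss": 0.003,
        "start_loss": 0.002,
        "frameshift_indel": 0.015,
        "inframe_indel": 0.005,
        "missense": 0.15,
        "splice_region": 0.02,
        "synonymous": 0.12,
        "promoter_5utr": 0.05,
        "3utr": 0.05,
        "non_coding_transcript_exon": 0.01,
        "intronic": 0.25,
        "upstream_of_gene": 0.05,
        "downstream_of_gene": 0.03,
        "intergenic": 0.23,
    }


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic multi-line cohort."""

    n_lines: int = 5
    n_variants: int = 20_000
    n_individuals: int = 100
    #: Balding-Nichols differentiation parameter; scalar applied to all lines.
    F: float = 0.2
    #: Beta(a, b) ancestral alternative-allele frequency spectrum (rare-skewed).
    ancestral_beta: tuple[float, float] = (0.3, 1.2)
    #: Fraction of variants private to a single line.
    private_fraction: float = 0.28
    #: Beta(a, b) frequency spectrum of private variants within their line.
    private_beta: tuple[float, float] = (0.5, 10.0)
    #: Consequence-category mixture (normalised internally).
    category_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIXTURE)
    )
    #: Multiplicative down-shift of generating frequencies per category; the
    #: key "missense_deleterious" targets missense variants with SIFT < 0.05.
    selection_shift: dict[str, float] = field(
        default_factory=lambda: {
            "splice_acceptor": 0.3,
            "splice_donor": 0.3,
            "stop_gain": 0.3,
            "stop_loss": 0.3,
            "start_loss": 0.3,
            "missense_deleterious": 0.25,
        }
    )
    #: Fraction of missense variants that are deleterious (SIFT < 0.05) and
    #: fraction with no SIFT score at all (unclassified).
    missense_deleterious_fraction: float = 0.25
    missense_unclassified_fraction: float = 0.10
    #: Fraction of upstream-of-gene variants placed within the promoter window.
    promoter_fraction: float = 0.066
    n_chromosomes: int = 2
    chromosome_length: int = 10_000_000
    #: Gamma(shape, scale) recombination rate per 1-Mb window (cM/Mb).
    recomb_gamma: tuple[float, float] = (2.0, 0.6)
    #: Variant placement intensity = 1 + coupling * rate.
    density_coupling: float = 2.0
    mean_coverage: float = 4.1
    depth_outlier_fraction: float = 0.01
    depth_outlier_multiplier: float = 5.0
    genotype_mode: str = "binomial"  # or "haplotype"
    hap_pool_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("need at least two lines")
        if not (0 < self.F < 1):
            raise ValueError("F must be in (0, 1)")
        if not (0 <= self.private_fraction < 1):
            raise ValueError("private_fraction must be in [0, 1)")
        total = sum(self.category_mixture.values())
        if total <= 0:
            raise ValueError("category mixture must have positive mass")
        self.category_mixture = {k: v / total for k, v in self.category_mixture.items()}
        if self.genotype_mode not in ("binomial", "haplotype"):
            raise ValueError("genotype_mode must be 'binomial' or 'haplotype'")
        n_windows = self.n_chromosomes * (self.chromosome_length // 1_000_000)
        if self.n_variants > n_windows * 900_000:
            raise ValueError("variant count infeasible for the genome size")


@dataclass
class SimulationResult:
    cohort: MultiLineCohort
    annotation: pd.DataFrame
    recomb_map: RecombinationMap
    depth_table: DepthTable
    ground_truth: pd.DataFrame
    config: SimulationConfig


_SO_EMIT = {  # internal category -> canonical SO term written to the annotation table
    "splice_acceptor": "splice_acceptor_variant",
    "splice_donor": "splice_donor_variant",
    "stop_gain": "stop_gained",
    "stop_loss": "stop_lost",
    "start_loss": "start_lost",
    "frameshift_indel": "frameshift_variant",
    "inframe_indel": "inframe_insertion",
    "missense": "missense_variant",
    "splice_region": "splice_region_variant",
    "synonymous": "synonymous_variant",
    "promoter_5utr": "5_prime_UTR_variant",
    "3utr": "3_prime_UTR_variant",
    "non_coding_transcript_exon": "non_coding_transcript_exon_variant",
    "intronic": "intron_variant",
    "upstream_of_gene": "upstream_gene_variant",
    "downstream_of_gene": "downstream_gene_variant",
    "intergenic": "intergenic_variant",
}

_TRANSCRIBED = {
    "splice_acceptor", "splice_donor", "stop_gain", "stop_loss", "start_loss",
    "frameshift_indel", "inframe_indel", "missense", "splice_region", "synonymous",
    "promoter_5utr", "3utr", "non_coding_transcript_exon", "intronic",
}

_BASES = np.array(list("ACGT"))


def _make_recomb_map(cfg: SimulationConfig, rng: np.random.Generator) -> RecombinationMap:
    rows = []
    shape, scale = cfg.recomb_gamma
    for c in range(1, cfg.n_chromosomes + 1):
        for start in range(0, cfg.chromosome_length, 1_000_000):
            end = min(start + 1_000_000, cfg.chromosome_length)
            rows.append({"chrom": str(c), "start": start, "end": end,
                         "rate": float(rng.gamma(shape, scale))})
    return RecombinationMap(pd.DataFrame(rows))


def _place_positions(
    cfg: SimulationConfig, rmap: RecombinationMap, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(chrom labels, positions) sampled with window intensity 1 + c * rate."""
    w = rmap.windows
    weight = (1.0 + cfg.density_coupling * w["rate"].to_numpy()) * (
        w["end"] - w["start"]
    ).to_numpy()
    widx = rng.choice(len(w), size=cfg.n_variants, p=weight / weight.sum())
    chroms = w["chrom"].to_numpy()[widx]
    starts = w["start"].to_numpy()[widx]
    ends = w["end"].to_numpy()[widx]
    pos = rng.integers(starts + 1, ends + 1)  # 1-based within half-open window
    order = np.lexsort((pos, chroms.astype(int)))
    chroms, pos = chroms[order], pos[order]
    # bump duplicate positions within a chromosome so variant keys are unique
    for c in np.unique(chroms):
        m = chroms == c
        p = pos[m]
        for i in range(1, len(p)):
            if p[i] <= p[i - 1]:
                p[i] = p[i - 1] + 1
        pos[m] = p
    return chroms, pos


def simulate_cohort(cfg: SimulationConfig) -> SimulationResult:
    """Generate a cohort, annotation, recombination map, depth table and
    ground-truth record from one seeded RNG stream."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_lines
    n = cfg.n_variants
    line_ids = [chr(ord("A") + i) for i in range(L)]

    rmap = _make_recomb_map(cfg, rng)
    chroms, pos = _place_positions(cfg, rmap, rng)

    cats = rng.choice(
        list(cfg.category_mixture), size=n, p=list(cfg.category_mixture.values())
    )
    # SIFT scores for missense variants
    sift = np.full(n, np.nan)
    is_mis = cats == "missense"
    n_mis = int(is_mis.sum())
    if n_mis:
        u = rng.random(n_mis)
        s = np.where(
            u < cfg.missense_deleterious_fraction,
            rng.uniform(0.0, 0.05, n_mis),
            rng.uniform(0.05, 1.0, n_mis),
        )
        s[rng.random(n_mis) < cfg.missense_unclassified_fraction] = np.nan
        sift[is_mis] = s

    # selection shift per variant
    shift = np.ones(n)
    for cat, s in cfg.selection_shift.items():
        if cat == "missense_deleterious":
            shift[is_mis & (sift < 0.05)] = s
        else:
            shift[cats == cat] = s

    is_private = rng.random(n) < cfg.private_fraction
    private_line = np.where(is_private, rng.integers(0, L, size=n), -1)

    a, b = cfg.ancestral_beta
    p_anc = np.clip(rng.beta(a, b, size=n) * shift, 1e-4, 1 - 1e-4)
    F = cfg.F
    line_freq = np.empty((n, L))
    bn_a = p_anc * (1 - F) / F
    bn_b = (1 - p_anc) * (1 - F) / F
    for l in range(L):
        line_freq[:, l] = rng.beta(bn_a, bn_b)
    pa, pb = cfg.private_beta
    priv_freq = np.clip(rng.beta(pa, pb, size=n) * shift, 1e-4, 1 - 1e-4)
    for l in range(L):
        mine = private_line == l
        line_freq[mine, l] = priv_freq[mine]
        line_freq[is_private & ~mine, l] = np.nan  # not called in other lines

    # alleles: SNVs for most categories, short indels for the indel categories
    ref = rng.choice(_BASES, size=n)
    alt = np.empty(n, dtype=object)
    for i in range(n):
        if cats[i] == "frameshift_indel":
            alt[i] = ref[i] + "".join(rng.choice(_BASES, size=1))
        elif cats[i] == "inframe_indel":
            alt[i] = ref[i] + "".join(rng.choice(_BASES, size=3))
        else:
            choices = [x for x in "ACGT" if x != ref[i]]
            alt[i] = choices[rng.integers(0, 3)]
    variants = [
        VariantKey(str(chroms[i]), int(pos[i]), str(ref[i]), str(alt[i])) for i in range(n)
    ]

    lines = {}
    for l, lid in enumerate(line_ids):
        called = ~is_private | (private_line == l)
        dosage = np.full((n, cfg.n_individuals), np.nan)
        pl = line_freq[:, l]
        idx = np.where(called)[0]
        if cfg.genotype_mode == "binomial":
            dosage[idx] = rng.binomial(2, pl[idx, None], size=(len(idx), cfg.n_individuals))
        else:
            pool = rng.random((len(idx), cfg.hap_pool_size)) < pl[idx, None]
            h1 = rng.integers(0, cfg.hap_pool_size, size=cfg.n_individuals)
            h2 = rng.integers(0, cfg.hap_pool_size, size=cfg.n_individuals)
            dosage[idx] = pool[:, h1].astype(float) + pool[:, h2].astype(float)
        lines[lid] = LineGenotypes(lid, [f"{lid}{j:04d}" for j in range(cfg.n_individuals)], dosage)
    cohort = MultiLineCohort(variants, lines)

    annotation = _make_annotation(cfg, rng, variants, cats, sift)

    depth = rng.gamma(10.0, cfg.mean_coverage / 10.0, size=n)
    outlier = rng.random(n) < cfg.depth_outlier_fraction
    depth[outlier] *= cfg.depth_outlier_multiplier
    depth_table = DepthTable(depth, cfg.mean_coverage)

    truth = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "true_category": cats,
            "true_sift": sift,
            "selection_shift": shift,
            "ancestral_freq": p_anc,
            "private_line": [line_ids[l] if l >= 0 else "" for l in private_line],
            "depth_outlier": outlier,
        }
    )
    for l, lid in enumerate(line_ids):
        truth[f"true_freq_{lid}"] = line_freq[:, l]
    # the generated category of upstream variants that the promoter rule will
    # reclassify is recorded from the annotation geometry
    truth["true_category_resolved"] = truth["true_category"].where(
        ~annotation["_promoter_target"].to_numpy(), "promoter_5utr"
    )
    annotation = annotation.drop(columns=["_promoter_target"])
    return SimulationResult(cohort, annotation, rmap, depth_table, truth, cfg)


def _make_annotation(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    variants: list[VariantKey],
    cats: np.ndarray,
    sift: np.ndarray,
) -> pd.DataFrame:
    """Annotation table in the external TSV schema (variant_id, so_terms,
    sift_score, transcript_id, strand, tss_pos, tx_start, tx_end)."""
    n = len(variants)
    window = AnalysisConfig().promoter_window
    strands = rng.choice(["+", "-"], size=n)
    rows = []
    for i, v in enumerate(variants):
        cat = cats[i]
        terms = [_SO_EMIT[cat]]
        # a second, milder transcript consequence exercises most-severe resolution
        if cat not in ("intergenic", "upstream_of_gene", "downstream_of_gene") and rng.random() < 0.3:
            terms.append("intron_variant")
        rng.shuffle(terms)
        strand = strands[i]
        tx_start = tx_end = tss = np.nan
        promoter_target = False
        if cat in _TRANSCRIBED:
            length = int(rng.integers(1_000, 20_000))
            offset = int(rng.integers(0, length))
            tx_start = max(1, v.pos - offset)
            tx_end = tx_start + length
            tss = tx_start if strand == "+" else tx_end
        elif cat == "upstream_of_gene":
            if rng.random() < cfg.promoter_fraction:
                d = int(rng.integers(1, window + 1))
                promoter_target = True
            else:
                d = int(rng.integers(window + 1, 5_000))
            tss = v.pos + d if strand == "+" else max(1, v.pos - d)
            if tss < 1:
                tss = np.nan
                promoter_target = False
        rows.append(
            {
                "variant_id": v.variant_id,
                "so_terms": ",".join(terms),
                "sift_score": sift[i],
                "transcript_id": f"TX{i:06d}" if not np.isnan(tss) else "",
                "strand": strand,
                "tss_pos": tss,
                "tx_start": tx_start,
                "tx_end": tx_end,
                "_promoter_target": promoter_target,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PhenotypeArchitecture:
    """Sparse causal variants plus polygenic background."""

    variance_targets: tuple[float, ...] = (0.03,)  # per causal variant, share of var(y)
    h2_polygenic: float = 0.3
    n_polygenic_markers: int = 2_000
    causal_af_range: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.variance_targets):
            raise ValueError("negative variance target")
        if not (0 <= self.h2_polygenic <= 1):
            raise ValueError("h2_polygenic must be in [0, 1]")
        if sum(self.variance_targets) + self.h2_polygenic >= 1.0:
            raise ValueError("causal targets plus polygenic variance exceed total variance")


def simulate_phenotypes(
    cohort: MultiLineCohort,
    line_id: str,
    architecture: PhenotypeArchitecture,
    seed: int,
    trait: str = "trait1",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Phenotypes for one line: y = sum_c x_c beta_c + g + e.

    Each causal effect is solved so that its realized genotypic variance
    beta_c^2 Var(x_c) equals the target share of the unit total variance; the
    polygenic term g is built from random effects on a random marker subset
    and scaled to the target background variance.  Returns (phenotype table,
    causal-effect ground truth, info dict with realized components).
    """
    rng = np.random.default_rng(seed)
    line = cohort.lines[line_id]
    D = line.dosage
    called = np.isfinite(D).all(axis=1)
    af = np.full(D.shape[0], np.nan)
    af[called] = D[called].mean(axis=1) / 2.0
    lo, hi = architecture.causal_af_range
    eligible = np.where(called & (af >= lo) & (af <= hi))[0]
    k = len(architecture.variance_targets)
    if len(eligible) < k:
        raise ValueError("not enough polymorphic variants for the causal architecture")
    causal = rng.choice(eligible, size=k, replace=False)

    n_ind = line.n_individuals
    y = np.zeros(n_ind)
    effects = []
    for c, target in zip(causal, architecture.variance_targets):
        x = D[c] - D[c].mean()
        vx = float(np.var(x))
        beta = np.sqrt(target / vx) if target > 0 else 0.0
        y += beta * x
        effects.append(
            {
                "variant_id": cohort.variants[c].variant_id,
                "beta_true": beta,
                "af": float(af[c]),
                "target_variance_pct": 100.0 * target,
            }
        )

    g = np.zeros(n_ind)
    if architecture.h2_polygenic > 0:
        poly_pool = np.where(called & (af > 0) & (af < 1))[0]
        poly_pool = poly_pool[~np.isin(poly_pool, causal)]
        m = min(architecture.n_polygenic_markers, len(poly_pool))
        markers = rng.choice(poly_pool, size=m, replace=False)
        W = D[markers] - D[markers].mean(axis=1, keepdims=True)
        alpha = rng.normal(size=m)
        g = alpha @ W
        vg = float(np.var(g))
        if vg > 0:
            g *= np.sqrt(architecture.h2_polygenic / vg)
    sigma_e2 = 1.0 - sum(architecture.variance_targets) - architecture.h2_polygenic
    e = rng.normal(scale=np.sqrt(sigma_e2), size=n_ind)
    y = y + g + e

    var_y = float(np.var(y))
    for eff in effects:
        eff["realized_variance_pct"] = (
            100.0 * eff["beta_true"] ** 2
            * 2 * eff["af"] * (1 - eff["af"]) / var_y
        )
    pheno = pd.DataFrame({"individual": line.individuals, "trait": trait, "value": y})
    info = {
        "realized_h2_polygenic": float(np.var(g) / var_y),
        "realized_var_y": var_y,
        "sigma_e2": sigma_e2,
    }
    return pheno, pd.DataFrame(effects), info


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as one VCF per line plus annotation, map, depth and
    ground-truth TSVs.  Returns the paths keyed by artefact name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = AnalysisConfig(seed=result.config.seed)
    paths: dict[str, Path] = {}
    for lid, line in result.cohort.lines.items():
        p = outdir / f"line_{lid}.vcf"
        write_vcf(p, result.cohort.variants, line.individuals, np.nan_to_num(line.dosage),
                  called=line.called)
        paths[f"vcf_{lid}"] = p
    for name, df in (
        ("annotation", result.annotation),
        ("recomb_map", result.recomb_map.windows),
        ("ground_truth", result.ground_truth),
    ):
        p = outdir / f"{name}.tsv"
        write_table(df, p, cfg)
        paths[name] = p
    p = outdir / "depth.tsv"
    write_table(
        pd.DataFrame(
            {
                "variant_id": [v.variant_id for v in result.cohort.variants],
                "depth": result.depth_table.depth,
                "mean_coverage": result.depth_table.mean_coverage,
            }
        ),
        p,
        cfg,
    )
    paths["depth"] = p
    return paths
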