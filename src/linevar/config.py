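"""Analysis configuration: the thresholds used across all stages, with defaults.

Every output table echoes the configuration and the RNG seed as ``#`` comment
lines so that any result file is traceable to the settings that produced it.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass


@dataclass
class AnalysisConfig:
    #: GWAS significance threshold on the p-value.
    alpha: float = 1e-6
    #: D' confidence-interval lower bound for a strong-LD call.
    ci_strong_low: float = 0.7
    #: D' confidence-interval upper bound that a strong-LD call must reach.
    ci_strong_high: float = 0.9
    #: Maximum pair distance (bp) at which LD is evaluated.
    pair_span: int = 5_000_000
    #: Minimum fraction of informative pairs in strong LD for a haplotype block.
    informative_fraction: float = 0.90
    #: Promoter window upstream of the TSS (bp, inclusive).
    promoter_window: int = 500
    #: SIFT score below which a missense variant is called deleterious.
    sift_cutoff: float = 0.05
    #: Number of variants sampled per category for the allele-load analysis.
    load_sample_size: int = 50_000
    #: Window size (bp) for variant-density statistics.
    window_size: int = 1_000_000
    #: Compute FST among segregating lines only ("segregating") or all called
    #: lines ("called").
    fst_mode: str = "segregating"
    #: Use Hudson-style sample-size weights for the line means in FST.
    fst_weighted: bool = False
    #: Mean-impute missing per-individual dosages at load time instead of failing.
    impute_missing: bool = False
    #: Round dosages to hard calls before the GWAS scan.
    gwas_hard_calls: bool = False
    #: Candidate selection considers all block members, not only significant ones.
    candidates_from_all_members: bool = False
    #: RNG seed, recorded in every output header.
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for name in ("ci_strong_low", "ci_strong_high", "informative_fraction", "sift_cutoff"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ci_strong_low > self.ci_strong_high:
            raise ValueError("ci_strong_low must not exceed ci_strong_high")
        for name in ("pair_span", "promoter_window", "load_sample_size", "window_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fst_mode not in ("segregating", "called"):
            raise ValueError("fst_mode must be 'segregating' or 'called'")

    @classmethod
    def from_file(cls, path: str) -> "AnalysisConfig":
        """Read a TOML config file; unknown keys are rejected."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def metadata_lines(self) -> list[str]:
        """``#``-prefixed lines echoed at the top of every output table."""
        items = dataclasses.asdict(self)
        return [f"# linevar config: {k}={v}" for k, v in items.items()]
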