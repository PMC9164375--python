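"""Core domain types shared by every analysis stage.

The central container is :class:`MultiLineCohort`: a set of genetically
diverged lines (closed breeding populations) genotyped at a shared index of
biallelic variants.  Per-line genotypes are stored as alternative-allele
dosages in ``[0, 2]``; a variant that was never called in a line is marked
*absent* (``NaN``) for that line, which is distinct from a dosage of 0
(called, homozygous reference everywhere).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_CHROM_NUM = re.compile(r"^(?:chr)?(\d+)$")


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Numeric chromosomes first in numeric order, then others lexically."""
    m = _CHROM_NUM.match(chrom)
    if m:
        return (int(m.group(1)), "")
    return (10**9, chrom)


@dataclass(frozen=True, order=True, slots=True)
class VariantKey:
    """A biallelic variant site: chromosome, 1-based position, ref and alt allele."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError(
                f"multiallelic site not supported: {self.chrom}:{self.pos} alt={self.alt!r}"
            )

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_id(cls, variant_id: str) -> "VariantKey":
        chrom, pos, ref, alt = variant_id.split(":")
        return cls(chrom, int(pos), ref, alt)

    def sort_key(self) -> tuple[tuple[int, str], int, str, str]:
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)


@dataclass
class LineGenotypes:
    """Dosage matrix for one line.

    ``dosage`` has shape ``(n_variants, n_individuals)`` aligned to the cohort
    variant index.  Rows that are all-``NaN`` mean the variant was not called
    in this line.
    """

    line_id: str
    individuals: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D matrix [n_variants x n_individuals]")
        if self.dosage.shape[1] != len(self.individuals):
            raise ValueError(
                f"line {self.line_id}: {self.dosage.shape[1]} dosage columns for "
                f"{len(self.individuals)} individuals"
            )
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError(f"line {self.line_id}: dosages outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def called(self) -> np.ndarray:
        """Boolean per-variant flag: called in this line (any non-absent dosage)."""
        return np.isfinite(self.dosage).any(axis=1)


@dataclass
class MultiLineCohort:
    """L diverged lines sharing one ordered variant index."""

    variants: list[VariantKey]
    lines: dict[str, LineGenotypes] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError("cohort requires at least one line")
        n = len(self.variants)
        for lg in self.lines.values():
            if lg.dosage.shape[0] != n:
                raise ValueError(
                    f"line {lg.line_id}: {lg.dosage.shape[0]} variant rows, cohort has {n}"
                )

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def line_ids(self) -> list[str]:
        return list(self.lines)

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index([v.variant_id for v in self.variants], name="variant_id")


@dataclass
class DepthTable:
    """Per-variant mean sequencing depth plus the cohort mean realized coverage."""

    depth: np.ndarray
    mean_coverage: float

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if np.any(self.depth < 0):
            raise ValueError("negative depth value")
        if self.mean_coverage <= 0:
            raise ValueError("mean realized coverage must be > 0")


@dataclass
class RecombinationMap:
    """Non-overlapping half-open windows with a recombination rate (cM/Mb) each."""

    windows: pd.DataFrame  # columns: chrom, start, end, rate

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "rate"}
        if not req.issubset(self.windows.columns):
            raise ValueError(f"recombination map needs columns {sorted(req)}")
        if (self.windows["rate"] < 0).any():
            raise ValueError("negative recombination rate")
        w = self.windows.sort_values(["chrom", "start"])
        for _, grp in w.groupby("chrom", sort=False):
            if (grp["end"].values[:-1] > grp["start"].values[1:]).any():
                raise ValueError("overlapping recombination-map windows")
        self.windows = w.reset_index(drop=True)
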