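"""Shared containers for the CSSL drought-QTL pipeline.

Conventions used throughout the package:

* genotype dosages are coded on the donor allele: ``0`` recurrent-parent
  homozygote, ``1`` heterozygote, ``2`` donor homozygote, ``-1`` missing;
* genomic positions are 1-based and inclusive internally; BED-like output
  files are 0-based half-open (the conversion lives in :mod:`csslmap.io`);
* a "line" is one chromosome segment substitution line (CSSL) accession.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

CONDITIONS = ("control", "drought")

#: column order of the long-format phenotype table
OBS_COLUMNS = ("line_id", "trait", "condition", "year", "replicate", "value")


@dataclass(frozen=True)
class ChromosomeMap:
    """A chromosome of the reference coordinate frame."""

    name: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name!r} has nonpositive length")


@dataclass(frozen=True)
class Segment:
    """One introgressed donor segment carried by a line."""

    chromosome: str
    start_bp: int
    end_bp: int
    dosage: int = 2  # 2 homozygous-donor, 1 heterozygous

    def __post_init__(self) -> None:
        if not 1 <= self.start_bp <= self.end_bp:
            raise ValueError("segment coordinates must satisfy 1 <= start <= end")
        if self.dosage not in (1, 2):
            raise ValueError("segment dosage must be 1 (het) or 2 (hom donor)")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class SegmentAssignment:
    """The donor-segment complement of a single CSSL."""

    line_id: str
    segments: list[Segment] = field(default_factory=list)

    def donor_bp(self) -> int:
        return sum(s.length_bp for s in self.segments)


@dataclass(frozen=True)
class QtlEffect:
    """Ground-truth causal locus with condition-specific additive effects.

    Effects are per donor-allele copy on the raw trait scale; a drought-only
    QTL has ``effect_control == 0``.
    """

    chromosome: str
    position_bp: int
    trait: str
    effect_control: float
    effect_drought: float


@dataclass
class SimulationTruth:
    """Everything a recovery test needs to know about a synthetic study."""

    qtl: list[QtlEffect]
    variance_components: dict[str, dict[str, float]]  # trait -> component -> var
    seed: int

    def __post_init__(self) -> None:
        for trait, comps in self.variance_components.items():
            for name, v in comps.items():
                if v < 0:
                    raise ValueError(
                        f"negative variance {name}={v} for trait {trait}"
                    )


@dataclass
class GenotypeData:
    """Dosage matrix plus marker metadata, the genotype currency of the package.

    ``matrix`` is ``lines x markers`` int8; ``info`` has columns
    ``marker_id, chromosome, position_bp, maf, missing_rate`` and is sorted by
    chromosome then position.
    """

    matrix: np.ndarray
    info: pd.DataFrame
    line_ids: list[str]

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.line_ids), len(self.info)):
            raise ValueError("genotype matrix shape does not match line/marker registries")
        codes = np.unique(self.matrix)
        bad = set(codes.tolist()) - {MISSING, 0, 1, 2}
        if bad:
            raise ValueError(f"illegal dosage codes {sorted(bad)}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.info)

    def marker_column(self, marker_id: str) -> np.ndarray:
        idx = self.info.index[self.info["marker_id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(marker_id)
        return self.matrix[:, self.info.index.get_loc(idx[0])]


def recompute_marker_stats(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (minor-allele frequency, missing rate) per marker column.

    The allele frequency is that of the donor allele folded to [0, 0.5].
    """
    obs = matrix != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(
            obs.sum(axis=0) > 0,
            np.where(matrix == MISSING, 0, matrix).sum(axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1)),
            np.nan,
        )
    maf = np.minimum(freq, 1.0 - freq)
    missing_rate = 1.0 - obs.mean(axis=0)
    return maf, missing_rate


@dataclass(frozen=True)
class QtlRecord:
    """Unified QTL interval record shared by the three mapping strategies."""

    name: str
    method: str  # gwas | linkage | bsa
    trait: str
    chromosome: str
    start_bp: int
    end_bp: int
    peak_bp: int
    statistic: float  # -log10 p, LOD, or max |delta index|

    def __post_init__(self) -> None:
        if not self.start_bp <= self.peak_bp <= self.end_bp:
            raise ValueError("QTL record must satisfy start <= peak <= end")


def qtl_records_frame(records: list[QtlRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "method": r.method,
                "trait": r.trait,
                "chromosome": r.chromosome,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "peak_bp": r.peak_bp,
                "statistic": r.statistic,
            }
            for r in records
        ]
    )
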