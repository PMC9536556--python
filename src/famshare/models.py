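"""Core domain types for family-based variant sharing analysis.

Coordinates are 1-based inclusive throughout (BED input is converted at the
I/O boundary). Genotypes are alternate-allele counts in {0, 1, 2} with -1 for
missing. A variant key is the string ``chrom:pos:ref:alt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

MISSING = -1

#: Predictor statuses: D damaging/deleterious, A disease-causing-automatic,
#: T tolerated/benign, U unknown or not scored. Only D and A qualify as votes.
STATUSES = ("D", "A", "T", "U")


class Region(str, Enum):
    exonic = "exonic"
    splicing = "splicing"
    ncRNA_exonic = "ncRNA_exonic"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    intronic = "intronic"
    upstream = "upstream"
    downstream = "downstream"
    intergenic = "intergenic"
    other = "other"


class Consequence(str, Enum):
    nonsynonymous = "nonsynonymous"
    synonymous = "synonymous"
    stopgain = "stopgain"
    stoploss = "stoploss"
    frameshift_insertion = "frameshift_insertion"
    frameshift_deletion = "frameshift_deletion"
    nonframeshift_insertion = "nonframeshift_insertion"
    nonframeshift_deletion = "nonframeshift_deletion"
    unknown = "unknown"


class Sex(str, Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


@dataclass
class Variant:
    """A single biallelic genomic substitution with annotation."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    rsid: Optional[str] = None
    genes: list[str] = field(default_factory=list)
    region: Region = Region.other
    consequence: Optional[Consequence] = None
    protein_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        self.region = Region(self.region)
        if self.consequence is not None:
            self.consequence = Consequence(self.consequence)
        # consequence is meaningful only for exonic variants
        if self.region is Region.exonic and self.consequence is None:
            self.consequence = Consequence.unknown
        if self.region is not Region.exonic and self.consequence is not None:
            raise ValueError(
                f"consequence set on non-exonic variant {self.key} ({self.region})"
            )

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class Individual:
    id: str
    family_id: str
    father_id: Optional[str]  # None for founder
    mother_id: Optional[str]
    sex: Sex = Sex.unknown
    affected: bool = False
    mz_group: Optional[str] = None
    genotyped: bool = True

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class PedigreeError(ValueError):
    pass


def validate_pedigree(individuals: list["Individual"]) -> None:
    """Check parent links resolve and monozygotic groups are coherent.

    Raises PedigreeError on unknown parent ids, half-specified parents, or
    mz_group members that differ in parents or sex.
    """
    by_id = {ind.id: ind for ind in individuals}
    for ind in individuals:
        if (ind.father_id is None) != (ind.mother_id is None):
            raise PedigreeError(f"{ind.id}: exactly one parent known; pedigree must be complete per nuclear family")
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None and pid not in by_id:
                raise PedigreeError(f"{ind.id}: unknown parent id {pid!r}")
    groups: dict[str, list[Individual]] = {}
    for ind in individuals:
        if ind.mz_group:
            groups.setdefault(ind.mz_group, []).append(ind)
    for label, members in groups.items():
        parents = {(m.father_id, m.mother_id) for m in members}
        if len(parents) > 1:
            raise PedigreeError(f"mz_group {label!r}: members have different parents")
        sexes = {m.sex for m in members}
        if len(sexes) > 1:
            raise PedigreeError(f"mz_group {label!r}: members have different sexes")


@dataclass
class GenotypeMatrix:
    """Alt-allele counts, variants x samples; -1 encodes a missing call.

    When phased haplotypes are available, ``haplotypes`` is a pair of
    variants x samples 0/1 arrays whose sum reproduces ``genotypes``.
    """

    samples: list[str]
    variant_keys: list[str]
    genotypes: np.ndarray  # int8, shape (n_variants, n_samples)
    haplotypes: Optional[tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.variant_keys), len(self.samples)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} inconsistent with "
                f"{len(self.variant_keys)} variants x {len(self.samples)} samples"
            )
        if self.haplotypes is not None:
            h1, h2 = self.haplotypes
            summed = h1.astype(np.int8) + h2.astype(np.int8)
            observed = self.genotypes >= 0
            if not np.array_equal(summed[observed], self.genotypes[observed]):
                raise ValueError("haplotypes do not sum to genotypes")

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def column(self, sample_id: str) -> np.ndarray:
        return self.genotypes[:, self.sample_index(sample_id)]

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        haps = None
        if self.haplotypes is not None:
            haps = (self.haplotypes[0][:, idx], self.haplotypes[1][:, idx])
        return GenotypeMatrix(
            samples=list(sample_ids),
            variant_keys=list(self.variant_keys),
            genotypes=self.genotypes[:, idx],
            haplotypes=haps,
        )


@dataclass(frozen=True)
class IBDSegment:
    """A pairwise shared interval; the sample pair is unordered."""

    id1: str
    id2: str
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    lod: float
    length_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.start_bp < self.end_bp:
            raise ValueError(
                f"IBD segment start must be < end ({self.chrom}:{self.start_bp}-{self.end_bp})"
            )
        if not np.isfinite(self.lod):
            raise ValueError("LOD must be finite")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.id1, self.id2))

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def intersect(self, other: "IBDSegment") -> Optional[tuple[int, int]]:
        """Overlap of the two intervals on the same chromosome, or None."""
        if self.chrom != other.chrom:
            return None
        lo = max(self.start_bp, other.start_bp)
        hi = min(self.end_bp, other.end_bp)
        return (lo, hi) if lo <= hi else None


@dataclass(frozen=True)
class GeneModel:
    symbol: str
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.symbol}: start {self.start_bp} > end {self.end_bp}")


class PopulationFrequency:
    """Alternate-allele frequencies: variant key -> population -> AF in [0, 1]."""

    def __init__(self, populations: list[str]):
        self.populations = list(populations)
        self._freqs: dict[str, dict[str, float]] = {}

    def set(self, key: str, population: str, af: float) -> None:
        if population not in self.populations:
            raise KeyError(f"population {population!r} not in declared panel")
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"allele frequency {af} outside [0, 1] for {key}/{population}")
        self._freqs.setdefault(key, {})[population] = af

    def get(self, key: str, population: str) -> Optional[float]:
        return self._freqs.get(key, {}).get(population)

    def __contains__(self, key: str) -> bool:
        return key in self._freqs

    def keys(self):
        return self._freqs.keys()

    def row(self, key: str) -> dict[str, float]:
        return dict(self._freqs.get(key, {}))

    def __len__(self) -> int:
        return len(self._freqs)


@dataclass
class PredictionProfile:
    """Ordered per-tool deleteriousness statuses for one variant."""

    key: str
    statuses: list[str]

    def __post_init__(self) -> None:
        bad = set(self.statuses) - set(STATUSES)
        if bad:
            raise ValueError(f"invalid predictor statuses {sorted(bad)} for {self.key}")

    def qualifying_votes(self, qualifying: frozenset = frozenset({"D", "A"})) -> int:
        return sum(1 for s in self.statuses if s in qualifying)
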