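"""Core domain types shared across the toolkit.

Coordinates are stored 0-based half-open internally and rendered 1-based
inclusive on output (the ``nt X–Y`` style used in reports); converting
twice is the identity.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

logger = logging.getLogger("ervkit")

DNA_ALPHABET = frozenset("ACGTN")
GAP = "-"


class ErvkitError(Exception):
    """Base class for all toolkit errors."""


class FastaFormatError(ErvkitError):
    pass


class AlignmentError(ErvkitError):
    pass


class ParameterError(ErvkitError):
    pass


class PlacementError(ErvkitError):
    pass


class UndefinedDistanceError(ErvkitError):
    pass


class SaturationError(UndefinedDistanceError):
    """K2P logarithm argument fell to zero or below (distance saturated)."""


class CompositionError(ErvkitError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open 0-based interval on a contig.

    ``to_1based`` renders the 1-based inclusive coordinates used in all
    human-facing reports.
    """

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ParameterError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ParameterError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def to_1based(self) -> tuple[int, int]:
        return self.start + 1, self.end

    @classmethod
    def from_1based(
        cls, contig: str, start1: int, end1: int, strand: str = "+"
    ) -> "GenomicInterval":
        return cls(contig, start1 - 1, end1, strand)

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.contig, self.start + offset, self.end + offset, self.strand
        )


@dataclass
class ProviralLocus:
    """One genomic ERV locus: sequence, up-to-500-nt flanks, annotations.

    ``sequence`` is the element in its own 5'->3' orientation (minus-strand
    loci are reverse-complemented on extraction); ``flank5``/``flank3`` are
    the host flanks in the same orientation.
    """

    id: str
    species: str
    interval: GenomicInterval
    sequence: str
    flank5: str = ""
    flank3: str = ""
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ParameterError(
                f"locus {self.id}: sequence contains non-DNA characters {sorted(bad)}"
            )


# -- run configuration --------------------------------------------------------

_CONFIG_TYPES: dict[str, type] = {}


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run.

    Defaults follow the source study where it states a value (neutral
    substitution rate 0.0045 subs/nt/My, 1000 bootstrap replicates) and are
    explicit, documented choices where it does not.
    """

    # molecular clock
    sr: float = 0.0045               # substitutions/nucleotide/My
    cv_threshold: float = 0.20       # exclude multi-method ages with CV above this
    sd_mode: str = "relative"        # "relative" (CV) or "absolute" SD exclusion
    # phylogeny
    bootstrap_reps: int = 1000
    support_threshold: float = 70.0  # percent, for subgroup calls
    min_subgroup_size: int = 5
    # structural annotation
    pbs_identity_threshold: float = 14 / 18
    pbs_search_window: int = 30      # nt past the 5'LTR end
    min_orf_len: int = 300
    intactness_k: int = 12
    intactness_min_segment: int = 50
    intact_coverage_threshold: float = 0.6
    motif_mode: str = "denovo"       # or "consensus_anchored"
    # LTR detection
    ltr_min_len: int = 300
    ltr_max_len: int = 750
    ltr_min_identity: float = 0.60
    # classification
    internal_probe_coverage: float = 0.2
    polya_min: int = 12
    polya_window: int = 30
    ortholog_identity_threshold: float = 0.75
    min_flank_overlap: int = 200
    flank_len: int = 500
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sr <= 0:
            raise ParameterError("substitution rate SR must be > 0")
        if self.bootstrap_reps < 1:
            raise ParameterError("bootstrap_reps must be >= 1")
        if not (0 <= self.support_threshold <= 100):
            raise ParameterError("support_threshold must be in [0, 100]")
        if self.sd_mode not in ("relative", "absolute"):
            raise ParameterError("sd_mode must be 'relative' or 'absolute'")
        if self.motif_mode not in ("denovo", "consensus_anchored"):
            raise ParameterError(
                "motif_mode must be 'denovo' or 'consensus_anchored'"
            )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load ``key = value`` lines; ``overrides`` (e.g. CLI flags) win."""
        values: dict = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise ParameterError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _coerce(cls, key, val)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def resolved(self, **overrides) -> "RunConfig":
        return dataclasses.replace(
            self, **{k: v for k, v in overrides.items() if v is not None}
        )

    def log(self) -> None:
        """Log the fully resolved configuration (including the seed)."""
        items = ", ".join(
            f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)
        )
        logger.info("resolved config: %s", items)

    def as_dict(self) -> Mapping[str, object]:
        return dataclasses.asdict(self)


def _coerce(cls, key: str, val: str):
    default = getattr(cls(), key)
    if isinstance(default, bool):
        return val.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(val)
    if isinstance(default, float):
        return float(val)
    return val


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTN-", "TGCAN-")
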