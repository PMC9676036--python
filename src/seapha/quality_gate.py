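"""Marine isolation-source keyword filtering and assembly-quality gating.

A genome is "marine" when its free-text isolation source contains any of the
marine-related keywords (case-insensitive substring match, so "estuar" hits
"estuarine").  The shipped default keyword list is a stand-in for the
external published list the analysis style derives from and is fully
user-replaceable.

The quality gate is the high-quality genome definition: N50 ≥ 50 000,
completeness ≥ 95 %, contamination ≤ 5 %, and all 31 universal bacterial
marker genes present — every boundary inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .tables_io import GenomeMetadata

__all__ = [
    "DEFAULT_MARINE_KEYWORDS",
    "QualityThresholds",
    "QualityVerdict",
    "marine_filter",
    "quality_gate",
    "spd_positive_filter",
    "read_keywords",
]

DEFAULT_MARINE_KEYWORDS: tuple[str, ...] = (
    "marine", "sea", "seawater", "ocean", "coastal", "estuar", "tidal",
    "saline", "sediment", "hydrothermal", "reef", "mangrove", "macroalga",
    "seaweed", "kelp",
)


@dataclass(frozen=True)
class QualityThresholds:
    n50_min: int = 50_000
    completeness_min: float = 95.0
    contamination_max: float = 5.0
    marker_count_required: int = 31


@dataclass(frozen=True)
class QualityVerdict:
    genome_id: str
    marine: bool
    matched_keyword: str | None
    pass_n50: bool
    pass_completeness: bool
    pass_contamination: bool
    pass_markers: bool

    @property
    def overall(self) -> bool:
        return (
            self.pass_n50
            and self.pass_completeness
            and self.pass_contamination
            and self.pass_markers
        )


def marine_filter(
    isolation_source: str, keywords: Sequence[str] = DEFAULT_MARINE_KEYWORDS
) -> tuple[bool, str | None]:
    """Case-insensitive substring match; returns the first keyword that hits."""
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    text = (isolation_source or "").lower()
    if not text:
        return False, None
    for kw in keywords:
        if kw.lower() in text:
            return True, kw
    return False, None


def quality_gate(
    m: GenomeMetadata,
    thresholds: QualityThresholds = QualityThresholds(),
    keywords: Sequence[str] = DEFAULT_MARINE_KEYWORDS,
) -> QualityVerdict:
    """Evaluate every gate rule (all boundaries inclusive) plus the marine flag."""
    marine, kw = marine_filter(m.isolation_source, keywords)
    return QualityVerdict(
        genome_id=m.genome_id,
        marine=marine,
        matched_keyword=kw,
        pass_n50=m.n50 >= thresholds.n50_min,
        pass_completeness=m.completeness >= thresholds.completeness_min,
        pass_contamination=m.contamination <= thresholds.contamination_max,
        pass_markers=m.marker_count == thresholds.marker_count_required,
    )


def spd_positive_filter(unique_spd_count: int, k: int = 1) -> bool:
    """True iff the genome carries ≥ k unique SPD enzyme families."""
    return unique_spd_count >= k


def read_keywords(path: str | Path) -> list[str]:
    """One keyword per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    if not out:
        raise ValueError(f"{path}: no keywords found")
    return out
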