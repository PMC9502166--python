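"""Tiered selection of high-confidence viral contigs.

Contigs pass a topology-aware length filter, then per-tool stringency
cut-offs; contigs called by all three prediction tools form the
extremely-conservative (XC) tier, those called by at least two form the
conservative tier.  Contamination region tables drive excision of
host-typed spans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

LINEAR_MIN_BP = 5000
CIRCULAR_MIN_BP = 1500

VALID_TOOLS = frozenset({"virsorter", "deepvirfinder", "marvel"})


class Topology(str, Enum):
    LINEAR = "linear"
    CIRCULAR = "circular"


class Tier(str, Enum):
    XC = "efam_xc"
    EFAM = "efam"
    NONE = "none"


class ScoreParseError(ValueError):
    """A tool-score row is missing a field its tool requires."""


@dataclass(frozen=True)
class ContigRecord:
    id: str
    sequence: str
    topology: Topology
    parent_id: str | None = None
    parent_start: int | None = None
    parent_end: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.id!r} has empty sequence")
        if not isinstance(self.topology, Topology):
            object.__setattr__(self, "topology", Topology(self.topology))

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ToolScore:
    contig_id: str
    tool: str
    category: int | None = None
    score: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.tool not in VALID_TOOLS:
            raise ScoreParseError(f"unknown tool {self.tool!r}")
        if self.tool == "virsorter" and self.category is None:
            raise ScoreParseError(
                f"virsorter row for {self.contig_id!r} lacks a category"
            )
        if self.tool == "deepvirfinder" and (
            self.score is None or self.p_value is None
        ):
            raise ScoreParseError(
                f"deepvirfinder row for {self.contig_id!r} needs score and p_value"
            )
        if self.tool == "marvel" and self.score is None:
            raise ScoreParseError(f"marvel row for {self.contig_id!r} lacks a score")


@dataclass(frozen=True)
class ContaminationRegion:
    contig_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    region_type: str  # "viral" | "host"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"bad region {self.start}-{self.end} on {self.contig_id!r}"
            )
        if self.region_type not in ("viral", "host"):
            raise ValueError(f"unknown region_type {self.region_type!r}")


@dataclass
class SelectionResult:
    tiers: dict[str, Tier] = field(default_factory=dict)
    passing_tools: dict[str, frozenset[str]] = field(default_factory=dict)
    trimmed_contigs: list[ContigRecord] = field(default_factory=list)

    def ids_for_tier(self, tier: Tier) -> set[str]:
        """Contig ids at `tier` stringency. The conservative tier is
        reported as a superset of the XC tier."""
        if tier == Tier.EFAM:
            wanted = (Tier.EFAM, Tier.XC)
        else:
            wanted = (tier,)
        return {cid for cid, t in self.tiers.items() if t in wanted}


def passes_length(contig: ContigRecord) -> bool:
    """Topology-aware minimum-length rule: >=5 kb linear, >=1.5 kb circular."""
    if contig.topology == Topology.LINEAR:
        return contig.length >= LINEAR_MIN_BP
    if contig.topology == Topology.CIRCULAR:
        return contig.length >= CIRCULAR_MIN_BP
    raise ValueError(f"unknown topology {contig.topology!r}")


def passes_stringency(score: ToolScore) -> bool:
    """Strictest per-tool cut-off: VirSorter category 1; DeepVirFinder
    score > 0.9 and p < 0.05; MARVEL score > 0.90."""
    if score.tool == "virsorter":
        return score.category == 1
    if score.tool == "deepvirfinder":
        return score.score > 0.9 and score.p_value < 0.05
    # marvel
    return score.score > 0.90


def _most_permissive(rows: Sequence[ToolScore]) -> ToolScore:
    """Resolve duplicate (contig, tool) rows; a passing row wins."""
    best = rows[0]
    for row in rows[1:]:
        if passes_stringency(row) and not passes_stringency(best):
            best = row
    return best


def collect_passing_tools(
    scores: Iterable[ToolScore],
) -> dict[str, frozenset[str]]:
    """Map contig id -> set of tools whose strictest cut-off it passes."""
    by_key: dict[tuple[str, str], list[ToolScore]] = {}
    for s in scores:
        by_key.setdefault((s.contig_id, s.tool), []).append(s)
    passing: dict[str, set[str]] = {}
    for (cid, tool), rows in by_key.items():
        if len(rows) > 1:
            logger.warning(
                "duplicate %s rows for contig %s; keeping most permissive",
                tool,
                cid,
            )
        row = _most_permissive(sorted(rows, key=lambda r: (
            r.category if r.category is not None else -1,
            r.score if r.score is not None else -1.0,
        )))
        passing.setdefault(cid, set())
        if passes_stringency(row):
            passing[cid].add(tool)
    return {cid: frozenset(tools) for cid, tools in passing.items()}


def assign_tier(passing_tools: frozenset[str] | set[str]) -> Tier:
    """Three passing tools -> XC tier; exactly two -> conservative tier."""
    n = len(set(passing_tools) & VALID_TOOLS)
    if n == 3:
        return Tier.XC
    if n == 2:
        return Tier.EFAM
    return Tier.NONE


def trim_contamination(
    contig: ContigRecord, regions: Sequence[ContaminationRegion]
) -> list[ContigRecord]:
    """Excise host-typed spans; each viral span becomes a child contig.

    Children are suffixed ``_<region index>`` (1-based over the viral
    regions) and inherit linear topology.  An empty region list passes
    the contig through unchanged.
    """
    if not regions:
        return [contig]
    relevant = sorted(
        (r for r in regions if r.contig_id == contig.id), key=lambda r: r.start
    )
    if not relevant:
        return [contig]
    prev_end = 0
    for r in relevant:
        if r.end > contig.length:
            raise ValueError(
                f"region {r.start}-{r.end} exceeds contig {contig.id!r} "
                f"length {contig.length}"
            )
        if r.start <= prev_end:
            raise ValueError(f"overlapping regions on contig {contig.id!r}")
        prev_end = r.end
    children: list[ContigRecord] = []
    idx = 0
    for r in relevant:
        if r.region_type != "viral":
            continue
        idx += 1
        seq = contig.sequence[r.start - 1 : r.end]
        children.append(
            ContigRecord(
                id=f"{contig.id}_{idx}",
                sequence=seq,
                topology=Topology.LINEAR,
                parent_id=contig.id,
                parent_start=r.start,
                parent_end=r.end,
            )
        )
    return children


def select_contigs(
    contigs: Sequence[ContigRecord],
    scores: Iterable[ToolScore],
    regions: Mapping[str, Sequence[ContaminationRegion]] | None = None,
    refilter_trimmed: bool = True,
) -> SelectionResult:
    """Full selection: length filter, tier assignment, contamination
    trimming, and (by default) re-application of the length filter to
    trimmed children."""
    regions = regions or {}
    passing = collect_passing_tools(scores)
    result = SelectionResult()
    for contig in contigs:
        if not passes_length(contig):
            continue
        tools = passing.get(contig.id, frozenset())
        tier = assign_tier(tools)
        result.tiers[contig.id] = tier
        result.passing_tools[contig.id] = tools
        if tier == Tier.NONE:
            continue
        for child in trim_contamination(contig, regions.get(contig.id, ())):
            if refilter_trimmed and child.parent_id is not None:
                if not passes_length(child):
                    continue
            result.trimmed_contigs.append(child)
    return result
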