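"""Benchmarking augmented-database viral discovery.

Compares baseline and augmented detection runs: per-sample contig-count
gains, length-binned gains, confidence-category transition tables, and
secondary-tool validation fractions for newly detected contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .contig_select import ToolScore

#: Default length bin edges (kb); open-ended final bin.
DEFAULT_BIN_EDGES_KB = (1.5, 3.0, 5.0, 10.0, 20.0)

RELAXED_DVF_SCORE = 0.7
RELAXED_DVF_P = 0.05
RELAXED_MARVEL_SCORE = 0.70

N_CATEGORIES = 6  # detection confidence categories 1..6; 0 = undetected


@dataclass(frozen=True)
class ContigCall:
    contig_id: str
    length: int
    category: int

    def __post_init__(self) -> None:
        if not 1 <= self.category <= N_CATEGORIES:
            raise ValueError(f"category {self.category} out of range 1-6")


@dataclass
class DetectionRun:
    sample_id: str
    calls: list[ContigCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.calls]
        if len(ids) != len(set(ids)):
            raise ValueError(
                f"run {self.sample_id!r} has duplicate contig calls"
            )

    @property
    def n_contigs(self) -> int:
        return len(self.calls)

    def by_id(self) -> dict[str, ContigCall]:
        return {c.contig_id: c for c in self.calls}


def percent_increase(n_base: float, n_aug: float) -> float | None:
    """100 * (aug - base) / base; None when undefined."""
    if n_base == 0:
        return None
    return 100.0 * (n_aug - n_base) / n_base


def per_sample_gain(baseline: DetectionRun, augmented: DetectionRun) -> dict:
    if baseline.sample_id != augmented.sample_id:
        raise ValueError("sample ids differ between runs")
    pct = percent_increase(baseline.n_contigs, augmented.n_contigs)
    return {
        "sample_id": baseline.sample_id,
        "n_baseline": baseline.n_contigs,
        "n_augmented": augmented.n_contigs,
        "gain": augmented.n_contigs - baseline.n_contigs,
        "percent_increase": round(pct, 1) if pct is not None else None,
    }


def aggregate_gains(
    pairs: Sequence[tuple[DetectionRun, DetectionRun]]
) -> dict:
    """Per-sample gain table plus mean/median counts and the percent
    increase of the mean count."""
    rows = [per_sample_gain(b, a) for b, a in pairs]
    base = [r["n_baseline"] for r in rows]
    aug = [r["n_augmented"] for r in rows]
    mean_base = float(np.mean(base)) if base else 0.0
    mean_aug = float(np.mean(aug)) if aug else 0.0
    mean_pct = percent_increase(mean_base, mean_aug)
    per_pcts = [r["percent_increase"] for r in rows if r["percent_increase"] is not None]
    return {
        "per_sample": rows,
        "mean_baseline": mean_base,
        "mean_augmented": mean_aug,
        "median_baseline": float(np.median(base)) if base else None,
        "median_augmented": float(np.median(aug)) if aug else None,
        "mean_count_percent_increase": (
            round(mean_pct, 1) if mean_pct is not None else None
        ),
        "mean_of_per_sample_increase": (
            float(np.mean(per_pcts)) if per_pcts else None
        ),
    }


def length_binned_gain(
    baseline: DetectionRun,
    augmented: DetectionRun,
    bin_edges_kb: Sequence[float] = DEFAULT_BIN_EDGES_KB,
) -> list[dict]:
    """Percent increase of detected-contig counts per length bin."""
    edges = list(bin_edges_kb)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError("bin edges must be strictly increasing")
    edges_bp = [e * 1000 for e in edges] + [float("inf")]

    def bin_of(length: int) -> int:
        for i in range(len(edges_bp) - 1):
            if edges_bp[i] <= length < edges_bp[i + 1]:
                return i
        return -1  # below first edge

    def counts(run: DetectionRun) -> list[int]:
        out = [0] * (len(edges_bp) - 1)
        for c in run.calls:
            b = bin_of(c.length)
            if b >= 0:
                out[b] += 1
        return out

    base_counts = counts(baseline)
    aug_counts = counts(augmented)
    rows = []
    for i in range(len(base_counts)):
        lo = edges[i]
        hi = edges[i + 1] if i + 1 < len(edges) else None
        pct = percent_increase(base_counts[i], aug_counts[i])
        rows.append(
            {
                "bin_kb": (lo, hi),
                "n_baseline": base_counts[i],
                "n_augmented": aug_counts[i],
                "percent_increase": (
                    round(pct, 1) if pct is not None else None
                ),
            }
        )
    return rows


def category_transitions(
    baseline: DetectionRun, augmented: DetectionRun
) -> dict:
    """7x7 transition counts (category 0 = undetected) plus derived
    upgrade/downgrade percentages per baseline category."""
    base_by_id = baseline.by_id()
    aug_by_id = augmented.by_id()
    counts = np.zeros((N_CATEGORIES + 1, N_CATEGORIES + 1), dtype=int)
    for cid in set(base_by_id) | set(aug_by_id):
        c_from = base_by_id[cid].category if cid in base_by_id else 0
        c_to = aug_by_id[cid].category if cid in aug_by_id else 0
        counts[c_from, c_to] += 1
    derived = {}
    for k in range(1, N_CATEGORIES + 1):
        row_total = counts[k].sum()
        if row_total == 0:
            continue
        upgraded = counts[k, 1] + counts[k, 2]
        undetected_or_down = counts[k, 0] + sum(
            counts[k, j] for j in range(1, N_CATEGORIES + 1) if j > k
        )
        derived[k] = {
            "n_baseline": int(row_total),
            "pct_to_high_confidence": round(100.0 * upgraded / row_total, 1),
            "pct_undetected_or_downgraded": round(
                100.0 * undetected_or_down / row_total, 1
            ),
        }
    return {"counts": counts, "derived": derived}


def validate_new_contigs(
    new_ids: Iterable[str],
    other_tool_scores: Sequence[ToolScore] = (),
    contamination: Mapping[str, float] | None = None,
    dvf_score: float = RELAXED_DVF_SCORE,
    dvf_p: float = RELAXED_DVF_P,
    marvel_score: float = RELAXED_MARVEL_SCORE,
) -> dict:
    """Fractions of newly detected contigs validated by secondary tools
    at relaxed thresholds and by contamination level."""
    new_ids = sorted(set(new_ids))
    n = len(new_ids)
    if n == 0:
        return {
            "n_new": 0,
            "n_validated": None,
            "validated_pct": None,
            "zero_contamination_pct": None,
            "high_contamination_pct": None,
        }
    passing: set[str] = set()
    for s in other_tool_scores:
        if s.contig_id not in set(new_ids):
            continue
        if s.tool == "deepvirfinder":
            if s.score is not None and s.p_value is not None:
                if s.score > dvf_score and s.p_value < dvf_p:
                    passing.add(s.contig_id)
        elif s.tool == "marvel":
            if s.score is not None and s.score > marvel_score:
                passing.add(s.contig_id)
    result = {
        "n_new": n,
        "n_validated": len(passing),
        "validated_pct": round(100.0 * len(passing) / n, 1),
    }
    if contamination is not None:
        zero = sum(
            1 for cid in new_ids if contamination.get(cid, 100.0) == 0.0
        )
        high = sum(
            1 for cid in new_ids if contamination.get(cid, 0.0) >= 50.0
        )
        result["n_zero_contamination"] = zero
        result["zero_contamination_pct"] = round(100.0 * zero / n, 1)
        result["n_high_contamination"] = high
        result["high_contamination_pct"] = round(100.0 * high / n, 1)
    else:
        result["zero_contamination_pct"] = None
        result["high_contamination_pct"] = None
    return result
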