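"""Readers and writers for the tabular and FASTA dialects the pipeline
consumes and emits.

Coordinates in region tables are 1-based inclusive.  BLAST tabular files
are the standard 12 columns, with an optional 13th subject-annotation
column for reference searches.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .annotate_consolidate import AnnotationRecord, ClusterAnnotation
from .benchmark_report import ContigCall, DetectionRun
from .contig_select import ContaminationRegion, ContigRecord, Topology, ToolScore
from .metaproteome_map import PeptideSpectrumMatch
from .protein_filter import DereplicationMap, HomologyHit, ProteinRecord

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_PRODIGAL_HEADER = re.compile(
    r"^(?P<id>\S+)\s*#\s*(?P<start>\d+)\s*#\s*(?P<end>\d+)\s*#\s*(?P<strand>-?1)"
)


def read_contigs(
    path: str | Path, topology_tsv: str | Path | None = None
) -> list[ContigRecord]:
    """Contig FASTA; topology from a sidecar TSV (contig_id, topology) or
    a `circular=true` header token, defaulting to linear."""
    topo_map: dict[str, Topology] = {}
    if topology_tsv is not None:
        with open(topology_tsv) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                topo_map[row[0]] = Topology(row[1])
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        topo = topo_map.get(rec.id)
        if topo is None:
            topo = (
                Topology.CIRCULAR
                if "circular=true" in rec.description.lower()
                else Topology.LINEAR
            )
        contigs.append(
            ContigRecord(id=rec.id, sequence=str(rec.seq).upper(), topology=topo)
        )
    return contigs


def write_contigs(contigs: Sequence[ContigRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            desc = ""
            if c.topology == Topology.CIRCULAR:
                desc = " circular=true"
            fh.write(f">{c.id}{desc}\n{c.sequence}\n")


def read_proteins(path: str | Path) -> list[ProteinRecord]:
    """Protein FASTA; gene-caller `# start # end # strand` headers parsed
    when present."""
    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _PRODIGAL_HEADER.match(rec.description)
        start = end = None
        strand = None
        if m:
            start, end = int(m.group("start")), int(m.group("end"))
            strand = "+" if m.group("strand") == "1" else "-"
        contig_id = rec.id.rsplit("_", 1)[0] if "_" in rec.id else ""
        proteins.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq),
                contig_id=contig_id,
                start=start,
                end=end,
                strand=strand,
            )
        )
    return proteins


def write_proteins(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n{p.sequence}\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def _optional_float(cell: str) -> float | None:
    return float(cell) if cell not in ("", "NA", "None") else None


def _optional_int(cell: str) -> int | None:
    return int(cell) if cell not in ("", "NA", "None") else None


def read_tool_scores(path: str | Path) -> list[ToolScore]:
    """TSV: contig_id, tool, category, score, p_value (header required)."""
    scores = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            scores.append(
                ToolScore(
                    contig_id=row["contig_id"],
                    tool=row["tool"],
                    category=_optional_int(row.get("category", "")),
                    score=_optional_float(row.get("score", "")),
                    p_value=_optional_float(row.get("p_value", "")),
                )
            )
    return scores


def write_tool_scores(scores: Sequence[ToolScore], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["contig_id", "tool", "category", "score", "p_value"])
        for s in scores:
            w.writerow(
                [
                    s.contig_id,
                    s.tool,
                    s.category if s.category is not None else "",
                    s.score if s.score is not None else "",
                    s.p_value if s.p_value is not None else "",
                ]
            )


def read_regions(path: str | Path) -> dict[str, list[ContaminationRegion]]:
    """TSV: contig_id, start, end, region_type (1-based inclusive)."""
    regions: dict[str, list[ContaminationRegion]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            r = ContaminationRegion(
                contig_id=row["contig_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                region_type=row["region_type"],
            )
            regions.setdefault(r.contig_id, []).append(r)
    for rows in regions.values():
        rows.sort(key=lambda r: r.start)
    return regions


def read_blast_tab(
    path: str | Path, with_annotation: bool = False
) -> list[HomologyHit]:
    """BLAST outfmt-6 (12 columns); `with_annotation` requires a 13th
    subject-annotation column."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: expected >= 12 columns")
            if with_annotation and len(cols) < 13:
                raise ValueError(
                    f"{path}:{lineno}: reference-search dialect requires a "
                    "13th subject-annotation column"
                )
            hits.append(
                HomologyHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pident=float(cols[2]),
                    aln_len=int(cols[3]),
                    qlen=int(cols[4]),
                    slen=int(cols[5]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                    subject_annotation=cols[12] if len(cols) > 12 else None,
                )
            )
    return hits


def write_blast_tab(hits: Sequence[HomologyHit], path: str | Path) -> None:
    """12-column tabular; qlen/slen stand in for the coordinate columns
    (mismatch/gapopen/q+s start/end written as 0)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for h in hits:
            row = [
                h.query_id,
                h.subject_id,
                f"{h.pident:.1f}",
                h.aln_len,
                h.qlen,
                h.slen,
                0,
                0,
                0,
                0,
                f"{h.evalue:.3g}",
                f"{h.bitscore:.1f}",
            ]
            if h.subject_annotation is not None:
                row.append(h.subject_annotation)
            w.writerow(row)


def read_clusters(path: str | Path) -> dict[str, list[str]]:
    """TSV: cluster_id, member_id."""
    clusters: dict[str, list[str]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[0] != "cluster_id":
            fh.seek(0)
            reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if row:
                clusters.setdefault(row[0], []).append(row[1])
    return clusters


def write_clusters(
    clusters: dict[str, Sequence[str]] | Iterable[tuple[str, Sequence[str]]],
    path: str | Path,
) -> None:
    items = clusters.items() if hasattr(clusters, "items") else clusters
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["cluster_id", "member_id"])
        for cid, members in items:
            for m in members:
                w.writerow([cid, m])


def read_derep_map(path: str | Path) -> DereplicationMap:
    mapping = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            mapping[row["member_id"]] = row["representative_id"]
    return DereplicationMap(representative_of=mapping)


def write_derep_map(derep: DereplicationMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["member_id", "representative_id"])
        for member, rep in sorted(derep.representative_of.items()):
            w.writerow([member, rep])


def read_annotation_records(path: str | Path) -> list[AnnotationRecord]:
    """DRAM-style TSV: protein_id, db, accession, description, rank."""
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append(
                AnnotationRecord(
                    protein_id=row["protein_id"],
                    source_db=row["db"],
                    accession=row.get("accession", ""),
                    description=row.get("description", ""),
                    rank=row.get("rank") or None,
                )
            )
    return records


def write_cluster_annotations(
    annotations: Sequence[ClusterAnnotation], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            [
                "cluster_id",
                "n_proteins",
                "detailed",
                "consensus",
                "previously_annotated",
                "structural",
                "virion_associated",
            ]
        )
        for a in annotations:
            detailed = "; ".join(
                f"{db}:{desc} (n={n})" for db, desc, n in a.detailed
            )
            w.writerow(
                [
                    a.cluster_id,
                    a.n_proteins,
                    detailed,
                    "; ".join(a.consensus),
                    int(a.previously_annotated),
                    int(a.structural),
                    int(a.virion_associated),
                ]
            )


def read_psms(path: str | Path) -> list[PeptideSpectrumMatch]:
    """TSV: spectrum_id, sample_id, peptide, score, is_decoy."""
    psms = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            psms.append(
                PeptideSpectrumMatch(
                    spectrum_id=row["spectrum_id"],
                    sample_id=row.get("sample_id", "sample_1"),
                    peptide=row["peptide"],
                    score=float(row["score"]),
                    is_decoy=row["is_decoy"].strip().lower()
                    in ("1", "true", "yes"),
                )
            )
    return psms


def write_psms(psms: Sequence[PeptideSpectrumMatch], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["spectrum_id", "sample_id", "peptide", "score", "is_decoy"])
        for p in psms:
            w.writerow(
                [p.spectrum_id, p.sample_id, p.peptide, f"{p.score:.4f}", int(p.is_decoy)]
            )


def read_detection_runs(path: str | Path) -> list[DetectionRun]:
    """TSV: sample_id, contig_id, length, category."""
    by_sample: dict[str, list[ContigCall]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            by_sample.setdefault(row["sample_id"], []).append(
                ContigCall(
                    contig_id=row["contig_id"],
                    length=int(row["length"]),
                    category=int(row["category"]),
                )
            )
    return [DetectionRun(sid, calls) for sid, calls in sorted(by_sample.items())]


def write_detection_runs(
    runs: Sequence[DetectionRun], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sample_id", "contig_id", "length", "category"])
        for run in runs:
            for c in run.calls:
                w.writerow([run.sample_id, c.contig_id, c.length, c.category])
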