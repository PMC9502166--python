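"""Seeded synthetic inputs with planted structure for every pipeline stage.

Generates protein families by mutating sampled ancestors, contaminant
proteins with strong prokaryotic reference hits, all-vs-all hit tables
with planted within/between-family e-values, detection-run pairs with
planted gains and category transitions, and PSM tables with planted
target/decoy score distributions and tryptic peptides — all byte-stable
under a fixed seed, with ground truth labels throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .benchmark_report import ContigCall, DetectionRun
from .metaproteome_map import PeptideSpectrumMatch
from .profile_hmm import AMINO_ACIDS, BACKGROUND
from .protein_filter import HomologyHit, ProteinRecord


@dataclass
class FixtureConfig:
    seed: int = 0
    n_families: int = 10
    family_size_range: tuple[int, int] = (3, 8)
    divergence: float = 0.05
    indel_rate: float = 0.0
    n_contaminants: int = 5
    contaminant_whitelisted_frac: float = 0.4
    contigs_per_sample: int = 50
    n_samples: int = 4
    frac_structural: float = 0.3
    ancestor_length_range: tuple[int, int] = (80, 400)
    psm_target_mean: float = 15.0
    psm_target_sd: float = 2.0
    psm_decoy_mean: float = 8.0
    psm_decoy_sd: float = 2.0
    n_psms: int = 2000

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ValueError("indel_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    family_of: dict[str, int] = field(default_factory=dict)
    contaminants: set[str] = field(default_factory=set)
    whitelisted_contaminants: set[str] = field(default_factory=set)
    virion_families: set[int] = field(default_factory=set)
    tier_of: dict[str, str] = field(default_factory=dict)
    tool_pass: dict[str, frozenset[str]] = field(default_factory=dict)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=BACKGROUND))


def _mutate(
    rng: np.random.Generator, seq: str, divergence: float, indel_rate: float
) -> str:
    out = []
    aas = list(AMINO_ACIDS)
    for ch in seq:
        r = rng.random()
        if indel_rate and r < indel_rate / 2:
            continue  # deletion
        if indel_rate and r < indel_rate:
            out.append(ch)
            out.append(aas[rng.integers(20)])  # insertion
            continue
        if rng.random() < divergence:
            choices = [a for a in aas if a != ch]
            out.append(choices[rng.integers(19)])
        else:
            out.append(ch)
    if not out:
        out.append(seq[0])
    return "".join(out)


def generate_families(
    config: FixtureConfig,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Planted protein families plus independent contaminant proteins."""
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    proteins: list[ProteinRecord] = []
    lo, hi = config.family_size_range
    alo, ahi = config.ancestor_length_range
    for fam in range(config.n_families):
        length = int(rng.integers(alo, ahi + 1))
        ancestor = _random_protein(rng, length)
        size = int(rng.integers(lo, hi + 1))
        for m in range(size):
            seq = _mutate(rng, ancestor, config.divergence, config.indel_rate)
            pid = f"fam{fam:03d}_p{m:02d}"
            proteins.append(
                ProteinRecord(id=pid, sequence=seq, contig_id=f"contig_{fam:03d}")
            )
            truth.family_of[pid] = fam
    for c in range(config.n_contaminants):
        length = int(rng.integers(alo, ahi + 1))
        pid = f"contam_p{c:02d}"
        proteins.append(
            ProteinRecord(
                id=pid,
                sequence=_random_protein(rng, length),
                contig_id=f"contig_host_{c:03d}",
            )
        )
        truth.contaminants.add(pid)
        if rng.random() < config.contaminant_whitelisted_frac:
            truth.whitelisted_contaminants.add(pid)
    n_virion = max(1, int(round(config.frac_structural * config.n_families)))
    truth.virion_families = set(range(n_virion))
    return proteins, truth


WHITELISTED_ANNOTATIONS = (
    "major capsid protein",
    "phage tail fiber protein",
    "portal protein",
    "terminase large subunit",
)
HOST_ANNOTATIONS = (
    "DNA polymerase III subunit alpha",
    "ribosomal protein S12",
    "ATP synthase subunit beta",
    "elongation factor Tu",
)


def generate_hits(
    proteins: list[ProteinRecord],
    truth: GroundTruth,
    config: FixtureConfig,
    between_family_rate: float = 0.01,
) -> tuple[list[HomologyHit], list[HomologyHit]]:
    """All-vs-all hits with planted e-values plus prokaryotic reference
    hits for the contaminants.

    Within-family pairs: e-value log-uniform in [1e-180, 1e-20], mutual
    coverage >= 0.8.  Between-family pairs (rate `between_family_rate`):
    e-values >= 1e-3.  Contaminants: reference hits with pident > 95,
    whitelisted fraction carrying virus-keyword subject annotations.
    """
    rng = np.random.default_rng(config.seed + 1)
    lengths = {p.id: len(p.sequence) for p in proteins}
    family_members: dict[int, list[str]] = {}
    for pid, fam in truth.family_of.items():
        family_members.setdefault(fam, []).append(pid)
    allvall: list[HomologyHit] = []
    for fam, members in sorted(family_members.items()):
        for u, v in itertools.combinations(sorted(members), 2):
            evalue = 10.0 ** rng.uniform(-180, -20)
            # full coverage of the shorter sequence; with low indel rates
            # this clears the 70% mutual-coverage filter
            aln = min(lengths[u], lengths[v])
            allvall.append(
                HomologyHit(
                    query_id=u,
                    subject_id=v,
                    pident=float(rng.uniform(40, 100)),
                    aln_len=aln,
                    qlen=lengths[u],
                    slen=lengths[v],
                    evalue=float(evalue),
                    bitscore=float(-np.log10(evalue)),
                )
            )
    fams = sorted(family_members)
    for fa, fb in itertools.combinations(fams, 2):
        for u in family_members[fa]:
            for v in family_members[fb]:
                if rng.random() < between_family_rate:
                    evalue = 10.0 ** rng.uniform(-3, 2)
                    allvall.append(
                        HomologyHit(
                            query_id=u,
                            subject_id=v,
                            pident=float(rng.uniform(20, 40)),
                            aln_len=min(lengths[u], lengths[v]) // 3,
                            qlen=lengths[u],
                            slen=lengths[v],
                            evalue=float(evalue),
                            bitscore=1.0,
                        )
                    )
    ref_hits: list[HomologyHit] = []
    for pid in sorted(truth.contaminants):
        if pid in truth.whitelisted_contaminants:
            ann = WHITELISTED_ANNOTATIONS[
                rng.integers(len(WHITELISTED_ANNOTATIONS))
            ]
        else:
            ann = HOST_ANNOTATIONS[rng.integers(len(HOST_ANNOTATIONS))]
        ref_hits.append(
            HomologyHit(
                query_id=pid,
                subject_id=f"ref_{pid}",
                pident=float(rng.uniform(95.5, 100.0)),
                aln_len=lengths[pid],
                qlen=lengths[pid],
                slen=lengths[pid],
                evalue=1e-50,
                bitscore=200.0,
                subject_annotation=ann,
            )
        )
    return allvall, ref_hits


def generate_detection_runs(
    config: FixtureConfig,
    gain_frac_short: float = 0.4,
    gain_frac_long: float = 0.1,
    cat6_to_cat2_frac: float = 0.6,
) -> tuple[list[DetectionRun], list[DetectionRun]]:
    """Baseline/augmented run pairs with planted short-contig-skewed
    gains and planted Cat6 -> Cat2 upgrades."""
    rng = np.random.default_rng(config.seed + 2)
    baselines, augmenteds = [], []
    for s in range(config.n_samples):
        sid = f"sample_{s:02d}"
        base_calls, aug_calls = [], []
        cat6_ids = []
        for c in range(config.contigs_per_sample):
            cid = f"{sid}_contig_{c:04d}"
            length = int(rng.choice([2000, 4000, 8000, 15000, 30000]))
            category = int(rng.integers(1, 7))
            base_calls.append(ContigCall(cid, length, category))
            if category == 6:
                cat6_ids.append((cid, length))
            aug_calls.append(ContigCall(cid, length, category))
        # planted upgrades: a fraction of Cat-6 contigs move to Cat 2
        n_up = int(round(cat6_to_cat2_frac * len(cat6_ids)))
        upgraded = {cid for cid, _ in cat6_ids[:n_up]}
        aug_calls = [
            ContigCall(c.contig_id, c.length, 2)
            if c.contig_id in upgraded
            else c
            for c in aug_calls
        ]
        # planted gains: new contigs, short-skewed
        n_short_new = int(round(gain_frac_short * config.contigs_per_sample))
        n_long_new = int(round(gain_frac_long * config.contigs_per_sample))
        for g in range(n_short_new):
            aug_calls.append(
                ContigCall(
                    f"{sid}_new_short_{g:04d}",
                    int(rng.integers(1500, 5000)),
                    int(rng.integers(1, 7)),
                )
            )
        for g in range(n_long_new):
            aug_calls.append(
                ContigCall(
                    f"{sid}_new_long_{g:04d}",
                    int(rng.integers(5000, 50000)),
                    int(rng.integers(1, 7)),
                )
            )
        baselines.append(DetectionRun(sid, base_calls))
        augmenteds.append(DetectionRun(sid, aug_calls))
    return baselines, augmenteds


def tryptic_peptides(sequence: str) -> list[str]:
    """Fully tryptic digestion: cleave after K/R, never before P."""
    peptides = []
    start = 0
    for i, ch in enumerate(sequence):
        if ch in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            peptides.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        peptides.append(sequence[start:])
    return peptides


def generate_psms(
    config: FixtureConfig,
    proteins: list[ProteinRecord],
    truth: GroundTruth,
) -> tuple[list[PeptideSpectrumMatch], set[str]]:
    """PSMs with planted target/decoy score distributions.

    Target peptides are tryptic fragments (length 6-50) of proteins in
    planted virion families; decoy peptides are reversed fragments.
    Returns (psms, set of planted true peptides).
    """
    rng = np.random.default_rng(config.seed + 3)
    virion_proteins = [
        p
        for p in proteins
        if truth.family_of.get(p.id) in truth.virion_families
    ]
    pool = []
    for p in virion_proteins:
        pool.extend(
            pep for pep in tryptic_peptides(p.sequence) if 6 <= len(pep) <= 50
        )
    pool = sorted(set(pool))
    if not pool:
        raise ValueError("no tryptic peptides available from virion families")
    psms: list[PeptideSpectrumMatch] = []
    true_peptides: set[str] = set()
    n_targets = config.n_psms // 2
    for i in range(config.n_psms):
        is_decoy = i >= n_targets
        pep = pool[rng.integers(len(pool))]
        if is_decoy:
            pep = pep[::-1]
            score = rng.normal(config.psm_decoy_mean, config.psm_decoy_sd)
        else:
            score = rng.normal(config.psm_target_mean, config.psm_target_sd)
            true_peptides.add(pep)
        psms.append(
            PeptideSpectrumMatch(
                spectrum_id=f"spec_{i:06d}",
                peptide=pep,
                score=float(score),
                is_decoy=is_decoy,
                sample_id=f"ms_sample_{int(rng.integers(2)):02d}",
            )
        )
    return psms, true_peptides
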