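"""Per-cluster multiple alignment and profile-HMM construction.

Each cluster alignment yields a match/insert/delete profile with
Laplace-smoothed emissions and transitions, serialized as concatenated
HMMER3 ASCII records.  A builtin center-star aligner keeps the pipeline
testable without external binaries; an external-aligner adapter shells
out to MUSCLE when present.

Simplifications relative to hmmbuild: unweighted observed counts with
Laplace pseudocounts (no Henikoff sequence weighting, no Dirichlet
mixture priors) and no E-value statistical calibration.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np

from .protein_filter import ProteinRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"

TRANSITIONS = ("mm", "mi", "md", "im", "ii", "dm", "dd")


def _load_background() -> np.ndarray:
    text = (
        resources.files("efam_forge.data")
        .joinpath("background_freqs.tsv")
        .read_text()
    )
    freqs = np.zeros(20)
    for line in text.strip().splitlines():
        aa, val = line.split("\t")
        freqs[AA_INDEX[aa]] = float(val)
    return freqs / freqs.sum()


BACKGROUND = _load_background()


class DegenerateAlignmentError(ValueError):
    """An alignment produced zero match columns."""


@dataclass
class MultipleAlignment:
    cluster_id: str
    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"cluster {self.cluster_id!r}: empty alignment")
        self.rows = [(pid, seq.upper().replace(".", GAP)) for pid, seq in self.rows]
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"cluster {self.cluster_id!r}: ragged alignment")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class ProfileHMM:
    name: str
    match_emissions: np.ndarray  # (K, 20)
    insert_emissions: np.ndarray  # (K+1, 20)
    transitions: np.ndarray  # (K+1, 7): mm mi md im ii dm dd
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())
    n_seqs: int = 0

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        k = self.length
        if k < 1:
            raise ValueError("profile has no match states")
        if self.insert_emissions.shape != (k + 1, 20):
            raise ValueError("insert emission shape mismatch")
        if self.transitions.shape != (k + 1, 7):
            raise ValueError("transition shape mismatch")
        for row in self.match_emissions:
            if abs(row.sum() - 1.0) > atol:
                raise ValueError("match emission row does not sum to 1")
        for row in self.insert_emissions:
            if abs(row.sum() - 1.0) > atol:
                raise ValueError("insert emission row does not sum to 1")
        t = self.transitions
        for grp in (t[:, 0:3], t[:, 3:5], t[:, 5:7]):
            if np.abs(grp.sum(axis=1) - 1.0).max() > atol:
                raise ValueError("transition group does not sum to 1")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def _pairwise_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    matrix = substitution_matrices.load("BLOSUM62")
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _sanitize(seq: str) -> str:
    # BLOSUM62 lacks O/U/J; map rare residues onto scored wildcards
    return (
        seq.replace("U", "C").replace("O", "K").replace("J", "L")
    )


def _insertion_profile(center: str, aligned_center: str, aligned_other: str):
    """Per-gap-slot insertion strings of `other` relative to the ungapped
    center: ins[j] = residues of other aligned before center position j."""
    ins: list[str] = [""] * (len(center) + 1)
    j = 0
    for c_char, o_char in zip(aligned_center, aligned_other):
        if c_char == GAP:
            ins[j] += o_char if o_char != GAP else ""
        else:
            j += 1
    return ins


def _center_star(named: list[tuple[str, str]]) -> list[tuple[str, str]]:
    aligner = _pairwise_aligner()
    n = len(named)
    scores = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(_sanitize(named[i][1]), _sanitize(named[j][1]))
            scores[i] += s
            scores[j] += s
    center_idx = int(np.lexsort((
        np.array([pid for pid, _ in named]), -scores
    ))[0])
    center_id, center_seq = named[center_idx]

    pairwise: list[tuple[str, str, str]] = []  # (id, aligned_center, aligned_other)
    for pid, seq in named:
        if pid == center_id:
            continue
        aln = aligner.align(_sanitize(center_seq), _sanitize(seq))[0]
        ac, ao = str(aln[0]), str(aln[1])
        pairwise.append((pid, ac, ao))

    # once a gap, always a gap: take the max insertion run at each slot
    lc = len(center_seq)
    max_ins = [0] * (lc + 1)
    profiles: dict[str, list[str]] = {}
    residues_at: dict[str, list[str]] = {}
    for pid, ac, ao in pairwise:
        ins = _insertion_profile(center_seq, ac, ao)
        profiles[pid] = ins
        res = []
        for c_char, o_char in zip(ac, ao):
            if c_char != GAP:
                res.append(o_char)
        residues_at[pid] = res
        for j, s in enumerate(ins):
            max_ins[j] = max(max_ins[j], len(s))

    def build_row(ins: list[str], res: list[str]) -> str:
        parts = []
        for j in range(lc + 1):
            parts.append(ins[j].ljust(max_ins[j], GAP))
            if j < lc:
                parts.append(res[j])
        return "".join(parts)

    rows = []
    for pid, seq in named:
        if pid == center_id:
            row = build_row([""] * (lc + 1), list(center_seq))
        else:
            # restore original residues (sanitization is scoring-only);
            # consume them in alignment order: ins[0], res[0], ins[1], ...
            orig = iter(seq)
            ins_out, res_out = [], []
            for j in range(lc + 1):
                ins_out.append(
                    "".join(
                        next(orig) for ch in profiles[pid][j]
                    )
                )
                if j < lc:
                    ch = residues_at[pid][j]
                    res_out.append(next(orig) if ch != GAP else GAP)
            row = build_row(ins_out, res_out)
        rows.append((pid, row))
    return rows


def align_cluster(
    sequences: Sequence[ProteinRecord],
    cluster_id: str = "cluster",
    backend: str = "builtin",
) -> MultipleAlignment:
    """Align cluster members.

    `builtin` runs a deterministic center-star progressive aligner
    (global pairwise, BLOSUM62, gap open -11 / extend -1); `external`
    shells out to ``muscle -maxiters 4``.
    """
    if len(sequences) < 2:
        raise ValueError("alignment requires at least 2 sequences")
    named = sorted([(p.id, p.sequence) for p in sequences])
    if backend == "builtin":
        return MultipleAlignment(cluster_id, _center_star(named))
    if backend == "external":
        return MultipleAlignment(cluster_id, _muscle_align(named))
    raise ValueError(f"unknown backend {backend!r}")


def _muscle_align(named: list[tuple[str, str]]) -> list[tuple[str, str]]:
    exe = shutil.which("muscle")
    if exe is None:
        raise RuntimeError(
            "external aligner 'muscle' not found on PATH; use "
            "backend='builtin' for the native center-star aligner"
        )
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.faa"
        outfile = Path(tmp) / "out.afa"
        infile.write_text(
            "".join(f">{pid}\n{seq}\n" for pid, seq in named)
        )
        subprocess.run(
            [exe, "-in", str(infile), "-out", str(outfile), "-maxiters", "4"],
            check=True,
            capture_output=True,
        )
        rows: list[tuple[str, str]] = []
        pid, chunks = None, []
        for line in outfile.read_text().splitlines():
            if line.startswith(">"):
                if pid is not None:
                    rows.append((pid, "".join(chunks)))
                pid, chunks = line[1:].split()[0], []
            else:
                chunks.append(line.strip())
        if pid is not None:
            rows.append((pid, "".join(chunks)))
    order = {p: i for i, (p, _) in enumerate(named)}
    rows.sort(key=lambda r: order[r[0]])
    return rows


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------


def assign_match_columns(msa: MultipleAlignment, symfrac: float = 0.5) -> list[bool]:
    """A column is a match column iff its non-gap fraction >= symfrac."""
    flags = []
    for col in range(msa.n_cols):
        non_gap = sum(1 for _, seq in msa.rows if seq[col] != GAP)
        flags.append(non_gap / msa.n_rows >= symfrac)
    if not any(flags):
        raise DegenerateAlignmentError(
            f"cluster {msa.cluster_id!r}: no match columns at symfrac={symfrac}"
        )
    return flags


def _state_path(seq: str, match_cols: Sequence[bool]) -> list[tuple[str, int]]:
    """M/I/D walk over alignment columns; node = match-column ordinal."""
    path: list[tuple[str, int]] = []
    node = 0
    for col, is_match in enumerate(match_cols):
        ch = seq[col]
        if is_match:
            node += 1
            path.append(("M" if ch != GAP else "D", node))
        elif ch != GAP:
            path.append(("I", node))
    return path


def _residue_counts(ch: str) -> np.ndarray:
    """Observed count vector; unknown residues spread over the background."""
    vec = np.zeros(20)
    idx = AA_INDEX.get(ch)
    if idx is None:
        logger.debug("non-standard residue %r counted as background wildcard", ch)
        return BACKGROUND.copy()
    vec[idx] = 1.0
    return vec


def build_profile(
    msa: MultipleAlignment,
    match_cols: Sequence[bool] | None = None,
    pseudocount: float = 1.0,
    symfrac: float = 0.5,
) -> ProfileHMM:
    """Counts + Laplace smoothing over the per-row M/I/D state paths."""
    if match_cols is None:
        match_cols = assign_match_columns(msa, symfrac)
    k = sum(match_cols)
    if k < 1:
        raise DegenerateAlignmentError("zero match columns")
    match_counts = np.zeros((k, 20))
    trans_counts = np.zeros((k + 1, 7))
    for _, seq in msa.rows:
        node = 0
        for col, is_match in enumerate(match_cols):
            ch = seq[col]
            if is_match and ch != GAP:
                match_counts[node] += _residue_counts(ch)
            if is_match:
                node += 1
        path = [("M", 0)] + _state_path(seq, match_cols) + [("M", k + 1)]
        for (s1, n1), (s2, n2) in zip(path, path[1:]):
            key = (s1 + s2).lower()
            trans_counts[n1][TRANSITIONS.index(key)] += 1.0

    match_em = match_counts + pseudocount
    match_em /= match_em.sum(axis=1, keepdims=True)
    insert_em = np.tile(BACKGROUND, (k + 1, 1))

    trans = trans_counts + pseudocount
    # terminal node: no D/M_{K+1} delete successor exists
    trans[k, TRANSITIONS.index("md")] = 0.0
    trans[k, TRANSITIONS.index("dd")] = 0.0
    for lo, hi in ((0, 3), (3, 5), (5, 7)):
        grp = trans[:, lo:hi]
        trans[:, lo:hi] = grp / grp.sum(axis=1, keepdims=True)

    profile = ProfileHMM(
        name=msa.cluster_id,
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=trans,
        n_seqs=msa.n_rows,
    )
    profile.validate()
    return profile


# ---------------------------------------------------------------------------
# Viterbi scoring
# ---------------------------------------------------------------------------


def _log2_odds(emission: np.ndarray, ch: str, background: np.ndarray) -> float:
    idx = AA_INDEX.get(ch)
    if idx is None:
        return 0.0
    return math.log2(emission[idx] / background[idx])


def score_viterbi(profile: ProfileHMM, seq: str) -> float:
    """Global-alignment Viterbi log-odds score in bits."""
    if profile.length < 1:
        raise ValueError("empty profile")
    seq = seq.rstrip("*").upper()
    if not seq:
        raise ValueError("empty sequence")
    k, n = profile.length, len(seq)
    neg = -math.inf

    def lt(node: int, key: str) -> float:
        p = profile.transitions[node][TRANSITIONS.index(key)]
        return math.log2(p) if p > 0 else neg

    vm = np.full((k + 1, n + 1), neg)
    vi = np.full((k + 1, n + 1), neg)
    vd = np.full((k + 1, n + 1), neg)
    vm[0][0] = 0.0
    for j in range(1, k + 1):
        prev = max(vm[j - 1][0] + lt(j - 1, "md"), vd[j - 1][0] + lt(j - 1, "dd"))
        vd[j][0] = prev
    for i in range(1, n + 1):
        ch = seq[i - 1]
        vi[0][i] = _log2_odds(profile.insert_emissions[0], ch, profile.background) + max(
            vm[0][i - 1] + lt(0, "mi"), vi[0][i - 1] + lt(0, "ii")
        )
        for j in range(1, k + 1):
            e_m = _log2_odds(profile.match_emissions[j - 1], ch, profile.background)
            vm[j][i] = e_m + max(
                vm[j - 1][i - 1] + lt(j - 1, "mm"),
                vi[j - 1][i - 1] + lt(j - 1, "im"),
                vd[j - 1][i - 1] + lt(j - 1, "dm"),
            )
            e_i = _log2_odds(profile.insert_emissions[j], ch, profile.background)
            vi[j][i] = e_i + max(
                vm[j][i - 1] + lt(j, "mi"), vi[j][i - 1] + lt(j, "ii")
            )
            vd[j][i] = max(
                vm[j - 1][i] + lt(j - 1, "md"), vd[j - 1][i] + lt(j - 1, "dd")
            )
    return max(
        vm[k][n] + lt(k, "mm"),
        vi[k][n] + lt(k, "im"),
        vd[k][n] + lt(k, "dm"),
    )


# ---------------------------------------------------------------------------
# HMMER3 ASCII serialization
# ---------------------------------------------------------------------------


def _fmt(p: float) -> str:
    if p <= 0.0:
        return "*"
    return f"{-math.log(p):.5f}"


def _parse(tok: str) -> float:
    if tok == "*":
        return 0.0
    return math.exp(-float(tok))


def write_hmm(profile: ProfileHMM, fh: TextIO) -> None:
    k = profile.length
    fh.write("HMMER3/f [efam-forge]\n")
    fh.write(f"NAME  {profile.name}\n")
    fh.write(f"LENG  {k}\n")
    fh.write("ALPH  amino\n")
    fh.write(f"NSEQ  {profile.n_seqs}\n")
    fh.write("HMM          " + "        ".join(AMINO_ACIDS) + "\n")
    fh.write(
        "            m->m     m->i     m->d     i->m     i->i     d->m     d->d\n"
    )
    ins0 = "  ".join(_fmt(p) for p in profile.insert_emissions[0])
    fh.write(f"          {ins0}\n")
    tr0 = "  ".join(_fmt(p) for p in profile.transitions[0])
    fh.write(f"          {tr0}\n")
    for j in range(1, k + 1):
        m = "  ".join(_fmt(p) for p in profile.match_emissions[j - 1])
        fh.write(f"{j:>7} {m}\n")
        i = "  ".join(_fmt(p) for p in profile.insert_emissions[j])
        fh.write(f"        {i}\n")
        t = "  ".join(_fmt(p) for p in profile.transitions[j])
        fh.write(f"        {t}\n")
    fh.write("//\n")


def write_hmm_db(profiles: Sequence[ProfileHMM], path: str | Path) -> None:
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate profile names in database")
    with open(path, "w") as fh:
        for p in profiles:
            p.validate(atol=1e-6)
            write_hmm(p, fh)


def read_hmm_db(path: str | Path) -> list[ProfileHMM]:
    profiles = []
    with open(path) as fh:
        text = fh.read()
    for record in text.split("//\n"):
        record = record.strip()
        if not record:
            continue
        profiles.append(_parse_record(record))
    return profiles


def _parse_record(record: str) -> ProfileHMM:
    lines = record.splitlines()
    name, leng, nseq = "", 0, 0
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("NAME"):
            name = line.split(maxsplit=1)[1].strip()
        elif line.startswith("LENG"):
            leng = int(line.split()[1])
        elif line.startswith("NSEQ"):
            nseq = int(line.split()[1])
        elif line.startswith("HMM "):
            body_start = i + 2
            break
    body = [ln.split() for ln in lines[body_start:] if ln.strip()]
    insert_em = np.zeros((leng + 1, 20))
    match_em = np.zeros((leng, 20))
    trans = np.zeros((leng + 1, 7))
    insert_em[0] = [_parse(t) for t in body[0]]
    trans[0] = [_parse(t) for t in body[1]]
    pos = 2
    for j in range(1, leng + 1):
        match_em[j - 1] = [_parse(t) for t in body[pos][1:21]]
        insert_em[j] = [_parse(t) for t in body[pos + 1][:20]]
        trans[j] = [_parse(t) for t in body[pos + 2][:7]]
        pos += 3
    return ProfileHMM(
        name=name,
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=trans,
        n_seqs=nseq,
    )


def build_cluster_profiles(
    clusters: Iterable[tuple[str, list[ProteinRecord]]],
    backend: str = "builtin",
    symfrac: float = 0.5,
) -> list[ProfileHMM]:
    """Align each cluster and build its profile, skipping degenerate ones."""
    profiles = []
    for cluster_id, members in clusters:
        msa = align_cluster(members, cluster_id=cluster_id, backend=backend)
        try:
            profiles.append(build_profile(msa, symfrac=symfrac))
        except DegenerateAlignmentError as exc:
            logger.warning("skipping cluster %s: %s", cluster_id, exc)
    return profiles
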