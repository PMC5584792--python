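"""Putative transporter annotation from homology, domain and hydropathy evidence.

A hypothetical riboswitch-regulated protein is promoted to *putative lysine
transporter* only when three lines of evidence agree: (i) its best local
alignment against a transporter reference set passes E-value <= 1e-5,
percent similarity >= 50 and query coverage >= 30; (ii) it carries a
catalogued transporter domain motif; and (iii) it has at least one predicted
transmembrane segment.

Local alignment is affine-gap Smith-Waterman (BLOSUM62 by default) via
Biopython's PairwiseAligner; "similarity" is the fraction of aligned columns
with a positive substitution score (BLAST's "Positives") and coverage is the
aligned span of the query.  E-values use the ungapped Karlin-Altschul
formula E = K m n exp(-lambda S); applied to gapped scores they are
approximate.  The transmembrane predictor is a Kyte-Doolittle sliding-window
heuristic (window 19, mean hydropathy > 1.6), a deliberately simple stand-in
for a full transmembrane-topology HMM whose counts on real proteins may
differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

DEFAULT_KARLIN = {"BLOSUM62": (0.3176, 0.134)}  # ungapped (lambda, K)


@dataclass(frozen=True)
class AlignmentStats:
    raw_score: float
    bit_score: float
    evalue: float | None
    similarity: float      # percent positives over aligned columns
    coverage: float        # percent of query spanned by the local alignment
    identity: float        # percent identities over aligned columns
    subject_id: str

    def __post_init__(self) -> None:
        for v, name in ((self.similarity, "similarity"), (self.coverage, "coverage")):
            if not 0 <= v <= 100:
                raise ValueError(f"{name} out of [0, 100]")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("E-value must be >= 0")


@dataclass(frozen=True)
class DomainMotif:
    accession: str
    name: str
    consensus: str
    max_mismatches: int


@dataclass
class TransporterEvidence:
    query_id: str
    best_hit: AlignmentStats | None
    passes_thresholds: bool
    has_transporter_domain: bool
    tm_segment_count: int
    verdict: str                     # putative_transporter | insufficient

    def __post_init__(self) -> None:
        if self.verdict == "putative_transporter":
            assert self.passes_thresholds and self.has_transporter_domain \
                and self.tm_segment_count >= 1


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(query: str, subject: str, matrix: str = "BLOSUM62",
                gap_open: float = 11.0, gap_extend: float = 1.0,
                subject_id: str = "", karlin: tuple[float, float] | None = None
                ) -> AlignmentStats:
    """Optimal affine-gap local alignment with BLAST-style summary statistics.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  Bit score
    uses the matrix's ungapped Karlin-Altschul parameters; the E-value field
    is left unset here (see :func:`estimate_evalue`).
    """
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    sub = aligner.substitution_matrix
    alns = aligner.align(query, subject)
    score = float(alns.score)
    if score <= 0:
        return AlignmentStats(0.0, 0.0, None, 0.0, 0.0, 0.0, subject_id)
    aln = alns[0]
    q_blocks, s_blocks = aln.aligned
    matched = positives = identities = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        for qi, si in zip(range(qs, qe), range(ss, se)):
            a, b = query[qi], subject[si]
            matched += 1
            try:
                if sub[a, b] > 0:
                    positives += 1
            except (KeyError, IndexError):
                pass
            if a == b:
                identities += 1
    q_span = int(q_blocks[-1][1] - q_blocks[0][0])
    s_span = int(s_blocks[-1][1] - s_blocks[0][0])
    columns = matched + (q_span - matched) + (s_span - matched)
    lam, k = karlin or DEFAULT_KARLIN.get(matrix, (0.3176, 0.134))
    bit = (lam * score - math.log(k)) / math.log(2)
    return AlignmentStats(
        raw_score=score, bit_score=bit, evalue=None,
        similarity=100.0 * positives / columns,
        coverage=100.0 * q_span / len(query),
        identity=100.0 * identities / columns,
        subject_id=subject_id)


def estimate_evalue(raw_score: float, query_len: int, db_size_residues: int,
                    lam: float = 0.3176, k: float = 0.134) -> float:
    """Karlin-Altschul E = K * m * n * exp(-lambda * S); monotone in score."""
    if query_len <= 0 or db_size_residues <= 0:
        raise ValueError("lengths must be positive")
    if lam <= 0 or k <= 0:
        raise ValueError("Karlin parameters must be positive")
    return k * query_len * db_size_residues * math.exp(-lam * raw_score)


# ---------------------------------------------------------------------------
# transmembrane segments


def tm_predict(protein: str, window: int = 19, threshold: float = 1.6,
               min_separation: int = 5) -> list[tuple[int, int]]:
    """Predict transmembrane segments from Kyte-Doolittle hydropathy.

    Sliding windows whose mean hydropathy exceeds ``threshold`` are collected
    into maximal runs; runs separated by fewer than ``min_separation`` window
    positions merge into one segment.  Each segment is reported as the
    half-open residue interval covered by its windows.
    """
    n = len(protein)
    if n < window:
        raise ValueError(f"protein length {n} shorter than window {window}")
    vals = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in protein.upper()])
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    above = means > threshold
    runs: list[list[int]] = []
    for i in np.flatnonzero(above):
        if runs and i <= runs[-1][1] + min_separation:
            runs[-1][1] = i
        else:
            runs.append([int(i), int(i)])
    return [(s, e + window) for s, e in runs]


# ---------------------------------------------------------------------------
# domain motifs and the verdict


def passes_thresholds(evalue: float, similarity: float, coverage: float,
                      evalue_max: float = 1e-5, similarity_min: float = 50.0,
                      coverage_min: float = 30.0) -> bool:
    """The published homology threshold triple, all boundaries inclusive."""
    return (evalue <= evalue_max and similarity >= similarity_min
            and coverage >= coverage_min)


def decide_verdict(thresholds_ok: bool, has_domain: bool, tm_count: int) -> str:
    """putative_transporter requires homology AND domain AND >= 1 TM segment."""
    return ("putative_transporter"
            if thresholds_ok and has_domain and tm_count >= 1 else "insufficient")


def load_domain_db() -> list[DomainMotif]:
    """Packaged transporter domain motif catalogue (synthetic, editable TSV)."""
    path = resources.files("riboregulon.data") / "transporter_domains.tsv"
    df = pd.read_csv(str(path), sep="\t", dtype={"max_mismatches": int})
    return [DomainMotif(r.accession, r["name"], r.consensus, int(r.max_mismatches))
            for _, r in df.iterrows()]


def match_domain(protein: str, motif: DomainMotif) -> bool:
    """Sliding comparison of the motif consensus within its mismatch budget."""
    m, n = len(motif.consensus), len(protein)
    if n < m:
        return False
    p = protein.upper()
    c = motif.consensus
    for i in range(n - m + 1):
        mism = 0
        for a, b in zip(p[i:i + m], c):
            if a != b:
                mism += 1
                if mism > motif.max_mismatches:
                    break
        else:
            return True
    return False


def annotate_hypothetical(query_id: str, query: str,
                          reference_db: Sequence[tuple[str, str]],
                          domain_db: Sequence[DomainMotif] | None = None,
                          evalue_max: float = 1e-5,
                          similarity_min: float = 50.0,
                          coverage_min: float = 30.0,
                          matrix: str = "BLOSUM62",
                          gap_open: float = 11.0, gap_extend: float = 1.0
                          ) -> TransporterEvidence:
    """Annotate one hypothetical protein against a transporter reference set.

    The best hit is the reference with the lowest E-value, then the highest
    similarity, then the highest coverage.  The verdict is
    ``putative_transporter`` only when the threshold triple passes AND a
    transporter domain motif is present AND at least one transmembrane
    segment is predicted.
    """
    if not reference_db:
        raise ValueError("reference_db must be non-empty")
    if domain_db is None:
        domain_db = load_domain_db()
    db_residues = sum(len(s) for _, s in reference_db)
    best: AlignmentStats | None = None
    for sid, sseq in reference_db:
        st = local_align(query, sseq, matrix=matrix, gap_open=gap_open,
                         gap_extend=gap_extend, subject_id=sid)
        ev = estimate_evalue(st.raw_score, len(query), db_residues) \
            if st.raw_score > 0 else math.inf
        st = AlignmentStats(st.raw_score, st.bit_score, ev, st.similarity,
                            st.coverage, st.identity, sid)
        if best is None or (st.evalue, -st.similarity, -st.coverage) < \
                (best.evalue, -best.similarity, -best.coverage):
            best = st
    passes = passes_thresholds(best.evalue, best.similarity, best.coverage,
                               evalue_max, similarity_min, coverage_min)
    has_domain = any(match_domain(query, m) for m in domain_db)
    tm_count = len(tm_predict(query)) if len(query) >= 19 else 0
    verdict = decide_verdict(passes, has_domain, tm_count)
    return TransporterEvidence(query_id, best, passes, has_domain, tm_count, verdict)


def write_evidence_tsv(evidence: Sequence[TransporterEvidence], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("query\tbest_subject\tevalue\tsimilarity\tcoverage\t"
                 "has_domain\ttm_count\tverdict\n")
        for e in evidence:
            b = e.best_hit
            fh.write(f"{e.query_id}\t{b.subject_id if b else ''}\t"
                     f"{'' if b is None or b.evalue is None else format(b.evalue, '.3g')}\t"
                     f"{b.similarity:.1f}\t{b.coverage:.1f}\t"
                     f"{int(e.has_transporter_domain)}\t{e.tm_segment_count}\t{e.verdict}\n")
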