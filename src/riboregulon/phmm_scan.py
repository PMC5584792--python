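"""Profile-HMM construction and genome scanning for riboswitch aptamers.

A profile hidden Markov model in the classic match/insert/delete architecture
is estimated from a seed alignment of aptamer sequences and used to scan
genomic DNA on both strands.  Scores are log-odds against an i.i.d. background
model, in bits.  Candidate hits are post-filtered for compatibility with the
comparative-analysis consensus secondary structure: a hit must realise a
minimum fraction of the consensus base pairs with Watson-Crick or GU pairings.

State layout (Durbin et al. convention): begin = M0, match states M1..ML,
end = M(L+1); insert states I0..IL; delete states D1..DL.  Transitions to
D(L+1) do not exist, so the final match/insert/delete states renormalise over
two outgoing edges instead of three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import AlignIO

NT_ORDER = "ACGT"
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")
_CANONICAL_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
                    ("G", "T"), ("T", "G")}
_OPEN = {"(": ")", "<": ">", "[": "]", "{": "}"}
_CLOSE = {v: k for k, v in _OPEN.items()}

NEG_INF = -np.inf


def encode_seq(seq: str) -> np.ndarray:
    """Map a nucleotide string to integer codes; any ambiguity code becomes N."""
    return np.array([_NT_INDEX.get(c, 4) for c in seq.upper()], dtype=np.int8)


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


class ModelDegeneracyError(ValueError):
    """Raised when an alignment yields a model with zero match states."""


@dataclass
class ProfileHMM:
    """Profile HMM over DNA with log-odds emission scores in bits.

    ``match_emissions`` and ``insert_emissions`` hold probability
    distributions (rows sum to 1); the derived ``*_logodds`` arrays carry an
    extra column for N, which scores 0 (background odds) everywhere.
    Transition arrays are log2 probabilities indexed by the source column
    ``k`` as laid out in the module docstring; illegal transitions are -inf.
    """

    length: int
    match_emissions: np.ndarray        # (L, 4)
    insert_emissions: np.ndarray       # (L+1, 4)
    background: np.ndarray             # (4,)
    pseudocount: float
    # log2 transition scores
    t_mm: np.ndarray  # (L+1,)  M_k -> M_{k+1} (k=L: -> end)
    t_mi: np.ndarray  # (L+1,)  M_k -> I_k
    t_md: np.ndarray  # (L+1,)  M_k -> D_{k+1}; entry L is -inf
    t_im: np.ndarray  # (L+1,)  I_k -> M_{k+1}
    t_ii: np.ndarray  # (L+1,)
    t_id: np.ndarray  # (L+1,)
    t_dm: np.ndarray  # (L+1,)  D_k -> M_{k+1}; entry 0 unused (-inf)
    t_di: np.ndarray  # (L+1,)
    t_dd: np.ndarray  # (L+1,)
    match_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ModelDegeneracyError("profile HMM needs at least one match state")
        self.match_logodds = self._logodds(self.match_emissions)
        self.insert_logodds = self._logodds(self.insert_emissions)

    def _logodds(self, emis: np.ndarray) -> np.ndarray:
        lo = np.log2(emis / self.background[None, :])
        return np.hstack([lo, np.zeros((lo.shape[0], 1))])  # N column

    @property
    def consensus(self) -> str:
        """Most probable residue of each match state."""
        return "".join(NT_ORDER[i] for i in self.match_emissions.argmax(axis=1))


@dataclass(frozen=True)
class RiboswitchHit:
    """A scored aptamer match on a genome, forward-strand half-open coords."""

    genome_id: str
    start: int
    end: int
    strand: str
    score: float
    window_index: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad hit interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not np.isfinite(self.score):
            raise ValueError("hit score must be finite")


@dataclass
class ConsensusStructure:
    """Base-paired consensus columns of the aptamer, from a dot-bracket string."""

    structure: str
    pairs: list[tuple[int, int]]

    @classmethod
    def from_dotbracket(cls, s: str) -> "ConsensusStructure":
        stack: list[int] = []
        pairs: list[tuple[int, int]] = []
        for i, c in enumerate(s):
            if c in _OPEN:
                stack.append(i)
            elif c in _CLOSE:
                if not stack:
                    raise ValueError(f"unbalanced bracket at column {i}")
                pairs.append((stack.pop(), i))
        if stack:
            raise ValueError("unbalanced brackets: unmatched opening")
        return cls(structure=s, pairs=sorted(pairs))

    def project(self, match_columns: Sequence[int]) -> "ConsensusStructure":
        """Restrict pairs to columns kept as match states, re-indexed to model
        state order; pairs losing a partner are dropped."""
        col_to_state = {c: k for k, c in enumerate(match_columns)}
        kept = [(col_to_state[a], col_to_state[b]) for a, b in self.pairs
                if a in col_to_state and b in col_to_state]
        return ConsensusStructure(structure=self.structure, pairs=kept)


# ---------------------------------------------------------------------------
# model construction


def _smooth(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    c = counts + pseudocount
    return c / c.sum()


def build_phmm(seed_alignment: Sequence[tuple[str, str]] | "AlignIO.MultipleSeqAlignment",
               pseudocount: float = 0.5,
               gap_threshold: float = 0.5,
               background: Sequence[float] | None = None) -> ProfileHMM:
    """Estimate a profile HMM from an aligned set of aptamer sequences.

    Columns whose gap fraction is <= ``gap_threshold`` become match states.
    Emission distributions use additive smoothing,
    (count + pseudocount) / (total + 4 * pseudocount); transitions are tallied
    from each row's match/insert/delete state path with the same smoothing.
    """
    rows = [item if isinstance(item, tuple) else (item.id, str(item.seq))
            for item in seed_alignment]
    if not rows:
        raise ValueError("empty seed alignment")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    seqs = [s.upper().replace("U", "T").replace(".", "-") for _, s in rows]
    ncol = len(seqs[0])
    if any(len(s) != ncol for s in seqs):
        raise ValueError("alignment rows differ in length")
    nrow = len(seqs)

    gap_frac = [sum(s[c] == "-" for s in seqs) / nrow for c in range(ncol)]
    match_cols = [c for c in range(ncol) if gap_frac[c] <= gap_threshold]
    L = len(match_cols)
    if L == 0:
        raise ModelDegeneracyError("no column passes the gap threshold; model degenerate")

    if background is None:
        bg = np.full(4, 0.25)
    else:
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()

    m_counts = np.zeros((L, 4))
    i_counts = np.zeros((L + 1, 4))
    # transition counts keyed by (src_kind, k) -> {dst_kind: n}
    tc = {kind: np.zeros((L + 1, 3)) for kind in "MID"}  # dst order M, I, D
    _DST = {"M": 0, "I": 1, "D": 2}

    is_match = [False] * ncol
    col_state = {}
    for k, c in enumerate(match_cols):
        is_match[c] = True
        col_state[c] = k

    for s in seqs:
        prev_kind, prev_k = "M", 0  # begin state
        for c in range(ncol):
            res = s[c]
            if is_match[c]:
                k = col_state[c] + 1
                kind = "D" if res == "-" else "M"
                if kind == "M" and res in _NT_INDEX and res != "N":
                    m_counts[k - 1, _NT_INDEX[res]] += 1
                tc[prev_kind][prev_k, _DST[kind]] += 1
                prev_kind, prev_k = kind, k
            else:
                if res == "-":
                    continue
                # insert residue, region I_{prev_k}
                if res in _NT_INDEX and res != "N":
                    i_counts[prev_k, _NT_INDEX[res]] += 1
                tc[prev_kind][prev_k, _DST["I"]] += 1
                prev_kind, prev_k = "I", prev_k
        tc[prev_kind][prev_k, _DST["M"]] += 1  # -> end

    match_emis = np.vstack([_smooth(m_counts[k], pseudocount) for k in range(L)])
    insert_emis = np.vstack([_smooth(i_counts[k], pseudocount) for k in range(L + 1)])

    def trans_row(kind: str, k: int) -> np.ndarray:
        counts = tc[kind][k].copy()
        allowed = np.array([True, True, k < L])  # no D_{L+1}
        pc = np.where(allowed, pseudocount, 0.0)
        tot = counts.sum() + pc.sum()
        probs = np.where(allowed, (counts + pc) / tot, 0.0)
        with np.errstate(divide="ignore"):
            return np.log2(probs)

    t = {kind: np.vstack([trans_row(kind, k) for k in range(L + 1)]) for kind in "MID"}
    return ProfileHMM(
        length=L, match_emissions=match_emis, insert_emissions=insert_emis,
        background=bg, pseudocount=pseudocount,
        t_mm=t["M"][:, 0], t_mi=t["M"][:, 1], t_md=t["M"][:, 2],
        t_im=t["I"][:, 0], t_ii=t["I"][:, 1], t_id=t["I"][:, 2],
        t_dm=np.concatenate([[NEG_INF], t["D"][1:, 0]]),
        t_di=np.concatenate([[NEG_INF], t["D"][1:, 1]]),
        t_dd=np.concatenate([[NEG_INF], t["D"][1:, 2]]),
        match_columns=match_cols,
    )


def read_seed_alignment(path: str) -> tuple[list[tuple[str, str]], ConsensusStructure | None]:
    """Read an aligned FASTA or Stockholm seed alignment.

    For Stockholm input, a ``#=GC SS_cons`` line is parsed into a
    :class:`ConsensusStructure` over alignment columns (project it with the
    model's ``match_columns`` before use).
    """
    fmt = "stockholm" if open(path).readline().startswith("# STOCKHOLM") else "fasta"
    aln = AlignIO.read(path, fmt)
    rows = [(rec.id, str(rec.seq)) for rec in aln]
    struct = None
    ss = aln.column_annotations.get("secondary_structure") if fmt == "stockholm" else None
    if ss:
        struct = ConsensusStructure.from_dotbracket(ss)
    return rows, struct


# ---------------------------------------------------------------------------
# Viterbi scoring


def viterbi_score(model: ProfileHMM, seq: str,
                  mode: str = "global") -> tuple[float, list[tuple[str, int, int | None]]]:
    """Best-path log-odds score (bits) of ``seq`` against the model.

    ``mode='global'`` forces the whole sequence through the model;
    ``mode='glocal'`` traverses the full model but lets flanking sequence
    score as background (0 bits per residue).  Returns the score and the
    state path as (state_kind, model_index, seq_index) triples, where
    seq_index is None for delete states.
    """
    if len(seq) == 0:
        raise ValueError("cannot score an empty sequence")
    if mode not in ("global", "glocal"):
        raise ValueError(f"unknown mode {mode!r}")
    x = encode_seq(seq)
    n, L = len(x), model.length
    em = model.match_logodds   # (L, 5)
    ei = model.insert_logodds  # (L+1, 5)

    vM = np.full((n + 1, L + 1), NEG_INF)
    vI = np.full((n + 1, L + 1), NEG_INF)
    vD = np.full((n + 1, L + 1), NEG_INF)
    ptr: dict[tuple[str, int, int], tuple[str, int, int]] = {}

    free_flank = mode == "glocal"
    # start: i=0, at begin (M_0) with score 0
    vM[0, 0] = 0.0
    # D chain at i=0 (deletions before any emission)
    for j in range(1, L + 1):
        cands = [("M", vM[0, j - 1] + model.t_md[j - 1]),
                 ("D", vD[0, j - 1] + model.t_dd[j - 1])]
        best_kind, best = max(cands, key=lambda kv: kv[1])
        if best > NEG_INF:
            vD[0, j] = best
            ptr[("D", j, 0)] = (best_kind, j - 1, 0)

    t_entry_m = model.t_mm  # from M_k
    for i in range(1, n + 1):
        ci = x[i - 1]
        if free_flank:
            vM[i, 0] = 0.0  # free prefix: remain at begin having consumed i residues
        # match and insert
        for j in range(1, L + 1):
            cands = [("M", vM[i - 1, j - 1] + t_entry_m[j - 1]),
                     ("I", vI[i - 1, j - 1] + model.t_im[j - 1]),
                     ("D", vD[i - 1, j - 1] + model.t_dm[j - 1])]
            kind, best = max(cands, key=lambda kv: kv[1])
            vM[i, j] = em[j - 1, ci] + best
            ptr[("M", j, i)] = (kind, j - 1, i - 1)
        for j in range(0, L + 1):
            cands = [("M", vM[i - 1, j] + model.t_mi[j]),
                     ("I", vI[i - 1, j] + model.t_ii[j]),
                     ("D", vD[i - 1, j] + model.t_di[j])]
            kind, best = max(cands, key=lambda kv: kv[1])
            vI[i, j] = ei[j, ci] + best
            ptr[("I", j, i)] = (kind, j, i - 1)
        for j in range(1, L + 1):
            cands = [("M", vM[i, j - 1] + model.t_md[j - 1]),
                     ("I", vI[i, j - 1] + model.t_id[j - 1]),
                     ("D", vD[i, j - 1] + model.t_dd[j - 1])]
            kind, best = max(cands, key=lambda kv: kv[1])
            vD[i, j] = best
            ptr[("D", j, i)] = (kind, j - 1, i)

    # termination: from M_L / I_L / D_L to end
    def end_score(i: int) -> tuple[float, tuple[str, int, int]]:
        cands = [(vM[i, L] + model.t_mm[L], ("M", L, i)),
                 (vI[i, L] + model.t_im[L], ("I", L, i)),
                 (vD[i, L] + model.t_dm[L], ("D", L, i))]
        return max(cands, key=lambda kv: kv[0])

    if free_flank:
        scored = [end_score(i) for i in range(n + 1)]
        score, back = max(scored, key=lambda kv: kv[0])
    else:
        score, back = end_score(n)

    path: list[tuple[str, int, int | None]] = []
    kind, j, i = back
    while not (kind == "M" and j == 0):
        path.append((kind, j, (i - 1) if kind in "MI" else None))
        kind, j, i = ptr[(kind, j, i)]
    path.reverse()
    return float(score), path


def batch_glocal_scores(model: ProfileHMM, windows: np.ndarray) -> np.ndarray:
    """Glocal Viterbi scores for many equal-length encoded windows at once.

    ``windows`` is an (n_windows, window_len) int8 array as produced by
    :func:`encode_seq`.  Vectorised across windows; used by genome scanning
    and threshold calibration.  Agrees with ``viterbi_score(mode='glocal')``.
    """
    W, n = windows.shape
    L = model.length
    em = model.match_logodds
    ei = model.insert_logodds

    vM = np.full((W, L + 1), NEG_INF)
    vI = np.full((W, L + 1), NEG_INF)
    vD = np.full((W, L + 1), NEG_INF)
    vM[:, 0] = 0.0
    for j in range(1, L + 1):
        vD[:, j] = np.maximum(vM[:, j - 1] + model.t_md[j - 1],
                              vD[:, j - 1] + model.t_dd[j - 1])
    best_end = np.maximum(vM[:, L] + model.t_mm[L],
                          np.maximum(vI[:, L] + model.t_im[L],
                                     vD[:, L] + model.t_dm[L]))

    for i in range(1, n + 1):
        ci = windows[:, i - 1].astype(np.intp)
        newM = np.empty_like(vM)
        newI = np.empty_like(vI)
        newD = np.full_like(vD, NEG_INF)
        newM[:, 0] = 0.0
        prevM, prevI, prevD = vM[:, :-1], vI[:, :-1], vD[:, :-1]
        best_in = np.maximum(prevM + model.t_mm[:-1][None, :],
                             np.maximum(prevI + model.t_im[:-1][None, :],
                                        prevD + model.t_dm[:-1][None, :]))
        newM[:, 1:] = em[np.arange(L)[None, :], ci[:, None]] + best_in
        best_ii = np.maximum(vM + model.t_mi[None, :],
                             np.maximum(vI + model.t_ii[None, :],
                                        vD + model.t_di[None, :]))
        newI = ei[np.arange(L + 1)[None, :], ci[:, None]] + best_ii
        for j in range(1, L + 1):
            newD[:, j] = np.maximum.reduce([newM[:, j - 1] + model.t_md[j - 1],
                                            newI[:, j - 1] + model.t_id[j - 1],
                                            newD[:, j - 1] + model.t_dd[j - 1]])
        vM, vI, vD = newM, newI, newD
        end_i = np.maximum(vM[:, L] + model.t_mm[L],
                           np.maximum(vI[:, L] + model.t_im[L],
                                      vD[:, L] + model.t_dm[L]))
        best_end = np.maximum(best_end, end_i)
    return best_end


# ---------------------------------------------------------------------------
# scanning & calibration


def _match_interval(path: list[tuple[str, int, int | None]]) -> tuple[int, int]:
    """Sequence span consumed by model states along a glocal Viterbi path."""
    pos = [i for kind, j, i in path if i is not None]
    if not pos:
        return (0, 0)
    return (min(pos), max(pos) + 1)


def scan_genome(model: ProfileHMM, genome_id: str, seq: str,
                threshold: float,
                window: int | None = None,
                step: int | None = None) -> list[RiboswitchHit]:
    """Scan both strands of a genome, returning merged above-threshold hits.

    Windows of ``window`` bases (default 2x model length) advance by ``step``
    (default model length / 2); each window is scored glocally.  Runs of
    overlapping above-threshold windows on one strand are merged into a
    single hit that keeps the maximum score and the maximising window's
    matched interval, reported in forward-strand half-open coordinates.
    """
    L = model.length
    window = 2 * L if window is None else window
    step = max(1, L // 2) if step is None else step
    if window < L:
        raise ValueError(f"window ({window}) must be >= model length ({L})")
    if step > window:
        raise ValueError("step must not exceed window")
    seq = seq.upper()
    n = len(seq)
    if n == 0:
        return []

    hits: list[RiboswitchHit] = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        starts = list(range(0, max(1, n - window + 1), step))
        if starts and starts[-1] + window < n:
            starts.append(n - window)
        wlen = min(window, n)
        enc = encode_seq(s)
        wins = np.stack([enc[st:st + wlen] for st in starts])
        scores = batch_glocal_scores(model, wins)
        above = [(i, st, sc) for i, (st, sc) in enumerate(zip(starts, scores))
                 if sc >= threshold]
        # cluster overlapping above-threshold windows
        clusters: list[list[tuple[int, int, float]]] = []
        for item in above:
            if clusters and item[1] < clusters[-1][-1][1] + wlen:
                clusters[-1].append(item)
            else:
                clusters.append([item])
        for cl in clusters:
            widx, wst, wsc = max(cl, key=lambda t: (t[2], -t[1]))
            _, path = viterbi_score(model, s[wst:wst + wlen], mode="glocal")
            a, b = _match_interval(path)
            if b <= a:
                continue
            # an aptamer call needs sequence evidence: ambiguity-only matches
            # (e.g. N runs, which score as background) are not hits
            if set(s[wst + a:wst + b]) <= {"N"}:
                continue
            lo, hi = wst + a, wst + b
            if strand == "-":
                lo, hi = n - hi, n - lo
            hits.append(RiboswitchHit(genome_id=genome_id, start=lo, end=hi,
                                      strand=strand, score=float(wsc),
                                      window_index=widx))
    # merge overlapping hits regardless of strand, keeping the maximum score:
    # a strong hit's reverse complement often shadows it on the other strand
    # because aptamer helices are partially self-complementary
    merged: list[RiboswitchHit] = []
    for h in sorted(hits, key=lambda h: (h.start, h.end, h.strand)):
        if merged and h.start < merged[-1].end:
            if h.score > merged[-1].score:
                merged[-1] = h
        else:
            merged.append(h)
    return sorted(merged, key=lambda h: (h.start, h.strand))


def iid_background(gc_content: float = 0.5) -> Callable[[np.random.Generator, int, int], np.ndarray]:
    """Sampler factory for i.i.d. background windows at a given GC fraction."""
    p = np.array([(1 - gc_content) / 2, gc_content / 2,
                  gc_content / 2, (1 - gc_content) / 2])

    def sample(rng: np.random.Generator, n_windows: int, length: int) -> np.ndarray:
        return rng.choice(4, size=(n_windows, length), p=p).astype(np.int8)

    return sample


def calibrate_threshold(model: ProfileHMM,
                        background_sampler: Callable[[np.random.Generator, int, int], np.ndarray],
                        target_fpr: float,
                        n_windows: int,
                        seed: int,
                        window: int | None = None) -> float:
    """Empirical (1 - target_fpr) score quantile over background windows."""
    if not 0 < target_fpr < 1:
        raise ValueError("target_fpr must lie in (0, 1)")
    if n_windows < 1 / target_fpr:
        raise ValueError(
            f"n_windows={n_windows} cannot resolve FPR {target_fpr}: need >= {int(np.ceil(1/target_fpr))}")
    window = 2 * model.length if window is None else window
    rng = np.random.default_rng(seed)
    wins = background_sampler(rng, n_windows, window)
    scores = batch_glocal_scores(model, np.asarray(wins, dtype=np.int8))
    return float(np.quantile(scores, 1 - target_fpr))


# ---------------------------------------------------------------------------
# structure-compatibility filter


def structure_compat(hit_seq: str, model: ProfileHMM, consensus: ConsensusStructure,
                     min_fraction: float = 0.7) -> tuple[float | None, bool | None]:
    """Check a hit against the consensus secondary structure.

    The hit is aligned to the model by global Viterbi; each consensus pair
    whose two columns are both realised by match states is scored canonical
    if the mapped nucleotides form a Watson-Crick or GU pair.  Returns
    (fraction, passed).  If no pair has both partners matched the result is
    indeterminate: (None, None).
    """
    _, path = viterbi_score(model, hit_seq, mode="global")
    state_to_pos = {j: i for kind, j, i in path if kind == "M" and i is not None}
    s = hit_seq.upper().replace("U", "T")
    evaluated = canonical = 0
    for a, b in consensus.pairs:
        pa, pb = state_to_pos.get(a + 1), state_to_pos.get(b + 1)
        if pa is None or pb is None:
            continue
        evaluated += 1
        if (s[pa], s[pb]) in _CANONICAL_PAIRS:
            canonical += 1
    if evaluated == 0:
        return None, None
    frac = canonical / evaluated
    return frac, frac >= min_fraction


# ---------------------------------------------------------------------------
# hit output


def write_hits_bed(hits: Iterable[RiboswitchHit], path: str) -> None:
    """6-column BED: name is hit index, score is bits x 100 as int."""
    with open(path, "w") as fh:
        for i, h in enumerate(hits):
            fh.write(f"{h.genome_id}\t{h.start}\t{h.end}\thit{i}\t"
                     f"{int(round(h.score * 100))}\t{h.strand}\n")


def write_hits_tsv(hits: Iterable[RiboswitchHit], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tstart\tend\tstrand\tscore_bits\twindow_index\n")
        for h in hits:
            fh.write(f"{h.genome_id}\t{h.start}\t{h.end}\t{h.strand}\t"
                     f"{h.score:.4f}\t{h.window_index}\n")


def read_hits_tsv(path: str) -> list[RiboswitchHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            g, s, e, st, sc, w = line.rstrip("\n").split("\t")
            hits.append(RiboswitchHit(g, int(s), int(e), st, float(sc), int(w)))
    return hits
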