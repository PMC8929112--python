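"""NLR identification by profile-HMM search for the NB-ARC domain.

The model is a plain Durbin-style profile HMM built from a seed alignment:
alignment columns with fewer than 50% gaps become match states; emissions and
transitions get Laplace (+1) pseudocounts; match emissions are scored as
log-odds against the background residue distribution estimated from the
alignment itself.

Search semantics are global in the model and local in the sequence: a hit
traverses every model position (as match or delete) while flanking sequence
residues are consumed by free self-loops that emit at background, so they
contribute zero bits. Scores are Viterbi best-path log-odds in bits. This is
deliberately simpler than HMMER's architecture (no forward E-values, no
model-local entry/exit) but exact and hand-checkable; the test suite verifies
it against brute-force alignment enumeration.

NLR class assignment (TIR-NLR / CCR-NLR / CC-NLR / NB-LRR) uses regex motif
rules loaded from a bundled config file, applied relative to the NB-ARC hit
span with priority TIR > CCR > CC > NB-LRR.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .core import AMINO_ACIDS, CHROM_NAME_PATTERN, FormatError, GeneModel, \
    ProteinRecord, is_chromosome

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = set("-.")

#: Default acceptance threshold in bits. An exact copy of the bundled seed
#: consensus scores far above this; shuffled sequences score far below.
DEFAULT_BIT_THRESHOLD = 25.0

NLR_CLASSES = ("TIR-NLR", "CCR-NLR", "CC-NLR", "NB-LRR")


@dataclass
class ProfileHMM:
    """Match/insert/delete profile HMM with log-odds match emissions.

    ``transitions[j]`` holds the 3x3 log2-probability matrix out of block j
    (rows: from M/I/D at j, columns: to M/I/D, where "to I" stays in block j
    and "to M"/"to D" advance to block j+1). Block 0 is begin, block
    ``length`` feeds the end state.
    """

    length: int
    match_probs: np.ndarray      # (L, 20) emission probabilities
    background: np.ndarray       # (20,) background probabilities
    transitions: np.ndarray      # (L + 1, 3, 3) log2 probabilities
    match_columns: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.length < 1:
            raise FormatError("profile HMM must have at least one match state")
        assert np.allclose(self.match_probs.sum(axis=1), 1.0)
        assert np.allclose(np.exp2(self.transitions).sum(axis=2), 1.0)

    @property
    def match_logodds(self) -> np.ndarray:
        return np.log2(self.match_probs) - np.log2(self.background)

    def consensus(self) -> str:
        """Highest-scoring (log-odds) residue per match state.

        Defined on the log-odds scale rather than raw emission probability
        so an exact consensus copy outscores every point mutant regardless
        of the background composition.
        """
        return "".join(AMINO_ACIDS[i] for i in self.match_logodds.argmax(axis=1))


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    score: float          # bits
    start: int            # 1-based inclusive residue span
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise FormatError(f"invalid hit span {self.start}-{self.end}")


@dataclass
class NLRAnnotation:
    gene_id: str
    nlr_class: str
    hits: list[DomainHit]

    def __post_init__(self):
        if self.nlr_class not in NLR_CLASSES:
            raise FormatError(f"unknown NLR class {self.nlr_class!r}")
        if not self.hits:
            raise FormatError("NLR annotation requires at least one NB-ARC hit")


# ------------------------------------------------------------ model build

_M, _I, _D = 0, 1, 2


def build_profile_hmm(seed_alignment: list[str]) -> ProfileHMM:
    """Estimate a profile HMM from an aligned set of sequences.

    Columns with < 50% gap characters become match states. Emission and
    transition counts get +1 pseudocounts. The background is the residue
    frequency over the whole alignment (+1 pseudocounts; flat if the
    alignment is degenerate).
    """
    if len(seed_alignment) < 2:
        raise FormatError("seed alignment needs at least 2 rows")
    rows = [r.upper() for r in seed_alignment]
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise FormatError("ragged seed alignment")
    for r in rows:
        bad = set(r) - set(AMINO_ACIDS) - GAP_CHARS - {"X"}
        if bad:
            raise FormatError(f"unexpected alignment characters: {sorted(bad)}")

    nrow = len(rows)
    gap_frac = [
        sum(r[c] in GAP_CHARS for r in rows) / nrow for c in range(ncol)
    ]
    match_cols = [c for c in range(ncol) if gap_frac[c] < 0.5]
    L = len(match_cols)
    if L == 0:
        raise FormatError("all alignment columns are majority-gap; empty model")

    # emissions
    em = np.ones((L, 20))  # +1 pseudocounts
    bg = np.ones(20)
    for r in rows:
        for ch in r:
            if ch in _AA_INDEX:
                bg[_AA_INDEX[ch]] += 1
    for j, c in enumerate(match_cols):
        for r in rows:
            ch = r[c]
            if ch in _AA_INDEX:
                em[j, _AA_INDEX[ch]] += 1
    em /= em.sum(axis=1, keepdims=True)
    bg /= bg.sum()

    # transitions: walk each row's state path over blocks 0..L
    match_set = set(match_cols)
    counts = np.ones((L + 1, 3, 3))  # +1 pseudocounts
    for r in rows:
        prev_state, prev_block = _M, 0  # begin
        for c in range(ncol):
            is_gap = r[c] in GAP_CHARS
            if c in match_set:
                state = _D if is_gap else _M
                counts[prev_block, prev_state, state] += 1
                prev_state, prev_block = state, prev_block + 1
            else:
                if not is_gap:  # insert residue at current block
                    counts[prev_block, prev_state, _I] += 1
                    prev_state = _I
        counts[prev_block, prev_state, _M] += 1  # exit to end
    with np.errstate(divide="ignore"):
        trans = np.log2(counts / counts.sum(axis=2, keepdims=True))
    return ProfileHMM(L, em, bg, trans, match_cols)


# ----------------------------------------------------------------- search


def _emission_logodds(hmm: ProfileHMM, sequence: str) -> np.ndarray:
    """(L, n) match-state log-odds per residue; X scores as background (0)."""
    n = len(sequence)
    out = np.empty((hmm.length, n))
    lo = hmm.match_logodds
    for i, ch in enumerate(sequence):
        if ch in _AA_INDEX:
            out[:, i] = lo[:, _AA_INDEX[ch]]
        elif ch == "X":
            out[:, i] = 0.0
        else:
            raise FormatError(f"residue {ch!r} outside alphabet")
    return out

NEG_INF = float("-inf")


def _viterbi_best(hmm: ProfileHMM, sequence: str):
    """Best glocal alignment: (score_bits, start, end) 1-based, or None.

    Flanking residues before the first and after the last emitted model
    residue are free (background emission, no transition cost), so only the
    aligned core contributes bits.
    """
    n = len(sequence)
    L = hmm.length
    if n == 0:
        return None
    e = _emission_logodds(hmm, sequence)
    t = hmm.transitions

    # vm[j][i]: best path ending in M_j having just emitted residue i
    vm = np.full((L + 1, n + 1), NEG_INF)
    vi = np.full((L + 1, n + 1), NEG_INF)
    vd = np.full((L + 1, n + 1), NEG_INF)
    sm = np.zeros((L + 1, n + 1), dtype=np.int32)  # start pointers
    si = np.zeros((L + 1, n + 1), dtype=np.int32)
    sd = np.zeros((L + 1, n + 1), dtype=np.int32)

    for i in range(1, n + 1):
        # entry: free flank up to i-1, then B -> (D_1..D_{j-1}) -> M_j is
        # handled by the D recursion from block 0; direct entry to M_1:
        vm[1, i] = t[0, _M, _M] + e[0, i - 1]
        sm[1, i] = i
    # deletes from begin (no emission): vd[1, i] = entry at residue boundary i
    for i in range(0, n + 1):
        vd[1, i] = t[0, _M, _D]
        sd[1, i] = i + 1  # first emitted residue will be i+1
    # inserts at block 0 are never better than the free flank; skip them.

    for j in range(1, L + 1):
        for i in range(0, n + 1):
            # insert at block j (emits background => 0 bits emission)
            if i >= 1:
                cands = (
                    (vm[j, i - 1] + t[j, _M, _I], sm[j, i - 1]),
                    (vi[j, i - 1] + t[j, _I, _I], si[j, i - 1]),
                    (vd[j, i - 1] + t[j, _D, _I], sd[j, i - 1]),
                )
                vi[j, i], si[j, i] = max(cands)
            if j < L:
                # delete at block j+1 (no emission)
                cands = (
                    (vm[j, i] + t[j, _M, _D], sm[j, i]),
                    (vi[j, i] + t[j, _I, _D], si[j, i]),
                    (vd[j, i] + t[j, _D, _D], sd[j, i]),
                )
                best, ptr = max(cands)
                if best > vd[j + 1, i]:
                    vd[j + 1, i], sd[j + 1, i] = best, ptr
                # match at block j+1 emitting residue i+1
                if i < n:
                    cands = (
                        (vm[j, i] + t[j, _M, _M], sm[j, i]),
                        (vi[j, i] + t[j, _I, _M], si[j, i]),
                        (vd[j, i] + t[j, _D, _M], sd[j, i]),
                    )
                    best, ptr = max(cands)
                    best += e[j, i]
                    if best > vm[j + 1, i + 1]:
                        vm[j + 1, i + 1], sm[j + 1, i + 1] = best, ptr

    best = None
    for i in range(0, n + 1):
        for v, s in (
            (vm[L, i] + t[L, _M, _M], sm[L, i]),
            (vi[L, i] + t[L, _I, _M], si[L, i]),
            (vd[L, i] + t[L, _D, _M], sd[L, i]),
        ):
            if v == NEG_INF:
                continue
            start, end = int(s), i
            if end < start:  # path emitted nothing (all-delete): degenerate
                continue
            if best is None or v > best[0]:
                best = (v, start, end)
    return best


def viterbi_search(hmm: ProfileHMM, protein: ProteinRecord,
                   bit_threshold: float = DEFAULT_BIT_THRESHOLD
                   ) -> list[DomainHit]:
    """All non-overlapping NB-ARC hits scoring >= ``bit_threshold`` bits.

    The best-scoring span is found first; its flanks are then searched
    recursively, so returned hits never overlap. Sorted best-first.
    """
    if hmm.length < 1 or len(protein.sequence) == 0:
        raise FormatError("model and protein must be nonempty")
    seq = protein.sequence.upper()
    hits: list[DomainHit] = []

    def _search(sub: str, offset: int):
        res = _viterbi_best(hmm, sub)
        if res is None:
            return
        score, start, end = res
        if score < bit_threshold:
            return
        hits.append(DomainHit(protein.id, float(score),
                              start + offset, end + offset))
        _search(sub[: start - 1], offset)
        _search(sub[end:], offset + end)

    _search(seq, 0)
    hits.sort(key=lambda h: (-h.score, h.start))
    return hits


def best_score(hmm: ProfileHMM, sequence: str) -> float:
    """Viterbi bit score of the best alignment (``-inf`` if none)."""
    res = _viterbi_best(hmm, sequence.upper())
    return NEG_INF if res is None else res[0]


# ----------------------------------------------------------- NLR calling


def _default_data(name: str) -> Path:
    return Path(str(resources.files("nlr_atlas").joinpath("data", name)))


def load_seed_alignment(path=None) -> list[str]:
    """The bundled synthetic NB-ARC-like seed alignment (or a user file)."""
    from .io import read_alignment

    return read_alignment(path or _default_data("nbarc_seed.synthetic.afa"))


def load_motifs(path=None) -> dict[str, str]:
    """Class-motif regex rules (data, not code): TIR / CCR / CC / LRR."""
    with open(path or _default_data("motifs.yaml")) as fh:
        cfg = yaml.safe_load(fh)
    return {k: str(v) for k, v in cfg["motifs"].items()}


def classify_nlr(annotation: NLRAnnotation | list[DomainHit],
                 protein: ProteinRecord,
                 motifs: Optional[dict[str, str]] = None) -> str:
    """Assign one of the four canonical NLR classes from motif rules.

    TIR and CCR and CC motifs must occur N-terminal of the NB-ARC span; the
    LRR rule fires C-terminal. Priority TIR > CCR > CC > NB-LRR; NB-LRR is
    the default when no N-terminal motif fires.
    """
    hits = annotation.hits if isinstance(annotation, NLRAnnotation) else annotation
    if not hits:
        raise FormatError("classification requires an NB-ARC hit")
    motifs = motifs or load_motifs()
    hit = hits[0]
    seq = protein.sequence.upper()
    nterm = seq[: hit.start - 1]
    cterm = seq[hit.end:]
    if re.search(motifs["tir"], nterm):
        return "TIR-NLR"
    if re.search(motifs["ccr"], nterm):
        return "CCR-NLR"
    if re.search(motifs["cc"], nterm):
        return "CC-NLR"
    # LRR rule confirms the default class but does not change it
    re.search(motifs["lrr"], cterm)
    return "NB-LRR"


def identify_nlrs(
    proteome: list[ProteinRecord],
    genes: list[GeneModel],
    hmm: ProfileHMM,
    bit_threshold: float = DEFAULT_BIT_THRESHOLD,
    chrom_pattern: str = CHROM_NAME_PATTERN,
    motifs: Optional[dict[str, str]] = None,
) -> list[NLRAnnotation]:
    """Scan a proteome and return one NLR annotation per positive gene.

    Proteins are mapped to genes by id (``<gene>`` or ``<gene>.<isoform>``);
    the longest isoform represents each gene. Genes on scaffolds (names not
    matching ``chrom_pattern``) are dropped. Proteins without a gene model
    are skipped with a warning.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    representative: dict[str, ProteinRecord] = {}
    skipped = 0
    for prot in proteome:
        gene_id = prot.id if prot.id in gene_by_id else prot.id.rsplit(".", 1)[0]
        if gene_id not in gene_by_id:
            skipped += 1
            continue
        cur = representative.get(gene_id)
        if cur is None or len(prot) > len(cur):
            representative[gene_id] = prot
    if skipped:
        warnings.warn(f"{skipped} proteins without a gene model were skipped")

    motifs = motifs or load_motifs()
    out: list[NLRAnnotation] = []
    for gene_id in sorted(representative):
        gene = gene_by_id[gene_id]
        if not is_chromosome(gene.chrom, chrom_pattern):
            continue
        prot = representative[gene_id]
        hits = viterbi_search(hmm, prot, bit_threshold)
        if not hits:
            continue
        out.append(
            NLRAnnotation(gene_id, classify_nlr(hits, prot, motifs), hits)
        )
    return out
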