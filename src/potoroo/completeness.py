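"""Cross-species identity, core-gene completeness, full-length isoform choice.

Completeness of a reference protein against a transcriptome is called from
pairwise alignment alone: ``complete`` when the best hit covers at least
``coverage_threshold`` (default 70%) of the reference, ``partial`` when any
hit reaches ``min_score`` but falls short of that coverage, ``absent``
otherwise.  Raw-score and coverage thresholds replace profile-HMM e-value
machinery; the classification rule is the content, not the search engine.

Alignments are textbook affine-gap dynamic programming (global
Needleman-Wunsch and local Smith-Waterman) with fully specified
tie-breaking, scored with a named substitution matrix (default BLOSUM62,
gap open 11 / extend 1).  No low-complexity masking is applied: short
degenerate peptides (e.g. arginine/lysine-rich ribosomal tails) must still
find their verbatim matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import substitution_matrices

from .sequtil import revcomp, translate

NEG_INF = float("-inf")
_AA = set("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass
class ScoringParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0       # opening a gap of length L costs open + L*extend
    gap_extend: float = 1.0
    seed_len: int = 4
    min_score: float = 50.0
    coverage_threshold: float = 0.70
    identity_denominator: str = "alignment"  # or "shorter"

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in (0, 1]")


@dataclass
class AlignmentResult:
    query_id: str
    target_id: str
    score: float
    identity_pct: float
    query_cov: float
    target_cov: float
    query_span: tuple = (0, 0)
    target_span: tuple = (0, 0)
    n_columns: int = 0
    n_identical: int = 0
    aligned_pairs: list = field(default_factory=list, repr=False)


@dataclass
class CompletenessCall:
    ref_id: str
    status: str                  # complete | partial | absent
    best_target_id: str | None
    coverage: float


@lru_cache(maxsize=4)
def _matrix_dict(name: str) -> dict:
    mat = substitution_matrices.load(name)
    alpha = mat.alphabet
    return {(a, b): float(mat[a, b]) for a in alpha for b in alpha}


def _check_protein(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    seq = seq.upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"{label} contains non-amino-acid characters {sorted(bad)}")
    return seq


def _identity_stats(a: str, b: str, pairs: list) -> tuple[int, int, int]:
    """(identical columns, alignment columns, aligned residue pairs)."""
    n_ident = sum(1 for i, j in pairs if a[i] == b[j])
    if pairs:
        cols = len(pairs)
        # gap columns: unaligned residues between / outside aligned pairs
        prev_i, prev_j = pairs[0]
        for i, j in pairs[1:]:
            cols += (i - prev_i - 1) + (j - prev_j - 1)
            prev_i, prev_j = i, j
    else:
        cols = 0
    return n_ident, cols, len(pairs)


def global_align_identity(a: str, b: str, params: ScoringParams | None = None,
                          query_id: str = "query", target_id: str = "target") -> AlignmentResult:
    """Global affine-gap alignment with percent identity.

    Identity is 100 x identical columns / alignment length including gap
    columns (or over the shorter sequence when
    ``identity_denominator='shorter'``).  Ties prefer a match column over a
    gap, then a gap in ``b``.
    """
    params = params or ScoringParams()
    a = _check_protein(a, "a")
    b = _check_protein(b, "b")
    sub = _matrix_dict(params.matrix)
    go, ge = params.gap_open + params.gap_extend, params.gap_extend
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(params.gap_open + ge * i)
    for j in range(1, m + 1):
        Y[0][j] = -(params.gap_open + ge * j)
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            diag = max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Mi[j] = diag + sub[(ai, b[j - 1])] if diag != NEG_INF else NEG_INF
            Xi[j] = max(Mp[j] - go, Xp[j] - ge, Yp[j] - go)
            Yi[j] = max(Mi[j - 1] - go, Yi[j - 1] - ge, Xi[j - 1] - go)
    score = max(M[n][m], X[n][m], Y[n][m])
    pairs = _traceback_global(a, b, M, X, Y, sub, go, ge)
    n_ident, cols, _ = _identity_stats(a, b, pairs)
    # global alignment: flanking end gaps count as columns too
    if pairs:
        first_i, first_j = pairs[0]
        last_i, last_j = pairs[-1]
        cols += max(first_i, first_j) + max(n - 1 - last_i, m - 1 - last_j)
    else:
        cols = max(n, m)
    denom = min(n, m) if params.identity_denominator == "shorter" else cols
    return AlignmentResult(
        query_id=query_id, target_id=target_id, score=score,
        identity_pct=100.0 * n_ident / denom if denom else 0.0,
        query_cov=1.0, target_cov=1.0,
        query_span=(0, n), target_span=(0, m),
        n_columns=cols, n_identical=n_ident, aligned_pairs=pairs,
    )


def _traceback_global(a, b, M, X, Y, sub, go, ge) -> list:
    n, m = len(a), len(b)
    i, j = n, m
    # preference: match column, then gap in b, then gap in a
    state = max(("M", "X", "Y"), key=lambda s: ({"M": M, "X": X, "Y": Y}[s][i][j], s == "M", s == "X"))
    pairs = []
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                break
            pairs.append((i - 1, j - 1))
            prev = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            target = M[i][j] - sub[(a[i - 1], b[j - 1])]
            state = _pick_state(prev, target)
            i, j = i - 1, j - 1
        elif state == "X":
            if i == 0:
                break
            if X[i][j] == X[i - 1][j] - ge and X[i - 1][j] != NEG_INF:
                cand = [("X", X[i - 1][j] - ge), ("M", M[i - 1][j] - go), ("Y", Y[i - 1][j] - go)]
            else:
                cand = [("M", M[i - 1][j] - go), ("X", X[i - 1][j] - ge), ("Y", Y[i - 1][j] - go)]
            state = _pick_exact(cand, X[i][j])
            i -= 1
        else:
            if j == 0:
                break
            if Y[i][j] == Y[i][j - 1] - ge and Y[i][j - 1] != NEG_INF:
                cand = [("Y", Y[i][j - 1] - ge), ("M", M[i][j - 1] - go), ("X", X[i][j - 1] - go)]
            else:
                cand = [("M", M[i][j - 1] - go), ("Y", Y[i][j - 1] - ge), ("X", X[i][j - 1] - go)]
            state = _pick_exact(cand, Y[i][j])
            j -= 1
    pairs.reverse()
    return pairs


def _pick_state(prev: tuple, target: float) -> str:
    for name, val in zip(("M", "X", "Y"), prev):
        if val == target:
            return name
    # floating point slack
    diffs = [abs(v - target) if v != NEG_INF else float("inf") for v in prev]
    return ("M", "X", "Y")[diffs.index(min(diffs))]


def _pick_exact(cand: list, target: float) -> str:
    for name, val in cand:
        if val == target:
            return name
    diffs = [(abs(v - target) if v != NEG_INF else float("inf"), k) for k, (name, v) in enumerate(cand)]
    return cand[min(diffs)[1]][0]


def smith_waterman(a: str, b: str, params: ScoringParams | None = None,
                   query_id: str = "query", target_id: str = "target") -> AlignmentResult:
    """Local affine-gap alignment (full quadratic DP, no banding)."""
    params = params or ScoringParams()
    a = _check_protein(a, "a")
    b = _check_protein(b, "b")
    sub = _matrix_dict(params.matrix)
    go, ge = params.gap_open + params.gap_extend, params.gap_extend
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            diag = max(Mp[j - 1], Xp[j - 1], Yp[j - 1], 0.0)
            Mi[j] = max(diag + sub[(ai, b[j - 1])], 0.0)
            Xi[j] = max(Mp[j] - go, Xp[j] - ge, Yp[j] - go)
            Yi[j] = max(Mi[j - 1] - go, Yi[j - 1] - ge, Xi[j - 1] - go)
            if Mi[j] > best:
                best, bi, bj = Mi[j], i, j
    pairs = _traceback_local(a, b, M, X, Y, sub, go, ge, bi, bj)
    n_ident, cols, _ = _identity_stats(a, b, pairs)
    if pairs:
        qs, ts = pairs[0]
        qe, te = pairs[-1][0] + 1, pairs[-1][1] + 1
    else:
        qs = ts = qe = te = 0
    denom = min(n, m) if params.identity_denominator == "shorter" else cols
    return AlignmentResult(
        query_id=query_id, target_id=target_id, score=best,
        identity_pct=100.0 * n_ident / denom if denom else 0.0,
        query_cov=(qe - qs) / n, target_cov=(te - ts) / m,
        query_span=(qs, qe), target_span=(ts, te),
        n_columns=cols, n_identical=n_ident, aligned_pairs=pairs,
    )


def _traceback_local(a, b, M, X, Y, sub, go, ge, i, j) -> list:
    pairs = []
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            if M[i][j] <= 0.0:
                break
            pairs.append((i - 1, j - 1))
            target = M[i][j] - sub[(a[i - 1], b[j - 1])]
            state = _pick_state((M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]), target)
            i, j = i - 1, j - 1
            if state == "M" and M[i][j] <= 0.0:
                break  # local alignment start reached
        elif state == "X":
            cand = [("M", M[i - 1][j] - go), ("X", X[i - 1][j] - ge), ("Y", Y[i - 1][j] - go)]
            state = _pick_exact(cand, X[i][j])
            i -= 1
        else:
            cand = [("M", M[i][j - 1] - go), ("Y", Y[i][j - 1] - ge), ("X", X[i][j - 1] - go)]
            state = _pick_exact(cand, Y[i][j])
            j -= 1
    pairs.reverse()
    return pairs


def six_frame_translate(nt: str) -> list[str]:
    """Translations in frames +0, +1, +2, -0, -1, -2; stops rendered as '*'."""
    nt = nt.upper()
    rc = revcomp(nt)
    return [translate(nt[f:]) for f in range(3)] + [translate(rc[f:]) for f in range(3)]


class ProteinSeedIndex:
    """seed_len-mer index over target proteins for candidate pre-filtering."""

    def __init__(self, targets: dict, seed_len: int = 4):
        self.targets = {k: _check_protein(v, k) for k, v in targets.items() if v}
        self.seed_len = seed_len
        self.table: dict[str, set] = {}
        for tid, seq in self.targets.items():
            for i in range(len(seq) - seed_len + 1):
                self.table.setdefault(seq[i : i + seed_len], set()).add(tid)


def search_protein(query: str, targets: dict | ProteinSeedIndex,
                   params: ScoringParams | None = None,
                   query_id: str = "query") -> list:
    """Seeded local search of one protein against a target set.

    Targets sharing no ``seed_len``-mer with the query are skipped; the
    survivors are aligned locally and hits with score >= ``min_score`` are
    returned ranked by score then target_id.  No complexity masking.
    """
    params = params or ScoringParams()
    index = targets if isinstance(targets, ProteinSeedIndex) else ProteinSeedIndex(targets, params.seed_len)
    query = _check_protein(query, "query")
    k = index.seed_len
    cands: set[str] = set()
    for i in range(len(query) - k + 1):
        cands |= index.table.get(query[i : i + k], set())
    hits = []
    for tid in sorted(cands):
        res = smith_waterman(query, index.targets[tid], params,
                             query_id=query_id, target_id=tid)
        if res.score >= params.min_score:
            hits.append(res)
    hits.sort(key=lambda h: (-h.score, h.target_id))
    return hits


def classify_completeness(ref_id: str, ref: str, hits: list,
                          params: ScoringParams | None = None) -> CompletenessCall:
    """complete / partial / absent call for one reference protein.

    Coverage is the fraction of the reference inside the aligned span of a
    hit; ``complete`` requires the best coverage among reported hits to
    reach ``coverage_threshold``.
    """
    params = params or ScoringParams()
    hits = [h for h in hits if h.score >= params.min_score]
    if not hits:
        return CompletenessCall(ref_id, "absent", None, 0.0)
    best = max(hits, key=lambda h: h.query_cov)
    if best.query_cov >= params.coverage_threshold:
        return CompletenessCall(ref_id, "complete", best.target_id, best.query_cov)
    return CompletenessCall(ref_id, "partial", best.target_id, best.query_cov)


def assess_core_set(refs: dict, targets: dict, params: ScoringParams | None = None) -> list:
    """Completeness calls for a whole reference set against target proteins."""
    params = params or ScoringParams()
    index = ProteinSeedIndex(targets, params.seed_len)
    calls = []
    for rid in sorted(refs):
        hits = search_protein(refs[rid], index, params, query_id=rid)
        calls.append(classify_completeness(rid, refs[rid], hits, params))
    return calls


@dataclass
class FullLengthChoice:
    transcript_id: str | None
    alignment: AlignmentResult | None
    reason: str = ""


def most_abundant_full_length(isoform_proteins: dict, tpms: dict, ref: str,
                              params: ScoringParams | None = None,
                              length_ratio: tuple = (0.85, 1.20),
                              end_slack: int = 15) -> FullLengthChoice:
    """Walk isoforms by decreasing abundance; keep the first full-length one.

    Full-length means the protein/reference length ratio falls inside
    ``length_ratio`` and the global alignment reaches within ``end_slack``
    residues of both reference termini.
    """
    params = params or ScoringParams()
    if not isoform_proteins:
        return FullLengthChoice(None, None, "no coding isoform")
    order = sorted(isoform_proteins, key=lambda t: (-tpms.get(t, 0.0), t))
    for tid in order:
        prot = isoform_proteins[tid]
        if not prot:
            continue
        ratio = len(prot) / len(ref)
        if not length_ratio[0] <= ratio <= length_ratio[1]:
            continue
        res = global_align_identity(ref, prot, params, query_id="ref", target_id=tid)
        aligned_ref = [i for i, _ in res.aligned_pairs]
        if not aligned_ref:
            continue
        if aligned_ref[0] <= end_slack and aligned_ref[-1] >= len(ref) - 1 - end_slack:
            return FullLengthChoice(tid, res)
    return FullLengthChoice(None, None, "no full-length isoform")
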