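"""Array-level DNA-binding motifs: prediction, comparison, scanning, overlap.

Each zinc finger contacts 3 bp through its recognition-helix residues at
positions -1, +3 and +6; an array of k fingers therefore defines a 3k-column
position weight matrix. Per-finger specificities come from a pluggable
predictor: either externally computed matrices (MEME/JASPAR-style text) or a
built-in simplified recognition-code lookup. The array PWM is assembled by
concatenating per-finger matrices N-to-C and taking the reverse complement,
so that the matrix reads along the strand the array binds.

Motif similarity follows the TomTom idea (best Pearson column correlation
over all offsets and both orientations) with an empirical permutation null
from column-shuffled targets. Genome scanning is log-odds scoring against a
zero-order background with an exact DP-derived score threshold for a
requested match p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alleles import ZnfArrayAllele

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Simplified zinc-finger recognition code: residues with a documented
#: dominant base preference; all other residues get a uniform column.
RECOGNITION_CODE = {
    "R": "G",
    "K": "G",
    "H": "G",
    "N": "A",
    "Q": "A",
    "D": "C",
    "E": "C",
}
PSEUDOCOUNT = 0.01


@dataclass
class FingerSpecificity:
    """4x3 column-stochastic base-preference matrix for one finger."""

    contacts: str
    pfm: np.ndarray

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.shape != (4, 3):
            raise ValueError("per-finger PFM must be 4x3")
        if np.any(self.pfm < 0) or not np.allclose(self.pfm.sum(axis=0), 1.0):
            raise ValueError("PFM columns must be stochastic")


@dataclass
class ArrayPWM:
    """Assembled array motif: 4 x (3k) probabilities plus background."""

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    reverse_complemented: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("matrix must be 4 x width")
        if not np.allclose(self.matrix.sum(axis=0), 1.0):
            raise ValueError("matrix columns must be stochastic")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        """Per-position log2 odds vs the background (bits)."""
        bg = np.maximum(self.background, 0.01)[:, None]
        return np.log2(np.maximum(self.matrix, 1e-12) / bg)

    def max_score(self) -> float:
        """Best attainable scan score, on the scanner's 1e-3-bit grid."""
        lo = np.round(self.log_odds() * 1000) / 1000.0
        return float(lo.max(axis=0).sum())


@dataclass(frozen=True)
class MotifSimilarity:
    query: str
    target: str
    best_offset: int
    best_orientation: str
    score: float
    p_value: float
    no_similarity: bool = False

    @property
    def neg_log10_p(self) -> float | None:
        return None if self.no_similarity else -float(np.log10(self.p_value))


@dataclass(frozen=True)
class GenomicHit:
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    motif: str


def _code_column(residue: str) -> np.ndarray:
    col = np.full(4, PSEUDOCOUNT)
    pref = RECOGNITION_CODE.get(residue)
    if pref is None:
        return np.full(4, 0.25)
    col[_BASE_IDX[pref]] += 1.0
    return col / col.sum()


def predict_finger_pfm(contacts: str, predictor=None) -> FingerSpecificity:
    """Per-finger 4x3 PFM for a 3-letter contact-residue string.

    ``predictor`` may be a callable ``contacts -> 4x3 matrix`` or a mapping
    from contact strings to matrices (e.g. loaded from external MEME/JASPAR
    text); without one, the built-in recognition-code fallback is used.
    Supplied matrices are normalization-checked and returned verbatim.
    """
    contacts = contacts.upper()
    if len(contacts) != 3 or any(c not in _AA for c in contacts):
        raise ValueError(f"invalid contact residues {contacts!r}")
    if predictor is not None:
        mat = predictor(contacts) if callable(predictor) else predictor[contacts]
        return FingerSpecificity(contacts, np.asarray(mat, dtype=float))
    # contact at helix -1 reads the 3' base, +6 the 5' base of the triplet
    # on the bound strand; reverse-complement assembly fixes the global
    # orientation, so columns here are simply in (-1, +3, +6) order.
    pfm = np.column_stack([_code_column(c) for c in contacts])
    return FingerSpecificity(contacts, pfm)


def reverse_complement_pwm(matrix: np.ndarray) -> np.ndarray:
    """Reverse column order and swap A<->T, C<->G rows."""
    return matrix[::-1, ::-1]


def assemble_array_pwm(
    array_or_name,
    per_finger: list[FingerSpecificity],
    background: np.ndarray | None = None,
) -> ArrayPWM:
    """Concatenate per-finger PFMs N-to-C and reverse-complement the result."""
    if not per_finger:
        raise ValueError("empty finger list")
    name = (
        array_or_name.name
        if isinstance(array_or_name, ZnfArrayAllele)
        else str(array_or_name)
    )
    concat = np.hstack([f.pfm for f in per_finger])
    mat = reverse_complement_pwm(concat)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return ArrayPWM(name=name, matrix=mat, background=bg)


def pwm_for_allele(array: ZnfArrayAllele, predictor=None) -> ArrayPWM:
    """Predict per-finger specificities for all kept fingers and assemble."""
    fingers = [
        predict_finger_pfm(c, predictor)
        for c, k in zip(array.contacts, array.kept_mask)
        if k and c != "---"
    ]
    return assemble_array_pwm(array, fingers)


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    """Center and L2-normalize columns; constant columns become zero."""
    c = m - m.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(c, axis=0, keepdims=True)
    return np.divide(c, norms, out=np.zeros_like(c), where=norms > 1e-12)


def _best_alignment(q: np.ndarray, t: np.ndarray, min_overlap: int):
    """Best summed column-Pearson over offsets/orientations; None if none.

    With normalized columns the Pearson correlation of two columns is their
    dot product (constant, e.g. uniform, columns contribute 0), so the score
    at each offset is a diagonal sum of one cross-correlation matrix.
    """
    qn = _normalize_columns(q)
    best = None
    for orient, tm in (("+", t), ("-", reverse_complement_pwm(t))):
        tn = _normalize_columns(tm)
        C = qn.T @ tn  # [i, j] = corr(q col i, t col j); offset = i - j
        wq, wt = C.shape
        for d in range(-wq + min_overlap, wt - min_overlap + 1):
            diag = np.diagonal(C, offset=d)
            if len(diag) < min_overlap:
                continue
            s = float(diag.sum())
            off = -d  # query index minus target index
            key = (s, orient == "+", -abs(off))
            if best is None or key > best[0]:
                best = (key, s, off, orient)
    if best is None:
        return None
    return best[1], best[2], best[3]


def compare_motifs(
    q: ArrayPWM,
    t: ArrayPWM,
    n_shuffles: int = 1000,
    seed: int = 0,
    min_overlap: int = 6,
) -> MotifSimilarity:
    """TomTom-style similarity with an empirical column-shuffle null.

    The p-value is the add-one-corrected fraction of column-shuffled targets
    whose best alignment scores strictly better than the observed one — the
    probability that a random motif would be better matched than the input —
    so it is never 0 and never exceeds 1.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be at least 100")
    obs = _best_alignment(q.matrix, t.matrix, min_overlap)
    if obs is None:
        return MotifSimilarity(
            q.name, t.name, 0, "+", float("nan"), 1.0, no_similarity=True
        )
    score, off, orient = obs
    rng = np.random.default_rng(seed)
    better = 0
    w = t.matrix.shape[1]
    for _ in range(n_shuffles):
        perm = rng.permutation(w)
        null = _best_alignment(q.matrix, t.matrix[:, perm], min_overlap)
        if null is not None and null[0] > score + 1e-12:
            better += 1
    p = (1 + better) / (n_shuffles + 1)
    return MotifSimilarity(q.name, t.name, off, orient, score, p)


def score_threshold_from_pvalue(pwm: ArrayPWM, p: float) -> float:
    """Smallest log-odds threshold (bits) with background tail prob <= p.

    The exact null distribution of the window score under the zero-order
    background is computed by dynamic programming over columns, with scores
    discretized to 1e-3 bits.
    """
    if not 0 < p < 1:
        if p >= 1:
            return float(np.round(pwm.log_odds().min(axis=0).sum(), 3))
        raise ValueError("p must be in (0, 1)")
    lo = np.round(pwm.log_odds() * 1000).astype(np.int64)
    bg = np.maximum(pwm.background, 0.01)
    bg = bg / bg.sum()
    lo_min = lo.min(axis=0).sum()
    lo_max = lo.max(axis=0).sum()
    size = int(lo_max - lo_min) + 1
    dist = np.zeros(size)
    dist[0] = 1.0
    cur_min = 0
    for col in range(lo.shape[1]):
        col_scores = lo[:, col]
        cmin = int(col_scores.min())
        new = np.zeros(size)
        for b in range(4):
            s = int(col_scores[b]) - cmin
            new[s : s + size - s] += bg[b] * dist[: size - s]
        dist = new
        cur_min += cmin
    # dist[i] = P(total integer score == cur_min + i)
    tail = np.cumsum(dist[::-1])[::-1]
    idx = np.searchsorted(tail <= p, True)
    if idx >= size:
        logger.warning("requested p=%g below resolution; using max score", p)
        return float(lo_max) / 1000.0
    return float(cur_min + idx) / 1000.0


def _encode(seq: str) -> np.ndarray:
    arr = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_IDX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return arr


def _window_scores(enc: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; NaN where a window has non-ACGT."""
    w = lo.shape[1]
    n = len(enc) - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    safe = np.where(enc < 0, 0, enc)
    for j in range(w):
        scores += lo[safe[j : j + n], j]
        valid &= enc[j : j + n] >= 0
    scores[~valid] = np.nan
    return scores


def scan_sequences(
    pwm: ArrayPWM, sequences: dict[str, str], threshold: float
) -> list[GenomicHit]:
    """Scan named sequences on both strands for windows scoring >= threshold.

    Minus-strand hits are reported in forward-strand half-open coordinates.
    """
    if not sequences:
        raise ValueError("no sequences to scan")
    lo_fwd = np.round(pwm.log_odds() * 1000) / 1000.0
    lo_rev = reverse_complement_pwm(lo_fwd)
    hits: list[GenomicHit] = []
    w = pwm.width
    for chrom in sequences:
        enc = _encode(sequences[chrom].upper())
        for strand, lo in (("+", lo_fwd), ("-", lo_rev)):
            sc = _window_scores(enc, lo)
            for pos in np.flatnonzero(sc >= threshold - 1e-9):
                hits.append(
                    GenomicHit(
                        chrom, int(pos), int(pos) + w, strand,
                        float(sc[pos]), pwm.name,
                    )
                )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def scan_genome(pwm: ArrayPWM, fasta, threshold: float) -> list[GenomicHit]:
    """Scan a genome FASTA file on both strands."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    if not seqs:
        raise ValueError(f"empty FASTA: {fasta}")
    return scan_sequences(pwm, seqs, threshold)


@dataclass(frozen=True)
class OverlapSummary:
    n_pairs: int
    jaccard: float


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def intersect_hits(a: list[GenomicHit], b: list[GenomicHit]) -> OverlapSummary:
    """Count hit pairs sharing >= 1 bp (strand-agnostic) plus coverage Jaccard.

    Pair counting is a per-chromosome sweep over start-sorted intervals;
    Jaccard is intersection over union of the merged base-pair coverage.
    """
    by_chrom_a: dict[str, list[GenomicHit]] = {}
    by_chrom_b: dict[str, list[GenomicHit]] = {}
    for h in a:
        by_chrom_a.setdefault(h.chrom, []).append(h)
    for h in b:
        by_chrom_b.setdefault(h.chrom, []).append(h)

    n_pairs = 0
    inter_bp = 0
    union_bp = 0
    for chrom in set(by_chrom_a) | set(by_chrom_b):
        ia = sorted((h.start, h.end) for h in by_chrom_a.get(chrom, []))
        ib = sorted((h.start, h.end) for h in by_chrom_b.get(chrom, []))
        # sweep: for each a-interval, advance over b-intervals that may overlap
        j0 = 0
        for s, e in ia:
            while j0 < len(ib) and ib[j0][1] <= s:
                j0 += 1
            j = j0
            while j < len(ib) and ib[j][0] < e:
                if min(e, ib[j][1]) > max(s, ib[j][0]):
                    n_pairs += 1
                j += 1
        ma, mb = _merge(ia), _merge(ib)
        cov_a = sum(e - s for s, e in ma)
        cov_b = sum(e - s for s, e in mb)
        ix = 0
        k = 0
        for s, e in ma:
            while k < len(mb) and mb[k][1] <= s:
                k += 1
            kk = k
            while kk < len(mb) and mb[kk][0] < e:
                ix += min(e, mb[kk][1]) - max(s, mb[kk][0])
                kk += 1
        inter_bp += ix
        union_bp += cov_a + cov_b - ix
    jac = inter_bp / union_bp if union_bp else 0.0
    return OverlapSummary(n_pairs=n_pairs, jaccard=jac)


def overlap_matrix(hit_sets: dict[str, list[GenomicHit]]):
    """Pairwise incident-count and Jaccard matrices over named hit sets."""
    import pandas as pd

    if len(hit_sets) < 2:
        raise ValueError("need at least 2 hit sets")
    names = list(hit_sets)
    n = len(names)
    counts = np.zeros((n, n), dtype=int)
    jac = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = intersect_hits(hit_sets[names[i]], hit_sets[names[j]])
            counts[i, j] = counts[j, i] = s.n_pairs
            jac[i, j] = jac[j, i] = s.jaccard
    return (
        pd.DataFrame(counts, index=names, columns=names),
        pd.DataFrame(jac, index=names, columns=names),
    )


def write_bed(hits: list[GenomicHit], path) -> None:
    """BED6: chrom, start, end, motif, score (bits x 100, rounded), strand."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.motif}"
                f"\t{round(h.score * 100)}\t{h.strand}\n"
            )


def read_bed(path) -> list[GenomicHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e, name, score, strand = line.split("\t")[:6]
            hits.append(
                GenomicHit(c, int(s), int(e), strand.strip(),
                           int(score) / 100.0, name)
            )
    return hits


def write_jaspar(pwms: list[ArrayPWM], path, counts_scale: int = 100) -> None:
    """JASPAR-style text: >name then one bracketed count row per base."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.name}\n")
            for bi, base in enumerate(BASES):
                row = " ".join(
                    f"{v * counts_scale:.2f}" for v in p.matrix[bi]
                )
                fh.write(f"{base}  [ {row} ]\n")


def read_jaspar(path) -> list[ArrayPWM]:
    pwms = []
    name, rows = None, []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    for line in lines + [">"]:
        if line.startswith(">"):
            if name is not None:
                mat = np.array(rows)
                mat = mat / mat.sum(axis=0, keepdims=True)
                pwms.append(ArrayPWM(name=name, matrix=mat))
            name, rows = line[1:].split()[0] if line[1:] else None, []
        else:
            inner = line.split("[")[1].split("]")[0]
            rows.append([float(x) for x in inner.split()])
    return pwms


def write_meme(pwms: list[ArrayPWM], path) -> None:
    """MEME minimal-format motif text."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write(
            "Background letter frequencies\n"
            + " ".join(f"{b} {f:.4f}" for b, f in zip(BASES, bg))
            + "\n\n"
        )
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= 100 E= 0\n"
            )
            for col in p.matrix.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[ArrayPWM]:
    pwms = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    bg = np.full(4, 0.25)
    while i < len(lines):
        line = lines[i]
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            header = lines[i + 1]
            w = int(header.split("w=")[1].split()[0])
            mat = np.array(
                [[float(x) for x in lines[i + 2 + r].split()] for r in range(w)]
            ).T
            mat = mat / mat.sum(axis=0, keepdims=True)
            pwms.append(ArrayPWM(name=name, matrix=mat, background=bg))
            i += 2 + w
            continue
        i += 1
    return pwms
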