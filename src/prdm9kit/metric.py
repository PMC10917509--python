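"""Weighted minimum edit distance between repeat-unit arrays.

Alleles are compared as sequences of repeat units under three event costs:
within-unit nucleotide change (w_mut, per mismatching nucleotide), whole-unit
insertion/deletion (w_indel) and tandem duplication/slippage (w_slippage).
A unit gained or lost next to an identical neighbour is charged the
discounted slippage cost; any other unit gain/loss is a full indel. The
distance is the minimum total cost over all monotone alignments of the two
unit sequences (dynamic programming). A mask variant removes the nine
hypervariable contact-codon nucleotides of each unit before comparison.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from .alleles import RepeatUnit, ZnfArrayAllele, resolve_contact_positions

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightScheme:
    """Edit costs for the repeat-unit metric.

    Defaults are the weights of the repeat edit-distance model:
    w_mut = 1, w_indel = 3.5, w_slippage = 1.75.
    """

    w_mut: float = 1.0
    w_indel: float = 3.5
    w_slippage: float = 1.75
    slippage_max_mismatch: int = 0

    def __post_init__(self) -> None:
        if min(self.w_mut, self.w_indel, self.w_slippage) <= 0:
            raise ValueError("all weights must be positive")
        if self.w_slippage > self.w_indel:
            raise ValueError("w_slippage must not exceed w_indel")


@dataclass(frozen=True)
class MaskSpec:
    """Which nucleotides to remove from each unit before comparison.

    ``contacts`` mode strips the 9 nucleotides of the three contact codons
    (recognition-helix positions -1, +3, +6), the sites under positive
    selection; ``none`` compares full units.
    """

    mode: str = "none"

    def __post_init__(self) -> None:
        if self.mode not in ("none", "contacts"):
            raise ValueError(f"unknown mask mode {self.mode!r}")


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix."""

    labels: list[str]
    values: np.ndarray
    mask: MaskSpec = field(default_factory=MaskSpec)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")


def masked_nt(unit: RepeatUnit, mask: MaskSpec) -> str:
    """Unit nucleotides after removing masked positions.

    In contacts mode the codon positions are resolved from the unit's own
    translation. A canonical-length unit whose C2H2 pattern cannot be
    resolved (e.g. an anchor residue was substituted) is masked at the
    canonical contact positions, keeping masking uniform across units of
    equal length; a shortened unresolvable unit is returned unmasked.
    """
    if mask.mode == "none":
        return unit.nt
    try:
        drop = set(resolve_contact_positions(unit).codon_nt_indices)
    except ValueError:
        from .alleles import CANONICAL_CONTACT_NT_IDX, UNIT_LEN

        if len(unit.nt) != UNIT_LEN:
            return unit.nt
        drop = set(CANONICAL_CONTACT_NT_IDX)
    return "".join(c for i, c in enumerate(unit.nt) if i not in drop)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def unit_cost(a: RepeatUnit, b: RepeatUnit, w: WeightScheme, mask: MaskSpec) -> float:
    """Nucleotide-level cost of substituting unit ``a`` by unit ``b``.

    Hamming distance (x w_mut) when the masked units have equal length;
    Levenshtein distance (x w_mut) otherwise, since Hamming is undefined for
    unequal lengths (shortened first units force this case).
    """
    sa, sb = masked_nt(a, mask), masked_nt(b, mask)
    if not sa or not sb:
        raise ValueError("unit empty after masking")
    if len(sa) == len(sb):
        return w.w_mut * _hamming(sa, sb)
    return w.w_mut * edlib.align(sa, sb, task="distance")["editDistance"]


def _gap_costs(units: list[RepeatUnit], w: WeightScheme) -> list[float]:
    """Cost of deleting each unit from its own array.

    A unit identical (up to slippage_max_mismatch nucleotides) to its
    immediate left or right neighbour is a slippage copy and costs
    w_slippage; otherwise it costs w_indel.
    """
    costs = []
    for i, u in enumerate(units):
        slip = False
        for j in (i - 1, i + 1):
            if 0 <= j < len(units) and len(units[j].nt) == len(u.nt):
                if _hamming(u.nt, units[j].nt) <= w.slippage_max_mismatch:
                    slip = True
                    break
        costs.append(w.w_slippage if slip else w.w_indel)
    return costs


def array_distance(
    A: ZnfArrayAllele,
    B: ZnfArrayAllele,
    w: WeightScheme = WeightScheme(),
    mask: MaskSpec = MaskSpec(),
) -> float:
    """Minimum weighted edit distance between two unit arrays.

    Global alignment DP over the kept units of each array; substitutions
    cost ``unit_cost``, gaps cost the owner-relative slippage/indel cost.
    Slippage is judged against neighbours in the unit's own array, which is
    symmetric in the two arguments.
    """
    ua, ub = A.kept_units(), B.kept_units()
    if not ua or not ub:
        raise ValueError("array with no kept units")
    del_a = _gap_costs(ua, w)
    ins_b = _gap_costs(ub, w)
    n, m = len(ua), len(ub)
    D = np.empty((n + 1, m + 1))
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        D[i, 0] = D[i - 1, 0] + del_a[i - 1]
    for j in range(1, m + 1):
        D[0, j] = D[0, j - 1] + ins_b[j - 1]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = min(
                D[i - 1, j - 1] + unit_cost(ua[i - 1], ub[j - 1], w, mask),
                D[i - 1, j] + del_a[i - 1],
                D[i, j - 1] + ins_b[j - 1],
            )
    return float(D[n, m])


def distance_matrix(
    arrays: list[ZnfArrayAllele],
    w: WeightScheme = WeightScheme(),
    mask: MaskSpec = MaskSpec(),
) -> DistanceMatrix:
    """All pairwise array distances as a symmetric zero-diagonal matrix."""
    names = [a.name for a in arrays]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate allele names: {dup}")
    if len(arrays) < 3:
        raise ValueError("need at least 3 arrays for a distance matrix")
    n = len(arrays)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = array_distance(arrays[i], arrays[j], w, mask)
    return DistanceMatrix(labels=names, values=M, mask=mask)


def _sanitize(label: str) -> str:
    clean = re.sub(r"\s+", "_", label.strip())
    if clean != label:
        logger.warning("sanitized label %r -> %r for PHYLIP output", label, clean)
    return clean


def write_phylip(m: DistanceMatrix, path) -> None:
    """Write a square PHYLIP distance matrix (6 decimal places)."""
    labels = [_sanitize(l) for l in m.labels]
    if any(len(l) > 250 for l in labels):
        raise ValueError("label longer than 250 characters")
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for lab, row in zip(labels, m.values):
            fh.write(lab + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip(path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix."""
    with open(path) as fh:
        tokens = fh.read().split()
    n = int(tokens[0])
    labels, rows, pos = [], [], 1
    for _ in range(n):
        labels.append(tokens[pos])
        rows.append([float(t) for t in tokens[pos + 1 : pos + 1 + n]])
        pos += 1 + n
    return DistanceMatrix(labels=labels, values=np.array(rows))
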