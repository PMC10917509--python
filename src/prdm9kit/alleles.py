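"""Reading, decomposing and translating zinc-finger minisatellite alleles.

An allele here is the nucleotide sequence of a tandem array of (canonically)
84-bp repeat units, each encoding one C2H2 zinc finger of 28 residues. The
module tiles the sequence into units, translates them, locates the
DNA-contacting residues of the recognition helix (positions -1, +3 and +6,
anchored on the first zinc-coordinating histidine at helix position +7) and
filters low-confidence repeats either by the C2H2 sequence pattern or by a
position-specific bit-score profile.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import edlib
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

UNIT_LEN = 84
#: C2H2 zinc-finger pattern: two Zn-coordinating cysteines, twelve residues,
#: then the two Zn-coordinating histidines.
C2H2_PATTERN = re.compile(r"C.{2,4}C.{12}(H).{3,5}H")
#: Recognition-helix position of the first Zn-coordinating histidine.
HELIX_ANCHOR = 7
DEFAULT_HELIX_OFFSETS = (-1, 3, 6)

#: A canonical C2H2 repeat unit used by the simulator as the ancestral state.
#: 28 residues; contacts (-1,+3,+6) are S/D/T at amino-acid indices 12/16/19.
CANONICAL_UNIT_AA = "YVCGRGECGRGFSVRSDVLTHQRTHTGE"
CANONICAL_UNIT_NT = (
    "TATGTGTGTGGAAGAGGTGAATGTGGCCGTGGGTTTAGTGTTCGCTCAGATGTCCTGACA"
    "CATCAACGGACCCATACTGGAGAG"
)
#: 0-based amino-acid indices of the contact residues in the canonical unit.
CANONICAL_CONTACT_AA_IDX = (12, 16, 19)
#: The nine nucleotide indices of the three contact codons in an 84-nt unit.
CANONICAL_CONTACT_NT_IDX = tuple(
    3 * i + j for i in CANONICAL_CONTACT_AA_IDX for j in range(3)
)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class NucleotideAllele:
    """A named minisatellite allele as an uppercase A/C/G/T string."""

    name: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        bad = re.search(r"[^ACGT]", self.sequence)
        if bad:
            raise ValueError(
                f"allele {self.name!r}: non-ACGT character "
                f"{bad.group()!r} at position {bad.start()}"
            )
        if not self.sequence:
            raise ValueError(f"allele {self.name!r}: empty sequence")


@dataclass
class RepeatUnit:
    """One repeat unit of the array: nucleotides, translation, completeness."""

    index: int
    nt: str
    aa: str = ""
    complete: bool = True

    def __post_init__(self) -> None:
        if len(self.nt) % 3:
            raise ValueError(
                f"unit {self.index}: length {len(self.nt)} not divisible by 3"
            )


@dataclass(frozen=True)
class ContactPositions:
    """Resolved DNA-contact residue positions within one repeat unit."""

    helix_offsets: tuple[int, ...]
    unit_indices: tuple[int, ...]
    codon_nt_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.helix_offsets) != 3 or len(self.codon_nt_indices) != 9:
            raise ValueError("expected 3 helix offsets and 9 codon nucleotides")


@dataclass
class ConfidenceModel:
    """Repeat-confidence filter: C2H2 pattern match, or profile bit score.

    In ``profile`` mode a unit is kept when its summed position-specific
    score strictly exceeds ``threshold_bits`` (the published gathering
    threshold is 17.7 bits, and confidence requires a score *above* it).
    """

    mode: str = "pattern"
    threshold_bits: float = 17.7
    profile: list[dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("pattern", "profile"):
            raise ValueError(f"unknown confidence mode {self.mode!r}")


@dataclass
class ZnfArrayAllele:
    """An allele decomposed into repeat units with contacts and kept-mask."""

    allele: NucleotideAllele
    units: list[RepeatUnit]
    contacts: list[str] = field(default_factory=list)
    kept_mask: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        joined = "".join(u.nt for u in self.units)
        if joined != self.allele.sequence:
            raise ValueError(
                f"{self.allele.name}: units do not concatenate to the sequence"
            )
        if not self.contacts:
            self.contacts = extract_contacts_from_units(self.units)
        if not self.kept_mask:
            self.kept_mask = [True] * len(self.units)
        if len(self.contacts) != len(self.units):
            raise ValueError("one contact triplet required per unit")

    @property
    def name(self) -> str:
        return self.allele.name

    def kept_units(self) -> list[RepeatUnit]:
        return [u for u, k in zip(self.units, self.kept_mask) if k]


def read_allele_fasta(path) -> list[NucleotideAllele]:
    """Read a multi-FASTA of allele nucleotide sequences.

    Headers must be unique; sequences are upper-cased and must be pure
    A/C/G/T (ambiguity codes are rejected — the alleles these files hold are
    assembled, cloned Sanger products, so any ambiguity is an upstream error).
    """
    alleles: list[NucleotideAllele] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seen.add(rec.id)
        alleles.append(
            NucleotideAllele(rec.id, str(rec.seq).upper(), source=str(path))
        )
    if not alleles:
        logger.warning("no FASTA records found in %s", path)
    return alleles


def _enumerate_segmentations(
    total: int, lengths: tuple[int, ...], cap: int = 20000
) -> list[tuple[int, ...]]:
    """All orderings of unit lengths from ``lengths`` summing to ``total``."""
    out: list[tuple[int, ...]] = []

    def rec(rem: int, acc: tuple[int, ...]) -> None:
        if len(out) > cap:
            raise ValueError("too many candidate segmentations")
        if rem == 0:
            out.append(acc)
            return
        for L in lengths:
            if L <= rem:
                rec(rem - L, acc + (L,))

    rec(total, ())
    return out


def _consensus(seqs: list[str]) -> str:
    if not seqs:
        return ""
    n = min(len(s) for s in seqs)
    cols = []
    for i in range(n):
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s[i]] = counts.get(s[i], 0) + 1
        # deterministic tie-break: highest count, then alphabetical base
        cols.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(cols)


def decompose_minisatellite(
    allele: NucleotideAllele,
    unit_len: int = UNIT_LEN,
    allowed_deletion_nt: frozenset[int] | set[int] = frozenset({9}),
) -> list[RepeatUnit]:
    """Tile an allele into repeat units of ``unit_len`` nt.

    When the length is not a multiple of ``unit_len``, shortened units of
    length ``unit_len - d`` (d an in-frame deletion size from
    ``allowed_deletion_nt``) are permitted. Among all valid segmentations the
    one whose units best match (smallest total Levenshtein distance to) the
    consensus of its own full-length units is chosen; ties go to the
    segmentation whose shortened units are leftmost. Shortened units are
    flagged ``complete=False``.
    """
    for d in allowed_deletion_nt:
        if d % 3 or d <= 0:
            raise ValueError(f"deletion size {d} is not a positive multiple of 3")
    lengths = tuple(
        sorted({unit_len} | {unit_len - d for d in allowed_deletion_nt}, reverse=True)
    )
    seq = allele.sequence
    try:
        segs = _enumerate_segmentations(len(seq), lengths)
    except ValueError as e:
        raise ValueError(f"{allele.name}: {e}") from e
    if not segs:
        rem = len(seq) % unit_len
        raise ValueError(
            f"{allele.name}: length {len(seq)} not expressible as repeat "
            f"units (remainder {rem} nt over full {unit_len}-nt units)"
        )

    def cut(seg: tuple[int, ...]) -> list[str]:
        pieces, pos = [], 0
        for L in seg:
            pieces.append(seq[pos : pos + L])
            pos += L
        return pieces

    def score(seg: tuple[int, ...]) -> float:
        pieces = cut(seg)
        full = [p for p in pieces if len(p) == unit_len]
        cons = _consensus(full) if full else _consensus(pieces)
        return sum(
            edlib.align(p, cons, task="distance")["editDistance"] for p in pieces
        )

    def short_positions(seg: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(i for i, L in enumerate(seg) if L < unit_len)

    # prefer fewest shortened units, then best consensus fit, then leftmost
    best = min(
        segs,
        key=lambda s: (len(short_positions(s)), score(s), short_positions(s)),
    )
    return [
        RepeatUnit(index=i, nt=p, complete=len(p) == unit_len)
        for i, p in enumerate(cut(best))
    ]


def translate_units(units: list[RepeatUnit]) -> list[RepeatUnit]:
    """Populate the amino-acid field of each unit (frame 0, standard code).

    A unit with an in-frame stop codon is flagged ``complete=False`` and its
    translation truncated at the stop; this is a warning, not an error.
    """
    out = []
    for u in units:
        aa = str(Seq(u.nt).translate())
        if "*" in aa:
            logger.warning("unit %d: in-frame stop codon; truncating", u.index)
            out.append(replace(u, aa=aa[: aa.index("*")], complete=False))
        else:
            out.append(replace(u, aa=aa))
    return out


def resolve_contact_positions(
    unit: RepeatUnit, helix_offsets: tuple[int, ...] = DEFAULT_HELIX_OFFSETS
) -> ContactPositions:
    """Locate the DNA-contacting residues of a unit's recognition helix.

    The first zinc-coordinating histidine sits at helix position +7; helix
    offset ``p`` therefore maps to amino-acid index ``h1 - 7 + p`` where
    ``h1`` is that histidine's index in the unit.
    """
    if not unit.aa:
        raise ValueError(f"unit {unit.index}: not translated")
    m = C2H2_PATTERN.search(unit.aa)
    if m is None:
        raise ValueError(f"unit {unit.index}: C2H2 pattern not found in {unit.aa!r}")
    h1 = m.start(1)
    aa_idx = tuple(h1 - HELIX_ANCHOR + p for p in helix_offsets)
    if min(aa_idx) < 0 or max(aa_idx) >= len(unit.aa):
        raise ValueError(
            f"unit {unit.index}: helix offsets {helix_offsets} fall outside unit"
        )
    nt_idx = tuple(3 * i + j for i in aa_idx for j in range(3))
    return ContactPositions(tuple(helix_offsets), aa_idx, nt_idx)


def extract_contacts_from_units(
    units: list[RepeatUnit],
    helix_offsets: tuple[int, ...] = DEFAULT_HELIX_OFFSETS,
) -> list[str]:
    out = []
    for u in units:
        try:
            cp = resolve_contact_positions(u, helix_offsets)
            out.append("".join(u.aa[i] for i in cp.unit_indices).upper())
        except ValueError:
            out.append("---")
    return out


def extract_contacts(array: ZnfArrayAllele) -> list[str]:
    """Per-unit 3-letter contact-residue strings; '---' where unresolvable."""
    return extract_contacts_from_units(array.units)


def _profile_score(aa: str, profile: list[dict[str, float]]) -> float:
    if len(aa) < len(profile):
        return float("-inf")
    return sum(profile[i].get(aa[i], float("-inf")) for i in range(len(profile)))


def filter_repeats(array: ZnfArrayAllele, model: ConfidenceModel) -> ZnfArrayAllele:
    """Set the kept-mask of an array from a confidence model.

    Pattern mode keeps units whose translation matches the C2H2 pattern.
    Profile mode keeps units whose position-specific log-odds score is
    strictly above ``model.threshold_bits``.
    """
    if model.mode == "profile":
        if model.profile is None:
            raise ValueError("profile mode requires a profile")
        mask = [
            _profile_score(u.aa, model.profile) > model.threshold_bits
            for u in array.units
        ]
    else:
        mask = [C2H2_PATTERN.search(u.aa) is not None for u in array.units]
    return ZnfArrayAllele(
        allele=array.allele,
        units=array.units,
        contacts=list(array.contacts),
        kept_mask=mask,
    )


def build_array(
    allele: NucleotideAllele,
    unit_len: int = UNIT_LEN,
    allowed_deletion_nt: frozenset[int] | set[int] = frozenset({9}),
) -> ZnfArrayAllele:
    """Decompose + translate + contact-extract an allele in one call."""
    units = translate_units(
        decompose_minisatellite(allele, unit_len, allowed_deletion_nt)
    )
    return ZnfArrayAllele(allele=allele, units=units)


def write_allele_table(arrays: list[ZnfArrayAllele], path) -> pd.DataFrame:
    """Write a TSV summary (name, unit count/lengths, contacts, kept-mask)."""
    df = pd.DataFrame(
        {
            "name": [a.name for a in arrays],
            "n_units": [len(a.units) for a in arrays],
            "unit_lengths": [
                ",".join(str(len(u.nt)) for u in a.units) for a in arrays
            ],
            "contacts": [",".join(a.contacts) for a in arrays],
            "kept_mask": [
                "".join("1" if k else "0" for k in a.kept_mask) for a in arrays
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df
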