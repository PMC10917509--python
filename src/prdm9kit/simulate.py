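"""Synthetic allele families and planted-motif genomes.

The allele simulator evolves a tandem array of canonical 84-bp zinc-finger
repeat units along a Yule tree of unit height. Three move types act on each
branch, with Poisson counts: within-unit point substitution (rate per unit
per unit branch length, with the nine contact-codon nucleotides mutating at
an elevated rate to mimic positive selection on the hypervariable sites),
whole-unit tandem duplication, and whole-unit deletion (array size floored
at one unit). Every event is logged so leaves can be reproduced exactly by
replay, and the generating tree is retained as truth for topology-recovery
checks.

The genome generator plants motif consensus sequences at known,
non-overlapping coordinates in i.i.d. background sequence so scanner recall
can be measured against truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alleles import (
    CANONICAL_CONTACT_NT_IDX,
    CANONICAL_UNIT_NT,
    NucleotideAllele,
    ZnfArrayAllele,
    build_array,
    resolve_contact_positions,
)
from .motifs import ArrayPWM, GenomicHit

logger = logging.getLogger(__name__)

BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SimulationConfig:
    """Rates and sizes for one simulated allele family.

    Rates are per unit branch length of the unit-height Yule tree:
    ``sub_rate`` per repeat unit, ``dup_rate``/``del_rate`` per array.
    """

    seed: int
    n_leaves: int = 8
    ancestral_units: int = 11
    unit_len: int = 84
    sub_rate: float = 2.0
    dup_rate: float = 0.3
    del_rate: float = 0.3
    contact_hypermut_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.n_leaves < 3 or self.ancestral_units < 2:
            raise ValueError("need n_leaves >= 3 and ancestral_units >= 2")
        if min(self.sub_rate, self.dup_rate, self.del_rate) < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SimulatedFamily:
    config: SimulationConfig
    true_tree: dendropy.Tree
    alleles: list[NucleotideAllele]
    event_log: list[dict] = field(default_factory=list)
    ancestor_units: list[str] = field(default_factory=list)

    def arrays(self) -> list[ZnfArrayAllele]:
        return [build_array(a) for a in self.alleles]


def yule_tree(n_leaves: int, rng: np.random.Generator) -> dendropy.Tree:
    """Sample a Yule tree rescaled to unit root-to-tip height.

    Pure-birth process at rate 1: starting from two lineages, exponential
    waiting times at total rate k split a uniformly chosen lineage until
    ``n_leaves`` are extant; a final waiting period ends the process and
    all tips are extended to the end time (ultrametric), then every branch
    is divided by the total height.
    """
    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    birth: dict[dendropy.Node, float] = {root: 0.0}
    t = 0.0
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active = [c1, c2]
    birth[c1] = birth[c2] = 0.0
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        birth_t = t
        k1, k2 = dendropy.Node(), dendropy.Node()
        parent.add_child(k1)
        parent.add_child(k2)
        parent.edge.length = birth_t - birth[parent]
        birth[k1] = birth[k2] = birth_t
        active.extend([k1, k2])
    t_end = t + rng.exponential(1.0 / n_leaves)
    for i, leaf in enumerate(active):
        leaf.edge.length = t_end - birth[leaf]
        label = f"allele{i + 1:02d}"
        leaf.taxon = tns.new_taxon(label)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / t_end
    # internal labels give every branch a stable identity for the event log
    for i, nd in enumerate(tree.preorder_node_iter()):
        if nd.taxon is None:
            nd.label = f"N{i}"
    tree.is_rooted = True
    return tree


def _contact_weights(unit_len: int, factor: float) -> np.ndarray:
    w = np.ones(unit_len)
    for i in CANONICAL_CONTACT_NT_IDX:
        if i < unit_len:
            w[i] = factor
    return w


def _apply_event(units: list[str], ev: dict) -> None:
    kind = ev["type"]
    if kind == "sub":
        u = ev["unit"]
        s = units[u]
        assert s[ev["pos"]] == ev["old"]
        units[u] = s[: ev["pos"]] + ev["new"] + s[ev["pos"] + 1 :]
    elif kind == "dup":
        units.insert(ev["unit"] + 1, units[ev["unit"]])
    elif kind == "del":
        units.pop(ev["unit"])
    else:
        raise ValueError(f"unknown event type {kind!r}")


def _evolve_branch(
    units: list[str],
    branch: str,
    length: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    log: list[dict],
) -> list[str]:
    units = list(units)
    n_sub = rng.poisson(cfg.sub_rate * len(units) * length)
    n_dup = rng.poisson(cfg.dup_rate * length)
    n_del = rng.poisson(cfg.del_rate * length)
    kinds = ["sub"] * n_sub + ["dup"] * n_dup + ["del"] * n_del
    rng.shuffle(kinds)
    weights = _contact_weights(cfg.unit_len, cfg.contact_hypermut_factor)
    pw = weights / weights.sum()
    for kind in kinds:
        if kind == "sub":
            u = int(rng.integers(len(units)))
            if len(units[u]) == cfg.unit_len:
                pos = int(rng.choice(cfg.unit_len, p=pw))
            else:
                pos = int(rng.integers(len(units[u])))
            old = units[u][pos]
            cstart = pos - pos % 3
            codon = list(units[u][cstart : cstart + 3])
            # alleles are functional: reject substitutions creating stops
            choices = []
            for b in BASES:
                if b == old:
                    continue
                codon[pos - cstart] = b
                if "".join(codon) not in _STOPS:
                    choices.append(b)
            codon[pos - cstart] = old
            new = rng.choice(choices)
            ev = {"branch": branch, "type": "sub", "unit": u,
                  "pos": pos, "old": old, "new": str(new)}
        elif kind == "dup":
            u = int(rng.integers(len(units)))
            ev = {"branch": branch, "type": "dup", "unit": u}
        else:
            if len(units) <= 1:
                logger.warning("branch %s: deletion skipped (floor 1 unit)", branch)
                continue
            u = int(rng.integers(len(units)))
            ev = {"branch": branch, "type": "del", "unit": u}
        _apply_event(units, ev)
        log.append(ev)
    return units


def _branch_id(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def simulate_allele_family(cfg: SimulationConfig) -> SimulatedFamily:
    """Evolve an ancestral repeat array along a Yule tree; fully seeded."""
    rng = np.random.default_rng(cfg.seed)
    tree = yule_tree(cfg.n_leaves, rng)
    ancestor = [CANONICAL_UNIT_NT[: cfg.unit_len]] * cfg.ancestral_units
    log: list[dict] = []
    states: dict[dendropy.Node, list[str]] = {tree.seed_node: ancestor}
    alleles: list[NucleotideAllele] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_units = states[node.parent_node]
        units = _evolve_branch(
            parent_units, _branch_id(node), node.edge.length or 0.0, cfg, rng, log
        )
        states[node] = units
        if node.is_leaf():
            alleles.append(
                NucleotideAllele(
                    name=node.taxon.label,
                    sequence="".join(units),
                    source=f"simulated seed={cfg.seed}",
                )
            )
    return SimulatedFamily(
        config=cfg,
        true_tree=tree,
        alleles=alleles,
        event_log=log,
        ancestor_units=ancestor,
    )


def replay_events(family: SimulatedFamily) -> dict[str, str]:
    """Re-derive every leaf sequence from the ancestor and the event log.

    The log is ordered; replay applies each branch's events while walking
    the true tree from the root. Exact agreement with the stored alleles is
    the simulator's lossless-provenance guarantee.
    """
    by_branch: dict[str, list[dict]] = {}
    for ev in family.event_log:
        by_branch.setdefault(ev["branch"], []).append(ev)
    tree = family.true_tree
    states = {tree.seed_node: list(family.ancestor_units)}
    leaves: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        units = list(states[node.parent_node])
        for ev in by_branch.get(_branch_id(node), []):
            _apply_event(units, ev)
        states[node] = units
        if node.is_leaf():
            leaves[node.taxon.label] = "".join(units)
    return leaves


def make_contact_only_variants(
    base: NucleotideAllele, n: int, seed: int
) -> list[NucleotideAllele]:
    """Variants of ``base`` differing only within contact codons.

    Each variant carries 1-3 substitutions confined to the nine
    contact-codon nucleotides of randomly chosen units, avoiding stop
    codons, so masked distances to the base (and between variants) are
    exactly zero while unmasked distances are positive.
    """
    rng = np.random.default_rng(seed)
    array = build_array(base)
    resolvable = []
    for u in array.units:
        try:
            cp = resolve_contact_positions(u)
            resolvable.append((u.index, cp.codon_nt_indices))
        except ValueError:
            continue
    if not resolvable:
        raise ValueError("no unit with resolvable contact positions")
    out = []
    for v in range(n):
        seq = list(base.sequence)
        n_changes = int(rng.integers(1, 4))
        done = 0
        while done < n_changes:
            ui, nt_idx = resolvable[int(rng.integers(len(resolvable)))]
            unit_start = sum(len(u.nt) for u in array.units[:ui])
            pos_in_unit = int(rng.choice(nt_idx))
            pos = unit_start + pos_in_unit
            old = seq[pos]
            new = str(rng.choice([b for b in BASES if b != old]))
            codon_start = pos - pos_in_unit % 3
            codon = seq[codon_start : codon_start + 3]
            codon[pos - codon_start] = new
            if "".join(codon) in _STOPS:
                continue
            seq[pos] = new
            done += 1
        out.append(
            NucleotideAllele(
                name=f"{base.name}_v{v + 1}",
                sequence="".join(seq),
                source=f"contact-only variant of {base.name}, seed={seed}",
            )
        )
    return out


@dataclass
class PlantedGenome:
    seed: int
    sequence: str
    background: np.ndarray
    plants: list[GenomicHit]
    chrom: str = "chrSim"


def plant_motif_genome(
    pwms: list[ArrayPWM],
    length: int,
    n_per_motif: int,
    seed: int,
    background: np.ndarray | None = None,
    out_fasta=None,
    out_bed=None,
) -> PlantedGenome:
    """I.i.d. background with each motif's consensus planted at known spots.

    Plant positions are non-overlapping and strands random; truth intervals
    are returned (and optionally written as FASTA + BED).
    """
    from .motifs import write_bed

    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    total_w = sum(p.width for p in pwms) * n_per_motif
    if length < 10 * total_w:
        raise ValueError("genome length must be >= 10x total planted width")
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(BASES), size=length, p=bg))
    occupied: list[tuple[int, int]] = []
    plants: list[GenomicHit] = []

    def overlaps(s: int, e: int) -> bool:
        return any(s < oe and os_ < e for os_, oe in occupied)

    comp = str.maketrans(BASES, "TGCA")
    for pwm in pwms:
        cons = pwm.consensus()
        for _ in range(n_per_motif):
            for attempt in range(1000):
                s = int(rng.integers(0, length - pwm.width + 1))
                if not overlaps(s, s + pwm.width):
                    break
            else:
                raise ValueError("could not place plant without overlap")
            strand = "+" if rng.random() < 0.5 else "-"
            planted = cons if strand == "+" else cons.translate(comp)[::-1]
            seq[s : s + pwm.width] = list(planted)
            occupied.append((s, s + pwm.width))
            plants.append(
                GenomicHit("chrSim", s, s + pwm.width, strand,
                           pwm.max_score(), pwm.name)
            )
    plants.sort(key=lambda h: (h.start, h.strand))
    genome = PlantedGenome(
        seed=seed, sequence="".join(seq), background=bg, plants=plants
    )
    if out_fasta is not None:
        with open(out_fasta, "w") as fh:
            fh.write(f">{genome.chrom}\n")
            for i in range(0, length, 70):
                fh.write(genome.sequence[i : i + 70] + "\n")
    if out_bed is not None:
        write_bed(plants, out_bed)
    return genome


def write_family(family: SimulatedFamily, fasta_path, newick_path=None,
                 events_path=None) -> None:
    """FASTA of leaf alleles, Newick truth tree, JSON-lines event log."""
    import json

    from .phylogeny import write_newick

    with open(fasta_path, "w") as fh:
        for a in family.alleles:
            fh.write(f">{a.name}\n")
            for i in range(0, len(a.sequence), 70):
                fh.write(a.sequence[i : i + 70] + "\n")
    if newick_path is not None:
        write_newick(family.true_tree, newick_path)
    if events_path is not None:
        with open(events_path, "w") as fh:
            for ev in family.event_log:
                fh.write(json.dumps(ev) + "\n")
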