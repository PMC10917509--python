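"""End-to-end orchestration: alleles -> distances -> trees -> motifs."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .alleles import (
    ConfidenceModel,
    build_array,
    filter_repeats,
    read_allele_fasta,
    write_allele_table,
)
from .metric import DistanceMatrix, MaskSpec, WeightScheme, distance_matrix, write_phylip
from .motifs import (
    overlap_matrix,
    pwm_for_allele,
    scan_genome,
    score_threshold_from_pvalue,
    write_bed,
    write_meme,
)
from .phylogeny import bionj_tree, root_on_outgroup, write_newick

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    alleles_fasta: str
    outdir: str
    outgroup: str | None = None
    weights: WeightScheme = field(default_factory=WeightScheme)
    confidence: ConfidenceModel = field(default_factory=ConfidenceModel)
    genome_fasta: str | None = None
    scan_pvalue: float = 1e-5
    n_shuffles: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.alleles_fasta).exists():
            raise FileNotFoundError(self.alleles_fasta)
        if self.genome_fasta and not Path(self.genome_fasta).exists():
            raise FileNotFoundError(self.genome_fasta)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run decompose -> filter -> distances -> trees (and optionally motifs).

    Returns a manifest dict (also written to the output directory) listing
    every produced file plus the parameters and seeds that produced it.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "weights": vars(cfg.weights).copy(),
        "inputs": {"alleles_fasta": str(cfg.alleles_fasta)},
        "outputs": {},
    }

    stage = "decompose"
    try:
        alleles = read_allele_fasta(cfg.alleles_fasta)
        arrays = [
            filter_repeats(build_array(a), cfg.confidence) for a in alleles
        ]
        if cfg.outgroup is not None and cfg.outgroup not in {
            a.name for a in arrays
        }:
            raise ValueError(
                f"outgroup {cfg.outgroup!r} not among alleles "
                f"{sorted(a.name for a in arrays)}"
            )
        table = out / "alleles.tsv"
        write_allele_table(arrays, table)
        manifest["outputs"]["allele_table"] = str(table)

        for mode in ("none", "contacts"):
            stage = f"distances[{mode}]"
            dm: DistanceMatrix = distance_matrix(
                arrays, cfg.weights, MaskSpec(mode)
            )
            tag = "full" if mode == "none" else "masked"
            phylip = out / f"distances_{tag}.phy"
            write_phylip(dm, phylip)
            manifest["outputs"][f"distances_{tag}"] = str(phylip)

            stage = f"tree[{mode}]"
            tree = bionj_tree(dm)
            if cfg.outgroup is not None:
                tree = root_on_outgroup(tree, cfg.outgroup)
            nwk = out / f"bionj_{tag}.nwk"
            write_newick(tree, nwk)
            manifest["outputs"][f"tree_{tag}"] = str(nwk)

        if cfg.genome_fasta:
            stage = "motifs"
            pwms = [pwm_for_allele(a) for a in arrays]
            meme = out / "motifs.meme"
            write_meme(pwms, meme)
            manifest["outputs"]["motifs_meme"] = str(meme)
            manifest["inputs"]["genome_fasta"] = str(cfg.genome_fasta)

            stage = "scan"
            hit_sets = {}
            for pwm in pwms:
                thr = score_threshold_from_pvalue(pwm, cfg.scan_pvalue)
                hits = scan_genome(pwm, cfg.genome_fasta, thr)
                bed = out / f"hits_{pwm.name}.bed"
                write_bed(hits, bed)
                hit_sets[pwm.name] = hits
                manifest["outputs"][f"hits_{pwm.name}"] = str(bed)

            stage = "overlap"
            counts, jac = overlap_matrix(hit_sets)
            counts.to_csv(out / "overlap_counts.tsv", sep="\t")
            jac.to_csv(out / "overlap_jaccard.tsv", sep="\t")
            manifest["outputs"]["overlap_counts"] = str(out / "overlap_counts.tsv")
            manifest["outputs"]["overlap_jaccard"] = str(out / "overlap_jaccard.tsv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"]["manifest"] = str(out / "manifest.json")
    return manifest
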