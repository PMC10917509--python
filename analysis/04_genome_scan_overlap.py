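"""Scan a planted genome with each allele's motif and quantify overlap.

Builds a synthetic genome with every allele's consensus site planted at
known coordinates, scans it with each PWM at a match p-value of 1e-4,
writes per-allele BED files, measures recall of the planted sites, and
computes the pairwise >=1 bp overlap-count and Jaccard matrices.
"""

from pathlib import Path

from prdm9kit.alleles import ConfidenceModel, build_array, filter_repeats, read_allele_fasta
from prdm9kit.motifs import (
    intersect_hits,
    overlap_matrix,
    pwm_for_allele,
    scan_sequences,
    score_threshold_from_pvalue,
    write_bed,
)
from prdm9kit.simulate import plant_motif_genome

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20240604
SCAN_P = 1e-4
GENOME_LEN = 200_000
N_ALLELES = 6  # scan a subset: pairwise overlap grows quadratically
PLANTS_PER_MOTIF = 5


def main() -> None:
    out = BASE / "scan"
    out.mkdir(parents=True, exist_ok=True)
    alleles = read_allele_fasta(BASE / "family" / "alleles.fasta")[:N_ALLELES]
    arrays = [filter_repeats(build_array(a), ConfidenceModel()) for a in alleles]
    pwms = [pwm_for_allele(a) for a in arrays]

    # the genome itself is bulky and fully regenerable from the seed; keep
    # it out of results/ and only persist the truth intervals
    scratch = BASE.parent / "scratch"
    scratch.mkdir(exist_ok=True)
    genome = plant_motif_genome(
        pwms, length=GENOME_LEN, n_per_motif=PLANTS_PER_MOTIF, seed=SEED,
        out_fasta=scratch / "planted_genome.fasta", out_bed=out / "truth.bed",
    )

    hit_sets = {}
    for pwm in pwms:
        thr = score_threshold_from_pvalue(pwm, SCAN_P)
        hits = scan_sequences(pwm, {genome.chrom: genome.sequence}, thr)
        write_bed(hits, out / f"hits_{pwm.name}.bed")
        hit_sets[pwm.name] = hits
        truth = [p for p in genome.plants if p.motif == pwm.name]
        recovered = sum(
            1 for p in truth if intersect_hits([p], hits).n_pairs > 0
        )
        print(
            f"{pwm.name}: {len(hits)} hits at p<={SCAN_P:g} "
            f"(threshold {thr:.2f} bits), {recovered}/{len(truth)} planted "
            f"sites recovered"
        )

    counts, jac = overlap_matrix(hit_sets)
    counts.to_csv(out / "overlap_counts.tsv", sep="\t")
    jac.to_csv(out / "overlap_jaccard.tsv", sep="\t")
    print(
        f"pairwise overlap written; mean off-diagonal Jaccard "
        f"{(jac.values.sum() - len(pwms)) / (len(pwms) ** 2 - len(pwms)):.3f}"
    )


if __name__ == "__main__":
    main()
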