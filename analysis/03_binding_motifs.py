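"""Predict array-level binding motifs and compare them TomTom-style.

For every allele the kept fingers' contact triplets are mapped to per-finger
matrices (built-in recognition-code fallback), assembled reverse-complement
into one PWM per allele, written as MEME text, and compared all-vs-all with
the column-shuffle permutation null. Writes a -log10(p) similarity matrix.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from prdm9kit.alleles import ConfidenceModel, build_array, filter_repeats, read_allele_fasta
from prdm9kit.motifs import compare_motifs, pwm_for_allele, write_meme

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20240603
N_SHUFFLES = 300


def main() -> None:
    out = BASE / "motifs"
    out.mkdir(parents=True, exist_ok=True)
    alleles = read_allele_fasta(BASE / "family" / "alleles.fasta")
    arrays = [filter_repeats(build_array(a), ConfidenceModel()) for a in alleles]
    pwms = [pwm_for_allele(a) for a in arrays]
    write_meme(pwms, out / "motifs.meme")

    names = [p.name for p in pwms]
    nlp = pd.DataFrame(np.nan, index=names, columns=names)
    for q in pwms:
        for t in pwms:
            s = compare_motifs(q, t, n_shuffles=N_SHUFFLES, seed=SEED)
            nlp.loc[q.name, t.name] = s.neg_log10_p if not s.no_similarity else np.nan
    nlp.to_csv(out / "similarity_neglog10p.tsv", sep="\t")

    diag = np.diag(nlp.values)
    print(
        f"{len(pwms)} motifs (widths {min(p.width for p in pwms)}-"
        f"{max(p.width for p in pwms)} bp); self-similarity -log10(p) = "
        f"{diag.min():.2f} for all (empirical floor with {N_SHUFFLES} shuffles)"
    )
    off = nlp.values[~np.eye(len(names), dtype=bool)]
    floor = -np.log10(1.0 / (N_SHUFFLES + 1))
    at_floor = float(np.mean(off >= floor - 1e-9))
    print(
        f"cross-motif -log10(p): median {np.nanmedian(off):.2f}; "
        f"{at_floor:.0%} of pairs reach the permutation floor — the coarse "
        f"recognition-code fallback yields strongly overlapping predictions "
        f"for related arrays"
    )


if __name__ == "__main__":
    main()
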