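#!/usr/bin/env python
"""Curate the simulated free-text descriptions and summarise the corpus.

Reads results/synthetic/molecules.tsv, runs the curation rules (stoplist,
variant merging, odourless removal), builds the dichotomous perceptual
matrix and reports its headline statistics: descriptors per molecule,
molecules per descriptor, and sparseness.
"""

from pathlib import Path

from odorspace import (
    CurationConfig,
    build_perceptual_matrix,
    cooccurrence,
    curate_records,
    matrix_stats,
    read_molecule_table,
)

IN = Path("results/synthetic/molecules.tsv")
OUT = Path("results/corpus")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = read_molecule_table(IN)
    records = curate_records(table, CurationConfig(merge_map={}))
    A = build_perceptual_matrix(records)
    A.write_tsv(OUT / "perceptual_matrix.tsv")
    A.write_triplets(OUT / "perceptual_triplets.tsv")
    stats = matrix_stats(A)
    stats.to_json(OUT / "corpus_stats.json")
    C = cooccurrence(A)
    C.to_frame().to_csv(OUT / "cooccurrence.tsv", sep="\t")

    print(f"molecules kept: {stats.n_molecules}, descriptors: {stats.n_descriptors}")
    print(
        f"descriptors/molecule: {stats.ap_m:.2f} "
        f"(range {stats.ap_m_range[0]}-{stats.ap_m_range[1]})"
    )
    print(
        f"molecules/descriptor: {stats.am_p:.2f} "
        f"(range {stats.am_p_range[0]}-{stats.am_p_range[1]})"
    )
    print(f"sparseness: {stats.sparseness_pct:.2f}%")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
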