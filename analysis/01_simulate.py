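#!/usr/bin/env python
"""Generate the synthetic odour database every later stage analyses.

Emulates a scraped odour database: ~1500 molecules, ~300 descriptor
vocabulary, ~97.7% sparse incidence, heavy-tailed descriptor popularity,
7 planted descriptor communities, a physico-chemical feature table whose
geometry follows the perceptual communities, and free-text descriptions
reassembled from the matrix with filler words so the curation stage has
real work to do.  Everything lands under results/synthetic/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from odorspace import SynthSpec, gen_feature_matrix, gen_perceptual_matrix, gen_token_stream

OUT = Path("results/synthetic")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42

SPEC = SynthSpec(
    m=1500,
    p=300,
    target_sparseness_pct=98.8,
    n_communities=7,
    within_preference=0.9,
    n_features=120,
    n_informative=40,
    congruence=1.0,
    noise_sd=0.5,
    n_constant_features=10,
    n_missing_features=8,
    seed=SEED,
)

FILLERS = ["powerful", "somewhat", "and", "with", "a", "note", "less", "like"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    A, mol_comm, desc_comm = gen_perceptual_matrix(SPEC)
    rng = np.random.default_rng(SEED + 99)

    # reassemble free-text descriptions with interleaved filler words
    rows = []
    for mid, row in zip(A.molecule_ids, A.values):
        words = [d for d, v in zip(A.descriptors, row) if v]
        text = []
        for w in words:
            if rng.random() < 0.4:
                text.append(FILLERS[rng.integers(len(FILLERS))])
            text.append(w)
        rows.append({"molecule_id": mid, "description": " ".join(text)})
    pd.DataFrame(rows).to_csv(OUT / "molecules.tsv", sep="\t", index=False)

    features = gen_feature_matrix(mol_comm, SPEC, molecule_ids=A.molecule_ids)
    features.to_csv(OUT / "features.csv")

    pd.DataFrame(
        {"molecule_id": A.molecule_ids, "community": mol_comm}
    ).to_csv(OUT / "planted_molecule_communities.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"descriptor": A.descriptors, "community": desc_comm}
    ).to_csv(OUT / "planted_descriptor_communities.tsv", sep="\t", index=False)

    vocab = list(A.descriptors)
    pairs = [
        (vocab[int(rng.integers(len(vocab)))], vocab[int(rng.integers(len(vocab)))])
        for _ in range(30)
    ]
    pairs = [(a, b) for a, b in pairs if a != b]
    stream = gen_token_stream(vocab, 50_000, pairs, seed=SEED + 7, pair_rate=0.08)
    (OUT / "corpus.txt").write_text(" ".join(stream.tokens) + "\n")

    print(f"molecules: {A.m}, descriptors: {A.p}")
    print(f"features: {features.shape[1]} columns (incl. 10 constant, 8 with gaps)")
    print(f"corpus: {len(stream.tokens)} tokens, {len(pairs)} planted pairs")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
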