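"""Synthetic odour-database generators.

Real odour databases are scraped and carry no accessions, so every pipeline
stage is exercised on generated inputs that reproduce their statistical
structure: dichotomous molecule x descriptor matrices at 96-99.5%
sparseness with heavy-tailed descriptor frequencies and planted descriptor
communities; physico-chemical feature tables whose cluster geometry is
congruent (or not) with the perceptual clusters; token streams with
controlled window co-occurrence; and exact discrete power-law degree
samples.  Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .curation import PerceptualMatrix
from .dualspace import FeatureMatrix
from .powerfit import sample_power_law
from .semantic import TokenStream

__all__ = [
    "SynthSpec",
    "gen_perceptual_matrix",
    "gen_feature_matrix",
    "gen_token_stream",
    "gen_power_law_degrees",
]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic odour database.

    Defaults mirror the structure of real scraped databases: ~3000 molecules
    with ~500 descriptors at 99.3% sparseness, descriptor popularity with a
    power-law tail (exponent 2), and 7 planted descriptor communities.
    """

    m: int = 3000
    p: int = 500
    target_sparseness_pct: float = 99.3
    freq_exponent: float = 2.0
    n_communities: int = 7
    within_preference: float = 0.9
    n_features: int = 100
    n_informative: int = 30
    congruence: float = 1.0
    noise_sd: float = 0.5
    n_constant_features: int = 0
    n_missing_features: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.congruence <= 1.0:
            raise ValueError("congruence must lie in [0, 1]")
        if not 0.0 < self.target_sparseness_pct < 100.0:
            raise ValueError("target_sparseness_pct must lie in (0, 100)")
        if self.freq_exponent <= 1.0:
            raise ValueError("freq_exponent must exceed 1")


def gen_perceptual_matrix(
    spec: SynthSpec,
) -> tuple[PerceptualMatrix, np.ndarray, np.ndarray]:
    """Generate a dichotomous perceptual matrix with planted communities.

    Descriptor popularity follows a discrete power law with the requested
    exponent; each molecule belongs to a community and draws a Poisson
    number of descriptors (mean matched to the target sparseness), picking
    within-community descriptors with probability ``within_preference``.

    Returns the matrix plus the planted molecule community labels and the
    descriptor community labels (aligned to the matrix's rows/columns after
    cleanup of empty rows and columns).
    """
    rng = np.random.default_rng(spec.seed)
    mean_count = (1.0 - spec.target_sparseness_pct / 100.0) * spec.p
    if mean_count < 1.0:
        raise ValueError(
            "infeasible sparseness: implied descriptor count per molecule < 1"
        )
    # heavy-tailed descriptor popularity
    popularity = sample_power_law(
        spec.freq_exponent, 1, spec.p, rng, x_max=100_000
    ).astype(float)
    desc_comm = rng.integers(0, spec.n_communities, size=spec.p)
    mol_comm = rng.integers(0, spec.n_communities, size=spec.m)

    values = np.zeros((spec.m, spec.p), dtype=np.int8)
    own_pool = [np.where(desc_comm == c)[0] for c in range(spec.n_communities)]
    other_pool = [np.where(desc_comm != c)[0] for c in range(spec.n_communities)]
    own_prob = [
        popularity[ix] / popularity[ix].sum() if ix.size else None for ix in own_pool
    ]
    other_prob = [
        popularity[ix] / popularity[ix].sum() if ix.size else None for ix in other_pool
    ]
    all_ix = np.arange(spec.p)
    all_prob = popularity / popularity.sum()
    for i in range(spec.m):
        count = 0
        while count < 1:
            count = rng.poisson(mean_count)
        count = min(count, spec.p)
        c = mol_comm[i]
        chosen: set[int] = set()
        for _ in range(count):
            if rng.random() < spec.within_preference and own_pool[c].size:
                pool, prob = own_pool[c], own_prob[c]
            elif other_pool[c].size:
                pool, prob = other_pool[c], other_prob[c]
            else:
                pool, prob = all_ix, all_prob
            chosen.add(int(rng.choice(pool, p=prob)))
        for j in chosen:
            values[i, j] = 1

    keep_rows = values.sum(axis=1) > 0
    keep_cols = values.sum(axis=0) > 0
    values = values[keep_rows][:, keep_cols]
    mol_ids = tuple(f"CAS-{i:06d}" for i in np.where(keep_rows)[0])
    descriptors = tuple(f"desc{j:04d}" for j in np.where(keep_cols)[0])
    A = PerceptualMatrix(molecule_ids=mol_ids, descriptors=descriptors, values=values)
    return A, mol_comm[keep_rows], desc_comm[keep_cols]


def gen_feature_matrix(
    labels: np.ndarray,
    spec: SynthSpec,
    *,
    molecule_ids: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Generate a physico-chemical feature table for labelled molecules.

    Informative features get class-dependent means separated proportionally
    to ``congruence`` (at 0 all classes coincide); the rest are pure noise.
    Constant and missing-value columns can be injected to exercise
    preprocessing.  Returned raw (unscaled), as a DRAGON-style export would
    be.
    """
    if spec.n_informative > spec.n_features:
        raise ValueError("n_informative exceeds n_features")
    rng = np.random.default_rng(spec.seed + 1)
    labels = np.asarray(labels)
    n = labels.size
    classes = np.unique(labels)
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
    # class centroids on the informative coordinates, separation ~ congruence
    centroids = rng.normal(0.0, 1.0, size=(classes.size, spec.n_informative))
    sep = 4.0 * spec.congruence
    for ci, c in enumerate(classes):
        X[labels == c, : spec.n_informative] += sep * centroids[ci]
    cols = [f"feat{j:04d}" for j in range(spec.n_features)]
    df = pd.DataFrame(X, columns=cols)
    for j in range(spec.n_constant_features):
        df[f"const{j:03d}"] = 1.0
    for j in range(spec.n_missing_features):
        col = rng.normal(size=n)
        col[rng.integers(0, n)] = np.nan
        df[f"miss{j:03d}"] = col
    if molecule_ids is not None:
        df.index = list(molecule_ids)
    else:
        df.index = [f"CAS-{i:06d}" for i in range(n)]
    df.index.name = "molecule_id"
    return df


def gen_token_stream(
    vocabulary,
    length: int,
    planted_pairs,
    seed: int = 0,
    *,
    pair_rate: float = 0.05,
    background: tuple[str, ...] = ("the", "of", "to", "it", "was", "on"),
) -> TokenStream:
    """Generate a token stream with controlled window-2 co-occurrence.

    Background tokens are interleaved with planted adjacent vocabulary
    pairs: at each position, with probability ``pair_rate`` a planted pair
    (a, b) is emitted adjacently, otherwise one background token.
    """
    rng = np.random.default_rng(seed)
    planted = [tuple(p) for p in planted_pairs]
    vocab = set(vocabulary)
    for a, b in planted:
        if a not in vocab or b not in vocab:
            raise ValueError("planted pair outside vocabulary")
    toks: list[str] = []
    while len(toks) < length:
        if planted and rng.random() < pair_rate:
            a, b = planted[rng.integers(0, len(planted))]
            toks.extend((a, b))
        else:
            toks.append(background[rng.integers(0, len(background))])
    return TokenStream(tokens=tuple(toks[:length]), source_tag=f"synthetic-seed{seed}")


def gen_power_law_degrees(
    alpha: float, x_min: int, n: int, seed: int = 0
) -> np.ndarray:
    """i.i.d. discrete power-law degree sample via inverse-CDF on the zeta
    tail (see :func:`odorspace.powerfit.sample_power_law`)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    return sample_power_law(alpha, x_min, n, rng)
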