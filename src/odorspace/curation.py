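"""Curation of free-text odour descriptions into a dichotomous perceptual matrix.

Each molecule in an odour database carries a free-text description such as
``"powerful green grass somewhat fruity gassy"``.  Curation lowercases and
whitespace-tokenizes the text, strips words that carry no qualitative
olfactory information (conjunctions, adverbs, suffixes, intensity words),
merges morphological variants onto a canonical descriptor, and drops
molecules described only as odourless.  The surviving descriptor sets are
assembled into the binary molecules x descriptors incidence matrix A, from
which the descriptor co-occurrence matrix C = A^T A follows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_STOPLIST",
    "DEFAULT_MERGE_MAP",
    "CurationConfig",
    "MoleculeRecord",
    "PerceptualMatrix",
    "CorpusStats",
    "CooccurrenceMatrix",
    "curate_description",
    "curate_records",
    "infer_morphological_merges",
    "build_perceptual_matrix",
    "matrix_stats",
    "cooccurrence",
    "read_molecule_table",
    "read_perceptual_matrix",
]

#: Words that carry no qualitative olfactory information.  Editable; seeded
#: with conjunctions, adverbs, suffix-like words, auxiliary verbs and
#: intensity words commonly found in odour databases.
DEFAULT_STOPLIST: frozenset[str] = frozenset(
    {
        "and", "or", "with", "of", "a", "an", "the", "in", "to", "at", "on",
        "less", "somewhat", "slightly", "very", "mild", "mildly", "strong",
        "strongly", "powerful", "weak", "faint", "intense",
        "like", "note", "notes", "nuance", "nuances", "undertone",
        "has", "is", "was", "have", "been", "being",
        "over", "preserves", "other", "when", "characteristic", "odor",
        "odour", "smell", "aroma", "scent",
    }
)

#: Variant -> canonical descriptor merges.  Values must themselves be
#: canonical (no chains).
DEFAULT_MERGE_MAP: dict[str, str] = {
    "alcoholic": "alcohol",
    "fruity": "fruit",
}


@dataclass(frozen=True)
class CurationConfig:
    """Rules applied when turning a raw description into descriptor tokens.

    Parameters
    ----------
    stoplist:
        Words removed outright.
    merge_map:
        Mapping of variant spellings onto canonical descriptors.  Values
        must not themselves be merge keys (no chains).
    drop_tokens:
        Descriptors whose presence removes the whole molecule, e.g.
        ``"odorless"``.
    """

    stoplist: frozenset[str] = DEFAULT_STOPLIST
    merge_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_MERGE_MAP))
    drop_tokens: frozenset[str] = frozenset({"odorless", "odourless"})

    def __post_init__(self) -> None:
        chained = [k for k, v in self.merge_map.items() if v in self.merge_map]
        if chained:
            raise ValueError(f"merge_map contains chains via keys {chained}")
        overlap = set(self.merge_map) & set(self.stoplist)
        if overlap:
            raise ValueError(f"stoplist and merge_map keys overlap: {sorted(overlap)}")


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: an identifier and its curated descriptor tokens."""

    molecule_id: str
    raw_description: str
    tokens: tuple[str, ...]


def curate_description(raw: str, config: CurationConfig | None = None) -> list[str]:
    """Curate one free-text description into an ordered descriptor list.

    Lowercases, splits on whitespace, removes stoplist words, applies the
    merge map, and collapses duplicates keeping first occurrence.  If any
    drop token (e.g. "odorless") is present the result is empty, marking
    the molecule for removal.
    """
    config = config or CurationConfig()
    out: list[str] = []
    seen: set[str] = set()
    for word in raw.lower().split():
        if word in config.stoplist:
            continue
        word = config.merge_map.get(word, word)
        if word in config.drop_tokens:
            return []
        if word not in seen:
            seen.add(word)
            out.append(word)
    return out


def infer_morphological_merges(
    token_lists: Iterable[Sequence[str]],
) -> dict[str, str]:
    """Infer ``-y`` / ``-like`` variant merges from a curated corpus.

    A token ``Xy`` or ``X-like``/``Xlike`` is merged onto ``X`` only when
    ``X`` itself already occurs as a descriptor somewhere in the corpus, so
    e.g. "woody" -> "wood" but "spicy" stays if "spic" never occurs.
    """
    vocab: set[str] = set()
    for toks in token_lists:
        vocab.update(toks)
    merges: dict[str, str] = {}
    for tok in vocab:
        for suffix in ("-like", "like", "y"):
            if tok.endswith(suffix) and len(tok) > len(suffix):
                stem = tok[: -len(suffix)]
                if stem in vocab:
                    merges[tok] = stem
                    break
    return merges


def curate_records(
    table: pd.DataFrame,
    config: CurationConfig | None = None,
    *,
    infer_merges: bool = False,
) -> list[MoleculeRecord]:
    """Curate a molecule table (columns ``molecule_id``, ``description``).

    With ``infer_merges`` a second pass merges morphological ``-y``/``-like``
    variants whose stem is already in the corpus vocabulary.
    """
    config = config or CurationConfig()
    ids = table["molecule_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate molecule_id in input table")
    raw = table["description"].fillna("").astype(str).tolist()
    token_lists = [curate_description(text, config) for text in raw]
    if infer_merges:
        extra = infer_morphological_merges(token_lists)
        if extra:
            token_lists = [
                list(dict.fromkeys(extra.get(t, t) for t in toks))
                for toks in token_lists
            ]
    return [
        MoleculeRecord(molecule_id=i, raw_description=r, tokens=tuple(toks))
        for i, r, toks in zip(ids, raw, token_lists)
    ]


@dataclass(frozen=True)
class PerceptualMatrix:
    """Dichotomous molecules x descriptors incidence matrix A.

    ``values[i, j] == 1`` iff descriptor ``j`` was used for molecule ``i``.
    Rows with no descriptors are removed before construction; columns are
    the corpus vocabulary in lexicographic order.
    """

    molecule_ids: tuple[str, ...]
    descriptors: tuple[str, ...]
    values: np.ndarray  # (m, p) int8 in {0, 1}

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.molecule_ids), columns=list(self.descriptors)
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "molecule_id"
        df.to_csv(path, sep="\t")

    def write_triplets(self, path: str | Path) -> None:
        """Write the nonzero entries as ``molecule_id<TAB>descriptor`` pairs."""
        rows, cols = np.nonzero(self.values)
        with open(path, "w") as fh:
            fh.write("molecule_id\tdescriptor\n")
            for i, j in zip(rows, cols):
                fh.write(f"{self.molecule_ids[i]}\t{self.descriptors[j]}\n")


def build_perceptual_matrix(records: Sequence[MoleculeRecord]) -> PerceptualMatrix:
    """Assemble the binary incidence matrix from curated records.

    Molecules with no surviving tokens are dropped; descriptor columns are
    the union of tokens, lexicographically sorted for determinism.
    """
    kept = [r for r in records if r.tokens]
    if not kept:
        raise ValueError("empty corpus: no molecule has any descriptor")
    descriptors = tuple(sorted({t for r in kept for t in r.tokens}))
    col = {d: j for j, d in enumerate(descriptors)}
    values = np.zeros((len(kept), len(descriptors)), dtype=np.int8)
    for i, r in enumerate(kept):
        for t in r.tokens:
            values[i, col[t]] = 1
    return PerceptualMatrix(
        molecule_ids=tuple(r.molecule_id for r in kept),
        descriptors=descriptors,
        values=values,
    )


@dataclass(frozen=True)
class CorpusStats:
    """Summary statistics of a perceptual matrix.

    ``ap_m`` is the mean number of descriptors per molecule, ``am_p`` the
    mean number of molecules per descriptor, and ``sparseness_pct`` the
    percentage of zero entries in A.
    """

    ap_m: float
    ap_m_range: tuple[int, int]
    am_p: float
    am_p_range: tuple[int, int]
    sparseness_pct: float
    n_molecules: int
    n_descriptors: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_molecules": self.n_molecules,
                    "n_descriptors": self.n_descriptors,
                    "avg_descriptors_per_molecule": self.ap_m,
                    "descriptors_per_molecule_range": list(self.ap_m_range),
                    "avg_occurrence_per_descriptor": self.am_p,
                    "occurrence_per_descriptor_range": list(self.am_p_range),
                    "sparseness_pct": self.sparseness_pct,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def matrix_stats(A: PerceptualMatrix) -> CorpusStats:
    """Compute per-molecule / per-descriptor averages and matrix sparseness.

    With ``S`` the total number of ones: AP_m = S/m, AM_p = S/p and
    sparseness = (1 - S/(m*p)) * 100.
    """
    vals = A.values
    total = int(vals.sum())
    row = vals.sum(axis=1)
    col = vals.sum(axis=0)
    m, p = vals.shape
    return CorpusStats(
        ap_m=total / m,
        ap_m_range=(int(row.min()), int(row.max())),
        am_p=total / p,
        am_p_range=(int(col.min()), int(col.max())),
        sparseness_pct=(1.0 - total / (m * p)) * 100.0,
        n_molecules=m,
        n_descriptors=p,
    )


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Descriptor co-occurrence counts C = A^T A.

    ``counts[i, j]`` is the number of molecules described by both
    descriptors i and j; the diagonal holds descriptor frequencies.
    """

    descriptors: tuple[str, ...]
    counts: np.ndarray  # (p, p) int64

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.descriptors), columns=list(self.descriptors)
        )


def cooccurrence(A: PerceptualMatrix) -> CooccurrenceMatrix:
    """Form the descriptor co-occurrence matrix C = A^T A over integers."""
    v = A.values.astype(np.int64)
    return CooccurrenceMatrix(descriptors=A.descriptors, counts=v.T @ v)


def read_perceptual_matrix(path: str | Path) -> PerceptualMatrix:
    """Read a perceptual matrix from the TSV written by ``write_tsv``."""
    df = pd.read_csv(path, sep="\t", index_col="molecule_id")
    return PerceptualMatrix(
        molecule_ids=tuple(df.index.astype(str)),
        descriptors=tuple(df.columns),
        values=df.to_numpy(dtype=np.int8),
    )


def read_molecule_table(path: str | Path) -> pd.DataFrame:
    """Read a molecule table (TSV or CSV by extension) with columns
    ``molecule_id`` and ``description``; extra columns are preserved."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"molecule_id", "description"} - set(df.columns)
    if missing:
        raise ValueError(f"molecule table missing columns: {sorted(missing)}")
    return df
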