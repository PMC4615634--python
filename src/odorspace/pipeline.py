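"""End-to-end orchestration of the odour-space analysis stages.

A :class:`RunConfig` (round-trippable to YAML) names the inputs — a
molecule table with free-text descriptions and, optionally, a
physico-chemical feature table and a token corpus — or a synthetic spec to
generate them, plus every stage parameter and seed.  :func:`run` executes
curate -> matrices -> network (null model, power law, communities) ->
semantic (optional) -> dual-space clustering -> prediction, writing every
table, graph and report into the output directory together with a manifest
recording the config hash, seeds, and a checksum per artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import curation, dualspace, network, predict, semantic, synth

__all__ = ["RunConfig", "PipelineError", "run"]

_STAGES = ("curate", "network", "semantic", "cluster", "predict")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with explicit seeds throughout."""

    out_dir: str = "results/run"
    molecule_table: str | None = None
    feature_table: str | None = None
    corpus_file: str | None = None
    synthetic: bool = True
    stages: tuple[str, ...] = _STAGES
    # synthetic spec
    synth_m: int = 500
    synth_p: int = 150
    synth_sparseness: float = 97.5
    synth_communities: int = 7
    synth_preference: float = 0.9
    synth_features: int = 60
    synth_informative: int = 20
    synth_congruence: float = 1.0
    synth_noise_sd: float = 0.5
    synth_token_length: int = 20000
    # stage parameters
    null_instances: int = 200
    resolution: float = 1.0
    louvain_restarts: int = 10
    window: int | None = None
    k_neighbor: int = 7
    k_max: int = 12
    folds: int = 5
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(config.stages),
        "artifacts": {},
    }

    def emit(path: Path) -> None:
        artifacts.append(path)

    try:
        # ---- inputs -------------------------------------------------------
        stage = "curate"
        spec = synth.SynthSpec(
            m=config.synth_m,
            p=config.synth_p,
            target_sparseness_pct=config.synth_sparseness,
            n_communities=config.synth_communities,
            within_preference=config.synth_preference,
            n_features=config.synth_features,
            n_informative=config.synth_informative,
            congruence=config.synth_congruence,
            noise_sd=config.synth_noise_sd,
            seed=config.seed,
        )
        if config.synthetic:
            A, mol_comm, desc_comm = synth.gen_perceptual_matrix(spec)
        else:
            if not config.molecule_table:
                raise PipelineError("stage curate: missing input molecule_table")
            table = curation.read_molecule_table(config.molecule_table)
            records = curation.curate_records(table)
            A = curation.build_perceptual_matrix(records)
            mol_comm = None

        if "curate" in config.stages:
            A.write_tsv(out / "perceptual_matrix.tsv")
            emit(out / "perceptual_matrix.tsv")
            A.write_triplets(out / "perceptual_triplets.tsv")
            emit(out / "perceptual_triplets.tsv")
            stats = curation.matrix_stats(A)
            stats.to_json(out / "corpus_stats.json")
            emit(out / "corpus_stats.json")

        C = curation.cooccurrence(A)
        G = network.build_graph(C)

        # ---- network ------------------------------------------------------
        if "network" in config.stages:
            stage = "network"
            summ = network.summarize(G)
            ns = summ.to_dict()
            ns["powerlaw"] = dataclasses.asdict(summ.powerlaw) if summ.powerlaw else None
            null = network.er_null(
                summ.n_nodes,
                summ.n_unweighted_edges,
                config.null_instances,
                seed=config.seed,
                clustering_emp=summ.clustering_avg,
            )
            report = {
                "summary": ns,
                "random_null": dataclasses.asdict(null),
                "top_hubs": network.top_hubs(G, min(10, G.number_of_nodes())),
            }
            _write_json(report, out / "network_summary.json")
            emit(out / "network_summary.json")
            nx.write_graphml(G, out / "cooccurrence.graphml")
            emit(out / "cooccurrence.graphml")
            nx.write_gexf(G, out / "cooccurrence.gexf")
            emit(out / "cooccurrence.gexf")
            part = network.detect_communities(
                G,
                resolution=config.resolution,
                seed=config.seed,
                restarts=config.louvain_restarts,
            )
            with open(out / "communities.tsv", "w") as fh:
                fh.write("descriptor\tcommunity\n")
                for node in sorted(part.assignment, key=str):
                    fh.write(f"{node}\t{part.assignment[node]}\n")
            emit(out / "communities.tsv")
            manifest["modularity_q"] = part.modularity_q

        # ---- semantic -----------------------------------------------------
        if "semantic" in config.stages:
            stage = "semantic"
            ap_m = curation.matrix_stats(A).ap_m
            window = config.window or semantic.window_for_ap(ap_m)
            if config.corpus_file:
                text = Path(config.corpus_file).read_text()
                stream = semantic.TokenStream.from_text(text, source_tag=config.corpus_file)
            else:
                rng = np.random.default_rng(config.seed + 7)
                vocab = list(A.descriptors)
                n_pairs = max(1, len(vocab) // 10)
                pairs = [
                    (vocab[int(rng.integers(len(vocab)))], vocab[int(rng.integers(len(vocab)))])
                    for _ in range(n_pairs)
                ]
                pairs = [(a, b) for a, b in pairs if a != b] or [(vocab[0], vocab[-1])]
                stream = synth.gen_token_stream(
                    vocab, config.synth_token_length, pairs, seed=config.seed + 7
                )
            G_sem = semantic.build_semantic_network(stream, A.descriptors, window)
            found = [n for n, d in G_sem.degree() if d > 0]
            sem_report: dict = {"window": window, "n_found": len(found)}
            if found:
                G_sub = semantic.matched_subnetwork(G, found)
                if G_sub.number_of_edges() and G_sem.number_of_edges():
                    rep = semantic.eigen_similarity(G_sub, G_sem)
                    sem_report.update(
                        {"k1": rep.k1, "k2": rep.k2, "k": rep.k, "sim": rep.sim}
                    )
            nx.write_graphml(G_sem, out / "semantic.graphml")
            emit(out / "semantic.graphml")
            _write_json(sem_report, out / "semantic_report.json")
            emit(out / "semantic_report.json")

        # ---- dual-space clustering ---------------------------------------
        labels_perc = None
        if "cluster" in config.stages or "predict" in config.stages:
            stage = "cluster"
            S_perc = dualspace.perceptual_similarity(A)
            res_perc = dualspace.spectral_xmeans(
                S_perc, k_max=config.k_max, seed=config.seed
            )
            labels_perc = res_perc.labels

        if "cluster" in config.stages or "predict" in config.stages:
            if config.synthetic:
                raw = synth.gen_feature_matrix(
                    mol_comm if mol_comm is not None else labels_perc, spec,
                    molecule_ids=A.molecule_ids,
                )
            else:
                if not config.feature_table:
                    raise PipelineError(
                        f"stage {stage}: missing input feature_table"
                    )
                raw = pd.read_csv(
                    config.feature_table, index_col="molecule_id"
                ).loc[list(A.molecule_ids)]
            X = dualspace.preprocess_features(raw)

        if "cluster" in config.stages:
            S_chem = dualspace.local_scaled_similarity(X, k_neighbor=config.k_neighbor)
            res_chem = dualspace.spectral_xmeans(
                S_chem, k_max=config.k_max, seed=config.seed
            )
            conc = dualspace.hubert_index(labels_perc, res_chem.labels)
            with open(out / "cluster_labels.tsv", "w") as fh:
                fh.write("molecule_id\tperceptual_cluster\tphysicochemical_cluster\n")
                for mid, lp, lc in zip(A.molecule_ids, labels_perc, res_chem.labels):
                    fh.write(f"{mid}\t{lp}\t{lc}\n")
            emit(out / "cluster_labels.tsv")
            _write_json(
                {
                    "k_perceptual": res_perc.k,
                    "k_physicochemical": res_chem.k,
                    "hubert_index": conc.hubert_index,
                    "both_same": conc.both_same,
                    "both_different": conc.both_different,
                    "discordant": conc.discordant,
                },
                out / "concordance.json",
            )
            emit(out / "concordance.json")

        # ---- prediction ---------------------------------------------------
        if "predict" in config.stages:
            stage = "predict"
            y = labels_perc
            counts = np.bincount(y)[1:]
            folds = int(min(config.folds, counts[counts > 0].min()))
            if folds < 2:
                raise PipelineError(
                    "stage predict: a perceptual class has fewer than 2 members"
                )
            data = predict.LabeledDataset(X=X, y=y)
            rep_no = predict.crossval_rf(
                data, folds=folds, with_selection=False, seed=config.seed
            )
            rep_fs = predict.crossval_rf(
                data, folds=folds, with_selection=True, seed=config.seed
            )
            _write_json(
                {
                    "roc_without_selection": rep_no.roc_auc,
                    "roc_with_selection": rep_fs.roc_auc,
                    "n_features_consensus": rep_fs.n_features_consensus,
                    "folds": folds,
                },
                out / "prediction_report.json",
            )
            emit(out / "prediction_report.json")
            with open(out / "consensus_features.tsv", "w") as fh:
                fh.write("feature\tfolds_selected\n")
                tally: dict[str, int] = {}
                for feats in rep_fs.selected_features_per_fold:
                    for fname in feats:
                        tally[fname] = tally.get(fname, 0) + 1
                for fname in sorted(tally, key=lambda f: (-tally[f], f)):
                    fh.write(f"{fname}\t{tally[fname]}\n")
            emit(out / "consensus_features.tsv")
    except PipelineError:
        raise
    except Exception as exc:  # partial outputs stay on disk with a marker
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineError(f"stage {stage}: {exc}") from exc

    manifest["artifacts"] = {p.name: _sha256(p) for p in sorted(artifacts)}
    _write_json(manifest, out / "manifest.json")
    return manifest
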