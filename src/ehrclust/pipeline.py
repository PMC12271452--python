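"""End-to-end pipeline orchestration with seeded reproducibility.

A single :class:`RunConfig` drives every stage; one global seed is split
deterministically into per-stage seeds, so a full run with the same config
and seed reproduces identical outputs for the deterministic stages.  Each
invocation writes into a fresh versioned run directory (``run-000``,
``run-001``, ...) under the configured output root, together with a manifest
recording inputs, outputs, content hashes and seeds.  Stage dependencies are
checked up front; a missing dependency raises an error naming the stage that
must run first.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ehrclust import __version__
from ehrclust.clustering import (
    ClusterModel,
    bootstrap_stability,
    fit_final_kmeans,
    precluster_for_sampling,
    select_optimal_k,
    splice_record,
    temporal_cohesion,
)
from ehrclust.encoder import (
    ModelConfig,
    diffcse_finetune,
    embed_patients,
    load_checkpoint,
    rtd_pretrain,
    save_checkpoint,
    token_embeddings,
)
from ehrclust.evaluation import (
    DiseaseMatrix,
    cdfipf,
    chi2_one_vs_all,
    comorbidity_similarity,
    crossgender_similarity,
    dfipf,
    observed_expected_exclusivity,
)
from ehrclust.lca import class_profiles, fit_lca, select_classes
from ehrclust.sequences import (
    prepare_sequences,
    read_sequences,
    read_vocabulary,
    write_sequences,
    write_vocabulary,
)
from ehrclust.synthetic import (
    DEFAULT_COMORBIDITY_PAIRS,
    DEFAULT_CONDITION_CODES,
    generate_cohort,
    read_cohort,
    table1_config,
    write_cohort,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "build-sequences",
    "pretrain",
    "finetune",
    "embed",
    "select-k",
    "cluster",
    "stability",
    "temporal",
    "evaluate",
    "lca",
)

_DEPENDENCIES: dict[str, tuple[str, ...]] = {
    "simulate": (),
    "build-sequences": ("simulate",),
    "pretrain": ("build-sequences",),
    "finetune": ("pretrain",),
    "embed": ("finetune",),
    "select-k": ("embed",),
    "cluster": ("select-k",),
    "stability": ("cluster",),
    "temporal": ("cluster",),
    "evaluate": ("cluster",),
    "lca": ("simulate",),
}

# Files whose presence marks a stage as complete.
_SENTINELS: dict[str, str] = {
    "simulate": "simulate/events.csv",
    "build-sequences": "build-sequences/sequences.csv",
    "pretrain": "pretrain/generator.npz",
    "finetune": "finetune/encoder.npz",
    "embed": "embed/embeddings_female.csv",
    "select-k": "select-k/kselection_female.csv",
    "cluster": "cluster/centroids_female.csv",
    "stability": "stability/stability_female.csv",
    "temporal": "temporal/cohesion_female.csv",
    "evaluate": "evaluate/cdfipf_female.csv",
    "lca": "lca/selection_female.csv",
}


class DependencyError(RuntimeError):
    """A requested stage is missing the outputs of an earlier stage."""


@dataclass
class RunConfig:
    """Desk-scale configuration for a full pipeline run."""

    outdir: str | Path = "runs"
    seed: int = 7
    n_patients: int = 300
    min_patient_count: int = 2
    max_len: int = 64
    hidden_size: int = 32
    discriminator_layers: int = 2
    generator_layers: int = 1
    attention_heads: int = 2
    pretrain_epochs: int = 2
    diffcse_epochs: int = 2
    batch_size: int = 32
    k_range: Sequence[int] = field(default_factory=lambda: list(range(2, 9)))
    kselect_replicates: int = 20
    kselect_fraction: float = 0.25
    n_sampling_strata: int = 20
    stability_replicates: int = 20
    stability_fraction: float = 0.25
    temporal_ages: Sequence[int] = field(default_factory=lambda: [60, 70, 80])
    lca_class_range: Sequence[int] = field(default_factory=lambda: [2, 3, 4])
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["outdir"] = str(payload["outdir"])
        payload["k_range"] = list(payload["k_range"])
        payload["temporal_ages"] = list(payload["temporal_ages"])
        payload["lca_class_range"] = list(payload["lca_class_range"])
        Path(path).write_text(json.dumps(payload, indent=2))


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed split from the global seed."""
    ss = np.random.SeedSequence([global_seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _new_run_dir(root: Path) -> Path:
    root.mkdir(parents=True, exist_ok=True)
    n = 0
    while (root / f"run-{n:03d}").exists():
        n += 1
    run_dir = root / f"run-{n:03d}"
    run_dir.mkdir()
    return run_dir


def _model_config(config: RunConfig, vocab_size: int, seed: int) -> ModelConfig:
    return ModelConfig(
        vocab_size=vocab_size,
        hidden_size=config.hidden_size,
        discriminator_layers=config.discriminator_layers,
        generator_layers=config.generator_layers,
        attention_heads=config.attention_heads,
        max_len=config.max_len,
        pretrain_epochs=config.pretrain_epochs,
        diffcse_epochs=config.diffcse_epochs,
        batch_size=config.batch_size,
        seed=seed,
    )


def _require(run_dir: Path, stage: str) -> None:
    for dep in _DEPENDENCIES[stage]:
        if not (run_dir / _SENTINELS[dep]).exists():
            raise DependencyError(
                f"stage {stage!r} requires outputs of stage {dep!r}; run {dep!r} first"
            )


def _load_strata(run_dir: Path) -> dict[str, tuple[list[str], np.ndarray]]:
    out = {}
    for stratum in ("female", "male"):
        df = pd.read_csv(run_dir / "embed" / f"embeddings_{stratum}.csv")
        ids = df["patient_id"].astype(str).tolist()
        out[stratum] = (ids, df.drop(columns=["patient_id"]).to_numpy())
    return out


def _run_stage(stage: str, config: RunConfig, run_dir: Path, seed: int) -> list[Path]:
    out = run_dir / stage
    out.mkdir(exist_ok=True)
    produced: list[Path] = []

    if stage == "simulate":
        cohort_cfg = table1_config(config.n_patients, seed=seed)
        records, truth = generate_cohort(cohort_cfg)
        paths = write_cohort(records, truth, out)
        produced += list(paths.values())

    elif stage == "build-sequences":
        records = read_cohort(run_dir / "simulate")
        seqs, vocab = prepare_sequences(
            records, min_patient_count=config.min_patient_count, max_len=config.max_len
        )
        produced.append(write_sequences(seqs, out / "sequences.csv"))
        produced.append(write_vocabulary(vocab, out / "vocabulary.csv"))

    elif stage == "pretrain":
        seqs = read_sequences(run_dir / "build-sequences" / "sequences.csv")
        vocab = read_vocabulary(
            run_dir / "build-sequences" / "vocabulary.csv", config.min_patient_count
        )
        mcfg = _model_config(config, len(vocab), seed)
        generator, _, report = rtd_pretrain(seqs, vocab, mcfg)
        produced.append(save_checkpoint(generator, vocab, out / "generator.npz"))
        (out / "pretrain_report.json").write_text(json.dumps(asdict_report(report)))
        produced.append(out / "pretrain_report.json")

    elif stage == "finetune":
        seqs = read_sequences(run_dir / "build-sequences" / "sequences.csv")
        encoder, vocab = load_checkpoint(run_dir / "pretrain" / "generator.npz")
        encoder, report = diffcse_finetune(
            encoder,
            seqs,
            vocab,
            temperature=encoder.config.diffcse_temperature,
            lambda_=encoder.config.diffcse_lambda,
            epochs=config.diffcse_epochs,
            seed=seed,
        )
        produced.append(save_checkpoint(encoder, vocab, out / "encoder.npz"))
        (out / "finetune_report.json").write_text(json.dumps(asdict_report(report)))
        produced.append(out / "finetune_report.json")

    elif stage == "embed":
        seqs = read_sequences(run_dir / "build-sequences" / "sequences.csv")
        encoder, vocab = load_checkpoint(run_dir / "finetune" / "encoder.npz")
        for stratum in ("female", "male"):
            sub = [s for s in seqs if s.gender == stratum]
            ids, emb = embed_patients(encoder, sub, vocab)
            df = pd.DataFrame(emb, columns=[f"e{j}" for j in range(emb.shape[1])])
            df.insert(0, "patient_id", ids)
            path = out / f"embeddings_{stratum}.csv"
            df.to_csv(path, index=False)
            produced.append(path)
        tokens, tok_emb = token_embeddings(encoder, vocab)
        tok_df = pd.DataFrame(tok_emb, columns=[f"e{j}" for j in range(tok_emb.shape[1])])
        tok_df.insert(0, "token", tokens)
        tok_path = out / "token_embeddings.csv"
        tok_df.to_csv(tok_path, index=False)
        produced.append(tok_path)

    elif stage == "select-k":
        for stratum, (_, emb) in _load_strata(run_dir).items():
            strata = precluster_for_sampling(
                emb, k=min(config.n_sampling_strata, emb.shape[0]), seed=seed
            )
            report = select_optimal_k(
                emb,
                config.k_range,
                replicates=config.kselect_replicates,
                fraction=config.kselect_fraction,
                seed=seed,
                strata=strata,
            )
            path = out / f"kselection_{stratum}.csv"
            report.table.assign(chosen_k=report.chosen_k).to_csv(path, index=False)
            produced.append(path)

    elif stage == "cluster":
        for stratum, (ids, emb) in _load_strata(run_dir).items():
            ksel = pd.read_csv(run_dir / "select-k" / f"kselection_{stratum}.csv")
            k = int(ksel["chosen_k"].iloc[0])
            model = fit_final_kmeans(emb, k, seed=seed, stratum=stratum)
            cent = pd.DataFrame(model.centroids)
            cent.insert(0, "cluster", range(k))
            cpath = out / f"centroids_{stratum}.csv"
            cent.to_csv(cpath, index=False)
            produced.append(cpath)
            labels = model.assign(emb)
            apath = out / f"assignments_{stratum}.csv"
            pd.DataFrame({"patient_id": ids, "cluster": labels}).to_csv(apath, index=False)
            produced.append(apath)

    elif stage == "stability":
        for stratum, (_, emb) in _load_strata(run_dir).items():
            model = _load_cluster_model(run_dir, stratum, seed)
            strata = precluster_for_sampling(
                emb, k=min(config.n_sampling_strata, emb.shape[0]), seed=seed
            )
            rep = bootstrap_stability(
                emb,
                model,
                replicates=config.stability_replicates,
                fraction=config.stability_fraction,
                seed=seed,
                strata=strata,
            )
            path = out / f"stability_{stratum}.csv"
            pd.DataFrame(
                {"cluster": range(model.k), "median_cosine_distance": rep.median_distance}
            ).to_csv(path, index=False)
            produced.append(path)

    elif stage == "temporal":
        records = read_cohort(run_dir / "simulate")
        encoder, vocab = load_checkpoint(run_dir / "finetune" / "encoder.npz")
        for stratum, (_, emb) in _load_strata(run_dir).items():
            model = _load_cluster_model(run_dir, stratum, seed)
            sub = [r for r in records if r.gender == stratum]
            by_age: dict[int, np.ndarray] = {}
            for age in config.temporal_ages:
                spliced = [splice_record(r, age) for r in sub]
                spliced = [r for r in spliced if r is not None]
                if not spliced:
                    continue
                seqs, _ = prepare_sequences(
                    spliced,
                    min_patient_count=config.min_patient_count,
                    max_len=config.max_len,
                    vocab=vocab,
                )
                _, aemb = embed_patients(encoder, seqs, vocab)
                if aemb.shape[0]:
                    by_age[age] = aemb
            rep = temporal_cohesion(by_age, emb, model)
            path = out / f"cohesion_{stratum}.csv"
            rep.per_age.to_csv(path, index=False)
            produced.append(path)
            dpath = out / f"cohesion_difference_{stratum}.csv"
            rep.cohesion_difference.to_csv(dpath, index=False)
            produced.append(dpath)

    elif stage == "evaluate":
        records = read_cohort(run_dir / "simulate")
        conditions = sorted(DEFAULT_CONDITION_CODES)
        cd_by_stratum = {}
        for stratum in ("female", "male"):
            sub = [r for r in records if r.gender == stratum]
            assign = pd.read_csv(run_dir / "cluster" / f"assignments_{stratum}.csv")
            order = {pid: i for i, pid in enumerate(assign["patient_id"].astype(str))}
            sub = sorted(
                (r for r in sub if r.patient_id in order), key=lambda r: order[r.patient_id]
            )
            matrix = DiseaseMatrix.from_records(sub, conditions, DEFAULT_CONDITION_CODES)
            weights = dfipf(matrix)
            labels = assign["cluster"].to_numpy()
            cmat = cdfipf(weights, labels, n_clusters=int(labels.max()) + 1)
            cd_by_stratum[stratum] = cmat
            path = out / f"cdfipf_{stratum}.csv"
            cmat.weights.to_csv(path)
            produced.append(path)
            assoc_rows = []
            for j, cond in enumerate(matrix.conditions):
                rep = chi2_one_vs_all(matrix.values[:, j], labels)
                assoc_rows.append(rep.table.assign(condition=cond))
            apath = out / f"associations_{stratum}.csv"
            pd.concat(assoc_rows).to_csv(apath, index=False)
            produced.append(apath)
            oe = observed_expected_exclusivity(matrix, labels)
            opath = out / f"observed_expected_{stratum}.csv"
            oe.to_csv(opath, index=False)
            produced.append(opath)
        tok_df = pd.read_csv(run_dir / "embed" / "token_embeddings.csv")
        tokens = tok_df["token"].astype(str).tolist()
        vecs = tok_df.drop(columns=["token"]).to_numpy()
        pairs = [
            (DEFAULT_CONDITION_CODES[a], DEFAULT_CONDITION_CODES[b])
            for a, b, _ in DEFAULT_COMORBIDITY_PAIRS
        ]
        sim = comorbidity_similarity(tokens, vecs, pairs, seed=seed)
        spath = out / "comorbidity_similarity.json"
        spath.write_text(
            json.dumps(
                {
                    "median": sim["median"],
                    "random_median": sim["random_median"],
                    "n_pairs": len(sim["pairs"]),
                }
            )
        )
        produced.append(spath)
        xg = crossgender_similarity(cd_by_stratum["female"], cd_by_stratum["male"])
        xpath = out / "crossgender_correlation.csv"
        xg.to_csv(xpath)
        produced.append(xpath)

    elif stage == "lca":
        records = read_cohort(run_dir / "simulate")
        conditions = sorted(DEFAULT_CONDITION_CODES)
        for stratum in ("female", "male"):
            sub = [r for r in records if r.gender == stratum]
            matrix = DiseaseMatrix.from_records(sub, conditions, DEFAULT_CONDITION_CODES)
            table, chosen = select_classes(
                matrix, config.lca_class_range, n_starts=3, seed=seed
            )
            path = out / f"selection_{stratum}.csv"
            table.assign(chosen=chosen).to_csv(path, index=False)
            produced.append(path)
            model = fit_lca(matrix, chosen, n_starts=3, seed=seed)
            ppath = out / f"profiles_{stratum}.csv"
            class_profiles(model).to_csv(ppath, index=False)
            produced.append(ppath)

    else:
        raise ValueError(f"unknown stage {stage!r}")

    return produced


def _load_cluster_model(run_dir: Path, stratum: str, seed: int) -> ClusterModel:
    cent = pd.read_csv(run_dir / "cluster" / f"centroids_{stratum}.csv")
    centroids = cent.drop(columns=["cluster"]).to_numpy()
    return ClusterModel(k=centroids.shape[0], centroids=centroids, stratum=stratum, seed=seed)


def asdict_report(report) -> dict:
    return {
        "total_loss": report.total_loss,
        "generator_loss": report.generator_loss,
        "discriminator_loss": report.discriminator_loss,
    }


def run(
    config: RunConfig,
    stages: Sequence[str],
    run_dir: Path | None = None,
) -> tuple[Path, dict]:
    """Run the requested stages in pipeline order inside a fresh run directory.

    Returns the run directory and the manifest.  Unknown stage names raise a
    ``ValueError``; a stage whose dependency has not produced outputs in the
    same run directory raises :class:`DependencyError` naming that stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage names: {unknown}")
    ordered = [s for s in STAGES if s in set(stages)]
    if run_dir is None:
        run_dir = _new_run_dir(Path(config.outdir))
    config.to_file(run_dir / "config.json")
    manifest: dict = {
        "run_dir": str(run_dir),
        "package_version": __version__,
        "global_seed": config.seed,
        "stages": {},
    }
    log_file = run_dir / "run.log"
    handler = logging.FileHandler(log_file)
    logging.getLogger().addHandler(handler)
    try:
        for stage in ordered:
            _require(run_dir, stage)
            seed = stage_seed(config.seed, stage)
            logger.info("running stage %s (seed %d)", stage, seed)
            produced = _run_stage(stage, config, run_dir, seed)
            manifest["stages"][stage] = {
                "seed": seed,
                "inputs": [
                    str(run_dir / _SENTINELS[d]) for d in _DEPENDENCIES[stage]
                ],
                "outputs": [
                    {"path": str(p.relative_to(run_dir)), "sha256": _sha256(p)}
                    for p in produced
                ],
            }
            (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    finally:
        logging.getLogger().removeHandler(handler)
    return run_dir, manifest
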