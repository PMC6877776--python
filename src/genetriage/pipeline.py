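"""End-to-end triage pipeline: ingest -> store -> featurize -> split ->
train -> evaluate -> rank.

A single declarative config (YAML or a :class:`PipelineConfig`) drives a
run; every stochastic component derives its seed from the one top-level
seed, so reruns with the same config are bit-identical for the
deterministic classifier families.  Each run emits metric report tables,
a probability ranking of unlabeled articles with the selected threshold
marked, and a machine-readable JSON manifest (seeds, vocabulary hashes,
package versions).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierSpec, predict_proba, train, vocabulary_hash
from .corpus import Corpus
from .evaluate import (
    cv_aucpr_ci,
    delong_test,
    gene_recall_threshold,
    pr_auc,
    roc_auc,
    score_test_set,
)
from .experiment import (
    REFERENCE_PRESETS,
    ImbalanceStrategy,
    SearchSpec,
    SplitSpec,
    apply_imbalance,
    random_search,
    stratified_split,
)
from .features import (
    BASE_SETS,
    COMBINATION_SETS,
    SignificanceConfig,
    build_feature_set,
)
from .readers import (
    assemble_corpus,
    read_gene_sets,
    read_labels,
    read_metamap,
    read_pubmed_xml,
    read_pubtator,
    read_semrep,
)
from .store import store_corpus

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "ingest"]

log = logging.getLogger("genetriage")

_KNOWN_SETS = set(BASE_SETS) | set(COMBINATION_SETS)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    pubmed_xml: str | None = None
    pubtator: str | None = None
    metamap: str | None = None
    semrep: str | None = None
    labels: str | None = None
    genes: str | None = None
    feature_sets: list[str] = field(default_factory=lambda: ["S1"])
    families: list[str] = field(default_factory=lambda: ["logistic"])
    imbalance_mode: str = "class_weights"
    train_fraction: float = 0.80
    gene_recall_target: float = 0.95
    preset: str | dict = "reference"
    search: dict | None = None  # when set: {"n_iter":..., "cv_folds":...}
    significant_cuis: str | None = None
    negation_cuis: str | None = None
    out_dir: str = "triage_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for s in self.feature_sets:
            if s not in _KNOWN_SETS:
                raise PipelineError("config", f"unknown feature set {s!r}")
        for fam in self.families:
            if fam not in REFERENCE_PRESETS:
                raise PipelineError("config", f"unknown classifier family {fam!r}")
        for name in ("pubmed_xml", "pubtator", "metamap", "semrep", "labels", "genes"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise PipelineError("config", f"{name} path does not exist: {path}")


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def ingest(config: PipelineConfig) -> Corpus:
    """Read the four annotation sources plus labels/genes into a Corpus."""
    if config.pubmed_xml is None:
        raise PipelineError("ingest", "pubmed_xml path is required")
    articles = read_pubmed_xml(config.pubmed_xml)
    texts = {a.pmid: (a.title, a.abstract) for a in articles}
    return assemble_corpus(
        articles,
        entities=read_pubtator(config.pubtator) if config.pubtator else None,
        concepts=(
            read_metamap(config.metamap, texts=texts) if config.metamap else None
        ),
        predications=read_semrep(config.semrep) if config.semrep else None,
        labels=read_labels(config.labels) if config.labels else None,
        gene_sets=read_gene_sets(config.genes) if config.genes else None,
    )


def run_pipeline(config: PipelineConfig, corpus: Corpus | None = None) -> dict[str, Any]:
    """Execute every stage; returns a manifest dict (also written to disk).

    Labeled articles are split 80/20 and drive training and evaluation;
    unlabeled articles are ranked by predicted probability with the
    selected gene-recall threshold marked.
    """
    t0 = time.time()
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO, format="%(asctime)s %(name)s %(message)s", force=False
    )

    if corpus is None:
        log.info("[ingest] reading annotation sources")
        corpus = ingest(config)
    store_path = out / "annotations.sqlite"
    store_corpus(corpus, store_path).close()
    log.info("[store] %d articles -> %s", len(corpus), store_path)

    labeled = Corpus(
        [a for a in corpus.articles if a.label is not None], name=corpus.name
    )
    unlabeled = Corpus(
        [a for a in corpus.articles if a.label is None], name=corpus.name
    )
    if len(labeled) < 4:
        raise PipelineError("split", "need at least 4 labeled articles")

    sig_cfg = (
        SignificanceConfig.from_files(config.significant_cuis, config.negation_cuis)
        if config.significant_cuis and config.negation_cuis
        else SignificanceConfig.default()
    )
    split_seed = _subseed(config.seed, 0)
    train_pmids, test_pmids = stratified_split(
        labeled, SplitSpec(train_fraction=config.train_fraction, seed=split_seed)
    )
    train_corpus = labeled.subset(train_pmids)
    test_corpus = labeled.subset(test_pmids)
    log.info("[split] %d train / %d test", len(train_corpus), len(test_corpus))

    presets: dict[str, dict] = {}
    searched: dict[str, Any] = {}
    if config.search:
        # hyper-parameters tuned once on the SemtypeCount features and reused
        spec = SearchSpec(seed=_subseed(config.seed, 1), **config.search)
        fm = build_feature_set(train_corpus, "SemtypeCount", cfg=sig_cfg, fit=True)
        y = np.array([a.label for a in train_corpus.articles])
        for fam in config.families:
            log.info("[tune] random search for %s", fam)
            res = random_search(fm.values, y, fam, spec)
            res.write(out / f"search_{fam}.tsv")
            presets[fam] = res.best_params
            searched[fam] = {"best_score": res.best_score, "best_params": repr(res.best_params)}
    elif config.preset == "reference":
        presets = {fam: REFERENCE_PRESETS[fam] for fam in config.families}
    elif isinstance(config.preset, dict):
        presets = {fam: config.preset.get(fam, {}) for fam in config.families}
    else:
        raise PipelineError("tune", f"unknown preset {config.preset!r}")

    imbalance = ImbalanceStrategy(
        mode=config.imbalance_mode, seed=_subseed(config.seed, 2)
    )
    y_train = np.array([a.label for a in train_corpus.articles])
    metric_rows = []
    auc_rows = []
    rank_frames = []
    vocab_hashes: dict[str, str] = {}
    baseline_scored: dict[str, Any] = {}
    sets_order = list(dict.fromkeys(config.feature_sets))
    if "BOW" in sets_order:  # evaluate the baseline first for DeLong pairing
        sets_order.remove("BOW")
        sets_order.insert(0, "BOW")
    for fam in config.families:
        for set_name in sets_order:
            try:
                log.info("[featurize] %s / %s", fam, set_name)
                fm_train = build_feature_set(train_corpus, set_name, cfg=sig_cfg, fit=True)
                fm_test = build_feature_set(
                    test_corpus, set_name, cfg=sig_cfg, fit=False,
                    vocabulary=fm_train.vocabulary,
                )
                vocab_hashes[set_name] = vocabulary_hash(fm_train.vocabulary)
                X, y, weights = apply_imbalance(fm_train.values, y_train, imbalance)
                cspec = ClassifierSpec(
                    family=fam,
                    hyper_parameters=presets.get(fam, {}),
                    seed=_subseed(config.seed, 3),
                )
                log.info("[train] %s / %s", fam, set_name)
                model = train(cspec, X, y, weights=weights)
                model.vocabulary = fm_train.vocabulary
                scored = score_test_set(model, fm_test, test_corpus)
                result = gene_recall_threshold(scored, target=config.gene_recall_target)
                report = result.report
                report.auroc = roc_auc(scored)
                report.aucpr = pr_auc(scored)
                mean_aucpr, ci, _ = cv_aucpr_ci(
                    fm_train.values, y_train, cspec, folds=5,
                    seed=_subseed(config.seed, 4),
                )
                report.aucpr_ci = ci
                metric_rows.append(
                    {"classifier": fam, "feature_set": set_name, **report.as_dict()}
                )
                auc_row = {
                    "classifier": fam,
                    "feature_set": set_name,
                    "aucpr_cv_mean": mean_aucpr,
                    "aucpr_ci_low": ci[0],
                    "aucpr_ci_high": ci[1],
                    "roc_auc": report.auroc,
                }
                key = fam
                if set_name == "BOW":
                    baseline_scored[key] = scored
                    auc_row["p_vs_bow"] = float("nan")
                elif key in baseline_scored:
                    _, _, _, p = delong_test(scored, baseline_scored[key])
                    auc_row["p_vs_bow"] = p
                else:
                    auc_row["p_vs_bow"] = float("nan")
                auc_rows.append(auc_row)
                if len(unlabeled):
                    fm_un = build_feature_set(
                        unlabeled, set_name, cfg=sig_cfg, fit=False,
                        vocabulary=fm_train.vocabulary,
                    )
                    probs = predict_proba(model, fm_un)
                    rank_frames.append(
                        pd.DataFrame(
                            {
                                "pmid": unlabeled.pmids,
                                "classifier": fam,
                                "feature_set": set_name,
                                "probability": probs,
                                "above_threshold": probs >= result.threshold,
                            }
                        ).sort_values("probability", ascending=False)
                    )
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"{fam}/{set_name}", str(exc)) from exc

    metrics = pd.DataFrame(metric_rows)
    metrics.to_csv(out / "metrics_gene_recall_threshold.tsv", sep="\t", index=False)
    aucs = pd.DataFrame(auc_rows)
    aucs.to_csv(out / "metrics_auc.tsv", sep="\t", index=False)
    if rank_frames:
        pd.concat(rank_frames).to_csv(out / "ranking.tsv", sep="\t", index=False)

    import sklearn

    from . import __version__

    manifest = {
        "package_version": __version__,
        "sklearn_version": sklearn.__version__,
        "seed": config.seed,
        "derived_seeds": {"split": split_seed},
        "n_articles": len(corpus),
        "n_train": len(train_corpus),
        "n_test": len(test_corpus),
        "n_unlabeled": len(unlabeled),
        "feature_sets": config.feature_sets,
        "families": config.families,
        "imbalance_mode": config.imbalance_mode,
        "vocabulary_hashes": vocab_hashes,
        "search": searched or None,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    log.info("[done] reports in %s (%.1fs)", out, manifest["elapsed_seconds"])
    return manifest
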