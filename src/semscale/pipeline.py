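"""End-to-end orchestration: corpus -> space -> embeddings -> cross-validated
severity scale -> bias report -> word scores.

The pipeline is deterministic: identical config + seed produce
byte-identical artifacts. Each stage persists its output as plain text in
the run directory, and each CLI stage can be re-run from the persisted
upstream artifacts, reproducing downstream outputs exactly. A manifest
records the config, the seed and a content hash that all tabular outputs
reference.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from semscale import bias as bias_mod
from semscale import synthetic
from semscale.embed import KeywordResponse, embed_dataset
from semscale.scale import (
    DEFAULT_DIMENSION_GRID,
    CvResult,
    RatedRecord,
    cross_validated_fit,
    make_folds,
    save_model,
    select_dimensions,
    train_scale,
)
from semscale.space import (
    SemanticSpace,
    SpaceConfig,
    build_space,
    count_cooccurrences,
    normalize_counts,
    read_ngram_counts,
    write_ngram_counts,
)
from semscale.synthetic import StudyConfig, StudyDataset
from semscale.wordscores import (
    make_bias_records,
    score_words,
    train_bias_scale,
    train_condition_scale,
    write_word_scores,
)

__all__ = ["RunConfig", "RunResult", "Diagnostic", "run_pipeline", "validate_inputs"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    With ``synthetic=True`` the corpus and study tables are generated from
    ``study_config``; otherwise ``corpus_path`` (an n-gram count file) and
    ``study_dir`` (p1.tsv/p2.tsv) must exist.
    """

    output_dir: str | Path = "runs/run"
    synthetic: bool = True
    corpus_path: str | Path | None = None
    study_dir: str | Path | None = None
    space: SpaceConfig = field(default_factory=lambda: SpaceConfig(n_dims=128))
    study_config: StudyConfig = field(default_factory=StudyConfig)
    n_folds: int = 10
    grid: tuple[int, ...] = DEFAULT_DIMENSION_GRID
    family: str = "linear"
    selection: str = "inner-cv"
    calibration_mode_human: str = "per-rater-means"
    calibration_mode_model: str = "per-event-means"
    fisher_z: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def manifest(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, Path):
                return str(v)
            if isinstance(v, dict):
                return {str(k): enc(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [enc(x) for x in v]
            return v

        payload = {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}
        # mappingproxy inside StudyConfig
        payload["study_config"]["conditions"] = {
            c: dataclasses.asdict(p) for c, p in self.study_config.conditions.items()
        }
        return payload


@dataclass
class RunResult:
    run_dir: Path
    space: SemanticSpace
    dataset_p1: pd.DataFrame
    dataset_p2: pd.DataFrame
    cv_result: CvResult
    severity_model: object
    bias_report: bias_mod.BiasReport
    word_scores: dict
    manifest: dict
    truth: dict | None = None


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "warning" | "fatal"
    message: str


def validate_inputs(
    p1: pd.DataFrame, p2: pd.DataFrame, keywords_per_response: int = 5
) -> list[Diagnostic]:
    """Check rating range, keyword counts, condition labels and coverage."""
    diags: list[Diagnostic] = []
    for name, df, required in (
        ("p1", p1, {"event_id", "condition", "keywords", "severity"}),
        ("p2", p2, {"rater_id", "event_id", "condition", "keywords", "severity"}),
    ):
        missing = required - set(df.columns)
        if missing:
            diags.append(Diagnostic("fatal", f"{name}: missing columns {sorted(missing)}"))
            continue
        sev = pd.to_numeric(df["severity"], errors="coerce")
        if sev.isna().any():
            diags.append(Diagnostic("fatal", f"{name}: non-numeric severities"))
        elif ((sev < 0) | (sev > 10)).any():
            bad = df.loc[(sev < 0) | (sev > 10)].index[:3].tolist()
            diags.append(
                Diagnostic("fatal", f"{name}: severities outside [0, 10] at rows {bad}")
            )
        unknown = set(df["condition"]) - {synthetic.PSYCHOLOGICAL, synthetic.PHYSICAL}
        if unknown:
            diags.append(Diagnostic("fatal", f"{name}: unknown condition labels {sorted(unknown)}"))
        n_words = df["keywords"].astype(str).str.split().str.len()
        short = int((n_words != keywords_per_response).sum())
        if short:
            diags.append(
                Diagnostic(
                    "warning",
                    f"{name}: {short} response(s) do not have exactly "
                    f"{keywords_per_response} keywords",
                )
            )
    if not diags or all(d.level == "warning" for d in diags):
        if "event_id" in p2.columns and "event_id" in p1.columns:
            unrated = set(p1["event_id"]) - set(p2["event_id"])
            if unrated:
                diags.append(
                    Diagnostic("warning", f"{len(unrated)} P1 event(s) have no P2 ratings")
                )
    return diags


def _records_from_table(
    df: pd.DataFrame, space: SemanticSpace, id_cols: Sequence[str]
) -> tuple[list[RatedRecord], list[int]]:
    responses = [
        KeywordResponse(
            words=tuple(str(row.keywords).split()),
            source_phase="P2" if "rater_id" in df.columns else "P1",
            owner_id=str(getattr(row, "rater_id", getattr(row, "participant_id", ""))),
            event_id=str(row.event_id),
        )
        for row in df.itertuples()
    ]
    embeddings, stats = embed_dataset(responses, space, skip_all_oov=True)
    if stats["n_skipped_all_oov"]:
        log.warning("%d response(s) skipped as fully out-of-vocabulary", stats["n_skipped_all_oov"])
    records, kept = [], []
    for i, (emb, row) in enumerate(zip(embeddings, df.itertuples())):
        if emb is None:
            continue
        rid = "|".join(str(getattr(row, c)) for c in id_cols)
        records.append(
            RatedRecord(
                record_id=rid,
                group=row.event_id,
                embedding=emb.vector,
                outcome=float(row.severity),
            )
        )
        kept.append(i)
    return records, kept


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage and write all artifacts into the run directory."""
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    manifest = config.manifest()
    manifest_hash = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest["manifest_hash"] = manifest_hash

    # stage 1: corpus and semantic space
    truth = None
    if config.synthetic:
        study_cfg = dataclasses.replace(config.study_config, seed=config.seed)
        vocab = synthetic.build_vocabulary(study_cfg)
        corpus = list(synthetic.generate_corpus(vocab, study_cfg))
        write_ngram_counts(corpus, run_dir / "corpus.ngrams")
    else:
        if config.corpus_path is None:
            raise FileNotFoundError("corpus_path required when synthetic=False")
        corpus = list(read_ngram_counts(config.corpus_path, n=config.space.n))
    log.info("stage build-space: %d n-grams", len(corpus))
    matrix = count_cooccurrences(corpus, config.space)
    space = build_space(normalize_counts(matrix, config.space), config.space)
    space.save(run_dir / "space", config.space)

    # stage 2: study tables
    if config.synthetic:
        dataset = synthetic.generate_study(study_cfg)
        synthetic.write_study(dataset, run_dir)
        p1, p2 = dataset.p1, dataset.p2
        truth = dataset.truth
    else:
        if config.study_dir is None:
            raise FileNotFoundError("study_dir required when synthetic=False")
        p1, p2 = synthetic.read_study(config.study_dir)
    diags = validate_inputs(p1, p2, config.study_config.keywords_per_response)
    for d in diags:
        (log.error if d.level == "fatal" else log.warning)("validate: %s", d.message)
    if any(d.level == "fatal" for d in diags):
        raise ValueError("fatal input diagnostics; aborting run")

    # stage 3: embeddings
    p2_records, p2_kept = _records_from_table(p2, space, ["rater_id", "event_id"])
    p1_records, p1_kept = _records_from_table(p1, space, ["event_id"])

    # stage 4: cross-validated severity scale on P2
    plan = make_folds(p2_records, n_folds=config.n_folds, seed=config.seed)
    cv = cross_validated_fit(
        p2_records,
        plan,
        grid=config.grid,
        family=config.family,
        selection=config.selection,
        seed=config.seed,
    )
    log.info(
        "stage train: cross-validated r=%.3f (r^2=%.3f), mean k=%.1f (SD %.1f)",
        cv.pearson_r, cv.pearson_r**2, cv.mean_k, cv.sd_k,
    )
    pd.DataFrame(
        [
            {"record_id": p.record_id, "predicted": p.predicted, "fold": p.fold, "k_dims": p.k_dims}
            for p in cv.predictions
        ]
    ).to_csv(run_dir / "cv_predictions.tsv", sep="\t", index=False)

    # stage 5: full-data severity model, applied to P1 (MP1)
    k_full = select_dimensions(
        p2_records, grid=config.grid, family=config.family,
        selection=config.selection, seed=config.seed,
    )
    severity_model = train_scale(p2_records, k_full, family=config.family)
    save_model(severity_model, run_dir / "severity_model.json")
    from semscale.scale import _predict_batch  # batch scoring of P1/P2

    mp1_preds = _predict_batch(
        severity_model, np.array([r.embedding for r in p1_records])
    )
    mp1 = {r.group: float(v) for r, v in zip(p1_records, mp1_preds)}

    # stage 6: bias report (MP2 = out-of-fold CV predictions)
    cv_by_id = {p.record_id: p.predicted for p in cv.predictions}
    mp2 = {}
    for rec in p2_records:
        rater_id, event_id = rec.record_id.split("|")
        mp2[(rater_id, event_id)] = cv_by_id[rec.record_id]
    p2_used = p2.iloc[p2_kept]
    p1_used = p1.iloc[p1_kept]
    report = bias_mod.build_bias_report(
        p1_used,
        p2_used,
        mp1=mp1,
        mp2=mp2,
        calibration_mode_human=config.calibration_mode_human,
        calibration_mode_model=config.calibration_mode_model,
        fisher_z=config.fisher_z,
    )
    report.save(run_dir)

    # stage 7: word scores on three scales
    corpus_words: dict[str, int] = {}
    for kw in pd.concat([p1_used["keywords"], p2_used["keywords"]]):
        for w in str(kw).split():
            corpus_words[w] = corpus_words.get(w, 0) + 1

    cond_records = [
        dataclasses.replace(
            rec, outcome=1.0 if cond == synthetic.PHYSICAL else 0.0
        )
        for rec, cond in zip(p2_records, p2_used["condition"])
    ]
    condition_model = train_condition_scale(
        cond_records, grid=config.grid, selection=config.selection, seed=config.seed
    )
    p1_sev = p1_used.set_index("event_id")["severity"].to_dict()
    bias_model = train_bias_scale(
        make_bias_records(p2_records, p1_sev),
        grid=config.grid, selection=config.selection, seed=config.seed,
    )
    word_scores = {
        "severity": score_words(severity_model, space, corpus_words, "severity"),
        "condition": score_words(condition_model, space, corpus_words, "condition"),
        "calibration_bias": score_words(bias_model, space, corpus_words, "calibration_bias"),
    }
    for name, scores in word_scores.items():
        write_word_scores(scores, run_dir / f"word_scores_{name}.tsv")

    manifest["cv_pearson_r"] = cv.pearson_r
    manifest["cv_fold_dims"] = cv.fold_dims
    manifest["full_model_k"] = k_full
    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return RunResult(
        run_dir=run_dir,
        space=space,
        dataset_p1=p1_used,
        dataset_p2=p2_used,
        cv_result=cv,
        severity_model=severity_model,
        bias_report=report,
        word_scores=word_scores,
        manifest=manifest,
        truth=truth,
    )
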