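"""End-to-end study orchestration.

``run_study`` executes label → split → featurize → tune/train → test
report → baseline report → curate → predict → prospective report, writing
every artifact with the config and seeds that produced it. All outputs are
deterministic given the config, so reruns reproduce identical bytes
(timings go to a separate, unhashed log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from fibrilscreen import io as fsio
from fibrilscreen.baseline import BaselineConfig, baseline_evaluate
from fibrilscreen.chem import Featurizer, FingerprintConfig, canonicalize
from fibrilscreen.curation import (
    CurationConfig,
    ProspectiveSelection,
    ReferenceSet,
    profile_library,
    select_prospective,
    similarity_histogram,
)
from fibrilscreen.labeling import (
    BINDER,
    NON_BINDER,
    CompoundRecord,
    LabelingConfig,
    label_from_ki,
    stratified_split,
)
from fibrilscreen.models import (
    ClassReport,
    SelectionConfig,
    TrainedModel,
    classification_report,
    default_families,
    tune_and_train,
)
from fibrilscreen import simulate

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Everything needed to (re)execute one study run."""

    output_dir: str
    dataset_path: Optional[str] = None  # None -> synthetic study dataset
    library_path: Optional[str] = None  # None -> synthetic screening library
    reference_smiles: Optional[dict[str, str]] = None
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    fingerprint: FingerprintConfig = field(default_factory=FingerprintConfig)
    test_fraction: float = 44 / 315
    split_seed: int = 7
    families: Optional[Sequence[str]] = None  # None -> all three
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    k_folds: int = 5
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    curation: CurationConfig = field(default_factory=CurationConfig)
    synthetic: simulate.SyntheticConfig = field(
        default_factory=simulate.SyntheticConfig
    )
    library_size: int = 3000
    seed: int = 0
    run_curation: bool = True

    def validate(self) -> None:
        for p in (self.dataset_path, self.library_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def to_manifest(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    k: enc(v) for k, v in dataclasses.asdict(obj).items()
                    if k != "pharmacophore_fp"
                }
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, np.floating):
                return float(obj)
            return obj

        d = {k: enc(v) for k, v in dataclasses.asdict(self).items()}
        # the manifest sits inside the output directory; recording the
        # absolute path would break byte-identical reruns elsewhere
        d.pop("output_dir", None)
        d["schema_version"] = CONFIG_SCHEMA_VERSION
        return d


@dataclass
class StudyResult:
    model: TrainedModel
    test_report: ClassReport
    baseline_report: ClassReport
    cv_results: dict
    selection: Optional[ProspectiveSelection]
    prospective_report: Optional[ClassReport]
    prospective_hits: Optional[dict]
    output_dir: Path


def _records_by_id(records: Sequence[CompoundRecord]) -> dict[str, CompoundRecord]:
    return {r.id: r for r in records}


def evaluate_prospective(
    predictions: Sequence[tuple[str, str]],
    measured: Sequence[CompoundRecord],
    cfg: LabelingConfig = LabelingConfig(),
    sub_hit_nM: float = 10.0,
) -> tuple[ClassReport, dict]:
    """Score predicted labels against measured outcomes.

    Returns the classification report plus a hit breakdown: true/false
    positives (with Ki where fitted), false negatives, and the sub-10 nM
    subset of confirmed binders.
    """
    by_id = _records_by_id(measured)
    missing = [cid for cid, _ in predictions if cid not in by_id]
    if missing:
        raise ValueError(f"predictions reference unmeasured compounds: {missing[:10]}")
    y_true, y_pred = [], []
    tps, fps, fns, sub_hits = [], [], [], []
    for cid, pred in predictions:
        rec = by_id[cid]
        true = label_from_ki(rec.measurement, cfg)
        y_true.append(true)
        y_pred.append(pred)
        ki = rec.measurement.ki_nM
        if pred == BINDER and true == BINDER:
            tps.append({"id": cid, "ki_nM": ki})
            if ki is not None and ki < sub_hit_nM:
                sub_hits.append({"id": cid, "ki_nM": ki})
        elif pred == BINDER and true == NON_BINDER:
            fps.append({"id": cid, "ki_nM": ki})
        elif pred == NON_BINDER and true == BINDER:
            fns.append({"id": cid, "ki_nM": ki})
    report = classification_report(y_true, y_pred)
    hits = {
        "n_predicted_binders": sum(1 for p in y_pred if p == BINDER),
        "true_positives": tps,
        "false_positives": fps,
        "false_negatives": fns,
        "sub_threshold_hits": sub_hits,
        "sub_threshold_nM": sub_hit_nM,
    }
    return report, hits


def _write_report(report: ClassReport, path: Path, stem: str) -> None:
    (path / f"{stem}.txt").write_text(report.to_text() + "\n")
    with open(path / f"{stem}.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def run_study(cfg: RunConfig) -> StudyResult:
    """Execute the full pipeline; artifacts land in ``cfg.output_dir``."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage: %s", name)
        timings[name] = time.time()
        return name

    def done(name):
        timings[name] = time.time() - timings[name]

    # ---- dataset -----------------------------------------------------
    stage("dataset")
    shifts: dict[str, float] = {}
    if cfg.dataset_path:
        records, n_skipped = fsio.read_compound_table(cfg.dataset_path, cfg.labeling)
        if n_skipped:
            logger.warning("dataset: skipped %d unparsable records", n_skipped)
    else:
        records, shifts = simulate.make_study_dataset(
            cfg.synthetic, cfg.labeling, return_shifts=True
        )
    fsio.write_compound_table(records, out / "dataset.csv")
    done("dataset")

    # ---- split -------------------------------------------------------
    stage("split")
    split = stratified_split(records, cfg.test_fraction, cfg.split_seed)
    fsio.write_split_manifest(split, out / "split.json")
    by_id = _records_by_id(records)
    train = [by_id[i] for i in split.train_ids]
    test = [by_id[i] for i in split.test_ids]
    done("split")

    # ---- featurize ---------------------------------------------------
    stage("featurize")
    featurizer = Featurizer(cfg.fingerprint)
    featurizer.fit([r.molecule for r in train])
    train_matrix = featurizer.transform([r.molecule for r in train])
    test_matrix = featurizer.transform([r.molecule for r in test])
    fsio.write_feature_matrix(train_matrix, out / "train_features.csv")
    done("featurize")

    # ---- tune/train --------------------------------------------------
    stage("train")
    families = default_families()
    if cfg.families is not None:
        families = [f for f in families if f.name in set(cfg.families)]
    y_train = [r.binder_label for r in train]
    model, cv_results = tune_and_train(
        train_matrix,
        y_train,
        families=families,
        k_folds=cfg.k_folds,
        seed=cfg.seed,
        selection=cfg.selection,
    )
    model.save(str(out / "model"))
    with open(out / "cv_results.json", "w") as fh:
        json.dump({k: v.summary() for k, v in cv_results.items()}, fh, indent=2)
    done("train")

    # ---- test report -------------------------------------------------
    stage("evaluate")
    y_test = [r.binder_label for r in test]
    y_pred, scores = model.predict(test_matrix)
    test_report = classification_report(y_test, y_pred)
    _write_report(test_report, out, "test_report")
    with open(out / "test_predictions.csv", "w") as fh:
        fh.write("id,true,pred,score\n")
        for r, t, p, s in zip(test, y_test, y_pred, scores):
            fh.write(f"{r.id},{t},{p},{s:.6f}\n")
    done("evaluate")

    # ---- similarity baseline ----------------------------------------
    stage("baseline")
    baseline_report = baseline_evaluate(train, test, cfg.baseline)
    _write_report(baseline_report, out, "baseline_report")
    done("baseline")

    selection = None
    prospective_report = None
    hits = None
    if cfg.run_curation:
        # ---- curation ------------------------------------------------
        stage("curate")
        ref_smiles = cfg.reference_smiles or simulate.reference_smiles()
        refs = ReferenceSet.from_molecules(
            [(name, canonicalize(smi, id=name)) for name, smi in ref_smiles.items()],
            cfg.fingerprint,
        )
        if cfg.library_path:
            library_mols, _ = fsio.read_smiles_file(cfg.library_path)
            library = [(m, "?") for m in library_mols]
        else:
            lib_cfg = dataclasses.replace(
                cfg.synthetic,
                n_compounds=cfg.library_size,
                alt_fraction=0.3,
                seed=cfg.seed + 1,
            )
            library = simulate.generate_library(lib_cfg)
        profiles = list(
            profile_library(
                (m for m, _ in library), refs, cfg.fingerprint, cfg.curation.alt_cutoff
            )
        )
        hist = similarity_histogram(profiles, bin_width=0.05)
        # overlay ticks: study compounds (train/test) on the library's
        # reference axes, prospective picks added after selection below
        data_profiles = list(
            profile_library(
                (r.molecule for r in records),
                refs,
                cfg.fingerprint,
                cfg.curation.alt_cutoff,
            )
        )
        hist["overlays"]["train_test"] = {
            name: [p.scores[i] for p in data_profiles]
            for i, name in enumerate(refs.names)
        }
        selection = select_prospective(profiles, cfg.curation)
        hist["overlays"]["prospective"] = {
            name: [selection.profiles[cid].scores[i] for cid in selection.ids()]
            for i, name in enumerate(refs.names)
        }
        with open(out / "similarity_histogram.json", "w") as fh:
            json.dump(hist, fh, indent=2)
        _plot_histogram(hist, out / "similarity_histogram.png")
        lib_by_id = {m.id: (m, c) for m, c in library}
        with open(out / "prospective_selection.csv", "w") as fh:
            fh.write("id,smiles,tag,nearest_reference,nearest_score\n")
            for cid, tag in selection.selected:
                p = selection.profiles[cid]
                m = lib_by_id[cid][0]
                fh.write(
                    f"{cid},{m.smiles_canonical},{tag},"
                    f"{p.nearest_reference},{p.nearest_score:.4f}\n"
                )
        done("curate")

        # ---- predict prospective ------------------------------------
        stage("predict")
        sel_mols = [lib_by_id[cid][0] for cid in selection.ids()]
        sel_matrix = featurizer.transform(sel_mols)
        sel_pred, sel_scores = model.predict(sel_matrix)
        with open(out / "prospective_predictions.csv", "w") as fh:
            fh.write("id,pred,score\n")
            for m, p, s in zip(sel_mols, sel_pred, sel_scores):
                fh.write(f"{m.id},{p},{s:.6f}\n")
        done("predict")

        # ---- prospective evaluation (synthetic wet lab) --------------
        if not cfg.library_path:
            stage("prospective_eval")
            sel_with_type = [lib_by_id[cid] for cid in selection.ids()]
            measured = simulate.measure_library(
                sel_with_type, cfg.synthetic, shifts, seed=cfg.seed + 2
            )
            fsio.write_compound_table(measured, out / "prospective_measured.csv")
            predictions = list(zip(selection.ids(), sel_pred))
            prospective_report, hits = evaluate_prospective(
                predictions, measured, cfg.labeling
            )
            _write_report(prospective_report, out, "prospective_report")
            with open(out / "prospective_hits.json", "w") as fh:
                json.dump(hits, fh, indent=2)
            done("prospective_eval")

    # ---- manifest ----------------------------------------------------
    manifest = cfg.to_manifest()
    manifest["artifacts"] = sorted(
        p.name for p in out.iterdir() if p.name not in ("timings.json",)
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "timings.json", "w") as fh:
        json.dump(timings, fh, indent=2)

    return StudyResult(
        model=model,
        test_report=test_report,
        baseline_report=baseline_report,
        cv_results={k: v.summary() for k, v in cv_results.items()},
        selection=selection,
        prospective_report=prospective_report,
        prospective_hits=hits,
        output_dir=out,
    )


def _plot_histogram(hist: dict, path: Path) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort
        return
    refs = list(hist["counts"])
    if not refs:
        return
    fig, axes = plt.subplots(1, len(refs), figsize=(4 * len(refs), 3), squeeze=False)
    edges = hist["bin_edges"]
    for ax, ref in zip(axes[0], refs):
        counts = hist["counts"][ref]
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", color="grey")
        ax.set_title(ref)
        ax.set_xlabel("Tanimoto similarity")
    axes[0][0].set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
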