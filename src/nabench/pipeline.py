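"""Batch evaluation: manifest → per-cutoff dataset metrics.

Glues the modules together the way the command-line interface uses them:
parse each structure, annotate it over the cutoff ladder, align every
program's score file, then aggregate per-protein AUCs and pooled binary
metrics per (program, cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import metrics
from .binding_annotation import AnnotationConfig, BindingAnnotation, annotate
from .prediction_io import PredictionSet, align_to_structure, load_manifest, read_predictions
from .sasa import SasaParams
from .structure_io import ComplexStructure, parse_structure

__all__ = ["EvaluatedStructure", "load_and_annotate", "evaluate_dataset", "evaluate_manifest"]


@dataclass
class EvaluatedStructure:
    structure: ComplexStructure
    annotations: list[BindingAnnotation]
    predictions: dict[str, PredictionSet]  # program -> aligned scores


def load_and_annotate(
    entries: Sequence[Mapping],
    config: AnnotationConfig | None = None,
    sasa_params: SasaParams | None = None,
) -> list[EvaluatedStructure]:
    """Parse, annotate and align every manifest entry."""
    config = config or AnnotationConfig()
    out = []
    for entry in entries:
        st = parse_structure(entry["pdb"])
        ann = annotate(st, config, sasa_params)
        residues = st.protein_residues()
        preds = {}
        for program, path in entry.get("scores", {}).items():
            raw = read_predictions(path, program=program, protein_id=st.id)
            preds[program] = align_to_structure(raw, residues)
        out.append(EvaluatedStructure(st, ann, preds))
    return out


def _binarize(pred: PredictionSet, threshold: float) -> list[int]:
    if pred.kind == "binary-coerced":
        return [int(v) for v in pred.scores.values()]
    return [int(v > threshold) for v in pred.scores.values()]


def evaluate_dataset(
    evaluated: Sequence[EvaluatedStructure],
    cutoffs: Sequence[float],
    dataset: str = "dataset",
    binary_threshold: float = 0.5,
) -> pd.DataFrame:
    """Long-format metrics table: one row per (program, cutoff).

    Columns: program, dataset, cutoff, wauc, mauc, tauc, sauc, n_proteins,
    n_excluded, sen, spc, ppv, acc, f1, mcc.  Binary metrics pool the
    confusion counts over all residues of all proteins; continuous scores
    are binarized at ``binary_threshold``, binary-coerced ones used as-is.
    """
    programs = sorted({p for ev in evaluated for p in ev.predictions})
    rows = []
    for program in programs:
        for cutoff in cutoffs:
            evals = []
            pooled = []
            conf = metrics.ConfusionCounts(0, 0, 0, 0)
            for ev in evaluated:
                pred = ev.predictions[program]
                order = [a.residue_key for a in ev.annotations]
                scores = [pred.scores[k] for k in order]
                labels = [int(a.labels[cutoff]) for a in ev.annotations]
                evals.append(metrics.evaluate_protein(ev.structure.id, scores, labels))
                pooled.append((scores, labels))
                conf = conf + metrics.confusion_counts(_binarize(pred, binary_threshold), labels)
            agg = metrics.aggregate_auc(evals)
            b = metrics.binary_metrics(conf)
            rows.append({
                "program": program,
                "dataset": dataset,
                "cutoff": cutoff,
                "wauc": agg.wauc,
                "mauc": agg.mauc,
                "tauc": metrics.pooled_auc(pooled),
                "sauc": metrics.sauc(evals),
                "n_proteins": agg.n_proteins,
                "n_excluded": agg.n_excluded_undefined_auc,
                "sen": b.sen, "spc": b.spc, "ppv": b.ppv,
                "acc": b.acc, "f1": b.f1, "mcc": b.mcc,
            })
    return pd.DataFrame(rows)


def evaluate_manifest(
    manifest_path: str | Path,
    cutoffs: Sequence[float] | None = None,
    dataset: str | None = None,
    config: AnnotationConfig | None = None,
    sasa_params: SasaParams | None = None,
) -> pd.DataFrame:
    """End-to-end: manifest file → metrics table."""
    config = config or AnnotationConfig()
    if cutoffs is not None:
        config = AnnotationConfig(
            cutoffs=tuple(cutoffs),
            dasa_threshold=config.dasa_threshold,
            min_binding_residues=config.min_binding_residues,
            min_chain_length=config.min_chain_length,
            funnel_radius=config.funnel_radius,
        )
    entries = load_manifest(manifest_path)
    evaluated = load_and_annotate(entries, config, sasa_params)
    name = dataset or Path(manifest_path).parent.name
    return evaluate_dataset(evaluated, config.cutoffs, dataset=name)
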