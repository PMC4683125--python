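"""Read per-residue predictor scores and align them to structure residues.

The canonical score file is a four-column TSV with header
``chain  resnum  icode  score`` (icode may be empty), one row per residue,
keyed by author chain ID and author residue numbering — the same
coordinate system the structure model uses.

Two normalization rules from common assessment practice are encoded here:

* binary predictors (binding / non-binding calls) are represented as
  scores 1/0 and flagged ``binary-coerced`` — rank-based metrics then see
  a single operating point;
* residues the predictor did not cover (e.g. unpredicted N/C termini) are
  taken as non-binding and filled with score 0 during alignment.

Scores are never rescaled or clipped: the metrics are rank-based, so any
monotone predictor scale must be preserved verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

from .structure_io import Residue

__all__ = [
    "PredictionSet",
    "PredictionFormatError",
    "AlignmentError",
    "read_predictions",
    "write_predictions",
    "align_to_structure",
    "load_manifest",
]

ResidueKey = tuple[str, int, str]
HEADER = ("chain", "resnum", "icode", "score")


class PredictionFormatError(ValueError):
    """Malformed or inconsistent score file."""


class AlignmentError(ValueError):
    """Prediction keys do not match the target structure chain."""


@dataclass
class PredictionSet:
    program: str
    protein_id: str
    scores: dict[ResidueKey, float]
    kind: Literal["continuous", "binary-coerced"]
    coverage: float = 1.0
    filled: frozenset[ResidueKey] = field(default_factory=frozenset)
    dropped: int = 0  # prediction keys absent from the structure

    def values(self) -> list[float]:
        return list(self.scores.values())


def _infer_kind(values) -> Literal["continuous", "binary-coerced"]:
    return "binary-coerced" if all(v in (0.0, 1.0) for v in values) else "continuous"


def read_predictions(
    path: str | Path,
    program: str = "",
    protein_id: str = "",
    dialect: Literal["tsv"] = "tsv",
) -> PredictionSet:
    """Parse a canonical score TSV into a :class:`PredictionSet`."""
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    scores: dict[ResidueKey, float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(h.strip() for h in header) != HEADER:
            raise PredictionFormatError(
                f"{path}:1: expected header {'	'.join(HEADER)!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise PredictionFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            chain, resnum_s, icode, score_s = parts
            try:
                resnum = int(resnum_s)
                score = float(score_s)
            except ValueError as exc:
                raise PredictionFormatError(f"{path}:{lineno}: {exc}") from exc
            key = (chain, resnum, icode.strip())
            if key in scores:
                raise PredictionFormatError(f"{path}:{lineno}: duplicate residue {key}")
            scores[key] = score
    return PredictionSet(
        program=program or path.stem,
        protein_id=protein_id,
        scores=scores,
        kind=_infer_kind(scores.values()),
    )


def write_predictions(scores: dict[ResidueKey, float], path: str | Path) -> None:
    """Write scores in the canonical TSV dialect (float repr, no rounding)."""
    lines = ["\t".join(HEADER)]
    for (chain, resnum, icode), s in scores.items():
        lines.append(f"{chain}\t{resnum}\t{icode}\t{s!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def align_to_structure(
    pred: PredictionSet,
    residues: Sequence[Residue],
    fill_policy: Literal["zero", "error"] = "zero",
    min_overlap: float = 0.5,
) -> PredictionSet:
    """Align a prediction set to the residues of a structure.

    After alignment every structure residue has a score; residues the
    predictor skipped get 0 (non-binding) under the ``zero`` policy and
    are flagged as filled.  Prediction keys absent from the structure are
    dropped (counted in ``dropped``).  If fewer than ``min_overlap`` of
    the prediction keys match the structure, the file most likely refers
    to a different chain and an :class:`AlignmentError` is raised.
    """
    if not residues:
        raise ValueError("structure residue list is empty")
    struct_keys = [r.key for r in residues]
    struct_set = set(struct_keys)
    matched = [k for k in pred.scores if k in struct_set]
    if pred.scores and len(matched) / len(pred.scores) < min_overlap:
        pk = sorted(pred.scores)
        raise AlignmentError(
            f"{pred.program}/{pred.protein_id}: only {len(matched)}/{len(pred.scores)} "
            f"prediction keys match the structure (prediction range "
            f"{pk[0]}..{pk[-1]}, structure range {struct_keys[0]}..{struct_keys[-1]})"
        )
    # keys filled on a previous alignment stay "missing" so coverage is
    # stable and alignment idempotent
    missing = [k for k in struct_keys if k not in pred.scores or k in pred.filled]
    if missing and fill_policy == "error":
        raise AlignmentError(
            f"{pred.program}/{pred.protein_id}: {len(missing)} structure residues "
            f"lack scores (first: {missing[0]})"
        )
    aligned = {k: (pred.scores[k] if k in pred.scores else 0.0) for k in struct_keys}
    coverage = (len(struct_keys) - len(missing)) / len(struct_keys)
    return replace(
        pred,
        scores=aligned,
        kind=_infer_kind(aligned.values()),
        coverage=coverage,
        filled=pred.filled | frozenset(missing),
        dropped=pred.dropped + (len(pred.scores) - len(matched)),
    )


def load_manifest(path: str | Path) -> list[dict]:
    """Load a batch-evaluation manifest (JSON).

    The manifest lists one entry per structure::

        {"structures": [
            {"id": ..., "pdb": ..., "truth": ...,
             "scores": {"<program>": "<score tsv path>", ...}},
        ]}

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    data = json.loads(path.read_text())
    base = path.parent
    entries = []
    for entry in data["structures"]:
        e = dict(entry)
        e["pdb"] = str((base / entry["pdb"]).resolve())
        if "truth" in entry:
            e["truth"] = str((base / entry["truth"]).resolve())
        e["scores"] = {
            prog: str((base / p).resolve()) for prog, p in entry.get("scores", {}).items()
        }
        entries.append(e)
    return entries
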