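"""Hierarchical binding-site labels and dataset-curation filters.

A protein residue is a nucleic-acid binding site at cutoff *c* when its
minimum any-atom distance to any nucleic-acid atom is ≤ *c* **and** its
accessible surface area decreases upon complex formation (ΔASA > 0 Ų by
default).  Labels are computed over a ladder of cutoffs (3.5–6.0 Å, 0.5 Å
step by default); by construction they are nested: binding at a smaller
cutoff implies binding at every larger one.

Curation rejects chains that cannot be meaningfully assessed: short
peptides, chains with too few binding residues, Cα-only traces, and
proteins made of two separate short peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .sasa import SasaParams, residue_delta_asa
from .structure_io import Atom, ComplexStructure, Residue, detect_ca_only

__all__ = [
    "AnnotationConfig",
    "BindingAnnotation",
    "Rejection",
    "min_distance",
    "annotate",
    "count_binding_sites",
    "curate",
    "annotation_table",
    "binding_intervals",
]

DEFAULT_CUTOFFS = (3.5, 4.0, 4.5, 5.0, 5.5, 6.0)


@dataclass
class AnnotationConfig:
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    dasa_threshold: float = 0.0  # strict inequality: ΔASA > threshold
    min_binding_residues: int = 3
    min_chain_length: int = 20
    funnel_radius: float = 12.0
    ca_only_tolerance: float = 0.95

    def __post_init__(self) -> None:
        cutoffs = tuple(float(c) for c in self.cutoffs)
        if any(c <= 0 for c in cutoffs):
            raise ValueError("cutoffs must be positive")
        if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
            raise ValueError("cutoffs must be strictly increasing")
        self.cutoffs = cutoffs
        if self.min_binding_residues < 1 or self.min_chain_length < 1:
            raise ValueError("min_binding_residues and min_chain_length must be >= 1")


@dataclass
class BindingAnnotation:
    """Per-residue minimum distance, ΔASA and label per cutoff."""

    residue_key: tuple[str, int, str]
    min_dist: float
    delta_asa: float
    labels: dict[float, bool]

    def label(self, cutoff: float) -> bool:
        return self.labels[cutoff]


@dataclass(frozen=True)
class Rejection:
    structure_id: str
    chain_id: str
    reason: str  # short_peptide | weak_binder | ca_only | split_peptides


def min_distance(residue: Residue, nucleic_atoms: Sequence[Atom] | np.ndarray) -> float:
    """Minimum Euclidean distance from any residue atom to any nucleic atom.

    Exact over all atom pairs (equals the brute-force double loop).
    """
    if isinstance(nucleic_atoms, np.ndarray):
        nuc = nucleic_atoms
    else:
        if not nucleic_atoms:
            raise ValueError("nucleic atom set is empty")
        nuc = np.array([a.coord for a in nucleic_atoms], dtype=float)
    if nuc.size == 0:
        raise ValueError("nucleic atom set is empty")
    res = residue.coords()
    return float(cdist(res, nuc).min())


def annotate(
    structure: ComplexStructure,
    config: AnnotationConfig | None = None,
    sasa_params: SasaParams | None = None,
) -> list[BindingAnnotation]:
    """One :class:`BindingAnnotation` per protein residue of the structure.

    Distances run against the union of all RNA and DNA chain atoms; the
    ΔASA gate is applied identically at every cutoff.
    """
    config = config or AnnotationConfig()
    if not structure.protein_chains or not structure.nucleic_chains:
        raise ValueError(
            f"{structure.id}: annotation needs at least one protein chain "
            "and one RNA/DNA chain"
        )
    nuc = np.array([a.coord for a in structure.nucleic_atoms()], dtype=float)
    asa = {r.residue_key: r.delta_asa for r in residue_delta_asa(structure, sasa_params)}

    out: list[BindingAnnotation] = []
    for res in structure.protein_residues():
        d = min_distance(res, nuc)
        dasa = asa[res.key]
        labels = {
            c: (d <= c and dasa > config.dasa_threshold) for c in config.cutoffs
        }
        out.append(BindingAnnotation(res.key, d, dasa, labels))
    return out


def count_binding_sites(annotations: Sequence[BindingAnnotation]) -> dict[float, int]:
    """Number of binding residues at each cutoff of the ladder."""
    if not annotations:
        return {}
    cutoffs = annotations[0].labels.keys()
    return {c: sum(a.labels[c] for a in annotations) for c in cutoffs}


def curate(
    structures: Sequence[ComplexStructure],
    annotations: Mapping[str, Sequence[BindingAnnotation]],
    config: AnnotationConfig | None = None,
) -> tuple[list[tuple[str, str]], list[Rejection]]:
    """Apply structure-intrinsic exclusion rules to protein chains.

    Returns ``(accepted, rejections)`` where accepted entries are
    ``(structure_id, chain_id)`` pairs and each rejection carries a
    machine-readable reason code:

    * ``short_peptide`` — chain shorter than ``min_chain_length`` residues;
    * ``split_peptides`` — a protein made of two separate short peptides
      (exactly two protein chains, both short);
    * ``ca_only`` — Cα-only trace;
    * ``weak_binder`` — fewer than ``min_binding_residues`` binding
      residues at the largest cutoff.

    ``annotations`` maps structure id to per-residue annotations computed
    at (at least) the largest cutoff in ``config``.
    """
    config = config or AnnotationConfig()
    top = max(config.cutoffs)
    accepted: list[tuple[str, str]] = []
    rejected: list[Rejection] = []
    for st in structures:
        ann = annotations.get(st.id, ())
        bound_by_chain: dict[str, int] = {}
        for a in ann:
            if a.labels.get(top, False):
                cid = a.residue_key[0]
                bound_by_chain[cid] = bound_by_chain.get(cid, 0) + 1
        prot = st.protein_chains
        short = [c for c in prot if len(c.residues) < config.min_chain_length]
        all_split = len(prot) == 2 and len(short) == 2
        for chain in prot:
            if len(chain.residues) < config.min_chain_length:
                reason = "split_peptides" if all_split else "short_peptide"
                rejected.append(Rejection(st.id, chain.chain_id, reason))
            elif detect_ca_only(chain.residues, config.ca_only_tolerance):
                rejected.append(Rejection(st.id, chain.chain_id, "ca_only"))
            elif bound_by_chain.get(chain.chain_id, 0) < config.min_binding_residues:
                rejected.append(Rejection(st.id, chain.chain_id, "weak_binder"))
            else:
                accepted.append((st.id, chain.chain_id))
    return accepted, rejected


def annotation_table(
    structure: ComplexStructure,
    annotations: Sequence[BindingAnnotation],
) -> pd.DataFrame:
    """Per-residue annotation table (one row per protein residue).

    Columns: chain, resnum, icode, aa, min_dist, delta_asa and one
    ``label_<cutoff>`` column per cutoff.
    """
    names = {r.key: r.name for r in structure.protein_residues()}
    rows = []
    for a in annotations:
        row = {
            "chain": a.residue_key[0],
            "resnum": a.residue_key[1],
            "icode": a.residue_key[2],
            "aa": names.get(a.residue_key, ""),
            "min_dist": a.min_dist,
            "delta_asa": a.delta_asa,
        }
        for c, lab in a.labels.items():
            row[f"label_{c:g}"] = int(lab)
        rows.append(row)
    return pd.DataFrame(rows)


def binding_intervals(
    annotations: Sequence[BindingAnnotation],
    cutoff: float,
) -> list[tuple[str, int, int]]:
    """Binding stretches per chain as BED-like intervals.

    Intervals are 0-based half-open over the *sequential residue index*
    within each chain (file order), not author numbering: ``(chain,
    start, end)`` covers residues ``start..end-1`` of that chain's
    annotated residue list.
    """
    by_chain: dict[str, list[BindingAnnotation]] = {}
    for a in annotations:
        by_chain.setdefault(a.residue_key[0], []).append(a)
    intervals: list[tuple[str, int, int]] = []
    for chain, anns in by_chain.items():
        start = None
        for i, a in enumerate(anns):
            if a.labels[cutoff] and start is None:
                start = i
            elif not a.labels[cutoff] and start is not None:
                intervals.append((chain, start, i))
                start = None
        if start is not None:
            intervals.append((chain, start, len(anns)))
    return intervals
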