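"""Seeded synthetic complexes and predictor scores with known ground truth.

The generator builds "ladder" complexes: a straight nucleic-acid axis
(pseudo-nucleotide atoms every 1 Å along z) and multi-atom protein
pseudo-residues whose anchor atoms sit at scripted distances from the
axis.  Because every anchor shares a z coordinate with a nucleic atom,
the true minimum residue–nucleic distance equals the scripted distance
exactly and is emitted as a truth table for oracle comparisons.

Residues within occlusion range of the axis lose accessible surface area
when the nucleic atoms are added, so binding residues (distance ≤ 6 Å)
have ΔASA > 0 by construction and every default complex passes curation
(length ≥ 20, ≥ 3 binding residues at 6 Å).

Score models emulate the statistical structure the assessment assumes —
scores correlated with distance to the interface:

* ``ideal``  — score = −min_dist (perfect ranking, AUC 1 at every cutoff);
* ``random`` — i.i.d. U(0,1) (no signal, AUC ≈ 0.5);
* ``funnel`` — amplitude·exp(−min_dist/λ) + N(0, σ), a smooth binding
  funnel (defaults λ = 4 Å, σ = 0.05);
* ``binary`` — the funnel score thresholded at its median, emitted as 0/1.

Identical (seed, spec) pairs produce byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .prediction_io import PredictionSet, write_predictions
from .structure_io import Atom, Chain, ComplexStructure, Residue, write_pdb

__all__ = [
    "SyntheticSpec",
    "generate_complex",
    "generate_scores",
    "generate_corpus",
    "SCORE_VARIANTS",
]

SCORE_VARIANTS = ("ideal", "random", "funnel", "binary")

_RNA_NAMES = ("A", "C", "G", "U")
_DNA_NAMES = ("DA", "DC", "DG", "DT")
# atom labels for the 5-atom pseudo-nucleotide (one atom per Å along z)
_NT_ATOMS = ("P", "O5'", "C5'", "C4'", "C3'")


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic corpus.

    ``chain_length`` protein pseudo-residues per complex; distances are
    drawn from ``distance_profile`` between ``d_min`` and ``d_max`` (Å)
    and permuted along the chain.  ``jitter`` adds a small per-protein
    uniform perturbation so proteins differ while the profile holds.
    """

    seed: int = 0
    n_proteins: int = 10
    chain_length: int = 200
    nucleic_type: Literal["RNA", "DNA"] = "RNA"
    geometry: Literal["ladder"] = "ladder"
    distance_profile: Literal["step", "linear", "funnel"] = "linear"
    d_min: float = 2.5
    d_max: float = 20.0
    step_near: float = 3.0
    step_far: float = 13.0
    step_frac_near: float = 0.3
    jitter: float = 0.2
    predictor_model: Literal["funnel"] = "funnel"
    amplitude: float = 1.0
    decay_length: float = 4.0  # λ of the exponential funnel, Å
    noise_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.d_min <= 1.5:
            raise ValueError("d_min must exceed 1.5 Å (steric overlap with the axis)")
        if self.d_max <= self.d_min:
            raise ValueError("d_max must exceed d_min")
        if self.chain_length < 2:
            raise ValueError("chain_length must be >= 2")


def _profile_distances(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.chain_length
    if spec.distance_profile == "step":
        n_near = max(1, round(spec.step_frac_near * n))
        d = np.concatenate([
            np.full(n_near, spec.step_near),
            np.full(n - n_near, spec.step_far),
        ])
    elif spec.distance_profile == "linear":
        d = np.linspace(spec.d_min, spec.d_max, n)
    elif spec.distance_profile == "funnel":
        t = np.linspace(0.0, 1.0, n)
        d = spec.d_min + (spec.d_max - spec.d_min) * t**2
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown profile {spec.distance_profile!r}")
    if spec.jitter > 0:
        lo = spec.d_min if spec.distance_profile != "step" else 1.6
        d = np.clip(d + rng.uniform(-spec.jitter, spec.jitter, size=n), lo, None)
    return rng.permutation(d)


def _protein_residue(index: int, dist: float) -> Residue:
    """5-atom alanine-like pseudo-residue; the CA anchor realizes ``dist``.

    The anchor sits at (dist, 0, 2·index); every nucleic atom lies on the
    z axis at integer z, so the nearest one is (0, 0, 2·index) at exactly
    ``dist``.  All other atoms sit at strictly larger axial distance.
    """
    z = 2.0 * index
    x = dist
    coords = {
        "CA": (x, 0.0, z),
        "N": (x + 1.5, 1.2, z),
        "C": (x + 1.5, -1.2, z),
        "O": (x + 2.8, -1.2, z),
        "CB": (x + 2.8, 1.2, z),
    }
    atoms = [Atom(name=n, element=n[0], coord=c) for n, c in coords.items()]
    return Residue(
        chain_id="A", seq_id=index + 1, insertion_code="", name="ALA",
        atoms=atoms, is_standard=True,
    )


def _nucleic_chain(spec: SyntheticSpec, z_max: float) -> Chain:
    names = _RNA_NAMES if spec.nucleic_type == "RNA" else _DNA_NAMES
    n_nt = int(z_max // len(_NT_ATOMS)) + 1
    residues = []
    for j in range(n_nt):
        atoms = [
            Atom(name=a, element=a[0], coord=(0.0, 0.0, float(len(_NT_ATOMS) * j + k)))
            for k, a in enumerate(_NT_ATOMS)
        ]
        residues.append(
            Residue(
                chain_id="B", seq_id=j + 1, insertion_code="",
                name=names[j % len(names)], atoms=atoms, is_standard=True,
            )
        )
    moltype: Literal["RNA", "DNA"] = spec.nucleic_type
    return Chain(chain_id="B", moltype=moltype, residues=residues)


def generate_complex(
    spec: SyntheticSpec, index: int = 0
) -> tuple[ComplexStructure, dict[tuple[str, int, str], float]]:
    """Build one ladder complex and its per-residue min-distance truth table.

    ``index`` selects the protein within the corpus; the RNG stream is
    derived from (seed, index) so each structure is independently seeded
    yet fully reproducible.
    """
    rng = np.random.default_rng([spec.seed, index])
    distances = _profile_distances(spec, rng)
    prot_residues = [_protein_residue(i, float(d)) for i, d in enumerate(distances)]
    z_max = 2.0 * (spec.chain_length - 1)
    chains = [
        Chain(chain_id="A", moltype="protein", residues=prot_residues),
        _nucleic_chain(spec, z_max),
    ]
    structure = ComplexStructure(id=f"synth{index:03d}", chains=chains)
    truth = {r.key: float(d) for r, d in zip(prot_residues, distances)}
    return structure, truth


def generate_scores(
    spec: SyntheticSpec,
    truth: dict[tuple[str, int, str], float],
    variant: str,
    index: int = 0,
) -> PredictionSet:
    """Per-residue scores for one complex under one score model."""
    if variant not in SCORE_VARIANTS:
        raise ValueError(f"unknown score variant {variant!r}")
    # distinct stream per (seed, structure, variant); offset keeps it
    # independent of the geometry stream
    rng = np.random.default_rng([spec.seed, index, 1 + SCORE_VARIANTS.index(variant)])
    keys = list(truth)
    d = np.array([truth[k] for k in keys])
    if variant == "ideal":
        s = -d
    elif variant == "random":
        s = rng.uniform(0.0, 1.0, size=len(d))
    else:  # funnel and binary share the funnel model
        s = spec.amplitude * np.exp(-d / spec.decay_length)
        s = s + rng.normal(0.0, spec.noise_sigma, size=len(d))
        if variant == "binary":
            s = (s > np.median(s)).astype(float)
    scores = {k: float(v) for k, v in zip(keys, s)}
    kind = "binary-coerced" if variant == "binary" else "continuous"
    return PredictionSet(
        program=variant, protein_id=f"synth{index:03d}", scores=scores, kind=kind
    )


def generate_corpus(
    spec: SyntheticSpec,
    outdir: str | Path,
    variants: Sequence[str] = SCORE_VARIANTS,
) -> Path:
    """Write a full corpus: PDBs, truth TSVs, score TSVs, and a manifest.

    Returns the manifest path; the manifest is consumable by the batch
    evaluator (`nabench evaluate`).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(spec.n_proteins):
        structure, truth = generate_complex(spec, i)
        pdb = outdir / f"{structure.id}.pdb"
        write_pdb(structure, pdb)
        truth_path = outdir / f"{structure.id}.truth.tsv"
        lines = ["chain\tresnum\ticode\tmin_dist"]
        for (chain, resnum, icode), dist in truth.items():
            lines.append(f"{chain}\t{resnum}\t{icode}\t{dist!r}")
        truth_path.write_text("\n".join(lines) + "\n")
        score_paths = {}
        for variant in variants:
            pred = generate_scores(spec, truth, variant, i)
            p = outdir / f"{structure.id}.{variant}.tsv"
            write_predictions(pred.scores, p)
            score_paths[variant] = p.name
        entries.append({
            "id": structure.id,
            "pdb": pdb.name,
            "truth": truth_path.name,
            "scores": score_paths,
        })
    manifest = {"spec": asdict(spec), "structures": entries}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest_path
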