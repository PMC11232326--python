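"""Synthetic knowledgebases and expression datasets (null and planted-signal).

Counts follow a negative-binomial model with a fixed dispersion so the
permutation machinery is exercised against overdispersed data.  Null datasets
draw every gene i.i.d. across ALL cells, making cell-type labels exchangeable
by construction; planted datasets then elevate the producer, transporter and
receptor genes of one chosen interaction in the sender/receiver cells and
suppress its consumers in the sender.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from .errors import DataError
from .ingest import CellMetadata, ExpressionMatrix
from .kb import (
    METABOLITE_CLASSES,
    EnzymeAnnotation,
    Interaction,
    KnowledgeBase,
    MetaboliteRecord,
    ReceptorComplex,
    TransporterAnnotation,
)

_CLASS_CYCLE = sorted(METABOLITE_CLASSES)

#: negative-binomial size parameter (smaller = more overdispersed)
DEFAULT_DISPERSION = 2.0


@dataclass
class PlantedTruth:
    """Ground truth of the single elevated (sender, receiver, interaction)."""

    sender: str
    receiver: str
    metabolite_id: str
    receptor: str  # canonical ";"-joined subunit string
    effect_size: float

    def __post_init__(self) -> None:
        if self.effect_size <= 1.0:
            raise DataError("effect_size must be > 1")


def make_toy_kb(
    n_metabolites: int,
    complex_fraction: float = 0.5,
    seed: int = 0,
    species: str = "human",
) -> KnowledgeBase:
    """Generate a small valid knowledgebase.

    Each metabolite receives 1–3 producer enzymes, 1–3 consumers, 0–2 dual
    ("both") enzymes, 0–2 transporters and exactly one receptor, which is a
    2-subunit complex with probability ``complex_fraction``.  Gene symbols
    are synthetic and disjoint across roles.  Deterministic per seed.
    """
    if n_metabolites < 1:
        raise DataError("n_metabolites must be >= 1")
    rng = np.random.default_rng(seed)
    metabolites: dict[str, MetaboliteRecord] = {}
    interactions: list[Interaction] = []
    enzymes: list[EnzymeAnnotation] = []
    transporters: list[TransporterAnnotation] = []
    for i in range(n_metabolites):
        mid = f"MET{i + 1:04d}"
        metabolites[mid] = MetaboliteRecord(
            metabolite_id=mid,
            name=f"metabolite-{i + 1}",
            hmdb_id=f"HMDB{7000000 + i:07d}",
            pubchem_cid=str(100000 + i),
            class_label=_CLASS_CYCLE[i % len(_CLASS_CYCLE)],
        )
        for j in range(int(rng.integers(1, 4))):
            enzymes.append(EnzymeAnnotation(mid, f"{mid}PRD{j + 1}", "producer"))
        for j in range(int(rng.integers(1, 4))):
            enzymes.append(EnzymeAnnotation(mid, f"{mid}CNS{j + 1}", "consumer"))
        for j in range(int(rng.integers(0, 3))):
            enzymes.append(EnzymeAnnotation(mid, f"{mid}DUO{j + 1}", "both"))
        for j in range(int(rng.integers(0, 3))):
            transporters.append(TransporterAnnotation(mid, f"{mid}TRP{j + 1}"))
        q = 2 if rng.random() < complex_fraction else 1
        subunits = tuple(f"{mid}RSU{h + 1}" for h in range(q))
        interactions.append(
            Interaction(
                metabolite_id=mid,
                receptor=ReceptorComplex(subunits),
                species=species,
                source="synthetic",
            )
        )
    return KnowledgeBase(
        species=species,
        metabolites=metabolites,
        interactions=interactions,
        enzymes=enzymes,
        transporters=transporters,
    )


def _nb_counts(
    rng: np.random.Generator, shape: tuple[int, int], mean: float, dispersion: float
) -> np.ndarray:
    if mean <= 0:
        return np.zeros(shape, dtype=np.float64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=shape).astype(np.float64)


def generate_null_dataset(
    kb: KnowledgeBase,
    n_types: int = 3,
    cells_per_type: int = 50,
    base_rate: float = 5.0,
    seed: int = 0,
    dispersion: float = DEFAULT_DISPERSION,
) -> tuple[ExpressionMatrix, CellMetadata]:
    """Label-exchangeable dataset: one count distribution for every gene and cell.

    Labels are assigned in fixed contiguous blocks of ``cells_per_type``.
    """
    if n_types < 2:
        raise DataError("n_types must be >= 2")
    rng = np.random.default_rng(seed)
    genes = sorted(kb.all_genes())
    n_cells = n_types * cells_per_type
    values = _nb_counts(rng, (len(genes), n_cells), base_rate, dispersion)
    cells = [f"cell{i + 1:05d}" for i in range(n_cells)]
    labels = {
        cells[i]: f"type{i // cells_per_type + 1}" for i in range(n_cells)
    }
    return ExpressionMatrix(genes, cells, values), CellMetadata(labels)


def generate_planted_dataset(
    kb: KnowledgeBase,
    truth: PlantedTruth,
    n_types: int = 3,
    cells_per_type: int = 50,
    base_rate: float = 5.0,
    seed: int = 0,
    dispersion: float = DEFAULT_DISPERSION,
) -> tuple[ExpressionMatrix, CellMetadata, PlantedTruth]:
    """Null backbone plus one elevated interaction.

    In the sender's cells, the planted metabolite's strict producer genes and
    transporter genes are multiplied by ``effect_size`` and its strict
    consumer genes divided by it (keeping net enzyme expression positive);
    in the receiver's cells, the receptor subunits are multiplied by
    ``effect_size``.  Dual-role ("both") enzymes are left untouched.
    """
    expr, meta = generate_null_dataset(
        kb, n_types=n_types, cells_per_type=cells_per_type,
        base_rate=base_rate, seed=seed, dispersion=dispersion,
    )
    if truth.metabolite_id not in kb.metabolites:
        raise DataError(f"planted metabolite {truth.metabolite_id!r} absent from the KB")
    rec = ReceptorComplex.parse(truth.receptor)
    matching = [
        it
        for it in kb.interactions
        if it.metabolite_id == truth.metabolite_id and it.receptor == rec
    ]
    if not matching:
        raise DataError(
            f"planted receptor {truth.receptor!r} is not an interaction of "
            f"{truth.metabolite_id!r}"
        )
    labels = [meta.types[c] for c in expr.cells]
    if truth.sender not in labels or truth.receiver not in labels:
        raise DataError("planted sender/receiver cell type absent from the dataset")

    gidx = {g: i for i, g in enumerate(expr.genes)}
    sender_cols = np.array([l == truth.sender for l in labels])
    receiver_cols = np.array([l == truth.receiver for l in labels])
    mid = truth.metabolite_id
    strict_prod = [
        e.gene for e in kb.enzymes if e.metabolite_id == mid and e.role == "producer"
    ]
    strict_cons = [
        e.gene for e in kb.enzymes if e.metabolite_id == mid and e.role == "consumer"
    ]
    eff = truth.effect_size
    values = expr.values.copy()
    for g in strict_prod + kb.transporter_genes(mid):
        values[np.ix_([gidx[g]], np.flatnonzero(sender_cols))] *= eff
    for g in strict_cons:
        values[np.ix_([gidx[g]], np.flatnonzero(sender_cols))] /= eff
    for g in matching[0].receptor.subunits:
        values[np.ix_([gidx[g]], np.flatnonzero(receiver_cols))] *= eff
    return ExpressionMatrix(list(expr.genes), list(expr.cells), values), meta, truth


def write_dataset(
    out_dir: str | Path,
    expr: ExpressionMatrix,
    meta: CellMetadata,
    format: str = "dense",
) -> None:
    """Write an expression matrix + META table in the dialects ingest reads.

    ``dense``: ``expression.tsv`` (gene rows, cell columns).  ``mtx``: an
    ``expression/`` directory with ``matrix.mtx``, ``genes.tsv``,
    ``barcodes.tsv``.  Always writes ``meta.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if format == "dense":
        with (out / "expression.tsv").open("w", encoding="utf-8", newline="") as fh:
            fh.write("gene\t" + "\t".join(expr.cells) + "\n")
            for i, g in enumerate(expr.genes):
                fh.write(g + "\t" + "\t".join(f"{v:g}" for v in expr.values[i]) + "\n")
    elif format == "mtx":
        mdir = out / "expression"
        mdir.mkdir(exist_ok=True)
        sparse = scipy.sparse.coo_matrix(expr.values)
        scipy.io.mmwrite(mdir / "matrix.mtx", sparse)
        (mdir / "genes.tsv").write_text("".join(f"{g}\n" for g in expr.genes))
        (mdir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in expr.cells))
    else:
        raise DataError(f"unknown dataset format {format!r}")
    with (out / "meta.tsv").open("w", encoding="utf-8", newline="") as fh:
        fh.write("cell\tcell_type\n")
        for c in expr.cells:
            fh.write(f"{c}\t{meta.types[c]}\n")
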