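"""Knowledgebase data model, TSV I/O, validation, summarization, orthology mapping.

The knowledgebase links metabolites to the receptor complexes they bind and
annotates, per metabolite, the enzymes that produce and/or consume it and the
transporters that move it across the membrane.  It is stored as four
tab-delimited UTF-8 tables:

* ``interactions.tsv``  — metabolite_id, receptor, species, source
* ``enzymes.tsv``       — metabolite_id, gene, role
* ``transporters.tsv``  — metabolite_id, gene
* ``metabolites.tsv``   — metabolite_id, name, hmdb_id, pubchem_cid, class_label

Receptor complexes are encoded as subunit gene symbols joined with ``";"``;
complex identity is order-insensitive (canonical form = sorted subunits).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import DataError, FormatError, ReferentialIntegrityError

logger = logging.getLogger(__name__)

ROLES = frozenset({"producer", "consumer", "both"})

#: Controlled vocabulary for metabolite class labels.
METABOLITE_CLASSES = frozenset(
    {
        "Lipids",
        "Organic acids and derivatives",
        "Organoheterocyclic compounds",
        "Organic oxygen compounds",
        "Benzenoids",
        "Nucleosides, nucleotides, and analogues",
        "Organic nitrogen compounds",
        "Phenylpropanoids and polyketides",
        "Inorganic compounds",
        "Other",
    }
)

SPECIES = frozenset({"human", "mouse"})


@dataclass(frozen=True)
class ReceptorComplex:
    """A receptor made of one or more subunit proteins (all required)."""

    subunits: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.subunits) < 1:
            raise DataError("a receptor complex needs at least one subunit")
        if any(not s for s in self.subunits):
            raise DataError("empty receptor subunit symbol")
        if len(set(self.subunits)) != len(self.subunits):
            raise DataError(f"duplicate subunits in complex {self.subunits}")

    @property
    def q(self) -> int:
        return len(self.subunits)

    @property
    def canonical(self) -> tuple[str, ...]:
        """Order-insensitive identity."""
        return tuple(sorted(self.subunits))

    @property
    def label(self) -> str:
        return ";".join(self.subunits)

    @property
    def canonical_label(self) -> str:
        return ";".join(self.canonical)

    @classmethod
    def parse(cls, text: str) -> "ReceptorComplex":
        return cls(tuple(s.strip() for s in text.split(";") if s.strip()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReceptorComplex):
            return NotImplemented
        return self.canonical == other.canonical

    def __hash__(self) -> int:
        return hash(self.canonical)


@dataclass
class MetaboliteRecord:
    metabolite_id: str
    name: str = ""
    hmdb_id: str | None = None
    pubchem_cid: str | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        if not self.metabolite_id:
            raise DataError("metabolite_id must be non-empty")


@dataclass(frozen=True)
class Interaction:
    """One metabolite ↔ receptor-complex pair for one species."""

    metabolite_id: str
    receptor: ReceptorComplex
    species: str = "human"
    source: str = ""

    def key(self) -> tuple[str, tuple[str, ...], str]:
        return (self.metabolite_id, self.receptor.canonical, self.species)


@dataclass(frozen=True)
class EnzymeAnnotation:
    metabolite_id: str
    gene: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DataError(
                f"unknown enzyme role {self.role!r} for gene {self.gene!r}; "
                f"expected one of {sorted(ROLES)}"
            )


@dataclass(frozen=True)
class TransporterAnnotation:
    metabolite_id: str
    gene: str


@dataclass
class KnowledgeBase:
    species: str
    metabolites: dict[str, MetaboliteRecord] = field(default_factory=dict)
    interactions: list[Interaction] = field(default_factory=list)
    enzymes: list[EnzymeAnnotation] = field(default_factory=list)
    transporters: list[TransporterAnnotation] = field(default_factory=list)

    def producer_genes(self, metabolite_id: str) -> list[str]:
        """Genes producing the metabolite ('both' entries included)."""
        return [
            e.gene
            for e in self.enzymes
            if e.metabolite_id == metabolite_id and e.role in ("producer", "both")
        ]

    def consumer_genes(self, metabolite_id: str) -> list[str]:
        """Genes consuming the metabolite ('both' entries included)."""
        return [
            e.gene
            for e in self.enzymes
            if e.metabolite_id == metabolite_id and e.role in ("consumer", "both")
        ]

    def transporter_genes(self, metabolite_id: str) -> list[str]:
        return [t.gene for t in self.transporters if t.metabolite_id == metabolite_id]

    def all_genes(self) -> set[str]:
        genes: set[str] = set()
        for it in self.interactions:
            genes.update(it.receptor.subunits)
        genes.update(e.gene for e in self.enzymes)
        genes.update(t.gene for t in self.transporters)
        return genes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (
            self.species == other.species
            and self.metabolites == other.metabolites
            and sorted(self.interactions, key=lambda i: i.key())
            == sorted(other.interactions, key=lambda i: i.key())
            and sorted(self.enzymes, key=lambda e: (e.metabolite_id, e.gene, e.role))
            == sorted(other.enzymes, key=lambda e: (e.metabolite_id, e.gene, e.role))
            and sorted(self.transporters, key=lambda t: (t.metabolite_id, t.gene))
            == sorted(other.transporters, key=lambda t: (t.metabolite_id, t.gene))
        )


@dataclass
class KBSummary:
    n_interactions: int
    n_metabolites: int
    n_receptors: int
    n_enzyme_entries: int
    n_transporter_entries: int
    role_counts: dict[str, int]
    role_percentages: dict[str, float]
    class_counts: dict[str, int]

    def as_text(self) -> str:
        lines = [
            f"interactions\t{self.n_interactions}",
            f"metabolites\t{self.n_metabolites}",
            f"receptors\t{self.n_receptors}",
            f"enzyme_entries\t{self.n_enzyme_entries}",
            f"transporter_entries\t{self.n_transporter_entries}",
        ]
        for role in ("producer", "consumer", "both"):
            lines.append(
                f"role_{role}\t{self.role_counts[role]}\t{self.role_percentages[role]}"
            )
        for cls_label in sorted(self.class_counts):
            lines.append(f"class\t{cls_label}\t{self.class_counts[cls_label]}")
        return "\n".join(lines) + "\n"


@dataclass
class OrthologyMap:
    """One-to-one gene-symbol mapping between two species."""

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        for src, tgt in self.pairs.items():
            if not src or not tgt:
                raise DataError("orthology map contains an empty gene symbol")

    def get(self, gene: str) -> str | None:
        return self.pairs.get(gene)

    @classmethod
    def read(cls, path: str | Path) -> "OrthologyMap":
        """Read a two-column TSV (source_gene, target_gene) with header."""
        path = Path(path)
        pairs: dict[str, str] = {}
        with path.open(encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            _require_columns(reader, ["source_gene", "target_gene"], path)
            for row in reader:
                src = row["source_gene"].strip()
                tgt = row["target_gene"].strip()
                if not src or not tgt:
                    raise DataError(f"{path}: empty gene symbol in orthology row")
                if src in pairs and pairs[src] != tgt:
                    raise DataError(
                        f"{path}: source gene {src!r} maps to multiple targets"
                    )
                pairs[src] = tgt
        return cls(pairs)


@dataclass
class Issue:
    severity: str  # "error" | "warning"
    entity: str
    message: str


@dataclass
class OrthologyDropReport:
    """What map_orthologs discarded for lack of a complete symbol mapping."""

    dropped_interactions: int = 0
    dropped_enzymes: int = 0
    dropped_transporters: int = 0

    @property
    def total(self) -> int:
        return self.dropped_interactions + self.dropped_enzymes + self.dropped_transporters


def _require_columns(reader: csv.DictReader, cols: Iterable[str], path: Path) -> None:
    have = reader.fieldnames or []
    for col in cols:
        if col not in have:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_kb(
    interactions_path: str | Path,
    enzymes_path: str | Path,
    transporters_path: str | Path,
    metabolites_path: str | Path,
    species: str,
) -> KnowledgeBase:
    """Read and validate a knowledgebase from its four TSV tables.

    Raises
    ------
    FormatError
        If a required column is missing.
    ReferentialIntegrityError
        If any metabolite_id does not resolve against the metabolites table.
    DataError
        On unknown enzyme roles or malformed receptor strings.
    """
    if species not in SPECIES:
        raise DataError(f"unknown species {species!r}; expected one of {sorted(SPECIES)}")
    metabolites: dict[str, MetaboliteRecord] = {}
    mpath = Path(metabolites_path)
    with mpath.open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(reader, ["metabolite_id", "name"], mpath)
        for row in reader:
            mid = row["metabolite_id"].strip()
            if mid in metabolites:
                raise DataError(f"{mpath}: duplicate metabolite_id {mid!r}")
            metabolites[mid] = MetaboliteRecord(
                metabolite_id=mid,
                name=row.get("name", "").strip(),
                hmdb_id=row.get("hmdb_id") or None,
                pubchem_cid=row.get("pubchem_cid") or None,
                class_label=row.get("class_label") or None,
            )

    interactions: list[Interaction] = []
    ipath = Path(interactions_path)
    with ipath.open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(reader, ["metabolite_id", "receptor"], ipath)
        for row in reader:
            interactions.append(
                Interaction(
                    metabolite_id=row["metabolite_id"].strip(),
                    receptor=ReceptorComplex.parse(row["receptor"]),
                    species=(row.get("species") or species).strip(),
                    source=(row.get("source") or "").strip(),
                )
            )

    enzymes: list[EnzymeAnnotation] = []
    epath = Path(enzymes_path)
    with epath.open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(reader, ["metabolite_id", "gene", "role"], epath)
        for row in reader:
            enzymes.append(
                EnzymeAnnotation(
                    metabolite_id=row["metabolite_id"].strip(),
                    gene=row["gene"].strip(),
                    role=row["role"].strip(),
                )
            )

    transporters: list[TransporterAnnotation] = []
    tpath = Path(transporters_path)
    with tpath.open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(reader, ["metabolite_id", "gene"], tpath)
        for row in reader:
            transporters.append(
                TransporterAnnotation(
                    metabolite_id=row["metabolite_id"].strip(),
                    gene=row["gene"].strip(),
                )
            )

    kb = KnowledgeBase(
        species=species,
        metabolites=metabolites,
        interactions=interactions,
        enzymes=enzymes,
        transporters=transporters,
    )
    orphans = [
        iss for iss in validate_kb(kb) if iss.severity == "error"
    ]
    if orphans:
        raise ReferentialIntegrityError(
            "knowledgebase failed referential-integrity checks: "
            + "; ".join(f"[{i.entity}] {i.message}" for i in orphans)
        )
    return kb


def read_kb_dir(kb_dir: str | Path, species: str) -> KnowledgeBase:
    """Read a knowledgebase from a directory with the four standard file names."""
    d = Path(kb_dir)
    return read_kb(
        d / "interactions.tsv",
        d / "enzymes.tsv",
        d / "transporters.tsv",
        d / "metabolites.tsv",
        species,
    )


def write_kb(kb: KnowledgeBase, out_dir: str | Path) -> None:
    """Write the four TSV tables of a knowledgebase into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / "metabolites.tsv").open("w", encoding="utf-8", newline="") as fh:
        fh.write("metabolite_id\tname\thmdb_id\tpubchem_cid\tclass_label\n")
        for mid in sorted(kb.metabolites):
            m = kb.metabolites[mid]
            fh.write(
                f"{m.metabolite_id}\t{m.name}\t{m.hmdb_id or ''}\t"
                f"{m.pubchem_cid or ''}\t{m.class_label or ''}\n"
            )
    with (out / "interactions.tsv").open("w", encoding="utf-8", newline="") as fh:
        fh.write("metabolite_id\treceptor\tspecies\tsource\n")
        for it in sorted(kb.interactions, key=lambda i: i.key()):
            fh.write(f"{it.metabolite_id}\t{it.receptor.label}\t{it.species}\t{it.source}\n")
    with (out / "enzymes.tsv").open("w", encoding="utf-8", newline="") as fh:
        fh.write("metabolite_id\tgene\trole\n")
        for e in sorted(kb.enzymes, key=lambda e: (e.metabolite_id, e.gene, e.role)):
            fh.write(f"{e.metabolite_id}\t{e.gene}\t{e.role}\n")
    with (out / "transporters.tsv").open("w", encoding="utf-8", newline="") as fh:
        fh.write("metabolite_id\tgene\n")
        for t in sorted(kb.transporters, key=lambda t: (t.metabolite_id, t.gene)):
            fh.write(f"{t.metabolite_id}\t{t.gene}\n")


def validate_kb(kb: KnowledgeBase) -> list[Issue]:
    """Check referential integrity and well-formedness; never raises.

    Broken foreign keys are errors; duplicate interactions, duplicate
    annotations, orphan annotations (metabolite never appears in the
    interactions table) and off-vocabulary class labels are warnings.
    """
    issues: list[Issue] = []
    known = set(kb.metabolites)
    interacting = {it.metabolite_id for it in kb.interactions}

    seen_interactions: set[tuple] = set()
    for it in kb.interactions:
        if it.metabolite_id not in known:
            issues.append(
                Issue("error", "interaction", f"unresolved metabolite_id {it.metabolite_id!r}")
            )
        if it.species != kb.species:
            issues.append(
                Issue(
                    "error",
                    "interaction",
                    f"species {it.species!r} differs from knowledgebase species {kb.species!r}",
                )
            )
        key = it.key()
        if key in seen_interactions:
            issues.append(
                Issue(
                    "warning",
                    "interaction",
                    f"duplicate interaction {it.metabolite_id} ~ {it.receptor.canonical_label}",
                )
            )
        seen_interactions.add(key)

    seen_enz: set[tuple[str, str]] = set()
    for e in kb.enzymes:
        if e.metabolite_id not in known:
            issues.append(
                Issue("error", "enzyme", f"unresolved metabolite_id {e.metabolite_id!r}")
            )
        elif e.metabolite_id not in interacting:
            issues.append(
                Issue(
                    "warning",
                    "enzyme",
                    f"orphan annotation: {e.metabolite_id!r} has no interaction",
                )
            )
        if (e.metabolite_id, e.gene) in seen_enz:
            issues.append(
                Issue("warning", "enzyme", f"duplicate entry ({e.metabolite_id}, {e.gene})")
            )
        seen_enz.add((e.metabolite_id, e.gene))

    seen_tr: set[tuple[str, str]] = set()
    for t in kb.transporters:
        if t.metabolite_id not in known:
            issues.append(
                Issue("error", "transporter", f"unresolved metabolite_id {t.metabolite_id!r}")
            )
        elif t.metabolite_id not in interacting:
            issues.append(
                Issue(
                    "warning",
                    "transporter",
                    f"orphan annotation: {t.metabolite_id!r} has no interaction",
                )
            )
        if (t.metabolite_id, t.gene) in seen_tr:
            issues.append(
                Issue("warning", "transporter", f"duplicate entry ({t.metabolite_id}, {t.gene})")
            )
        seen_tr.add((t.metabolite_id, t.gene))

    for m in kb.metabolites.values():
        if m.class_label is not None and m.class_label not in METABOLITE_CLASSES:
            issues.append(
                Issue(
                    "warning",
                    "metabolite",
                    f"class_label {m.class_label!r} outside controlled vocabulary",
                )
            )
    return issues


def summarize_kb(kb: KnowledgeBase) -> KBSummary:
    """Count entries and compute enzyme role percentages (one decimal)."""
    role_counts = {"producer": 0, "consumer": 0, "both": 0}
    for e in kb.enzymes:
        role_counts[e.role] += 1
    total = sum(role_counts.values())
    if total > 0:
        role_percentages = {
            role: round(100.0 * n / total, 1) for role, n in role_counts.items()
        }
    else:
        role_percentages = {role: 0.0 for role in role_counts}
    class_counts: dict[str, int] = {}
    for m in kb.metabolites.values():
        if m.class_label:
            class_counts[m.class_label] = class_counts.get(m.class_label, 0) + 1
    receptors = {it.receptor.canonical for it in kb.interactions}
    return KBSummary(
        n_interactions=len(kb.interactions),
        n_metabolites=len(kb.metabolites),
        n_receptors=len(receptors),
        n_enzyme_entries=total,
        n_transporter_entries=len(kb.transporters),
        role_counts=role_counts,
        role_percentages=role_percentages,
        class_counts=class_counts,
    )


def map_orthologs(
    kb: KnowledgeBase,
    omap: OrthologyMap | Mapping[str, str],
    target_species: str,
) -> tuple[KnowledgeBase, OrthologyDropReport]:
    """Translate every gene symbol in the knowledgebase to the target species.

    Entries containing any unmapped symbol are dropped (receptor complexes
    are all-or-nothing) and counted in the returned drop report.  Metabolite
    records are carried over unchanged.
    """
    if isinstance(omap, Mapping):
        omap = OrthologyMap(dict(omap))
    if not omap.pairs:
        raise DataError("orthology map is empty; nothing can be mapped")
    if target_species not in SPECIES:
        raise DataError(f"unknown target species {target_species!r}")

    report = OrthologyDropReport()
    interactions: list[Interaction] = []
    for it in kb.interactions:
        mapped = [omap.get(s) for s in it.receptor.subunits]
        if any(m is None for m in mapped):
            report.dropped_interactions += 1
            continue
        interactions.append(
            Interaction(
                metabolite_id=it.metabolite_id,
                receptor=ReceptorComplex(tuple(mapped)),  # type: ignore[arg-type]
                species=target_species,
                source=it.source,
            )
        )
    enzymes: list[EnzymeAnnotation] = []
    for e in kb.enzymes:
        tgt = omap.get(e.gene)
        if tgt is None:
            report.dropped_enzymes += 1
            continue
        enzymes.append(EnzymeAnnotation(e.metabolite_id, tgt, e.role))
    transporters: list[TransporterAnnotation] = []
    for t in kb.transporters:
        tgt = omap.get(t.gene)
        if tgt is None:
            report.dropped_transporters += 1
            continue
        transporters.append(TransporterAnnotation(t.metabolite_id, tgt))

    if report.total:
        logger.info(
            "map_orthologs dropped %d interactions, %d enzyme entries, %d transporter entries",
            report.dropped_interactions,
            report.dropped_enzymes,
            report.dropped_transporters,
        )
    mapped_kb = KnowledgeBase(
        species=target_species,
        metabolites=dict(kb.metabolites),
        interactions=interactions,
        enzymes=enzymes,
        transporters=transporters,
    )
    return mapped_kb, report
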