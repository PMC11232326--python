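"""Candidate enumeration, scoring of all triples, permutation significance, FDR.

The unit of inference is the (sender cell type, receiver cell type,
metabolite–receptor interaction) triple.  Enzyme and transporter gene sets are
filtered by expressed fraction in the SENDER; receptor subunits by expressed
fraction in the RECEIVER (a complex is skipped from the testable set if any
subunit fails).  Significance is a one-sided empirical p-value from shuffling
cell-type labels over all cells and re-running the whole
profile → filter → score pipeline per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .ingest import (
    CellMetadata,
    CellTypeProfile,
    ExpressionMatrix,
    normalize,
    profile_cell_types,
    read_expression,
    read_metadata,
)
from .kb import KnowledgeBase
from .scoring import NEGATIVE_E_POLICIES


@dataclass
class AnalysisConfig:
    """Knobs of one communication analysis run."""

    min_frac_pct: float = 10.0  # N: drop genes expressed in < N% of a type's cells
    n_perm: int = 100
    alpha: float = 0.05
    seed: int = 0
    negative_e_policy: str = "literal"
    normalization: str = "cpm"
    include_autocrine: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_frac_pct <= 100.0:
            raise ConfigError("min_frac_pct must lie in [0, 100]")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError("alpha must lie in (0, 1]")
        if self.negative_e_policy not in NEGATIVE_E_POLICIES:
            raise ConfigError(f"unknown negative-E policy {self.negative_e_policy!r}")
        if self.normalization not in ("cpm", "none"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")


RESULT_COLUMNS = [
    "sender",
    "receiver",
    "metabolite_id",
    "metabolite_name",
    "receptor",
    "E",
    "T",
    "M",
    "R",
    "MR_score",
    "p_value",
    "q_value",
]

SORT_KEYS = ["p_value", "MR_score", "sender", "receiver", "metabolite_id", "receptor"]
SORT_ASCENDING = [True, False, True, True, True, True]


def apply_fraction_filter(
    profile: CellTypeProfile, genes: Iterable[str], cell_type: str, N: float
) -> set[str]:
    """Genes expressed in at least N% of the type's cells (ties pass).

    Genes absent from the expression matrix are never retained.
    """
    return {
        g
        for g in genes
        if profile.has_gene(g) and profile.expr_frac(g, cell_type) * 100.0 >= N
    }


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------


@dataclass
class _InteractionBlock:
    metabolite_id: str
    metabolite_name: str
    receptor_label: str
    prod_idx: np.ndarray  # matrix rows of producer genes present in the matrix
    cons_idx: np.ndarray
    trans_idx: np.ndarray
    rec_idx: np.ndarray
    rec_complete: bool  # all receptor subunits present in the matrix


def _masked_gmean(vals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Column-wise geometric mean over masked rows; empty/zero columns give 0.

    ``vals`` and ``mask`` have shape (set size, n_types); returns (n_types,).
    Log-domain so that long products cannot underflow.
    """
    if vals.shape[0] == 0:
        return np.zeros(vals.shape[1], dtype=np.float64)
    cnt = mask.sum(axis=0)
    has_zero = ((vals <= 0.0) & mask).any(axis=0)
    logs = np.where(mask & (vals > 0.0), np.log(np.where(vals > 0.0, vals, 1.0)), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gm = np.exp(logs.sum(axis=0) / cnt)
    gm = np.where((cnt == 0) | has_zero, 0.0, gm)
    return gm


def _build_blocks(kb: KnowledgeBase, gene_index: dict[str, int]) -> list[_InteractionBlock]:
    blocks: list[_InteractionBlock] = []
    for it in kb.interactions:
        mid = it.metabolite_id
        name = kb.metabolites[mid].name if mid in kb.metabolites else ""
        prod = [gene_index[g] for g in kb.producer_genes(mid) if g in gene_index]
        cons = [gene_index[g] for g in kb.consumer_genes(mid) if g in gene_index]
        trans = [gene_index[g] for g in kb.transporter_genes(mid) if g in gene_index]
        subunits = it.receptor.subunits
        complete = all(g in gene_index for g in subunits)
        rec = [gene_index[g] for g in subunits if g in gene_index]
        blocks.append(
            _InteractionBlock(
                metabolite_id=mid,
                metabolite_name=name,
                receptor_label=it.receptor.canonical_label,
                prod_idx=np.asarray(prod, dtype=np.intp),
                cons_idx=np.asarray(cons, dtype=np.intp),
                trans_idx=np.asarray(trans, dtype=np.intp),
                rec_idx=np.asarray(rec, dtype=np.intp),
                rec_complete=complete,
            )
        )
    return blocks


def _block_scores(
    block: _InteractionBlock,
    mean: np.ndarray,
    frac: np.ndarray,
    N: float,
    policy: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-type E, T, M (senders) and R, receptor-pass flags (receivers)."""
    pct = 100.0 * frac
    e_prod = _masked_gmean(mean[block.prod_idx], pct[block.prod_idx] >= N)
    e_cons = _masked_gmean(mean[block.cons_idx], pct[block.cons_idx] >= N)
    E = e_prod - e_cons
    T = _masked_gmean(mean[block.trans_idx], pct[block.trans_idx] >= N)
    e_eff = E if policy == "literal" else np.maximum(E, 0.0)
    M = np.hypot(e_eff, T)
    K = mean.shape[1]
    if block.rec_complete:
        full = np.ones((block.rec_idx.size, K), dtype=bool)
        R = _masked_gmean(mean[block.rec_idx], full)
        rec_pass = (pct[block.rec_idx] >= N).all(axis=0)
    else:
        R = np.zeros(K, dtype=np.float64)
        rec_pass = np.zeros(K, dtype=bool)
    return E, T, M, R, rec_pass


class _Engine:
    """Shared state for scoring one dataset under arbitrary label assignments."""

    def __init__(
        self,
        expr: ExpressionMatrix,
        meta: CellMetadata,
        kb: KnowledgeBase,
        config: AnalysisConfig,
    ) -> None:
        missing = [c for c in expr.cells if c not in meta.types]
        if missing:
            raise DataError(
                f"{len(missing)} matrix cells missing from META, e.g. {missing[:5]}"
            )
        labels = [meta.types[c] for c in expr.cells]
        self.cell_types = sorted(set(labels))
        if len(self.cell_types) < 2:
            raise DataError("communication analysis needs at least 2 cell types")
        tindex = {t: i for i, t in enumerate(self.cell_types)}
        self.labels = np.array([tindex[l] for l in labels], dtype=np.intp)
        self.K = len(self.cell_types)
        self.X = expr.values
        self.B = (expr.values > 0).astype(np.float64)
        gene_index = {g: i for i, g in enumerate(expr.genes)}
        if not (kb.all_genes() & set(expr.genes)):
            raise DataError(
                "no overlap between knowledgebase genes and matrix genes "
                "(species or symbol-case mismatch?)"
            )
        self.blocks = _build_blocks(kb, gene_index)
        self.config = config
        # fixed enumeration of (sender, receiver) ordered pairs
        self.pairs = [
            (s, r)
            for s in range(self.K)
            for r in range(self.K)
            if config.include_autocrine or s != r
        ]

    def profile_arrays(self, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        onehot = np.zeros((labels.size, self.K), dtype=np.float64)
        onehot[np.arange(labels.size), labels] = 1.0
        counts = onehot.sum(axis=0)
        mean = (self.X @ onehot) / counts
        frac = (self.B @ onehot) / counts
        return mean, frac

    def stats(self, labels: np.ndarray) -> np.ndarray:
        """Test statistic per triple: MR, zeroed where the receptor fails."""
        mean, frac = self.profile_arrays(labels)
        cfg = self.config
        out = np.empty(len(self.blocks) * len(self.pairs), dtype=np.float64)
        pos = 0
        for block in self.blocks:
            _, _, M, R, rec_pass = _block_scores(
                block, mean, frac, cfg.min_frac_pct, cfg.negative_e_policy
            )
            for s, r in self.pairs:
                out[pos] = np.hypot(M[s], R[r]) if rec_pass[r] else 0.0
                pos += 1
        return out

    def observed_table(self) -> pd.DataFrame:
        mean, frac = self.profile_arrays(self.labels)
        cfg = self.config
        rows = []
        for block in self.blocks:
            E, T, M, R, rec_pass = _block_scores(
                block, mean, frac, cfg.min_frac_pct, cfg.negative_e_policy
            )
            for s, r in self.pairs:
                mr = float(np.hypot(M[s], R[r]))
                rows.append(
                    {
                        "sender": self.cell_types[s],
                        "receiver": self.cell_types[r],
                        "metabolite_id": block.metabolite_id,
                        "metabolite_name": block.metabolite_name,
                        "receptor": block.receptor_label,
                        "E": float(E[s]),
                        "T": float(T[s]),
                        "M": float(M[s]),
                        "R": float(R[r]),
                        "MR_score": mr,
                        "testable": bool(rec_pass[r]) and mr > 0.0,
                    }
                )
        return pd.DataFrame(rows)


def score_pass(
    profile: CellTypeProfile, kb: KnowledgeBase, config: AnalysisConfig
) -> pd.DataFrame:
    """Score every (sender, receiver, interaction) triple, no p-values yet.

    Returns one row per triple with E, T, M, R, MR_score and a ``testable``
    flag (False where the receptor failed the receiver's fraction filter or
    MR = 0).
    """
    gene_index = {g: i for i, g in enumerate(profile.genes)}
    if not (kb.all_genes() & set(profile.genes)):
        raise DataError(
            "no overlap between knowledgebase genes and matrix genes "
            "(species or symbol-case mismatch?)"
        )
    blocks = _build_blocks(kb, gene_index)
    K = len(profile.cell_types)
    pairs = [
        (s, r)
        for s in range(K)
        for r in range(K)
        if config.include_autocrine or s != r
    ]
    rows = []
    for block in blocks:
        E, T, M, R, rec_pass = _block_scores(
            block, profile.mean, profile.frac, config.min_frac_pct, config.negative_e_policy
        )
        for s, r in pairs:
            mr = float(np.hypot(M[s], R[r]))
            rows.append(
                {
                    "sender": profile.cell_types[s],
                    "receiver": profile.cell_types[r],
                    "metabolite_id": block.metabolite_id,
                    "metabolite_name": block.metabolite_name,
                    "receptor": block.receptor_label,
                    "E": float(E[s]),
                    "T": float(T[s]),
                    "M": float(M[s]),
                    "R": float(R[r]),
                    "MR_score": mr,
                    "testable": bool(rec_pass[r]) and mr > 0.0,
                }
            )
    return pd.DataFrame(rows)


def permutation_pvalues(
    expr: ExpressionMatrix,
    meta: CellMetadata,
    kb: KnowledgeBase,
    config: AnalysisConfig,
    observed: pd.DataFrame,
) -> np.ndarray:
    """Empirical one-sided p-values by cell-label permutation.

    ``expr`` must already be normalized (label shuffling commutes with
    per-cell normalization).  For each permutation the full
    profile → filter → score pipeline is recomputed; the p-value is
    (1 + #{permuted MR >= observed MR}) / (n_perm + 1).  Untestable triples
    get p = 1.  Rows of ``observed`` are matched by triple key, so any row
    order is accepted.
    """
    if config.n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    engine = _Engine(expr, meta, kb, config)
    obs_stat = engine.stats(engine.labels)
    internal = engine.observed_table()
    rng = np.random.default_rng(config.seed)
    exceed = np.zeros(obs_stat.size, dtype=np.int64)
    for _ in range(config.n_perm):
        perm_labels = engine.labels[rng.permutation(engine.labels.size)]
        exceed += engine.stats(perm_labels) >= obs_stat
    p = (1.0 + exceed) / (config.n_perm + 1.0)
    p[~internal["testable"].to_numpy()] = 1.0

    key = ["sender", "receiver", "metabolite_id", "receptor"]
    internal = internal.assign(p_value=p)
    merged = observed.merge(
        internal[key + ["p_value"]], on=key, how="left", validate="one_to_one"
    )
    if merged["p_value"].isna().any():
        raise DataError("observed table rows do not match the enumerated triples")
    return merged["p_value"].to_numpy()


def analyze(
    expr: ExpressionMatrix,
    meta: CellMetadata,
    kb: KnowledgeBase,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Full pipeline on in-memory inputs: normalize → profile → score → permute → BH.

    Deterministic given ``config.seed``; output sorted by (p ascending,
    MR descending, sender, receiver, metabolite_id, receptor).
    """
    norm = normalize(expr, mode=config.normalization)
    profile = profile_cell_types(norm, meta)
    table = score_pass(profile, kb, config)
    table["p_value"] = permutation_pvalues(norm, meta, kb, config, table)
    testable = table["testable"].to_numpy()
    q = np.ones(len(table), dtype=np.float64)
    if testable.any():
        q[testable] = adjust_bh(table.loc[testable, "p_value"].to_numpy())
    table["q_value"] = q
    table = table.sort_values(
        SORT_KEYS, ascending=SORT_ASCENDING, kind="mergesort"
    ).reset_index(drop=True)
    return table


def run_analysis(
    expr_path: str | Path,
    meta_path: str | Path,
    kb: KnowledgeBase,
    config: AnalysisConfig,
    expr_format: str | None = None,
) -> pd.DataFrame:
    """File-level entry point; see :func:`analyze` for the pipeline contract."""
    expr_path = Path(expr_path)
    if expr_format is None:
        expr_format = "mtx_dir" if expr_path.is_dir() else "dense_tsv"
    expr = read_expression(expr_path, format=expr_format)
    meta = read_metadata(meta_path)
    return analyze(expr, meta, kb, config)
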