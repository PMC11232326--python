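"""Naive scalar reference implementation used as an independent oracle.

Deliberately avoids the vectorized engine: per-cell-type means and fractions
come from the public profile API, gene sets are filtered with
``apply_fraction_filter``, and each triple is scored with the scalar
functions from ``metacomm.scoring``.
"""

from __future__ import annotations

import math

from metacomm import (
    AnalysisConfig,
    CellMetadata,
    ExpressionMatrix,
    KnowledgeBase,
    apply_fraction_filter,
    normalize,
    profile_cell_types,
)
from metacomm.scoring import geometric_mean


def naive_reference(
    expr: ExpressionMatrix,
    meta: CellMetadata,
    kb: KnowledgeBase,
    config: AnalysisConfig,
) -> dict[tuple[str, str, str, str], dict[str, float]]:
    """Scalar per-triple re-implementation of the scoring pass.

    Returns {(sender, receiver, metabolite_id, receptor): {E, T, M, R, MR, testable}}.
    """
    expr = normalize(expr, mode=config.normalization)
    profile = profile_cell_types(expr, meta)
    N = config.min_frac_pct
    out: dict[tuple[str, str, str, str], dict[str, float]] = {}
    for it in kb.interactions:
        mid = it.metabolite_id
        for sender in profile.cell_types:
            prod = sorted(
                apply_fraction_filter(profile, kb.producer_genes(mid), sender, N)
            )
            cons = sorted(
                apply_fraction_filter(profile, kb.consumer_genes(mid), sender, N)
            )
            trans = sorted(
                apply_fraction_filter(profile, kb.transporter_genes(mid), sender, N)
            )
            E = geometric_mean(
                [profile.mean_expr(g, sender) for g in prod]
            ) - geometric_mean([profile.mean_expr(g, sender) for g in cons])
            T = geometric_mean([profile.mean_expr(g, sender) for g in trans])
            e_eff = E if config.negative_e_policy == "literal" else max(E, 0.0)
            M = math.hypot(e_eff, T)
            for receiver in profile.cell_types:
                if not config.include_autocrine and sender == receiver:
                    continue
                subunits = it.receptor.subunits
                passing = apply_fraction_filter(profile, subunits, receiver, N)
                rec_pass = len(passing) == len(subunits)
                R = geometric_mean([profile.mean_expr(g, receiver) for g in subunits])
                MR = math.hypot(M, R)
                out[(sender, receiver, mid, it.receptor.canonical_label)] = {
                    "E": E,
                    "T": T,
                    "M": M,
                    "R": R,
                    "MR": MR,
                    "testable": rec_pass and MR > 0,
                }
    return out
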