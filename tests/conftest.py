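"""Shared fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from metacomm import (
    CellMetadata,
    EnzymeAnnotation,
    ExpressionMatrix,
    Interaction,
    KnowledgeBase,
    MetaboliteRecord,
    ReceptorComplex,
    TransporterAnnotation,
)


@pytest.fixture
def toy_kb() -> KnowledgeBase:
    """One metabolite, two producers, one consumer, one transporter, 2-subunit receptor."""
    return KnowledgeBase(
        species="human",
        metabolites={
            "M1": MetaboliteRecord("M1", name="histamine", class_label="Organic nitrogen compounds")
        },
        interactions=[Interaction("M1", ReceptorComplex(("RS1", "RS2")), "human", "test")],
        enzymes=[
            EnzymeAnnotation("M1", "P1", "producer"),
            EnzymeAnnotation("M1", "P2", "producer"),
            EnzymeAnnotation("M1", "C1", "consumer"),
        ],
        transporters=[TransporterAnnotation("M1", "T1")],
    )


@pytest.fixture
def toy_dataset() -> tuple[ExpressionMatrix, CellMetadata]:
    """One cell per type; sender 'A' carries the machinery, receiver 'B' the receptor.

    Chosen so that with N = 0 and no normalization the scoring chain gives
    E = 3, T = 4, M = 5, R = 8, MR = sqrt(89).
    """
    genes = ["P1", "P2", "C1", "T1", "RS1", "RS2"]
    cells = ["a1", "b1"]
    values = np.array(
        [
            [2.0, 0.0],
            [8.0, 0.0],
            [1.0, 0.0],
            [4.0, 0.0],
            [0.0, 2.0],
            [0.0, 32.0],
        ]
    )
    return ExpressionMatrix(genes, cells, values), CellMetadata({"a1": "A", "b1": "B"})
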