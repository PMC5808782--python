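import numpy as np
import pandas as pd
import pytest

from tissuescore import (
    Association,
    ExpressionDataset,
    GoldStandard,
    ScoredChannel,
    TissueOntology,
)


@pytest.fixture
def chain_onto():
    """A -> B -> C chain plus an unrelated D."""
    return TissueOntology(
        names={"A": "a", "B": "b", "C": "c", "D": "d"},
        parents={"A": {"B"}, "B": {"C"}},
        major_tissues={"C"},
    )


@pytest.fixture
def liver_onto():
    return TissueOntology(
        names={
            "BTO:LIVER": "liver",
            "BTO:HEP": "hepatocyte",
            "BTO:KIDNEY": "kidney",
            "BTO:ROOT": "whole body",
        },
        parents={
            "BTO:LIVER": {"BTO:ROOT"},
            "BTO:KIDNEY": {"BTO:ROOT"},
            "BTO:HEP": {"BTO:LIVER"},
        },
        major_tissues={"BTO:LIVER", "BTO:KIDNEY"},
    )


def make_dataset(values, genes=None, tissues=None, organism="human", unit="arbitrary"):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    tissues = tissues or [f"T{j}" for j in range(arr.shape[1])]
    return ExpressionDataset(
        dataset_id="test",
        organism=organism,
        unit=unit,
        values=pd.DataFrame(arr, index=genes, columns=tissues),
    )


def make_channel(entries, channel="experiments", organism="human"):
    """entries: iterable of (gene, tissue, raw, confidence, stars) or shorter."""
    assocs = []
    for e in entries:
        e = tuple(e) + (None,) * (5 - len(e))
        assocs.append(
            Association(gene=e[0], tissue=e[1], raw=e[2], confidence=e[3], stars=e[4])
        )
    return ScoredChannel(channel=channel, organism=organism, associations=assocs)


def make_gold(pairs, organism="human", source="synthetic"):
    return GoldStandard(organism=organism, pairs=frozenset(pairs), source=source)


def random_dag(rng, n_terms):
    """Random DAG: each non-root term gets 1-2 parents among earlier terms."""
    names = {f"T{i}": f"term {i}" for i in range(n_terms)}
    parents = {}
    for i in range(1, n_terms):
        k = int(rng.integers(1, 3))
        choices = rng.choice(i, size=min(k, i), replace=False)
        parents[f"T{i}"] = {f"T{j}" for j in choices}
    return TissueOntology(names=names, parents=parents)


def brute_force_ancestors(onto, term):
    """Repeated edge expansion until fixpoint (independent oracle)."""
    closure = set(onto.parents.get(term, set()))
    while True:
        extra = set()
        for t in closure:
            extra |= set(onto.parents.get(t, set()))
        if extra <= closure:
            return closure
        closure |= extra
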