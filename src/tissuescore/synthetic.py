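"""Synthetic worlds with planted truth: ontology, per-organism expression
truth, ortholog groups, datasets of controlled quality, incomplete gold
standards and toy literature corpora.

Everything is seed-deterministic: the same ``WorldParams`` (including seed)
produce byte-identical fixture files. Expression follows a two-class
log-normal model — truly expressed pairs draw from lognormal(mu_on, sigma),
unexpressed pairs from lognormal(mu_off, sigma) — so dataset quality is the
class separation (mu_on - mu_off) / sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ExpressionDataset, GoldStandard, OrthologGroups
from .ontology import TissueOntology

#: taxon prefixes used when writing synthetic ortholog-group files
SYNTH_TAXIDS = {"human": "9606", "mouse": "10090", "rat": "10116", "pig": "9823"}


@dataclass(frozen=True)
class DatasetQuality:
    """Two-class log-normal expression model parameters."""

    mu_on: float = 3.0
    mu_off: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_on <= self.mu_off:
            raise ValidationError("mu_on must exceed mu_off")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")

    @property
    def separation(self) -> float:
        return (self.mu_on - self.mu_off) / self.sigma


@dataclass
class WorldParams:
    organisms: tuple[str, ...] = ("human", "mouse")
    n_genes: int = 200
    n_tissues: int = 10
    prevalence: float = 0.3  # P(gene truly expressed in a tissue)
    ortholog_coverage: float = 0.8  # fraction of genes with a 1:1 partner
    gs_coverage: float = 0.5  # fraction of true pairs annotated
    non11_fraction: float = 0.1  # fraction of groups given an in-paralog
    divergence: float = 0.0  # fraction of transferred truths flipped
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence <= 1:
            raise ValidationError("prevalence must lie in (0, 1]")
        if not 0 <= self.ortholog_coverage <= 1:
            raise ValidationError("ortholog_coverage must lie in [0, 1]")
        if not 0 < self.gs_coverage <= 1:
            raise ValidationError("gs_coverage must lie in (0, 1]")
        if not 0 <= self.non11_fraction <= 1:
            raise ValidationError("non11_fraction must lie in [0, 1]")
        if not 0 <= self.divergence <= 1:
            raise ValidationError("divergence must lie in [0, 1]")
        if self.n_genes < 1 or self.n_tissues < 1:
            raise ValidationError("need at least one gene and one tissue")
        if len(self.organisms) < 1 or len(set(self.organisms)) != len(self.organisms):
            raise ValidationError("organisms must be unique and non-empty")


@dataclass
class World:
    params: WorldParams
    ontology: TissueOntology
    tissues: list[str]  # measurement-level (major) terms
    genes: dict[str, list[str]]  # organism -> gene ids
    truth: dict[str, set[tuple[str, str]]]  # organism -> true (gene, tissue)
    groups: OrthologGroups
    gene_names: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    tissue_names: dict[str, set[str]] = field(default_factory=dict)


def _gene_id(org: str, i: int) -> str:
    return f"{org[:3].upper()}{i:05d}"


def _tissue_id(i: int) -> str:
    return f"BTO:9{i:06d}"


def simulate_world(params: WorldParams) -> World:
    """Build ontology, per-organism truth and ortholog groups from params.

    The ontology is a root plus one major term per tissue; truth for the
    reference organism is Bernoulli(prevalence) per (gene, tissue) and is
    copied across 1:1-linked orthologs (optionally flipped at the divergence
    rate). A ``non11_fraction`` of groups receive an extra same-organism
    member so 1:1 filtering is exercised.
    """
    rng = np.random.default_rng(params.seed)
    orgs = list(params.organisms)

    root = _tissue_id(0)
    tissues = [_tissue_id(i + 1) for i in range(params.n_tissues)]
    names = {root: "whole body"}
    parents: dict[str, set[str]] = {}
    for i, t in enumerate(tissues):
        names[t] = f"tissue {i + 1}"
        parents[t] = {root}
    onto = TissueOntology(names=names, parents=parents, major_tissues=set(tissues))

    genes = {org: [_gene_id(org, i) for i in range(params.n_genes)] for org in orgs}

    # truth for the reference organism
    ref = orgs[0]
    truth: dict[str, set[tuple[str, str]]] = {o: set() for o in orgs}
    base = rng.random((params.n_genes, params.n_tissues)) < params.prevalence
    for i, g in enumerate(genes[ref]):
        for j, t in enumerate(tissues):
            if base[i, j]:
                truth[ref].add((g, t))

    # ortholog groups: the first floor(q * n) gene indices are linked 1:1:...:1
    n_linked = int(np.floor(params.ortholog_coverage * params.n_genes))
    groups: list[tuple[str, tuple[tuple[str, str], ...]]] = []
    linked = set(range(n_linked))
    for i in range(n_linked):
        members = tuple((org, genes[org][i]) for org in orgs)
        if len(orgs) > 1 and rng.random() < params.non11_fraction:
            # add an in-paralog from the reference organism's unlinked genes
            extra_idx = n_linked + int(rng.integers(0, max(params.n_genes - n_linked, 1)))
            extra_idx = min(extra_idx, params.n_genes - 1)
            if extra_idx not in linked:
                members = members + ((ref, genes[ref][extra_idx]),)
        groups.append((f"OG{i:05d}", members))

    # truth for other organisms: copy across orthologs, independent otherwise
    for org in orgs[1:]:
        flips = rng.random((params.n_genes, params.n_tissues)) < params.divergence
        indep = rng.random((params.n_genes, params.n_tissues)) < params.prevalence
        for i in range(params.n_genes):
            for j, t in enumerate(tissues):
                if i < n_linked:
                    val = bool(base[i, j]) ^ bool(flips[i, j])
                else:
                    val = bool(indep[i, j])
                if val:
                    truth[org].add((genes[org][i], t))

    gene_names = {
        g: {(org, g)} for org in orgs for g in genes[org]
    }
    tissue_names = {names[t]: {t} for t in tissues}
    return World(
        params=params,
        ontology=onto,
        tissues=tissues,
        genes=genes,
        truth=truth,
        groups=OrthologGroups(groups=groups),
        gene_names=gene_names,
        tissue_names=tissue_names,
    )


def simulate_dataset(
    world: World,
    organism: str,
    quality: DatasetQuality,
    seed: int,
    dataset_id: str | None = None,
    unit: str = "arbitrary",
) -> ExpressionDataset:
    """Draw a raw expression matrix for one organism from the quality model."""
    if organism not in world.genes:
        raise ValidationError(f"unknown organism {organism!r}")
    rng = np.random.default_rng(seed)
    genes = world.genes[organism]
    tissues = world.tissues
    truth = world.truth[organism]
    on = np.array(
        [[(g, t) in truth for t in tissues] for g in genes], dtype=bool
    )
    mu = np.where(on, quality.mu_on, quality.mu_off)
    values = rng.lognormal(mean=mu, sigma=quality.sigma)
    df = pd.DataFrame(values, index=genes, columns=tissues)
    return ExpressionDataset(
        dataset_id=dataset_id or f"{organism}-sim{seed}",
        organism=organism,
        unit=unit,
        values=df,
    )


def simulate_gold_standard(
    world: World,
    organism: str,
    coverage: float,
    seed: int,
    contamination: float = 0.0,
) -> GoldStandard:
    """Uniform subsample of true pairs at rate *coverage*; optionally add a
    ``contamination`` fraction of false pairs."""
    if not 0 < coverage <= 1:
        raise ValidationError("coverage must lie in (0, 1]")
    if not 0 <= contamination < 1:
        raise ValidationError("contamination must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    true_pairs = sorted(world.truth[organism])
    keep = rng.random(len(true_pairs)) < coverage
    pairs = {p for p, k in zip(true_pairs, keep) if k}
    if contamination > 0:
        false_pairs = sorted(
            {
                (g, t)
                for g in world.genes[organism]
                for t in world.tissues
            }
            - set(true_pairs)
        )
        n_false = int(round(contamination * len(pairs)))
        idx = rng.choice(len(false_pairs), size=min(n_false, len(false_pairs)), replace=False)
        pairs |= {false_pairs[i] for i in sorted(idx)}
    if not pairs:
        raise ValidationError("gold-standard subsample came out empty; raise coverage")
    return GoldStandard(organism=organism, pairs=frozenset(pairs), source="synthetic")


def simulate_corpus(
    world: World,
    organism: str,
    n_docs: int,
    seed: int,
    base_rate: float = 0.3,
    elevation: float = 0.6,
) -> list[tuple[str, list[str]]]:
    """Toy abstracts co-mentioning gene and tissue names.

    Each document picks a random gene and tissue; with probability
    ``base_rate + elevation * is_true_pair`` they share a sentence (strong
    co-mention), otherwise they sit in separate sentences (weak co-mention).
    Zero elevation therefore yields scores uncorrelated with the truth.
    """
    if base_rate + elevation > 1 + 1e-9:
        raise ValidationError("base_rate + elevation must not exceed 1")
    rng = np.random.default_rng(seed)
    genes = world.genes[organism]
    tissues = world.tissues
    tissue_name = {t: world.ontology.names[t] for t in tissues}
    truth = world.truth[organism]
    corpus: list[tuple[str, list[str]]] = []
    for d in range(n_docs):
        g = genes[int(rng.integers(0, len(genes)))]
        t = tissues[int(rng.integers(0, len(tissues)))]
        p_same = base_rate + (elevation if (g, t) in truth else 0.0)
        if rng.random() < p_same:
            sentences = [f"Expression of {g} was detected in {tissue_name[t]}."]
        else:
            sentences = [
                f"We examined {g} in several conditions.",
                f"Samples were taken from {tissue_name[t]}.",
            ]
        corpus.append((f"DOC{d:05d}", sentences))
    return corpus
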