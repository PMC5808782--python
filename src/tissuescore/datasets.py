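"""Standardization of raw matrices: probe/transcript -> gene collapsing,
replicate averaging and tissue-label -> ontology-term mapping.

Rules: when several probes map to one gene the gene value is the plain
arithmetic mean of the probe values (raw scale, no log transform); a probe
whose alias resolves to more than one gene is filtered out before any
averaging; unmapped probes are removed. All removals are counted and
returned alongside the standardized dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ParseError, ValidationError
from .io_formats import ExpressionDataset
from .ontology import TissueOntology


@dataclass
class AliasDictionary:
    """alias -> set of canonical gene identifiers, for one organism."""

    organism: str
    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for alias, targets in self.entries.items():
            if not alias:
                raise ValidationError("empty alias in dictionary")
            if not targets:
                raise ValidationError(f"alias {alias!r} maps to no identifiers")

    def __len__(self) -> int:
        return len(self.entries)


def read_alias_dictionary(path, organism: str) -> AliasDictionary:
    """TSV of (alias, canonical id); one row per mapping, repeats allowed."""
    path = Path(path)
    entries: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("expected 2 columns (alias, id)", str(path), lineno)
            entries.setdefault(fields[0], set()).add(fields[1])
    return AliasDictionary(organism=organism, entries=entries)


@dataclass(frozen=True)
class MappingReport:
    """Accounting of row/column fates during a standardization step."""

    n_input: int
    n_kept: int
    n_dropped_ambiguous: int = 0
    n_dropped_unmapped: int = 0
    dropped: tuple[str, ...] = ()


def map_identifiers(
    raw: ExpressionDataset, alias_dict: AliasDictionary
) -> tuple[ExpressionDataset, MappingReport]:
    """Collapse probe/transcript rows to canonical gene identifiers.

    k probes mapping to one gene -> per-tissue arithmetic mean of the k probe
    rows. Ambiguous probes (alias resolving to >1 gene) and unmapped probes
    are removed; the report accounts for every input probe.
    """
    if not alias_dict.entries:
        raise ValidationError("alias dictionary is empty")
    target: dict[str, str] = {}
    dropped_amb: list[str] = []
    dropped_unmapped: list[str] = []
    for probe in raw.genes:
        genes = alias_dict.entries.get(probe)
        if genes is None:
            dropped_unmapped.append(probe)
        elif len(genes) > 1:
            dropped_amb.append(probe)
        else:
            target[probe] = next(iter(genes))
    if not target:
        raise ValidationError("no probes could be mapped to a unique gene")
    kept = raw.values.loc[sorted(target)]
    gene_for_row = pd.Series([target[p] for p in kept.index], index=kept.index)
    collapsed = kept.groupby(gene_for_row).mean().sort_index()
    ds = ExpressionDataset(
        dataset_id=raw.dataset_id,
        organism=raw.organism,
        unit=raw.unit,
        values=collapsed,
    )
    report = MappingReport(
        n_input=len(raw.genes),
        n_kept=len(target),
        n_dropped_ambiguous=len(dropped_amb),
        n_dropped_unmapped=len(dropped_unmapped),
        dropped=tuple(sorted(dropped_amb + dropped_unmapped)),
    )
    return ds, report


def average_replicates(
    ds: ExpressionDataset, sample_to_tissue: dict[str, str]
) -> tuple[ExpressionDataset, MappingReport]:
    """Collapse sample columns to one column per tissue (arithmetic mean).

    Samples absent from the mapping are dropped and counted.
    """
    assigned = [s for s in ds.tissues if s in sample_to_tissue]
    if not assigned:
        raise ValidationError("sample-to-tissue mapping covers zero samples")
    dropped = [s for s in ds.tissues if s not in sample_to_tissue]
    sub = ds.values[assigned]
    tissue_for_col = pd.Series([sample_to_tissue[s] for s in assigned], index=assigned)
    collapsed = sub.T.groupby(tissue_for_col).mean().T
    collapsed = collapsed[sorted(collapsed.columns)]
    out = ExpressionDataset(
        dataset_id=ds.dataset_id, organism=ds.organism, unit=ds.unit, values=collapsed
    )
    report = MappingReport(
        n_input=len(ds.tissues),
        n_kept=len(assigned),
        n_dropped_unmapped=len(dropped),
        dropped=tuple(sorted(dropped)),
    )
    return out, report


def map_tissue_labels(
    ds: ExpressionDataset, label_to_term: dict[str, str], onto: TissueOntology
) -> tuple[ExpressionDataset, MappingReport]:
    """Rename free-text tissue columns to ontology term ids.

    Labels without a mapping are dropped and counted. Two labels mapping to
    the same term is an error: merge them first with
    :func:`average_replicates`.
    """
    rename: dict[str, str] = {}
    dropped: list[str] = []
    for label in ds.tissues:
        term = label_to_term.get(label)
        if term is None:
            dropped.append(label)
            continue
        if term not in onto:
            raise ValidationError(f"label {label!r} maps to unknown term {term!r}")
        if term in rename.values():
            raise ValidationError(
                f"two labels map to term {term!r}; pre-merge with average_replicates"
            )
        rename[label] = term
    if not rename:
        raise ValidationError("no tissue labels could be mapped to ontology terms")
    sub = ds.values[list(rename)].rename(columns=rename)
    sub = sub[sorted(sub.columns)]
    out = ExpressionDataset(
        dataset_id=ds.dataset_id, organism=ds.organism, unit=ds.unit, values=sub
    )
    report = MappingReport(
        n_input=len(ds.tissues),
        n_kept=len(rename),
        n_dropped_unmapped=len(dropped),
        dropped=tuple(sorted(dropped)),
    )
    return out, report
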