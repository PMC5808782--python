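"""Readers and writers for every external file dialect the pipeline touches.

All tabular files are TSV: tab separator, "." decimal, no quoting. Writers
are deterministic (sorted rows, fixed float formatting) so that identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .ontology import TissueOntology

UNITS = ("intensity", "FPKM", "TPM", "arbitrary")

#: NCBI-taxon-style numeric prefixes used in orthologous-group member files.
DEFAULT_TAXA: dict[str, str] = {
    "9606": "human",
    "10090": "mouse",
    "10116": "rat",
    "9823": "pig",
}


def _fmt(v: float | None) -> str:
    """Stable float formatting for writers ('' for missing)."""
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return format(float(v), ".6g")


@dataclass
class ExpressionDataset:
    """Organism-tagged gene x tissue matrix of raw expression values."""

    dataset_id: str
    organism: str
    unit: str
    values: pd.DataFrame  # index: genes, columns: tissues

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unit {self.unit!r} not one of {UNITS}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dup[:5]}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate tissue identifiers: {dup[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        if np.any(arr < 0):
            raise ValidationError("expression values must be >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GoldStandard:
    """Trusted gene-tissue pairs used for benchmarking."""

    organism: str
    pairs: frozenset[tuple[str, str]]
    source: str = "curated"  # curated | orthology-transferred | synthetic
    n_dropped: int = 0  # rows dropped during reading/transfer (unmappable)

    def __post_init__(self) -> None:
        if self.source not in ("curated", "orthology-transferred", "synthetic"):
            raise ValidationError(f"unknown gold-standard source {self.source!r}")
        self.pairs = frozenset(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def genes(self) -> set[str]:
        return {g for g, _ in self.pairs}

    def tissues(self) -> set[str]:
        return {t for _, t in self.pairs}


@dataclass
class OrthologGroups:
    """Orthologous groups: list of (group id, ((organism, gene), ...))."""

    groups: list[tuple[str, tuple[tuple[str, str], ...]]]
    n_dropped_members: int = 0

    def __len__(self) -> int:
        return len(self.groups)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(
    path, dataset_id: str, organism: str, unit: str = "arbitrary"
) -> ExpressionDataset:
    """Read a TSV expression matrix: header = tissue labels, col 0 = genes."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError("empty file", str(path), 1)
        cols = header.split("\t")
        tissues = cols[1:]
        if not tissues:
            raise ParseError("header has no tissue columns", str(path), 1)
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(tissues) + 1:
                raise ParseError(
                    f"expected {len(tissues) + 1} fields, found {len(fields)}",
                    str(path),
                    lineno,
                )
            genes.append(fields[0])
            try:
                vals = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise ParseError(f"non-numeric value: {exc}", str(path), lineno)
            if any(v < 0 for v in vals):
                raise ParseError("negative expression value", str(path), lineno)
            rows.append(vals)
    if len(set(genes)) != len(genes):
        seen: set[str] = set()
        dups = sorted({g for g in genes if g in seen or seen.add(g)})
        raise ValidationError(f"duplicate gene rows: {dups[:5]}")
    values = pd.DataFrame(rows, index=genes, columns=tissues, dtype=float)
    return ExpressionDataset(
        dataset_id=dataset_id, organism=organism, unit=unit, values=values
    )


def write_expression_matrix(ds: ExpressionDataset, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(ds.tissues) + "\n")
        arr = ds.values.to_numpy(dtype=float)
        for i, gene in enumerate(ds.genes):
            fh.write(gene + "\t" + "\t".join(_fmt(v) for v in arr[i]) + "\n")


# ---------------------------------------------------------------------------
# OBO ontology (minimal subset: id / name / is_a / is_obsolete)


def read_ontology_obo(path, major_tissues: set[str] | None = None) -> TissueOntology:
    """Parse a minimal OBO 1.2 subset into a tissue DAG.

    Only ``id``, ``name``, ``is_a`` and ``is_obsolete`` tags are honoured;
    relationship lines (part_of etc.) are ignored. Obsolete terms are
    excluded. Cycles and dangling is_a targets are validation errors.
    """
    path = Path(path)
    names: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    cur_id: str | None = None
    cur_name: str | None = None
    cur_parents: set[str] = set()
    cur_obsolete = False
    in_term = False

    def flush():
        nonlocal cur_id, cur_name, cur_parents, cur_obsolete
        if in_term and cur_id is not None and not cur_obsolete:
            names[cur_id] = cur_name if cur_name is not None else cur_id
            if cur_parents:
                parents[cur_id] = set(cur_parents)
        cur_id, cur_name, cur_parents, cur_obsolete = None, None, set(), False

    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                continue
            if not in_term or not line:
                continue
            if ":" not in line:
                continue
            tag, _, val = line.partition(":")
            val = val.split("!")[0].strip()
            tag = tag.strip()
            if tag == "id":
                cur_id = val
            elif tag == "name":
                cur_name = val
            elif tag == "is_a":
                cur_parents.add(val)
            elif tag == "is_obsolete" and val.lower() == "true":
                cur_obsolete = True
    flush()
    if not names:
        raise ParseError("no terms found", str(path))
    return TissueOntology(
        names=names, parents=parents, major_tissues=set(major_tissues or ())
    )


def write_ontology_obo(onto: TissueOntology, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(onto.names):
            fh.write(f"\n[Term]\nid: {term}\nname: {onto.names[term]}\n")
            for p in sorted(onto.parents.get(term, ())):
                fh.write(f"is_a: {p} ! {onto.names[p]}\n")


# ---------------------------------------------------------------------------
# orthologous groups (eggNOG members dialect)


def read_orthogroups(path, taxa: dict[str, str] | None = None) -> OrthologGroups:
    """Read an eggNOG-members-style TSV: group id in column 0, comma-separated
    ``taxid.protein_id`` member tokens in the last column.

    Members whose taxon prefix is not in the *taxa* allow-list are dropped and
    counted; groups left empty are omitted.
    """
    if taxa is None:
        taxa = DEFAULT_TAXA
    path = Path(path)
    groups: list[tuple[str, tuple[tuple[str, str], ...]]] = []
    dropped = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("expected >= 2 tab-separated columns", str(path), lineno)
            group_id = fields[0]
            members: list[tuple[str, str]] = []
            for token in fields[-1].split(","):
                token = token.strip()
                if not token:
                    continue
                if "." not in token:
                    raise ParseError(
                        f"member token {token!r} lacks a '.' separator",
                        str(path),
                        lineno,
                    )
                taxid, _, gene = token.partition(".")
                org = taxa.get(taxid)
                if org is None:
                    dropped += 1
                    continue
                members.append((org, gene))
            if members:
                groups.append((group_id, tuple(members)))
    return OrthologGroups(groups=groups, n_dropped_members=dropped)


def write_orthogroups(
    groups: OrthologGroups, path, taxa: dict[str, str] | None = None
) -> None:
    if taxa is None:
        taxa = DEFAULT_TAXA
    org_to_taxid = {v: k for k, v in taxa.items()}
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for group_id, members in groups.groups:
            tokens = ",".join(f"{org_to_taxid[org]}.{gene}" for org, gene in members)
            fh.write(f"{group_id}\t{tokens}\n")


# ---------------------------------------------------------------------------
# gold-standard annotation pairs


def read_annotation_pairs(
    path,
    organism: str,
    source: str = "curated",
    label_to_term: dict[str, str] | None = None,
) -> GoldStandard:
    """Read (gene, tissue) pairs from TSV; free-text tissue labels are mapped
    through *label_to_term* when given, unmappable labels dropped and counted.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    dropped = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("gene\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("expected >= 2 columns (gene, tissue)", str(path), lineno)
            gene, tissue = fields[0], fields[1]
            if label_to_term is not None:
                term = label_to_term.get(tissue, tissue if tissue.count(":") else None)
                if term is None:
                    dropped += 1
                    continue
                tissue = term
            pairs.add((gene, tissue))
    if not pairs:
        raise ValidationError(f"{path}: gold standard is empty")
    return GoldStandard(
        organism=organism, pairs=frozenset(pairs), source=source, n_dropped=dropped
    )


def write_annotation_pairs(gs: GoldStandard, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\ttissue\n")
        for gene, tissue in sorted(gs.pairs):
            fh.write(f"{gene}\t{tissue}\n")


# ---------------------------------------------------------------------------
# scored-channel TSV (download-style dialect)

CHANNEL_COLUMNS = ("gene", "tissue", "tissue_name", "channel", "raw", "confidence", "stars")


def write_channel(assocs, path, onto: TissueOntology | None = None) -> None:
    """Write a scored channel as TSV, sorted by gene then descending stars.

    Columns: gene, tissue term id, tissue name, channel, raw value (empty if
    n/a), confidence, stars. Byte output is deterministic for fixed input.
    """
    path = Path(path)
    rows = sorted(
        assocs.associations,
        key=lambda a: (a.gene, -(a.stars if a.stars is not None else -math.inf), a.tissue),
    )
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(CHANNEL_COLUMNS) + "\n")
        for a in rows:
            name = onto.names.get(a.tissue, a.tissue) if onto is not None else a.tissue
            fh.write(
                "\t".join(
                    (
                        a.gene,
                        a.tissue,
                        name,
                        assocs.channel,
                        _fmt(a.raw),
                        _fmt(a.confidence),
                        _fmt(a.stars),
                    )
                )
                + "\n"
            )


def read_channel(path, organism: str):
    """Read a channel TSV written by :func:`write_channel`."""
    from .scoring import Association, ScoredChannel

    path = Path(path)
    assocs = []
    channel = None
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CHANNEL_COLUMNS:
            raise ParseError(f"unexpected header {header}", str(path), 1)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(CHANNEL_COLUMNS):
                raise ParseError(
                    f"expected {len(CHANNEL_COLUMNS)} fields, found {len(fields)}",
                    str(path),
                    lineno,
                )
            gene, tissue, _name, ch, raw, conf, stars = fields
            if channel is None:
                channel = ch
            elif ch != channel:
                raise ParseError(f"mixed channels {channel!r}/{ch!r}", str(path), lineno)
            assocs.append(
                Association(
                    gene=gene,
                    tissue=tissue,
                    raw=float(raw) if raw else None,
                    confidence=float(conf) if conf else None,
                    stars=float(stars) if stars else None,
                )
            )
    return ScoredChannel(
        channel=channel or "experiments", organism=organism, associations=assocs
    )


# ---------------------------------------------------------------------------
# enrichment curves / fits / calibration


def write_curve(curve, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("x\te\tn\n")
        for b in curve.bins:
            fh.write(f"{_fmt(b.x)}\t{_fmt(b.e)}\t{b.n}\n")


def read_curve(path, window: int | None = None, step: int | None = None):
    from .scoring import EnrichmentBin, EnrichmentCurve

    path = Path(path)
    bins = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("x\te"):
            raise ParseError("not a curve file", str(path), 1)
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            x, e, n = line.split("\t")
            bins.append(EnrichmentBin(x=float(x), e=float(e), n=int(n)))
    if not bins:
        raise ValidationError(f"{path}: empty curve")
    w = window if window is not None else bins[0].n
    return EnrichmentCurve(bins=bins, window=w, step=step if step is not None else w)


def write_fit(fit, path) -> None:
    path = Path(path)
    payload = {"a0": fit.a0, "a1": fit.a1, "a2": fit.a2, "a3": fit.a3, "rss": fit.rss}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_fit(path):
    from .scoring import SigmoidFit

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return SigmoidFit(**{k: float(payload[k]) for k in ("a0", "a1", "a2", "a3", "rss")})


def write_calibration(cal, path) -> None:
    payload = {"star_max": cal.star_max, "breakpoints": cal.breakpoints}
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_calibration(path):
    from .scoring import CalibrationFunction

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return CalibrationFunction(
        breakpoints=[(float(c), float(s)) for c, s in payload["breakpoints"]],
        star_max=float(payload["star_max"]),
    )


# ---------------------------------------------------------------------------
# toy literature corpus: TSV of (doc id, sentence index, sentence text)


def write_corpus(corpus: list[tuple[str, list[str]]], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("doc\tsentence\ttext\n")
        for doc_id, sentences in corpus:
            for i, s in enumerate(sentences):
                fh.write(f"{doc_id}\t{i}\t{s}\n")


def read_corpus(path) -> list[tuple[str, list[str]]]:
    path = Path(path)
    docs: dict[str, list[tuple[int, str]]] = {}
    order: list[str] = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != "doc\tsentence\ttext":
            raise ParseError(f"unexpected corpus header {header!r}", str(path), 1)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError("expected 3 columns", str(path), lineno)
            doc_id, idx, text = fields
            if doc_id not in docs:
                docs[doc_id] = []
                order.append(doc_id)
            docs[doc_id].append((int(idx), text))
    return [(d, [t for _, t in sorted(docs[d])]) for d in order]


# ---------------------------------------------------------------------------
# correlation matrices / ROC points


def write_matrix(matrix: pd.DataFrame, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("dataset\t" + "\t".join(matrix.columns) + "\n")
        for label, row in matrix.iterrows():
            fh.write(label + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def write_roc(roc, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("threshold\ttpr\tfpr\n")
        for thr, tpr, fpr in roc.points:
            thr_s = "inf" if math.isinf(thr) else _fmt(thr)
            fh.write(f"{thr_s}\t{_fmt(tpr)}\t{_fmt(fpr)}\n")
        fh.write(f"# auc\t{_fmt(roc.auc)}\n")
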