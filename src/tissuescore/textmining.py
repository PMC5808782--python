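"""Dictionary-based gene/tissue co-mention counting on a sentence-split
corpus, and conversion of weighted counts into a normalized co-occurrence
score.

Matching is exact longest-alias matching, case-insensitive, on word
boundaries — deliberately simple; no stemming, no learned NER. A gene is
attributed to an organism only when the organism's name (Linnaean or common)
appears in the document, except when the alias is unambiguous (it names a
gene of a single organism).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ValidationError
from .scoring import Association, ScoredChannel

W_SENTENCE = 1.0
W_ABSTRACT = 0.2
ALPHA = 0.6


@dataclass
class CoMentionCounts:
    """Weighted co-mention counts with their margins."""

    C: dict[tuple[str, str], float] = field(default_factory=dict)
    w_sentence: float = W_SENTENCE
    w_abstract: float = W_ABSTRACT

    @property
    def C_gene(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (g, _t), c in self.C.items():
            out[g] = out.get(g, 0.0) + c
        return out

    @property
    def C_tissue(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (_g, t), c in self.C.items():
            out[t] = out.get(t, 0.0) + c
        return out

    @property
    def C_total(self) -> float:
        return sum(self.C.values())


class _Matcher:
    """Longest-match, case-insensitive alias matcher over word boundaries."""

    def __init__(self, aliases: dict[str, set]):
        if not aliases:
            raise ValidationError("empty dictionary")
        self.aliases = {a.lower(): targets for a, targets in aliases.items()}
        ordered = sorted(self.aliases, key=len, reverse=True)
        pattern = "|".join(re.escape(a) for a in ordered)
        self.rx = re.compile(rf"(?<!\w)(?:{pattern})(?!\w)", re.IGNORECASE)

    def find(self, text: str) -> set:
        """All targets of aliases matched in *text*."""
        hits = set()
        for m in self.rx.finditer(text):
            hits |= set(self.aliases[m.group(0).lower()])
        return hits

    def find_aliases(self, text: str) -> set[str]:
        """Matched alias keys (lowercased)."""
        return {m.group(0).lower() for m in self.rx.finditer(text)}


def count_comentions(
    corpus: list[tuple[str, list[str]]],
    gene_names: dict[str, set[tuple[str, str]]],
    tissue_names: dict[str, set[str]],
    organisms: dict[str, list[str]] | None = None,
    w_sentence: float = W_SENTENCE,
    w_abstract: float = W_ABSTRACT,
) -> dict[str, CoMentionCounts]:
    """Count weighted gene-tissue co-mentions per organism.

    *gene_names* maps alias -> set of (organism, gene id); *tissue_names*
    maps alias -> set of tissue term ids; *organisms* maps organism label ->
    list of species names for explicit-mention disambiguation.

    Per document: a (gene, tissue) pair co-mentioned in at least one common
    sentence adds ``w_sentence`` once; a pair co-mentioned in the document
    but never within a sentence adds ``w_abstract``.
    """
    if not gene_names or not tissue_names:
        raise ValidationError("empty dictionaries")
    gene_matcher = _Matcher(gene_names)
    tissue_matcher = _Matcher(tissue_names)
    org_matcher = (
        _Matcher({name: {org} for org, names in organisms.items() for name in names})
        if organisms
        else None
    )
    all_orgs = {org for targets in gene_names.values() for org, _ in targets}
    counts: dict[str, CoMentionCounts] = {
        org: CoMentionCounts(w_sentence=w_sentence, w_abstract=w_abstract)
        for org in sorted(all_orgs)
    }
    # alias -> organisms it names; an alias naming genes of a single organism
    # needs no explicit species mention to be attributed
    alias_orgs = {
        alias: {org for org, _ in targets}
        for alias, targets in gene_matcher.aliases.items()
    }

    for _doc_id, sentences in corpus:
        doc_text = " ".join(sentences)
        doc_orgs = org_matcher.find(doc_text) if org_matcher else set()

        doc_genes: set[tuple[str, str]] = set()
        doc_tissues: set[str] = set()
        sentence_pairs: set[tuple[tuple[str, str], str]] = set()
        for s in sentences:
            g_hits = {
                (org, gene)
                for alias in gene_matcher.find_aliases(s)
                for org, gene in gene_matcher.aliases[alias]
                if org in doc_orgs or len(alias_orgs[alias]) == 1
            }
            t_hits = tissue_matcher.find(s)
            doc_genes |= g_hits
            doc_tissues |= t_hits
            for g in g_hits:
                for t in t_hits:
                    sentence_pairs.add((g, t))
        for g in doc_genes:
            for t in doc_tissues:
                w = w_sentence if (g, t) in sentence_pairs else w_abstract
                org, gene = g
                cc = counts[org]
                cc.C[(gene, t)] = cc.C.get((gene, t), 0.0) + w
    return counts


def cooccurrence_score(
    counts: CoMentionCounts, alpha: float = ALPHA
) -> list[tuple[str, str, float]]:
    """Score pairs as s = C^alpha * (C * C_total / (C_gene * C_tissue))^(1-alpha).

    alpha = 1 reduces to the raw weighted counts; lower alpha weights the
    normalization by how often the gene and tissue are mentioned with other
    partners. Pairs with zero count are omitted.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [0, 1]")
    cg = counts.C_gene
    ct = counts.C_tissue
    total = counts.C_total
    out = []
    for (g, t), c in sorted(counts.C.items()):
        if c == 0:
            continue
        s = c**alpha * (c * total / (cg[g] * ct[t])) ** (1.0 - alpha)
        out.append((g, t, float(s)))
    return out


def textmining_channel(
    counts: CoMentionCounts, organism: str, alpha: float = ALPHA
) -> ScoredChannel:
    """Wrap co-occurrence scores as a textmining evidence channel.

    Raw value and confidence are both the co-occurrence score s, so the
    channel can serve as the calibration reference.
    """
    assocs = [
        Association(gene=g, tissue=t, raw=s, confidence=s)
        for g, t, s in cooccurrence_score(counts, alpha=alpha)
    ]
    return ScoredChannel(channel="textmining", organism=organism, associations=assocs)
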