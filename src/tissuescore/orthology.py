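"""1:1 ortholog extraction from orthologous groups and cross-organism
transfer of gold-standard annotations.

Only strict 1:1 relationships are used: a group contributes a pair exactly
when it holds one gene of each organism. A gene appearing in several groups
would make its pairing ambiguous, so all pairs involving it are voided
(conservative) and counted. When several group sources are supplied (e.g. a
rodent-level file and a mammal-level file) the first source that yields a
pair for a gene wins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import ValidationError
from .io_formats import GoldStandard, OrthologGroups


@dataclass
class OrthologMap:
    """Bijective cross-organism gene pairing."""

    org_a: str
    org_b: str
    pairs: frozenset[tuple[str, str]]
    n_voided: int = 0

    def __post_init__(self) -> None:
        self.pairs = frozenset(self.pairs)
        a_genes = [a for a, _ in self.pairs]
        b_genes = [b for _, b in self.pairs]
        if len(set(a_genes)) != len(a_genes) or len(set(b_genes)) != len(b_genes):
            raise ValidationError("ortholog map is not a bijection")

    def __len__(self) -> int:
        return len(self.pairs)

    def forward(self) -> dict[str, str]:
        return {a: b for a, b in self.pairs}

    def backward(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}

    def reversed(self) -> "OrthologMap":
        return OrthologMap(
            org_a=self.org_b,
            org_b=self.org_a,
            pairs=frozenset((b, a) for a, b in self.pairs),
            n_voided=self.n_voided,
        )


def one_to_one_pairs(
    groups: OrthologGroups | list[OrthologGroups], org_a: str, org_b: str
) -> OrthologMap:
    """Extract 1:1 ortholog pairs between two organisms.

    A group contributes (geneA, geneB) iff it contains exactly one gene of
    each organism. Genes drawn into more than one candidate pair (multi-group
    membership) have all their pairs discarded and counted in ``n_voided``.
    A list of group sources is treated as an ordered precedence list: a gene
    paired by an earlier source is ignored in later sources.
    """
    if org_a == org_b:
        raise ValidationError("org_a and org_b must differ")
    sources = groups if isinstance(groups, list) else [groups]

    final: set[tuple[str, str]] = set()
    claimed_a: set[str] = set()
    claimed_b: set[str] = set()
    n_voided = 0
    for source in sources:
        candidates: list[tuple[str, str]] = []
        for _gid, members in source.groups:
            a_genes = [g for org, g in members if org == org_a]
            b_genes = [g for org, g in members if org == org_b]
            if len(a_genes) == 1 and len(b_genes) == 1:
                candidates.append((a_genes[0], b_genes[0]))
        count_a = Counter(a for a, _ in candidates)
        count_b = Counter(b for _, b in candidates)
        kept = [(a, b) for a, b in candidates if count_a[a] == 1 and count_b[b] == 1]
        n_voided += len(candidates) - len(kept)
        for a, b in kept:
            # earlier sources take precedence for genes they already paired
            if a in claimed_a or b in claimed_b:
                continue
            final.add((a, b))
            claimed_a.add(a)
            claimed_b.add(b)
    return OrthologMap(
        org_a=org_a, org_b=org_b, pairs=frozenset(final), n_voided=n_voided
    )


def one_to_one_across(
    groups: OrthologGroups, orgs: list[str]
) -> set[tuple[str, ...]]:
    """Gene tuples from groups holding exactly one gene of each organism.

    Tuples follow the order of *orgs*. Genes appearing in several qualifying
    groups void all their tuples (same conservative rule as the pairwise
    extraction).
    """
    if len(orgs) < 2:
        raise ValidationError("need at least two organisms")
    if len(set(orgs)) != len(orgs):
        raise ValidationError("duplicate organism in list")
    candidates: list[tuple[str, ...]] = []
    for _gid, members in groups.groups:
        per_org: dict[str, list[str]] = {o: [] for o in orgs}
        for org, gene in members:
            if org in per_org:
                per_org[org].append(gene)
        if all(len(per_org[o]) == 1 for o in orgs):
            candidates.append(tuple(per_org[o][0] for o in orgs))
    # void tuples sharing any (organism, gene) slot
    seen: dict[tuple[int, str], int] = {}
    bad: set[int] = set()
    for i, tup in enumerate(candidates):
        for slot, gene in enumerate(tup):
            key = (slot, gene)
            if key in seen:
                bad.add(i)
                bad.add(seen[key])
            else:
                seen[key] = i
    return {t for i, t in enumerate(candidates) if i not in bad}


def transfer_gold_standard(gs: GoldStandard, omap: OrthologMap) -> GoldStandard:
    """Transfer (gene, tissue) annotations to the map's target organism.

    Pairs whose gene is not in the map are dropped and counted; tissue terms
    are preserved verbatim.
    """
    if not omap.pairs:
        raise ValidationError("ortholog map is empty")
    if gs.organism != omap.org_a:
        raise ValidationError(
            f"gold standard is for {gs.organism!r} but map source is {omap.org_a!r}"
        )
    fwd = omap.forward()
    out: set[tuple[str, str]] = set()
    dropped = 0
    for gene, tissue in gs.pairs:
        mapped = fwd.get(gene)
        if mapped is None:
            dropped += 1
        else:
            out.add((mapped, tissue))
    if not out:
        raise ValidationError("no gold-standard pairs survived orthology transfer")
    return GoldStandard(
        organism=omap.org_b,
        pairs=frozenset(out),
        source="orthology-transferred",
        n_dropped=dropped,
    )


def classify_homologs(
    groups: OrthologGroups, query: tuple[str, str]
) -> list[tuple[str, str, str]]:
    """Co-members of the query's group(s) as (gene, organism, relation).

    Same-organism co-members are paralogs, other-organism co-members
    orthologs. A gene in no group yields an empty list.
    """
    q_org, q_gene = query
    out: dict[tuple[str, str], str] = {}
    for _gid, members in groups.groups:
        if (q_org, q_gene) not in members:
            continue
        for org, gene in members:
            if (org, gene) == (q_org, q_gene):
                continue
            out[(gene, org)] = "paralog" if org == q_org else "ortholog"
    return [(g, o, rel) for (g, o), rel in sorted(out.items())]
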