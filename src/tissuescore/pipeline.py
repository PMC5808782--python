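"""End-to-end pipeline: simulate -> ingest -> gold-standard transfer ->
benchmark -> fit -> score -> calibrate -> propagate -> integrate ->
correlate/ROC, with every intermediate written in the documented TSV/JSON
dialects so any stage can be rerun from disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import io_formats as iof
from . import ontology as onto_mod
from . import scoring, synthetic, textmining
from .benchmark import correlation_matrix, roc_against_gold
from .errors import TissueScoreError, ValidationError
from .orthology import one_to_one_pairs, transfer_gold_standard
from .scoring import Association, ScoredChannel

log = logging.getLogger("tissuescore")


@dataclass
class DatasetSpec:
    dataset_id: str
    organism: str
    mu_on: float = 3.0
    mu_off: float = 0.0
    sigma: float = 1.0

    def quality(self) -> synthetic.DatasetQuality:
        return synthetic.DatasetQuality(
            mu_on=self.mu_on, mu_off=self.mu_off, sigma=self.sigma
        )


@dataclass
class RunConfig:
    """Flat, file-round-trippable pipeline configuration."""

    outdir: str = "run"
    seed: int = 0
    organisms: tuple[str, ...] = ("human", "mouse")
    n_genes: int = 200
    n_tissues: int = 8
    prevalence: float = 0.3
    ortholog_coverage: float = 0.8
    gs_coverage: float = 0.5
    non11_fraction: float = 0.1
    divergence: float = 0.0
    datasets: list[DatasetSpec] = field(default_factory=list)
    window: int = 100
    step: int = 0  # 0 -> non-overlapping (step = window)
    anchors: list[tuple[float, float]] = field(
        default_factory=lambda: [list(a) for a in scoring.DEFAULT_ANCHORS]
    )
    alpha: float = textmining.ALPHA
    w_sentence: float = textmining.W_SENTENCE
    w_abstract: float = textmining.W_ABSTRACT
    n_docs: int = 300
    knowledge_stars: float = 4.0
    roc_tissues: list[str] = field(default_factory=list)  # empty -> first 4 majors

    def __post_init__(self) -> None:
        self.organisms = tuple(self.organisms)
        self.datasets = [
            d if isinstance(d, DatasetSpec) else DatasetSpec(**d) for d in self.datasets
        ]
        if not self.datasets:
            self.datasets = [
                DatasetSpec(dataset_id=f"{org}-hi", organism=org) for org in self.organisms
            ]
        for d in self.datasets:
            if d.organism not in self.organisms:
                raise ValidationError(
                    f"dataset {d.dataset_id!r} references unknown organism {d.organism!r}"
                )

    def world_params(self) -> synthetic.WorldParams:
        return synthetic.WorldParams(
            organisms=self.organisms,
            n_genes=self.n_genes,
            n_tissues=self.n_tissues,
            prevalence=self.prevalence,
            ortholog_coverage=self.ortholog_coverage,
            gs_coverage=self.gs_coverage,
            non11_fraction=self.non11_fraction,
            divergence=self.divergence,
            seed=self.seed,
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**payload)

    def to_file(self, path) -> None:
        payload = asdict(self)
        payload["organisms"] = list(self.organisms)
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def _dirs(cfg: RunConfig) -> dict[str, Path]:
    out = Path(cfg.outdir)
    dirs = {
        name: out / name
        for name in ("world", "gs", "curves", "fits", "channels", "results")
    }
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)
    return dirs


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> synthetic.World:
    """Generate the synthetic world and write every fixture file."""
    d = _dirs(cfg)
    world = synthetic.simulate_world(cfg.world_params())
    iof.write_ontology_obo(world.ontology, d["world"] / "ontology.obo")
    iof.write_orthogroups(world.groups, d["world"] / "orthogroups.tsv")
    for k, spec in enumerate(cfg.datasets):
        ds = synthetic.simulate_dataset(
            world,
            spec.organism,
            spec.quality(),
            seed=cfg.seed * 1000 + 17 * k + 1,
            dataset_id=spec.dataset_id,
        )
        iof.write_expression_matrix(ds, d["world"] / f"{spec.dataset_id}.tsv")
    ref = cfg.organisms[0]
    gs = synthetic.simulate_gold_standard(
        world, ref, coverage=cfg.gs_coverage, seed=cfg.seed * 1000 + 911
    )
    iof.write_annotation_pairs(gs, d["gs"] / f"{ref}.curated.tsv")
    corpus = synthetic.simulate_corpus(
        world, ref, n_docs=cfg.n_docs, seed=cfg.seed * 1000 + 523
    )
    iof.write_corpus(corpus, d["world"] / "corpus.tsv")
    # dictionaries for text mining (names are the synthetic ids themselves)
    with (d["world"] / "gene_names.tsv").open("w", encoding="utf-8") as fh:
        for alias in sorted(world.gene_names):
            for org, gene in sorted(world.gene_names[alias]):
                fh.write(f"{alias}\t{org}\t{gene}\n")
    with (d["world"] / "tissue_names.tsv").open("w", encoding="utf-8") as fh:
        for alias in sorted(world.tissue_names):
            for term in sorted(world.tissue_names[alias]):
                fh.write(f"{alias}\t{term}\n")
    return world


def _load_world_files(cfg: RunConfig):
    d = _dirs(cfg)
    onto = iof.read_ontology_obo(d["world"] / "ontology.obo")
    major = {t for t in onto.terms if onto.parents.get(t)}  # non-root terms
    onto = onto.with_major_tissues(major)
    taxid_to_org = {v: k for k, v in synthetic.SYNTH_TAXIDS.items()}
    groups = iof.read_orthogroups(d["world"] / "orthogroups.tsv", taxa=taxid_to_org)
    datasets = {
        spec.dataset_id: iof.read_expression_matrix(
            d["world"] / f"{spec.dataset_id}.tsv",
            dataset_id=spec.dataset_id,
            organism=spec.organism,
        )
        for spec in cfg.datasets
    }
    return onto, groups, datasets


def stage_transfer_gs(cfg: RunConfig) -> dict[str, iof.GoldStandard]:
    """Read the reference gold standard and transfer it to every other organism."""
    d = _dirs(cfg)
    ref = cfg.organisms[0]
    gs_ref = iof.read_annotation_pairs(
        d["gs"] / f"{ref}.curated.tsv", organism=ref, source="synthetic"
    )
    _onto, groups, _ = _load_world_files(cfg)
    out = {ref: gs_ref}
    for org in cfg.organisms[1:]:
        omap = one_to_one_pairs(groups, ref, org)
        gs_t = transfer_gold_standard(gs_ref, omap)
        iof.write_annotation_pairs(gs_t, d["gs"] / f"{org}.transferred.tsv")
        log.info("transferred gs to %s: %d pairs (%d dropped)", org, len(gs_t), gs_t.n_dropped)
        out[org] = gs_t
    return out


def _load_gold_standards(cfg: RunConfig) -> dict[str, iof.GoldStandard]:
    d = _dirs(cfg)
    ref = cfg.organisms[0]
    out = {
        ref: iof.read_annotation_pairs(
            d["gs"] / f"{ref}.curated.tsv", organism=ref, source="synthetic"
        )
    }
    for org in cfg.organisms[1:]:
        out[org] = iof.read_annotation_pairs(
            d["gs"] / f"{org}.transferred.tsv",
            organism=org,
            source="orthology-transferred",
        )
    return out


def stage_textmining(cfg: RunConfig) -> ScoredChannel:
    """Score the toy corpus and write the reference text-mining channel."""
    d = _dirs(cfg)
    corpus = iof.read_corpus(d["world"] / "corpus.tsv")
    gene_names: dict[str, set[tuple[str, str]]] = {}
    for line in (d["world"] / "gene_names.tsv").read_text(encoding="utf-8").splitlines():
        alias, org, gene = line.split("\t")
        gene_names.setdefault(alias, set()).add((org, gene))
    tissue_names: dict[str, set[str]] = {}
    for line in (d["world"] / "tissue_names.tsv").read_text(encoding="utf-8").splitlines():
        alias, term = line.split("\t")
        tissue_names.setdefault(alias, set()).add(term)
    ref = cfg.organisms[0]
    counts = textmining.count_comentions(
        corpus,
        gene_names,
        tissue_names,
        w_sentence=cfg.w_sentence,
        w_abstract=cfg.w_abstract,
    )[ref]
    ch = textmining.textmining_channel(counts, organism=ref, alpha=cfg.alpha)
    iof.write_channel(ch, d["channels"] / f"textmining.{ref}.tsv")
    return ch


def stage_benchmark_fit_score(cfg: RunConfig) -> dict[str, ScoredChannel]:
    """Per dataset: enrichment curve -> sigmoid fit -> confidence channel."""
    d = _dirs(cfg)
    _onto, _groups, datasets = _load_world_files(cfg)
    golds = _load_gold_standards(cfg)
    out: dict[str, ScoredChannel] = {}
    for spec in cfg.datasets:
        ds = datasets[spec.dataset_id]
        gs = golds[spec.organism]
        step = cfg.step or cfg.window
        curve = scoring.fold_enrichment_curve(ds, gs, window=cfg.window, step=step)
        iof.write_curve(curve, d["curves"] / f"{spec.dataset_id}.tsv")
        fit = scoring.fit_sigmoid(curve)
        iof.write_fit(fit, d["fits"] / f"{spec.dataset_id}.json")
        ch = scoring.score_dataset(ds, fit)
        iof.write_channel(ch, d["channels"] / f"experiments.{spec.dataset_id}.tsv")
        out[spec.dataset_id] = ch
    return out


def stage_calibrate(cfg: RunConfig) -> scoring.CalibrationFunction:
    """Build the single calibration from the text-mining reference channel,
    then star every confidence-bearing channel (negative scores dropped)."""
    d = _dirs(cfg)
    ref = cfg.organisms[0]
    reference = iof.read_channel(d["channels"] / f"textmining.{ref}.tsv", organism=ref)
    anchors = tuple((float(q), float(s)) for q, s in cfg.anchors)
    cal = scoring.calibrate_stars(reference, anchors=anchors)
    iof.write_calibration(cal, d["results"] / "calibration.json")
    starred = scoring.apply_stars(reference, cal)
    iof.write_channel(starred, d["channels"] / f"textmining.{ref}.starred.tsv")
    for spec in cfg.datasets:
        ch = iof.read_channel(
            d["channels"] / f"experiments.{spec.dataset_id}.tsv", organism=spec.organism
        )
        starred = scoring.apply_stars(ch, cal)
        iof.write_channel(
            starred, d["channels"] / f"experiments.{spec.dataset_id}.starred.tsv"
        )
    return cal


def stage_knowledge(cfg: RunConfig) -> dict[str, ScoredChannel]:
    """Knowledge channel: curated/transferred pairs at a fixed star level."""
    d = _dirs(cfg)
    golds = _load_gold_standards(cfg)
    out = {}
    for org, gs in golds.items():
        assocs = [
            Association(gene=g, tissue=t, stars=cfg.knowledge_stars)
            for g, t in sorted(gs.pairs)
        ]
        ch = ScoredChannel(channel="knowledge", organism=org, associations=assocs)
        iof.write_channel(ch, d["channels"] / f"knowledge.{org}.tsv")
        out[org] = ch
    return out


def stage_propagate_integrate(cfg: RunConfig) -> dict[str, ScoredChannel]:
    """Propagate starred channels up the ontology, restrict to the major set
    and integrate the channels of each organism (max stars per pair)."""
    d = _dirs(cfg)
    onto, _groups, _datasets = _load_world_files(cfg)
    ref = cfg.organisms[0]
    integrated: dict[str, ScoredChannel] = {}
    for org in cfg.organisms:
        members: list[ScoredChannel] = []
        kn_path = d["channels"] / f"knowledge.{org}.tsv"
        if kn_path.exists():
            members.append(iof.read_channel(kn_path, organism=org))
        if org == ref:
            tm = d["channels"] / f"textmining.{ref}.starred.tsv"
            if tm.exists():
                members.append(iof.read_channel(tm, organism=org))
        for spec in cfg.datasets:
            if spec.organism != org:
                continue
            members.append(
                iof.read_channel(
                    d["channels"] / f"experiments.{spec.dataset_id}.starred.tsv",
                    organism=org,
                )
            )
        members = [
            onto_mod.restrict_to_major(onto_mod.propagate_scores(m, onto), onto)
            for m in members
        ]
        # integrate_channels rejects duplicate pairs within a channel; multiple
        # experiments datasets are distinct ScoredChannel objects, so collapse
        # each before handing them over
        merged = scoring.integrate_channels(members)
        iof.write_channel(merged, d["channels"] / f"integrated.{org}.tsv")
        integrated[org] = merged
    return integrated


def stage_correlate_roc(cfg: RunConfig) -> dict:
    """Cross-dataset correlation matrix and per-dataset ROC against gold."""
    d = _dirs(cfg)
    onto, groups, _datasets = _load_world_files(cfg)
    golds = _load_gold_standards(cfg)
    channels = []
    labels = []
    for spec in cfg.datasets:
        channels.append(
            iof.read_channel(
                d["channels"] / f"experiments.{spec.dataset_id}.starred.tsv",
                organism=spec.organism,
            )
        )
        labels.append(spec.dataset_id)
    maps = {}
    for i, a in enumerate(cfg.organisms):
        for b in cfg.organisms[i + 1 :]:
            maps[(a, b)] = one_to_one_pairs(groups, a, b)
    report: dict = {"seed": cfg.seed, "datasets": {}, "auc": {}}
    if len(channels) >= 2:
        mat = correlation_matrix(channels, labels=labels, maps=maps)
        iof.write_matrix(mat, d["results"] / "correlations.tsv")
        report["correlations"] = {
            f"{labels[i]}|{labels[j]}": (None if mat.iloc[i, j] != mat.iloc[i, j] else float(mat.iloc[i, j]))
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        }
    roc_tissues = cfg.roc_tissues or sorted(onto.major_tissues)[: min(4, len(onto.major_tissues))]
    for spec, ch in zip(cfg.datasets, channels):
        roc = roc_against_gold(ch, golds[spec.organism], set(roc_tissues))
        iof.write_roc(roc, d["results"] / f"roc.{spec.dataset_id}.tsv")
        report["auc"][spec.dataset_id] = roc.auc
        report["datasets"][spec.dataset_id] = {
            "organism": spec.organism,
            "n_associations": len(ch),
        }
    (d["results"] / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns the final report dict."""
    stages = [
        ("simulate", stage_simulate),
        ("transfer-gs", stage_transfer_gs),
        ("textmining", stage_textmining),
        ("benchmark", stage_benchmark_fit_score),
        ("calibrate", stage_calibrate),
        ("knowledge", stage_knowledge),
        ("propagate-integrate", stage_propagate_integrate),
        ("correlate-roc", stage_correlate_roc),
    ]
    result = None
    for name, fn in stages:
        log.info("stage %s", name)
        try:
            result = fn(cfg)
        except TissueScoreError as exc:
            raise TissueScoreError(f"stage {name!r} failed: {exc}") from exc
    cfg.to_file(Path(cfg.outdir) / "config.json")
    return result  # type: ignore[return-value]
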