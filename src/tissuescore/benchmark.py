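"""Agreement between scored datasets (Pearson correlations, within and
across organisms) and against the gold standard (ROC curves).

Correlation vectors are built over the common genes (genes expressed in at
least one tissue in each channel, matched through 1:1 orthologs across
organisms) and common tissues; a pair absent from one channel contributes a
zero star score by default (``mode='zero_fill'``), or is dropped with
``mode='intersect'``. Negative-score associations are expected to have been
filtered already by calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedCorrelationError, ValidationError
from .io_formats import GoldStandard
from .orthology import OrthologMap
from .scoring import ScoredChannel

#: Benchmark tissues used for ROC curves by default (term names; callers
#: supply term ids matching their ontology).
DEFAULT_ROC_TISSUE_NAMES = ("nervous system", "liver", "heart", "kidney")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 3:
        raise UndefinedCorrelationError(
            f"need at least 3 paired observations, got {x.size}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    return float(np.corrcoef(x, y)[0, 1])


def _common_universe(
    a: ScoredChannel,
    b: ScoredChannel,
    omap: OrthologMap | None,
    tissues: set[str] | None = None,
):
    """Shared (geneA, geneB) pairs and shared tissues of two channels."""
    tis_a, tis_b = a.tissues(), b.tissues()
    common_t = tis_a & tis_b
    if tissues is not None:
        common_t &= tissues
    if not common_t:
        raise ValidationError("channels share no tissues")
    genes_a, genes_b = a.genes(), b.genes()
    if omap is None:
        if a.organism != b.organism:
            raise ValidationError(
                "channels from different organisms require an ortholog map"
            )
        gene_pairs = [(g, g) for g in sorted(genes_a & genes_b)]
    else:
        if (omap.org_a, omap.org_b) == (b.organism, a.organism):
            omap = omap.reversed()
        if (omap.org_a, omap.org_b) != (a.organism, b.organism):
            raise ValidationError(
                f"ortholog map {omap.org_a}->{omap.org_b} does not link "
                f"{a.organism} and {b.organism}"
            )
        gene_pairs = sorted(
            (ga, gb) for ga, gb in omap.pairs if ga in genes_a and gb in genes_b
        )
    if not gene_pairs:
        raise ValidationError("channels share no genes")
    return gene_pairs, sorted(common_t)


def dataset_correlation(
    a: ScoredChannel,
    b: ScoredChannel,
    omap: OrthologMap | None = None,
    mode: str = "zero_fill",
    tissues: set[str] | None = None,
) -> float:
    """Pearson r between the star scores of two channels.

    Vectors run over (common gene x common tissue); with ``zero_fill`` a pair
    absent from one channel scores 0 there, with ``intersect`` only pairs
    present in both channels are compared.
    """
    if mode not in ("zero_fill", "intersect"):
        raise ValidationError(f"unknown mode {mode!r}")
    gene_pairs, common_t = _common_universe(a, b, omap, tissues)
    sa, sb = a.star_map(), b.star_map()
    xs, ys = [], []
    for ga, gb in gene_pairs:
        for t in common_t:
            va = sa.get((ga, t))
            vb = sb.get((gb, t))
            if mode == "intersect" and (va is None or vb is None):
                continue
            xs.append(va if va is not None else 0.0)
            ys.append(vb if vb is not None else 0.0)
    return _pearson(np.array(xs), np.array(ys))


def correlation_matrix(
    channels: list[ScoredChannel],
    labels: list[str] | None = None,
    maps: dict[tuple[str, str], OrthologMap] | None = None,
    mode: str = "zero_fill",
) -> pd.DataFrame:
    """Symmetric matrix of pairwise dataset correlations (diagonal = 1).

    Cross-organism cells use the ortholog map registered for the organism
    pair (either orientation). Cells whose correlation is undefined are NaN.
    """
    if len(channels) < 2:
        raise ValidationError("need at least two channels")
    if labels is None:
        labels = [f"{c.organism}:{c.channel}:{i}" for i, c in enumerate(channels)]
    maps = maps or {}
    n = len(channels)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = channels[i], channels[j]
            omap = None
            if a.organism != b.organism:
                omap = maps.get((a.organism, b.organism)) or maps.get(
                    (b.organism, a.organism)
                )
            try:
                r = dataset_correlation(a, b, omap=omap, mode=mode)
            except (UndefinedCorrelationError, ValidationError):
                r = np.nan
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=labels, columns=labels)


def per_tissue_correlation(
    a: ScoredChannel,
    b: ScoredChannel,
    tissue: str,
    omap: OrthologMap | None = None,
    mode: str = "zero_fill",
) -> float:
    """Correlation restricted to a single tissue column."""
    if tissue not in a.tissues():
        raise ValidationError(f"tissue {tissue!r} absent from channel a")
    if tissue not in b.tissues():
        raise ValidationError(f"tissue {tissue!r} absent from channel b")
    return dataset_correlation(a, b, omap=omap, mode=mode, tissues={tissue})


@dataclass
class ROCResult:
    """ROC points ordered from the strictest to the loosest threshold."""

    points: list[tuple[float, float, float]]  # (threshold, TPR, FPR)
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0 + 1e-12):
            raise ValidationError(f"auc out of range: {self.auc}")


def roc_against_gold(
    ch: ScoredChannel, gs: GoldStandard, tissues: set[str]
) -> ROCResult:
    """ROC of a channel's star scores against the gold standard.

    Positives are gold-standard pairs restricted to genes shared between the
    channel and the gold standard and to the given benchmark tissues;
    negatives are the remaining (shared gene x tissue) pairs. Gold-standard
    incompleteness makes the FPR an upper bound. Pairs absent from the
    channel score 0; tied scores move together (one threshold point).
    """
    if not tissues:
        raise ValidationError("benchmark tissue set is empty")
    shared_genes = sorted(ch.genes() & gs.genes())
    if not shared_genes:
        raise ValidationError("no genes shared with the gold standard")
    tlist = sorted(tissues)
    stars = ch.star_map()
    labels, scores = [], []
    for g in shared_genes:
        for t in tlist:
            labels.append((g, t) in gs.pairs)
            scores.append(stars.get((g, t), 0.0))
    labels_arr = np.array(labels, dtype=bool)
    scores_arr = np.array(scores, dtype=float)
    n_pos = int(labels_arr.sum())
    n_neg = int((~labels_arr).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"need both positives and negatives (got {n_pos} / {n_neg})"
        )

    order = np.argsort(-scores_arr, kind="stable")
    sorted_scores = scores_arr[order]
    sorted_labels = labels_arr[order]
    points: list[tuple[float, float, float]] = [(math.inf, 0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = sorted_scores.size
    while i < n:
        thr = sorted_scores[i]
        j = i
        while j < n and sorted_scores[j] == thr:
            tp += bool(sorted_labels[j])
            fp += not sorted_labels[j]
            j += 1
        points.append((float(thr), tp / n_pos, fp / n_neg))
        i = j
    fprs = np.array([p[2] for p in points])
    tprs = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tprs, fprs))
    return ROCResult(points=points, auc=auc)


def homolog_profile_correlation(
    query: dict[str, float],
    other: dict[str, float],
    major_tissues: list[str] | set[str],
) -> float:
    """Pearson r between two gene profiles over the major-tissue list.

    Profiles map tissue term -> integrated star score; missing tissues score
    0. Requires at least 3 major tissues with a score in either profile.
    """
    tlist = sorted(major_tissues)
    usable = [t for t in tlist if t in query or t in other]
    if len(usable) < 3:
        raise UndefinedCorrelationError(
            f"only {len(usable)} usable tissues; need at least 3"
        )
    x = np.array([query.get(t, 0.0) for t in tlist])
    y = np.array([other.get(t, 0.0) for t in tlist])
    return _pearson(x, y)
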