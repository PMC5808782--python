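"""Core scoring method: fold-enrichment curves against a gold standard,
sigmoid fitting, confidence scores, star calibration and channel integration.

The central quantity is fold enrichment: the fraction of a score-sorted
window's gene-tissue pairs found in the gold standard, divided by the
fraction expected when sampling genes and tissues at random. A sigmoid fitted
to (raw expression, fold enrichment) turns raw values into confidence scores;
a single monotone calibration function then maps confidences onto a common
0-5 star scale shared by every evidence channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ValidationError

CHANNELS = ("knowledge", "experiments", "textmining", "integrated")
STAR_MAX = 5.0

#: Default calibration anchors: (confidence quantile, stars). The reference
#: channel's median confidence maps to 2 stars, its extremes to 0 and 5.
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (0.5, 2.0),
    (1.0, STAR_MAX),
)


@dataclass(frozen=True)
class Association:
    """One gene-tissue association with its evidence scores.

    ``raw`` is the platform-specific expression value (None when not
    applicable, e.g. curated evidence), ``confidence`` the fold-enrichment
    scale score, ``stars`` the calibrated 0-5 score.
    """

    gene: str
    tissue: str
    raw: float | None = None
    confidence: float | None = None
    stars: float | None = None

    def score_key(self) -> float:
        """Score used for propagation/ordering: stars, else confidence, else raw."""
        for v in (self.stars, self.confidence, self.raw):
            if v is not None:
                return v
        return float("-inf")


@dataclass
class ScoredChannel:
    """A set of scored associations from one evidence channel of one organism."""

    channel: str
    organism: str
    associations: list[Association] = field(default_factory=list)
    #: for integrated channels: (gene, tissue) -> contributing channel names
    sources: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValidationError(
                f"unknown channel {self.channel!r}; expected one of {CHANNELS}"
            )

    def __len__(self) -> int:
        return len(self.associations)

    def genes(self) -> set[str]:
        return {a.gene for a in self.associations}

    def tissues(self) -> set[str]:
        return {a.tissue for a in self.associations}

    def star_map(self) -> dict[tuple[str, str], float]:
        """(gene, tissue) -> stars; raises on duplicates within the channel."""
        out: dict[tuple[str, str], float] = {}
        for a in self.associations:
            key = (a.gene, a.tissue)
            if key in out:
                raise ValidationError(
                    f"duplicate association {key} in channel {self.channel!r}"
                )
            out[key] = a.stars if a.stars is not None else 0.0
        return out


@dataclass(frozen=True)
class EnrichmentBin:
    x: float  # mean raw expression of the bin's pairs
    e: float  # fold enrichment of the bin
    n: int  # pairs in bin


@dataclass
class EnrichmentCurve:
    bins: list[EnrichmentBin]
    window: int
    step: int

    def __post_init__(self) -> None:
        for b in self.bins:
            if not math.isfinite(b.x) or b.x < 0:
                raise ValidationError(f"bin mean expression must be finite >= 0, got {b.x}")
            if b.e < 0:
                raise ValidationError(f"fold enrichment must be >= 0, got {b.e}")

    @property
    def x(self) -> np.ndarray:
        return np.array([b.x for b in self.bins])

    @property
    def e(self) -> np.ndarray:
        return np.array([b.e for b in self.bins])


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted sigmoid on the log10-expression axis.

    score(x) = a0 + (a1 - a0) / (1 + exp(-a2 * (log10 x - a3)))

    a0/a1 are the lower/upper asymptotes in fold-enrichment units, a2 the
    slope and a3 the midpoint in log10 raw-expression units.
    """

    a0: float
    a1: float
    a2: float
    a3: float
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if self.a1 < self.a0:
            raise ValidationError("sigmoid requires a1 >= a0")
        if self.a2 < 0:
            raise ValidationError("sigmoid requires a2 >= 0")


def eval_sigmoid(fit: SigmoidFit, x) -> float | np.ndarray:
    """Evaluate the fitted sigmoid at raw expression x (> 0).

    Total for x > 0: at the midpoint x = 10**a3 the value is (a0 + a1) / 2,
    and the output is bounded in [a0, a1].
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("eval_sigmoid requires x > 0 (apply a pseudo-floor first)")
    z = -fit.a2 * (np.log10(x) - fit.a3)
    # expit-style stable logistic
    out = fit.a0 + (fit.a1 - fit.a0) / (1.0 + np.exp(np.clip(z, -700, 700)))
    return float(out) if out.ndim == 0 else out


def expected_fraction(gs, genes: set[str], tissues: set[str]) -> float:
    """Fraction of the genes x tissues grid annotated in the gold standard."""
    if not genes or not tissues:
        raise ValidationError("gene and tissue universes must be non-empty")
    restricted = sum(1 for (g, t) in gs.pairs if g in genes and t in tissues)
    if restricted == 0:
        raise ValidationError(
            "no gold-standard pairs within the dataset universe; cannot benchmark"
        )
    return restricted / (len(genes) * len(tissues))


def fold_enrichment_curve(
    ds,
    gs,
    window: int = 100,
    step: int | None = None,
    tissues: set[str] | None = None,
) -> EnrichmentCurve:
    """Benchmark a dataset against a gold standard in expression-sorted windows.

    Restricts to genes shared between the dataset and the gold standard (and
    to *tissues* if given, else to tissues present in both), sorts all
    gene-tissue pairs by descending raw value, and computes fold enrichment
    per window of *window* pairs advanced by *step* (default: non-overlapping,
    step = window). Ties in raw value are broken by (gene, tissue) lexicographic
    order so the curve is deterministic and row-order independent.
    """
    if step is None:
        step = window
    if window < 1 or step < 1:
        raise ValidationError("window and step must be >= 1")

    gs_genes = {g for g, _ in gs.pairs}
    gs_tissues = {t for _, t in gs.pairs}
    genes = sorted(set(ds.genes) & gs_genes)
    tset = set(ds.tissues) & (set(tissues) if tissues is not None else gs_tissues)
    tlist = sorted(tset)
    if not genes or not tlist:
        raise ValidationError("no genes/tissues in common with the gold standard")

    exp_frac = expected_fraction(gs, set(genes), tset)

    sub = ds.values.loc[genes, tlist]
    raw = sub.to_numpy(dtype=float).ravel()
    pair_genes = np.repeat(np.array(genes, dtype=object), len(tlist))
    pair_tissues = np.tile(np.array(tlist, dtype=object), len(genes))
    n = raw.size
    if n < window:
        raise ValidationError(
            f"only {n} gene-tissue pairs but window={window}; use a smaller window"
        )

    order = np.lexsort((pair_tissues, pair_genes, -raw))
    raw = raw[order]
    in_gs = np.fromiter(
        ((g, t) in gs.pairs for g, t in zip(pair_genes[order], pair_tissues[order])),
        dtype=bool,
        count=n,
    )

    bins = []
    for start in range(0, n - window + 1, step):
        sl = slice(start, start + window)
        hits = int(in_gs[sl].sum())
        e = (hits / window) / exp_frac
        bins.append(EnrichmentBin(x=float(raw[sl].mean()), e=float(e), n=window))
    return EnrichmentCurve(bins=bins, window=window, step=step)


def _sigmoid_residuals(theta, lx, e):
    a0, d, a2, a3 = theta
    z = np.clip(-a2 * (lx - a3), -700, 700)
    return a0 + d / (1.0 + np.exp(z)) - e


def fit_sigmoid(
    curve: EnrichmentCurve,
    pseudo_floor: float | None = None,
) -> SigmoidFit:
    """Least-squares fit of the sigmoid to (log10 x, e) bin points.

    Constrained to a1 >= a0 >= 0 and a2 >= 0 (parametrized via d = a1 - a0).
    Multi-start initialization: a3 over deciles of the log10 x range crossed
    with a2 in {0.5, 1, 2}. Unweighted residuals; best run by RSS wins.
    """
    if len(curve.bins) < 4:
        raise ValidationError("need at least 4 bins to fit 4 parameters")
    x = curve.x
    if pseudo_floor is None:
        pos = x[x > 0]
        pseudo_floor = float(pos.min()) * 0.5 if pos.size else 1e-12
    lx = np.log10(np.maximum(x, pseudo_floor))
    e = curve.e

    e_lo, e_hi = float(e.min()), float(e.max())
    a0_init = max(e_lo, 0.0)
    d_init = max(e_hi - e_lo, 1e-6)
    lo, hi = float(lx.min()), float(lx.max())
    a3_grid = np.linspace(lo, hi, 10) if hi > lo else np.array([lo])

    best = None
    best_rss = np.inf
    for a3_0 in a3_grid:
        for a2_0 in (0.5, 1.0, 2.0):
            try:
                res = least_squares(
                    _sigmoid_residuals,
                    x0=[a0_init, d_init, a2_0, a3_0],
                    bounds=([0.0, 0.0, 0.0, -np.inf], [np.inf] * 4),
                    args=(lx, e),
                    method="trf",
                )
            except Exception:
                continue
            rss = float(2 * res.cost)
            if rss < best_rss:
                best_rss = rss
                best = res.x
    if best is None:
        raise FitError("sigmoid fit failed for every initialization")
    a0, d, a2, a3 = (float(v) for v in best)
    return SigmoidFit(a0=a0, a1=a0 + d, a2=a2, a3=a3, rss=best_rss)


def score_dataset(
    ds, fit: SigmoidFit, channel: str = "experiments", pseudo_floor: float | None = None
) -> ScoredChannel:
    """Assign confidence = sigmoid(raw) to every gene-tissue pair of a dataset.

    Zero raw values are lifted to a pseudo-floor (half the smallest positive
    value in the dataset by default) before the log10 transform. No filtering
    happens here; star calibration and negative-score removal come later.
    """
    values = ds.values.to_numpy(dtype=float)
    if pseudo_floor is None:
        pos = values[values > 0]
        pseudo_floor = float(pos.min()) * 0.5 if pos.size else 1e-12
    assocs = []
    for i, gene in enumerate(ds.genes):
        for j, tissue in enumerate(ds.tissues):
            raw = float(values[i, j])
            conf = eval_sigmoid(fit, max(raw, pseudo_floor))
            assocs.append(
                Association(gene=gene, tissue=tissue, raw=raw, confidence=conf)
            )
    return ScoredChannel(channel=channel, organism=ds.organism, associations=assocs)


@dataclass
class CalibrationFunction:
    """Monotone piecewise-linear confidence -> stars map.

    Linear between breakpoints; linearly extrapolated beyond the outermost
    breakpoints using the nearest segment of nonzero width (a confidence below
    the lowest anchor can therefore map to a negative pre-clamp score, which
    marks the association for removal). Evaluation clamps to [0, star_max]
    only after the negative-filter decision, so call sites use
    :meth:`pre_clamp` + clamp.
    """

    breakpoints: list[tuple[float, float]]
    star_max: float = STAR_MAX

    def __post_init__(self) -> None:
        confs = [c for c, _ in self.breakpoints]
        stars = [s for _, s in self.breakpoints]
        if len(self.breakpoints) < 1:
            raise ValidationError("calibration needs at least one breakpoint")
        if any(c2 < c1 for c1, c2 in zip(confs, confs[1:])):
            raise ValidationError("breakpoint confidences must be non-decreasing")
        if any(s2 < s1 for s1, s2 in zip(stars, stars[1:])):
            raise ValidationError("breakpoint stars must be non-decreasing")

    def _edge_slope(self, reverse: bool) -> float:
        pts = list(reversed(self.breakpoints)) if reverse else self.breakpoints
        for (c1, s1), (c2, s2) in zip(pts, pts[1:]):
            if c1 != c2:
                return (s2 - s1) / (c2 - c1)
        return 0.0

    def pre_clamp(self, confidence: float) -> float:
        """Piecewise-linear value before clamping (may be negative)."""
        confs = [c for c, _ in self.breakpoints]
        stars = [s for _, s in self.breakpoints]
        c0, s0 = self.breakpoints[0]
        cn, sn = self.breakpoints[-1]
        if confidence < c0:
            return s0 + self._edge_slope(reverse=False) * (confidence - c0)
        if confidence > cn:
            return sn + self._edge_slope(reverse=True) * (confidence - cn)
        return float(np.interp(confidence, confs, stars))

    def __call__(self, confidence: float) -> float:
        return float(np.clip(self.pre_clamp(confidence), 0.0, self.star_max))


def calibrate_stars(
    reference: ScoredChannel,
    anchors: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS,
    star_max: float = STAR_MAX,
) -> CalibrationFunction:
    """Build the shared confidence -> stars map from a reference channel.

    Each anchor is (confidence quantile in [0, 1], stars); the breakpoint
    confidences are the stated quantiles of the reference channel's
    confidence distribution. One single calibration is then applied to every
    dataset of every organism.
    """
    if not reference.associations:
        raise ValidationError("reference channel is empty")
    qs = [q for q, _ in anchors]
    stars = [s for _, s in anchors]
    if any(not 0 <= q <= 1 for q in qs):
        raise ValidationError("anchor quantiles must lie in [0, 1]")
    if any(s2 < s1 for s1, s2 in zip(stars, stars[1:])):
        raise ValidationError("anchor stars must be non-decreasing")
    confs = np.array(
        [a.confidence for a in reference.associations if a.confidence is not None]
    )
    if confs.size == 0:
        raise ValidationError("reference channel carries no confidences")
    bp = [(float(np.quantile(confs, q)), float(s)) for q, s in anchors]
    bp.sort()
    return CalibrationFunction(breakpoints=bp, star_max=star_max)


def apply_stars(assocs: ScoredChannel, cal: CalibrationFunction) -> ScoredChannel:
    """Calibrate confidences to stars; drop associations with negative scores.

    The pre-clamp calibrated value decides removal (strictly below 0 -> the
    association is not retained); survivors get stars clamped to
    [0, star_max].
    """
    kept = []
    for a in assocs.associations:
        if a.confidence is None:
            raise ValidationError(
                f"association ({a.gene}, {a.tissue}) has no confidence to calibrate"
            )
        pre = cal.pre_clamp(a.confidence)
        if pre < 0:
            continue
        stars = float(min(pre, cal.star_max))
        kept.append(
            Association(
                gene=a.gene,
                tissue=a.tissue,
                raw=a.raw,
                confidence=a.confidence,
                stars=stars,
            )
        )
    return ScoredChannel(
        channel=assocs.channel, organism=assocs.organism, associations=kept
    )


def integrate_channels(channels: list[ScoredChannel]) -> ScoredChannel:
    """Combine evidence channels into one integrated channel per organism.

    Per (gene, tissue) the integrated stars are the MAX over channels; the
    contributing channels are recorded in ``sources``.
    """
    if not channels:
        raise ValidationError("need at least one channel to integrate")
    organisms = {c.organism for c in channels}
    if len(organisms) > 1:
        raise ValidationError(f"channels span multiple organisms: {sorted(organisms)}")

    best: dict[tuple[str, str], Association] = {}
    contrib: dict[tuple[str, str], list[str]] = {}
    for ch in channels:
        seen: set[tuple[str, str]] = set()
        for a in ch.associations:
            key = (a.gene, a.tissue)
            if key in seen:
                raise ValidationError(
                    f"duplicate association {key} in channel {ch.channel!r}"
                )
            seen.add(key)
            contrib.setdefault(key, []).append(ch.channel)
            stars = a.stars if a.stars is not None else 0.0
            cur = best.get(key)
            if cur is None or stars > (cur.stars or 0.0):
                best[key] = Association(
                    gene=a.gene,
                    tissue=a.tissue,
                    raw=None,
                    confidence=a.confidence,
                    stars=stars,
                )
    out = [best[k] for k in sorted(best)]
    return ScoredChannel(
        channel="integrated",
        organism=organisms.pop(),
        associations=out,
        sources={k: tuple(v) for k, v in sorted(contrib.items())},
    )
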