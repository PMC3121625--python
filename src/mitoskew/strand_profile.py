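"""Sliding-window (G+T)/(A+C) profiles, trend fits, origin calls, skew atlas.

The windowed ratio is the classic single-strandedness proxy for circular
mitogenomes replicated by strand displacement: the longer a stretch stays
single-stranded the more G/T it accumulates on the exposed strand, so the
profile minimum marks the light-strand origin (shortest exposure) and the
maximum the heavy-strand origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .composition import BaseCounts, at_skew, gc_skew
from .genome_io import AnnotatedGenome

DEFAULT_WINDOW_LEFT = 149
DEFAULT_WINDOW_RIGHT = 150


@dataclass
class RatioProfile:
    """Per-position windowed (G+T)/(A+C) values; NaN where A+C == 0."""

    values: np.ndarray
    window_left: int = DEFAULT_WINDOW_LEFT
    window_right: int = DEFAULT_WINDOW_RIGHT

    @property
    def window_size(self) -> int:
        return self.window_left + self.window_right + 1

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TrendFit:
    slope: float
    intercept: float
    threshold: float
    threshold_mode: str
    shading_mask: np.ndarray = field(repr=False)


@dataclass
class OriInference:
    oriL_position: int
    oriL_genes: tuple[str, str]
    oriH_position: int
    oriH_genes: tuple[str, str]
    smoothed: np.ndarray = field(repr=False)
    smooth_span: int = 300
    tie_oriL: bool = False
    tie_oriH: bool = False


@dataclass(frozen=True)
class SkewPoint:
    genome_id: str
    group: str
    at_skew: float
    gc_skew: float


@dataclass
class GroupEllipse:
    group: str
    n: int
    mean: np.ndarray
    eigenvalues: np.ndarray      # descending: major, minor
    eigenvectors: np.ndarray     # columns, matching eigenvalues
    minimum: np.ndarray          # per-axis (at_skew, gc_skew) min
    maximum: np.ndarray
    degenerate: bool = False


def _circular_window_sums(indicator: np.ndarray, left: int, right: int) -> np.ndarray:
    """Sum of ``indicator`` over [p-left, p+right] (circular) for every p."""
    head = indicator[len(indicator) - left :] if left else indicator[:0]
    tail = indicator[:right]
    ext = np.concatenate([head, indicator, tail])
    cs = np.concatenate([[0], np.cumsum(ext)])
    w = left + right + 1
    return cs[w:] - cs[:-w]


def ratio_profile(
    genome: AnnotatedGenome | str,
    window_left: int = DEFAULT_WINDOW_LEFT,
    window_right: int = DEFAULT_WINDOW_RIGHT,
) -> RatioProfile:
    """(G+T)/(A+C) over the circular window [p-left, p+right] at every position p.

    Ns count in neither numerator nor denominator; windows whose denominator
    is zero are flagged undefined (NaN).
    """
    seq = genome if isinstance(genome, str) else genome.sequence
    w = window_left + window_right + 1
    if len(seq) < w:
        raise ValueError(f"genome of length {len(seq)} shorter than window {w}")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    gt = ((arr == ord("G")) | (arr == ord("T"))).astype(np.int64)
    ac = ((arr == ord("A")) | (arr == ord("C"))).astype(np.int64)
    gt_sum = _circular_window_sums(gt, window_left, window_right)
    ac_sum = _circular_window_sums(ac, window_left, window_right)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(ac_sum > 0, gt_sum / np.maximum(ac_sum, 1), np.nan)
    return RatioProfile(values=values, window_left=window_left, window_right=window_right)


def fit_trend(
    profile: RatioProfile,
    threshold: float | str = "slope",
    k: float = 1.0,
) -> TrendFit:
    """OLS of ratio against position over defined points, plus a shading mask.

    ``threshold`` selects the shading constant compared against raw ratios:
    the fitted ``"slope"`` value itself (the convention of the figure this
    reproduces, dimensionally odd but kept), ``"mean_sd"`` for mean + k*sd of
    the defined ratios, or an explicit float.
    """
    defined = profile.defined
    if defined.sum() < 2:
        raise ValueError("need at least two defined profile positions to fit a trend")
    x = np.flatnonzero(defined).astype(float)
    y = profile.values[defined]
    slope, intercept = np.polyfit(x, y, 1)
    if isinstance(threshold, str):
        if threshold == "slope":
            thr, mode = float(slope), "slope"
        elif threshold == "mean_sd":
            thr, mode = float(y.mean() + k * y.std(ddof=0)), "mean_sd"
        else:
            raise ValueError(f"unknown threshold mode {threshold!r}")
    else:
        thr, mode = float(threshold), "explicit"
    mask = np.zeros(len(profile), dtype=bool)
    mask[defined] = profile.values[defined] > thr
    return TrendFit(
        slope=float(slope), intercept=float(intercept),
        threshold=thr, threshold_mode=mode, shading_mask=mask,
    )


def circular_moving_average(values: np.ndarray, span: int) -> np.ndarray:
    """NaN-aware circular moving average over a ``span``-wide window."""
    span = min(span, len(values))
    left = (span - 1) // 2
    right = span - 1 - left
    finite = np.isfinite(values)
    filled = np.where(finite, values, 0.0)
    num = _circular_window_sums(filled, left, right)
    den = _circular_window_sums(finite.astype(np.int64), left, right)
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1), np.nan)


def flanking_genes(genome: AnnotatedGenome, position: int) -> tuple[str, str]:
    """(left, right) nearest annotated genes; a containing gene appears on both sides."""
    length = len(genome)
    containing = []
    for f in genome.features:
        for iv in f.intervals:
            if iv.wraps:
                if position >= iv.start or position < iv.end - length:
                    containing.append(f.name)
            elif iv.start <= position < iv.end:
                containing.append(f.name)
    if containing:
        return containing[0], containing[0]
    best_left, dl = "", length + 1
    best_right, dr = "", length + 1
    for f in genome.features:
        for iv in f.intervals:
            end = iv.end % length if iv.wraps else iv.end
            d = (position - end) % length
            if d < dl:
                dl, best_left = d, f.name
            d = (iv.start - position) % length
            if d < dr:
                dr, best_right = d, f.name
    return best_left, best_right


def infer_origins(
    profile: RatioProfile, genome: AnnotatedGenome, smooth_span: int = 300
) -> OriInference:
    """Call oriL at the smoothed-profile minimum and oriH at its maximum.

    Ties are broken toward the smallest position and reported.
    """
    if len(profile) != len(genome):
        raise ValueError("profile and genome lengths differ")
    smoothed = circular_moving_average(profile.values, smooth_span)
    if not np.isfinite(smoothed).any():
        raise ValueError("profile entirely undefined; cannot infer origins")
    lo = int(np.nanargmin(smoothed))
    hi = int(np.nanargmax(smoothed))
    tie_lo = int(np.sum(smoothed == smoothed[lo])) > 1
    tie_hi = int(np.sum(smoothed == smoothed[hi])) > 1
    return OriInference(
        oriL_position=lo,
        oriL_genes=flanking_genes(genome, lo),
        oriH_position=hi,
        oriH_genes=flanking_genes(genome, hi),
        smoothed=smoothed,
        smooth_span=smooth_span,
        tie_oriL=tie_lo,
        tie_oriH=tie_hi,
    )


# ---------------------------------------------------------------------------
# comparative skew atlas


def skew_point(genome: AnnotatedGenome, group: str, counts: BaseCounts | None = None) -> SkewPoint:
    from .composition import base_counts  # local import to avoid cycle at module load

    counts = counts if counts is not None else base_counts(genome.sequence)
    return SkewPoint(genome.id, group, at_skew(counts), gc_skew(counts))


def group_ellipse(points: list[SkewPoint], min_points: int = 2) -> GroupEllipse:
    """Mean, covariance eigen-structure and min/max cross of one group."""
    if len(points) < min_points:
        raise ValueError(f"need >= {min_points} points for an ellipse, got {len(points)}")
    xy = np.array([[p.at_skew, p.gc_skew] for p in points], dtype=float)
    mean = xy.mean(axis=0)
    centered = xy - mean
    cov = centered.T @ centered / max(len(points) - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)       # ascending
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    degenerate = bool(eigvals[-1] <= 1e-12 * max(eigvals[0], 1.0))
    return GroupEllipse(
        group=points[0].group,
        n=len(points),
        mean=mean,
        eigenvalues=np.clip(eigvals, 0.0, None),
        eigenvectors=eigvecs,
        minimum=xy.min(axis=0),
        maximum=xy.max(axis=0),
        degenerate=degenerate,
    )


def skew_atlas(
    genomes: list[AnnotatedGenome], grouping: dict[str, str]
) -> tuple[list[SkewPoint], list[GroupEllipse]]:
    """Per-genome main-strand skew points plus per-group covariance ellipses.

    ``grouping`` maps genome id -> group label; genomes without a label get
    their own singleton group.  Ellipses are built for groups of >= 3 points
    (collinear groups are flagged degenerate).
    """
    points = [skew_point(g, grouping.get(g.id, g.id)) for g in genomes]
    ellipses = []
    for group in sorted({p.group for p in points}):
        members = [p for p in points if p.group == group]
        if len(members) >= 3:
            ellipses.append(group_ellipse(members))
    return points, ellipses


def profile_to_tsv(profile: RatioProfile, fit: TrendFit | None = None) -> str:
    lines = ["position\tratio\tshaded"]
    mask = fit.shading_mask if fit is not None else np.zeros(len(profile), dtype=bool)
    for i, (v, s) in enumerate(zip(profile.values, mask)):
        val = "NA" if math.isnan(v) else f"{v:.6f}"
        lines.append(f"{i}\t{val}\t{int(bool(s))}")
    return "\n".join(lines) + "\n"


def atlas_points_to_tsv(points: list[SkewPoint]) -> str:
    lines = ["genome\tgroup\tat_skew\tgc_skew"]
    for p in points:
        lines.append(f"{p.genome_id}\t{p.group}\t{p.at_skew:.6f}\t{p.gc_skew:.6f}")
    return "\n".join(lines) + "\n"


def ellipses_to_json_obj(ellipses: list[GroupEllipse]) -> list[dict]:
    out = []
    for e in ellipses:
        out.append(
            {
                "group": e.group,
                "n": e.n,
                "mean": e.mean.tolist(),
                "eigenvalues": e.eigenvalues.tolist(),
                "eigenvectors": e.eigenvectors.tolist(),
                "min": e.minimum.tolist(),
                "max": e.maximum.tolist(),
                "degenerate": e.degenerate,
            }
        )
    return out
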