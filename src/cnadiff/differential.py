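"""Paired differential copy-number profiling.

Given two normalized, centered profiles (resistant "test" vs parental "ref"),
the comparison first equalizes their dynamics: the profile with the lower
interquartile range is mapped onto the other by ordinary least squares
(low-IQR profile as predictor, high-IQR profile as response), so that shared
aberrations cancel when the probe-wise difference test − ref is taken.  The
difference profile is then treated as a profile in its own right: its calling
threshold is recomputed from its own consecutive-probe differences, it is
CBS-segmented and called, and every non-neutral segment becomes an annotated
region carrying the segment mean of the difference (the differential log2
ratio, positive = gained in the test sample), overlapping genes and
cytobands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import CalledSegmentedProfile, call_segments, calling_threshold
from .normalization import Log2Profile
from .probe_io import GenomeAnnotation
from .segmentation import CbsParams, Segment, cbs_segment, smooth_outliers

MAX_PROBE_LOSS_FRACTION = 0.05


@dataclass(frozen=True)
class ScalingFit:
    low_sample: str
    high_sample: str
    slope: float
    intercept: float
    iqr_low: float
    iqr_high: float


@dataclass(frozen=True)
class AnnotatedRegion:
    chrom: str
    start: int  # bp, 0-based half-open
    end: int
    n_probes: int
    diff_l2r: float
    call: str  # gain | loss
    genes: tuple[str, ...] = ()
    cytobands: tuple[str, ...] = ()


@dataclass
class DifferentialResult:
    diff_profile: Log2Profile
    called: CalledSegmentedProfile
    scaling: ScalingFit
    regions: list[AnnotatedRegion] = field(default_factory=list)
    n_dropped_probes: int = 0

    def regions_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": r.chrom,
                "start": r.start + 1,  # 1-based inclusive on output
                "end": r.end,
                "n_probes": r.n_probes,
                "diff_l2r": round(r.diff_l2r, 6),
                "call": r.call,
                "cytobands": ";".join(r.cytobands),
                "genes": ";".join(r.genes),
            }
            for r in self.regions
        ]
        cols = ["chrom", "start", "end", "n_probes", "diff_l2r", "call", "cytobands", "genes"]
        return pd.DataFrame(rows, columns=cols)


def profile_dynamics(profile: Log2Profile) -> float:
    """Profile dynamics = interquartile range of probe values (linear-interpolation quantiles)."""
    if len(profile) < 4:
        raise ValueError("dynamics needs >= 4 probes")
    q75, q25 = np.percentile(profile.values, [75, 25])
    return float(q75 - q25)


def _intersect(a: Log2Profile, b: Log2Profile):
    ids_a = a.probes["probe_id"]
    ids_b = b.probes["probe_id"]
    if len(ids_a) == len(ids_b) and ids_a.equals(ids_b):
        return a, b, 0
    common = pd.Index(ids_a).intersection(pd.Index(ids_b))
    lost = max(len(a), len(b)) - len(common)
    worst = lost / max(len(a), len(b))
    if worst > MAX_PROBE_LOSS_FRACTION:
        raise ValueError(
            f"probe universes differ by {worst:.1%} (> {MAX_PROBE_LOSS_FRACTION:.0%}): "
            "mismatched array designs"
        )
    mask_a = ids_a.isin(common).to_numpy()
    mask_b = ids_b.isin(common).to_numpy()
    a2 = Log2Profile(a.sample_id, a.probes[mask_a].reset_index(drop=True),
                     a.values[mask_a], list(a.normalization_log))
    b2 = Log2Profile(b.sample_id, b.probes[mask_b].reset_index(drop=True),
                     b.values[mask_b], list(b.normalization_log))
    return a2, b2, lost


MIN_SCALING_CORRELATION = 0.05
SCALING_OUTLIER_MADS = 3.0
SCALING_MAX_ITER = 5


def _iqr_match(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    qx = float(np.subtract(*np.percentile(x, [75, 25])))
    qy = float(np.subtract(*np.percentile(y, [75, 25])))
    slope = qy / qx if qx > 0 else 1.0
    return slope, float(np.median(y) - slope * np.median(x))


def _deming_core(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    mx, my = x.mean(), y.mean()
    sxx = float(np.mean((x - mx) ** 2))
    syy = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    r = sxy / np.sqrt(sxx * syy) if sxx > 0 and syy > 0 else 0.0
    # no resolvable shared structure: the Deming solution diverges as r -> 0,
    # so fall back to plain dynamic-range matching; the guard scales with the
    # sampling noise of r
    if abs(r) < max(MIN_SCALING_CORRELATION, 4.0 / np.sqrt(len(x))):
        return _iqr_match(x, y)
    d = syy - sxx
    slope = (d + np.sqrt(d * d + 4.0 * sxy * sxy)) / (2.0 * sxy)
    return float(slope), float(my - slope * mx)


def _deming_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Robust errors-in-variables line fit of y on x with equal error variances.

    Both log2 profiles carry probe noise of the same magnitude, so ordinary
    least squares would shrink the slope by the inter-profile correlation and
    leave shared aberrations only partially cancelled in the difference; the
    Deming (lambda = 1) solution estimates the structural slope consistently.
    Probes where the pair genuinely differs (acquired aberrations) follow a
    different structural relation and would distort the fit, so the fit is
    iterated with an outlier mask: starting from a plain dynamic-range match,
    probes whose residual exceeds 3 robust SDs (1.4826 * MAD) are excluded,
    the Deming solution is recomputed on the remaining probes, and the mask is
    re-derived from all probes each round until it stabilizes.  Essentially
    uncorrelated profiles have no shared structure to regress on; the scale is
    then matched by the ratio of interquartile ranges.
    """
    mask = np.ones(len(x), dtype=bool)
    slope, intercept = _iqr_match(x, y)
    for _ in range(SCALING_MAX_ITER):
        res = y - (slope * x + intercept)
        med = np.median(res)
        mad = 1.4826 * float(np.median(np.abs(res - med)))
        if mad == 0.0:
            break
        new_mask = np.abs(res - med) <= SCALING_OUTLIER_MADS * mad
        if new_mask.sum() < 10:
            break
        slope, intercept = _deming_core(x[new_mask], y[new_mask])
        if (new_mask == mask).all():
            break
        mask = new_mask
    return slope, intercept


def scale_pair(a: Log2Profile, b: Log2Profile) -> tuple[Log2Profile, Log2Profile, ScalingFit]:
    """Regress the lower-dynamics profile onto the higher-dynamics one.

    The profile with the smaller IQR (ties broken by sample_id order) is the
    regression predictor; its values are replaced by slope*low + intercept,
    mapping it into the high-dynamics profile's scale (Deming fit, see
    :func:`_deming_fit`).  The high profile is untouched.  Profiles are
    returned in the argument order.
    """
    a, b, _ = _intersect(a, b)
    iqr_a, iqr_b = profile_dynamics(a), profile_dynamics(b)
    if iqr_a < iqr_b or (iqr_a == iqr_b and a.sample_id <= b.sample_id):
        low, high, low_is_a = a, b, True
    else:
        low, high, low_is_a = b, a, False
    x = low.values
    y = high.values
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate regression: {low.sample_id!r} has zero variance")
    slope, intercept = _deming_fit(x, y)
    scaled = low.with_values(slope * x + intercept, "dynamics_scaled")
    fit = ScalingFit(
        low_sample=low.sample_id,
        high_sample=high.sample_id,
        slope=float(slope),
        intercept=float(intercept),
        iqr_low=min(iqr_a, iqr_b),
        iqr_high=max(iqr_a, iqr_b),
    )
    if low_is_a:
        return scaled, high, fit
    return high, scaled, fit


MERGE_LEVEL_RATIO = 0.5


def merge_called_runs(segments: list[Segment], calls: list[str]) -> list[tuple[Segment, str]]:
    """Collapse contiguous same-call segments at the same aberration level.

    CBS may split one aberration into adjacent segments whose means differ
    only by estimation error or within-region heterogeneity; those are one
    region scientifically and are merged (probe-weighted mean).  Adjacent
    same-call segments at clearly different levels (the smaller |mean| below
    half the larger) represent distinct copy states and are kept apart.
    """
    merged: list[tuple[Segment, str]] = []
    for seg, call in zip(segments, calls):
        if call == "neutral":
            continue
        if merged:
            prev, prev_call = merged[-1]
            similar = min(abs(prev.mean), abs(seg.mean)) >= MERGE_LEVEL_RATIO * max(
                abs(prev.mean), abs(seg.mean)
            )
            if (prev_call == call and prev.chrom == seg.chrom and similar
                    and prev.probe_index_range[1] == seg.probe_index_range[0]):
                n = prev.n_probes + seg.n_probes
                mean = (prev.mean * prev.n_probes + seg.mean * seg.n_probes) / n
                merged[-1] = (
                    Segment(prev.chrom, prev.start, seg.end, n, mean,
                            (prev.probe_index_range[0], seg.probe_index_range[1])),
                    call,
                )
                continue
        merged.append((seg, call))
    return merged


def annotate_regions(segments: list[Segment], calls: list[str],
                     ann: GenomeAnnotation | None) -> list[AnnotatedRegion]:
    """Merge same-call runs and attach overlapping gene symbols and cytobands."""
    regions = []
    for seg, call in merge_called_runs(segments, calls):
        if ann is None:
            genes, bands = (), ()
        else:
            genes = tuple(ann.names("gene", seg.chrom, seg.start, seg.end))
            bands = tuple(ann.names("cytoband", seg.chrom, seg.start, seg.end))
        regions.append(
            AnnotatedRegion(seg.chrom, seg.start, seg.end, seg.n_probes,
                            float(seg.mean), call, genes, bands)
        )
    return regions


def differential_regions(
    test: Log2Profile,
    ref: Log2Profile,
    cbs: CbsParams | None = None,
    ann: GenomeAnnotation | None = None,
    threshold_source: str = "diff",
) -> DifferentialResult:
    """Dynamics-scale, difference, re-segment, re-call and annotate a profile pair.

    The difference is always oriented test − ref (positive = gained in the
    test sample) regardless of which side was rescaled.  By default the
    calling threshold is recomputed on the difference profile
    (``threshold_source='diff'``); 'test' or 'ref' inherit the corresponding
    input profile's threshold instead.
    """
    cbs = cbs or CbsParams()
    a, b, _ = _intersect(test, ref)
    if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
        # a constant profile (e.g. noiseless identity data) has nothing to
        # regress; fall back to the identity scaling
        iqr_a = float(np.subtract(*np.percentile(a.values, [75, 25])))
        iqr_b = float(np.subtract(*np.percentile(b.values, [75, 25])))
        low, high = (a, b) if iqr_a <= iqr_b else (b, a)
        test_s, ref_s = a, b
        fit = ScalingFit(low.sample_id, high.sample_id, 1.0, 0.0,
                         min(iqr_a, iqr_b), max(iqr_a, iqr_b))
    else:
        test_s, ref_s, fit = scale_pair(a, b)
    diff_values = test_s.values - ref_s.values
    diff = Log2Profile(
        f"{test.sample_id}-vs-{ref.sample_id}",
        test_s.probes,
        diff_values,
        list(test.normalization_log) + ["differential"],
    )
    diff = smooth_outliers(diff)
    if threshold_source == "diff":
        thr = calling_threshold(diff)
    elif threshold_source == "test":
        thr = calling_threshold(test_s)
    elif threshold_source == "ref":
        thr = calling_threshold(ref_s)
    else:
        raise ValueError(f"unknown threshold_source {threshold_source!r}")
    segmented = cbs_segment(diff, cbs)
    called = call_segments(segmented, thr)
    regions = annotate_regions(called.segments, called.calls, ann)
    regions.sort(key=lambda r: -abs(r.diff_l2r))
    n_dropped = max(len(test), len(ref)) - len(diff)
    return DifferentialResult(diff, called, fit, regions, n_dropped)
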