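"""Profile centering and gain/neutral/loss calling.

Centering: the probe-value density is estimated by Gaussian kernel density
estimation (Silverman bandwidth, linear-binned 2,048-point grid convolved with
the Gaussian kernel — the standard binned approximation); local maxima are
ranked by density height, and among the three most populated peaks the one
closest to zero ("most centered": a log ratio of zero is the balanced state)
is subtracted from all probe values and segment means.  A flag switches to the
alternative reading (peak closest to the distribution's center of mass).

Calling threshold: one-fourth of the median absolute difference between
consecutive probes' log2 values along the genome.  Consecutive pairs that
straddle a chromosome junction are excluded by default (they contribute
artifactual jumps); ``include_junctions=True`` restores the literal
along-the-genome reading.  Segments with |mean| strictly above the threshold
are called gains/losses; a mean exactly at the threshold is neutral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .normalization import Log2Profile
from .segmentation import SegmentedProfile

KDE_GRID_SIZE = 2_048
MIN_PROBES_FOR_CENTERING = 100
PEAK_MIN_HEIGHT_FRACTION = 0.05


@dataclass(frozen=True)
class CenteringResult:
    offset: float
    peak_locations: tuple[float, ...]  # up to 3, ranked by density height
    chosen_peak_index: int
    bandwidth: float


@dataclass(frozen=True)
class CallThreshold:
    value: float
    n_pairs: int
    degenerate: bool = False


@dataclass
class CalledSegmentedProfile(SegmentedProfile):
    calls: list[str] = field(default_factory=list)
    threshold: CallThreshold | None = None
    centering: CenteringResult | None = None

    @property
    def n_gain(self) -> int:
        return sum(c == "gain" for c in self.calls)

    @property
    def n_loss(self) -> int:
        return sum(c == "loss" for c in self.calls)


def silverman_bandwidth(values: np.ndarray) -> float:
    n = len(values)
    sd = float(np.std(values))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        spread = max(sd, 1e-6)
    return 0.9 * spread * n ** (-0.2)


def density_peaks(values: np.ndarray, grid_size: int = KDE_GRID_SIZE):
    """(locations, heights, bandwidth) of local density maxima, height-ranked.

    The density is a binned Gaussian KDE: counts on a uniform grid padded by
    3 bandwidths, convolved with a Gaussian of the Silverman bandwidth.
    """
    bw = silverman_bandwidth(values)
    lo = values.min() - 3 * bw
    hi = values.max() + 3 * bw
    if hi <= lo:
        raise ValueError("degenerate density: zero-width support")
    counts, edges = np.histogram(values, bins=grid_size, range=(lo, hi))
    binw = edges[1] - edges[0]
    dens = gaussian_filter1d(counts.astype(float), sigma=bw / binw, mode="constant")
    centers = 0.5 * (edges[:-1] + edges[1:])
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    idx = np.flatnonzero(interior) + 1
    if len(idx) == 0:
        # strictly monotone or flat density: fall back to the global maximum
        idx = np.array([int(np.argmax(dens))])
    order = np.argsort(dens[idx])[::-1]
    idx = idx[order]
    # "populated" peaks only: smoothing isolated tail points creates tiny
    # bumps that are local maxima but carry no mass
    keep = dens[idx] >= PEAK_MIN_HEIGHT_FRACTION * dens[idx[0]]
    idx = idx[keep]
    return centers[idx], dens[idx], bw


def center_profile(
    profile: Log2Profile,
    segmented: SegmentedProfile | None = None,
    rule: str = "nearest-zero",
) -> tuple[Log2Profile, SegmentedProfile | None, CenteringResult]:
    """Center a profile on the most centered of its three most populated density peaks.

    Returns the shifted profile, the correspondingly shifted segmentation (or
    None if none was given) and the centering diagnostics.
    """
    if len(profile) < MIN_PROBES_FOR_CENTERING:
        raise ValueError(f"centering needs >= {MIN_PROBES_FOR_CENTERING} probes")
    locs, heights, bw = density_peaks(profile.values)
    top = locs[:3]
    if rule == "nearest-zero":
        anchor = 0.0
    elif rule == "nearest-center":
        anchor = float(profile.values.mean())
    else:
        raise ValueError(f"unknown centering rule {rule!r}")
    chosen = int(np.argmin(np.abs(top - anchor)))
    offset = float(top[chosen])
    centered = profile.with_values(profile.values - offset, "center")
    shifted_seg = segmented.shifted(offset) if segmented is not None else None
    result = CenteringResult(offset, tuple(float(v) for v in top), chosen, bw)
    return centered, shifted_seg, result


def calling_threshold(profile: Log2Profile, include_junctions: bool = False) -> CallThreshold:
    """One-fourth of the median |difference between consecutive probe values|.

    Pairs spanning chromosome junctions are excluded unless
    ``include_junctions``.  An all-constant profile yields a zero threshold
    with a degeneracy warning.
    """
    if len(profile) < 2:
        raise ValueError("threshold needs >= 2 probes")
    if include_junctions:
        diffs = np.abs(np.diff(profile.values))
    else:
        parts = [np.abs(np.diff(v)) for _, v in profile.chromosome_values() if len(v) >= 2]
        if not parts:
            raise ValueError("no within-chromosome consecutive pairs")
        diffs = np.concatenate(parts)
    value = float(np.median(diffs)) / 4.0
    degenerate = value == 0.0
    if degenerate:
        warnings.warn("degenerate profile: calling threshold is zero", stacklevel=2)
    return CallThreshold(value=value, n_pairs=len(diffs), degenerate=degenerate)


def call_segments(segmented: SegmentedProfile, threshold: CallThreshold,
                  centering: CenteringResult | None = None) -> CalledSegmentedProfile:
    """Ternary gain/neutral/loss calls: gain iff mean > +t, loss iff mean < -t (strict)."""
    t = threshold.value
    calls = []
    for seg in segmented.segments:
        if seg.mean > t:
            calls.append("gain")
        elif seg.mean < -t:
            calls.append("loss")
        else:
            calls.append("neutral")
    return CalledSegmentedProfile(
        sample_id=segmented.sample_id,
        segments=list(segmented.segments),
        params=segmented.params,
        calls=calls,
        threshold=threshold,
        centering=centering,
    )
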