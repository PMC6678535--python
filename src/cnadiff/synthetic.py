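"""Synthetic paired aCGH data with known ground truth.

The generator emulates a ~180K-probe two-channel oligo array: probes are spread
proportionally to hg19-like chromosome lengths with jittered spacing; each
probe carries a smooth spatial GC field in [0.3, 0.7].  A sample pair shares
baseline ("shared") copy-number aberrations, and the resistant member
additionally carries acquired ("resistant_only") aberrations.  Channel
intensities are back-computed from the true per-probe log2 ratio: the
reference channel is a lognormal baseline (log2 mean 10, SD 1.8 — intensities
spanning roughly three decades, as on real arrays), the test channel is
reference * 2**(true log2); quadratic GC bias and an intensity-dependent dye
multiplier are then applied and Gaussian probe noise added in log space, with
a small fraction of heavy-tailed outlier probes.  Everything is deterministic
under a fixed seed, and a truth table of regions closes the loop for
end-to-end recovery checks.

Default noise settings: probe noise SD 0.25 on the log2 ratio, GC bias
amplitude 0.3, dye bias amplitude 0.1, outlier rate 0.001.  Default acquired
amplitudes are drawn from ±{0.58, 1.0, 3.2, 4.7} — spanning the differential
log2-ratio magnitudes reported for acquired aberrations in drug-resistant
osteosarcoma lines (locations are synthetic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .dose_response import DoseResponseData, four_pl
from .probe_io import DEFAULT_CHROM_ORDER, GenomeAnnotation, ProbeSet

# hg19 chromosome lengths, Mb (rounded); proportions drive probe allocation.
HG19_CHROM_MB: dict[str, float] = {
    "chr1": 249.25, "chr2": 243.20, "chr3": 198.02, "chr4": 191.15,
    "chr5": 180.92, "chr6": 171.12, "chr7": 159.14, "chr8": 146.36,
    "chr9": 141.21, "chr10": 135.53, "chr11": 135.01, "chr12": 133.85,
    "chr13": 115.17, "chr14": 107.35, "chr15": 102.53, "chr16": 90.35,
    "chr17": 81.20, "chr18": 78.08, "chr19": 59.13, "chr20": 63.03,
    "chr21": 48.13, "chr22": 51.30, "chrX": 155.27, "chrY": 59.37,
}

DEFAULT_AMPLITUDES = (0.58, 1.0, 3.2, 4.7)


@dataclass
class ArrayDesign:
    n_probes: int
    chrom_lengths: dict[str, int]  # bp
    probes: pd.DataFrame  # probe_id, chrom, start, end (0-based half-open), gc
    chrom_order: tuple[str, ...] = DEFAULT_CHROM_ORDER

    def __len__(self) -> int:
        return len(self.probes)


@dataclass(frozen=True)
class CnaRegion:
    chrom: str
    start: int
    end: int
    delta_log2: float
    scope: str  # "shared" | "resistant_only"

    def __post_init__(self) -> None:
        if self.delta_log2 == 0:
            raise ValueError("delta_log2 must be non-zero")
        if self.scope not in ("shared", "resistant_only"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.start >= self.end:
            raise ValueError("empty CNA region")


@dataclass
class CnaSpec:
    regions: list[CnaRegion] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"chrom": r.chrom, "start": r.start, "end": r.end,
                 "delta_log2": r.delta_log2, "scope": r.scope}
                for r in self.regions
            ],
            columns=["chrom", "start", "end", "delta_log2", "scope"],
        )


@dataclass(frozen=True)
class NoiseModel:
    probe_noise_sd: float = 0.25       # SD of the log2 ratio
    gc_bias_amplitude: float = 0.3     # peak quadratic GC effect, log2 units
    dye_bias_amplitude: float = 0.1    # intensity-dependent reference multiplier amplitude
    outlier_rate: float = 0.001
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.8

    def __post_init__(self) -> None:
        if self.probe_noise_sd < 0:
            raise ValueError("probe_noise_sd must be >= 0")
        if not 0 <= self.outlier_rate <= 0.01:
            raise ValueError("outlier_rate must lie in [0, 0.01]")


def generate_design(n_probes: int = 180_000, seed: int = 0,
                    chrom_mb: dict[str, float] | None = None) -> ArrayDesign:
    """Probes spread proportionally to chromosome lengths with jittered spacing."""
    if n_probes < 1_000:
        raise ValueError("n_probes must be >= 1,000")
    chrom_mb = chrom_mb or HG19_CHROM_MB
    rng = np.random.default_rng(seed)
    total = sum(chrom_mb.values())
    chroms = list(chrom_mb)
    counts = {c: int(round(n_probes * chrom_mb[c] / total)) for c in chroms}
    drift = n_probes - sum(counts.values())
    counts[chroms[0]] += drift  # absorb rounding in the largest chromosome

    frames = []
    k = 0
    for chrom in chroms:
        length = int(chrom_mb[chrom] * 1e6)
        c = counts[chrom]
        spacing = length / c
        centers = (np.arange(c) + 0.5) * spacing
        centers = centers + rng.uniform(-0.4, 0.4, size=c) * spacing
        starts = np.clip(np.sort(centers).astype(np.int64), 0, length - 61)
        # enforce strictly increasing starts so probes stay sortable and unique
        starts = np.maximum.accumulate(starts + np.arange(c) * 0)
        for i in range(1, c):
            if starts[i] <= starts[i - 1]:
                starts[i] = starts[i - 1] + 1
        # smooth spatial GC field: filtered white noise scaled by the filter's
        # theoretical output SD (normalizing by the realized per-chromosome SD
        # would blow up when the chromosome is shorter than the filter),
        # plus small per-probe jitter so no two probes tie exactly
        sigma = max(5.0, min(50.0, c / 6.0))
        gc_raw = gaussian_filter1d(rng.normal(size=c), sigma=sigma, mode="reflect")
        theo_sd = np.sqrt(1.0 / (2.0 * sigma * np.sqrt(np.pi)))
        gc = 0.5 + 0.07 * gc_raw / theo_sd + rng.uniform(-0.02, 0.02, size=c)
        gc = np.clip(gc, 0.3, 0.7)
        frames.append(pd.DataFrame({
            "probe_id": [f"P{k + i:07d}" for i in range(c)],
            "chrom": chrom,
            "start": starts,
            "end": starts + 60,
            "gc": gc,
        }))
        k += c
    probes = pd.concat(frames, ignore_index=True)
    lengths = {c: int(chrom_mb[c] * 1e6) for c in chroms}
    return ArrayDesign(n_probes, lengths, probes, tuple(chroms))


def random_cna_spec(design: ArrayDesign, n_shared: int = 5, n_acquired: int = 3,
                    min_probes: int = 80, max_probes: int = 300,
                    amplitudes: tuple[float, ...] = DEFAULT_AMPLITUDES,
                    seed: int = 0) -> CnaSpec:
    """Place non-overlapping CNA regions of ``min_probes``..``max_probes`` probes.

    Amplitude magnitudes are sampled from ``amplitudes`` with random sign.
    Shared regions go into both pair members, acquired into the resistant one.
    """
    rng = np.random.default_rng(seed)
    probes = design.probes
    chrom_groups = {c: g for c, g in probes.groupby("chrom", sort=False)}
    chroms = list(chrom_groups)
    weights = np.array([len(chrom_groups[c]) for c in chroms], float)
    weights /= weights.sum()
    taken: list[tuple[str, int, int]] = []
    regions: list[CnaRegion] = []
    scopes = ["shared"] * n_shared + ["resistant_only"] * n_acquired
    for scope in scopes:
        for _ in range(1_000):
            chrom = rng.choice(chroms, p=weights)
            g = chrom_groups[chrom]
            n_in = int(rng.integers(min_probes, max_probes + 1))
            if n_in + 10 >= len(g):
                continue
            i0 = int(rng.integers(5, len(g) - n_in - 5))
            start = int(g["start"].iloc[i0])
            end = int(g["end"].iloc[i0 + n_in - 1])
            if any(c == chrom and start < e and s < end for c, s, e in taken):
                continue
            amp = float(rng.choice(amplitudes)) * float(rng.choice([-1.0, 1.0]))
            regions.append(CnaRegion(chrom, start, end, amp, scope))
            taken.append((chrom, start, end))
            break
        else:
            raise RuntimeError("could not place CNA region without overlap")
    return CnaSpec(regions)


def true_log2(design: ArrayDesign, cna: CnaSpec, scope_filter) -> np.ndarray:
    """Sum of region deltas covering each probe midpoint, for scopes passing the filter."""
    mid = (design.probes["start"].to_numpy() + design.probes["end"].to_numpy()) // 2
    chrom = design.probes["chrom"].to_numpy()
    out = np.zeros(len(design.probes))
    for r in cna.regions:
        if not scope_filter(r.scope):
            continue
        mask = (chrom == r.chrom) & (mid >= r.start) & (mid < r.end)
        out[mask] += r.delta_log2
    return out


def _check_no_same_scope_overlap(cna: CnaSpec) -> None:
    by_scope: dict[str, list[CnaRegion]] = {}
    for r in cna.regions:
        by_scope.setdefault(r.scope, []).append(r)
    for scope, regs in by_scope.items():
        for a in range(len(regs)):
            for b in range(a + 1, len(regs)):
                x, y = regs[a], regs[b]
                if x.chrom == y.chrom and x.start < y.end and y.start < x.end:
                    raise ValueError(
                        f"overlapping {scope} regions at {x.chrom}: ambiguous truth"
                    )


def _synthesize_channels(design: ArrayDesign, truth: np.ndarray, noise: NoiseModel,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = len(design.probes)
    gc = design.probes["gc"].to_numpy()
    lref = rng.normal(noise.baseline_log2_mean, noise.baseline_log2_sd, size=n)
    ltest = lref + truth
    # quadratic GC bias on the test channel, peak amplitude in log2 units
    gz = (gc - 0.5) / 0.2
    gc_eff = noise.gc_bias_amplitude * (gz ** 2)
    ltest = ltest + gc_eff - gc_eff.mean()
    # intensity-dependent dye multiplier on the reference channel
    A = 0.5 * (ltest + lref)
    z = (A - A.mean()) / (A.std() + 1e-12)
    mult = np.maximum(1.0 + noise.dye_bias_amplitude * z, 0.2)
    lref = lref + np.log2(mult)
    # per-channel noise; the log2 ratio then has SD probe_noise_sd
    ch_sd = noise.probe_noise_sd / np.sqrt(2.0)
    ltest = ltest + rng.normal(0.0, ch_sd, size=n)
    lref = lref + rng.normal(0.0, ch_sd, size=n)
    if noise.outlier_rate > 0:
        n_out = rng.binomial(n, noise.outlier_rate)
        if n_out:
            sel = rng.choice(n, size=n_out, replace=False)
            ltest[sel] += rng.standard_t(3, size=n_out) * 4.0 * max(noise.probe_noise_sd, 0.05)
    return np.power(2.0, ltest), np.power(2.0, lref)


def simulate_pair(design: ArrayDesign, cna: CnaSpec, noise: NoiseModel | None = None,
                  seed: int = 0) -> tuple[ProbeSet, ProbeSet, pd.DataFrame]:
    """Paired parental/resistant probe sets plus the ground-truth region table."""
    noise = noise or NoiseModel()
    _check_no_same_scope_overlap(cna)
    rng = np.random.default_rng([seed, 1])
    truth_parental = true_log2(design, cna, lambda s: s == "shared")
    truth_resistant = true_log2(design, cna, lambda s: True)

    def build(sample_id: str, truth: np.ndarray, r: np.random.Generator) -> ProbeSet:
        test, ref = _synthesize_channels(design, truth, noise, r)
        df = design.probes[["probe_id", "chrom", "start", "end", "gc"]].copy()
        df["intensity_test"] = test
        df["intensity_ref"] = ref
        df = df[["probe_id", "chrom", "start", "end", "intensity_test", "intensity_ref", "gc"]]
        return ProbeSet(sample_id, df, design.chrom_order)

    parental = build("parental", truth_parental, np.random.default_rng([seed, 2]))
    resistant = build("resistant", truth_resistant, np.random.default_rng([seed, 3]))
    return parental, resistant, cna.to_frame()


def score_differential(result, truth: pd.DataFrame, tol: float = 0.1) -> dict:
    """Compare called differential regions with the generator truth table.

    A truth acquired region is recovered when some called region overlaps it,
    matches its sign and has |diff_l2r - delta| < tol.  Also counts called
    regions overlapping shared (baseline) regions — the differential should
    cancel those — and called regions overlapping no truth region at all.
    """
    acquired = truth[truth["scope"] == "resistant_only"]
    shared = truth[truth["scope"] == "shared"]

    def overlaps(region, row) -> bool:
        return (region.chrom == row["chrom"] and region.start < row["end"]
                and row["start"] < region.end)

    recovered = 0
    errors = []
    for _, row in acquired.iterrows():
        hit = None
        for reg in result.regions:
            if overlaps(reg, row) and np.sign(reg.diff_l2r) == np.sign(row["delta_log2"]):
                hit = reg
                break
        if hit is not None and abs(hit.diff_l2r - row["delta_log2"]) < tol:
            recovered += 1
            errors.append(abs(hit.diff_l2r - row["delta_log2"]))
    shared_called = 0
    spurious = 0
    for reg in result.regions:
        if any(overlaps(reg, row) for _, row in shared.iterrows()):
            shared_called += 1
        elif not any(overlaps(reg, row) for _, row in acquired.iterrows()):
            spurious += 1
    return {
        "n_called": len(result.regions),
        "n_acquired": len(acquired),
        "n_recovered": recovered,
        "n_shared_called": shared_called,
        "n_spurious": spurious,
        "max_abs_error": max(errors) if errors else np.nan,
        "exact": recovered == len(acquired) and shared_called == 0
                 and len(result.regions) == len(acquired),
    }


def simulate_dose_response(ic50: float, doses, top: float = 1.0, bottom: float = 0.0,
                           hill: float = 1.0, replicates: int = 3,
                           noise_sd: float = 0.05, seed: int = 0,
                           compound: str = "drug", sample_id: str = "sample") -> DoseResponseData:
    """4PL-curve viability measurements with Gaussian noise, clipped at zero."""
    doses = np.asarray(doses, float)
    nz = doses[doses > 0]
    if not (nz.min() <= ic50 <= nz.max()):
        raise ValueError("truth ic50 must lie within the dose range")
    rng = np.random.default_rng(seed)
    all_d = np.repeat(doses, replicates)
    resp = four_pl(all_d, top, bottom, hill, ic50)
    resp = np.clip(resp + rng.normal(0.0, noise_sd, size=len(all_d)), 0.0, None)
    reps = np.tile(np.arange(replicates), len(doses))
    return DoseResponseData(compound, sample_id, all_d, resp, reps)


def make_annotation(design: ArrayDesign, bands_per_chrom: int = 8,
                    genes: list[tuple[str, int, int, str]] | None = None) -> GenomeAnnotation:
    """Synthetic annotation: equal-width cytobands per chromosome plus optional genes."""
    ann = GenomeAnnotation()
    from intervaltree import IntervalTree

    for chrom, length in design.chrom_lengths.items():
        tree = IntervalTree()
        width = length // bands_per_chrom
        arm = chrom.replace("chr", "")
        for b in range(bands_per_chrom):
            start = b * width
            end = length if b == bands_per_chrom - 1 else (b + 1) * width
            side = "p" if b < bands_per_chrom // 2 else "q"
            tree.addi(start, end, f"{arm}{side}{b + 1}")
        ann.cytobands[chrom] = tree
    if genes:
        for chrom, start, end, name in genes:
            ann.genes.setdefault(chrom, IntervalTree()).addi(start, end, name)
    return ann
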