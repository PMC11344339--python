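"""Pairwise identity-by-descent (PI_HAT) estimation and founder-haplotype scans.

The estimator is the classic method of moments on biallelic SNPs: for a
SNP with allele frequencies p and q = 1 − p, the probability of observing
identity-by-state (IBS) 0/1/2 conditional on sharing 0/1/2 alleles IBD is

    P(IBS0|Z0) = 2 p²q²              P(IBS1|Z1) = 2pq
    P(IBS1|Z0) = 4pq(p² + q²)        P(IBS2|Z1) = 1 − 2pq
    P(IBS2|Z0) = p⁴ + q⁴ + 4p²q²     P(IBS2|Z2) = 1

(each row sums to 1).  Solving the moment equations in cascade gives
ẑ0, ẑ1, ẑ2, which are truncated to [0, 1] and renormalized;
PI_HAT = ẑ2 + ẑ1/2 is the expected proportion of alleles shared IBD
(0 = unrelated, 0.5 = parent–offspring, 1 = identical genomes).

A founder haplotype around an index variant is detected by scanning
expanding SNP windows (±h SNPs, h on a fixed grid) and comparing the mean
pairwise PI_HAT among carriers with the same statistic at randomly placed
control intervals elsewhere in the genome.  The scan is exposed as a
model/results pair: :class:`FounderScan` holds the data and window
configuration, ``fit()`` returns a :class:`FounderScanResults` with the
curves, the control dispersion, the segment call, ``summary()`` and
``plot()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = [
    "GenotypePanel",
    "IBDEstimate",
    "ScanCurve",
    "ControlSummary",
    "SegmentCall",
    "FounderScan",
    "FounderScanResults",
    "estimate_freqs",
    "ibd_mom_estimate",
    "windowed_scan",
    "control_curves",
    "shared_segment_call",
    "read_vcf_panel",
    "read_pedmap_panel",
    "write_vcf_panel",
]

MISSING = -1


# ---------------------------------------------------------------------------
# Genotype panel
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Biallelic SNP dosage matrix with positions and allele frequencies.

    ``genotypes`` is (n_samples, n_snps) int8 with entries 0/1/2 (allele
    dosage) or −1 for missing.  SNPs are stored in chromosome blocks with
    strictly increasing positions within each chromosome.  ``freqs`` may
    be supplied (e.g. reference-population frequencies) or estimated from
    the panel.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ids: list[str]
    genotypes: np.ndarray
    freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.pos)):
            raise ValueError("genotype matrix must be samples × snps")
        if len(self.chrom) != len(self.pos) or len(self.ids) != len(self.pos):
            raise ValueError("chrom/pos/ids length mismatch")
        # chromosome-block layout with increasing positions
        seen: dict[str, int] = {}
        blocks: dict[str, list[int]] = {}
        order = 0
        prev = None
        for i, c in enumerate(self.chrom):
            if c != prev:
                if c in seen:
                    raise ValueError(f"chromosome {c} appears in non-contiguous blocks")
                seen[c] = order
                order += 1
                prev = c
                blocks[c] = [i, i]
            else:
                blocks[c][1] = i
        for c, (a, b) in blocks.items():
            if b > a and not np.all(np.diff(self.pos[a:b + 1]) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        self._blocks = {c: (a, b) for c, (a, b) in blocks.items()}
        if self.freqs is not None:
            self.freqs = np.asarray(self.freqs, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def chrom_slice(self, chrom: str) -> slice:
        if chrom not in self._blocks:
            raise KeyError(f"chromosome {chrom!r} not in panel")
        a, b = self._blocks[chrom]
        return slice(a, b + 1)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._blocks)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in panel") from None

    def nearest_snp(self, chrom: str, position: int) -> int:
        """Global index of the panel SNP nearest to (chrom, position)."""
        sl = self.chrom_slice(chrom)
        p = self.pos[sl]
        j = int(np.searchsorted(p, position))
        cands = [k for k in (j - 1, j) if 0 <= k < len(p)]
        best = min(cands, key=lambda k: abs(int(p[k]) - position))
        return sl.start + best

    def effective_freqs(self) -> np.ndarray:
        return self.freqs if self.freqs is not None else estimate_freqs(self)[0]

    def subset_snps(self, mask: np.ndarray) -> "GenotypePanel":
        idx = np.flatnonzero(mask)
        return GenotypePanel(
            list(self.samples), self.chrom[idx], self.pos[idx],
            [self.ids[i] for i in idx], self.genotypes[:, idx],
            None if self.freqs is None else self.freqs[idx])

    def quality_filter(self, min_maf: float = 0.05, max_missing: float = 0.05) -> "GenotypePanel":
        """Stand-in for an array 'high-confidence variant' list: keep SNPs
        with MAF ≥ ``min_maf`` and per-SNP missingness ≤ ``max_missing``."""
        f, mono = estimate_freqs(self)
        maf = np.minimum(f, 1 - f)
        miss = np.mean(self.genotypes == MISSING, axis=0)
        keep = (~mono) & np.isfinite(f) & (maf >= min_maf) & (miss <= max_missing)
        return self.subset_snps(keep)


def estimate_freqs(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP alternate-allele frequency and a monomorphic/unusable flag.

    frequency = Σdosage / (2 × non-missing count); SNPs with no calls get
    NaN and are flagged, as are frequencies of exactly 0 or 1.
    """
    g = panel.genotypes
    valid = g != MISSING
    n = valid.sum(axis=0)
    dose = np.where(valid, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n > 0, dose / (2.0 * np.maximum(n, 1)), np.nan)
    mono = (~np.isfinite(f)) | (f <= 0.0) | (f >= 1.0)
    return f, mono


# ---------------------------------------------------------------------------
# Method-of-moments estimator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IBDEstimate:
    z0: float
    z1: float
    z2: float
    pi_hat: float
    n_snps_used: int
    low_confidence: bool = False


def _pair_components(ga: np.ndarray, gb: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Per-SNP moment components for a sample pair, shape (8, n_snps).

    Rows: IBS0/1/2 indicators, then ΣP(IBS0|Z0), ΣP(IBS1|Z0), ΣP(IBS2|Z0),
    ΣP(IBS1|Z1), ΣP(IBS2|Z1) integrands.  SNPs that are missing in either
    sample or uninformative (freq outside (0,1)) contribute zeros.
    """
    ga = np.asarray(ga)
    gb = np.asarray(gb)
    p = np.asarray(freqs, dtype=float)
    valid = (ga != MISSING) & (gb != MISSING) & np.isfinite(p) & (p > 0.0) & (p < 1.0)
    q = 1.0 - p
    ibs = 2 - np.abs(ga.astype(np.int16) - gb.astype(np.int16))
    out = np.zeros((8, len(p)))
    out[0] = valid & (ibs == 0)
    out[1] = valid & (ibs == 1)
    out[2] = valid & (ibs == 2)
    pq = p * q
    out[3] = 2.0 * pq * pq
    out[4] = 4.0 * pq * (p * p + q * q)
    out[5] = p ** 4 + q ** 4 + 4.0 * pq * pq
    out[6] = 2.0 * pq
    out[7] = 1.0 - 2.0 * pq
    out[3:] *= valid
    return out


def _z_from_sums(S: np.ndarray) -> np.ndarray:
    """Solve the moment equations from summed components.

    ``S`` has shape (8, m) for m windows; returns (4, m): z0, z1, z2,
    pi_hat after truncation to [0,1] and renormalization.  Windows with
    no usable SNPs give NaN.
    """
    S = np.atleast_2d(S.T).T if S.ndim == 1 else S
    N0, N1, N2, S00, S10, S20, S11, S21 = S
    N = N0 + N1 + N2
    with np.errstate(invalid="ignore", divide="ignore"):
        z0 = N0 / S00
        z1 = (N1 - z0 * S10) / S11
        z2 = (N2 - z0 * S20 - z1 * S21) / N
    z = np.vstack([z0, z1, z2])
    z = np.clip(z, 0.0, None)
    total = z.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(total > 0, z / total, np.nan)
    z = np.where(N > 0, z, np.nan)
    pi = z[2] + 0.5 * z[1]
    return np.vstack([z, pi])


def ibd_mom_estimate(g_a: np.ndarray, g_b: np.ndarray, freqs: np.ndarray,
                     min_informative: int = 20) -> IBDEstimate:
    """Method-of-moments IBD estimate for one sample pair.

    Identical genotype vectors give PI_HAT = 1 exactly; independent
    Hardy–Weinberg draws give PI_HAT ≈ 0.  Symmetric in (a, b).  Pairs
    with fewer than ``min_informative`` usable SNPs are flagged
    low-confidence (the estimate is still returned).
    """
    comp = _pair_components(g_a, g_b, freqs)
    sums = comp.sum(axis=1, keepdims=True)
    z0, z1, z2, pi = _z_from_sums(sums)[:, 0]
    n_used = int(sums[0, 0] + sums[1, 0] + sums[2, 0])
    return IBDEstimate(float(z0), float(z1), float(z2), float(pi), n_used,
                       low_confidence=n_used < min_informative)


# ---------------------------------------------------------------------------
# Windowed scan
# ---------------------------------------------------------------------------

@dataclass
class ScanCurve:
    """Mean pairwise PI_HAT as a function of window half-width (in SNPs)."""

    index_variant: tuple[str, int]
    index_snp: int                      # global SNP index in the panel
    half_widths: np.ndarray             # SNP counts, strictly increasing
    mean_pihat: np.ndarray
    n_snps: np.ndarray                  # effective SNPs per window (chromosome-end truncated)
    window_lo_pos: np.ndarray
    window_hi_pos: np.ndarray
    per_pair: np.ndarray | None = None  # (n_pairs, n_h)
    pair_labels: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class ControlSummary:
    """Per-half-width mean and dispersion of scan curves at random control intervals."""

    n_intervals: int
    half_widths: np.ndarray
    mean_curve: np.ndarray
    sd_curve: np.ndarray
    curves: np.ndarray                  # (n_intervals, n_h)
    interval_snps: np.ndarray           # global SNP index of each control locus
    metadata: dict = field(default_factory=dict)


def _pair_curve_sums(panel: GenotypePanel, freqs: np.ndarray, ia: int, ib: int,
                     index_snp: int, half_widths: np.ndarray):
    """Window sums for one pair at one index SNP, via prefix sums over the
    widest window; returns (S, n_eff, (lo_idx, hi_idx) per h)."""
    sl = panel.chrom_slice(str(panel.chrom[index_snp]))
    hmax = int(half_widths[-1])
    lo = max(sl.start, index_snp - hmax)
    hi = min(sl.stop - 1, index_snp + hmax)
    comp = _pair_components(panel.genotypes[ia, lo:hi + 1],
                            panel.genotypes[ib, lo:hi + 1],
                            freqs[lo:hi + 1])
    cs = np.concatenate([np.zeros((8, 1)), np.cumsum(comp, axis=1)], axis=1)
    a = np.maximum(sl.start, index_snp - half_widths) - lo
    b = np.minimum(sl.stop - 1, index_snp + half_widths) - lo
    S = cs[:, b + 1] - cs[:, a]
    return S, (b - a + 1), (a + lo, b + lo)


def windowed_scan(panel: GenotypePanel, index_variant: tuple[str, int],
                  carrier_samples: Sequence[str], max_flank: int = 500,
                  step: int = 50, freqs: np.ndarray | None = None,
                  index_snp: int | None = None) -> ScanCurve:
    """Mean pairwise PI_HAT among carriers in expanding windows around an index variant.

    For each half-width h in {step, 2·step, …, max_flank} the window is
    the index SNP ± h panel SNPs, truncated at chromosome ends (the
    effective SNP count is recorded).  Requires ≥ 2 carriers.
    """
    if len(carrier_samples) < 2:
        raise ValueError("windowed scan requires at least 2 carrier samples")
    if max_flank < step or step < 1:
        raise ValueError("require step >= 1 and max_flank >= step")
    chrom, position = index_variant
    if index_snp is None:
        index_snp = panel.nearest_snp(str(chrom), int(position))
    f = freqs if freqs is not None else panel.effective_freqs()
    half_widths = np.arange(step, max_flank + 1, step, dtype=int)
    idxs = [panel.sample_index(s) for s in carrier_samples]
    pairs = list(combinations(range(len(idxs)), 2))
    per_pair = np.empty((len(pairs), len(half_widths)))
    n_eff = None
    lo_idx = hi_idx = None
    for k, (x, y) in enumerate(pairs):
        S, n_eff, (lo_idx, hi_idx) = _pair_curve_sums(
            panel, f, idxs[x], idxs[y], index_snp, half_widths)
        per_pair[k] = _z_from_sums(S)[3]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_pair, axis=0)
    labels = [(carrier_samples[x], carrier_samples[y]) for x, y in pairs]
    return ScanCurve((str(chrom), int(position)), index_snp, half_widths, mean,
                     np.asarray(n_eff), panel.pos[lo_idx], panel.pos[hi_idx],
                     per_pair=per_pair, pair_labels=labels)


def _place_control_indices(panel: GenotypePanel, n_intervals: int, max_flank: int,
                           rng: np.random.Generator,
                           exclude_snp: int | None = None) -> np.ndarray:
    """Random control loci, pairwise non-overlapping within 2·max_flank SNPs
    on the same chromosome (rejection sampling, seeded).  Returns as many
    as can be placed, with a warning if fewer than requested."""
    min_sep = 2 * max_flank
    chosen: list[int] = [] if exclude_snp is None else [exclude_snp]
    placed: list[int] = []
    attempts = 0
    max_attempts = max(1000, 200 * n_intervals)
    while len(placed) < n_intervals and attempts < max_attempts:
        attempts += 1
        cand = int(rng.integers(0, panel.n_snps))
        c = panel.chrom[cand]
        ok = all(panel.chrom[o] != c or abs(o - cand) > min_sep for o in chosen)
        if ok:
            chosen.append(cand)
            placed.append(cand)
    if len(placed) < n_intervals:
        warnings.warn(f"could only place {len(placed)} of {n_intervals} "
                      f"non-overlapping control intervals", stacklevel=2)
    # ties/ordering: deterministic report order by genomic coordinate
    placed.sort(key=lambda i: (str(panel.chrom[i]), int(panel.pos[i])))
    return np.asarray(placed, dtype=int)


def control_curves(panel: GenotypePanel, carrier_samples: Sequence[str],
                   n_intervals: int = 200, max_flank: int = 500, step: int = 50,
                   seed: int | np.random.Generator | None = None,
                   freqs: np.ndarray | None = None,
                   exclude_snp: int | None = None) -> ControlSummary:
    """Scan curves at randomly placed control loci (genome-wide null).

    Deterministic under a fixed seed; dispersion is the SD across
    intervals of the per-interval carrier-pair mean, per half-width.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half_widths = np.arange(step, max_flank + 1, step, dtype=int)
    f = freqs if freqs is not None else panel.effective_freqs()
    if n_intervals == 0:
        empty = np.zeros((0, len(half_widths)))
        return ControlSummary(0, half_widths, np.full(len(half_widths), np.nan),
                              np.full(len(half_widths), np.nan), empty,
                              np.zeros(0, dtype=int),
                              metadata={"requested": 0})
    loci = _place_control_indices(panel, n_intervals, max_flank, rng, exclude_snp)
    curves = np.empty((len(loci), len(half_widths)))
    for r, snp in enumerate(loci):
        sc = windowed_scan(panel, (str(panel.chrom[snp]), int(panel.pos[snp])),
                           carrier_samples, max_flank, step, freqs=f,
                           index_snp=int(snp))
        curves[r] = sc.mean_pihat
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(curves, axis=0)
        sd = np.nanstd(curves, axis=0, ddof=1) if len(loci) > 1 else np.full(len(half_widths), np.nan)
    return ControlSummary(len(loci), half_widths, mean, sd, curves, loci,
                          metadata={"requested": n_intervals,
                                    "separation_snps": 2 * max_flank,
                                    "snp_filter": "MAF/missingness stand-in for "
                                                  "'highly confident' array variants"})


# ---------------------------------------------------------------------------
# Segment call
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentCall:
    decision: str                    # "founder-compatible" | "negative"
    extent_snps: int                 # estimated shared-segment SNP count
    span_mb: float                   # genomic span of that extent around the index
    detection_range_h: int | None    # largest half-width significantly above control
    unbounded: bool = False
    plateau_pihat: float = float("nan")

    @property
    def is_founder_compatible(self) -> bool:
        return self.decision == "founder-compatible"


def _fit_segment_extent(scan: ScanCurve, baseline: np.ndarray) -> tuple[int, float, bool]:
    """Estimate the shared-segment SNP count from the erosion of the scan curve.

    The expected curve under a contiguous shared block of s SNPs centred
    on the index is mean(h) ≈ baseline(h) + π_seg · min(s, n_h)/n_h, i.e.
    flat while the window sits inside the block and diluted ∝ 1/n_h
    beyond it.  A 1-D grid search over s with the closed-form π_seg given
    s minimizes the squared error over the h grid.
    """
    n_h = scan.n_snps.astype(float)
    y = scan.mean_pihat - np.where(np.isfinite(baseline), baseline, 0.0)
    good = np.isfinite(y)
    if good.sum() == 0:
        return 0, float("nan"), False
    n_max = int(n_h[good].max())
    sse = np.empty(n_max)
    amps = np.empty(n_max)
    for s in range(1, n_max + 1):
        fshape = np.minimum(s, n_h) / n_h
        denom = float((fshape[good] ** 2).sum())
        amp = float((fshape[good] * y[good]).sum()) / denom
        resid = y[good] - amp * fshape[good]
        sse[s - 1] = float((resid ** 2).sum())
        amps[s - 1] = amp
    best_s = int(np.argmin(sse)) + 1
    # every s at or below the smallest window fits identically (the window
    # grid cannot resolve segments shorter than its smallest window), and
    # exact ties can extend further: report the largest tied s
    while best_s < n_max and sse[best_s] <= sse[best_s - 1] + 1e-12:
        best_s += 1
    best_amp = float(amps[best_s - 1])
    unbounded = best_s >= n_max
    return best_s, best_amp, unbounded


def shared_segment_call(scan: ScanCurve, control: ControlSummary,
                        margin_sd: float = 3.0, min_extent_snps: int = 100,
                        panel: GenotypePanel | None = None) -> SegmentCall:
    """Decide whether carriers share a founder segment and size it.

    Detection uses the control-margin rule: half-widths where the scan
    mean exceeds the control mean by ``margin_sd`` control SDs are
    significant, and the largest such h is the detection range.  The
    *extent* (shared SNP count) is estimated separately by inverting the
    dilution of the curve (see :func:`_fit_segment_extent`), because
    residual sharing from a finite segment stays detectable in windows
    much wider than the segment itself.  Decision is founder-compatible
    iff sharing is significant somewhere and the extent reaches
    ``min_extent_snps``.
    """
    if len(scan.half_widths) != len(control.half_widths) or \
            np.any(scan.half_widths != control.half_widths):
        raise ValueError("scan and control must share the same half-width grid")
    sd = np.where(np.isfinite(control.sd_curve) & (control.sd_curve > 0),
                  control.sd_curve, np.nan)
    with np.errstate(invalid="ignore"):
        significant = scan.mean_pihat > control.mean_curve + margin_sd * sd
    significant = np.where(np.isfinite(scan.mean_pihat), significant, False)
    detection = int(scan.half_widths[significant].max()) if significant.any() else None

    # saturation: near-total sharing with no erosion means the segment extends
    # beyond the widest window and cannot be bounded by this scan
    saturated = bool(np.isfinite(scan.mean_pihat[-1]) and scan.mean_pihat[-1] >= 0.9
                     and (scan.mean_pihat[0] - scan.mean_pihat[-1]) <= 0.05)
    if saturated:
        extent, amp, unbounded = int(scan.n_snps[-1]), float(scan.mean_pihat[-1]), True
    else:
        extent, amp, unbounded = _fit_segment_extent(scan, control.mean_curve)
        if unbounded:
            extent = int(scan.n_snps[-1])

    span_mb = float("nan")
    if panel is not None and extent > 0:
        sl = panel.chrom_slice(scan.index_variant[0])
        half = extent // 2
        lo = max(sl.start, scan.index_snp - half)
        hi = min(sl.stop - 1, scan.index_snp + half)
        span_mb = (int(panel.pos[hi]) - int(panel.pos[lo])) / 1e6

    positive = detection is not None and extent >= min_extent_snps
    return SegmentCall("founder-compatible" if positive else "negative",
                       extent, span_mb, detection, unbounded=unbounded,
                       plateau_pihat=amp)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class FounderScan:
    """Founder-haplotype IBD scan model.

    Parameters
    ----------
    panel
        Genotype panel (all cohort samples; frequencies are estimated
        from it unless the panel carries ``freqs``).
    index_variant
        ``(chrom, position)`` of the variant of interest; mapped to the
        nearest panel SNP.
    carriers
        Sample ids of the variant carriers (≥ 2).
    max_flank, step
        Window grid in SNP counts: half-widths step, 2·step, …, max_flank.
    min_maf, max_missing
        SNP pre-filter standing in for a curated high-confidence array
        variant list.
    """

    def __init__(self, panel: GenotypePanel, index_variant: tuple[str, int],
                 carriers: Sequence[str], max_flank: int = 500, step: int = 50,
                 min_maf: float = 0.05, max_missing: float = 0.05):
        self.raw_panel = panel
        self.panel = panel.quality_filter(min_maf=min_maf, max_missing=max_missing)
        self.index_variant = (str(index_variant[0]), int(index_variant[1]))
        self.carriers = list(carriers)
        for s in self.carriers:
            self.panel.sample_index(s)
        if len(self.carriers) < 2:
            raise ValueError("at least 2 carriers required")
        self.max_flank = int(max_flank)
        self.step = int(step)
        self.min_maf = min_maf
        self.max_missing = max_missing

    def fit(self, n_controls: int = 200, seed: int | None = None,
            margin_sd: float = 3.0, min_extent_snps: int = 100,
            cohort_baseline_pairs: int = 0) -> "FounderScanResults":
        """Run the scan, the randomized control and the segment call.

        ``cohort_baseline_pairs`` > 0 additionally computes the scan curve
        over that many randomly chosen cohort sample pairs (the "full
        cohort" reference curve); 0 skips it.
        """
        rng = np.random.default_rng(seed)
        freqs = self.panel.effective_freqs()
        scan = windowed_scan(self.panel, self.index_variant, self.carriers,
                             self.max_flank, self.step, freqs=freqs)
        control = control_curves(self.panel, self.carriers, n_controls,
                                 self.max_flank, self.step, seed=rng,
                                 freqs=freqs, exclude_snp=scan.index_snp)
        call = shared_segment_call(scan, control, margin_sd=margin_sd,
                                   min_extent_snps=min_extent_snps,
                                   panel=self.panel)
        baseline = None
        if cohort_baseline_pairs > 0:
            all_pairs = list(combinations(self.panel.samples, 2))
            k = min(cohort_baseline_pairs, len(all_pairs))
            sel = rng.choice(len(all_pairs), size=k, replace=False)
            # reuse the scan machinery pair by pair
            hw = scan.half_widths
            vals = np.empty((k, len(hw)))
            for r, pi_idx in enumerate(sel):
                a, b = all_pairs[int(pi_idx)]
                S, _, _ = _pair_curve_sums(self.panel, freqs,
                                           self.panel.sample_index(a),
                                           self.panel.sample_index(b),
                                           scan.index_snp, hw)
                vals[r] = _z_from_sums(S)[3]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                baseline = np.nanmean(vals, axis=0)
        return FounderScanResults(self, scan, control, call,
                                  cohort_baseline=baseline, seed=seed)


class FounderScanResults:
    """Fitted founder scan: curves, control dispersion and the segment call."""

    def __init__(self, model: FounderScan, scan: ScanCurve, control: ControlSummary,
                 segment: SegmentCall, cohort_baseline: np.ndarray | None = None,
                 seed: int | None = None):
        self.model = model
        self.scan = scan
        self.control = control
        self.segment = segment
        self.cohort_baseline = cohort_baseline
        self.seed = seed

    def to_frame(self):
        """Tidy per-half-width table (h, n SNPs, scan mean, control mean/SD)."""
        import pandas as pd

        df = pd.DataFrame({
            "half_width_snps": self.scan.half_widths,
            "n_snps": self.scan.n_snps,
            "mean_pihat": self.scan.mean_pihat,
            "control_mean": self.control.mean_curve,
            "control_sd": self.control.sd_curve,
        })
        if self.cohort_baseline is not None:
            df["cohort_mean"] = self.cohort_baseline
        return df

    def summary(self) -> str:
        chrom, pos = self.scan.index_variant
        lines = [
            "Founder-haplotype IBD scan",
            "=" * 60,
            f"Index variant:      {chrom}:{pos} (panel SNP #{self.scan.index_snp})",
            f"Carriers:           {len(self.model.carriers)} "
            f"({len(self.scan.pair_labels)} pairs)",
            f"Window grid:        ±{self.model.step}..±{self.model.max_flank} SNPs "
            f"(step {self.model.step})",
            f"Control intervals:  {self.control.n_intervals}",
            f"SNP filter:         MAF ≥ {self.model.min_maf}, missingness ≤ "
            f"{self.model.max_missing} (stand-in for curated array variants)",
            "",
            self.to_frame().to_string(index=False, float_format=lambda x: f"{x:.4f}"),
            "",
            f"Decision:           {self.segment.decision}",
            f"Segment extent:     {self.segment.extent_snps} SNPs"
            + (" (unbounded)" if self.segment.unbounded else ""),
            f"Genomic span:       {self.segment.span_mb:.2f} Mb",
            f"Detection range:    ±{self.segment.detection_range_h} SNPs"
            if self.segment.detection_range_h is not None else "Detection range:    none",
        ]
        return "\n".join(lines)

    def plot(self, path=None):
        """Two-panel figure: scan around the index variant (per-pair and
        mean) and the randomized-control mean ± 3 SD."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        h = self.scan.half_widths
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        if self.scan.per_pair is not None:
            for row, lab in zip(self.scan.per_pair, self.scan.pair_labels):
                ax1.plot(h, row, color="0.75", lw=0.8)
        ax1.plot(h, self.scan.mean_pihat, "o-", color="tab:red", label="carrier mean")
        if self.cohort_baseline is not None:
            ax1.plot(h, self.cohort_baseline, "s--", color="tab:blue", label="cohort")
        ax1.set_title(f"scan at {self.scan.index_variant[0]}:{self.scan.index_variant[1]}")
        ax1.set_xlabel("half-width (SNPs)")
        ax1.set_ylabel(r"mean $\hat{\pi}$ (PI_HAT)")
        ax1.legend(frameon=False)
        m, s = self.control.mean_curve, self.control.sd_curve
        ax2.plot(h, m, "o-", color="tab:gray", label="control mean")
        ok = np.isfinite(s)
        ax2.fill_between(h[ok], (m - 3 * s)[ok], (m + 3 * s)[ok], color="tab:gray",
                         alpha=0.25, label="±3 SD")
        ax2.plot(h, self.scan.mean_pihat, "o-", color="tab:red", alpha=0.6)
        ax2.set_title(f"{self.control.n_intervals} random control intervals")
        ax2.set_xlabel("half-width (SNPs)")
        ax2.legend(frameon=False)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_vcf_panel(path) -> GenotypePanel:
    """Load biallelic SNPs from a VCF into a :class:`GenotypePanel` (GT field)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, ids, rows = [], [], [], []
    code = {0: 0, 1: 1, 3: 2, 2: MISSING}   # cyvcf2 gt_types: 2 = unknown
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append([code[int(t)] for t in var.gt_types])
    geno = np.asarray(rows, dtype=np.int8).T if rows else np.zeros((len(samples), 0), np.int8)
    return GenotypePanel(samples, np.asarray(chroms, dtype=object),
                         np.asarray(poss, dtype=np.int64), ids, geno)


def write_vcf_panel(panel: GenotypePanel, path, ref: str = "A", alt: str = "G") -> None:
    """Write the panel as a minimal uncompressed VCF (GT only)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in panel.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        for j in range(panel.n_snps):
            gts = "\t".join(gt_str[int(g)] for g in panel.genotypes[:, j])
            fh.write(f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.ids[j]}\t{ref}\t{alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_pedmap_panel(ped_path, map_path) -> GenotypePanel:
    """Load a text PED/MAP pair.  Dosages count the first allele observed
    per SNP (A1); the moment estimator is symmetric in allele labelling."""
    chroms, ids, poss = [], [], []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chroms.append(parts[0])
            ids.append(parts[1])
            poss.append(int(parts[3]))
    n_snps = len(poss)
    samples, rows = [], []
    a1: list[str | None] = [None] * n_snps
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(f"PED row for {parts[1] if len(parts) > 1 else '?'} has "
                                 f"{len(parts) - 6} allele fields, expected {2 * n_snps}")
            samples.append(parts[1])
            alleles = parts[6:]
            row = np.empty(n_snps, dtype=np.int8)
            for j in range(n_snps):
                x, y = alleles[2 * j], alleles[2 * j + 1]
                if x == "0" or y == "0":
                    row[j] = MISSING
                    continue
                if a1[j] is None:
                    a1[j] = x
                row[j] = (x == a1[j]) + (y == a1[j])
            rows.append(row)
    geno = np.vstack(rows) if rows else np.zeros((0, n_snps), np.int8)
    return GenotypePanel(samples, np.asarray(chroms, dtype=object),
                         np.asarray(poss, dtype=np.int64), ids, geno)
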