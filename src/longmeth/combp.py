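"""Spatially corrected region calling from per-probe p-values.

The pipeline mirrors the classical comb-p procedure:

1. estimate the autocorrelation of z-transformed p-values in genomic
   distance bins (:func:`estimate_acf`);
2. smooth each probe's p-value with its +/- window neighbourhood using the
   Stouffer-Liptak combination, whose variance term is inflated by the
   binned pairwise correlations (:func:`slk_correct`);
3. find maximal runs of corrected p-values below a seed threshold with
   consecutive probes at most ``dist`` apart (:func:`find_candidate_regions`);
4. combine each candidate's *raw* p-values into a single region p
   (:func:`region_pvalue`) -- candidates were found on smoothed values, so
   combining the smoothed values again would double-count evidence;
5. adjust the region p for the number of similarly sized regions the covered
   genome could hold (:func:`sidak_adjust`).

Negative estimated correlations are clipped to zero before combination so
the variance term stays valid; pair distances beyond the last ACF bin reuse
the last bin's value.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from . import coords
from .errors import InsufficientPairsError

_P_FLOOR = 1e-16
_P_CEIL = 1.0 - 1e-16


def _clamp_p(p):
    return np.clip(np.asarray(p, dtype=float), _P_FLOOR, _P_CEIL)


def _as_chrom(chrom, n):
    if chrom is None:
        return np.zeros(n, dtype=object)
    return np.asarray(chrom, dtype=object)


def _chrom_segments(chrom):
    """Yield (start, stop) index slices of consecutive equal chromosome labels."""
    n = len(chrom)
    start = 0
    for i in range(1, n + 1):
        if i == n or chrom[i] != chrom[start]:
            yield start, i
            start = i


@dataclass
class AcfEstimate:
    """Distance-binned autocorrelation of z-transformed p-values."""

    bin_edges: np.ndarray  # 0, step, 2*step, ..., window
    correlations: np.ndarray  # one value per bin, estimated then gap-filled
    n_pairs: np.ndarray

    @property
    def step(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def sigma(self, distances) -> np.ndarray:
        """Correlation used in combination for the given pair distances.

        Clipped to [0, 1]; distances beyond the last bin inherit its value,
        distance 0 (position ties) falls in the first bin.
        """
        d = np.atleast_1d(np.asarray(distances, dtype=float))
        idx = np.clip(np.ceil(d / self.step).astype(int) - 1, 0, len(self.correlations) - 1)
        return np.clip(self.correlations[idx], 0.0, 1.0)


def estimate_acf(pvals, positions, window: int = 500, step: int = 50,
                 chrom=None, min_pairs: int = 10) -> AcfEstimate:
    """Estimate p-value autocorrelation in ``step``-wide distance bins up to ``window``.

    Probes are z-transformed (z = Phi^-1(1 - p)); for each bin the Pearson
    correlation is computed over all same-chromosome probe pairs whose
    distance falls in the bin.  Bins with fewer than ``min_pairs`` pairs
    inherit the previous bin's value (0 for a first bin with too few pairs);
    a bin whose z-values are constant gets correlation 0 with a warning.
    """
    p = _clamp_p(pvals)
    pos = np.asarray(positions, dtype=np.int64)
    if p.shape != pos.shape:
        raise ValueError("pvals and positions must have equal length")
    ch = _as_chrom(chrom, len(p))
    for a, b in _chrom_segments(ch):
        if np.any(np.diff(pos[a:b]) < 0):
            raise ValueError("positions must be sorted within each chromosome")
    z = norm.isf(p)

    edges = np.arange(0, window + step, step, dtype=float)
    nbins = len(edges) - 1
    pair_d, pair_i, pair_j = [], [], []
    for a, b in _chrom_segments(ch):
        seg = pos[a:b]
        for i in range(len(seg)):
            hi = np.searchsorted(seg, seg[i] + window, side="right")
            for j in range(i + 1, hi):
                pair_d.append(seg[j] - seg[i])
                pair_i.append(a + i)
                pair_j.append(a + j)
    if not pair_d:
        raise InsufficientPairsError(
            f"no same-chromosome probe pairs within {window} bp; "
            "cannot estimate spatial correlation"
        )
    pair_d = np.asarray(pair_d, dtype=float)
    zi = z[np.asarray(pair_i)]
    zj = z[np.asarray(pair_j)]
    bin_idx = np.clip(np.ceil(pair_d / step).astype(int) - 1, 0, nbins - 1)

    corr = np.zeros(nbins)
    n_pairs = np.zeros(nbins, dtype=int)
    prev = 0.0
    for b in range(nbins):
        mask = bin_idx == b
        n_pairs[b] = int(mask.sum())
        if n_pairs[b] < min_pairs:
            corr[b] = prev
            continue
        x, y = zi[mask], zj[mask]
        if np.var(x) < 1e-30 or np.var(y) < 1e-30:
            warnings.warn(f"constant z in ACF bin {b}; correlation set to 0", stacklevel=2)
            corr[b] = 0.0
        else:
            corr[b] = float(np.corrcoef(x, y)[0, 1])
        prev = corr[b]
    return AcfEstimate(bin_edges=edges, correlations=corr, n_pairs=n_pairs)


def _stouffer_liptak(z_vals: np.ndarray, distances: np.ndarray, acf: AcfEstimate | None) -> float:
    """Combined z for a set of probes with pairwise distances ``distances``."""
    k = len(z_vals)
    sigma_sum = 0.0
    if k > 1 and len(distances):
        sig = acf.sigma(distances) if acf is not None else np.zeros(len(distances))
        sigma_sum = float(np.sum(sig))
    return float(np.sum(z_vals) / np.sqrt(k + 2.0 * sigma_sum))


def _pair_distances(pos: np.ndarray) -> np.ndarray:
    d = np.abs(pos[:, None] - pos[None, :])
    iu = np.triu_indices(len(pos), k=1)
    return d[iu].astype(float)


def slk_correct(pvals, positions, acf: AcfEstimate, window: int = 500, chrom=None):
    """Neighbourhood-smoothed (Stouffer-Liptak) p-value for every probe.

    Each probe is combined with all same-chromosome probes within
    ``+/- window`` bp.  Isolated probes keep their raw p exactly.
    """
    p = _clamp_p(pvals)
    pos = np.asarray(positions, dtype=np.int64)
    ch = _as_chrom(chrom, len(p))
    z = norm.isf(p)
    out = np.empty(len(p))
    for a, b in _chrom_segments(ch):
        seg = pos[a:b]
        for i in range(len(seg)):
            lo = np.searchsorted(seg, seg[i] - window, side="left")
            hi = np.searchsorted(seg, seg[i] + window, side="right")
            if hi - lo == 1:
                out[a + i] = np.asarray(pvals, dtype=float)[a + i]
                continue
            nb_pos = seg[lo:hi]
            zc = _stouffer_liptak(z[a + lo:a + hi], _pair_distances(nb_pos), acf)
            out[a + i] = float(norm.sf(zc))
    return np.clip(out, _P_FLOOR, 1.0)


def find_candidate_regions(corrected_pvals, positions, seed_p: float = 0.1,
                           dist: int = 500, chrom=None):
    """Maximal runs of probes with corrected p < ``seed_p`` and gaps <= ``dist``.

    Returns a list of dicts ``{"chrom", "indices"}`` with indices into the
    input arrays; genomic extent is derived downstream.
    """
    p = np.asarray(corrected_pvals, dtype=float)
    pos = np.asarray(positions, dtype=np.int64)
    ch = _as_chrom(chrom, len(p))
    regions = []
    for a, b in _chrom_segments(ch):
        run = []
        last_pos = None
        for i in range(a, b):
            if np.isfinite(p[i]) and p[i] < seed_p:
                if run and pos[i] - last_pos > dist:
                    regions.append({"chrom": ch[i], "indices": np.asarray(run)})
                    run = []
                run.append(i)
                last_pos = pos[i]
            else:
                if run:
                    regions.append({"chrom": ch[i], "indices": np.asarray(run)})
                    run = []
                    last_pos = None
        if run:
            regions.append({"chrom": ch[b - 1], "indices": np.asarray(run)})
    return regions


def region_pvalue(pvals, positions, acf: AcfEstimate | None) -> float:
    """Single Stouffer-Liptak combination of a region's raw p-values."""
    p_raw = np.asarray(pvals, dtype=float)
    if p_raw.size == 0:
        raise ValueError("region must contain at least one probe")
    if p_raw.size == 1:
        return float(p_raw[0])
    p = _clamp_p(p_raw)
    pos = np.asarray(positions, dtype=np.int64)
    zc = _stouffer_liptak(norm.isf(p), _pair_distances(pos), acf)
    return float(np.clip(norm.sf(zc), _P_FLOOR, 1.0))


def sidak_adjust(slk_p: float, region_width: int, total_covered_bases: int) -> float:
    """Sidak correction: 1 - (1 - p)^(coverage / width).

    ``total_covered_bases / region_width`` is the number of similarly sized
    regions the analysed genome could hold; a ratio below 1 is clamped to 1.
    """
    if not (0.0 <= slk_p <= 1.0):
        raise ValueError(f"slk_p must be in [0, 1], got {slk_p}")
    if region_width < 1:
        raise ValueError("region_width must be >= 1")
    ratio = max(float(total_covered_bases) / float(region_width), 1.0)
    if slk_p == 0.0:
        return 0.0
    if slk_p == 1.0:
        return 1.0
    return float(-np.expm1(ratio * np.log1p(-slk_p)))


@dataclass
class RegionResult:
    """A called region; ``start``/``stop`` are 0-based half-open."""

    chrom: str
    start: int
    stop: int
    probe_ids: list = field(default_factory=list)
    n_probes: int = 0
    slk_p: float = np.nan
    sidak_p: float = np.nan
    leading_probe: str | None = None

    @property
    def width(self) -> int:
        return coords.interval_width(self.start, self.stop)

    @property
    def midpoint(self) -> int:
        return coords.interval_midpoint(self.start, self.stop)


def total_coverage(positions, chrom=None) -> int:
    """Spanned extent (max pos - min pos) of analysed probes, summed over chromosomes."""
    pos = np.asarray(positions, dtype=np.int64)
    ch = _as_chrom(chrom, len(pos))
    total = 0
    for a, b in _chrom_segments(ch):
        total += int(pos[a:b].max() - pos[a:b].min())
    return total


def call_regions(pvals, positions, chrom, probe_ids, window: int = 500,
                 step: int = 50, seed_p: float = 0.1, dist: int = 500) -> list[RegionResult]:
    """Full regional pipeline: ACF -> SLK smoothing -> peaks -> region p -> Sidak.

    Inputs must be sorted by (chromosome, position); ``probe_ids`` key the
    per-probe results.  Returns one :class:`RegionResult` per candidate run
    (no retention filtering here; see :mod:`longmeth.dmr`).
    """
    p = np.asarray(pvals, dtype=float)
    pos = np.asarray(positions, dtype=np.int64)
    ch = _as_chrom(chrom, len(p))
    ids = np.asarray(probe_ids, dtype=object)
    finite = np.isfinite(p)
    p, pos, ch, ids = p[finite], pos[finite], ch[finite], ids[finite]
    if len(p) < 2:
        return []
    acf = estimate_acf(p, pos, window=window, step=step, chrom=ch)
    corrected = slk_correct(p, pos, acf, window=window, chrom=ch)
    candidates = find_candidate_regions(corrected, pos, seed_p=seed_p, dist=dist, chrom=ch)
    coverage = total_coverage(pos, ch)
    out = []
    for cand in candidates:
        idx = cand["indices"]
        rpos = pos[idx]
        rp = p[idx]
        start, stop = coords.points_to_interval(int(rpos.min()), int(rpos.max()))
        slk = region_pvalue(rp, rpos, acf)
        sidak = sidak_adjust(slk, coords.interval_width(start, stop), coverage)
        lead_order = np.lexsort((rpos, rp))  # smallest p, ties -> lowest position
        out.append(
            RegionResult(
                chrom=str(cand["chrom"]),
                start=start,
                stop=stop,
                probe_ids=list(ids[idx]),
                n_probes=int(len(idx)),
                slk_p=slk,
                sidak_p=sidak,
                leading_probe=str(ids[idx][lead_order[0]]),
            )
        )
    return out
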