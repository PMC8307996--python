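"""Spectral preprocessing: TSP referencing and normalization, COW and
icoshift alignment, STOCSY, and metabolite relative integrals.

The relative integral of a metabolite is the sum of data points over its
resonance window(s) after alignment, with the third quartile (Q3) of a
signal-free noise region subtracted.  Two subtraction conventions are
offered: ``once`` subtracts Q3 a single time per integral (the literal
reading), ``per_point`` subtracts Q3 for every point in the region (the
baseline-style correction); both are exposed because the convention in use
matters only as a constant offset per region size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .containers import FeatureTable, SpectraSet, Spectrum1D, window_mask

log = logging.getLogger("rheumet.preproc")

DEFAULT_NOISE_WINDOW = (9.7, 10.3)  # signal-free in serum CPMG spectra

__all__ = [
    "RegionDef", "NoiseSpec", "DEFAULT_NOISE_WINDOW",
    "reference_to_tsp", "normalize_to_tsp", "cow_align", "icoshift_align",
    "stocsy", "integrate_regions", "panel_to_regions",
    "load_regions", "save_regions", "preprocess_set",
]


@dataclass
class RegionDef:
    """A named integration region: one or more disjoint ppm windows."""

    name: str
    windows: list[tuple[float, float]]
    multiplicity: str = ""

    def __post_init__(self) -> None:
        for lo, hi in self.windows:
            if not lo < hi:
                raise ValueError(f"region {self.name}: window [{lo},{hi}) empty")
        wins = sorted(self.windows)
        for (a, b), (c, d) in zip(wins, wins[1:]):
            if c < b:
                raise ValueError(f"region {self.name}: overlapping windows")


@dataclass
class NoiseSpec:
    """Signal-free window whose Q3 is subtracted from every integral."""

    window: tuple[float, float] = DEFAULT_NOISE_WINDOW
    mode: str = "once"  # or "per_point"

    def __post_init__(self) -> None:
        if self.mode not in ("once", "per_point"):
            raise ValueError("mode must be 'once' or 'per_point'")
        lo, hi = self.window
        if not lo < hi:
            raise ValueError("noise window empty")


# --------------------------------------------------------------------------
# referencing and normalization
# --------------------------------------------------------------------------

def _parabolic_apex(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Apex position via parabola through the 3 points around index i."""
    if i == 0 or i == len(x) - 1:
        return x[i]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return x[i]
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1, 1))
    return x[i] + delta * (x[min(i + 1, len(x) - 1)] - x[i])


def reference_to_tsp(s: Spectrum1D,
                     search_window: tuple[float, float] = (-0.3, 0.3)
                     ) -> Spectrum1D:
    """Translate the ppm axis so the tallest peak in the search window
    (the TSP resonance) sits at exactly 0.000 ppm.  Intensities unchanged.

    Raises ``ValueError("TSP not found")`` when no local maximum rises more
    than 5 noise MADs above the window median.
    """
    mask = window_mask(s.ppm, *search_window)
    if not mask.any():
        raise ValueError("search window outside axis range")
    win_ppm, win_y = s.ppm[mask], s.intensity[mask]
    med = np.median(win_y)
    mad = np.median(np.abs(win_y - med))
    i = int(np.argmax(win_y))
    if mad == 0 or win_y[i] <= med + 5 * mad:
        raise ValueError("TSP not found")
    apex = _parabolic_apex(win_ppm, win_y, i)
    return Spectrum1D(s.ppm - apex, s.intensity.copy(), s.sample_id)


def normalize_to_tsp(s: Spectrum1D,
                     tsp_window: tuple[float, float] = (-0.05, 0.05),
                     target_area: float = 100.0) -> Spectrum1D:
    """Scale intensities so the TSP-window point sum equals ``target_area``."""
    if target_area <= 0:
        raise ValueError("target_area must be positive")
    tsp_sum = s.intensity[window_mask(s.ppm, *tsp_window)].sum()
    if tsp_sum <= 0:
        raise ValueError("TSP sum is not positive; cannot normalize")
    return Spectrum1D(s.ppm.copy(), s.intensity * (target_area / tsp_sum),
                      s.sample_id)


# --------------------------------------------------------------------------
# correlation optimized warping
# --------------------------------------------------------------------------

def _seg_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cow_align(target: Spectrum1D, reference: Spectrum1D,
              segment_length: int = 60, slack: int = 3,
              max_offset: int | None = None) -> Spectrum1D:
    """Correlation optimized warping of ``target`` onto ``reference``.

    Piecewise-linear warp found by dynamic programming over segment
    boundary offsets: boundaries move by at most ``slack`` points per
    segment (cumulative offset capped at ``max_offset``, default
    ``5*slack``), endpoints are fixed, and the summed per-segment Pearson
    correlation with the reference is maximized.  As a safeguard the
    identity warp is returned whenever the warped spectrum's global
    correlation with the reference would drop below the unwarped one.
    """
    if not np.array_equal(target.ppm, reference.ppm):
        raise ValueError("target and reference must share one axis")
    n = len(target)
    if segment_length <= 2 * slack or slack < 1:
        raise ValueError("need segment_length > 2*slack >= 2")
    if n < 2 * segment_length:
        raise ValueError("spectrum too short for the given segment length")
    if max_offset is None:
        max_offset = 5 * slack

    bounds = list(range(0, n - segment_length + 1, segment_length))
    bounds.append(n - 1)  # last segment absorbs the remainder
    nseg = len(bounds) - 1
    y, ref = target.intensity, reference.intensity

    def offset_range(i: int) -> range:
        if i == 0 or i == nseg:
            return range(0, 1)
        m = min(slack * i, slack * (nseg - i), max_offset)
        return range(-m, m + 1)

    NEG = -np.inf
    score: list[dict[int, float]] = [dict() for _ in range(nseg + 1)]
    back: list[dict[int, int]] = [dict() for _ in range(nseg + 1)]
    score[0][0] = 0.0
    for i in range(nseg):
        lo_r, hi_r = bounds[i], bounds[i + 1]
        ref_seg = ref[lo_r:hi_r + 1]
        for u_next in offset_range(i + 1):
            best, arg = NEG, None
            b_hi = bounds[i + 1] + u_next
            for u in offset_range(i):
                if u not in score[i] or abs(u_next - u) > slack:
                    continue
                b_lo = bounds[i] + u
                if b_hi - b_lo < 3 or b_lo < 0 or b_hi > n - 1:
                    continue
                seg = np.interp(np.linspace(b_lo, b_hi, hi_r - lo_r + 1),
                                np.arange(b_lo, b_hi + 1), y[b_lo:b_hi + 1])
                val = score[i][u] + _seg_corr(seg, ref_seg)
                if val > best:
                    best, arg = val, u
            if arg is not None:
                score[i + 1][u_next] = best
                back[i + 1][u_next] = arg
    if 0 not in score[nseg]:
        raise ValueError("no feasible warp path")
    # backtrack
    offs = [0] * (nseg + 1)
    for i in range(nseg, 0, -1):
        offs[i - 1] = back[i][offs[i]]
    warped = np.empty_like(y)
    for i in range(nseg):
        lo_r, hi_r = bounds[i], bounds[i + 1]
        b_lo, b_hi = bounds[i] + offs[i], bounds[i + 1] + offs[i + 1]
        seg = np.interp(np.linspace(b_lo, b_hi, hi_r - lo_r + 1),
                        np.arange(b_lo, b_hi + 1), y[b_lo:b_hi + 1])
        warped[lo_r:hi_r + 1] = seg
    # identity fallback: never hand back something less correlated
    if _seg_corr(warped, ref) < _seg_corr(y, ref):
        return target.copy()
    return Spectrum1D(reference.ppm.copy(), warped, target.sample_id)


# --------------------------------------------------------------------------
# icoshift
# --------------------------------------------------------------------------

def _apply_shift(seg: np.ndarray, c: int) -> np.ndarray:
    """Rigid shift of segment content by ``c`` points (positive = toward
    higher indices); vacated points take the interval-edge value."""
    if c == 0:
        return seg.copy()
    out = np.empty_like(seg)
    if c > 0:
        out[c:] = seg[:-c]
        out[:c] = seg[0]
    else:
        out[:c] = seg[-c:]
        out[c:] = seg[-1]
    return out


def _best_correction(seg: np.ndarray, ref: np.ndarray, max_shift: int) -> int:
    """Correction shift maximizing full-length cross-correlation with the
    reference (candidates are edge-padded, so all lags share one support).
    A segment displaced by +k points gets correction -k."""
    max_shift = min(max_shift, len(seg) // 3)
    rc = ref - ref.mean()
    best_c, best = 0, -np.inf
    for c in range(-max_shift, max_shift + 1):
        cand = _apply_shift(seg, c)
        v = float(np.dot(cand - cand.mean(), rc))
        if v > best:
            best, best_c = v, c
    return best_c


def icoshift_align(sset: SpectraSet,
                   intervals: list[tuple[float, float]],
                   max_shift: int = 10,
                   reference: str | int = "mean") -> SpectraSet:
    """Interval-wise rigid alignment (icoshift).

    Within each ppm interval every sample is shifted by the integer lag
    (|lag| <= max_shift) that maximizes the cross-correlation with the
    reference signal (pointwise ``mean`` or ``median`` spectrum, or a sample
    index).  Vacated points are filled with the interval-edge values; points
    outside the intervals are untouched.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    out = sset.copy()
    if reference == "mean":
        ref_full = sset.matrix.mean(axis=0)
    elif reference == "median":
        ref_full = np.median(sset.matrix, axis=0)
    elif isinstance(reference, (int, np.integer)):
        ref_full = sset.matrix[int(reference)]
    else:
        raise ValueError("reference must be 'mean', 'median' or an index")
    for lo, hi in intervals:
        idx = np.flatnonzero(window_mask(sset.ppm, lo, hi))
        if idx.size < 3:
            raise ValueError(f"interval [{lo},{hi}) shorter than 3 points")
        sl = slice(idx.min(), idx.max() + 1)
        ref_seg = ref_full[sl]
        for r in range(out.n_samples):
            seg = out.matrix[r, sl]
            c = _best_correction(seg, ref_seg, max_shift)
            if c != 0:
                out.matrix[r, sl] = _apply_shift(seg, c)
    return out


# --------------------------------------------------------------------------
# STOCSY
# --------------------------------------------------------------------------

def stocsy(sset: SpectraSet, driver_ppm: float
           ) -> tuple[np.ndarray, np.ndarray]:
    """Statistical total correlation spectroscopy.

    Correlates the intensity at the data point nearest ``driver_ppm``
    against every point across samples; returns (Pearson correlation
    vector, covariance vector).
    """
    if sset.n_samples < 3:
        raise ValueError("need at least 3 samples")
    j = int(np.argmin(np.abs(sset.ppm - driver_ppm)))
    d = sset.matrix[:, j]
    if d.std() == 0:
        raise ValueError("zero-variance driver point")
    X = sset.matrix - sset.matrix.mean(axis=0)
    dc = d - d.mean()
    cov = X.T @ dc / (sset.n_samples - 1)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / (sd * dc.std(ddof=1))
    corr[~np.isfinite(corr)] = 0.0
    return corr, cov


# --------------------------------------------------------------------------
# relative integrals
# --------------------------------------------------------------------------

def integrate_regions(sset: SpectraSet, regions: list[RegionDef],
                      noise: NoiseSpec | None = None) -> FeatureTable:
    """Relative integrals: per sample and region, the sum of data points
    over the region's windows minus the Q3 of the noise region (``once``)
    or Q3 times the number of region points (``per_point``).

    Negative corrected integrals are retained and flagged.
    """
    noise = noise or NoiseSpec()
    names = [r.name for r in regions]
    if len(set(names)) != len(names):
        raise ValueError("duplicate region names")
    masks = {}
    for r in regions:
        m = np.zeros(sset.ppm.size, dtype=bool)
        for lo, hi in r.windows:
            wm = window_mask(sset.ppm, lo, hi)
            if not wm.any():
                raise ValueError(f"region {r.name}: window [{lo},{hi}) "
                                 "is off the ppm axis")
            m |= wm
        masks[r.name] = m
    nmask = window_mask(sset.ppm, *noise.window)
    if not nmask.any():
        raise ValueError("noise window is off the ppm axis")
    q3 = np.percentile(sset.matrix[:, nmask], 75, axis=1)
    vals = np.empty((sset.n_samples, len(regions)))
    for k, r in enumerate(regions):
        raw = sset.matrix[:, masks[r.name]].sum(axis=1)
        if noise.mode == "once":
            vals[:, k] = raw - q3
        else:
            vals[:, k] = raw - q3 * masks[r.name].sum()
    values = pd.DataFrame(vals, index=sset.meta.index, columns=names)
    flags = values < 0
    n_neg = int(flags.to_numpy().sum())
    if n_neg:
        log.warning("%d negative corrected integrals retained (flagged)",
                    n_neg)
    return FeatureTable(values, sset.meta.copy(), flags)


def panel_to_regions(panel, pad_ppm: float = 0.010) -> list[RegionDef]:
    """Default integration regions from a multiplet panel: one window per
    resonance covering the multiplet extent plus ``pad_ppm`` on each side.
    The TSP reference peak gets no region (it is the normalization anchor,
    not an analyte)."""
    from .synthdata import SPECTROMETER_MHZ, _PATTERN_LINES
    regions = []
    for m in panel:
        if m.name == "TSP":
            continue
        n = _PATTERN_LINES[m.pattern]
        half = ((n - 1) / 2.0) * m.j_hz / SPECTROMETER_MHZ \
            + 2.5 * m.linewidth_hz / SPECTROMETER_MHZ + pad_ppm
        regions.append(RegionDef(
            m.name, [(m.center_ppm - half, m.center_ppm + half)], m.pattern))
    return regions


def save_regions(regions: list[RegionDef], path) -> None:
    obj = [{"name": r.name, "windows": [list(map(float, w)) for w in r.windows],
            "multiplicity": r.multiplicity} for r in regions]
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def load_regions(path) -> list[RegionDef]:
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    return [RegionDef(d["name"], [tuple(w) for w in d["windows"]],
                      d.get("multiplicity", "")) for d in obj]


# --------------------------------------------------------------------------
# batch driver
# --------------------------------------------------------------------------

def preprocess_set(sset: SpectraSet, regions: list[RegionDef],
                   noise: NoiseSpec | None = None,
                   max_shift: int = 10,
                   tsp_target_area: float = 100.0,
                   align: bool = True) -> FeatureTable:
    """Reference, normalize, icoshift-align and integrate a spectra set.

    Samples whose TSP peak cannot be located are dropped with a warning.
    Alignment intervals are the region windows padded by 0.01 ppm and
    merged only where they overlap (the TSP window is excluded from
    alignment); aligning each resonance region independently lets the
    per-metabolite jitter be corrected metabolite by metabolite.
    """
    kept, rows = [], []
    for sid in sset.sample_ids:
        try:
            s = reference_to_tsp(sset.spectrum(sid))
        except ValueError as exc:
            log.warning("dropping %s: %s", sid, exc)
            continue
        s = normalize_to_tsp(s, target_area=tsp_target_area)
        rows.append(np.interp(sset.ppm[::-1], s.ppm[::-1],
                              s.intensity[::-1])[::-1])
        kept.append(sid)
    aligned = SpectraSet(sset.ppm, np.array(rows), sset.meta.loc[kept])
    if align:
        intervals = _merged_intervals(regions, pad=0.0)
        aligned = icoshift_align(aligned, intervals, max_shift=max_shift)
    return integrate_regions(aligned, regions, noise)


def _merged_intervals(regions: list[RegionDef], pad: float
                      ) -> list[tuple[float, float]]:
    spans = sorted((lo - pad, hi + pad)
                   for r in regions for lo, hi in r.windows)
    merged = [list(spans[0])]
    for lo, hi in spans[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(m) for m in merged]
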