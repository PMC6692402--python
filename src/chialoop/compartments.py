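"""Contact-matrix binning, iterative correction, and A/B compartments.

Long-range (inter-ligation) contacts are binned by anchor midpoints into
per-chromosome symmetric count matrices, balanced by iterative correction
(equalising unmasked bin marginals), and compartmentalised: the first
principal component of the correlation matrix of the distance-normalised
(observed/expected) map splits bins into A (positive, active) and B
(negative) after orienting the sign by active-mark peak density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomeLayout, LoopSet, PeakSet, ValidationError, warn


@dataclass
class ContactMatrix:
    """Per-chromosome symmetric contact matrices at one bin size."""

    binsize: int
    layout: GenomeLayout
    matrices: dict            # chrom -> (n_bins, n_bins) float array
    balanced: bool = False
    mask: dict = field(default_factory=dict)   # chrom -> bool array (True = masked)
    biases: dict = field(default_factory=dict)

    def n_bins(self, chrom: str) -> int:
        return -(-self.layout.length(chrom) // self.binsize)


@dataclass
class CompartmentTrack:
    """Per-bin eigenvector values and A/B/NA labels."""

    binsize: int
    df: pd.DataFrame  # chrom, bin, start, end, value, label

    def a_fraction(self, chrom: str | None = None) -> float:
        sub = self.df if chrom is None else self.df[self.df["chrom"] == chrom]
        called = sub[sub["label"] != "NA"]
        if len(called) == 0:
            return float("nan")
        return float((called["label"] == "A").mean())


def bin_contacts(loops: LoopSet, layout: GenomeLayout, binsize: int,
                 min_span: int = 8000) -> ContactMatrix:
    """Bin intrachromosomal contacts by anchor midpoints.

    A contact contributes its PET count to the bin pair of its two anchor
    midpoints; contacts whose midpoint distance is <= ``min_span`` are
    excluded (inter-ligation convention). Diagonal mass is counted once.
    """
    if binsize <= 0:
        raise ValueError("binsize must be positive")
    mats = {c: np.zeros((-(-l // binsize),) * 2)
            for c, l in zip(layout.chrom_names, layout.chrom_lengths)}
    df = loops.df
    intra = df[df["chrom1"] == df["chrom2"]]
    for row in intra.itertuples(index=False):
        m1 = (row.start1 + row.end1) // 2
        m2 = (row.start2 + row.end2) // 2
        if abs(m2 - m1) <= min_span:
            continue
        if row.chrom1 not in mats:
            raise ValidationError(f"unknown chromosome {row.chrom1!r}")
        M = mats[row.chrom1]
        b1, b2 = m1 // binsize, m2 // binsize
        if b1 >= M.shape[0] or b2 >= M.shape[0]:
            raise ValidationError(
                f"anchor midpoint outside layout on {row.chrom1}")
        M[b1, b2] += row.pet_count
        if b1 != b2:
            M[b2, b1] += row.pet_count
    return ContactMatrix(binsize, layout, mats)


def ice_balance(matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-6,
                mask_fraction: float = 0.02) -> ContactMatrix:
    """Iterative correction: equalise unmasked row sums by multiplicative biases.

    Bins in the lowest ``mask_fraction`` of marginal mass — and all
    zero-mass bins — are masked before balancing. Raises on an all-zero
    matrix or on non-convergence (the error carries the iteration trace).
    """
    if matrix.balanced:
        raise ValueError("matrix already balanced")
    out_m, out_mask, out_bias = {}, {}, {}
    total = sum(m.sum() for m in matrix.matrices.values())
    if total == 0:
        raise ValidationError("cannot balance an all-zero contact matrix")
    for chrom, M in matrix.matrices.items():
        M = M.astype(float).copy()
        marg = M.sum(axis=1)
        mask = marg == 0
        if mask_fraction > 0 and (~mask).any():
            cut = np.quantile(marg[~mask], mask_fraction)
            cand = mask | (marg <= cut)
            if (~cand).any():  # never mask every bin (e.g. constant matrix)
                mask = cand
        M[mask, :] = 0.0
        M[:, mask] = 0.0
        bias = np.ones(M.shape[0])
        trace = []
        if (~mask).sum() == 0 or M.sum() == 0:
            out_m[chrom], out_mask[chrom], out_bias[chrom] = M, mask, bias
            continue
        converged = False
        for it in range(max_iter):
            s = M.sum(axis=1)
            live = s[~mask]
            ratio = live.max() / live.min() if live.min() > 0 else np.inf
            trace.append(ratio - 1)
            if ratio - 1 <= tol:
                converged = True
                break
            d = np.where(mask, 1.0, s / live.mean())
            d[d == 0] = 1.0
            M /= d[:, None]
            M /= d[None, :]
            bias *= d
        else:
            s = M.sum(axis=1)
            live = s[~mask]
            if live.min() > 0 and live.max() / live.min() - 1 <= tol:
                converged = True
        if not converged:
            raise ValidationError(
                f"iterative correction did not converge on {chrom} "
                f"after {max_iter} iterations; trace tail {trace[-5:]}")
        out_m[chrom], out_mask[chrom], out_bias[chrom] = M, mask, bias
    return ContactMatrix(matrix.binsize, matrix.layout, out_m,
                         balanced=True, mask=out_mask, biases=out_bias)


def _observed_expected(M: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Distance-stratified O/E; zero-mass distances imputed from the nearest."""
    n = M.shape[0]
    live = ~mask
    expected = np.zeros(n)
    for d in range(n):
        vals = np.diagonal(M, offset=d)
        sel = live[:n - d] & live[d:]
        expected[d] = vals[sel].mean() if sel.any() else 0.0
    nz = np.flatnonzero(expected > 0)
    if nz.size == 0:
        return np.zeros_like(M)
    for d in range(n):
        if expected[d] == 0:
            expected[d] = expected[nz[np.argmin(np.abs(nz - d))]]
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return M / expected[idx]


def _power_iteration(S: np.ndarray, tol: float = 1e-8,
                     max_iter: int = 10_000) -> np.ndarray:
    """Leading eigenvector of a symmetric PSD matrix, positive-first-entry."""
    rng_free = np.ones(S.shape[0]) / np.sqrt(S.shape[0])
    v = rng_free
    for _ in range(max_iter):
        w = S @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
            v = w
            break
        v = w
    first = np.flatnonzero(np.abs(v) > 1e-12)
    if first.size and v[first[0]] < 0:
        v = -v
    return v


def call_compartments(matrix: ContactMatrix, active_peaks: PeakSet,
                      min_bins: int = 10) -> CompartmentTrack:
    """A/B compartments from PC1 of the O/E correlation matrix.

    Per chromosome the balanced map is distance-normalised, the bin-bin
    Pearson correlation matrix computed over unmasked bins, and the first
    principal component extracted by power iteration; the sign is oriented
    so bins richer in active-mark peaks score positive (label A).
    """
    if not matrix.balanced:
        raise ValueError("call_compartments requires a balanced matrix")
    binsize = matrix.binsize
    peak_mid = {}
    for chrom, sub in active_peaks.df.groupby("chrom", sort=False):
        peak_mid[chrom] = ((sub["start"] + sub["end"]) // 2).to_numpy()
    rows = []
    for chrom in matrix.layout.chrom_names:
        M = matrix.matrices[chrom]
        n = M.shape[0]
        mask = matrix.mask.get(chrom, np.zeros(n, bool))
        values = np.full(n, np.nan)
        live = np.flatnonzero(~mask)
        if live.size < min_bins:
            warn(f"{chrom}: fewer than {min_bins} unmasked bins; track is NA")
        else:
            oe = _observed_expected(M, mask)[np.ix_(live, live)]
            sd = oe.std(axis=0)
            ok = sd > 0
            live = live[ok]
            oe = oe[np.ix_(ok, ok)]
            if live.size >= min_bins:
                C = np.corrcoef(oe)
                Xc = C - C.mean(axis=0, keepdims=True)
                S = Xc.T @ Xc
                v = _power_iteration(S)
                proj = Xc @ v
                # orient: positive = higher active-peak density
                dens = np.zeros(live.size)
                mids = peak_mid.get(chrom, np.array([], dtype=int))
                if mids.size:
                    bins = mids // binsize
                    counts = np.bincount(bins, minlength=n)
                    dens = counts[live]
                pos = proj > 0
                if dens[pos].sum() < dens[~pos].sum():
                    proj = -proj
                values[live] = proj
        length = matrix.layout.length(chrom)
        for b in range(n):
            val = values[b]
            label = "NA" if np.isnan(val) else ("A" if val > 0 else "B")
            rows.append((chrom, b, b * binsize, min((b + 1) * binsize, length),
                         val, label))
    df = pd.DataFrame(rows, columns=["chrom", "bin", "start", "end",
                                     "value", "label"])
    return CompartmentTrack(binsize, df)
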