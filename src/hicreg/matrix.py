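"""Contact-matrix data model, I/O, balancing and normalization.

The on-disk dialect is a sparse triplet text file, one matrix per
chromosome per sample::

    #chrom,resolution,n_bins
    bin_i<TAB>bin_j<TAB>count

with 0-based bin indices and only the upper triangle stored (i <= j).
Bin ``k`` covers the half-open genomic interval ``[k*res, (k+1)*res)``.

In memory a matrix is dense and symmetric (desk-scale chromosomes, a few
thousand bins). Balancing weights are per-bin positive factors with NaN
marking masked (low-coverage) bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "OEMatrix",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "kr_balance",
    "observed_expected",
    "quantile_normalize",
    "scc",
    "coarsen",
    "pool",
]


class MatrixParseError(ValueError):
    """Raised for malformed triplet matrix files; message carries the line number."""


@dataclass
class ContactMatrix:
    """Symmetric binned cis contact matrix for one chromosome.

    Attributes
    ----------
    chrom : str
        Chromosome name.
    resolution : int
        Bin size in bp.
    counts : ndarray
        Dense symmetric ``(n_bins, n_bins)`` nonnegative array. Raw
        matrices hold integer counts; normalized matrices hold floats.
    balance_weights : ndarray or None
        Per-bin multiplicative factor; NaN on masked bins. ``None``
        until :func:`kr_balance` has run.
    balance_converged : bool
        Whether the last balancing run met its tolerance.
    """

    chrom: str
    resolution: int
    counts: np.ndarray
    balance_weights: np.ndarray | None = None
    balance_converged: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(c, c.T):
            raise ValueError("counts must be symmetric")
        self.counts = c

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def masked_bins(self) -> np.ndarray:
        """Boolean mask of bins excluded from balancing/analysis."""
        if self.balance_weights is None:
            return np.zeros(self.n_bins, dtype=bool)
        return np.isnan(self.balance_weights)

    def balanced(self) -> np.ndarray:
        """W C W with NaN on masked rows/columns.

        Requires :func:`kr_balance` to have been applied first.
        """
        if self.balance_weights is None:
            raise ValueError("matrix is not balanced; run kr_balance first")
        w = self.balance_weights
        return self.counts * np.outer(w, w)


@dataclass
class OEMatrix:
    """Observed/expected transform of a balanced matrix.

    ``values[i, j]`` is the balanced contact divided by the mean balanced
    contact at genomic gap ``|i-j|``; NaN marks masked entries. Per-gap
    means of unmasked entries are 1 by construction.
    """

    chrom: str
    resolution: int
    values: np.ndarray
    expected: np.ndarray  # per-gap expected profile, NaN for masked strata

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# I/O


def read_matrix(path) -> ContactMatrix:
    """Read a triplet-dialect contact matrix.

    Symmetric storage is reconstructed regardless of which triangle the
    file uses. Malformed lines raise :class:`MatrixParseError` with the
    1-based line number.
    """
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise MatrixParseError("line 1: missing '#chrom,resolution,n_bins' header")
        parts = header.lstrip("#").split(",")
        if len(parts) != 3:
            raise MatrixParseError("line 1: header must be '#chrom,resolution,n_bins'")
        chrom = parts[0].strip()
        try:
            resolution = int(parts[1])
            n_bins = int(parts[2])
        except ValueError as exc:
            raise MatrixParseError(f"line 1: non-integer resolution/n_bins: {exc}") from None
        counts = np.zeros((n_bins, n_bins))
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise MatrixParseError(f"line {lineno}: expected 3 tab-separated fields")
            try:
                i, j = int(fields[0]), int(fields[1])
                v = float(fields[2])
            except ValueError:
                raise MatrixParseError(f"line {lineno}: non-numeric triplet") from None
            if i < 0 or j < 0 or i >= n_bins or j >= n_bins:
                raise MatrixParseError(f"line {lineno}: bin index out of range [0, {n_bins})")
            if v < 0:
                raise MatrixParseError(f"line {lineno}: negative count")
            counts[i, j] = v
            counts[j, i] = v
    return ContactMatrix(chrom=chrom, resolution=resolution, counts=counts)


def write_matrix(m: ContactMatrix, path) -> None:
    """Write the upper triangle of nonzero entries in canonical (i, j) order."""
    iu, ju = np.nonzero(np.triu(m.counts))
    vals = m.counts[iu, ju]
    with open(path, "w") as fh:
        fh.write(f"#{m.chrom},{m.resolution},{m.n_bins}\n")
        for i, j, v in zip(iu, ju, vals):
            if float(v).is_integer():
                fh.write(f"{i}\t{j}\t{int(v)}\n")
            else:
                fh.write(f"{i}\t{j}\t{v!r}\n")


def write_weights(m: ContactMatrix, path) -> None:
    """Write balancing weights as a two-column TSV (bin, weight)."""
    if m.balance_weights is None:
        raise ValueError("matrix has no balancing weights")
    with open(path, "w") as fh:
        fh.write("bin\tweight\n")
        for k, w in enumerate(m.balance_weights):
            fh.write(f"{k}\t{'NA' if np.isnan(w) else repr(float(w))}\n")


# ---------------------------------------------------------------------------
# KR balancing


def _kr_newton(A: np.ndarray, tol: float, max_outer: int, delta: float = 0.1,
               Delta: float = 3.0) -> tuple[np.ndarray, bool]:
    """Knight-Ruiz inner-outer Newton iteration.

    Solves diag(x) A diag(x) 1 = 1 for a symmetric nonnegative A with
    positive row sums; the inner loop is a conjugate-gradient solve of
    the Newton system, preconditioned by the current iterate.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol ** 2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rho_km2 = rho_km1
    rout = rho_km1
    rold = rout
    outer = 0
    while rout > rt:
        outer += 1
        if outer > max_outer:
            return x, False
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = p @ w
            if denom <= 0 or not np.isfinite(denom):
                return x, False
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                neg = ap < 0
                gamma = ((delta - y[neg]) / ap[neg]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                big = ynew > Delta
                gamma = ((Delta - y[big]) / ap[big]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 2 * n:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o ** 2 > 0.1:
            eta = max(eta, g * eta_o ** 2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))
    return x, True


def _sinkhorn(A: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, bool]:
    """Iterative proportional fitting fallback: x <- x / sqrt-adjusted row sums."""
    n = A.shape[0]
    x = np.ones(n)
    for _ in range(max_iter):
        s = x * (A @ x)
        if np.abs(s - 1.0).max() < tol:
            return x, True
        x = x / np.sqrt(s)
    return x, np.abs(x * (A @ x) - 1.0).max() < tol


def kr_balance(m: ContactMatrix, tol: float = 1e-8, max_iter: int = 200,
               mask_quantile: float = 0.01) -> np.ndarray:
    """Knight-Ruiz matrix balancing; stores and returns per-bin weights.

    Bins with zero marginal, or whose nonzero coverage falls in the
    lowest ``mask_quantile`` fraction, are masked (NaN weight) before
    balancing. After balancing, every unmasked row of W C W sums to 1
    within ``tol``. If the Newton iteration stalls, an iterative
    proportional fitting pass is tried; persistent non-convergence is
    flagged on ``m.balance_converged`` and logged, never silent.
    """
    n = m.n_bins
    rowsum = m.counts.sum(axis=1)
    mask = rowsum <= 0
    nz = rowsum[rowsum > 0]
    if nz.size and mask_quantile > 0:
        cutoff = np.quantile(nz, mask_quantile)
        cand = mask | (rowsum <= cutoff)
        if (~cand).sum() >= 2:  # never mask the whole chromosome
            mask = cand
    weights = np.full(n, np.nan)
    keep = ~mask
    if keep.sum() < 2:
        m.balance_weights = weights
        m.balance_converged = False
        logger.warning("kr_balance: fewer than 2 unmasked bins on %s", m.chrom)
        return weights
    A = m.counts[np.ix_(keep, keep)]
    x, ok = _kr_newton(A, tol=tol, max_outer=max_iter)
    if not ok:
        logger.warning("kr_balance: Newton iteration stalled on %s; falling back to IPF", m.chrom)
        x, ok = _sinkhorn(A, tol=tol, max_iter=50 * max_iter)
    weights[keep] = x
    m.balance_weights = weights
    m.balance_converged = bool(ok)
    if not ok:
        logger.warning("kr_balance: did not converge on %s within max_iter", m.chrom)
    return weights


# ---------------------------------------------------------------------------
# Observed / expected


def observed_expected(m: ContactMatrix, min_pairs: int = 2) -> OEMatrix:
    """Distance-normalized (observed/expected) transform of a balanced matrix.

    ``expected(d)`` is the mean balanced count over unmasked bin pairs at
    gap ``d``; strata with fewer than ``min_pairs`` unmasked pairs are
    masked, as are entries where expected is 0 but observed positive.
    """
    B = m.balanced()
    mask = m.masked_bins
    B[mask, :] = np.nan
    B[:, mask] = np.nan
    n = m.n_bins
    oe = np.full((n, n), np.nan)
    expected = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(B, d)
        valid = np.isfinite(diag)
        npairs = int(valid.sum())
        if npairs < min_pairs:
            continue
        exp_d = diag[valid].mean()
        expected[d] = exp_d
        idx = np.arange(n - d)
        if exp_d == 0:
            if (diag[valid] > 0).any():
                warnings.warn(f"gap {d}: expected 0 with positive observed; stratum masked")
            continue
        vals = diag / exp_d
        oe[idx, idx + d] = vals
        oe[idx + d, idx] = vals
    return OEMatrix(chrom=m.chrom, resolution=m.resolution, values=oe, expected=expected)


# ---------------------------------------------------------------------------
# Cross-sample quantile normalization


def quantile_normalize(matrices: list[ContactMatrix]) -> list[ContactMatrix]:
    """Stratum-wise quantile normalization of balanced matrices across samples.

    Within each genomic-gap stratum, the nonzero balanced values of every
    sample are rank-mapped onto the mean empirical distribution across
    samples, so per-stratum sorted values agree across samples afterwards.
    Returns new matrices whose ``counts`` hold the normalized balanced
    values (weights set to 1).
    """
    if not matrices:
        return []
    n = matrices[0].n_bins
    res = matrices[0].resolution
    chrom = matrices[0].chrom
    for m in matrices:
        if m.n_bins != n or m.resolution != res:
            raise ValueError("matrices must share chromosome shape and resolution")
    bals = [m.balanced() if m.balance_weights is not None else m.counts.astype(float)
            for m in matrices]
    outs = [np.zeros((n, n)) for _ in matrices]
    for d in range(n):
        idx = np.arange(n - d)
        diags = [np.nan_to_num(np.diagonal(b, d)) for b in bals]
        nz_vals = []
        for diag in diags:
            v = diag[diag > 0]
            nz_vals.append(np.sort(v))
        lengths = [len(v) for v in nz_vals]
        if max(lengths, default=0) == 0:
            continue
        grid_len = max(lengths)
        grid = np.linspace(0.0, 1.0, grid_len)
        curves = []
        for v in nz_vals:
            if len(v) == 0:
                continue
            pos = np.linspace(0.0, 1.0, len(v)) if len(v) > 1 else np.array([0.5])
            curves.append(np.interp(grid, pos, v))
        ref = np.mean(curves, axis=0)
        for s, diag in enumerate(diags):
            k = lengths[s]
            if k == 0:
                continue
            order = np.argsort(diag[diag > 0], kind="stable")
            pos = np.linspace(0.0, 1.0, k) if k > 1 else np.array([0.5])
            mapped = np.interp(pos, grid, ref)
            newvals = np.empty(k)
            newvals[order] = mapped
            out_diag = np.zeros(n - d)
            out_diag[diag > 0] = newvals
            outs[s][idx, idx + d] = out_diag
            outs[s][idx + d, idx] = out_diag
    result = []
    for m, out in zip(matrices, outs):
        cm = ContactMatrix(chrom=chrom, resolution=res, counts=out)
        cm.balance_weights = np.ones(n)
        keep_mask = m.masked_bins
        cm.balance_weights[keep_mask] = np.nan
        result.append(cm)
    return result


# ---------------------------------------------------------------------------
# Stratum-adjusted correlation (reproducibility)


def scc(m1: ContactMatrix, m2: ContactMatrix, max_distance: int = 5_000_000,
        smooth_window: int = 3) -> float:
    """Stratum-adjusted correlation coefficient between two samples.

    Both matrices are smoothed with a 2D mean filter of ``smooth_window``
    bins, then Pearson correlations per genomic-gap stratum (up to
    ``max_distance``) are combined with Cochran-style weights
    ``N_d * sqrt(var_x var_y)``. All-zero or degenerate strata are skipped.
    """
    if m1.counts.shape != m2.counts.shape:
        raise ValueError("matrices must have identical shape")
    a = m1.balanced() if m1.balance_weights is not None else m1.counts.astype(float)
    b = m2.balanced() if m2.balance_weights is not None else m2.counts.astype(float)
    a = np.nan_to_num(a)
    b = np.nan_to_num(b)
    if smooth_window > 1:
        a = ndimage.uniform_filter(a, size=smooth_window, mode="nearest")
        b = ndimage.uniform_filter(b, size=smooth_window, mode="nearest")
    n = m1.n_bins
    dmax = min(n - 1, max(1, max_distance // m1.resolution))
    num = 0.0
    den = 0.0
    for d in range(1, dmax + 1):
        x = np.diagonal(a, d)
        y = np.diagonal(b, d)
        if x.size < 2:
            continue
        vx, vy = x.var(), y.var()
        if vx == 0 or vy == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        w = x.size * np.sqrt(vx * vy)
        num += w * r
        den += w
    if den == 0:
        return float("nan")
    return float(num / den)


# ---------------------------------------------------------------------------
# Resolution / replicate helpers


def coarsen(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Aggregate to a coarser resolution by summing ``factor x factor`` blocks."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    n = m.n_bins
    n_coarse = int(np.ceil(n / factor))
    padded = np.zeros((n_coarse * factor, n_coarse * factor))
    padded[:n, :n] = m.counts
    out = padded.reshape(n_coarse, factor, n_coarse, factor).sum(axis=(1, 3))
    return ContactMatrix(chrom=m.chrom, resolution=m.resolution * factor, counts=out)


def pool(matrices: list[ContactMatrix]) -> ContactMatrix:
    """Sum raw counts across replicates (read pooling)."""
    if not matrices:
        raise ValueError("no matrices to pool")
    base = matrices[0]
    total = np.zeros_like(base.counts)
    for m in matrices:
        if m.counts.shape != base.counts.shape or m.resolution != base.resolution:
            raise ValueError("pooled matrices must share shape and resolution")
        total = total + m.counts
    return ContactMatrix(chrom=base.chrom, resolution=base.resolution, counts=total)
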