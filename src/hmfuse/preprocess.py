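"""Spectral preprocessing for 1D NMR blocks.

The pipeline order is fixed: asymmetric-least-squares baseline correction,
polynomial warping alignment to the block's median spectrum, total-area
normalization to unit AUC, adaptive binning, and finally autoscaling of the
resulting bin table.  Bin integrals can be read as relative metabolite
concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse
import scipy.sparse.linalg

__all__ = [
    "Spectrum",
    "SpectraBlock",
    "BinTable",
    "Scaler",
    "als_baseline",
    "ptw_align",
    "total_area_normalize",
    "ai_bin",
    "autoscale",
    "apply_scaler",
    "preprocess_block",
]


@dataclass
class Spectrum:
    """One 1D spectrum on a strictly monotone ppm grid."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    block_id: str = ""
    group: str = ""

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.size != self.intensity.size:
            raise ValueError("ppm and intensity must have equal length")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm grid must be strictly monotone")


@dataclass
class SpectraBlock:
    """Samples x points intensity matrix sharing one ppm grid."""

    ppm: np.ndarray
    intensities: np.ndarray
    metadata: pd.DataFrame  # indexed by sample_id, with a 'group' column
    block_id: str = ""

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.metadata), self.ppm.size):
            raise ValueError("intensity matrix shape does not match grid/metadata")
        if self.metadata.index.duplicated().any():
            raise ValueError("sample ids must be unique")

    @property
    def sample_ids(self) -> list:
        return list(self.metadata.index)

    @property
    def groups(self) -> np.ndarray:
        return self.metadata["group"].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensities.T, index=pd.Index(self.ppm, name="ppm"),
            columns=self.metadata.index,
        )

    def write_csv(self, spectra_path, metadata_path=None) -> None:
        self.to_frame().to_csv(spectra_path)
        if metadata_path is not None:
            md = self.metadata.copy()
            md.insert(0, "block", self.block_id)
            md.to_csv(metadata_path, index_label="sample_id")

    @classmethod
    def read_csv(cls, spectra_path, metadata_path, block_id="") -> "SpectraBlock":
        df = pd.read_csv(spectra_path, index_col=0)
        md = pd.read_csv(metadata_path, index_col=0)
        md = md.loc[df.columns]
        return cls(
            ppm=df.index.to_numpy(float),
            intensities=df.to_numpy(float).T,
            metadata=md.drop(columns=[c for c in ("block",) if c in md]),
            block_id=block_id,
        )


@dataclass
class BinTable:
    """Per-sample integrals over half-open ppm intervals [lo, hi)."""

    boundaries: list  # list of (lo, hi) tuples, ascending, non-overlapping
    values: pd.DataFrame  # rows = samples, columns = 'lo_hi' labels
    noise_flags: np.ndarray  # True where the bin never rises above noise
    metadata: pd.DataFrame
    block_id: str = ""

    def __post_init__(self):
        los = np.array([b[0] for b in self.boundaries])
        his = np.array([b[1] for b in self.boundaries])
        if np.any(his <= los) or np.any(los[1:] < his[:-1]):
            raise ValueError("bins must be non-overlapping and sorted")

    @property
    def labels(self) -> list:
        return list(self.values.columns)

    def signal(self) -> "BinTable":
        """Restrict to bins that rise above the noise threshold."""
        keep = ~self.noise_flags
        return BinTable(
            boundaries=[b for b, k in zip(self.boundaries, keep) if k],
            values=self.values.loc[:, keep],
            noise_flags=np.zeros(int(keep.sum()), dtype=bool),
            metadata=self.metadata,
            block_id=self.block_id,
        )

    def write(self, csv_path, boundaries_json_path=None) -> None:
        self.values.to_csv(csv_path, index_label="sample_id")
        if boundaries_json_path is not None:
            import json

            with open(boundaries_json_path, "w") as fh:
                json.dump(
                    {
                        "block_id": self.block_id,
                        "boundaries": [[float(a), float(b)] for a, b in self.boundaries],
                        "noise_flags": [bool(f) for f in self.noise_flags],
                    },
                    fh,
                    indent=1,
                )


@dataclass
class Scaler:
    """Column means and standard deviations learned on a training matrix."""

    mean_: np.ndarray
    sd_: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.mean_.size:
            raise ValueError(
                f"matrix has {X.shape[-1]} columns, scaler expects {self.mean_.size}"
            )
        return (X - self.mean_) / self.sd_

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.sd_ + self.mean_


def als_baseline(
    intensity, lam: float = 1e6, p: float = 1e-3, n_iter: int = 10
):
    """Asymmetric least-squares baseline (Eilers' iterative scheme).

    Minimises sum_i w_i (x_i - z_i)^2 + lam * sum (d2 z)^2 with asymmetric
    weights w_i = p where x_i > z_i and 1 - p elsewhere, refreshed n_iter
    times.  Returns (baseline, corrected).
    """
    x = np.asarray(intensity, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points for second differences")
    if lam <= 0 or not (0 < p < 1) or n_iter < 1:
        raise ValueError("require lam > 0, 0 < p < 1, n_iter >= 1")
    import scipy.linalg

    D = scipy.sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    DtD = (lam * (D.T @ D)).todia()
    # upper banded storage of the SPD pentadiagonal system for solveh_banded
    band_pen = np.zeros((3, n))
    for off in (0, 1, 2):
        band_pen[2 - off, off:] = DtD.diagonal(off)
    # the affine part of x lies in the penalty's null space; removing it
    # before the solve avoids catastrophic cancellation for large lam
    t = np.arange(n, dtype=float)
    trend = np.polyval(np.polyfit(t, x, 1), t)
    xr = x - trend
    w = np.ones(n)
    zr = xr.copy()
    for _ in range(n_iter):
        band = band_pen.copy()
        band[2] += w
        rhs = w * xr
        zr = scipy.linalg.solveh_banded(band, rhs)
        # one step of iterative refinement: the system is ill-conditioned
        # for large lam and the raw solve loses digits
        A = scipy.sparse.diags(w, 0) + DtD
        zr = zr + scipy.linalg.solveh_banded(band, rhs - A @ zr)
        w = np.where(xr > zr, p, 1.0 - p)
    z = zr + trend
    return z, x - z


def _warp_positions(coeffs: np.ndarray, n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    pos = np.zeros(n)
    for k, a in enumerate(coeffs):
        pos += a * i**k
    return pos


def _apply_warp(x: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    n = x.size
    pos = np.clip(_warp_positions(coeffs, n), 0, n - 1)
    return np.interp(pos, np.arange(n, dtype=float), x)


def ptw_align(intensity, reference, degree: int = 2, max_shift: int | None = None):
    """Parametric warping: aligned(i) = intensity(w(i)), w(i) = sum a_k i^k.

    Coefficients maximise the Pearson correlation with the reference; found
    by a coarse integer scan of the constant shift a0 followed by
    Nelder-Mead refinement of all coefficients.  Returns (coeffs, aligned).
    a0 is positive when the input's features sit at higher indices than the
    reference's (w reaches forward to fetch them).
    """
    x = np.asarray(intensity, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float).ravel()
    if x.size != ref.size:
        raise ValueError("intensity and reference lengths differ")
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    if np.std(ref) == 0:
        raise ValueError("flat reference: correlation undefined")
    n = x.size
    ident = np.zeros(degree + 1)
    ident[1] = 1.0
    if np.array_equal(x, ref):
        return ident, x.copy()
    if max_shift is None:
        max_shift = max(5, n // 20)

    refc = ref - ref.mean()
    ref_norm = np.linalg.norm(refc)

    def neg_corr(coeffs):
        warped = _apply_warp(x, coeffs)
        wc = warped - warped.mean()
        denom = np.linalg.norm(wc) * ref_norm
        if denom == 0:
            return 1.0
        return -float(wc @ refc) / denom

    best_a0, best_val = 0.0, np.inf
    for shift in range(-max_shift, max_shift + 1):
        c = ident.copy()
        c[0] = float(shift)
        v = neg_corr(c)
        if v < best_val:
            best_val, best_a0 = v, float(shift)

    # optimise in scaled parameters: displacement d(i) = c0 + c1 u + c2 u^2...
    # with u = i/n, so all parameters live on a grid-point scale.
    def to_coeffs(params):
        c = ident.copy()
        for k in range(degree + 1):
            c[k] += params[k] / float(n) ** k if k > 0 else params[k]
        return c

    x0 = np.zeros(degree + 1)
    x0[0] = best_a0
    res = scipy.optimize.minimize(
        lambda pp: neg_corr(to_coeffs(pp)),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 2000},
    )
    coeffs = to_coeffs(res.x)
    if neg_corr(coeffs) > best_val:  # keep the grid solution if refinement hurt
        coeffs = ident.copy()
        coeffs[0] = best_a0
    return coeffs, _apply_warp(x, coeffs)


def total_area_normalize(matrix, sample_ids=None) -> np.ndarray:
    """Divide each row by its sum so every spectrum has unit total area."""
    M = np.asarray(matrix, dtype=float)
    one_d = M.ndim == 1
    if one_d:
        M = M[None, :]
    sums = M.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        name = sample_ids[bad[0]] if sample_ids is not None else f"row {bad[0]}"
        raise ValueError(f"non-positive total area for sample {name}")
    out = M / sums[:, None]
    return out[0] if one_d else out


def _bin_quality(seg: np.ndarray, i1: int, i2: int, exponent: float) -> float:
    """Summed per-sample bin value for the bin spanning columns [i1, i2]."""
    mx = seg[:, i1 : i2 + 1].max(axis=1)
    edge = 0.5 * (seg[:, i1] + seg[:, i2])
    v = mx - edge
    v[v < 0] = 0.0
    if exponent != 1.0:
        v = v**exponent
    return float(v.sum())


def _best_split(M: np.ndarray, i1: int, i2: int, min_pts: int, exponent: float):
    """Exhaustive scan of split points; returns (quality_sum, j) or None.

    A split at j makes children [i1, j] and [j+1, i2]; both must span at
    least min_pts points.
    """
    lo = i1 + min_pts - 1
    hi = i2 - min_pts
    if hi < lo:
        return None
    js = np.arange(lo, hi + 1)
    # cumulative maxima from the left and right for all samples at once
    seg = M[:, i1 : i2 + 1]
    cmax_l = np.maximum.accumulate(seg, axis=1)
    cmax_r = np.maximum.accumulate(seg[:, ::-1], axis=1)[:, ::-1]
    off = js - i1
    vl = cmax_l[:, off] - 0.5 * (M[:, i1][:, None] + M[:, js])
    vr = cmax_r[:, off + 1] - 0.5 * (M[:, js + 1] + M[:, i2][:, None])
    vl[vl < 0] = 0.0
    vr[vr < 0] = 0.0
    if exponent != 1.0:
        vl = vl**exponent
        vr = vr**exponent
    tot = vl.sum(axis=0) + vr.sum(axis=0)
    k = int(np.argmax(tot))
    return float(tot[k]), int(js[k])


def _split_recursive(M, i1, i2, min_pts, exponent, out):
    parent = _bin_quality(M, i1, i2, exponent)
    found = _best_split(M, i1, i2, min_pts, exponent)
    if found is not None and found[0] > parent:
        j = found[1]
        _split_recursive(M, i1, j, min_pts, exponent, out)
        _split_recursive(M, j + 1, i2, min_pts, exponent, out)
    else:
        out.append((i1, i2))


def ai_bin(
    block: SpectraBlock,
    noise_region: tuple,
    min_bin_width: float,
    quality_exponent: float = 1.0,
) -> BinTable:
    """Adaptive binning by recursive splitting of the full ppm range.

    Splits are placed at the boundary maximising the summed bin quality
    (max-over-bin minus mean edge intensity, per sample) and kept only when
    they raise the total above the parent bin's quality; bins whose maximum
    intensity never exceeds mean + 3 sd of the noise region are flagged as
    noise.  Bin values are trapezoidal integrals over the ppm grid.
    """
    ppm = block.ppm
    M = block.intensities
    step = float(np.median(np.abs(np.diff(ppm))))
    min_pts = max(2, int(round(min_bin_width / step)))
    if min_pts > ppm.size:
        raise ValueError("min_bin_width wider than the spectral range")
    lo, hi = sorted(noise_region)
    noise_mask = (ppm >= lo) & (ppm <= hi)
    if not noise_mask.any():
        raise ValueError("noise region contains no grid points")
    noise_pts = M[:, noise_mask]
    threshold = float(noise_pts.mean() + 3.0 * noise_pts.std())

    segments: list = []
    _split_recursive(M, 0, ppm.size - 1, min_pts, quality_exponent, segments)
    segments.sort()

    boundaries = []
    labels = []
    flags = []
    cols = []
    for (i1, i2) in segments:
        plo = float(ppm[i1])
        phi = float(ppm[i2 + 1]) if i2 + 1 < ppm.size else float(ppm[-1] + step)
        boundaries.append((plo, phi))
        labels.append(f"{plo:.4f}_{phi:.4f}")
        # a bin is noise when the TYPICAL sample never rises above the
        # threshold: the median of per-sample maxima is robust against the
        # joint maximum of thousands of noise draws exceeding 3 sd
        per_sample_max = M[:, i1 : i2 + 1].max(axis=1)
        flags.append(bool(np.median(per_sample_max) <= threshold))
        cols.append(np.trapezoid(M[:, i1 : i2 + 1], ppm[i1 : i2 + 1], axis=1))
    values = pd.DataFrame(
        np.column_stack(cols), index=block.metadata.index, columns=labels
    )
    return BinTable(
        boundaries=boundaries,
        values=values,
        noise_flags=np.array(flags, dtype=bool),
        metadata=block.metadata,
        block_id=block.block_id,
    )


def autoscale(matrix):
    """Column-wise mean-centering and division by the sample sd (ddof=1)."""
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("autoscaling needs a matrix with at least 2 rows")
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd <= 0)
    if zero.size:
        raise ValueError(f"zero-variance columns: {zero.tolist()}")
    scaler = Scaler(mean_=mu, sd_=sd)
    return scaler.transform(M), scaler


def autoscale_fit_tolerant(matrix):
    """Autoscaling that maps zero-variance columns to zeros (internal use)."""
    M = np.asarray(matrix, dtype=float)
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    sd = np.where(sd > 1e-12, sd, 1.0)
    scaler = Scaler(mean_=mu, sd_=sd)
    return scaler.transform(M), scaler


def apply_scaler(matrix, scaler: Scaler) -> np.ndarray:
    """Scale a matrix with training-set parameters only."""
    return scaler.transform(np.asarray(matrix, dtype=float))


def preprocess_block(
    block: SpectraBlock,
    lam: float = 1e6,
    p: float = 1e-3,
    n_iter: int = 10,
    warp_degree: int = 2,
    noise_region: tuple = (8.6, 9.0),
    min_bin_width: float = 0.02,
    signal_only: bool = True,
) -> BinTable:
    """Full block pipeline: baseline, alignment, normalization, binning.

    Alignment uses the block's median spectrum as reference.  Autoscaling is
    deliberately left to the modelling step so that scalers are always fit
    on training rows only.
    """
    corrected = np.empty_like(block.intensities)
    for i in range(block.intensities.shape[0]):
        _, corrected[i] = als_baseline(block.intensities[i], lam=lam, p=p, n_iter=n_iter)
    reference = np.median(corrected, axis=0)
    aligned = np.empty_like(corrected)
    for i in range(corrected.shape[0]):
        _, aligned[i] = ptw_align(corrected[i], reference, degree=warp_degree)
    normalized = total_area_normalize(aligned, sample_ids=block.sample_ids)
    work = SpectraBlock(
        ppm=block.ppm, intensities=normalized, metadata=block.metadata,
        block_id=block.block_id,
    )
    table = ai_bin(work, noise_region=noise_region, min_bin_width=min_bin_width)
    return table.signal() if signal_only else table
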