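"""Static regional features: fALFF, ReHo, and degree centrality.

fALFF (fractional amplitude of low-frequency fluctuation) is the
fraction of a series' spectrum falling in a target band; the two bands
used throughout are slow-5 (0.01-0.027 Hz, "f1ALFF") and slow-4
(0.027-0.073 Hz, "f2ALFF").  It is computed on detrended but
*unfiltered* series: the denominator spans the entire positive-frequency
range, which prior band-passing would distort.

ReHo (regional homogeneity) is Kendall's coefficient of concordance W of
a voxel's time course with its spatial neighbors (27-voxel cube by
default), computed on filtered series.  Degree centrality counts (BDC)
or sums (WDC) suprathreshold positive correlations from each voxel to
all other in-mask voxels.

All voxel maps are averaged within atlas parcels to give the regional
feature blocks; with only parcel-level series available, fALFF and
degree centrality are computed directly on the node graph while ReHo is
undefined (it needs a voxel neighborhood) and raises if requested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats

from . import preprocess as pp

__all__ = [
    "falff",
    "kendall_w",
    "reho",
    "degree_centrality",
    "parcel_aggregate",
    "extract_static_voxel",
    "extract_static_node",
    "STATIC_METRICS",
]

STATIC_METRICS = ("f1ALFF", "f2ALFF", "ReHo", "BDC", "WDC")

SLOW5 = (0.01, 0.027)
SLOW4 = (0.027, 0.073)


def falff(
    x: np.ndarray,
    tr_seconds: float,
    band: tuple[float, float] = SLOW5,
    spectrum: str = "power",
    return_flags: bool = False,
):
    """Band fraction of the spectrum of each column of ``x``.

    Parameters
    ----------
    x : (T,) or (T, V) array of detrended, unfiltered series.
    band : closed frequency interval in Hz; bins at the edges count.
    spectrum : "power" (default) sums squared FFT magnitudes, i.e. the
        band's share of signal energy, which is robust to spectral
        leakage; "amplitude" sums raw magnitudes (the classic toolbox
        convention).  Both lie in [0, 1] and agree in expectation for
        white noise.
    return_flags : also return a boolean array marking degenerate (flat)
        series, for which the value is 0.
    """
    arr = np.asarray(x, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    n = arr.shape[0]
    if spectrum not in ("power", "amplitude"):
        raise ValueError("spectrum must be 'power' or 'amplitude'")
    low, high = band
    pp._check_band(tr_seconds, low, high)
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    band_bins = (freqs >= low) & (freqs <= high)
    pos_bins = freqs > 0
    if not band_bins.any():
        min_t = int(np.ceil(1.0 / (high * tr_seconds)))
        raise ValueError(
            f"band {band} contains no frequency bin at T={n}, TR={tr_seconds}s; "
            f"need at least ~{min_t} time points"
        )
    mag = np.abs(np.fft.rfft(arr, axis=0))
    if spectrum == "power":
        mag = mag**2
    num = mag[band_bins].sum(axis=0)
    den = mag[pos_bins].sum(axis=0)
    flags = den <= 0
    out = np.zeros(arr.shape[1])
    np.divide(num, den, out=out, where=~flags)
    if squeeze:
        out, flags = float(out[0]), bool(flags[0])
    if return_flags:
        return out, flags
    return out


def kendall_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance W of K series over n time points.

    ``W = 12 * sum_t (R_t - mean R)^2 / (K^2 (n^3 - n))`` where ``R_t``
    is the rank sum across the K series at time ``t`` (average ranks for
    ties; no tie correction).  K=1 gives W=1 by the same formula.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 2:
        raise ValueError("series must be (K, n)")
    k, n = s.shape
    if n < 3:
        raise ValueError("Kendall W needs at least 3 time points")
    ranks = scipy.stats.rankdata(s, axis=1)
    rsum = ranks.sum(axis=0)
    dev = rsum - k * (n + 1) / 2.0
    return float(12.0 * (dev**2).sum() / (k**2 * (n**3 - n)))


_NEIGHBOR_KERNELS = {}


def _neighbor_kernel(neighborhood: int) -> np.ndarray:
    if neighborhood not in (7, 19, 27):
        raise ValueError("neighborhood must be 7, 19 or 27")
    if neighborhood not in _NEIGHBOR_KERNELS:
        kern = np.zeros((3, 3, 3), dtype=float)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    nz = sum(v != 0 for v in (dx, dy, dz))
                    if neighborhood == 7 and nz > 1:
                        continue
                    if neighborhood == 19 and nz > 2:
                        continue
                    kern[dx + 1, dy + 1, dz + 1] = 1.0
        _NEIGHBOR_KERNELS[neighborhood] = kern
    return _NEIGHBOR_KERNELS[neighborhood]


def reho(
    data4d: np.ndarray,
    atlas: np.ndarray,
    neighborhood: int = 27,
) -> np.ndarray:
    """Voxelwise ReHo map (Kendall W over each voxel's in-mask neighborhood).

    ``atlas > 0`` defines the mask.  Edge voxels use however many in-mask
    neighbors they have (K adjusted); no padding.  Returns a 3-D map with
    zeros outside the mask.
    """
    data4d = np.asarray(data4d, dtype=float)
    if data4d.ndim != 4:
        raise ValueError("data4d must be (x, y, z, t)")
    if data4d.shape[:3] != atlas.shape:
        raise ValueError("atlas shape does not match the volume")
    n = data4d.shape[3]
    if n < 3:
        raise ValueError("ReHo needs at least 3 time points")
    kern = _neighbor_kernel(neighborhood)
    mask = atlas > 0
    ranks = scipy.stats.rankdata(data4d, axis=3)
    ranks[~mask] = 0.0
    kcount = scipy.ndimage.correlate(
        mask.astype(float), kern, mode="constant", cval=0.0
    )
    ssq = np.zeros(atlas.shape)
    mean_rank = (n + 1) / 2.0
    for t in range(n):
        rsum = scipy.ndimage.correlate(ranks[..., t], kern, mode="constant", cval=0.0)
        dev = rsum - kcount * mean_rank
        ssq += dev**2
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 12.0 * ssq / (kcount**2 * (n**3 - n))
    w[~mask] = 0.0
    return w


def degree_centrality(
    series: np.ndarray,
    r_threshold: float = 0.25,
    return_flags: bool = False,
):
    """Binary and weighted degree centrality of each column of ``series``.

    Pearson correlation of every pair of columns; edges are correlations
    strictly above ``r_threshold`` (negative correlations never count).
    ``BDC`` counts edges, ``WDC`` sums their weights.  Zero-variance
    columns get r=0 everywhere (no edges) and are flagged.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("series must be (T, V) with V >= 2")
    t_len = x.shape[0]
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    flags = sd == 0
    safe = np.where(flags, 1.0, sd)
    z = xc / safe
    r = (z.T @ z) / t_len
    r[flags, :] = 0.0
    r[:, flags] = 0.0
    np.fill_diagonal(r, 0.0)
    edges = r > r_threshold
    bdc = edges.sum(axis=1).astype(float)
    wdc = np.where(edges, r, 0.0).sum(axis=1)
    if return_flags:
        return bdc, wdc, flags
    return bdc, wdc


def parcel_aggregate(voxel_map: np.ndarray, atlas: np.ndarray) -> pd.Series:
    """Mean voxel value per atlas label, ordered by label id (1..N).

    Raises with the offending labels if any parcel is empty.
    """
    atlas = np.asarray(atlas)
    voxel_map = np.asarray(voxel_map, dtype=float)
    if voxel_map.shape != atlas.shape:
        raise ValueError("map and atlas shapes differ")
    n_parcels = int(atlas.max())
    if n_parcels < 1:
        raise ValueError("atlas has no labels")
    flat_lab = atlas.ravel()
    counts = np.bincount(flat_lab, minlength=n_parcels + 1)
    empty = [int(i) for i in range(1, n_parcels + 1) if counts[i] == 0]
    if empty:
        raise ValueError(f"empty parcels: {empty}")
    sums = np.bincount(flat_lab, weights=voxel_map.ravel(), minlength=n_parcels + 1)
    means = sums[1:] / counts[1:]
    return pd.Series(means, index=pd.RangeIndex(1, n_parcels + 1, name="parcel"))


def _voxel_series(data4d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return data4d[mask].T  # (T, V)


def extract_static_voxel(
    vol4d: np.ndarray,
    atlas: np.ndarray,
    tr_seconds: float,
    n_drop: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    bands: tuple = (SLOW5, SLOW4),
    r_threshold: float = 0.25,
    neighborhood: int = 27,
    falff_spectrum: str = "power",
) -> pd.DataFrame:
    """All five static metrics at parcel level from a raw 4-D volume.

    fALFF runs on dropped+detrended series; ReHo and degree centrality on
    the fully band-passed series.  Returns a (parcel x metric) frame with
    columns ``f1ALFF, f2ALFF, ReHo, BDC, WDC``.
    """
    vol4d = np.asarray(vol4d, dtype=float)
    mask = atlas > 0
    raw = _voxel_series(vol4d, mask)
    detr = pp.detrend_linear(pp.drop_initial_volumes(raw, n_drop=n_drop))
    filt = pp.preprocess(raw, tr_seconds, n_drop=n_drop, low_hz=low_hz, high_hz=high_hz)

    def to_map(values: np.ndarray) -> np.ndarray:
        m = np.zeros(atlas.shape)
        m[mask] = values
        return m

    out = {}
    for name, band in zip(("f1ALFF", "f2ALFF"), bands):
        vals = falff(detr, tr_seconds, band=band, spectrum=falff_spectrum)
        out[name] = parcel_aggregate(to_map(vals), atlas)

    filt_vol = np.zeros(vol4d.shape[:3] + (filt.shape[0],))
    filt_vol[mask] = filt.T
    out["ReHo"] = parcel_aggregate(reho(filt_vol, atlas, neighborhood=neighborhood), atlas)

    bdc, wdc = degree_centrality(filt, r_threshold=r_threshold)
    out["BDC"] = parcel_aggregate(to_map(bdc), atlas)
    out["WDC"] = parcel_aggregate(to_map(wdc), atlas)
    return pd.DataFrame(out)


def extract_static_node(
    series: np.ndarray,
    tr_seconds: float,
    n_drop: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    bands: tuple = (SLOW5, SLOW4),
    r_threshold: float = 0.25,
    include_reho: bool = False,
    falff_spectrum: str = "power",
) -> pd.DataFrame:
    """Node-level fallback: fALFF and degree centrality on parcel series.

    ReHo has no node-level definition here (it needs a spatial voxel
    neighborhood) and raises if requested.
    """
    if include_reho:
        raise ValueError(
            "ReHo is undefined on parcel-level series; provide voxel volumes"
        )
    x = np.asarray(series, dtype=float)
    detr = pp.detrend_linear(pp.drop_initial_volumes(x, n_drop=n_drop))
    filt = pp.preprocess(x, tr_seconds, n_drop=n_drop, low_hz=low_hz, high_hz=high_hz)
    n = x.shape[1]
    idx = pd.RangeIndex(1, n + 1, name="parcel")
    out = {}
    for name, band in zip(("f1ALFF", "f2ALFF"), bands):
        out[name] = pd.Series(
            falff(detr, tr_seconds, band=band, spectrum=falff_spectrum), index=idx
        )
    bdc, wdc = degree_centrality(filt, r_threshold=r_threshold)
    out["BDC"] = pd.Series(bdc, index=idx)
    out["WDC"] = pd.Series(wdc, index=idx)
    return pd.DataFrame(out)
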