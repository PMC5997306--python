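"""SNP-index / ΔSNP-index bulked-segregant statistics.

The SNP-index of a bulk at a site is the fraction of reads carrying the
non-reference allele; ΔSNP-index is the difference between the resistant
(BR) and susceptible (BS) bulks, index_BR - index_BS. Away from the
selected locus both bulks are random draws from the F2 and the expected
index is 0.5; near a strongly selected locus one bulk approaches fixation.

The module provides site-level computation, the site filters used to drop
error-like and shallow sites, sliding-window smoothing, permutation
confidence intervals under a depth-conditioned binomial null, and
candidate-region calling by fixed threshold or by CI exceedance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from bsaqtl.errors import DataError

__all__ = [
    "snp_index",
    "delta_snp_index",
    "make_track",
    "filter_snp_sites",
    "sliding_windows",
    "permutation_ci",
    "call_regions",
]


def snp_index(alt, depth):
    """Fraction of reads with the non-reference allele; NaN at depth 0.

    Accepts scalars or arrays. Raises :class:`DataError` if any alternative
    count exceeds its depth.
    """
    alt_a = np.asarray(alt, dtype=float)
    depth_a = np.asarray(depth, dtype=float)
    if np.any(alt_a > depth_a):
        raise DataError("alt count exceeds depth")
    if np.any(alt_a < 0) or np.any(depth_a < 0):
        raise DataError("negative counts")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(depth_a > 0, alt_a / np.where(depth_a > 0, depth_a, 1), np.nan)
    if np.isscalar(alt) and np.isscalar(depth):
        return float(out)
    return out


def delta_snp_index(index_br, index_bs):
    """index_BR - index_BS; missing if either index is missing."""
    br = np.asarray(index_br, dtype=float)
    bs = np.asarray(index_bs, dtype=float)
    out = br - bs
    if np.isscalar(index_br) and np.isscalar(index_bs):
        return float(out)
    return out


def make_track(counts_br: pd.DataFrame, counts_bs: pd.DataFrame) -> pd.DataFrame:
    """Join per-bulk count tables into a per-site SNP-index track.

    Inputs need columns ``chrom, pos, ref_count, alt_count`` (a ``depth``
    column is recomputed as ref+alt). The join is outer on (chrom, pos);
    a site absent from one bulk has missing index there.
    """
    frames = []
    for name, counts in (("br", counts_br), ("bs", counts_bs)):
        c = counts.copy()
        depth = c["ref_count"].to_numpy() + c["alt_count"].to_numpy()
        c[f"depth_{name}"] = depth
        c[f"index_{name}"] = snp_index(c["alt_count"].to_numpy(), depth)
        frames.append(c[["chrom", "pos", f"depth_{name}", f"index_{name}"]])
    track = frames[0].merge(frames[1], on=["chrom", "pos"], how="outer")
    track[["depth_br", "depth_bs"]] = track[["depth_br", "depth_bs"]].fillna(0).astype(int)
    track["delta"] = track["index_br"] - track["index_bs"]
    return track.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)


def filter_snp_sites(
    track: pd.DataFrame, index_floor: float = 0.3, depth_floor: int = 7
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop error-like and shallow sites from a SNP-index track.

    A site is removed iff the index is below ``index_floor`` in *both*
    bulks, or depth is below ``depth_floor`` in *either* bulk, or the index
    is missing in either bulk. Returns ``(kept, removed)`` where ``removed``
    carries a comma-joined ``reason`` column per dropped site.
    """
    if index_floor < 0 or depth_floor < 0:
        raise ValueError("thresholds must be >= 0")
    ibr = track["index_br"].to_numpy(dtype=float)
    ibs = track["index_bs"].to_numpy(dtype=float)
    low_index = (ibr < index_floor) & (ibs < index_floor)
    low_depth = (track["depth_br"].to_numpy() < depth_floor) | (
        track["depth_bs"].to_numpy() < depth_floor
    )
    missing = np.isnan(ibr) | np.isnan(ibs)
    low_index = low_index & ~missing
    drop = low_index | low_depth | missing
    reasons = []
    for li, ld, mi in zip(low_index[drop], low_depth[drop], missing[drop]):
        r = []
        if li:
            r.append("low_index_both_bulks")
        if ld:
            r.append("low_depth")
        if mi:
            r.append("missing_index")
        reasons.append(",".join(r))
    removed = track.loc[drop, ["chrom", "pos"]].copy()
    removed["reason"] = reasons
    return track.loc[~drop].reset_index(drop=True), removed.reset_index(drop=True)


def _window_starts(step: int, window: int, last_pos: int) -> np.ndarray:
    # 1-based anchors 1, 1+step, ...; emit every window whose span touches
    # [1, last_pos], so partial windows at the chromosome end are included.
    n = int(np.ceil(last_pos / step))
    return 1 + step * np.arange(max(n, 1))


def sliding_windows(
    track: pd.DataFrame,
    window: int = 1_000_000,
    step: int = 1_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window means of SNP-index and ΔSNP-index.

    Windows are half-open ``[start, start + window)`` anchored at
    ``start = 1 + j*step`` within each chromosome, extending to the
    chromosome length if given, else to the last observed site. Window
    means are plain averages over contained non-missing sites; windows
    without sites carry NaN means and ``n_sites`` 0.
    """
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    out = []
    for chrom, grp in track.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise DataError(f"positions not sorted on {chrom}")
        last = chrom_lengths[chrom] if chrom_lengths else int(pos[-1]) if len(pos) else 0
        if last == 0:
            continue
        starts = _window_starts(step, window, last)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        cols = {}
        for name in ("index_br", "index_bs", "delta"):
            v = grp[name].to_numpy(dtype=float)
            ok = ~np.isnan(v)
            csum = np.concatenate([[0.0], np.cumsum(np.where(ok, v, 0.0))])
            ccnt = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
            cnt = ccnt[hi] - ccnt[lo]
            with np.errstate(invalid="ignore"):
                cols[name] = np.where(cnt > 0, (csum[hi] - csum[lo]) / np.maximum(cnt, 1), np.nan)
            if name == "delta":
                n_sites = cnt
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window,
                    "n_sites": n_sites,
                    "mean_index_br": cols["index_br"],
                    "mean_index_bs": cols["index_bs"],
                    "mean_delta": cols["delta"],
                }
            )
        )
    if not out:
        return pd.DataFrame(
            columns=[
                "chrom",
                "start",
                "end",
                "n_sites",
                "mean_index_br",
                "mean_index_bs",
                "mean_delta",
            ]
        )
    return pd.concat(out, ignore_index=True)


def permutation_ci(
    track: pd.DataFrame,
    window: int = 1_000_000,
    step: int = 1_000,
    n_perm: int = 1000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence = 0,
    pooled: bool = False,
    bulk_size: int | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window profile with permutation confidence bounds on ΔSNP-index.

    Null model: at each site, alternative counts are redrawn
    Binomial(observed depth, 0.5) independently in both bulks — the F2
    expectation with no selected locus — and the null Δ is windowed exactly
    like the observed data, ``n_perm`` times. ``ci_low``/``ci_high`` are the
    (1-level)/2 and 1-(1-level)/2 empirical quantiles of the null window
    means, per window (or pooled genome-wide with ``pooled=True``).

    With ``bulk_size`` set, each null replicate first resamples the bulk
    composition per site (allele frequency ~ Binomial(2*bulk_size, 0.5) /
    (2*bulk_size)), adding the pooling variance of a finite bulk to the
    read-sampling variance.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    profile = sliding_windows(track, window, step, chrom_lengths)
    rng = np.random.default_rng(seed)

    usable = track[(track["depth_br"] > 0) & (track["depth_bs"] > 0)]
    null = np.full((n_perm, len(profile)), np.nan, dtype=np.float32)
    for chrom, grp in usable.groupby("chrom", sort=False):
        rows = profile.index[profile["chrom"] == chrom].to_numpy()
        if rows.size == 0:
            continue
        pos = grp["pos"].to_numpy()
        d_br = grp["depth_br"].to_numpy()
        d_bs = grp["depth_bs"].to_numpy()
        starts = profile.loc[rows, "start"].to_numpy()
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        cnt = hi - lo
        for p in range(n_perm):
            if bulk_size is None:
                f_br = f_bs = 0.5
            else:
                f_br = rng.binomial(2 * bulk_size, 0.5, size=pos.size) / (2 * bulk_size)
                f_bs = rng.binomial(2 * bulk_size, 0.5, size=pos.size) / (2 * bulk_size)
            delta = rng.binomial(d_br, f_br) / d_br - rng.binomial(d_bs, f_bs) / d_bs
            csum = np.concatenate([[0.0], np.cumsum(delta)])
            with np.errstate(invalid="ignore"):
                means = np.where(cnt > 0, (csum[hi] - csum[lo]) / np.maximum(cnt, 1), np.nan)
            null[p, rows] = means
    q = (1.0 - level) / 2.0
    if pooled:
        flat = null[~np.isnan(null)]
        lo_q, hi_q = np.quantile(flat, [q, 1.0 - q]) if flat.size else (np.nan, np.nan)
        profile["ci_low"] = lo_q
        profile["ci_high"] = hi_q
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            lo_q = np.nanquantile(null, q, axis=0)
            hi_q = np.nanquantile(null, 1.0 - q, axis=0)
        profile["ci_low"] = lo_q
        profile["ci_high"] = hi_q
    return profile


def call_regions(
    profile: pd.DataFrame,
    mode: str = "fixed",
    threshold: float = 0.5,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Candidate regions: maximal runs of consecutive windows passing a criterion.

    ``fixed`` mode keeps windows with mean ΔSNP-index >= ``threshold``
    (or ``|Δ| >= threshold`` with ``two_sided=True``, for data whose allele
    orientation makes the selected locus negative); ``ci`` mode keeps
    windows whose Δ falls outside ``[ci_low, ci_high]``. Runs are broken by
    windows with no sites. A region spans the first window start to the
    last window end; the peak window is the leftmost window with maximal
    (absolute) Δ.
    """
    if len(profile) == 0:
        raise ValueError("empty window profile")
    if mode not in ("fixed", "ci"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "ci" and not {"ci_low", "ci_high"}.issubset(profile.columns):
        raise ValueError("ci mode requires ci_low/ci_high columns")
    regions = []
    for chrom, grp in profile.groupby("chrom", sort=False):
        delta = grp["mean_delta"].to_numpy(dtype=float)
        if mode == "fixed":
            stat = np.abs(delta) if two_sided else delta
            hit = stat >= threshold
        else:
            hit = (delta < grp["ci_low"].to_numpy()) | (delta > grp["ci_high"].to_numpy())
        hit &= ~np.isnan(delta)
        if not hit.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], hit.astype(int), [0]])))
        for a, b in zip(edges[::2], edges[1::2]):
            run = grp.iloc[a:b]
            score = run["mean_delta"].to_numpy(dtype=float)
            peak = int(np.argmax(np.abs(score) if two_sided else score))
            regions.append(
                {
                    "chrom": chrom,
                    "start": int(run["start"].iloc[0]),
                    "end": int(run["end"].iloc[-1]),
                    "n_windows": len(run),
                    "peak_start": int(run["start"].iloc[peak]),
                    "peak_end": int(run["end"].iloc[peak]),
                    "peak_delta": float(score[peak]),
                    "mean_index_br": float(np.nanmean(run["mean_index_br"].to_numpy(dtype=float))),
                    "mean_index_bs": float(np.nanmean(run["mean_index_bs"].to_numpy(dtype=float))),
                }
            )
    cols = [
        "chrom",
        "start",
        "end",
        "n_windows",
        "peak_start",
        "peak_end",
        "peak_delta",
        "mean_index_br",
        "mean_index_bs",
    ]
    return pd.DataFrame(regions, columns=cols)
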