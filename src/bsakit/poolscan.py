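"""Sliding-window genome scan over pooled read counts.

Computes per-SNP allele-frequency differentiation between two pools,
SNP-rank windows of mean dAF and pooled heterozygosity (Hp), the
wild-type/mutant Hp ratio, empirical top-fraction thresholds, and merged
candidate intervals.

Windows are defined by SNP rank (e.g. 5,000 SNPs stepped by 1,000), never
by bp; physical spans are derived for reporting only and windows never
cross chromosome boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OrderingError",
    "ZeroDepthError",
    "site_delta_af",
    "delta_af_table",
    "make_windows",
    "window_delta_af",
    "window_hp",
    "hp_ratio",
    "window_stats",
    "empirical_top_fraction",
    "call_candidate_interval",
    "scan",
    "ScanResult",
]

DEFAULT_WINDOW_SNPS = 5_000
DEFAULT_STEP_SNPS = 1_000
DEFAULT_MIN_SNPS = 4_000
DEFAULT_EPSILON = 1e-4


class OrderingError(ValueError):
    """Input sites are not sorted by (chrom, pos)."""


class ZeroDepthError(ValueError):
    """A pool has zero read depth at a site entering a per-site statistic."""


def site_delta_af(mut_ref: int, mut_alt: int, wt_ref: int, wt_alt: int) -> float:
    """Absolute difference in alt-allele frequency between the two pools."""
    dm = mut_ref + mut_alt
    dw = wt_ref + wt_alt
    if dm <= 0 or dw <= 0:
        raise ZeroDepthError("both pools need depth > 0")
    return abs(mut_alt / dm - wt_alt / dw)


def delta_af_table(sites: pd.DataFrame) -> tuple[pd.Series, int]:
    """Vectorised per-site dAF.

    Returns (values, n_excluded); zero-depth sites get NaN rather than being
    silently dropped, and the exclusion count is reported alongside.
    """
    dm = (sites["mut_ref"] + sites["mut_alt"]).to_numpy(dtype=float)
    dw = (sites["wt_ref"] + sites["wt_alt"]).to_numpy(dtype=float)
    ok = (dm > 0) & (dw > 0)
    vals = np.full(len(sites), np.nan)
    vals[ok] = np.abs(
        sites["mut_alt"].to_numpy(dtype=float)[ok] / dm[ok]
        - sites["wt_alt"].to_numpy(dtype=float)[ok] / dw[ok]
    )
    return pd.Series(vals, index=sites.index, name="daf"), int((~ok).sum())


def _check_sorted(sites: pd.DataFrame) -> None:
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    # chromosome blocks must be contiguous and positions nondecreasing within
    seen = {}
    prev = None
    for i, c in enumerate(chrom):
        if c != prev:
            if c in seen:
                raise OrderingError("chromosome blocks are not contiguous")
            seen[c] = i
            prev = c
    for c, start in seen.items():
        block = pos[chrom == c]
        if np.any(np.diff(block) < 0):
            raise OrderingError(f"positions not sorted on {c}")


def make_windows(
    sites: pd.DataFrame,
    window_snps: int = DEFAULT_WINDOW_SNPS,
    step_snps: int = DEFAULT_STEP_SNPS,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> pd.DataFrame:
    """Enumerate SNP-rank window spans per chromosome.

    Spans start at ranks 1, 1+step, 1+2*step, ... within each chromosome and
    are emitted when they contain at least ``min_snps`` SNPs; truncated spans
    at the chromosome end are allowed down to that minimum.

    Returns a DataFrame with chrom, first_snp_index / last_snp_index (1-based
    ranks within the chromosome, inclusive), istart/istop (absolute iloc
    offsets into ``sites``, half-open), start_pos/end_pos, n_snps.
    """
    if window_snps < 1 or step_snps < 1 or min_snps < 1:
        raise ValueError("window, step and min SNP counts must be positive")
    _check_sorted(sites)
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    rows = []
    offset = 0
    for c in pd.unique(chrom):
        n = int((chrom == c).sum())
        for start in range(0, n, step_snps):
            stop = min(start + window_snps, n)
            count = stop - start
            if count < min_snps:
                continue
            rows.append(
                {
                    "chrom": c,
                    "first_snp_index": start + 1,
                    "last_snp_index": stop,
                    "istart": offset + start,
                    "istop": offset + stop,
                    "start_pos": int(pos[offset + start]),
                    "end_pos": int(pos[offset + stop - 1]),
                    "n_snps": count,
                }
            )
        offset += n
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "first_snp_index",
            "last_snp_index",
            "istart",
            "istop",
            "start_pos",
            "end_pos",
            "n_snps",
        ],
    )


def window_delta_af(window_sites: pd.DataFrame) -> float:
    """Arithmetic mean of per-site dAF over a window (zero-depth sites excluded)."""
    vals, _ = delta_af_table(window_sites)
    return float(np.nanmean(vals.to_numpy()))


def window_hp(window_sites: pd.DataFrame, pool: str) -> float:
    """Pooled heterozygosity Hp = 2*S_maj*S_min / (S_maj + S_min)^2.

    Major/minor read counts are taken per SNP within the requested pool
    (``"mut"`` or ``"wt"``); sums run over the window. Returns NaN when the
    window has no reads in that pool.
    """
    if pool not in ("mut", "wt"):
        raise ValueError("pool must be 'mut' or 'wt'")
    ref = window_sites[f"{pool}_ref"].to_numpy(dtype=float)
    alt = window_sites[f"{pool}_alt"].to_numpy(dtype=float)
    s_maj = float(np.maximum(ref, alt).sum())
    s_min = float(np.minimum(ref, alt).sum())
    total = s_maj + s_min
    if total == 0:
        return float("nan")
    return 2.0 * s_maj * s_min / total**2


def hp_ratio(
    hp_wt: float, hp_mut: float, epsilon: float = DEFAULT_EPSILON, invert: bool = False
) -> float:
    """Epsilon-stabilised Hp ratio; wild-type over mutant by default.

    Elevated values flag mutant-pool homozygosity. ``invert=True`` gives the
    opposite orientation for callers that prefer it.
    """
    if math.isnan(hp_wt) or math.isnan(hp_mut):
        return float("nan")
    num, den = (hp_mut, hp_wt) if invert else (hp_wt, hp_mut)
    return (num + epsilon) / (den + epsilon)


def window_stats(
    sites: pd.DataFrame,
    window_snps: int = DEFAULT_WINDOW_SNPS,
    step_snps: int = DEFAULT_STEP_SNPS,
    min_snps: int = DEFAULT_MIN_SNPS,
    epsilon: float = DEFAULT_EPSILON,
    invert_ratio: bool = False,
) -> pd.DataFrame:
    """Per-window mean dAF, per-pool Hp, and the Hp ratio.

    Vectorised via prefix sums; equivalent to evaluating window_delta_af /
    window_hp on every span from make_windows.
    """
    windows = make_windows(sites, window_snps, step_snps, min_snps)
    if windows.empty:
        for col in ("mean_daf", "hp_mut", "hp_wt", "hp_ratio", "n_excluded"):
            windows[col] = pd.Series(dtype=float)
        return windows

    daf, _ = delta_af_table(sites)
    daf_arr = daf.to_numpy()
    ok = ~np.isnan(daf_arr)
    cs_daf = np.concatenate([[0.0], np.cumsum(np.where(ok, daf_arr, 0.0))])
    cs_ok = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])

    def prefix(col_a, col_b, fn):
        a = sites[col_a].to_numpy(dtype=float)
        b = sites[col_b].to_numpy(dtype=float)
        return np.concatenate([[0.0], np.cumsum(fn(a, b))])

    cs = {
        ("mut", "maj"): prefix("mut_ref", "mut_alt", np.maximum),
        ("mut", "min"): prefix("mut_ref", "mut_alt", np.minimum),
        ("wt", "maj"): prefix("wt_ref", "wt_alt", np.maximum),
        ("wt", "min"): prefix("wt_ref", "wt_alt", np.minimum),
    }

    i0 = windows["istart"].to_numpy()
    i1 = windows["istop"].to_numpy()
    n_ok = cs_ok[i1] - cs_ok[i0]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_daf = np.where(n_ok > 0, (cs_daf[i1] - cs_daf[i0]) / n_ok, np.nan)

        hp = {}
        for pool in ("mut", "wt"):
            s_maj = cs[(pool, "maj")][i1] - cs[(pool, "maj")][i0]
            s_min = cs[(pool, "min")][i1] - cs[(pool, "min")][i0]
            tot = s_maj + s_min
            hp[pool] = np.where(tot > 0, 2.0 * s_maj * s_min / tot**2, np.nan)

    num, den = (hp["mut"], hp["wt"]) if invert_ratio else (hp["wt"], hp["mut"])
    windows["mean_daf"] = mean_daf
    windows["hp_mut"] = hp["mut"]
    windows["hp_wt"] = hp["wt"]
    windows["hp_ratio"] = (num + epsilon) / (den + epsilon)
    windows["n_excluded"] = (i1 - i0) - n_ok
    return windows


def empirical_top_fraction(values, fraction: float = 0.01) -> tuple[float, np.ndarray]:
    """Threshold and flags for the empirical top ``fraction`` of values.

    The threshold is the smallest value among the ceil(fraction*N) largest
    finite values; every value >= threshold is flagged, so ties at the
    threshold are all included.
    """
    vals = np.asarray(values, dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("need at least one finite value")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    k = math.ceil(fraction * finite.size)
    threshold = float(np.sort(finite)[::-1][k - 1])
    flags = np.zeros(vals.size, dtype=bool)
    with np.errstate(invalid="ignore"):
        flags[np.isfinite(vals)] = vals[np.isfinite(vals)] >= threshold
    return threshold, flags


def call_candidate_interval(flagged_windows: pd.DataFrame) -> pd.DataFrame:
    """Union of flagged window spans, merged per chromosome.

    Spans are converted to BED convention (0-based half-open); overlapping or
    book-ended spans merge. Output is sorted by (chrom, start).
    """
    cols = ["chrom", "start", "end"]
    if flagged_windows.empty:
        return pd.DataFrame(columns=cols)
    spans = flagged_windows[["chrom", "start_pos", "end_pos"]].copy()
    spans["start"] = spans["start_pos"] - 1  # 1-based inclusive -> 0-based half-open
    spans["end"] = spans["end_pos"]
    merged = []
    for c, grp in spans.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                merged.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((c, cur_s, cur_e))
    return pd.DataFrame(merged, columns=cols)


@dataclass
class ScanResult:
    """Windows with statistics plus thresholds and called intervals."""

    windows: pd.DataFrame
    daf_threshold: float | None
    hp_ratio_threshold: float | None
    intervals_daf: pd.DataFrame
    intervals_hp: pd.DataFrame


def scan(
    sites: pd.DataFrame,
    window_snps: int = DEFAULT_WINDOW_SNPS,
    step_snps: int = DEFAULT_STEP_SNPS,
    min_snps: int = DEFAULT_MIN_SNPS,
    top_fraction: float = 0.01,
    epsilon: float = DEFAULT_EPSILON,
    stat: str = "both",
    invert_ratio: bool = False,
) -> ScanResult:
    """Full window scan: statistics, empirical thresholds, candidate intervals.

    ``stat`` selects which statistic drives interval calling: ``"daf"``,
    ``"hp-ratio"`` or ``"both"``.
    """
    if stat not in ("daf", "hp-ratio", "both"):
        raise ValueError("stat must be 'daf', 'hp-ratio' or 'both'")
    windows = window_stats(
        sites, window_snps, step_snps, min_snps, epsilon=epsilon, invert_ratio=invert_ratio
    )
    daf_thr = hp_thr = None
    empty = pd.DataFrame(columns=["chrom", "start", "end"])
    int_daf = int_hp = empty
    if not windows.empty:
        if stat in ("daf", "both"):
            daf_thr, flags = empirical_top_fraction(windows["mean_daf"], top_fraction)
            windows["flag_daf"] = flags
            int_daf = call_candidate_interval(windows[flags])
        if stat in ("hp-ratio", "both"):
            hp_thr, flags = empirical_top_fraction(windows["hp_ratio"], top_fraction)
            windows["flag_hp"] = flags
            int_hp = call_candidate_interval(windows[flags])
    return ScanResult(windows, daf_thr, hp_thr, int_daf, int_hp)
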