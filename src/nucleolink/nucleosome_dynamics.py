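"""Nucleosome calling and two-condition dynamic-nucleosome classification.

Reads are MNase-seq fragment midpoints (one integer position per mapped
mononucleosome fragment).  Calling smooths the midpoint histogram with a
Gaussian kernel and takes local maxima separated by at least a minimum
distance as summits; reads within half a footprint (73 bp) of their nearest
summit define the call's occupancy (depth-normalised read support) and
fuzziness (standard deviation of member midpoints, in bp).

A wild-type and a mutant map are compared by mutual-nearest-summit pairing.
Three per-nucleosome statistics are computed:

* occupancy: one-sided Poisson tail on the mutant summit count with the
  depth-scaled wild-type count as rate, in the direction of the change;
* fuzziness: two-sided F-test on the variances of member midpoints;
* point difference: the same Poisson tail computed on fixed-window read
  counts at the reference summit, which is what flags re-positioned
  nucleosomes whose local signal moved.

A nucleosome is "altered" when any flag fires: a position shift requires a
summit displacement inside a configured range (50-90 bp by default) plus a
significant point difference; fuzziness and occupancy changes require their
log10 p-values at or below the cutoff (default -15, i.e. p <= 1e-15).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy import stats

__all__ = [
    "NucleosomeParams",
    "reads_by_chrom",
    "occupancy_track",
    "call_nucleosomes",
    "match_nucleosomes",
    "occupancy_test",
    "fuzziness_test",
    "classify_dynamic",
    "compare_maps",
    "summarize_alterations",
    "map_statistics",
    "FOOTPRINT",
]

#: Canonical nucleosome footprint in bp; calls span a dyad-centred footprint.
FOOTPRINT = 147
_HALF = FOOTPRINT // 2  # 73
_LN10 = math.log(10.0)


@dataclass
class NucleosomeParams:
    smoothing_sigma: float = 15.0  # bp, Gaussian kernel for the midpoint histogram
    min_distance: int = 100  # bp, minimum summit separation
    min_reads: int = 3  # minimum read support per call
    pairing_window: int = 100  # bp, mutual-nearest pairing limit
    point_halfwidth: int = 36  # bp, fixed window for the point-difference count
    log10p_cutoff: float = -15.0
    shift_range: tuple[int, int] = (50, 90)


def reads_by_chrom(reads) -> dict[str, np.ndarray]:
    """Normalise midpoint input (DataFrame with chrom/pos or dict) to sorted arrays."""
    if isinstance(reads, dict):
        return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in reads.items()}
    return {
        chrom: np.sort(sub["pos"].to_numpy(dtype=np.int64))
        for chrom, sub in reads.groupby("chrom")
    }


def occupancy_track(
    reads, chrom_lengths: dict[str, int], smoothing_sigma: float = 15.0
) -> dict[str, np.ndarray]:
    """Per-bp smoothed midpoint-density track for each chromosome."""
    by = reads_by_chrom(reads)
    out = {}
    for chrom, length in chrom_lengths.items():
        counts = np.zeros(length, dtype=float)
        pos = by.get(chrom)
        if pos is not None and len(pos):
            np.add.at(counts, np.clip(pos, 0, length - 1), 1.0)
        out[chrom] = (
            gaussian_filter1d(counts, smoothing_sigma) if smoothing_sigma else counts
        )
    return out


def _window_counts(sorted_pos: np.ndarray, centers: np.ndarray, halfwidth: int):
    lo = np.searchsorted(sorted_pos, centers - halfwidth, side="left")
    hi = np.searchsorted(sorted_pos, centers + halfwidth + 1, side="left")
    return hi - lo


def call_nucleosomes(
    reads,
    chrom_lengths: dict[str, int],
    params: NucleosomeParams | None = None,
    exclude: dict[str, list[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Call nucleosomes from read midpoints.

    Returns a coordinate-sorted frame with columns chrom, start, end, summit,
    n_reads, fuzziness.  ``exclude`` removes summits inside the given spans
    (used for centromeres, whose nucleosomes are not recoverable in this
    kind of data and are left uncalled).
    """
    params = params or NucleosomeParams()
    by = reads_by_chrom(reads)
    frames = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"zero-length chromosome {chrom!r}")
        pos = by.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        counts = np.zeros(length, dtype=float)
        np.add.at(counts, np.clip(pos, 0, length - 1), 1.0)
        smooth = gaussian_filter1d(counts, params.smoothing_sigma)
        summits, _ = find_peaks(
            smooth, distance=params.min_distance, height=1e-12
        )
        if len(summits) == 0:
            continue
        if exclude and chrom in exclude:
            keep = np.ones(len(summits), dtype=bool)
            for s, e in exclude[chrom]:
                keep &= ~((summits >= s) & (summits < e))
            summits = summits[keep]
            if len(summits) == 0:
                continue
        # assign each read to its nearest summit within half a footprint
        right = np.searchsorted(summits, pos)
        left = np.clip(right - 1, 0, len(summits) - 1)
        right = np.clip(right, 0, len(summits) - 1)
        d_left = np.abs(pos - summits[left])
        d_right = np.abs(pos - summits[right])
        nearest = np.where(d_right < d_left, right, left)
        dist = np.minimum(d_left, d_right)
        ok = dist <= _HALF
        idx, rpos = nearest[ok], pos[ok].astype(float)
        n = np.bincount(idx, minlength=len(summits))
        s1 = np.bincount(idx, weights=rpos, minlength=len(summits))
        s2 = np.bincount(idx, weights=rpos * rpos, minlength=len(summits))
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = s1 / np.maximum(n, 1)
            var = np.where(
                n > 1, (s2 - n * mean * mean) / np.maximum(n - 1, 1), 0.0
            )
        fuzz = np.sqrt(np.maximum(var, 0.0))
        keep = n >= params.min_reads
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.maximum(summits[keep] - _HALF, 0),
                    "end": np.minimum(summits[keep] + _HALF + 1, length),
                    "summit": summits[keep],
                    "n_reads": n[keep],
                    "fuzziness": fuzz[keep],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "summit", "n_reads", "fuzziness"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "summit"], ignore_index=True)


def match_nucleosomes(
    wt: pd.DataFrame, mut: pd.DataFrame, window: int = 100
) -> pd.DataFrame:
    """Mutual-nearest-summit pairing of two call lists.

    Calls whose nearest partner is farther than ``window`` bp (or not mutual)
    appear unpaired, with the partner index set to -1; they are treated
    downstream as a complete occupancy loss/gain at that position.
    """
    rows = []
    chroms = sorted(set(wt["chrom"]) | set(mut["chrom"]))
    for chrom in chroms:
        w = wt[wt["chrom"] == chrom].reset_index()
        m = mut[mut["chrom"] == chrom].reset_index()
        ws = w["summit"].to_numpy()
        ms = m["summit"].to_numpy()
        if len(ws) and len(ms):
            # nearest mutant for each wt
            j = np.clip(np.searchsorted(ms, ws), 0, len(ms) - 1)
            jl = np.clip(j - 1, 0, len(ms) - 1)
            near_m = np.where(
                np.abs(ms[j] - ws) <= np.abs(ms[jl] - ws), j, jl
            )
            i = np.clip(np.searchsorted(ws, ms), 0, len(ws) - 1)
            il = np.clip(i - 1, 0, len(ws) - 1)
            near_w = np.where(
                np.abs(ws[i] - ms) <= np.abs(ws[il] - ms), i, il
            )
            paired_w = np.full(len(ws), -1)
            for wi in range(len(ws)):
                mj = near_m[wi]
                if near_w[mj] == wi and abs(ms[mj] - ws[wi]) <= window:
                    paired_w[wi] = mj
            # rescue pass: a summit shifted by more than half the spacing can
            # lose mutuality to an unshifted neighbour; greedily pair the
            # leftovers that still lie within the window
            taken = set(paired_w[paired_w >= 0])
            free_w = [wi for wi in range(len(ws)) if paired_w[wi] < 0]
            free_m = [mj for mj in range(len(ms)) if mj not in taken]
            cands = sorted(
                (abs(int(ms[mj]) - int(ws[wi])), wi, mj)
                for wi in free_w
                for mj in free_m
                if abs(int(ms[mj]) - int(ws[wi])) <= window
            )
            used_w: set[int] = set()
            used_m: set[int] = set()
            for _, wi, mj in cands:
                if wi in used_w or mj in used_m:
                    continue
                paired_w[wi] = mj
                used_w.add(wi)
                used_m.add(mj)
        else:
            paired_w = np.full(len(ws), -1)
        taken = set(paired_w[paired_w >= 0])
        for wi in range(len(ws)):
            mj = paired_w[wi]
            rows.append(
                {
                    "chrom": chrom,
                    "wt_idx": int(w.loc[wi, "index"]),
                    "mut_idx": int(m.loc[mj, "index"]) if mj >= 0 else -1,
                    "wt_summit": int(ws[wi]),
                    "mut_summit": int(ms[mj]) if mj >= 0 else -1,
                    "shift_bp": float(abs(ms[mj] - ws[wi])) if mj >= 0 else np.nan,
                }
            )
        for mj in range(len(ms)):
            if mj not in taken:
                rows.append(
                    {
                        "chrom": chrom,
                        "wt_idx": -1,
                        "mut_idx": int(m.loc[mj, "index"]),
                        "wt_summit": -1,
                        "mut_summit": int(ms[mj]),
                        "shift_bp": np.nan,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["chrom", "wt_idx", "mut_idx", "wt_summit", "mut_summit", "shift_bp"],
    )


def occupancy_test(
    wt_count: float, mut_count: float, depth_factor: float = 1.0
) -> tuple[float, str]:
    """One-sided Poisson tail on the mutant count, rate = depth-scaled WT count.

    Returns (log10 p, direction).  The tail is taken in the direction of the
    observed change; equal counts give p = 1 and direction 'none'.  A zero
    wild-type count is floored at a rate of 1 so that gains over nothing
    remain testable with a finite p.
    """
    if depth_factor <= 0:
        raise ValueError("depth_factor must be positive")
    if wt_count == 0 and mut_count == 0:
        return 0.0, "none"
    lam = max(wt_count * depth_factor, 1.0 if wt_count == 0 else wt_count * depth_factor)
    obs = mut_count
    if obs > lam:
        log10p = stats.poisson.logsf(obs - 1, lam) / _LN10
        direction = "up"
    elif obs < lam:
        log10p = stats.poisson.logcdf(obs, lam) / _LN10
        direction = "down"
    else:
        return 0.0, "none"
    if log10p >= math.log10(0.5):
        direction = "none"
    return float(min(log10p, 0.0)), direction


def fuzziness_test(sd1: float, n1: int, sd2: float, n2: int) -> float:
    """Two-sided F-test on midpoint variances; returns log10 p (NaN if n < 2)."""
    if n1 < 2 or n2 < 2:
        return float("nan")
    v1, v2 = sd1 * sd1, sd2 * sd2
    if v1 == 0 and v2 == 0:
        return 0.0
    if v2 > v1:
        v1, v2, n1, n2 = v2, v1, n2, n1
    if v2 == 0:
        return float("-inf")
    F = v1 / v2
    log10p = (math.log(2.0) + stats.f.logsf(F, n1 - 1, n2 - 1)) / _LN10
    return float(min(log10p, 0.0))


def compare_maps(
    wt_reads,
    mut_reads,
    chrom_lengths: dict[str, int],
    params: NucleosomeParams | None = None,
    exclude: dict[str, list[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Call, pair and test two midpoint maps; one row per (paired or lone) call.

    Depth normalisation scales the wild-type rate by total-read ratio
    (mutant/wild-type) before the Poisson tests.
    """
    params = params or NucleosomeParams()
    wt_by = reads_by_chrom(wt_reads)
    mut_by = reads_by_chrom(mut_reads)
    wt_calls = call_nucleosomes(wt_by, chrom_lengths, params, exclude)
    mut_calls = call_nucleosomes(mut_by, chrom_lengths, params, exclude)
    pairs = match_nucleosomes(wt_calls, mut_calls, params.pairing_window)

    wt_total = sum(len(v) for v in wt_by.values())
    mut_total = sum(len(v) for v in mut_by.values())
    depth = mut_total / wt_total if wt_total else 1.0

    recs = []
    for chrom, sub in pairs.groupby("chrom", sort=False):
        wpos = wt_by.get(chrom, np.empty(0, dtype=np.int64))
        mpos = mut_by.get(chrom, np.empty(0, dtype=np.int64))
        ref = np.where(
            sub["wt_summit"].to_numpy() >= 0,
            sub["wt_summit"].to_numpy(),
            sub["mut_summit"].to_numpy(),
        )
        w_point = _window_counts(wpos, ref, params.point_halfwidth)
        m_point = _window_counts(mpos, ref, params.point_halfwidth)
        for row, wp, mp in zip(sub.itertuples(index=False), w_point, m_point):
            wt_n = (
                float(wt_calls.loc[row.wt_idx, "n_reads"]) if row.wt_idx >= 0 else 0.0
            )
            mut_n = (
                float(mut_calls.loc[row.mut_idx, "n_reads"])
                if row.mut_idx >= 0
                else 0.0
            )
            # for lone calls, occupancy evidence comes from the fixed window
            occ_wt = wt_n if row.wt_idx >= 0 and row.mut_idx >= 0 else float(wp)
            occ_mut = mut_n if row.wt_idx >= 0 and row.mut_idx >= 0 else float(mp)
            occ_log10p, occ_dir = occupancy_test(occ_wt, occ_mut, depth)
            point_log10p, _ = occupancy_test(float(wp), float(mp), depth)
            if row.wt_idx >= 0 and row.mut_idx >= 0:
                fuzz_log10p = fuzziness_test(
                    float(wt_calls.loc[row.wt_idx, "fuzziness"]),
                    int(wt_n),
                    float(mut_calls.loc[row.mut_idx, "fuzziness"]),
                    int(mut_n),
                )
            else:
                fuzz_log10p = float("nan")
            recs.append(
                {
                    "chrom": chrom,
                    "wt_summit": row.wt_summit,
                    "mut_summit": row.mut_summit,
                    "shift_bp": row.shift_bp,
                    "wt_reads": wt_n,
                    "mut_reads": mut_n,
                    "occ_log10p": occ_log10p,
                    "occ_direction": occ_dir,
                    "fuzz_log10p": fuzz_log10p,
                    "point_log10p": point_log10p,
                }
            )
    out = pd.DataFrame(recs)
    out.attrs["wt_total_reads"] = wt_total
    out.attrs["mut_total_reads"] = mut_total
    out.attrs["depth_factor"] = depth
    return out


def classify_dynamic(
    comparisons: pd.DataFrame,
    log10p_cutoff: float = -15.0,
    shift_range: tuple[float, float] = (50.0, 90.0),
) -> pd.DataFrame:
    """Flag each comparison row for position shift / fuzziness / occupancy change.

    ``log10p_cutoff`` of -15 means p <= 1e-15 (significance at least that
    strong), the convention used for deeply sequenced maps; shallower maps
    warrant a cutoff matched to their depth.
    """
    lo, hi = shift_range
    shift = (
        comparisons["shift_bp"].between(lo, hi)
        & (comparisons["point_log10p"] <= log10p_cutoff)
    ).fillna(False)
    fuzz = (comparisons["fuzz_log10p"] <= log10p_cutoff).fillna(False)
    occ = (comparisons["occ_log10p"] <= log10p_cutoff) & (
        comparisons["occ_direction"] != "none"
    )
    out = comparisons.copy()
    out["position_shift"] = shift.to_numpy(dtype=bool)
    out["fuzziness_change"] = fuzz.to_numpy(dtype=bool)
    out["occupancy_change"] = occ.to_numpy(dtype=bool)
    out["occupancy_subtype"] = np.where(
        out["occupancy_change"],
        np.where(comparisons["occ_direction"] == "up", "increase", "decrease"),
        "",
    )
    out["altered"] = shift | fuzz | occ
    return out


def summarize_alterations(classified: pd.DataFrame, total_nucleosomes: int) -> dict:
    """Per-category counts plus the altered fraction of all nucleosomes.

    'altered' counts nucleosomes with at least one flag (categories may
    co-occur, so it is not the column sum).
    """
    if total_nucleosomes <= 0:
        raise ValueError("total_nucleosomes must be positive")
    n_classified = int(len(classified))
    if total_nucleosomes < n_classified:
        raise ValueError("total_nucleosomes smaller than number classified")
    altered = int(classified["altered"].sum()) if n_classified else 0
    inc = (
        int((classified["occupancy_subtype"] == "increase").sum())
        if n_classified
        else 0
    )
    dec = (
        int((classified["occupancy_subtype"] == "decrease").sum())
        if n_classified
        else 0
    )
    return {
        "altered": altered,
        "position_shift": int(classified["position_shift"].sum()) if n_classified else 0,
        "fuzziness_change": int(classified["fuzziness_change"].sum())
        if n_classified
        else 0,
        "occupancy_change": int(classified["occupancy_change"].sum())
        if n_classified
        else 0,
        "occupancy_increase": inc,
        "occupancy_decrease": dec,
        "total_nucleosomes": int(total_nucleosomes),
        "percent_altered": 100.0 * altered / total_nucleosomes,
    }


def map_statistics(calls: pd.DataFrame) -> dict:
    """Distributions of fuzziness, neighbour distance and occupancy for a map."""
    dists = []
    for _, sub in calls.groupby("chrom"):
        s = np.sort(sub["summit"].to_numpy())
        if len(s) >= 2:
            dists.append(np.diff(s))
    distances = np.concatenate(dists) if dists else np.empty(0)
    fuzz = calls["fuzziness"].to_numpy(dtype=float)
    occ = calls["n_reads"].to_numpy(dtype=float)

    def _summary(x: np.ndarray) -> dict:
        if len(x) == 0:
            return {"n": 0}
        return {
            "n": int(len(x)),
            "mean": float(np.mean(x)),
            "median": float(np.median(x)),
            "q25": float(np.quantile(x, 0.25)),
            "q75": float(np.quantile(x, 0.75)),
        }

    return {
        "fuzziness": fuzz,
        "distances": distances,
        "occupancy": occ,
        "fuzziness_summary": _summary(fuzz),
        "distance_summary": _summary(distances),
        "occupancy_summary": _summary(occ),
    }
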