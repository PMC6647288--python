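"""Tiling-array cohesin peak calling and region-level quantitation.

Probe tables carry one row per probe (chrom, pos = probe centre on a 5 bp
grid, signal = log2 IP/input, pvalue).  The caller:

1. subtracts the untagged-strain signal probe-by-probe (background
   correction; the p-value stays that of the tagged strain),
2. keeps probes with p < alpha AND positive corrected signal,
3. merges runs of qualifying probes, allowing internal gaps up to
   ``max_gap`` bp, and discards runs shorter than ``min_run`` bp.

Peak signal is the sum of member corrected signals.  Because tagged and
untagged (or two conditions) hybridise to separate arrays with no common
internal control, per-region amounts are only ever compared after
normalising the mutant/wild-type ratio to its genome-wide value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import GenomicInterval, IGRCatalog, overlaps

__all__ = [
    "CohesinPeak",
    "correct_signal",
    "select_probes",
    "assemble_peaks",
    "region_cohesin_amount",
    "normalized_condition_ratio",
    "feature_overlap_counts",
    "peaks_to_frame",
]

PROBE_LENGTH = 25  # bp footprint of one probe, centred on its position


@dataclass(frozen=True)
class CohesinPeak:
    interval: GenomicInterval
    peak_signal: float  # sum of member positive corrected signals
    n_probes: int


def correct_signal(tagged: pd.DataFrame, untagged: pd.DataFrame) -> pd.DataFrame:
    """Background-correct tagged probe signal by the untagged strain.

    Grids are aligned on (chrom, pos); a probe missing from the untagged
    table contributes 0 background (with a warning), since arrays
    occasionally drop probes.  Probes present only in the untagged table
    are ignored.
    """
    merged = tagged.merge(
        untagged[["chrom", "pos", "signal"]],
        on=["chrom", "pos"],
        how="left",
        suffixes=("", "_untagged"),
    )
    missing = merged["signal_untagged"].isna().sum()
    if missing:
        warnings.warn(f"{missing} probes missing from untagged table; treated as 0")
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "signal": merged["signal"] - merged["signal_untagged"].fillna(0.0),
            "pvalue": merged["pvalue"],
        }
    )
    return out.sort_values(["chrom", "pos"], ignore_index=True)


def select_probes(corrected: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Qualifying probes: p strictly below alpha AND positive corrected signal."""
    keep = (corrected["pvalue"] < alpha) & (corrected["signal"] > 0)
    return corrected[keep].reset_index(drop=True)


def assemble_peaks(
    qualifying: pd.DataFrame,
    max_gap: int = 250,
    min_run: int = 30,
    probe_length: int = PROBE_LENGTH,
    mode: str = "footprint",
) -> list[CohesinPeak]:
    """Merge runs of qualifying probes into peaks.

    ``mode='footprint'`` (default) extends each probe to its ``probe_length``
    footprint centred on the probe position; gaps are measured edge-to-edge
    between footprints, and the emitted interval spans footprint edges.
    ``mode='centers'`` measures gaps between probe centres and spans them,
    which localises boundaries to within one probe step.  In either mode a
    run shorter than ``min_run`` bp is discarded (a single isolated probe
    never qualifies with the defaults).
    """
    if mode not in ("footprint", "centers"):
        raise ValueError("mode must be 'footprint' or 'centers'")
    half_lo = (probe_length - 1) // 2 if mode == "footprint" else 0
    half_hi = probe_length - 1 - half_lo if mode == "footprint" else 0
    peaks: list[CohesinPeak] = []
    for chrom, sub in qualifying.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        sig = sub["signal"].to_numpy(dtype=float)
        if len(pos) == 0:
            continue
        starts = pos - half_lo
        ends = pos + half_hi + 1
        run_start = 0
        for i in range(1, len(pos) + 1):
            open_gap = i < len(pos) and starts[i] - ends[i - 1] <= max_gap
            if open_gap:
                continue
            s, e = int(starts[run_start]), int(ends[i - 1])
            if e - s >= min_run:
                peaks.append(
                    CohesinPeak(
                        GenomicInterval(chrom, s, e),
                        float(sig[run_start:i].sum()),
                        int(i - run_start),
                    )
                )
            run_start = i
    return peaks


def peaks_to_frame(peaks: list[CohesinPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.interval.chrom for p in peaks],
            "start": [p.interval.start for p in peaks],
            "end": [p.interval.end for p in peaks],
            "peak_signal": [p.peak_signal for p in peaks],
            "n_probes": [p.n_probes for p in peaks],
        }
    )


def region_cohesin_amount(
    qualifying: pd.DataFrame,
    regions: dict[str, list[GenomicInterval]],
) -> dict[str, float]:
    """Sum of qualifying corrected signals per region class, plus 'genome'.

    A probe belongs to a region when its centre falls inside; a probe can
    contribute to several classes (classes are quantified independently).
    """
    out: dict[str, float] = {"genome": float(qualifying["signal"].sum())}
    by_chrom = {c: sub for c, sub in qualifying.groupby("chrom")}
    for cls, ivs in regions.items():
        total = 0.0
        n_hit = 0
        for iv in ivs:
            sub = by_chrom.get(iv.chrom)
            if sub is None:
                continue
            pos = sub["pos"].to_numpy()
            lo = np.searchsorted(pos, iv.start, side="left")
            hi = np.searchsorted(pos, iv.end, side="left")
            if hi > lo:
                total += float(sub["signal"].to_numpy()[lo:hi].sum())
                n_hit += 1
        if not ivs:
            warnings.warn(f"region class {cls!r} is empty; amount set to 0")
        out[cls] = total
    return out


def normalized_condition_ratio(
    amount_mut: dict[str, float], amount_wt: dict[str, float]
) -> dict[str, float]:
    """Per-region mutant/wild-type signal ratio, normalised so genome == 1.

    Undefined regions (zero wild-type amount) come back as NaN.
    """
    if amount_wt.get("genome", 0.0) <= 0:
        raise ValueError("genome-wide wild-type amount must be positive")
    genome_ratio = amount_mut["genome"] / amount_wt["genome"]
    out = {}
    for cls, wt_amt in amount_wt.items():
        mut_amt = amount_mut.get(cls, 0.0)
        if wt_amt <= 0:
            warnings.warn(f"wild-type amount for {cls!r} is 0; ratio undefined")
            out[cls] = float("nan")
        else:
            out[cls] = (mut_amt / wt_amt) / genome_ratio
    return out


def feature_overlap_counts(
    peaks: list[CohesinPeak],
    catalogs: dict[str, list[GenomicInterval]],
    igrs: IGRCatalog | None = None,
) -> dict:
    """Features overlapped by >= 1 bp by any peak, per class.

    Returns counts per catalog class; with an IGR catalog supplied, also the
    breakdown of cohesin-overlapped IGRs by flanking-gene orientation.
    """
    peak_ivs = [p.interval for p in peaks]

    def _count(ivs: list[GenomicInterval]) -> int:
        return sum(
            1 for iv in ivs if any(overlaps(iv, piv) >= 1 for piv in peak_ivs)
        )

    out = {"counts": {cls: _count(ivs) for cls, ivs in catalogs.items()}}
    if igrs is not None:
        orient: dict[str, int] = {}
        for igr in igrs.igrs:
            if any(overlaps(igr.interval, piv) >= 1 for piv in peak_ivs):
                orient[igr.orientation] = orient.get(igr.orientation, 0) + 1
        out["igr_by_orientation"] = orient
    return out
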