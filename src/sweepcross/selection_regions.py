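"""Intersect CLR and omega tracks into selection regions and sweep targets.

The two scans vote independently: a CLR grid point is retained when its
Lambda reaches the genome-wide top-1% threshold AND its maximizing window
contains at least one omega grid point in the omega top 1%.  The maximizing
windows of retained points are merged (union, touching windows included) into
regions affected by selection.  Within each retained point's window, the
likely target of selection is the contiguous run of grid points with Lambda
above the CLR threshold that contains the focal point, converted to base
pairs with half-grid-spacing padding.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_core import GenomicInterval


def percentile_threshold(values, q: float = 0.99) -> float:
    """Empirical quantile (linear interpolation) over finite values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values")
    if v.size < 100:
        warnings.warn(f"quantile from only {v.size} values is unstable")
    return float(np.quantile(v, q))


def intersect_clr_omega(
    clr_track: pd.DataFrame,
    omega_track: pd.DataFrame,
    q: float = 0.99,
    per_chromosome: bool = False,
) -> pd.DataFrame:
    """Retained CLR points: top-q Lambda whose window holds a top-q omega.

    Both tracks must share the grid.  Thresholds are computed genome-wide by
    default (``per_chromosome`` switches to per-chromosome cuts).  Ties at a
    threshold count as above.
    """
    clr_chroms = list(pd.unique(clr_track["chrom"]))
    om_chroms = list(pd.unique(omega_track["chrom"]))
    if clr_chroms != om_chroms:
        raise ValueError("CLR and omega tracks cover different chromosomes")
    for chrom in clr_chroms:
        a = clr_track.loc[clr_track["chrom"] == chrom, "position"].to_numpy()
        b = omega_track.loc[omega_track["chrom"] == chrom, "position"].to_numpy()
        if a.size != b.size or not np.array_equal(a, b):
            raise ValueError(f"grid mismatch between tracks on {chrom}")

    def _one(clr_sub: pd.DataFrame, om_sub: pd.DataFrame) -> pd.DataFrame:
        clr_thr = percentile_threshold(clr_sub["clr"], q)
        om_thr = percentile_threshold(om_sub["omega"], q)
        keep = []
        for chrom, grp in clr_sub[clr_sub["clr"] >= clr_thr].groupby(
            "chrom", sort=False
        ):
            om_pos = om_sub.loc[
                (om_sub["chrom"] == chrom) & (om_sub["omega"] >= om_thr),
                "position",
            ].to_numpy()
            om_pos.sort()
            for _, row in grp.iterrows():
                lo = np.searchsorted(om_pos, row["win_start"], side="left")
                hi = np.searchsorted(om_pos, row["win_end"], side="right")
                if hi > lo:
                    keep.append(row)
        out = pd.DataFrame(keep, columns=clr_sub.columns)
        out.attrs["clr_threshold"] = clr_thr
        out.attrs["omega_threshold"] = om_thr
        return out

    if not per_chromosome:
        return _one(clr_track, omega_track)
    parts = []
    thresholds = {}
    for chrom in clr_chroms:
        part = _one(
            clr_track[clr_track["chrom"] == chrom],
            omega_track[omega_track["chrom"] == chrom],
        )
        thresholds[chrom] = (
            part.attrs["clr_threshold"],
            part.attrs["omega_threshold"],
        )
        parts.append(part)
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    out.attrs["thresholds"] = thresholds
    return out


def merge_regions(retained: pd.DataFrame) -> list[GenomicInterval]:
    """Union of the retained points' maximizing windows (touching merged)."""
    regions: list[GenomicInterval] = []
    if len(retained) == 0:
        return regions
    for chrom, grp in retained.groupby("chrom", sort=False):
        ivs = grp[["win_start", "win_end"]].to_numpy().tolist()
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:  # overlap or touching
                cur_e = max(cur_e, e)
            else:
                regions.append(GenomicInterval(str(chrom), int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        regions.append(GenomicInterval(str(chrom), int(cur_s), int(cur_e)))
    return regions


def extract_targets(
    retained: pd.DataFrame,
    clr_track: pd.DataFrame,
    threshold: float,
) -> list[GenomicInterval]:
    """Threshold-crossing target regions inside each retained point's window.

    For each retained point, the maximal contiguous run of grid points with
    Lambda >= threshold containing the focal position is converted to a bp
    interval with half-spacing padding, clipped to the window; overlapping
    targets are merged.
    """
    targets: list[tuple[str, int, int]] = []
    for chrom, grp in retained.groupby("chrom", sort=False):
        track = clr_track[clr_track["chrom"] == chrom]
        pos = track["position"].to_numpy()
        lam = track["clr"].to_numpy()
        spacing = int(np.min(np.diff(pos))) if pos.size > 1 else 1000
        above = lam >= threshold
        for _, row in grp.iterrows():
            focal = int(np.searchsorted(pos, row["position"]))
            if not above[focal]:
                raise AssertionError(
                    "retained focal point below the CLR threshold"
                )
            lo = focal
            while lo > 0 and above[lo - 1] and pos[lo - 1] >= row["win_start"]:
                lo -= 1
            hi = focal
            while (
                hi + 1 < pos.size
                and above[hi + 1]
                and pos[hi + 1] < row["win_end"]
            ):
                hi += 1
            start = max(int(pos[lo] - spacing / 2), int(row["win_start"]))
            end = min(int(pos[hi] + spacing / 2), int(row["win_end"]))
            if start < end:
                targets.append((str(chrom), start, end))

    # merge overlapping targets from different retained points
    merged: list[GenomicInterval] = []
    targets.sort()
    for chrom, s, e in targets:
        if merged and merged[-1].chrom == chrom and s <= merged[-1].end:
            last = merged.pop()
            merged.append(GenomicInterval(chrom, last.start, max(last.end, e)))
        else:
            merged.append(GenomicInterval(chrom, s, e))
    return merged


def selection_scan_summary(
    clr_track: pd.DataFrame,
    omega_track: pd.DataFrame,
    q: float = 0.99,
    per_chromosome: bool = False,
) -> dict:
    """Run the full intersect -> merge -> target pipeline; returns all pieces."""
    retained = intersect_clr_omega(clr_track, omega_track, q, per_chromosome)
    regions = merge_regions(retained)
    thr = retained.attrs.get("clr_threshold")
    if thr is None:
        thr = percentile_threshold(clr_track["clr"], q)
    targets = extract_targets(retained, clr_track, thr) if len(retained) else []
    return {
        "retained": retained,
        "regions": regions,
        "targets": targets,
        "clr_threshold": thr,
        "omega_threshold": retained.attrs.get("omega_threshold"),
    }
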