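"""Minimal read-depth copy-number caller.

Binned mean depth is normalized by the genome-wide median (copy ratio
1.0 at CN=2) and segmented greedily: consecutive bins join the running
segment while their ratio stays within ``change_threshold`` of its mean;
segments shorter than ``min_bins`` are absorbed into the neighbour with
the closer mean.  Integer copy number is ``round(2 * mean_ratio)``
(half-up).  No GC correction is applied — synthetic references are
GC-neutral; see the methods note for the implication on real data.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval

DEFAULT_CHANGE_THRESHOLD = 0.25
DEFAULT_MIN_BINS = 3


def normalize(profile: pd.DataFrame) -> pd.DataFrame:
    """Add a ``ratio`` column (depth / genome median depth)."""
    median = float(profile["mean_depth"].median())
    if median <= 0:
        raise ValueError("median depth is zero; cannot normalize")
    out = profile.copy()
    out["ratio"] = out["mean_depth"] / median
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def segment_cn(
    profile: pd.DataFrame,
    change_threshold: float = DEFAULT_CHANGE_THRESHOLD,
    min_bins: int = DEFAULT_MIN_BINS,
) -> list[tuple[GenomicInterval, int]]:
    """Greedy segmentation of normalized ratios into integer-CN segments.

    ``profile`` needs columns contig/bin_start/bin_end/ratio with sorted,
    non-overlapping bins.
    """
    if "ratio" not in profile.columns:
        profile = normalize(profile)
    results: list[tuple[GenomicInterval, int]] = []
    for contig, sub in profile.groupby("contig", sort=False):
        sub = sub.sort_values("bin_start")
        ratios = sub["ratio"].to_numpy()
        starts = sub["bin_start"].to_numpy()
        ends = sub["bin_end"].to_numpy()

        # greedy split on ratio jumps
        groups: list[list[int]] = [[0]]
        for i in range(1, len(ratios)):
            current = groups[-1]
            mean = ratios[current].mean() if isinstance(current, np.ndarray) else np.mean(
                [ratios[j] for j in current]
            )
            if abs(ratios[i] - mean) > change_threshold:
                groups.append([i])
            else:
                current.append(i)

        # absorb short segments into the neighbour with the closer mean
        changed = True
        while changed and len(groups) > 1:
            changed = False
            for gi, g in enumerate(groups):
                if len(g) >= min_bins:
                    continue
                mean = np.mean([ratios[j] for j in g])
                left = np.mean([ratios[j] for j in groups[gi - 1]]) if gi > 0 else None
                right = (
                    np.mean([ratios[j] for j in groups[gi + 1]])
                    if gi < len(groups) - 1
                    else None
                )
                if left is None and right is None:
                    continue
                if right is None or (
                    left is not None and abs(mean - left) <= abs(mean - right)
                ):
                    groups[gi - 1].extend(g)
                else:
                    groups[gi + 1][:0] = g
                del groups[gi]
                changed = True
                break

        # merge adjacent groups with equal called CN
        merged: list[tuple[int, int, int]] = []  # (first_bin, last_bin, cn)
        for g in groups:
            cn = _round_half_up(2 * float(np.mean([ratios[j] for j in g])))
            if merged and merged[-1][2] == cn:
                merged[-1] = (merged[-1][0], g[-1], cn)
            else:
                merged.append((g[0], g[-1], cn))
        for first, last, cn in merged:
            results.append(
                (GenomicInterval(contig, int(starts[first]), int(ends[last])), cn)
            )
    return results


def call_cn(
    profile: pd.DataFrame,
    change_threshold: float = DEFAULT_CHANGE_THRESHOLD,
    min_bins: int = DEFAULT_MIN_BINS,
) -> list[tuple[GenomicInterval, int]]:
    """Normalize then segment a raw depth profile."""
    return segment_cn(normalize(profile), change_threshold, min_bins)


def cn_table(segments: Sequence[tuple[GenomicInterval, int]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"contig": iv.contig, "start": iv.start, "end": iv.end, "cn": cn}
            for iv, cn in segments
        ]
    )


__all__ = [
    "DEFAULT_CHANGE_THRESHOLD",
    "DEFAULT_MIN_BINS",
    "normalize",
    "segment_cn",
    "call_cn",
    "cn_table",
]
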