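"""Binned feature-density profiles and region-panel comparison tables.

A feature is assigned to the bin containing its start coordinate, so counts
are conserved (a feature spanning a bin boundary is counted once). An
overlap-weighted mode distributes each feature across bins in proportion to
its overlap instead, for track visualisation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .seqio import Region


def profile_features(
    tracks: Mapping[str, Sequence[Region]],
    region: Region,
    bin: int = 10_000,
    weighted: bool = False,
) -> pd.DataFrame:
    """Per-bin counts and densities for each feature track within ``region``.

    Returns a long-format frame with columns ``bin_start``, ``bin_end``,
    ``feature_id``, ``count``, ``density_per_kb``; bins tile the region
    exactly and the last bin may be short. Features on other sequences or
    starting outside the region are ignored.
    """
    if bin < 1:
        raise ValueError("bin must be >= 1")
    edges = list(range(region.start, region.end, bin)) + [region.end]
    nbins = len(edges) - 1
    rows = []
    for fid in sorted(tracks):
        counts = [0.0] * nbins
        for f in tracks[fid]:
            if f.seq_id != region.seq_id:
                continue
            if weighted:
                for b in range(nbins):
                    ov = min(f.end, edges[b + 1]) - max(f.start, edges[b])
                    if ov > 0:
                        counts[b] += ov / f.length
            else:
                if region.start <= f.start < region.end:
                    counts[(f.start - region.start) // bin] += 1
        for b in range(nbins):
            width = edges[b + 1] - edges[b]
            rows.append(
                {
                    "bin_start": edges[b],
                    "bin_end": edges[b + 1],
                    "feature_id": fid,
                    "count": counts[b],
                    "density_per_kb": 1000.0 * counts[b] / width,
                }
            )
    return pd.DataFrame(rows)


def compare_regions(
    panels: Mapping[str, Region],
    tracks: Mapping[str, Sequence[Region]],
) -> pd.DataFrame:
    """Count/length/frequency table: one row per (panel, feature track).

    ``frequency_per_kb`` is exactly ``1000 * count / panel length``, the
    same identity used for quadruplex frequencies.
    """
    if not panels:
        raise ValueError("panels must be non-empty")
    rows = []
    for pname, preg in panels.items():
        for fid in sorted(tracks):
            count = sum(
                1
                for f in tracks[fid]
                if f.seq_id == preg.seq_id and preg.start <= f.start < preg.end
            )
            rows.append(
                {
                    "region_name": pname,
                    "feature_id": fid,
                    "count": count,
                    "length_bp": preg.length,
                    "frequency_per_kb": 1000.0 * count / preg.length,
                }
            )
    return pd.DataFrame(rows)
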