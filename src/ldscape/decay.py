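"""LD decay profiles: mean r^2 per inter-marker distance class.

The default distance classes are the chip-panel convention
[0,10), [10,20), [20,40), [40,60), [60,100), [100,200), [200,500),
[500,1000) kb — half-open, closed on the left.  A decay table also answers
the design question "how many evenly spaced markers does a genome scan
need": the spacing at which mean r^2 first drops below a useful-LD threshold.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: (lower, upper) kb edges of the standard distance classes.
DEFAULT_CLASSES_KB: tuple[tuple[float, float], ...] = (
    (0, 10), (10, 20), (20, 40), (40, 60), (60, 100), (100, 200), (200, 500), (500, 1000),
)

DECAY_COLUMNS = [
    "population", "class_lower_kb", "class_upper_kb",
    "n_pairs", "mean_r2", "mean_dist_bp", "maf_threshold",
]


def bin_decay(
    pairs: pd.DataFrame,
    classes_kb: tuple[tuple[float, float], ...] = DEFAULT_CLASSES_KB,
    maf_threshold: float = 0.05,
    population: str = "",
) -> pd.DataFrame:
    """Mean r^2 per distance class over pairs where both SNPs pass the MAF bound.

    ``pairs`` is a windowed-scan table (needs distance_bp, r2, maf_i, maf_j).
    Class membership is half-open [lower, upper) in kb; a pair at exactly a
    class boundary belongs to the upper class.  Empty classes keep count 0 and
    NaN mean.  The representative distance recorded per class is the mean of
    member pair distances.
    """
    keep = (
        (pairs["maf_i"] >= maf_threshold)
        & (pairs["maf_j"] >= maf_threshold)
        & np.isfinite(pairs["r2"])
    )
    sub = pairs.loc[keep]
    dist_kb = sub["distance_bp"].to_numpy() / 1000.0
    rows = []
    for lower, upper in classes_kb:
        in_class = (dist_kb >= lower) & (dist_kb < upper)
        r2 = sub["r2"].to_numpy()[in_class]
        d = sub["distance_bp"].to_numpy()[in_class]
        rows.append(
            {
                "population": population,
                "class_lower_kb": lower,
                "class_upper_kb": upper,
                "n_pairs": int(in_class.sum()),
                "mean_r2": float(r2.mean()) if r2.size else float("nan"),
                "mean_dist_bp": float(d.mean()) if d.size else float("nan"),
                "maf_threshold": maf_threshold,
            }
        )
    return pd.DataFrame(rows, columns=DECAY_COLUMNS)


@dataclass(frozen=True)
class MarkerDensity:
    """Marker spacing/count needed for a genome scan at a given LD threshold."""

    spacing_bp: float
    marker_count: int
    below_panel_resolution: bool = False


def required_marker_density(
    table: pd.DataFrame, genome_length_bp: float, r2_threshold: float = 0.20
) -> MarkerDensity:
    """Marker spacing supported by a decay table at a useful-LD threshold.

    Classes are scanned in distance order; the spacing is the upper edge of
    the most distant class whose mean r^2 still meets the threshold, stopping
    at the first failure.  If even the first class fails, the spacing falls
    back to the first class's upper edge and the result is flagged as denser
    than the panel resolves.  marker_count = ceil(genome_length / spacing).
    """
    means = table["mean_r2"].to_numpy()
    uppers_bp = table["class_upper_kb"].to_numpy() * 1000.0
    defined = np.isfinite(means)
    if not defined.any():
        raise ValueError("decay table has no class with a defined mean")
    spacing = None
    for mean, upper, ok in zip(means, uppers_bp, defined):
        if not ok or mean < r2_threshold:
            break
        spacing = upper
    if spacing is None:
        return MarkerDensity(
            spacing_bp=float(uppers_bp[0]),
            marker_count=math.ceil(genome_length_bp / uppers_bp[0]),
            below_panel_resolution=True,
        )
    return MarkerDensity(
        spacing_bp=float(spacing),
        marker_count=math.ceil(genome_length_bp / spacing),
    )
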