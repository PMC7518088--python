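"""Alpha diversity (richness, Shannon H) and Bray-Curtis dissimilarity.

Shannon H is reported in nats (-sum p ln p over non-zero proportions),
so it is invariant to whether a row holds counts or percent abundances.
Bray-Curtis, BC(u, v) = sum|u_i - v_i| / sum(u_i + v_i), is computed on
percent-normalised rows; a counts-unit table is normalised internally
with a warning, since equal row sums are what make Bray-Curtis a pure
composition distance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import Metadata, OtuTable

__all__ = [
    "richness", "shannon", "bray_curtis", "distance_matrix",
    "alpha_diversity", "volume_group_summary",
]


def richness(sample_row) -> int:
    """Number of OTUs with non-zero abundance in the row."""
    row = np.asarray(sample_row, dtype=float)
    if (row < 0).any():
        raise ValueError("abundances must be non-negative")
    return int((row > 0).sum())


def shannon(sample_row) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) over non-zero
    proportions; 0 for a single-taxon sample."""
    row = np.asarray(sample_row, dtype=float)
    if (row < 0).any():
        raise ValueError("abundances must be non-negative")
    total = row.sum()
    if total == 0:
        raise ValueError("cannot compute Shannon diversity of an all-zero row")
    p = row[row > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity sum|u - v| / sum(u + v), in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("rows must share the same OTU ordering and length")
    denom = float((u + v).sum())
    if denom == 0:
        raise ValueError("both rows are all-zero; Bray-Curtis is undefined")
    return float(np.abs(u - v).sum() / denom)


def distance_matrix(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances between all samples of a table."""
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    values = table.values()
    zero = values.sum(axis=1) == 0
    if zero.any():
        bad = [str(table.sample_ids[i]) for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero sample row(s): {', '.join(bad)}")
    if table.unit == "counts":
        warnings.warn("counts-unit table: normalising to percent abundance "
                      "before Bray-Curtis", stacklevel=2)
        values = 100.0 * values / values.sum(axis=1, keepdims=True)
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in table.sample_ids])


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample richness and Shannon H as a DataFrame."""
    rows = {sid: {"richness": richness(table.sample_row(sid)),
                  "shannon": shannon(table.sample_row(sid))}
            for sid in table.sample_ids}
    return pd.DataFrame.from_dict(rows, orient="index")


def volume_group_summary(values: pd.Series, metadata: Metadata) -> pd.DataFrame:
    """Boxplot-style summary of a per-sample statistic grouped by filtered
    volume (the 0 mL bin holds the blanks): median, quartiles, and
    Tukey whiskers (most extreme points within 1.5*IQR of the box)."""
    rows = []
    vols = pd.Series({sid: metadata.volume(sid) for sid in values.index
                      if sid in metadata})
    for vol in sorted(vols.unique()):
        group = values[vols.index[vols == vol]].astype(float)
        q1, med, q3 = group.quantile([0.25, 0.5, 0.75])
        iqr = q3 - q1
        inliers = group[(group >= q1 - 1.5 * iqr) & (group <= q3 + 1.5 * iqr)]
        rows.append({"volume_ml": int(vol), "n": len(group), "median": med,
                     "q1": q1, "q3": q3,
                     "whisker_low": inliers.min(), "whisker_high": inliers.max()})
    return pd.DataFrame(rows).set_index("volume_ml")
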