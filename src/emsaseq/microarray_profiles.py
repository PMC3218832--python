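"""Protein-binding-microarray probe profiles and cross-dimer comparison.

Each probe carries one variable 11-mer in one of four flanking
configurations.  Raw intensities are log2-transformed and z-standardized
within each array (replicate); a probe's z is the median across
replicates, and a dimer's binding profile is the element-wise median of
its four flank-specific z vectors.  Profiles of different dimers are
compared by Pearson correlation and clustered by complete-linkage on
Euclidean distance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def probe_zscores(intensities: pd.DataFrame) -> pd.Series:
    """Per-probe z-scores from an intensity table (probes x replicates).

    Intensities are log2-transformed and mean/SD standardized within
    each replicate column; the per-probe median across replicate z
    values is returned.  A zero-variance array yields all-zero z (a
    degenerate but well-defined convention).  Non-positive intensities
    are an error naming the offending probe.
    """
    values = intensities.to_numpy(dtype=float)
    if (values <= 0).any():
        bad = intensities.index[np.where(values <= 0)[0][0]]
        raise ValueError(f"non-positive intensity at probe {bad!r}")
    logv = np.log2(values)
    sd = logv.std(axis=0, ddof=0)
    mean = logv.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (logv - mean) / sd
    z = np.where(sd > 0, z, 0.0)
    return pd.Series(np.median(z, axis=1), index=intensities.index, name="z")


def dimer_profile(flank_z: pd.DataFrame) -> pd.Series:
    """Element-wise median across flank-specific z vectors (probes x flanks).

    Probes must share one ordering across flank columns; a missing flank
    column is tolerated with a warning and the median is taken over the
    remaining ones.
    """
    if flank_z.shape[1] < 4:
        warnings.warn(
            f"only {flank_z.shape[1]} flank datasets present; "
            "profile is the median of those available",
            stacklevel=2,
        )
    return flank_z.median(axis=1).rename("profile_z")


def profile_similarity(profiles: pd.DataFrame):
    """Pearson similarity and complete-linkage dendrogram of dimer profiles.

    ``profiles`` has one row per dimer, one column per probe.  Returns
    ``(corr, linkage_matrix)``: a symmetric unit-diagonal correlation
    DataFrame (NaN where a profile is constant) and the scipy linkage
    matrix from complete-linkage clustering of Euclidean distances.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least two dimer profiles")
    values = profiles.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(values)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=profiles.index, columns=profiles.index)
    link = hierarchy.linkage(pdist(values, metric="euclidean"), method="complete")
    return corr_df, link


def load_intensity_table(path) -> pd.DataFrame:
    """Read a probe intensity TSV: probe_id, flank_id, then replicate columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"probe_id", "flank_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"intensity table must contain columns {sorted(required)}")
    return df


def dimer_profile_from_table(table: pd.DataFrame) -> pd.Series:
    """Full path from a long intensity table to one dimer profile.

    The table holds one row per (probe, flank) with replicate intensity
    columns; z-scores are computed within each flank-specific dataset
    (treating each replicate column as one array), then the per-probe
    median across flanks is taken.
    """
    replicate_cols = [c for c in table.columns if c not in ("probe_id", "flank_id")]
    flank_z = {}
    for flank, sub in table.groupby("flank_id"):
        sub = sub.set_index("probe_id")
        flank_z[flank] = probe_zscores(sub[replicate_cols])
    return dimer_profile(pd.DataFrame(flank_z))
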