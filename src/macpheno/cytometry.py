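"""Surface-marker MFI profiling across macrophage phenotypes.

Input boundary is a tidy per-sample MFI table (gating happens upstream, on
the instrument); this module runs every pairwise phenotype contrast per
marker through the shared statistics engine and derives qualitative
"elevated in" calls: a marker is elevated in phenotype P versus Q when P's
group mean exceeds Q's and the two-tailed comparison is significant at the
chosen alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .stats import compare_groups, group_stats

__all__ = ["MarkerProfile", "marker_profile",
           "KNOWN_MARKERS", "KNOWN_PHENOTYPES"]

KNOWN_MARKERS = ("CD86", "CD64", "CD206", "CD11b")
KNOWN_PHENOTYPES = ("THP-1", "M0", "M1", "M2")
REQUIRED_COLUMNS = ("sample", "marker", "phenotype", "replicate", "mfi")


@dataclass(frozen=True)
class MarkerProfile:
    """Marker x phenotype summary plus pairwise contrasts and elevation calls.

    ``comparisons`` columns: marker, phenotype_a, phenotype_b, mean_diff
    (b - a), t, df, p, r_squared, f, f_p, call — where ``call`` names the
    elevated phenotype or is ``"ns"``. ``elevated`` maps each marker to the
    phenotypes called elevated in at least one contrast.
    """

    summary: pd.DataFrame       # marker, phenotype, n, mean, sd
    comparisons: pd.DataFrame
    elevated: dict[str, set[str]]
    alpha: float


def marker_profile(records: pd.DataFrame, alpha: float = 0.05,
                   variance_model: str = "pooled") -> MarkerProfile:
    """All pairwise phenotype comparisons per marker, with elevation calls.

    Unknown marker or phenotype labels raise; phenotype groups with fewer
    than 2 replicates for a marker are excluded from that marker's
    comparisons with a warning.
    """
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"MFI table missing columns: {sorted(missing)}")
    bad_markers = set(records["marker"]) - set(KNOWN_MARKERS)
    if bad_markers:
        raise ValueError(f"unknown marker label(s): {sorted(bad_markers)}")
    bad_phen = set(records["phenotype"]) - set(KNOWN_PHENOTYPES)
    if bad_phen:
        raise ValueError(f"unknown phenotype label(s): {sorted(bad_phen)}")
    if (records["mfi"].to_numpy(float) < 0).any():
        raise ValueError("MFI values must be >= 0")

    summary = (records.groupby(["marker", "phenotype"], as_index=False)
               .agg(n=("mfi", "size"), mean=("mfi", "mean"), sd=("mfi", "std")))

    rows = []
    elevated: dict[str, set[str]] = {}
    for marker, grp in records.groupby("marker", sort=True):
        groups = {}
        for phen, g in grp.groupby("phenotype"):
            if len(g) < 2:
                warnings.warn(f"{marker}/{phen}: fewer than 2 replicates; "
                              "excluded from comparisons", stacklevel=2)
                continue
            groups[phen] = group_stats(g["mfi"].to_numpy(float), label=phen)
        elevated[marker] = set()
        order = [p for p in KNOWN_PHENOTYPES if p in groups]
        for pa, pb in combinations(order, 2):
            res = compare_groups(groups[pa], groups[pb],
                                 variance_model=variance_model)
            call = "ns"
            if res.p_two_tailed < alpha:
                call = pb if res.mean_diff > 0 else pa
                elevated[marker].add(call)
            rows.append({"marker": marker, "phenotype_a": pa, "phenotype_b": pb,
                         "mean_diff": res.mean_diff, "t": abs(res.t_stat),
                         "df": res.df, "p": res.p_two_tailed,
                         "r_squared": res.r_squared, "f": res.f_stat,
                         "f_p": res.f_p, "call": call})
    comparisons = pd.DataFrame(rows, columns=[
        "marker", "phenotype_a", "phenotype_b", "mean_diff", "t", "df", "p",
        "r_squared", "f", "f_p", "call"])
    return MarkerProfile(summary=summary, comparisons=comparisons,
                         elevated=elevated, alpha=alpha)
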