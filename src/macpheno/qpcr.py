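"""Relative expression quantification by the 2^-ddCq method.

ddCq workflow: per sample, dCq = Cq(target) - Cq(reference gene); ddCq =
dCq - mean dCq of the calibrator group (resting M0 macrophages by default,
18S rRNA as reference); RQ = 2**(-ddCq). Primer efficiency is estimated from
a standard-curve dilution series (Cq vs log10 input, least squares) and
reported for QC only — fold changes are computed with the ideal base-2
amplification, uncorrected, as is standard once efficiencies validate close
to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["FoldChangeResult", "StandardCurve", "fold_change",
           "standard_curve_efficiency", "summarize_fold_changes"]

REQUIRED_CQ_COLUMNS = ("sample", "gene", "phenotype", "replicate", "cq")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution series: Cq = intercept + slope * log10(input)."""

    gene: str
    log10_input: np.ndarray
    cq_values: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    @property
    def valid(self) -> bool:
        return self.slope < 0

    @property
    def efficiency_pct(self) -> float:
        """Amplification efficiency in percent: 100% = perfect doubling."""
        if not self.valid:
            raise ValueError(f"curve for {self.gene!r} has non-negative slope; "
                             "efficiency undefined")
        return (10.0 ** (-1.0 / self.slope) - 1.0) * 100.0


@dataclass(frozen=True)
class FoldChangeResult:
    """Per-sample fold changes plus per-group summaries."""

    per_sample: pd.DataFrame  # sample, gene, phenotype, delta_cq, delta_delta_cq, rq
    per_group: pd.DataFrame   # gene, phenotype, mean_rq, sd_rq, n
    reference_gene: str
    calibrator_phenotype: str


def _validate_cq_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_CQ_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    cq = records["cq"].to_numpy(float)
    if not np.all(np.isfinite(cq)) or np.any(cq <= 0):
        raise ValueError("all Cq values must be finite and positive")
    return records


def fold_change(records: pd.DataFrame, reference_gene: str = "18S",
                calibrator_phenotype: str = "M0",
                average_replicates: bool = False) -> FoldChangeResult:
    """2^-ddCq relative quantification of every non-reference gene.

    Parameters
    ----------
    records
        Tidy Cq table with columns ``sample, gene, phenotype, replicate, cq``.
        Every (sample, replicate) must carry a reference-gene row.
    reference_gene, calibrator_phenotype
        Normalization gene and baseline group. The calibrator group's mean
        dCq defines ddCq = 0, so its mean ddCq is exactly 0 and its geometric
        mean RQ is exactly 1.
    average_replicates
        When True, technical replicates are averaged per (sample, gene)
        before dCq; by default each listed row is treated as a sample.
    """
    records = _validate_cq_table(records)
    keys = ["sample"] if average_replicates else ["sample", "replicate"]
    work = records.copy()
    if average_replicates:
        work = (work.groupby(["sample", "gene", "phenotype"], as_index=False)
                    .agg(cq=("cq", "mean")))
        work["replicate"] = 0

    ref = work[work["gene"] == reference_gene]
    if ref.empty:
        raise ValueError(f"no rows for reference gene {reference_gene!r}")
    ref = ref.set_index(keys)["cq"]
    if ref.index.has_duplicates:
        ref = ref.groupby(level=list(range(len(keys)))).mean()

    targets = work[work["gene"] != reference_gene].copy()
    idx = pd.MultiIndex.from_frame(targets[keys]) if len(keys) > 1 else \
        pd.Index(targets[keys[0]])
    ref_cq = ref.reindex(idx)
    if ref_cq.isna().any():
        bad = targets.loc[np.asarray(ref_cq.isna()), "sample"].unique()
        raise ValueError(f"missing reference-gene Cq for sample(s): {list(bad)}")
    targets["delta_cq"] = targets["cq"].to_numpy() - ref_cq.to_numpy()

    out = []
    for gene, grp in targets.groupby("gene", sort=True):
        calib = grp[grp["phenotype"] == calibrator_phenotype]
        if calib.empty:
            raise ValueError(f"gene {gene!r}: no rows in calibrator group "
                             f"{calibrator_phenotype!r}")
        calib_mean = calib["delta_cq"].mean()
        g = grp.copy()
        g["delta_delta_cq"] = g["delta_cq"] - calib_mean
        g["rq"] = 2.0 ** (-g["delta_delta_cq"])
        out.append(g)
    per_sample = pd.concat(out, ignore_index=True)[
        ["sample", "gene", "phenotype", "replicate", "delta_cq",
         "delta_delta_cq", "rq"]]
    per_group = (per_sample.groupby(["gene", "phenotype"], as_index=False)
                 .agg(mean_rq=("rq", "mean"), sd_rq=("rq", "std"), n=("rq", "size")))
    return FoldChangeResult(per_sample=per_sample, per_group=per_group,
                            reference_gene=reference_gene,
                            calibrator_phenotype=calibrator_phenotype)


def standard_curve_efficiency(log10_input, cq_values, gene: str = "") -> StandardCurve:
    """Least-squares standard curve and primer efficiency.

    Needs >= 3 dilution points with distinct log10 input amounts. A
    non-negative slope yields a curve flagged invalid (``valid`` False);
    accessing ``efficiency_pct`` on it raises.
    """
    x = np.asarray(log10_input, dtype=float)
    y = np.asarray(cq_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("log10_input and cq_values must be matching 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 dilution points")
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct dilution levels")
    fit = sps.linregress(x, y)
    return StandardCurve(gene=gene, log10_input=x, cq_values=y,
                         slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue**2))


def summarize_fold_changes(result: FoldChangeResult) -> pd.DataFrame:
    """Per-group output table ``gene, phenotype, mean_rq, sd_rq, n``."""
    return result.per_group.copy()
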