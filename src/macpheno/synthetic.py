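"""Seeded synthetic data emulating the three measurement modalities.

The study this package analyzes deposited no raw data, so every downstream
stage is exercised on generated inputs with known ground truth:

* two-channel membrane images — ring-shaped cells whose membrane pixels emit
  a Poisson photon count split between the ordered and disordered emission
  channels according to a ground-truth GP;
* LUV calibration measurements — per-vesicle intensity pairs whose raw GP is
  centered on a chosen ``gp_mes``;
* cytokine RQ tables (IL-1B / IL-6 / IL-10 across M0 / M1 / M2) — normal
  draws whose group means reproduce the published pairwise mean differences
  and whose group SDs are solved from the published SEMs of those
  differences;
* surface-marker MFI tables (CD86 / CD64 / CD206 / CD11b) — same normal
  model at n = 3 per group.

Group means are under-determined by published pairwise differences, so each
gene/marker needs one free baseline; the defaults pin these baselines
(documented per table below) and every other mean follows by exact
additivity of the published differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gp import ChannelPair

__all__ = [
    "SyntheticImageSpec",
    "SyntheticCell",
    "SyntheticField",
    "SyntheticExpressionSpec",
    "generate_membrane_images",
    "generate_calibration_set",
    "generate_expression_table",
    "generate_mfi_table",
    "solve_group_sds",
    "DEFAULT_GP_TRUE",
    "DEFAULT_EXPRESSION_MEANS",
    "DEFAULT_EXPRESSION_SEMS",
    "DEFAULT_MFI_MEANS",
    "DEFAULT_MFI_SEMS",
    "default_expression_spec",
]

PHENOTYPES = ("M0", "M1", "M2")

# Ground-truth internal GP per phenotype: the published group means on the
# x100 reporting scale (56.98 / 63.56 / 69.99), so ordering is M2 > M1 > M0.
DEFAULT_GP_TRUE: dict[str, float] = {"M0": 0.5698, "M1": 0.6356, "M2": 0.6999}

# Published pairwise mean differences fix the mean structure up to one free
# baseline per gene. IL-1B baseline: M0 = 1 (resting-state fold change);
# IL-10 baseline: M0 = 100 RQ units, chosen so all group means stay several
# group-SDs above zero (M1 sits 37.69 units below M0 and the published SEMs
# imply large group SDs).
DEFAULT_EXPRESSION_MEANS: dict[str, dict[str, float]] = {
    "IL1B": {"M0": 1.0, "M1": 1.0 + 370.9, "M2": 1.0 + 199.6},
    "IL6": {"M0": 1.0, "M1": 1.0 + 11.71, "M2": 1.0 + 2.36},
    "IL10": {"M0": 100.0, "M1": 100.0 - 37.69, "M2": 100.0 + 30.28},
}

# Published SEMs of the pairwise differences, keyed (low, high) phenotype.
DEFAULT_EXPRESSION_SEMS: dict[str, dict[tuple[str, str], float]] = {
    "IL1B": {("M0", "M1"): 45.53, ("M0", "M2"): 90.23, ("M1", "M2"): 101.0},
    "IL6": {("M0", "M1"): 2.14, ("M0", "M2"): 0.92, ("M1", "M2"): 2.25},
    "IL10": {("M0", "M1"): 6.74, ("M0", "M2"): 19.91, ("M1", "M2"): 19.43},
}

# Marker MFI means. Baselines: CD86 M0 = 50, CD64 M0 = 30, CD206 M0 = 10
# arbitrary detector units; CD11b THP-1 = 6.33 and M0 = 431 are published
# group means, with M1/M2 held at the M0 level (differentiation, not
# polarization, drives CD11b). Other means follow the published differences.
DEFAULT_MFI_MEANS: dict[str, dict[str, float]] = {
    "CD86": {"M0": 50.0, "M1": 50.0 + 214.3, "M2": 50.0 + 212.3},
    "CD64": {"M0": 30.0, "M1": 30.0 + 286.7, "M2": 30.0 + 0.33},
    "CD206": {"M0": 10.0, "M1": 10.0 - 1.67, "M2": 10.0 + 8.67},
    "CD11b": {"THP-1": 6.33, "M0": 431.0, "M1": 431.0, "M2": 431.0},
}

DEFAULT_MFI_SEMS: dict[str, dict[tuple[str, str], float]] = {
    "CD86": {("M0", "M1"): 26.72, ("M0", "M2"): 19.84, ("M1", "M2"): 31.00},
    "CD64": {("M0", "M1"): 22.60, ("M0", "M2"): 9.63, ("M1", "M2"): 23.42},
    "CD206": {("M0", "M1"): 1.05, ("M0", "M2"): 1.49, ("M1", "M2"): 1.33},
}
# CD11b: only the THP-1 vs M0 SEM (20.84) is published; one equation, two
# unknown SDs. The THP-1 SD is pinned at 2.0 (mean 6.33 constrains it) and
# the macrophage-group SD absorbs the rest.
CD11B_SEM_THP1_M0 = 20.84
CD11B_SD_THP1 = 2.0

MFI_N_REPLICATES = 3  # df = 4 in the published marker comparisons => n = 3
EXPRESSION_N_REPLICATES = 9  # df = 16 in the cytokine comparisons => n = 9


def solve_group_sds(sem_ab: float, sem_ac: float, sem_bc: float,
                    n: int) -> tuple[float, float, float]:
    """Solve three per-group SDs from the SEMs of the three pairwise differences.

    For equal group sizes n, the SEM of a two-group mean difference satisfies
    sem_xy**2 = (var_x + var_y) / n under both the pooled and Welch models,
    giving a linear system in the three group variances. Raises if the SEMs
    are mutually inconsistent (a variance would be non-positive).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    v_ab, v_ac, v_bc = (n * s**2 for s in (sem_ab, sem_ac, sem_bc))
    va = (v_ab + v_ac - v_bc) / 2.0
    vb = v_ab - va
    vc = v_ac - va
    if min(va, vb, vc) <= 0:
        raise ValueError("inconsistent SEM triple: implied variance <= 0")
    return math.sqrt(va), math.sqrt(vb), math.sqrt(vc)


# ---------------------------------------------------------------------------
# membrane images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticImageSpec:
    """Conditions for one synthetic field of ring-shaped membrane cells.

    ``photon_budget`` is the expected photon count per membrane pixel summed
    over both emission channels; the ordered channel receives the fraction
    (1 + gp_true) / 2 of it. ``background_rate`` is the expected count per
    non-membrane pixel, split evenly between channels. With ``noise`` off the
    expected counts are emitted exactly (no Poisson draw).
    """

    image_size: tuple[int, int] = (160, 160)
    n_cells: int = 20
    ring_outer_radius_px: int = 10
    ring_thickness_px: int = 3
    gp_true: float = 0.5
    photon_budget: float = 2000.0
    background_rate: float = 20.0
    seed: int = 0
    noise: bool = True

    def __post_init__(self) -> None:
        if not (-1 < self.gp_true < 1):
            raise ValueError(f"gp_true must be strictly inside (-1, 1), got {self.gp_true}")
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if not (1 <= self.ring_thickness_px < self.ring_outer_radius_px):
            raise ValueError("need 1 <= ring_thickness_px < ring_outer_radius_px")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")


@dataclass(frozen=True)
class SyntheticCell:
    cell_id: str
    center: tuple[int, int]
    mask: np.ndarray  # exact ring pixels, boolean


@dataclass(frozen=True)
class SyntheticField:
    """One generated image: channels plus per-cell ground truth."""

    phenotype: str
    channels: ChannelPair
    cells: tuple[SyntheticCell, ...]
    gp_true: float

    @property
    def membrane_mask(self) -> np.ndarray:
        out = np.zeros(self.channels.shape, dtype=bool)
        for c in self.cells:
            out |= c.mask
        return out

    @property
    def label_mask(self) -> np.ndarray:
        """Integer-labeled ground-truth mask (0 = background, k = cell k)."""
        out = np.zeros(self.channels.shape, dtype=np.uint8)
        for k, c in enumerate(self.cells, start=1):
            out[c.mask] = k
        return out


def _place_centers(spec: SyntheticImageSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Jittered-grid, overlap-free cell centers (deterministic under seed)."""
    h, w = spec.image_size
    r = spec.ring_outer_radius_px
    pitch = 2 * r + 4  # >= 4 px clearance between neighboring rings
    rows = (h - 2) // pitch
    cols = (w - 2) // pitch
    if rows * cols < spec.n_cells:
        raise ValueError(
            f"cannot place {spec.n_cells} rings of radius {r} in a "
            f"{h}x{w} image ({rows * cols} grid slots available)")
    slots = [(i, j) for i in range(rows) for j in range(cols)]
    order = rng.permutation(len(slots))[: spec.n_cells]
    jitter_max = (pitch - 2 * r) // 2 - 1  # keeps rings disjoint and in-bounds
    centers = []
    for idx in order:
        i, j = slots[idx]
        cy = 1 + i * pitch + pitch // 2
        cx = 1 + j * pitch + pitch // 2
        if jitter_max > 0:
            cy += int(rng.integers(-jitter_max, jitter_max + 1))
            cx += int(rng.integers(-jitter_max, jitter_max + 1))
        centers.append((cy, cx))
    return centers


def _ring_mask(shape: tuple[int, int], center: tuple[int, int],
               outer: int, thickness: int) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    return (d2 <= outer**2) & (d2 > (outer - thickness) ** 2)


def generate_membrane_images(
    spec: SyntheticImageSpec,
    phenotype: str = "unknown",
) -> SyntheticField:
    """Generate one field of ring cells with known GP.

    Membrane pixels emit expected counts ``f * B`` (ordered) and
    ``(1 - f) * B`` (disordered) with ``f = (1 + gp_true) / 2``; background
    pixels emit ``background_rate / 2`` in each channel. Counts are Poisson
    unless ``spec.noise`` is False.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(spec, rng)
    shape = spec.image_size
    cells = tuple(
        SyntheticCell(cell_id=f"{phenotype}_c{k:02d}", center=c,
                      mask=_ring_mask(shape, c, spec.ring_outer_radius_px,
                                      spec.ring_thickness_px))
        for k, c in enumerate(centers)
    )
    membrane = np.zeros(shape, dtype=bool)
    for c in cells:
        membrane |= c.mask

    f = (1.0 + spec.gp_true) / 2.0
    expected_o = np.where(membrane, f * spec.photon_budget, spec.background_rate / 2.0)
    expected_d = np.where(membrane, (1.0 - f) * spec.photon_budget, spec.background_rate / 2.0)
    if spec.noise:
        io = rng.poisson(expected_o).astype(float)
        id_ = rng.poisson(expected_d).astype(float)
    else:
        io, id_ = expected_o, expected_d
    return SyntheticField(phenotype=phenotype, channels=ChannelPair(io, id_),
                          cells=cells, gp_true=spec.gp_true)


def generate_phenotype_fields(
    gp_true: Mapping[str, float] = DEFAULT_GP_TRUE,
    n_cells: int = 20,
    photon_budget: float = 2000.0,
    seed: int = 0,
    **kwargs,
) -> dict[str, SyntheticField]:
    """One field per phenotype, with per-phenotype ground-truth GP and
    independent sub-seeds derived from ``seed``."""
    fields = {}
    for k, (phen, gp) in enumerate(sorted(gp_true.items())):
        spec = SyntheticImageSpec(n_cells=n_cells, gp_true=gp,
                                  photon_budget=photon_budget,
                                  seed=(seed * 31 + k) % (2**31), **kwargs)
        fields[phen] = generate_membrane_images(spec, phenotype=phen)
    return fields


# ---------------------------------------------------------------------------
# LUV calibration measurements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationSet:
    """Per-vesicle (ordered, disordered) intensity pairs plus the reference GP."""

    gp_ref: float
    gp_mes: float
    pairs: np.ndarray  # shape (n, 2)


def generate_calibration_set(gp_ref: float, gp_mes: float, n_vesicles: int = 50,
                             noise_sd: float = 0.02, seed: int = 0,
                             total_intensity: float = 1000.0) -> CalibrationSet:
    """Synthetic LUV reference measurements.

    Each vesicle's raw GP (G = 1) is ``gp_mes`` plus Gaussian noise of SD
    ``noise_sd`` (clipped to the open interval (-1, 1) so intensities stay
    positive); intensities are ``total_intensity * (1 +/- gp) / 2``.
    ``gp_ref`` is carried through as the literature value to be recovered by
    calibration.
    """
    if not (-1 < gp_ref < 1 and -1 < gp_mes < 1):
        raise ValueError("gp_ref and gp_mes must be in (-1, 1)")
    if n_vesicles < 1:
        raise ValueError("need at least one vesicle")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    gp = gp_mes + noise_sd * rng.standard_normal(n_vesicles)
    gp = np.clip(gp, -0.999, 0.999)
    ordered = total_intensity * (1.0 + gp) / 2.0
    disordered = total_intensity * (1.0 - gp) / 2.0
    return CalibrationSet(gp_ref=gp_ref, gp_mes=gp_mes,
                          pairs=np.column_stack([ordered, disordered]))


# ---------------------------------------------------------------------------
# expression (RQ) tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Normal model for per-replicate RQ values, gene x phenotype.

    ``group_mean[gene][phenotype]`` / ``group_sd[gene][phenotype]`` give the
    normal parameters; the defaults reproduce the published pairwise mean
    differences exactly (additively consistent) with group SDs solved from
    the published difference SEMs at n = 9.
    """

    genes: tuple[str, ...]
    phenotypes: tuple[str, ...]
    group_mean: Mapping[str, Mapping[str, float]]
    group_sd: Mapping[str, Mapping[str, float]]
    n_replicates: int = EXPRESSION_N_REPLICATES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need n_replicates >= 2")
        for g in self.genes:
            for p in self.phenotypes:
                if g not in self.group_mean or p not in self.group_mean[g]:
                    raise ValueError(f"missing group mean for {g}/{p}")
                if g not in self.group_sd or p not in self.group_sd[g]:
                    raise ValueError(f"missing group sd for {g}/{p}")
                if self.group_sd[g][p] < 0:
                    raise ValueError(f"negative sd for {g}/{p}")


def default_expression_spec(seed: int = 0,
                            n_replicates: int = EXPRESSION_N_REPLICATES
                            ) -> SyntheticExpressionSpec:
    """Expression spec at the published mean-difference / SEM structure."""
    sds: dict[str, dict[str, float]] = {}
    for gene, sems in DEFAULT_EXPRESSION_SEMS.items():
        s0, s1, s2 = solve_group_sds(sems[("M0", "M1")], sems[("M0", "M2")],
                                     sems[("M1", "M2")], n_replicates)
        sds[gene] = {"M0": s0, "M1": s1, "M2": s2}
    return SyntheticExpressionSpec(
        genes=tuple(DEFAULT_EXPRESSION_MEANS), phenotypes=PHENOTYPES,
        group_mean=DEFAULT_EXPRESSION_MEANS, group_sd=sds,
        n_replicates=n_replicates, seed=seed)


def generate_expression_table(spec: SyntheticExpressionSpec) -> pd.DataFrame:
    """Tidy table ``sample, gene, phenotype, replicate, value`` of RQ draws.

    Values are plain normal draws; with the study's published SEMs the
    implied group SDs are large relative to some means, so occasional
    negative draws can occur — they are left as-is (the downstream
    comparisons are location/scale statistics on an affine RQ scale).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for gene in spec.genes:
        for phen in spec.phenotypes:
            vals = rng.normal(spec.group_mean[gene][phen],
                              spec.group_sd[gene][phen], spec.n_replicates)
            for r, v in enumerate(vals):
                rows.append({"sample": f"{phen}_{r:02d}", "gene": gene,
                             "phenotype": phen, "replicate": r, "value": float(v)})
    return pd.DataFrame(rows, columns=["sample", "gene", "phenotype",
                                       "replicate", "value"])


# ---------------------------------------------------------------------------
# MFI tables
# ---------------------------------------------------------------------------

def generate_mfi_table(seed: int = 0,
                       n_replicates: int = MFI_N_REPLICATES) -> pd.DataFrame:
    """Tidy table ``sample, marker, phenotype, replicate, mfi`` at n = 3.

    Group means/SDs reproduce the published marker contrasts: CD64 high only
    in M1, CD206 high in M2, CD86 high in both M1 and M2 versus M0, CD11b
    elevated in all macrophage groups versus the THP-1 monocyte baseline.
    Draws are clipped at 0 (MFI is nonnegative); at the default parameters
    the clipping probability is negligible (< 2% in the worst group).
    """
    sds: dict[str, dict[str, float]] = {}
    for marker, sems in DEFAULT_MFI_SEMS.items():
        s0, s1, s2 = solve_group_sds(sems[("M0", "M1")], sems[("M0", "M2")],
                                     sems[("M1", "M2")], n_replicates)
        sds[marker] = {"M0": s0, "M1": s1, "M2": s2}
    v_mac = n_replicates * CD11B_SEM_THP1_M0**2 - CD11B_SD_THP1**2
    sd_mac = math.sqrt(v_mac)
    sds["CD11b"] = {"THP-1": CD11B_SD_THP1, "M0": sd_mac, "M1": sd_mac, "M2": sd_mac}

    rng = np.random.default_rng(seed)
    rows = []
    for marker, means in DEFAULT_MFI_MEANS.items():
        for phen, mu in means.items():
            vals = np.clip(rng.normal(mu, sds[marker][phen], n_replicates), 0.0, None)
            for r, v in enumerate(vals):
                rows.append({"sample": f"{phen}_{r:02d}", "marker": marker,
                             "phenotype": phen, "replicate": r, "mfi": float(v)})
    return pd.DataFrame(rows, columns=["sample", "marker", "phenotype",
                                       "replicate", "mfi"])
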