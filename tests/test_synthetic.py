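"""Synthetic-data generators: determinism, photon accounting, published structure."""

import numpy as np
import pandas as pd
import pytest

from macpheno.gp import gp_pixelwise, raw_reference_gp
from macpheno.synthetic import (DEFAULT_EXPRESSION_MEANS, DEFAULT_MFI_MEANS,
                                SyntheticExpressionSpec, SyntheticImageSpec,
                                default_expression_spec,
                                generate_calibration_set,
                                generate_expression_table,
                                generate_membrane_images, generate_mfi_table,
                                solve_group_sds)


def test_image_determinism():
    spec = SyntheticImageSpec(seed=42, n_cells=5, image_size=(120, 120))
    a = generate_membrane_images(spec)
    b = generate_membrane_images(spec)
    assert np.array_equal(a.channels.ordered_channel, b.channels.ordered_channel)
    assert np.array_equal(a.channels.disordered_channel, b.channels.disordered_channel)
    assert np.array_equal(a.membrane_mask, b.membrane_mask)


def test_noise_free_photon_split(noiseless_field):
    """gp_true = 0.5 -> ordered:disordered = 3:1 on ring pixels, summing to
    the photon budget; gp_true = 0 -> symmetric split."""
    f = noiseless_field
    mask = f.membrane_mask
    io = f.channels.ordered_channel[mask]
    id_ = f.channels.disordered_channel[mask]
    assert np.allclose(io / id_, 3.0)
    assert np.allclose(io + id_, 2000.0)  # photon conservation

    flat = generate_membrane_images(SyntheticImageSpec(
        image_size=(80, 80), n_cells=2, gp_true=0.0, noise=False, seed=1))
    m = flat.membrane_mask
    assert np.array_equal(flat.channels.ordered_channel[m],
                          flat.channels.disordered_channel[m])


def test_gp_recovery_from_noisy_image(noisy_field):
    """Mean GP over the ground-truth mask recovers gp_true within 0.02."""
    gp_map = gp_pixelwise(noisy_field.channels, 1.0)
    mask = noisy_field.membrane_mask
    assert abs(gp_map.gp[mask].mean() - 0.3) <= 0.02


def test_cell_masks_are_rings_and_disjoint(noiseless_field):
    total = np.zeros(noiseless_field.channels.shape, dtype=int)
    for cell in noiseless_field.cells:
        total += cell.mask.astype(int)
        assert cell.mask.sum() > 0
    assert total.max() == 1  # no overlap between cells


def test_image_spec_validation():
    with pytest.raises(ValueError):
        SyntheticImageSpec(gp_true=1.0)
    with pytest.raises(ValueError):
        SyntheticImageSpec(photon_budget=0.0)
    with pytest.raises(ValueError):
        SyntheticImageSpec(ring_thickness_px=12, ring_outer_radius_px=10)
    with pytest.raises(ValueError, match="cannot place"):
        generate_membrane_images(SyntheticImageSpec(
            image_size=(30, 30), n_cells=10, ring_outer_radius_px=10))


def test_calibration_set_exact_when_noiseless():
    cal = generate_calibration_set(0.6, 0.4, n_vesicles=5, noise_sd=0.0, seed=1)
    gp = raw_reference_gp(cal.pairs[:, 0], cal.pairs[:, 1])
    assert np.allclose(gp, 0.4)
    sym = generate_calibration_set(0.2, 0.0, n_vesicles=5, noise_sd=0.0, seed=1)
    assert np.allclose(sym.pairs[:, 0], sym.pairs[:, 1])
    with pytest.raises(ValueError):
        generate_calibration_set(0.6, 0.4, noise_sd=-0.1)


def test_calibration_set_mean_within_standard_error():
    cal = generate_calibration_set(0.6, 0.4, n_vesicles=200, noise_sd=0.02, seed=1)
    gp = raw_reference_gp(cal.pairs[:, 0], cal.pairs[:, 1])
    assert abs(gp.mean() - 0.4) <= 3 * 0.02 / np.sqrt(200)


def test_solve_group_sds_round_trip():
    """Solved SDs reproduce the input SEM triple exactly."""
    n = 9
    s0, s1, s2 = solve_group_sds(45.53, 90.23, 101.0, n)
    assert np.sqrt((s0**2 + s1**2) / n) == pytest.approx(45.53)
    assert np.sqrt((s0**2 + s2**2) / n) == pytest.approx(90.23)
    assert np.sqrt((s1**2 + s2**2) / n) == pytest.approx(101.0)
    with pytest.raises(ValueError, match="inconsistent"):
        solve_group_sds(1.0, 1.0, 10.0, 9)


def test_expression_defaults_reproduce_published_differences():
    means = DEFAULT_EXPRESSION_MEANS
    # IL-1B: (M1-M0) - (M2-M0) = 370.9 - 199.6 = 171.3
    il1b = means["IL1B"]
    assert il1b["M1"] - il1b["M2"] == pytest.approx(171.3)
    # IL-10: (M1-M0) + (M2-M1) = -37.69 + 67.97 = 30.28
    il10 = means["IL10"]
    assert (il10["M1"] - il10["M0"]) + (il10["M2"] - il10["M1"]) == \
        pytest.approx(30.28)
    # additivity holds exactly for every gene
    for g in means:
        m = means[g]
        assert (m["M1"] - m["M0"]) + (m["M2"] - m["M1"]) == \
            pytest.approx(m["M2"] - m["M0"], abs=1e-12)


def test_expression_table_structure_and_determinism():
    spec = default_expression_spec(seed=5)
    a = generate_expression_table(spec)
    b = generate_expression_table(spec)
    pd.testing.assert_frame_equal(a, b)
    assert set(a["gene"]) == {"IL1B", "IL6", "IL10"}
    assert set(a["phenotype"]) == {"M0", "M1", "M2"}
    assert a.groupby(["gene", "phenotype"]).size().eq(9).all()


def test_expression_zero_sd_yields_group_means():
    means = {"g": {"M0": 1.0, "M1": 5.0, "M2": 3.0}}
    sds = {"g": {"M0": 0.0, "M1": 0.0, "M2": 0.0}}
    spec = SyntheticExpressionSpec(genes=("g",), phenotypes=("M0", "M1", "M2"),
                                   group_mean=means, group_sd=sds,
                                   n_replicates=4, seed=0)
    table = generate_expression_table(spec)
    for phen, expected in means["g"].items():
        assert (table.loc[table["phenotype"] == phen, "value"] == expected).all()


def test_expression_spec_validation():
    with pytest.raises(ValueError, match="missing group mean"):
        SyntheticExpressionSpec(genes=("g", "h"), phenotypes=("M0",),
                                group_mean={"g": {"M0": 1.0}},
                                group_sd={"g": {"M0": 0.0}}, seed=0)


def test_simulated_sems_match_published_within_10pct():
    """Monte-Carlo SEM of each pairwise difference vs the published SEM."""
    from macpheno.synthetic import DEFAULT_EXPRESSION_SEMS
    diffs = {k: [] for g in DEFAULT_EXPRESSION_SEMS
             for k in [(g, pair) for pair in DEFAULT_EXPRESSION_SEMS[g]]}
    for seed in range(300):
        t = generate_expression_table(default_expression_spec(seed=seed))
        gm = t.groupby(["gene", "phenotype"])["value"].mean()
        for gene, sems in DEFAULT_EXPRESSION_SEMS.items():
            for (pa, pb) in sems:
                diffs[(gene, (pa, pb))].append(gm[gene, pb] - gm[gene, pa])
    for (gene, pair), vals in diffs.items():
        published = DEFAULT_EXPRESSION_SEMS[gene][pair]
        assert np.std(vals) == pytest.approx(published, rel=0.10)


def test_mfi_table_determinism_and_published_differences():
    a = generate_mfi_table(seed=3)
    b = generate_mfi_table(seed=3)
    pd.testing.assert_frame_equal(a, b)
    means = DEFAULT_MFI_MEANS
    assert means["CD64"]["M1"] - means["CD64"]["M0"] == pytest.approx(286.7)
    # published group means 431 and 6.33 print their difference as 424.7
    assert means["CD11b"]["M0"] - means["CD11b"]["THP-1"] == \
        pytest.approx(424.7, abs=0.05)
    assert means["CD86"]["M1"] - means["CD86"]["M0"] == pytest.approx(214.3)
    assert means["CD206"]["M2"] - means["CD206"]["M0"] == pytest.approx(8.67)
    # n = 3 replicates per phenotype per marker; MFI nonnegative
    assert a.groupby(["marker", "phenotype"]).size().eq(3).all()
    assert (a["mfi"] >= 0).all()
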