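"""Simulator contracts: analytic signal model, determinism, and the
closed-form behaviour of the qPCR/ELISA generators."""

import numpy as np
import pandas as pd
import pytest

import iresscreen as ir
from iresscreen import screen_io as sio
from iresscreen.errors import IntegrityError, ParameterError, SizingError


def test_zero_noise_wells_match_analytic_signal_model(noiseless_config):
    """At zero noise every well equals baseline x gene_effect recomputed by
    hand from the ground truth (gene_effect = 1 + k(m - 1))."""
    cfg = noiseless_config
    library, layout, meas, truth = ir.simulate_primary_screen(cfg)
    mult = truth.genes.set_index("gene_symbol")["effect_multiplier"]
    kd = truth.knockdown.set_index(["gene_symbol", "sirna_index"])["efficiency"]
    merged = meas.merge(layout, on=["plate_id", "well"])
    for row in merged.itertuples(index=False):
        if row.content_type == sio.CONTENT_GENE:
            k = kd.loc[(row.gene_symbol, int(row.sirna_index))]
            expect = cfg.baseline_signal * (1 + k * (mult.loc[row.gene_symbol] - 1))
        elif row.content_type == sio.CONTENT_SCRAMBLED:
            expect = cfg.baseline_signal
        elif row.content_type == sio.CONTENT_FLUC:
            expect = cfg.baseline_signal * 0.05
        else:
            expect = cfg.baseline_signal * 0.25
        assert row.value == pytest.approx(expect, rel=1e-12)


def test_neutral_gene_wells_equal_baseline_at_zero_noise(noiseless_config):
    cfg = noiseless_config
    _, layout, meas, truth = ir.simulate_primary_screen(cfg)
    neutral = truth.genes.loc[truth.genes["sign"] == "none", "gene_symbol"]
    merged = meas.merge(layout, on=["plate_id", "well"])
    vals = merged.loc[merged["gene_symbol"].isin(neutral), "value"]
    assert len(vals) > 0
    assert np.all(vals == cfg.baseline_signal)


def test_same_seed_gives_bit_identical_tables(small_config):
    a = ir.simulate_primary_screen(small_config)
    b = ir.simulate_primary_screen(small_config)
    pd.testing.assert_frame_equal(a[0], b[0])
    pd.testing.assert_frame_equal(a[1], b[1])
    pd.testing.assert_frame_equal(a[2], b[2])
    pd.testing.assert_frame_equal(a[3].genes, b[3].genes)


def test_empty_library_yields_control_only_plates():
    cfg = ir.SimulationConfig(n_genes=0, seed=1)
    library, layout, meas, truth = ir.simulate_primary_screen(cfg)
    assert library.empty
    assert truth.genes.empty
    assert set(layout["content_type"]) <= {
        sio.CONTENT_SCRAMBLED, sio.CONTENT_FLUC, sio.CONTENT_PLK1}
    assert len(meas) == len(layout) > 0


def test_screen_geometry_triplicates_and_controls(small_config):
    """Every gene x siRNA reaction appears on exactly 3 replicate plates and
    every plate carries 4 scrambled + 1 FLuc control."""
    _, layout, _, _ = ir.simulate_primary_screen(small_config)
    gene_rows = layout[layout["content_type"] == sio.CONTENT_GENE]
    per_reaction = gene_rows.groupby(["gene_symbol", "sirna_index"]).size()
    assert (per_reaction == 3).all()
    assert len(per_reaction) == small_config.n_genes * 3
    per_plate = layout.groupby("plate_id")["content_type"].value_counts().unstack()
    assert (per_plate[sio.CONTENT_SCRAMBLED] == 4).all()
    assert (per_plate[sio.CONTENT_FLUC] == 1).all()


def test_sibling_sirnas_land_on_different_plates():
    """siRNA-set-major plating: a gene's reagents never share a plate when
    the library spans several plates (keeps their scores independent)."""
    cfg = ir.SimulationConfig(n_genes=300, seed=3)
    _, layout, _, _ = ir.simulate_primary_screen(cfg)
    gene_rows = layout[(layout["content_type"] == sio.CONTENT_GENE)
                       & (layout["replicate_index"] == 1)]
    plates_per_gene = gene_rows.groupby("gene_symbol")["plate_id"].nunique()
    assert (plates_per_gene == 3).all()


def test_effect_multiplier_monotone_in_expected_signal():
    base = dict(n_genes=5, seed=5, noise_cv=0.0, plate_effect_sd=0.0)
    vals = []
    for m in (1.0, 2.0, 4.0):
        cfg = ir.SimulationConfig(
            planted_regulators=(ir.PlantedRegulator("GENE00002", m),), **base)
        _, layout, meas, _ = ir.simulate_primary_screen(cfg)
        merged = meas.merge(layout, on=["plate_id", "well"])
        vals.append(merged.loc[merged["gene_symbol"] == "GENE00002", "value"].mean())
    assert vals[0] < vals[1] < vals[2]


def test_neutral_well_cv_matches_noise_cv():
    cfg = ir.SimulationConfig(n_genes=1200, seed=42, plate_effect_sd=0.0)
    _, layout, meas, _ = ir.simulate_primary_screen(cfg)
    merged = meas.merge(layout, on=["plate_id", "well"])
    vals = merged.loc[merged["content_type"] == sio.CONTENT_GENE, "value"]
    assert len(vals) >= 10_000
    cv = vals.std() / vals.mean()
    assert cv == pytest.approx(cfg.noise_cv, abs=0.01)


def test_capacity_overflow_names_required_vs_available():
    cfg = ir.SimulationConfig(n_genes=100, seed=1, max_plates=2)
    with pytest.raises(SizingError, match="plates"):
        ir.simulate_primary_screen(cfg)


def test_invalid_config_rejected():
    with pytest.raises(ParameterError):
        ir.SimulationConfig(n_genes=5, noise_cv=-0.1)
    with pytest.raises(ParameterError):
        ir.SimulationConfig(n_genes=5, n_neg_controls_per_plate=0)
    with pytest.raises(ParameterError):
        ir.PlantedRegulator("G", 0.0)


# -- secondary-screen generator ----------------------------------------------

def test_secondary_channels_zero_noise(noiseless_config):
    """ires_specific regulators perturb only the IRES channel; toxic genes
    depress all three channels jointly; neutral genes sit at control level."""
    cfg = noiseless_config
    genes = ["GENE00003", "GENE00007", "GENE00011", "GENE00001"]
    layout, meas = ir.simulate_secondary_screen(cfg, genes)
    norm = ir.normalize_screen(meas, layout)
    rx = ir.aggregate_replicates(norm, layout, min_replicates=1)
    scores = rx.pivot_table(index="gene_symbol", columns="channel", values="score")
    # non-specific negative regulator (m=4): both reporters up, viability ok
    assert scores.loc["GENE00003", "fluc_ires"] == pytest.approx(400)
    assert scores.loc["GENE00003", "fluc_cap"] == pytest.approx(400)
    assert scores.loc["GENE00003", "atp"] == pytest.approx(100)
    # ires-specific positive regulator (m=0.3): IRES down, cap & ATP at 100
    assert scores.loc["GENE00007", "fluc_ires"] == pytest.approx(30)
    assert scores.loc["GENE00007", "fluc_cap"] == pytest.approx(100)
    assert scores.loc["GENE00007", "atp"] == pytest.approx(100)
    # toxic gene (PLK1-like, m=0.25): all channels at 25%
    assert scores.loc["GENE00011"].to_numpy() == pytest.approx([25, 25, 25])
    # neutral gene: all channels at 100%
    assert scores.loc["GENE00001"].to_numpy() == pytest.approx([100, 100, 100])


def test_secondary_unknown_gene_rejected(small_config):
    with pytest.raises(IntegrityError, match="NOSUCH"):
        ir.simulate_secondary_screen(small_config, ["NOSUCH"])
    with pytest.raises(ParameterError):
        ir.simulate_secondary_screen(small_config, [])


# -- qPCR generator -----------------------------------------------------------

def test_qpcr_identity_ratio_gives_identical_cts(small_config):
    df = ir.simulate_qpcr(small_config, true_ratio=1.0, efficiency=2.0,
                          n_per_group=3, ct_noise_sd=0.0)
    t = df[(df["group"] == "treated") & (df["role"] == "target")]["ct"]
    c = df[(df["group"] == "control") & (df["role"] == "target")]["ct"]
    assert np.array_equal(t.to_numpy(), c.to_numpy())


def test_qpcr_quarter_ratio_shifts_target_ct_by_two_cycles(small_config):
    """dCt = -log2(0.25) = 2 at perfect doubling."""
    df = ir.simulate_qpcr(small_config, true_ratio=0.25, efficiency=2.0,
                          n_per_group=3, ct_noise_sd=0.0)
    t = df[(df["group"] == "treated") & (df["role"] == "target")]["ct"].iloc[0]
    c = df[(df["group"] == "control") & (df["role"] == "target")]["ct"].iloc[0]
    assert t - c == pytest.approx(2.0, abs=1e-12)
    ref_t = df[(df["group"] == "treated") & (df["role"] == "reference")]["ct"]
    ref_c = df[(df["group"] == "control") & (df["role"] == "reference")]["ct"]
    assert np.array_equal(ref_t.to_numpy(), ref_c.to_numpy())


def test_qpcr_reproducible_and_validated(small_config):
    a = ir.simulate_qpcr(small_config, 0.5, 1.9, 3)
    b = ir.simulate_qpcr(small_config, 0.5, 1.9, 3)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ParameterError):
        ir.simulate_qpcr(small_config, 0.5, 1.0, 3)
    with pytest.raises(ParameterError):
        ir.simulate_qpcr(small_config, 0.0, 2.0, 3)


# -- ELISA generator ----------------------------------------------------------

def test_elisa_exact_means_at_zero_noise(small_config):
    df = ir.simulate_elisa(small_config, control_mean=100.0,
                           percent_reduction=0.25, n_per_group=3, noise_sd=0.0)
    assert np.all(df.loc[df["group"] == "treated", "concentration"] == 75.0)
    assert np.all(df.loc[df["group"] == "control", "concentration"] == 100.0)
    same = ir.simulate_elisa(small_config, 100.0, 0.0, 3, noise_sd=0.0)
    assert same["concentration"].nunique() == 1


def test_elisa_reproducible_and_validated(small_config):
    a = ir.simulate_elisa(small_config, 100.0, 0.25, 4)
    b = ir.simulate_elisa(small_config, 100.0, 0.25, 4)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ParameterError):
        ir.simulate_elisa(small_config, 100.0, 0.25, 1)
    with pytest.raises(ParameterError):
        ir.simulate_elisa(small_config, 100.0, 1.0, 3)
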