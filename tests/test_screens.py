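"""Per-modality screen tests: constructed fixtures, interval-mapping oracle,
filter semantics, and determinism/monotonicity properties."""
import numpy as np
import pandas as pd
import pytest

from omnilevel.screens import (
    build_mutation_matrix,
    collapse_probes_to_genes,
    map_mirna_targets,
    map_segments_to_genes,
    screen_copy_number,
    screen_expression,
    screen_methylation,
    screen_mirna,
    screen_mutations,
)
from omnilevel.types import (
    GeneModel,
    MutationCall,
    OmicsMatrix,
    SampleDesign,
    SegmentRecord,
    ThresholdConfig,
)

CFG = ThresholdConfig()


def _paired_design(n):
    t = [f"T{i}" for i in range(n)]
    nn = [f"N{i}" for i in range(n)]
    return SampleDesign(tumor=t, normal=nn, pairs=list(zip(t, nn)))


def _matrix(values, features, samples, kind="expression"):
    return OmicsMatrix(
        pd.DataFrame(values, index=features, columns=samples), kind
    )


# ------------------------------------------------------------- expression


def test_expression_single_planted_gene_called():
    """20 perfect pairs, one gene at 4x normal: exactly that gene is called."""
    design = _paired_design(20)
    n_genes = 5
    vals = np.full((n_genes, 40), 10.0)
    vals[2, :20] = 40.0  # tumor columns first
    expr = _matrix(vals, [f"g{i}" for i in range(n_genes)], design.tumor + design.normal)
    res = screen_expression(expr, design, CFG)
    assert res.called_set == {"g2"}
    row = res.table.loc["g2"]
    assert row["effect"] == pytest.approx(4.0)
    assert row["p"] == pytest.approx(2 / 2**20)
    # flat genes carry no paired signal: reported untested
    assert not res.table.loc["g0", "tested"]


def test_expression_requires_pairs():
    expr = _matrix([[1.0, 2.0]], ["g"], ["A", "B"])
    with pytest.raises(ValueError):
        screen_expression(expr, SampleDesign(tumor=["A"], normal=["B"]), CFG)


def test_expression_fold_without_significance_not_called():
    """Fold above threshold but inconsistent sign pattern: q too large."""
    rng = np.random.default_rng(0)
    design = _paired_design(10)
    normal = np.full(10, 10.0)
    tumor = np.array([60, 2, 55, 3, 50, 2, 45, 3, 40, 2], dtype=float)
    vals = np.concatenate([tumor, normal])[None, :]
    expr = _matrix(vals, ["g"], design.tumor + design.normal)
    res = screen_expression(expr, design, CFG)
    row = res.table.loc["g"]
    assert row["effect"] >= CFG.ge_fold
    assert row["q"] > CFG.ge_fdr
    assert not row["called"]


def test_expression_empty_matrix_gives_empty_result():
    design = _paired_design(3)
    expr = _matrix(np.empty((0, 6)), [], design.tumor + design.normal)
    res = screen_expression(expr, design, CFG)
    assert len(res.table) == 0


# ----------------------------------------------------------- segment map


def _brute_force_gene_copies(segments, gene, sample):
    """Per-base oracle: average linear copy over covered bases of the gene."""
    copies = []
    for base in range(gene.start, gene.end + 1):
        for seg in segments:
            if seg.sample_id == sample and seg.chrom == gene.chrom and seg.start <= base <= seg.end:
                copies.append(seg.linear_copy)
                break
    return (float(np.mean(copies)), False) if copies else (2.0, True)


def test_segment_map_closed_form_values():
    genes = [GeneModel("G1", "1", 100, 199)]
    segs = [SegmentRecord("S1", "1", 1, 500, 0.585)]
    out = map_segments_to_genes(segs, genes)
    assert out.copies.data.loc["G1", "S1"] == pytest.approx(2 * 2**0.585)
    assert not out.imputed.loc["G1", "S1"]


def test_segment_map_two_equal_overlaps_average():
    genes = [GeneModel("G1", "1", 101, 300)]
    segs = [
        SegmentRecord("S1", "1", 1, 200, 0.0),  # copy 2 over 100 bases
        SegmentRecord("S1", "1", 201, 400, 1.0),  # copy 4 over 100 bases
    ]
    out = map_segments_to_genes(segs, genes)
    assert out.copies.data.loc["G1", "S1"] == pytest.approx(3.0)


def test_segment_map_absent_chromosome_imputes_neutral():
    genes = [GeneModel("G1", "7", 100, 200)]
    segs = [SegmentRecord("S1", "1", 1, 500, 0.3)]
    out = map_segments_to_genes(segs, genes)
    assert out.copies.data.loc["G1", "S1"] == 2.0
    assert bool(out.imputed.loc["G1", "S1"])


def test_segment_map_matches_per_base_oracle_on_random_genomes():
    rng = np.random.default_rng(21)
    for _ in range(20):
        segments, genes = _random_toy_genome(rng)
        out = map_segments_to_genes(segments, genes, samples=["S1", "S2"])
        for gene in genes:
            for sample in ("S1", "S2"):
                expected, imputed = _brute_force_gene_copies(segments, gene, sample)
                got = out.copies.data.loc[gene.gene_id, sample]
                assert got == pytest.approx(expected, rel=1e-9), (gene, sample)
                assert bool(out.imputed.loc[gene.gene_id, sample]) == imputed


def _random_toy_genome(rng, genome_size=2000):
    """Random non-overlapping segments (with gaps) and random genes."""
    segments = []
    for sample in ("S1", "S2"):
        pos = 1
        while pos < genome_size:
            length = int(rng.integers(50, 400))
            end = min(pos + length - 1, genome_size)
            if rng.random() > 0.3:  # leave ~30% gaps uncovered
                segments.append(
                    SegmentRecord(sample, "1", pos, end, float(rng.normal(0, 0.5)))
                )
            pos = end + 1 + int(rng.integers(0, 100))
    genes = []
    for i in range(int(rng.integers(3, 8))):
        start = int(rng.integers(1, genome_size - 100))
        genes.append(
            GeneModel(f"G{i}", "1", start, start + int(rng.integers(10, 300)))
        )
    return segments, genes


def test_segment_weighting_modes_differ_only_on_unequal_overlaps():
    genes = [GeneModel("G1", "1", 101, 300)]
    equal = [
        SegmentRecord("S1", "1", 1, 200, 0.0),
        SegmentRecord("S1", "1", 201, 400, 1.0),
    ]
    unequal = [
        SegmentRecord("S1", "1", 1, 250, 0.0),  # 150 bases of the gene
        SegmentRecord("S1", "1", 251, 400, 1.0),  # 50 bases
    ]
    for segs, should_differ in ((equal, False), (unequal, True)):
        w = map_segments_to_genes(segs, genes, weighting="length").copies.data.iloc[0, 0]
        u = map_segments_to_genes(segs, genes, weighting="unweighted").copies.data.iloc[0, 0]
        assert (abs(w - u) > 1e-9) == should_differ


def test_copy_number_screen_planted_gain_called():
    design = _paired_design(20)
    vals = np.full((3, 40), 2.0)
    vals[1, :20] = 3.0  # planted 1.5-fold gain
    copies = _matrix(vals, ["g0", "g1", "g2"], design.tumor + design.normal, "copy_number")
    res = screen_copy_number(copies, design, CFG)
    assert res.called_set == {"g1"}
    assert res.table.loc["g1", "effect"] == pytest.approx(1.5)
    # all-neutral genes have constant zero differences: untested
    assert not res.table.loc["g0", "tested"]


def test_copy_number_below_fold_floor_not_called():
    design = _paired_design(20)
    vals = np.full((1, 40), 2.0)
    vals[0, :20] = 2.2  # 1.1-fold: significant but below the 1.2 floor
    copies = _matrix(vals, ["g"], design.tumor + design.normal, "copy_number")
    res = screen_copy_number(copies, design, CFG)
    row = res.table.loc["g"]
    assert row["q"] <= CFG.cn_fdr and not row["called"]


# ------------------------------------------------------------ methylation


def test_collapse_probes_mean_and_missing_propagation():
    beta = _matrix(
        [[0.2, np.nan], [0.4, np.nan], [0.6, 0.5]],
        ["p1", "p2", "p3"],
        ["A", "B"],
        "beta",
    )
    out = collapse_probes_to_genes(beta, {"p1": "g1", "p2": "g1", "p3": "g2"})
    assert out.data.loc["g1", "A"] == pytest.approx(0.3)
    assert np.isnan(out.data.loc["g1", "B"])  # all probes missing
    assert out.data.loc["g2", "B"] == pytest.approx(0.5)  # single probe identity


def _beta_platform(delta_by_gene, n_tumor, n_normal, prefix):
    genes = sorted(delta_by_gene)
    t = [f"{prefix}T{i}" for i in range(n_tumor)]
    n = [f"{prefix}N{i}" for i in range(n_normal)]
    rng = np.random.default_rng(hash(prefix) % 2**31)
    rows = []
    for g in genes:
        base = 0.5
        tumor_vals = base - delta_by_gene[g] + rng.normal(0, 0.01, n_tumor)
        normal_vals = base + rng.normal(0, 0.01, n_normal)
        rows.append(np.clip(np.concatenate([tumor_vals, normal_vals]), 0, 1))
    return (
        _matrix(np.array(rows), genes, t + n, "beta"),
        SampleDesign(tumor=t, normal=n),
    )


def test_methylation_requires_both_platforms():
    strong = {"g1": 0.2, "g2": 0.0}
    ma, da = _beta_platform(strong, 20, 20, "A")
    mb, db = _beta_platform({"g1": 0.2, "g2": 0.2}, 20, 20, "B")
    res = screen_methylation(ma, mb, da, db, CFG)
    assert res.called_set == {"g1"}  # g2 significant on platform B only
    assert res.table.loc["g1", "effect"] >= CFG.me_delta_beta


def test_methylation_small_delta_floor():
    ma, da = _beta_platform({"g1": 0.04}, 20, 20, "A")
    mb, db = _beta_platform({"g1": 0.04}, 20, 20, "B")
    res = screen_methylation(ma, mb, da, db, CFG)
    row = res.table.loc["g1"]
    assert row["delta_beta_a"] < 0.05 and not row["called"]


def test_methylation_missing_group_rejected():
    ma, da = _beta_platform({"g1": 0.1}, 5, 5, "A")
    empty_design = SampleDesign(tumor=["zz"], normal=da.normal)
    with pytest.raises(ValueError):
        screen_methylation(ma, ma, empty_design, da, CFG)


# ------------------------------------------------------------------ miRNA


def test_mirna_planted_downregulation_called():
    rng = np.random.default_rng(4)
    t = [f"T{i}" for i in range(20)]
    n = [f"N{i}" for i in range(40)]
    tumor = 2 ** (6 + rng.normal(0, 0.3, (2, 20)))
    normal = 2 ** (6 + rng.normal(0, 0.3, (2, 40)))
    normal[0] *= 4.0  # planted: normal = 4x tumor
    m = _matrix(np.concatenate([tumor, normal], axis=1), ["miR-a", "miR-b"], t + n, "mirna")
    res = screen_mirna(m, SampleDesign(tumor=t, normal=n), CFG)
    assert res.called_set == {"miR-a"}
    assert res.table.loc["miR-a", "effect"] == pytest.approx(4.0, rel=0.3)


def test_mirna_constant_feature_degenerate_not_called():
    t, n = ["T0", "T1"], ["N0", "N1"]
    m = _matrix([[5.0, 5.0, 5.0, 5.0]], ["miR-c"], t + n, "mirna")
    res = screen_mirna(m, SampleDesign(tumor=t, normal=n), CFG)
    row = res.table.loc["miR-c"]
    assert row["p"] == 1.0 and not row["called"]


def test_mirna_small_group_rejected():
    m = _matrix([[1.0, 2.0]], ["miR"], ["T0", "N0"], "mirna")
    with pytest.raises(ValueError):
        screen_mirna(m, SampleDesign(tumor=["T0"], normal=["N0"]), CFG)


def test_map_mirna_targets_union_and_missing(caplog):
    targets = {"miR-X": {"g1", "g2"}, "miR-Y": {"g2", "g3"}}
    assert map_mirna_targets([], targets) == set()
    assert map_mirna_targets(["miR-X", "miR-Y"], targets) == {"g1", "g2", "g3"}
    import logging

    with caplog.at_level(logging.WARNING, logger="omnilevel"):
        out = map_mirna_targets(["miR-X", "miR-Z"], targets)
    assert out == {"g1", "g2"}
    assert "absent" in caplog.text


# -------------------------------------------------------------- mutations


def test_mutation_matrix_dedup_and_silent_filter():
    calls = [
        MutationCall("TP53", "S1", "Missense_Mutation"),
        MutationCall("TP53", "S1", "Nonsense_Mutation"),
        MutationCall("GATA3", "S2", "Silent"),
        MutationCall("TTN", "S9", "Missense_Mutation"),  # outside cohort
    ]
    m = build_mutation_matrix(calls, ["S1", "S2"])
    assert m.data.loc["TP53", "S1"] == 1  # collapsed, not 2
    assert "GATA3" not in m.data.index  # Silent-only gene dropped
    assert "TTN" not in m.data.index  # sample outside the cohort
    m_all = build_mutation_matrix(calls, ["S1", "S2"], "all")
    assert m_all.data.loc["GATA3", "S2"] == 1
    m_keep = build_mutation_matrix(calls, ["S1", "S2"], {"Silent"})
    assert list(m_keep.data.index) == ["GATA3"]


def test_mutation_matrix_empty_calls():
    m = build_mutation_matrix([], ["S1"])
    assert m.data.shape == (0, 1)


def _mutation_fixture(case_mutated, n_case, bg_mutated, n_bg, gene="TP53"):
    calls = []
    case_ids = [f"C{i}" for i in range(n_case)]
    extra_ids = [f"B{i}" for i in range(n_bg - n_case)]
    bg_ids = case_ids + extra_ids
    for s in case_ids[:case_mutated]:
        calls.append(MutationCall(gene, s, "Missense_Mutation"))
    for s in extra_ids[: bg_mutated - case_mutated]:
        calls.append(MutationCall(gene, s, "Missense_Mutation"))
    return (
        build_mutation_matrix(calls, case_ids),
        build_mutation_matrix(calls, bg_ids),
        case_ids,
        bg_ids,
    )


def test_mutation_screen_tp53_worked_example():
    case, bg, _, _ = _mutation_fixture(42, 54, 308, 992)
    res = screen_mutations(case, bg, CFG)
    row = res.table.loc["TP53"]
    assert row["effect"] == pytest.approx(7.7727, rel=1e-3)
    assert row["p"] < 1e-9
    assert row["called"]


def test_mutation_screen_zero_case_gene_not_called():
    case, bg, case_ids, bg_ids = _mutation_fixture(0, 10, 5, 100)
    res = screen_mutations(case, bg, CFG)
    assert res.table.loc["TP53", "effect"] == 0.0
    assert not res.table.loc["TP53", "called"]


def test_mutation_screen_enriched_small_cohort_called():
    case, bg, _, _ = _mutation_fixture(5, 10, 5, 100)
    res = screen_mutations(case, bg, CFG)
    row = res.table.loc["TP53"]
    assert row["p"] < 0.05 and row["called"]


# ------------------------------------------------------------- properties


def test_screens_deterministic_and_row_permutation_equivariant(small_study):
    res1 = screen_expression(small_study.expression, small_study.expression_design, CFG)
    res2 = screen_expression(small_study.expression, small_study.expression_design, CFG)
    pd.testing.assert_frame_equal(res1.table, res2.table)
    shuffled = OmicsMatrix(
        small_study.expression.data.iloc[::-1], small_study.expression.kind
    )
    res3 = screen_expression(shuffled, small_study.expression_design, CFG)
    pd.testing.assert_frame_equal(res3.table.sort_index(), res1.table.sort_index())


def test_tightening_thresholds_never_adds_calls(small_study, small_result):
    from omnilevel.pipeline import run_study

    tight = ThresholdConfig(
        ge_fold=3.0, ge_fdr=0.01, cn_fold=1.4, cn_fdr=0.01,
        me_delta_beta=0.1, me_fdr=0.01, mr_fold=3.0, mr_fdr=0.01, gm_p=0.01,
    )
    tight_result = run_study(small_study, tight)
    for m in ("GE", "CN", "ME", "GM"):
        assert tight_result.screens[m].called_set <= small_result.screens[m].called_set
    assert tight_result.mirna_screen.called_set <= small_result.mirna_screen.called_set
    assert tight_result.mr_genes <= small_result.mr_genes
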