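"""P/ND coding, condition verdicts and raw-expression comparison."""

import dataclasses

import numpy as np
import pytest

from ripchip.array_io import GeneAnnotation
from ripchip.errors import GeneNotOnArrayError
from ripchip.perturbation import (
    CODE_ND,
    CODE_P,
    build_report,
    compare_conditions,
    compare_raw_expression,
    score_or_code,
)
from ripchip.pipeline import scan_to_standardized
from ripchip.synthetic_data import SyntheticConfig, simulate_experiment

from conftest import make_scan, make_spot


def small_annotation(n_genes, probes=1):
    return [
        GeneAnnotation(f"g{i}.p{j}", f"g{i}", True)
        for i in range(n_genes)
        for j in range(probes)
    ]


def background_scan(n_genes, rng, extra=()):
    """A scan with log-normal background plus any extra spots."""
    spots = []
    for i in range(n_genes):
        ip = float(10 ** rng.normal(2, 0.3))
        ref = float(10 ** rng.normal(2, 0.3))
        spots.append(make_spot(f"g{i}.p0", ip=ip, ref=ref, ip_frac=0.95, ref_frac=0.95))
    return make_scan(list(extra) + spots)


class TestScoreOrCode:
    def test_undetectable_gene_coded_nd(self):
        rng = np.random.default_rng(0)
        ann = [GeneAnnotation("gX.p1", "gX", True), GeneAnnotation("gX.p2", "gX", True)]
        ann += [GeneAnnotation(f"g{i}.p0", f"g{i}", True) for i in range(300)]
        dim = [
            make_spot("gX.p1", ip_frac=0.60, ref_frac=0.95),
            make_spot("gX.p2", ip_frac=0.85, ref_frac=0.95),
        ]
        scan = background_scan(300, rng, extra=dim)
        # both spots below the stand-alone IP threshold (0.90 on PCR arrays)
        assert score_or_code("gX", scan, ann) == CODE_ND

    def test_small_background_with_detectable_gene_coded_p(self):
        rng = np.random.default_rng(1)
        ann = small_annotation(12)
        scan = background_scan(12, rng)
        # replace probe ids to match the annotation
        scan = make_scan(
            [dataclasses.replace(s, probe_id=f"g{i}.p0") for i, s in enumerate(scan.spots)]
        )
        assert score_or_code("g3", scan, ann, min_background=200) == CODE_P

    def test_numeric_score_agrees_with_standardize(self):
        rng = np.random.default_rng(2)
        ann = [GeneAnnotation(f"g{i}.p0", f"g{i}", True) for i in range(400)]
        scan = background_scan(400, rng)
        value = score_or_code("g7", scan, ann, min_background=200)
        std, _ = scan_to_standardized(scan, ann, min_background=200)
        assert value == pytest.approx(std.s["g7"])

    def test_gene_absent_from_design_raises(self):
        rng = np.random.default_rng(3)
        ann = [GeneAnnotation(f"g{i}.p0", f"g{i}", True) for i in range(250)]
        scan = background_scan(250, rng)
        with pytest.raises(GeneNotOnArrayError):
            score_or_code("not_a_gene", scan, ann)


class TestCompareConditions:
    @pytest.mark.parametrize("control,treated,expected", [
        # enrichment lost on blocking translation of the message
        ([4.1, 3.8], [CODE_ND, 0.3], "lost"),
        # a second target keeps its enrichment in the same mutant
        ([4.1, 3.8], [3.5, 2.2], "retained"),
        # never enriched in the baseline arm
        ([1.0], [0.5], "inconclusive"),
        # disagreement between treated replicates
        ([3.0, 3.0], [3.5, 0.1], "inconclusive"),
        # ND counts as below threshold in the baseline arm too
        ([CODE_ND, 4.0], [0.1], "inconclusive"),
    ])
    def test_verdicts(self, control, treated, expected):
        assert compare_conditions(control, treated, tau=2.0) == expected

    def test_p_resolved_only_when_verdict_is_unambiguous(self):
        # P in the treated arm flips the verdict between lost and retained
        assert compare_conditions([4.0], [CODE_P], tau=2.0) == "inconclusive"
        # here the other treated replicate is already above threshold, so the
        # lost verdict is impossible either way, but so is retained/lost
        # agreement -> still inconclusive unless both readings agree
        assert compare_conditions([4.0], [3.0, CODE_P], tau=2.0) == "inconclusive"
        # baseline P cannot change an already-failed baseline condition
        assert compare_conditions([CODE_P, 1.0], [0.1], tau=2.0) == "inconclusive"

    def test_empty_arm_is_an_error(self):
        with pytest.raises(ValueError):
            compare_conditions([], [1.0])

    def test_swapping_arms_never_maps_lost_to_lost(self):
        control, treated = [4.1, 3.8], [CODE_ND, 0.3]
        assert compare_conditions(control, treated) == "lost"
        assert compare_conditions(treated, control) == "inconclusive"


class TestCompareRawExpression:
    def test_pass_through_pairs_per_probe(self):
        ann = [GeneAnnotation(f"gX.p{j}", "gX", True) for j in (1, 2, 3)]
        plus = make_scan([make_spot(f"gX.p{j}", ip=1.0, ref=float(100 + j)) for j in (1, 2, 3)])
        minus = make_scan([make_spot(f"gX.p{j}", ip=1.0, ref=float(200 + j)) for j in (1, 2, 3)])
        pairs = compare_raw_expression(plus, minus, "gX", ann)
        assert len(pairs) == 3
        assert pairs[0].plus_atg_ref == 101.0 and pairs[0].minus_atg_ref == 201.0

    def test_gene_absent_from_either_design_raises(self):
        ann = [GeneAnnotation("gX.p1", "gX", True)]
        plus = make_scan([make_spot("gX.p1")])
        minus = make_scan([make_spot("other.p1")])
        with pytest.raises(GeneNotOnArrayError):
            compare_raw_expression(plus, minus, "gX", ann)

    def test_unchanged_abundance_gives_ratio_near_one(self):
        cfg = SyntheticConfig(seed=3, n_genes=600, k=1, condition="control")
        scans, truth = simulate_experiment(cfg)
        target = truth.minus_atg_gene or max(truth.target_effects)
        mcfg = dataclasses.replace(cfg, condition="minus_atg")
        mscans, mtruth = simulate_experiment(mcfg)
        pairs = compare_raw_expression(
            scans[0], mscans[0], mtruth.minus_atg_gene, truth.annotation
        )
        ratios = [p.plus_atg_ref / p.minus_atg_ref for p in pairs]
        assert np.median(ratios) == pytest.approx(1.0, abs=0.5)

    def test_degraded_mrna_reveals_tenfold_drop(self):
        cfg = SyntheticConfig(seed=3, n_genes=600, k=1, condition="control")
        scans, truth = simulate_experiment(cfg)
        mcfg = dataclasses.replace(
            cfg, condition="minus_atg", minus_atg_abundance_factor=0.1
        )
        mscans, mtruth = simulate_experiment(mcfg)
        pairs = compare_raw_expression(
            scans[0], mscans[0], mtruth.minus_atg_gene, truth.annotation
        )
        ratios = [p.plus_atg_ref / p.minus_atg_ref for p in pairs]
        assert np.median(ratios) == pytest.approx(10.0, rel=0.5)


class TestBuildReport:
    def test_report_cells_and_verdicts(self):
        cfg = SyntheticConfig(seed=5, n_genes=800, k=2)
        control_scans, truth = simulate_experiment(cfg)
        puro_scans, _ = simulate_experiment(dataclasses.replace(cfg, condition="puromycin"))
        genes = sorted(truth.target_effects) + [truth.bait_gene]
        report = build_report(
            truth.bait_gene, genes, control_scans, puro_scans, truth.annotation
        )
        assert len(report.cells) == len(genes) * 4  # 2 arms x 2 replicates
        verdicts = {v.mrna: v.verdict for v in report.verdicts}
        # polysome disassembly removes every translation-dependent enrichment
        assert all(v == "lost" for v in verdicts.values())
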