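import numpy as np
import pytest
from Bio import Align as bp_align

from _oracles import exhaustive_align_score
from aqp_profiler.features import (AlignParams, Alignment, FeatureNotFoundError,
                                   extract_feature_profile, find_npa_motifs,
                                   global_align, project_positions,
                                   select_best_reference)
from aqp_profiler.seqio import FEATURE_KEYS, ProteinSequence
from aqp_profiler.synthetic import (DEFAULT_FEATURE_POSITIONS, PlantSpec,
                                    make_query, make_reference_panel)


def seq(r, i="s"):
    return ProteinSequence(id=i, residues=r)


class TestGlobalAlign:
    def test_self_alignment_is_gapless_identity(self):
        s = seq("MNPAVRGGKLW")
        aln = global_align(s, s)
        assert aln.identity == 1.0
        assert "-" not in aln.aligned_query + aln.aligned_ref

    def test_npa_vs_npg_identity(self):
        aln = global_align(seq("NPA"), seq("NPG"))
        assert aln.identity == pytest.approx(2 / 3)

    @pytest.mark.parametrize("pair", [
        ("NPAVR", "NPAR"), ("WWKL", "KLWW"), ("MKT", "MASKT"),
        ("GGG", "WWWW"), ("ACDEFG", "ACDFG"), ("LIVF", "LIVF"),
    ])
    def test_score_matches_exhaustive_enumeration(self, pair):
        q, r = pair
        ours = global_align(seq(q), seq(r)).score
        oracle = exhaustive_align_score(q, r)
        assert ours == pytest.approx(oracle)

    def test_score_matches_biopython_aligner(self):
        aligner = bp_align.PairwiseAligner()
        aligner.substitution_matrix = bp_align.substitution_matrices.load("BLOSUM62")
        aligner.mode = "global"
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = "".join(rng.choice(aas, size=rng.integers(20, 60)))
            b = "".join(rng.choice(aas, size=rng.integers(20, 60)))
            assert global_align(seq(a), seq(b)).score == pytest.approx(
                aligner.score(a, b))

    def test_score_beats_handmade_ungapped_alignment(self):
        from Bio.Align import substitution_matrices
        blosum = substitution_matrices.load("BLOSUM62")
        a, b = "MNPARSTK", "MNPGRSTK"
        handmade = sum(blosum[x, y] for x, y in zip(a, b))
        assert global_align(seq(a), seq(b)).score >= handmade

    def test_degapped_strings_equal_inputs(self):
        aln = global_align(seq("MKTWW"), seq("MASKTW"))
        assert aln.aligned_query.replace("-", "") == "MKTWW"
        assert aln.aligned_ref.replace("-", "") == "MASKTW"

    def test_deterministic_repeat(self):
        a, b = seq("NPAVRGG"), seq("NPGVRG")
        first = global_align(a, b)
        second = global_align(a, b)
        assert first == second


class TestProjection:
    def test_identity_alignment_maps_positions_unchanged(self):
        s = seq("MNPAVRG")
        aln = global_align(s, s)
        projected = project_positions(aln, {"NPA_LB": 2, "H2": 6})
        assert projected == {"NPA_LB": 2, "H2": 6}

    def test_reference_position_in_query_deletion_is_unresolved(self):
        aln = Alignment(query_id="q", ref_id="r",
                        aligned_query="MK--W", aligned_ref="MKTVW",
                        score=0.0, identity=0.6)
        projected = project_positions(aln, {"gone": 3, "kept": 5})
        assert projected["gone"] is None
        assert projected["kept"] == 3

    def test_position_outside_reference_is_error(self):
        s = seq("MNPAVRG")
        aln = global_align(s, s)
        with pytest.raises(ValueError, match="outside"):
            project_positions(aln, {"bad": 99})


class TestBestReference:
    def test_identical_query_selects_that_reference(self, panel):
        target = panel[3]
        ref, aln = select_best_reference(target.sequence, panel)
        assert ref.id == target.id
        assert aln.identity == 1.0

    def test_tie_keeps_table_order(self):
        a = make_reference_panel(0)[0]
        twin_first = a
        import dataclasses
        twin_second = dataclasses.replace(
            a, sequence=ProteinSequence(id="twin", residues=a.sequence.residues))
        query = seq(a.sequence.residues, "q")
        ref, _ = select_best_reference(query, [twin_first, twin_second])
        assert ref.id == twin_first.id
        ref2, _ = select_best_reference(query, [twin_second, twin_first])
        assert ref2.id == "twin"

    def test_pip_like_query_selects_pip_anchor(self, panel):
        q, _ = make_query(PlantSpec(subfamily="PIP", class_label="PIP2",
                                    flank_mutation_rate=0.1, seed=42))
        ref, _ = select_best_reference(q, panel)
        assert ref.subfamily == "PIP"

    def test_empty_panel_is_error(self):
        with pytest.raises(ValueError):
            select_best_reference(seq("NPA"), [])


class TestNpaMotifs:
    def test_planted_variant_motifs_recovered(self):
        q, truth = make_query(PlantSpec(subfamily="TIP", class_label="TIP1",
                                        npa_lb="NPT", npa_le="NPA", seed=9))
        lb, le = find_npa_motifs(q, list(truth.tm_layout))
        assert (lb.motif, lb.start) == ("NPT", truth.feature_positions["NPA_LB"])
        assert (le.motif, le.start) == ("NPA", truth.feature_positions["NPA_LE"])

    def test_no_motif_and_no_anchor_raises(self):
        with pytest.raises(FeatureNotFoundError):
            find_npa_motifs(seq("AAAA"), None)

    def test_anchor_fallback_when_tm_count_wrong(self):
        q, truth = make_query(PlantSpec(subfamily="PIP", class_label="PIP1", seed=3))
        anchor_positions = {"NPA_LB": truth.feature_positions["NPA_LB"],
                            "NPA_LE": truth.feature_positions["NPA_LE"]}
        lb, le = find_npa_motifs(q, tm_segments=[(1, 20)],  # not six segments
                                 anchor_positions=anchor_positions)
        assert lb.start == truth.feature_positions["NPA_LB"]
        assert le.start == truth.feature_positions["NPA_LE"]


class TestFeatureProfile:
    def test_query_identical_to_anchor_reproduces_annotation(self, panel):
        anchor = panel[0]
        prof = extract_feature_profile(anchor.sequence, panel)
        assert prof.anchor_ref_id == anchor.id
        res = anchor.sequence.residues
        pos = anchor.feature_positions
        assert prof.npa_lb == res[pos["NPA_LB"] - 1:pos["NPA_LB"] + 2]
        assert prof.arr == tuple(res[pos[k] - 1] for k in ("H2", "H5", "LE1", "LE2"))
        assert prof.unresolved == set()

    def test_planted_features_recovered_exactly(self, panel):
        q, truth = make_query(PlantSpec(subfamily="NIP", class_label="NIP4",
                                        flank_mutation_rate=0.0, seed=17))
        prof = extract_feature_profile(q, panel)
        tr, tp = truth.feature_residues, truth.feature_positions
        assert prof.npa_lb == tr["NPA_LB"] and prof.npa_lb_pos == tp["NPA_LB"]
        assert prof.npa_le == tr["NPA_LE"] and prof.npa_le_pos == tp["NPA_LE"]
        assert prof.arr == tuple(tr[k] for k in ("H2", "H5", "LE1", "LE2"))
        assert prof.froger == tuple(tr[f"P{k}"] for k in range(1, 6))
        assert prof.sdp == tuple(tr[f"SDP{k}"] for k in range(1, 10))

    def test_recovery_degrades_with_mutation_rate(self, panel):
        def recovery(rate, n=15):
            hits = 0
            total = 0
            for k in range(n):
                q, truth = make_query(PlantSpec(subfamily="PIP", class_label="PIP1",
                                                flank_mutation_rate=rate,
                                                seed=1000 + k))
                prof = extract_feature_profile(q, panel)
                tr = truth.feature_residues
                checks = ([prof.npa_lb == tr["NPA_LB"], prof.npa_le == tr["NPA_LE"]]
                          + [a == tr[k2] for a, k2 in zip(prof.arr,
                                                          ("H2", "H5", "LE1", "LE2"))]
                          + [a == tr[f"P{j}"] for a, j in zip(prof.froger, range(1, 6))]
                          + [a == tr[f"SDP{j}"] for a, j in zip(prof.sdp, range(1, 10))])
                hits += sum(checks)
                total += len(checks)
            return hits / total
        low, high = recovery(0.05), recovery(0.45)
        assert low == 1.0
        assert high <= low
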