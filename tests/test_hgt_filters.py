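"""Individual HGT validation filters and the full screening cascade."""

import math

import numpy as np
import pandas as pd
import pytest

from nanohgt.architecture import GeneModel
from nanohgt.errors import DataError, ScreenInputError
from nanohgt.hgt_filters import (
    CoverageTrack,
    PafRecord,
    ScreenConfig,
    filter_ciliate_homologs,
    filter_dna_rna_consistency,
    filter_intronless,
    filter_spanning_reads,
    filter_stress_de,
    filter_telomere_flanked,
    run_hgt_screen,
    tree_nesting_check,
)
from nanohgt.homology import HitRecord


def _gene(gid="g1", cid="c1", exons=((0, 300),), strand="+"):
    return GeneModel(gid, cid, strand, tuple(exons), tuple(exons))


def _paf(tname, tlen, tstart, tend, qname="r1"):
    alen = tend - tstart
    return PafRecord(qname, alen, 0, alen, "+", tname, tlen, tstart, tend, alen, alen, 60)


def _track(contig, depths, window=100, source="DNA"):
    starts = tuple(i * window for i in range(len(depths)))
    ends = tuple(s + window for s in starts)
    return CoverageTrack(contig, starts, ends, tuple(float(d) for d in depths), source)


class TestTelomereFilter:
    def test_both_passes_one_fails(self):
        status = {"c1": "both", "c2": "one"}
        assert filter_telomere_flanked(_gene(cid="c1"), status)
        assert not filter_telomere_flanked(_gene(cid="c2"), status)

    def test_unclassified_contig_rejected(self):
        with pytest.raises(DataError, match="unclassified"):
            filter_telomere_flanked(_gene(cid="cX"), {"c1": "both"})


class TestSpanningFilter:
    def test_five_constructed_spanning_rows_pass(self):
        alns = [_paf("c1", 2000, 5, 1990, qname=f"r{i}") for i in range(5)]
        assert filter_spanning_reads("c1", 2000, alns) == (5, True)

    def test_half_coverage_read_not_counted(self):
        alns = [_paf("c1", 2000, 0, 1000)]
        assert filter_spanning_reads("c1", 2000, alns) == (0, False)

    def test_absent_contig_counts_zero(self):
        assert filter_spanning_reads("cX", 2000, [_paf("c1", 2000, 0, 2000)]) == (0, False)

    def test_end_slack_boundary(self):
        # starts exactly at end_slack: counted; one bp beyond: not
        at = [_paf("c1", 2000, 50, 2000, qname=f"r{i}") for i in range(3)]
        beyond = [_paf("c1", 2000, 51, 2000, qname=f"r{i}") for i in range(3)]
        assert filter_spanning_reads("c1", 2000, at) == (3, True)
        assert filter_spanning_reads("c1", 2000, beyond) == (0, False)


class TestCoverageFilter:
    def test_identical_tracks_have_rho_one_and_pass(self):
        d = _track("c1", [10, 20, 30, 25, 15])
        r = _track("c1", [10, 20, 30, 25, 15], source="RNA")
        rho, breadth, ok = filter_dna_rna_consistency("c1", d, r)
        assert rho == pytest.approx(1.0) and breadth == 1.0 and ok

    def test_zero_rna_fails_on_breadth(self):
        d = _track("c1", [10, 20, 30, 25, 15])
        r = _track("c1", [0, 0, 0, 0, 0], source="RNA")
        rho, breadth, ok = filter_dna_rna_consistency("c1", d, r)
        assert math.isnan(rho) and breadth == 0.0 and not ok

    def test_monotone_inversion_gives_rho_minus_one_and_fails(self):
        d = _track("c1", [10, 20, 30, 40, 50])
        r = _track("c1", [50, 40, 30, 20, 10], source="RNA")
        rho, _breadth, ok = filter_dna_rna_consistency("c1", d, r)
        assert rho == pytest.approx(-1.0) and not ok

    def test_constant_dna_track_decided_by_breadth_alone(self):
        d = _track("c1", [30, 30, 30, 30])
        r = _track("c1", [5, 6, 7, 8], source="RNA")
        rho, breadth, ok = filter_dna_rna_consistency("c1", d, r)
        assert math.isnan(rho) and breadth == 1.0 and ok

    def test_window_mismatch_rejected(self):
        d = _track("c1", [10, 20, 30])
        r = _track("c1", [10, 20], source="RNA")
        with pytest.raises(DataError, match="windows differ"):
            filter_dna_rna_consistency("c1", d, r)

    def test_breadth_restricted_to_cds_windows(self):
        d = _track("c1", [10, 20, 30, 40])
        r = _track("c1", [0, 5, 5, 0], source="RNA")
        # CDS covers windows 1-2 only: breadth there is 1.0
        _rho, breadth, _ok = filter_dna_rna_consistency(
            "c1", d, r, cds_intervals=[(150, 250)]
        )
        assert breadth == 1.0


class TestSimpleFilters:
    def test_intronless(self):
        assert filter_intronless(_gene(exons=((0, 300),)))
        assert not filter_intronless(_gene(exons=((0, 100), (200, 300))))

    def test_panel_filter_boundary_evalue_counts_as_hit(self):
        def hit(evalue, taxon):
            return HitRecord("g1", "s", 40.0, 100, evalue, 80.0, taxon, "self_lineage")

        assert filter_ciliate_homologs("g1", [])
        assert not filter_ciliate_homologs("g1", [hit(1e-20, "Tetrahymena_thermophila")])
        assert not filter_ciliate_homologs("g1", [hit(1e-5, "Tetrahymena_thermophila")])
        assert filter_ciliate_homologs("g1", [hit(2e-5, "Tetrahymena_thermophila")])

    def test_stress_de_pass_and_fail(self):
        de = pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g2"],
                "condition": ["hypoxia", "cold", "hypoxia"],
                "log2FC": [3.0, 0.1, 0.0],
                "FDR": [1e-4, 0.9, 0.5],
            }
        )
        ok, conds = filter_stress_de("g1", de)
        assert ok and conds == ["hypoxia"]
        ok2, conds2 = filter_stress_de("g2", de)
        assert not ok2 and conds2 == []


class TestTreeNesting:
    GROUPS = {
        "BacA": "prokaryote",
        "BacB": "prokaryote",
        "EukA": "eukaryote",
        "EukB": "eukaryote",
    }

    def test_query_sister_to_bacterium_with_full_support_is_nested(self):
        nwk = "(((q:0.1,BacA:0.1)100:0.1,BacB:0.2)95:0.1,(EukA:0.3,EukB:0.3)99:0.1);"
        assert tree_nesting_check(nwk, "q", self.GROUPS) == "nested"

    def test_query_inside_eukaryote_clade_is_not_nested(self):
        nwk = "(((q:0.1,EukA:0.1)100:0.1,EukB:0.2)95:0.1,(BacA:0.3,BacB:0.3)99:0.1);"
        assert tree_nesting_check(nwk, "q", self.GROUPS) == "not_nested"

    def test_low_or_missing_support_is_unresolved(self):
        low = "(((q:0.1,BacA:0.1)40:0.1,BacB:0.2)95:0.1,(EukA:0.3,EukB:0.3)99:0.1);"
        missing = "(((q:0.1,BacA:0.1):0.1,BacB:0.2)95:0.1,(EukA:0.3,EukB:0.3)99:0.1);"
        assert tree_nesting_check(low, "q", self.GROUPS) == "unresolved"
        assert tree_nesting_check(missing, "q", self.GROUPS) == "unresolved"

    def test_query_on_multifurcating_root_is_unresolved(self):
        star = "(q:0.1,BacA:0.1,BacB:0.1,EukA:0.1);"
        assert tree_nesting_check(star, "q", self.GROUPS) == "unresolved"

    def test_absent_query_rejected(self):
        with pytest.raises(DataError, match="absent"):
            tree_nesting_check("(a:1,b:1);", "q", self.GROUPS)


class TestFullScreen:
    def _run(self, bundle_inputs, truth, config=None):
        from nanohgt.architecture import classify_contigs

        _counts, status = classify_contigs(bundle_inputs["genome"])
        return run_hgt_screen(
            genome=bundle_inputs["genome"],
            genes=bundle_inputs["genes"],
            hits=bundle_inputs["hits"],
            contig_status=status,
            alignments=bundle_inputs["alignments"],
            dna_cov=bundle_inputs["dna_cov"],
            rna_cov=bundle_inputs["rna_cov"],
            de_table=bundle_inputs["de_table"],
            trees=bundle_inputs["trees"],
            panel_hits=bundle_inputs["panel_hits"],
            config=config or ScreenConfig(),
        )

    def test_final_calls_equal_planted_alien_set(self, small_bundle, bundle_inputs):
        verdicts, report = self._run(bundle_inputs, small_bundle.truth)
        assert set(report["final_calls"]) == small_bundle.truth.alien_gene_ids

    def test_ai_only_config_calls_every_ai_positive(self, small_bundle, bundle_inputs):
        cfg = ScreenConfig(enabled=())
        verdicts, report = self._run(bundle_inputs, small_bundle.truth, cfg)
        assert set(report["final_calls"]) == {v.gene_id for v in verdicts}

    def test_enabling_filters_never_adds_calls(self, small_bundle, bundle_inputs):
        chain = [
            (),
            ("telomere",),
            ("telomere", "intronless"),
            ("telomere", "intronless", "stress_de"),
            ("telomere", "intronless", "stress_de", "spanning", "coverage"),
            ScreenConfig().enabled,
        ]
        prev = None
        for enabled in chain:
            _v, report = self._run(
                bundle_inputs, small_bundle.truth, ScreenConfig(enabled=tuple(enabled))
            )
            calls = set(report["final_calls"])
            if prev is not None:
                assert calls <= prev
            prev = calls

    def test_ledger_complete_for_every_candidate(self, small_bundle, bundle_inputs):
        cfg = ScreenConfig(enabled=("telomere", "intronless"))
        verdicts, _report = self._run(bundle_inputs, small_bundle.truth, cfg)
        assert verdicts
        for v in verdicts:
            row = v.to_row()
            assert row["telomere_pass"] in (0, 1)
            assert row["intronless_pass"] in (0, 1)
            # disabled filters are explicit, never silently absent
            assert row["spanning_pass"] == "disabled"
            assert row["de_pass"] == "disabled"
            assert row["tree_verdict"] == "disabled"

    def test_missing_input_error_names_the_filter(self, small_bundle, bundle_inputs):
        from nanohgt.architecture import classify_contigs

        _counts, status = classify_contigs(bundle_inputs["genome"])
        with pytest.raises(ScreenInputError, match="stress_de"):
            run_hgt_screen(
                genome=bundle_inputs["genome"],
                genes=bundle_inputs["genes"],
                hits=bundle_inputs["hits"],
                contig_status=status,
                alignments=bundle_inputs["alignments"],
                dna_cov=bundle_inputs["dna_cov"],
                rna_cov=bundle_inputs["rna_cov"],
                de_table=None,
                trees=bundle_inputs["trees"],
                panel_hits=bundle_inputs["panel_hits"],
            )

    def test_verdicts_ordered_by_gene_id(self, small_bundle, bundle_inputs):
        verdicts, _ = self._run(bundle_inputs, small_bundle.truth)
        ids = [v.gene_id for v in verdicts]
        assert ids == sorted(ids)
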