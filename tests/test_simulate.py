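"""Synthetic bundle generator: determinism, truth consistency, separability."""

import json

import dendropy
import numpy as np
import pytest

from nanohgt import architecture, homology
from nanohgt.errors import ConfigurationError, DataError
from nanohgt.simulate import (
    SimConfig,
    SyntheticTruth,
    simulate_bundle,
    simulate_gene_tree,
    simulate_hit_table,
    simulate_mac_genome,
)


def _contig_seqs(fasta_text):
    seqs, cur = {}, None
    for line in fasta_text.splitlines():
        if line.startswith(">"):
            cur = line[1:].split()[0]
            seqs[cur] = []
        else:
            seqs[cur].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


class TestMacGenome:
    def test_forced_both_fraction_puts_telomeres_at_both_ends(self, tmp_path):
        cfg = SimConfig(n_contigs=5, n_alien=0, telomere_fractions=(1.0, 0.0, 0.0), seed=3)
        fasta, _gff, truth = simulate_mac_genome(cfg)
        assert all(s == "both" for s in truth.telomere_status_by_contig.values())
        for cid, seq in _contig_seqs(fasta).items():
            calls = architecture.scan_telomeres(architecture.Contig(cid, seq))
            assert calls[0].present and calls[1].present

    def test_status_counts_match_independent_multinomial_oracle(self):
        cfg = SimConfig(n_contigs=500, telomere_fractions=(0.5, 0.3, 0.2), n_alien=10, seed=1)
        _fa, _gff, truth = simulate_mac_genome(cfg)
        # documented sampling contract: statuses are the first draw on the
        # genome substream (spawn_key=(0,))
        rng = np.random.default_rng(np.random.SeedSequence(1, spawn_key=(0,)))
        expected = rng.choice(np.array(["both", "one", "none"]), size=500, p=np.array([0.5, 0.3, 0.2]))
        cids = sorted(truth.telomere_status_by_contig)
        got = [truth.telomere_status_by_contig[c] for c in cids]
        assert got == [str(s) for s in expected]

    def test_identical_seed_byte_identical_different_seed_differs(self):
        cfg1 = SimConfig(n_contigs=30, n_alien=2, seed=1)
        b1 = simulate_bundle(cfg1)
        b2 = simulate_bundle(SimConfig(n_contigs=30, n_alien=2, seed=1))
        for attr in ("genome_fasta", "annotation_gff3", "hits_tsv", "reads_paf",
                     "dna_bedgraph", "rna_bedgraph", "de_tsv"):
            assert getattr(b1, attr) == getattr(b2, attr)
        assert b1.trees == b2.trees
        b3 = simulate_bundle(SimConfig(n_contigs=30, n_alien=2, seed=2))
        assert b1.genome_fasta != b3.genome_fasta

    def test_truth_cross_references_emitted_files(self, small_bundle, bundle_dir):
        truth = small_bundle.truth
        gff_ids = {
            line.split("ID=")[1].split(";")[0]
            for line in small_bundle.annotation_gff3.splitlines()
            if "\tgene\t" in line
        }
        assert truth.alien_gene_ids <= gff_ids
        assert set(truth.gene_ids) == gff_ids
        seqs = _contig_seqs(small_bundle.genome_fasta)
        assert set(truth.telomere_status_by_contig) == set(seqs)
        # truth.json round-trips
        truth2 = SyntheticTruth.from_dict(json.loads((bundle_dir / "truth.json").read_text()))
        assert truth2.alien_gene_ids == truth.alien_gene_ids

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(telomere_fractions=(0.5, 0.5, 0.5))
        with pytest.raises(ConfigurationError):
            SimConfig(genes_per_contig_dist=(0.9, 0.0, 0.0))
        with pytest.raises(ConfigurationError):
            simulate_mac_genome(SimConfig(n_contigs=4, n_alien=100, seed=0))


class TestHitTable:
    def test_downstream_screen_recovers_planted_ids_exactly(self):
        cfg = SimConfig(n_contigs=110, n_alien=10, seed=7)
        _fa, _gff, truth = simulate_mac_genome(cfg)
        hits_text = simulate_hit_table(truth, seed=7)
        tmap = {t: "outgroup" for t in
                ("Desulfobacteraceae_bacterium", "Halanaerobium_praevalens",
                 "Salinibacter_ruber", "Methanohalophilus_mahii")}
        tmap.update({t: "ingroup" for t in
                     ("Saccharomyces_cerevisiae", "Arabidopsis_thaliana",
                      "Dictyostelium_discoideum", "Homo_sapiens")})
        tmap.update({t: "self_lineage" for t in ("Oxytricha_trifallax", "Stylonychia_lemnae")})
        import io
        records = homology.read_hit_table(io.StringIO(hits_text), tmap)
        results = homology.alien_index_table(records)
        assert {q for q, r in results.items() if r.is_alien} == truth.alien_gene_ids
        # every query has at least one hit row
        assert set(results) == set(truth.gene_ids)
        # margins guarantee AI beyond threshold + 1 on both sides
        for q, r in results.items():
            if q in truth.alien_gene_ids:
                assert r.ai > 0.05 + 1
            else:
                assert r.ai < -(0.05 + 1)

    def test_empty_truth_rejected(self):
        empty = SyntheticTruth([], set(), {}, {}, {}, {}, set(), set())
        with pytest.raises(DataError):
            simulate_hit_table(empty, seed=0)


class TestReadsCoverageDE:
    def test_paf_rows_respect_contig_bounds_and_support_plan(self, small_bundle):
        lengths = {k: len(v) for k, v in _contig_seqs(small_bundle.genome_fasta).items()}
        truth = small_bundle.truth
        qualifying = {cid: 0 for cid in lengths}
        for line in small_bundle.reads_paf.splitlines():
            f = line.split("\t")
            tname, tlen, ts, te = f[5], int(f[6]), int(f[7]), int(f[8])
            assert tlen == lengths[tname]
            assert 0 <= ts < te <= tlen
            if te - ts >= 0.95 * tlen and ts <= 50 and te >= tlen - 50:
                qualifying[tname] += 1
        for cid in lengths:
            if cid in truth.spanning_supported:
                assert qualifying[cid] >= small_bundle.config.spanning_reads_per_contig
            else:
                assert qualifying[cid] == 0

    def test_coverage_windows_tile_each_contig_exactly(self, small_bundle):
        lengths = {k: len(v) for k, v in _contig_seqs(small_bundle.genome_fasta).items()}
        for text in (small_bundle.dna_bedgraph, small_bundle.rna_bedgraph):
            intervals = {}
            for line in text.splitlines():
                c, s, e, _d = line.split("\t")
                intervals.setdefault(c, []).append((int(s), int(e)))
            assert set(intervals) == set(lengths)
            for cid, ivs in intervals.items():
                ivs.sort()
                assert ivs[0][0] == 0 and ivs[-1][1] == lengths[cid]
                assert all(a[1] == b[0] for a, b in zip(ivs, ivs[1:]))

    def test_de_table_one_row_per_gene_per_condition_with_margins(self, small_bundle):
        truth = small_bundle.truth
        cfg = small_bundle.config
        seen = set()
        for line in small_bundle.de_tsv.splitlines()[1:]:
            gid, cond, lfc, fdr = line.split("\t")
            assert (gid, cond) not in seen
            seen.add((gid, cond))
            lfc, fdr = float(lfc), float(fdr)
            if cond in truth.de_responders.get(gid, set()):
                assert abs(lfc) >= 2 and fdr <= 0.01
            else:
                assert abs(lfc) <= 0.2 and fdr >= 0.5
        assert len(seen) == len(truth.gene_ids) * len(cfg.de_conditions)


class TestGeneTrees:
    def test_newick_round_trips_with_expected_leaf_set(self, small_config):
        _fa, _gff, truth = simulate_mac_genome(small_config)
        gid = sorted(truth.alien_gene_ids)[0]
        nwk, groups = simulate_gene_tree(truth, gid, small_config)
        tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
        leaves = {l.taxon.label for l in tree.leaf_node_iter()}
        assert leaves == {gid} | set(groups)

    def test_topology_classes_yield_opposite_nesting_verdicts(self, small_config):
        from nanohgt.hgt_filters import tree_nesting_check

        _fa, _gff, truth = simulate_mac_genome(small_config)
        alien = sorted(truth.alien_gene_ids)[0]
        native = next(g for g, c in sorted(truth.tree_topology_class.items())
                      if c == "nested_eukaryote")
        nwk_a, groups = simulate_gene_tree(truth, alien, small_config)
        nwk_n, _ = simulate_gene_tree(truth, native, small_config)
        assert tree_nesting_check(nwk_a, alien, groups) == "nested"
        assert tree_nesting_check(nwk_n, native, groups) == "not_nested"

    def test_unknown_gene_rejected(self, small_config):
        _fa, _gff, truth = simulate_mac_genome(small_config)
        with pytest.raises(DataError):
            simulate_gene_tree(truth, "no_such_gene", small_config)
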