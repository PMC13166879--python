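"""Synthetic MAC-genome bundle generator with planted ground truth.

Emulates the inputs the analysis consumes, at desk scale: a fragmented
macronuclear assembly of telomere-capped nanochromosomes carrying 1-3 genes
each; coding genes sampled codon-by-codon under a reassignable genetic code
(ciliate nuclear by default: in-frame TAA/TAG are glutamine, every CDS ends in
TGA); a small set of planted "alien" genes with shifted GC composition,
prokaryote-dominated homology hits, no introns, stress-responsive expression
and prokaryote-nested gene trees; long-read alignments spanning supported
nanochromosomes end to end; matched DNA/RNA coverage tracks; a differential
expression table; and per-candidate gene trees.  A truth record ties every
planted feature together so downstream stages can be scored exactly.

Randomness: a single root seed is expanded into independent per-stream
substreams (genome=0, hits=1, reads=2, coverage=3, DE=4, trees=5) via
``numpy.random.SeedSequence(seed, spawn_key=(stream,))``, so adding a stream
never perturbs the others and identical config+seed yields byte-identical
output.  The first draw on the genome stream is the per-contig telomere
status vector ``rng.choice(["both","one","none"], size=n_contigs, p=fractions)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .codons import GeneticCode
from .errors import ConfigurationError, DataError

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "Bundle",
    "simulate_mac_genome",
    "simulate_hit_table",
    "simulate_panel_hits",
    "simulate_read_alignments",
    "simulate_coverage",
    "simulate_de_table",
    "simulate_gene_tree",
    "simulate_bundle",
    "write_bundle",
]

# stream indices for SeedSequence spawn keys
_GENOME, _HITS, _READS, _COVERAGE, _DE, _TREES = range(6)

STATUSES = ("both", "one", "none")

PROK_TAXA = (
    "Desulfobacteraceae_bacterium",
    "Halanaerobium_praevalens",
    "Salinibacter_ruber",
    "Methanohalophilus_mahii",
)
EUK_TAXA = (
    "Saccharomyces_cerevisiae",
    "Arabidopsis_thaliana",
    "Dictyostelium_discoideum",
    "Homo_sapiens",
)
SELF_LINEAGE_TAXA = ("Oxytricha_trifallax", "Stylonychia_lemnae")

#: Nine-species reference ciliate panel used by the lineage-exclusion filter.
CILIATE_PANEL = (
    "Oxytricha_trifallax",
    "Stylonychia_lemnae",
    "Euplotes_vannus",
    "Tetrahymena_thermophila",
    "Paramecium_tetraurelia",
    "Ichthyophthirius_multifiliis",
    "Stentor_coeruleus",
    "Fabrea_salina",
    "Pseudocohnilembus_persalinus",
)

_TREE_PROK_LEAVES = ("Desulfobacteraceae_bacterium", "Halanaerobium_praevalens", "Salinibacter_ruber")
_TREE_EUK_LEAVES = ("Saccharomyces_cerevisiae", "Arabidopsis_thaliana", "Dictyostelium_discoideum")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic bundle.

    Defaults mirror the architecture of a spirotrich MAC genome: telomere
    completeness fractions and genes-per-contig probabilities follow the
    published proportions for such assemblies (both-ends 52.54%, one-end
    32.12%; 61.53% one-gene and 25.12% two-gene contigs), mean gene length
    1495 bp, native GC 38.32%, and the ciliate nuclear code.  The alien
    composition uses a clearly shifted GC so planted transfers carry a
    compositional signal.
    """

    n_contigs: int = 500
    telomere_fractions: tuple[float, float, float] = (0.5254, 0.3212, 0.1534)
    genes_per_contig_dist: tuple[float, float, float] = (0.6153, 0.2512, 0.1335)
    mean_gene_len: int = 1495
    gc_native: float = 0.3832
    gc_alien: float = 0.55
    n_alien: int = 10
    genetic_code_id: str = "ciliate"
    telomere_unit: str = "CCCCAAAA"
    telomere_copies: int = 3
    spanning_reads_per_contig: int = 5
    de_conditions: tuple[str, ...] = ("low_temperature", "hypoxia", "high_salinity")
    frac_intronless_native: float = 0.59
    native_de_responder_frac: float = 0.10
    coverage_inconsistent_frac: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.telomere_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("telomere_fractions must sum to 1")
        if abs(sum(self.genes_per_contig_dist) - 1.0) > 1e-9:
            raise ConfigurationError("genes_per_contig_dist must sum to 1")
        if min(self.telomere_fractions) < 0 or min(self.genes_per_contig_dist) < 0:
            raise ConfigurationError("probabilities must be non-negative")
        if self.n_contigs < 1:
            raise ConfigurationError("n_contigs must be positive")
        if self.n_alien < 0:
            raise ConfigurationError("n_alien must be non-negative")
        if not 0 < self.gc_native < 1 or not 0 < self.gc_alien < 1:
            raise ConfigurationError("GC fractions must lie in (0,1)")
        if len(self.telomere_unit) != 8:
            raise ConfigurationError("telomere_unit must be 8 bp")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown simulate config keys: {sorted(unknown)}")
        for key in ("telomere_fractions", "genes_per_contig_dist", "de_conditions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated bundle."""

    gene_ids: list[str]
    alien_gene_ids: set[str]
    telomere_status_by_contig: dict[str, str]
    gene_contig: dict[str, str]
    de_responders: dict[str, set[str]]
    tree_topology_class: dict[str, str]
    spanning_supported: set[str]
    coverage_consistent: set[str]

    def to_dict(self) -> dict:
        return {
            "gene_ids": list(self.gene_ids),
            "alien_gene_ids": sorted(self.alien_gene_ids),
            "telomere_status_by_contig": dict(sorted(self.telomere_status_by_contig.items())),
            "gene_contig": dict(sorted(self.gene_contig.items())),
            "de_responders": {g: sorted(c) for g, c in sorted(self.de_responders.items())},
            "tree_topology_class": dict(sorted(self.tree_topology_class.items())),
            "spanning_supported": sorted(self.spanning_supported),
            "coverage_consistent": sorted(self.coverage_consistent),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        return cls(
            gene_ids=list(d["gene_ids"]),
            alien_gene_ids=set(d["alien_gene_ids"]),
            telomere_status_by_contig=dict(d["telomere_status_by_contig"]),
            gene_contig=dict(d["gene_contig"]),
            de_responders={g: set(c) for g, c in d["de_responders"].items()},
            tree_topology_class=dict(d["tree_topology_class"]),
            spanning_supported=set(d["spanning_supported"]),
            coverage_consistent=set(d["coverage_consistent"]),
        )


def _stream(seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, *extra)))


_BASES = np.array(list("ACGT"))


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=_base_probs(gc))])


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _codon_table(rng: np.random.Generator, code: GeneticCode, gc: float, concentration: float = 200.0):
    """Dirichlet-smoothed codon frequency table over the sense codons.

    Base weights are the product of per-base probabilities at the target GC;
    one Dirichlet draw centred on those weights gives each genome a slightly
    individual, but seeded, codon bias.
    """
    sense = np.array(code.sense_codons)
    probs = _base_probs(gc)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    w = np.array([np.prod([probs[base_idx[b]] for b in c]) for c in sense])
    w = w / w.sum()
    table = rng.dirichlet(concentration * w)
    return sense, table


def _sample_cds(rng, sense, table, n_codons: int, code: GeneticCode) -> str:
    body = "".join(sense[rng.choice(len(sense), size=n_codons - 2, p=table)])
    stops = code.stop_codons
    if len(stops) == 1:
        stop = stops[0]
    else:
        probs = np.ones(len(stops)) / len(stops)
        stop = stops[rng.choice(len(stops), p=probs)]
    return "ATG" + body + stop


@dataclass
class _GenePlan:
    gene_id: str
    contig_id: str
    alien: bool
    strand: str
    cds: str
    exon_cds_splits: list[int]  # CDS bp offsets where introns are inserted
    intron_lens: list[int]


@dataclass
class Bundle:
    """All emitted texts plus the truth record, held in memory."""

    config: SimConfig
    genome_fasta: str
    annotation_gff3: str
    hits_tsv: str
    taxon_map_tsv: str
    panel_hits_tsv: str
    reads_paf: str
    dna_bedgraph: str
    rna_bedgraph: str
    de_tsv: str
    trees: dict[str, str]  # gene_id -> newick
    tree_groups_tsv: str
    truth: SyntheticTruth


def simulate_mac_genome(config: SimConfig) -> tuple[str, str, SyntheticTruth]:
    """Generate the assembly (FASTA), annotation (GFF3) and truth record.

    Contigs receive telomeric repeat runs at 0, 1 or 2 ends per their sampled
    status; genes are drawn under the configured genetic code (in-frame
    TAA/TAG permitted as sense codons under the ciliate preset, terminal codon
    drawn from the code's stop set — always TGA for the ciliate code); alien
    genes use the shifted-GC composition, are intronless, and are placed on
    both-telomere contigs so that downstream structural filters can pass them.
    """
    rng = _stream(config.seed, _GENOME)
    code = GeneticCode.preset(config.genetic_code_id)

    # draw 1: per-contig telomere status (documented sampling contract)
    statuses = rng.choice(np.array(STATUSES), size=config.n_contigs, p=np.array(config.telomere_fractions))
    # draw 2: genes per contig (category "3+" realized as exactly 3 genes;
    # the published distributions do not constrain the tail)
    gene_counts = rng.choice(np.array([1, 2, 3]), size=config.n_contigs, p=np.array(config.genes_per_contig_dist))

    contig_ids = [f"ctg{i + 1:05d}" for i in range(config.n_contigs)]
    both_contigs = [cid for cid, st in zip(contig_ids, statuses) if st == "both"]
    total_genes = int(gene_counts.sum())
    if config.n_alien > total_genes:
        raise ConfigurationError(
            f"n_alien={config.n_alien} exceeds total planted genes {total_genes}"
        )
    if config.n_alien > len(both_contigs):
        raise ConfigurationError(
            f"n_alien={config.n_alien} exceeds the {len(both_contigs)} contigs "
            "with both telomeres available to host alien genes"
        )
    alien_hosts = set(
        rng.choice(np.array(both_contigs), size=config.n_alien, replace=False)
    ) if config.n_alien else set()

    sense_nat, table_nat = _codon_table(rng, code, config.gc_native)
    sense_ali, table_ali = _codon_table(rng, code, config.gc_alien)

    mean_codons = max(20, config.mean_gene_len // 3)
    telo5 = config.telomere_unit * config.telomere_copies
    telo3 = _revcomp(config.telomere_unit) * config.telomere_copies

    fasta_lines: list[str] = []
    gff_lines: list[str] = ["##gff-version 3"]
    truth = SyntheticTruth(
        gene_ids=[],
        alien_gene_ids=set(),
        telomere_status_by_contig={},
        gene_contig={},
        de_responders={},
        tree_topology_class={},
        spanning_supported=set(),
        coverage_consistent=set(),
    )

    for cid, status, n_genes in zip(contig_ids, statuses, gene_counts):
        truth.telomere_status_by_contig[cid] = str(status)
        is_alien_host = cid in alien_hosts

        plans: list[_GenePlan] = []
        for k in range(int(n_genes)):
            gid = f"{cid}.g{k + 1}"
            alien = is_alien_host and k == 0
            n_codons = max(60, int(round(rng.normal(mean_codons, mean_codons / 4))))
            if alien:
                cds = _sample_cds(rng, sense_ali, table_ali, n_codons, code)
                splits, introns = [], []
            else:
                cds = _sample_cds(rng, sense_nat, table_nat, n_codons, code)
                if rng.random() < config.frac_intronless_native:
                    splits, introns = [], []
                else:
                    n_exons = 2 + int(rng.poisson(0.83))
                    cut_candidates = np.arange(30, len(cds) - 30)
                    n_cuts = min(n_exons - 1, len(cut_candidates))
                    splits = sorted(
                        int(x) for x in rng.choice(cut_candidates, size=n_cuts, replace=False)
                    )
                    introns = [max(50, int(round(rng.normal(78, 8)))) for _ in splits]
            strand = "+" if rng.random() < 0.5 else "-"
            plans.append(_GenePlan(gid, cid, alien, strand, cds, splits, introns))
            truth.gene_ids.append(gid)
            truth.gene_contig[gid] = cid
            if alien:
                truth.alien_gene_ids.add(gid)

        # assemble the contig sequence and record exon coordinates
        pieces: list[str] = []
        pos = 0
        if status == "one":
            one_end_is_5p = rng.random() < 0.5
        if status == "both" or (status == "one" and one_end_is_5p):
            pieces.append(telo5)
            pos += len(telo5)
        gene_records = []  # (plan, exons genomic 0-based half-open ascending)
        for plan in plans:
            spacer = _random_dna(rng, int(rng.integers(60, 200)), config.gc_native)
            pieces.append(spacer)
            pos += len(spacer)
            # exon pieces of the CDS in sense orientation, introns interleaved
            bounds = [0] + plan.exon_cds_splits + [len(plan.cds)]
            exon_seqs = [plan.cds[a:b] for a, b in zip(bounds, bounds[1:])]
            block_parts: list[str] = []
            exon_local: list[tuple[int, int]] = []
            cursor = 0
            for i, ex in enumerate(exon_seqs):
                exon_local.append((cursor, cursor + len(ex)))
                block_parts.append(ex)
                cursor += len(ex)
                if i < len(plan.intron_lens):
                    ilen = plan.intron_lens[i]
                    block_parts.append(_random_dna(rng, ilen, config.gc_native))
                    cursor += ilen
            block = "".join(block_parts)
            if plan.strand == "-":
                block = _revcomp(block)
                L = len(block)
                exon_local = sorted((L - e, L - s) for s, e in exon_local)
            exons = [(pos + s, pos + e) for s, e in exon_local]
            pieces.append(block)
            pos += len(block)
            gene_records.append((plan, exons))
        tail_spacer = _random_dna(rng, int(rng.integers(60, 200)), config.gc_native)
        pieces.append(tail_spacer)
        pos += len(tail_spacer)
        if status == "both" or (status == "one" and not one_end_is_5p):
            pieces.append(telo3)
            pos += len(telo3)
        seq = "".join(pieces)

        fasta_lines.append(f">{cid}")
        for i in range(0, len(seq), 60):
            fasta_lines.append(seq[i : i + 60])

        for plan, exons in gene_records:
            gff_lines.extend(_gff_gene_lines(cid, plan, exons))

        if status == "both":
            truth.spanning_supported.add(cid)

    # coverage-consistency plan (drawn on the genome stream so the truth record
    # is complete after this call; the coverage stream only adds noise)
    non_alien_contigs = [c for c in contig_ids if c not in alien_hosts]
    n_bad = int(round(config.coverage_inconsistent_frac * len(non_alien_contigs)))
    bad = set(rng.choice(np.array(non_alien_contigs), size=n_bad, replace=False)) if n_bad else set()
    truth.coverage_consistent = set(contig_ids) - bad

    # DE responders: every alien gene responds in >=1 condition; a background
    # fraction of native genes responds too (stress regulons are not HGT-only)
    conditions = list(config.de_conditions)
    for gid in truth.gene_ids:
        if gid in truth.alien_gene_ids:
            k = 1 + int(rng.integers(0, len(conditions)))
            chosen = rng.choice(np.array(conditions), size=k, replace=False)
            truth.de_responders[gid] = set(str(c) for c in chosen)
        elif rng.random() < config.native_de_responder_frac:
            chosen = rng.choice(np.array(conditions), size=1, replace=False)
            truth.de_responders[gid] = set(str(c) for c in chosen)

    # gene trees: every alien gene nests inside a prokaryote clade; a few
    # native genes get eukaryote-nested trees for contrast
    for gid in sorted(truth.alien_gene_ids):
        truth.tree_topology_class[gid] = "nested_prokaryote"
    natives = [g for g in truth.gene_ids if g not in truth.alien_gene_ids]
    for gid in natives[:3]:
        truth.tree_topology_class[gid] = "nested_eukaryote"

    return "\n".join(fasta_lines) + "\n", "\n".join(gff_lines) + "\n", truth


def _gff_gene_lines(cid: str, plan: _GenePlan, exons: list[tuple[int, int]]) -> list[str]:
    """GFF3 rows (1-based closed) for one gene: gene/mRNA/exon/CDS with phase."""
    gid = plan.gene_id
    start = exons[0][0] + 1
    end = exons[-1][1]
    lines = [
        f"{cid}\tnanohgt_sim\tgene\t{start}\t{end}\t.\t{plan.strand}\t.\tID={gid}",
        f"{cid}\tnanohgt_sim\tmRNA\t{start}\t{end}\t.\t{plan.strand}\t.\tID={gid}.t1;Parent={gid}",
    ]
    for i, (s, e) in enumerate(exons, 1):
        lines.append(
            f"{cid}\tnanohgt_sim\texon\t{s + 1}\t{e}\t.\t{plan.strand}\t.\t"
            f"ID={gid}.t1.exon{i};Parent={gid}.t1"
        )
    # CDS phase follows transcript order: descending genomic order on '-'
    tx_order = exons if plan.strand == "+" else list(reversed(exons))
    cum = 0
    phases = []
    for s, e in tx_order:
        phases.append((3 - cum % 3) % 3)
        cum += e - s
    if plan.strand == "-":
        phases = list(reversed(phases))
    for i, ((s, e), ph) in enumerate(zip(exons, phases), 1):
        lines.append(
            f"{cid}\tnanohgt_sim\tCDS\t{s + 1}\t{e}\t.\t{plan.strand}\t{ph}\t"
            f"ID={gid}.t1.cds{i};Parent={gid}.t1"
        )
    return lines


# ---------------------------------------------------------------------------
# homology hits


@dataclass(frozen=True)
class HitMarginParams:
    """E-value margins controlling Alien Index separability.

    Margins are log10 units between best ingroup and best outgroup E-values.
    The default minimum margin of 5 guarantees |AI| = margin * ln(10) > 11,
    far beyond threshold + 1, so the downstream screen separates planted
    classes with certainty.
    """

    margin_log10: tuple[float, float] = (5.0, 40.0)
    best_exponent: tuple[float, float] = (20.0, 60.0)
    self_lineage_prob: float = 0.2
    native_missing_outgroup_prob: float = 0.3


def _hit_row(rng, query, subject, evalue, taxon) -> str:
    pident = rng.uniform(25, 90)
    length = int(rng.integers(100, 400))
    mismatch = int(round(length * (1 - pident / 100)))
    bitscore = 50 + 2 * max(0.0, -math.log10(evalue + 1e-300))
    qs = int(rng.integers(1, 50))
    return "\t".join(
        [
            query, subject, f"{pident:.1f}", str(length), str(mismatch), "0",
            str(qs), str(qs + length - 1), "1", str(length),
            f"{evalue:.3e}", f"{bitscore:.1f}", taxon,
        ]
    )


def simulate_hit_table(
    truth: SyntheticTruth,
    params: HitMarginParams = HitMarginParams(),
    seed: int = 0,
) -> str:
    """Taxon-annotated homology hit table (12 BLAST columns + taxon label).

    Alien genes get their best outgroup (prokaryote) E-value smaller than the
    best ingroup (eukaryote) E-value by the configured log10 margin, and vice
    versa for native genes, so AI separates the classes by construction.
    Every query has at least one hit row.
    """
    if not truth.gene_ids:
        raise DataError("truth record lists no genes")
    rng = _stream(seed, _HITS)
    lo_m, hi_m = params.margin_log10
    lo_e, hi_e = params.best_exponent
    rows: list[str] = []
    for gid in truth.gene_ids:
        alien = gid in truth.alien_gene_ids
        best_exp = rng.uniform(lo_e, hi_e)
        margin = rng.uniform(lo_m, hi_m)
        weak_exp = max(1.0, best_exp - margin)
        if alien:
            # strong prokaryote hits, weak eukaryote hits
            n_prok = int(rng.integers(2, 5))
            for j in range(n_prok):
                e = 10 ** -(best_exp - rng.uniform(0, 3) * min(j, 1))
                taxon = str(rng.choice(np.array(PROK_TAXA)))
                rows.append(_hit_row(rng, gid, f"prok_hom_{gid}_{j}", e, taxon))
            for j in range(int(rng.integers(1, 3))):
                e = 10 ** -(weak_exp - rng.uniform(0, min(2.0, weak_exp - 0.5)))
                taxon = str(rng.choice(np.array(EUK_TAXA)))
                rows.append(_hit_row(rng, gid, f"euk_hom_{gid}_{j}", e, taxon))
        else:
            n_euk = int(rng.integers(1, 4))
            for j in range(n_euk):
                e = 10 ** -(best_exp - rng.uniform(0, 3) * min(j, 1))
                taxon = str(rng.choice(np.array(EUK_TAXA)))
                rows.append(_hit_row(rng, gid, f"euk_hom_{gid}_{j}", e, taxon))
            if rng.random() > params.native_missing_outgroup_prob:
                e = 10 ** -(weak_exp - rng.uniform(0, min(2.0, weak_exp - 0.5)))
                taxon = str(rng.choice(np.array(PROK_TAXA)))
                rows.append(_hit_row(rng, gid, f"prok_hom_{gid}_0", e, taxon))
        if rng.random() < params.self_lineage_prob:
            e = 10 ** -rng.uniform(30, 80)
            taxon = str(rng.choice(np.array(SELF_LINEAGE_TAXA)))
            rows.append(_hit_row(rng, gid, f"self_hom_{gid}", e, taxon))
    return "\n".join(rows) + "\n"


def taxon_map_tsv() -> str:
    """Static taxon -> group map covering every taxon the simulator emits."""
    lines = [f"{t}\toutgroup" for t in PROK_TAXA]
    lines += [f"{t}\tingroup" for t in EUK_TAXA]
    lines += [f"{t}\tself_lineage" for t in SELF_LINEAGE_TAXA]
    return "\n".join(lines) + "\n"


def simulate_panel_hits(truth: SyntheticTruth, seed: int = 0) -> str:
    """Hits against the nine-ciliate reference panel.

    Native genes are broadly conserved across ciliates (strong hits in several
    panel species); planted alien genes are absent from the panel, which is
    exactly what the lineage-exclusion filter keys on.
    """
    rng = _stream(seed, _HITS, 1)
    rows: list[str] = []
    for gid in truth.gene_ids:
        if gid in truth.alien_gene_ids:
            continue
        n_species = int(rng.integers(3, len(CILIATE_PANEL) + 1))
        species = rng.choice(np.array(CILIATE_PANEL), size=n_species, replace=False)
        for sp in species:
            e = 10 ** -rng.uniform(20, 80)
            rows.append(_hit_row(rng, gid, f"{sp}_hom_{gid}", e, str(sp)))
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# read alignments, coverage, DE, trees


def _contig_lengths(genome_fasta: str) -> dict[str, int]:
    lengths: dict[str, int] = {}
    cur = None
    for line in genome_fasta.splitlines():
        if line.startswith(">"):
            cur = line[1:].split()[0]
            lengths[cur] = 0
        elif cur is not None:
            lengths[cur] += len(line.strip())
    if not lengths:
        raise DataError("empty genome FASTA")
    return lengths


def simulate_read_alignments(genome_fasta: str, truth: SyntheticTruth, config: SimConfig) -> str:
    """PAF alignments: spanning reads for supported contigs, partial otherwise.

    Supported contigs (those with both telomeres) get
    ``spanning_reads_per_contig`` alignments each covering >=95% of the contig
    with both ends within 50 bp of the termini; other contigs get only
    partial alignments that fail the downstream spanning test.
    """
    lengths = _contig_lengths(genome_fasta)
    rng = _stream(config.seed, _READS)
    rows: list[str] = []
    read_no = 0
    for cid in lengths:
        tlen = lengths[cid]
        if cid in truth.spanning_supported:
            trim_max = max(1, min(20, int(0.02 * tlen)))
            for _ in range(config.spanning_reads_per_contig):
                read_no += 1
                ts = int(rng.integers(0, trim_max))
                te = tlen - int(rng.integers(0, trim_max))
                alen = te - ts
                nmatch = int(alen * rng.uniform(0.9, 0.99))
                rows.append(
                    f"read{read_no:06d}\t{alen + 40}\t10\t{10 + alen}\t+\t"
                    f"{cid}\t{tlen}\t{ts}\t{te}\t{nmatch}\t{alen}\t60"
                )
        else:
            for _ in range(2):
                read_no += 1
                frac = rng.uniform(0.3, 0.6)
                alen = max(50, int(tlen * frac))
                ts = int(rng.integers(0, max(1, tlen - alen)))
                te = ts + alen
                nmatch = int(alen * rng.uniform(0.9, 0.99))
                rows.append(
                    f"read{read_no:06d}\t{alen + 40}\t10\t{10 + alen}\t+\t"
                    f"{cid}\t{tlen}\t{ts}\t{te}\t{nmatch}\t{alen}\t60"
                )
    return "\n".join(rows) + "\n"


def simulate_coverage(
    genome_fasta: str, truth: SyntheticTruth, config: SimConfig, window: int = 100
) -> tuple[str, str]:
    """DNA and RNA bedGraph tracks tiling every contig in ``window`` bp bins.

    Consistent contigs share a latent per-window profile so the two tracks are
    strongly rank-correlated; inconsistent contigs get a zeroed RNA track.
    Coordinates are 0-based half-open and tile each contig exactly.
    """
    lengths = _contig_lengths(genome_fasta)
    rng = _stream(config.seed, _COVERAGE)
    dna_rows: list[str] = []
    rna_rows: list[str] = []
    for cid, tlen in lengths.items():
        n_win = (tlen + window - 1) // window
        latent = rng.uniform(0.5, 1.5, size=n_win)
        dna_base = rng.uniform(30, 60)
        rna_base = rng.uniform(10, 40)
        dna = dna_base * latent * (1 + rng.normal(0, 0.02, size=n_win))
        consistent = cid in truth.coverage_consistent
        if consistent:
            rna = rna_base * latent * (1 + rng.normal(0, 0.02, size=n_win))
        else:
            rna = np.zeros(n_win)
        for i in range(n_win):
            s = i * window
            e = min(s + window, tlen)
            dna_rows.append(f"{cid}\t{s}\t{e}\t{max(0.0, dna[i]):.2f}")
            rna_rows.append(f"{cid}\t{s}\t{e}\t{max(0.0, rna[i]):.2f}")
    return "\n".join(dna_rows) + "\n", "\n".join(rna_rows) + "\n"


def simulate_de_table(truth: SyntheticTruth, config: SimConfig) -> str:
    """Differential-expression table: one row per gene per condition.

    Responders get |log2FC| >= 2 at FDR <= 0.01 in their responding
    conditions; all other rows are null (|log2FC| <= 0.2, FDR >= 0.5).
    """
    if not config.de_conditions:
        raise ConfigurationError("de_conditions must be non-empty")
    rng = _stream(config.seed, _DE)
    rows = ["gene_id\tcondition\tlog2FC\tFDR"]
    for gid in truth.gene_ids:
        responding = truth.de_responders.get(gid, set())
        for cond in config.de_conditions:
            if cond in responding:
                lfc = rng.uniform(2, 6) * (1 if rng.random() < 0.7 else -1)
                fdr = 10 ** -rng.uniform(3, 8)
            else:
                lfc = rng.uniform(-0.2, 0.2)
                fdr = rng.uniform(0.5, 1.0)
            rows.append(f"{gid}\t{cond}\t{lfc:.3f}\t{fdr:.3e}")
    return "\n".join(rows) + "\n"


def simulate_gene_tree(
    truth: SyntheticTruth, gene_id: str, config: SimConfig
) -> tuple[str, dict[str, str]]:
    """Newick gene tree for one candidate plus its leaf -> group map.

    For ``nested_prokaryote`` the query's smallest enclosing clade contains
    only prokaryote leaves with support >= 90; for ``nested_eukaryote`` the
    query nests among eukaryote leaves instead.  Seeding is per-gene (derived
    from the root seed and the gene's index) so trees are reproducible
    independent of generation order.
    """
    if gene_id not in truth.tree_topology_class:
        raise DataError(f"gene {gene_id!r} has no tree topology class in truth")
    idx = truth.gene_ids.index(gene_id)
    rng = _stream(config.seed, _TREES, idx)

    def bl() -> str:
        return f"{rng.uniform(0.05, 0.4):.3f}"

    def sup() -> int:
        return int(rng.integers(90, 101))

    p1, p2, p3 = _TREE_PROK_LEAVES
    e1, e2, e3 = _TREE_EUK_LEAVES
    topo = truth.tree_topology_class[gene_id]
    if topo == "nested_prokaryote":
        newick = (
            f"((({gene_id}:{bl()},{p1}:{bl()}){sup()}:{bl()},"
            f"({p2}:{bl()},{p3}:{bl()}){sup()}:{bl()}){sup()}:{bl()},"
            f"({e1}:{bl()},({e2}:{bl()},{e3}:{bl()}){sup()}:{bl()}){sup()}:{bl()});"
        )
    else:
        newick = (
            f"((({gene_id}:{bl()},{e1}:{bl()}){sup()}:{bl()},"
            f"({e2}:{bl()},{e3}:{bl()}){sup()}:{bl()}){sup()}:{bl()},"
            f"({p1}:{bl()},({p2}:{bl()},{p3}:{bl()}){sup()}:{bl()}){sup()}:{bl()});"
        )
    groups = {l: "prokaryote" for l in _TREE_PROK_LEAVES}
    groups.update({l: "eukaryote" for l in _TREE_EUK_LEAVES})
    return newick, groups


# ---------------------------------------------------------------------------
# bundle assembly


def simulate_bundle(config: SimConfig) -> Bundle:
    """Generate the complete input bundle in memory."""
    fasta, gff, truth = simulate_mac_genome(config)
    hits = simulate_hit_table(truth, seed=config.seed)
    panel = simulate_panel_hits(truth, seed=config.seed)
    paf = simulate_read_alignments(fasta, truth, config)
    dna_bg, rna_bg = simulate_coverage(fasta, truth, config)
    de = simulate_de_table(truth, config)
    trees: dict[str, str] = {}
    groups: dict[str, str] = {}
    for gid in sorted(truth.tree_topology_class):
        nwk, g = simulate_gene_tree(truth, gid, config)
        trees[gid] = nwk
        groups.update(g)
    groups_tsv = "".join(f"{leaf}\t{grp}\n" for leaf, grp in sorted(groups.items()))
    return Bundle(
        config=config,
        genome_fasta=fasta,
        annotation_gff3=gff,
        hits_tsv=hits,
        taxon_map_tsv=taxon_map_tsv(),
        panel_hits_tsv=panel,
        reads_paf=paf,
        dna_bedgraph=dna_bg,
        rna_bedgraph=rna_bg,
        de_tsv=de,
        trees=trees,
        tree_groups_tsv=groups_tsv,
        truth=truth,
    )


BUNDLE_FILENAMES = {
    "genome_fasta": "genome.fasta",
    "annotation_gff3": "annotation.gff3",
    "hits_tsv": "hits.tsv",
    "taxon_map_tsv": "taxon_map.tsv",
    "panel_hits_tsv": "panel_hits.tsv",
    "reads_paf": "reads.paf",
    "dna_bedgraph": "dna_coverage.bedgraph",
    "rna_bedgraph": "rna_coverage.bedgraph",
    "de_tsv": "de.tsv",
    "tree_groups_tsv": "tree_groups.tsv",
}


def write_bundle(config: SimConfig, outdir) -> dict[str, Path]:
    """Generate a bundle and write every file under ``outdir``.

    Returns a name -> path map; trees go under ``trees/<gene_id>.nwk`` and the
    truth record to ``truth.json``.
    """
    bundle = simulate_bundle(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for attr, fname in BUNDLE_FILENAMES.items():
        p = outdir / fname
        p.write_text(getattr(bundle, attr))
        paths[attr] = p
    tree_dir = outdir / "trees"
    tree_dir.mkdir(exist_ok=True)
    for gid, nwk in bundle.trees.items():
        (tree_dir / f"{gid}.nwk").write_text(nwk + "\n")
    paths["trees"] = tree_dir
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(bundle.truth.to_dict(), indent=1, sort_keys=True) + "\n")
    paths["truth"] = truth_path
    return paths
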