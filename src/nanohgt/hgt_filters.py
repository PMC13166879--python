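"""Validation cascade for horizontally-transferred gene candidates.

Alien-Index-positive genes pass through a series of stringent structural,
expression and phylogenetic filters before a final HGT call, mirroring how
transfers into a fragmented MAC genome are validated in practice:

* the host nanochromosome must carry telomeres at both ends (a complete,
  endogenous chromosome rather than a contaminant fragment);
* multiple long reads must span the entire nanochromosome end to end;
* DNA- and RNA-level coverage must be consistent along the contig;
* the candidate must be intronless (introns argue for native origin);
* the candidate must be absent from a panel of reference ciliate proteomes;
* the candidate must be differentially expressed under at least one stress;
* the candidate must nest inside a well-supported prokaryotic clade of its
  gene tree.

The final call is the strict conjunction of every enabled filter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .architecture import Contig, GeneModel, TelomereParams
from .errors import DataError, ScreenInputError
from .homology import HitRecord, alien_index_table

__all__ = [
    "PafRecord",
    "CoverageTrack",
    "CandidateVerdict",
    "ScreenConfig",
    "read_paf",
    "read_sam",
    "read_alignments",
    "read_bedgraph",
    "read_de_table",
    "filter_telomere_flanked",
    "filter_spanning_reads",
    "filter_dna_rna_consistency",
    "filter_intronless",
    "filter_ciliate_homologs",
    "filter_stress_de",
    "tree_nesting_check",
    "run_hgt_screen",
]


# ---------------------------------------------------------------------------
# input readers


@dataclass(frozen=True)
class PafRecord:
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alnlen: int
    mapq: int


def read_paf(path) -> list[PafRecord]:
    """Read the 12 mandatory PAF columns (extra tag columns ignored)."""
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise DataError(f"PAF {path}: line {i} has {len(parts)} columns (<12)")
            try:
                records.append(
                    PafRecord(
                        parts[0], int(parts[1]), int(parts[2]), int(parts[3]),
                        parts[4], parts[5], int(parts[6]), int(parts[7]),
                        int(parts[8]), int(parts[9]), int(parts[10]), int(parts[11]),
                    )
                )
            except ValueError as exc:
                raise DataError(f"PAF {path}: malformed line {i}: {exc}") from exc
    return records


def read_sam(path) -> list[PafRecord]:
    """Read a SAM file (for real long-read data) into PAF-equivalent records."""
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_name is None:
                continue
            tlen = sam.get_reference_length(aln.reference_name)
            records.append(
                PafRecord(
                    qname=aln.query_name or "?",
                    qlen=aln.infer_read_length() or 0,
                    qstart=aln.query_alignment_start,
                    qend=aln.query_alignment_end,
                    strand="-" if aln.is_reverse else "+",
                    tname=aln.reference_name,
                    tlen=tlen,
                    tstart=aln.reference_start,
                    tend=aln.reference_end or aln.reference_start,
                    nmatch=0,
                    alnlen=(aln.reference_end or aln.reference_start) - aln.reference_start,
                    mapq=aln.mapping_quality,
                )
            )
    return records


def read_alignments(path) -> list[PafRecord]:
    """Dispatch on file extension: .paf (native) or .sam."""
    suffix = Path(path).suffix.lower()
    if suffix == ".sam":
        return read_sam(path)
    return read_paf(path)


@dataclass(frozen=True)
class CoverageTrack:
    """Windowed depths tiling one contig."""

    contig: str
    starts: tuple[int, ...]
    ends: tuple[int, ...]
    depths: tuple[float, ...]
    source: str = "DNA"

    def __post_init__(self):
        if any(d < 0 for d in self.depths):
            raise DataError(f"coverage track {self.contig}: negative depth")
        for i in range(1, len(self.starts)):
            if self.starts[i] != self.ends[i - 1]:
                raise DataError(f"coverage track {self.contig}: windows do not tile")


def read_bedgraph(path, source: str = "DNA") -> dict[str, CoverageTrack]:
    """Read a bedGraph (0-based half-open) into per-contig coverage tracks."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "start", "end", "depth"], comment="#"
    )
    tracks: dict[str, CoverageTrack] = {}
    for contig, sub in df.groupby("contig", sort=False):
        sub = sub.sort_values("start")
        tracks[str(contig)] = CoverageTrack(
            str(contig),
            tuple(int(x) for x in sub["start"]),
            tuple(int(x) for x in sub["end"]),
            tuple(float(x) for x in sub["depth"]),
            source,
        )
    return tracks


def read_de_table(path) -> pd.DataFrame:
    """Read the DE results table (gene_id, condition, log2FC, FDR)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "condition", "log2FC", "FDR"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"DE table {path} missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# individual filters


def filter_telomere_flanked(gene: GeneModel, status_map: Mapping[str, str]) -> bool:
    """Pass iff the gene's contig carries telomeres at both ends."""
    if gene.contig_id not in status_map:
        raise DataError(f"contig {gene.contig_id!r} of gene {gene.id} is unclassified")
    return status_map[gene.contig_id] == "both"


def filter_spanning_reads(
    contig_id: str,
    contig_len: int,
    alignments: Sequence[PafRecord],
    min_reads: int = 3,
    min_cov_frac: float = 0.95,
    end_slack: int = 50,
) -> tuple[int, bool]:
    """Count reads spanning the whole nanochromosome.

    A read spans iff its target interval covers >= ``min_cov_frac`` of the
    contig, starts within ``end_slack`` bp of position 0 and ends within
    ``end_slack`` bp of the contig end.  Contigs absent from the alignment
    set count zero and fail.
    """
    count = 0
    for rec in alignments:
        if rec.tname != contig_id:
            continue
        if (
            rec.tend - rec.tstart >= min_cov_frac * contig_len
            and rec.tstart <= end_slack
            and rec.tend >= contig_len - end_slack
        ):
            count += 1
    return count, count >= min_reads


def filter_dna_rna_consistency(
    contig_id: str,
    dna: CoverageTrack,
    rna: CoverageTrack,
    min_rho: float = 0.5,
    min_rna_breadth: float = 0.8,
    cds_intervals: Sequence[tuple[int, int]] | None = None,
) -> tuple[float, float, bool]:
    """Spearman consistency of DNA vs RNA windowed depth plus RNA breadth.

    ``rho`` is the Spearman correlation over matched windows; ``breadth`` is
    the fraction of CDS-overlapping windows (all windows when no CDS intervals
    are given) with RNA depth > 0.  A constant track makes rho undefined
    (reported as NaN) and the verdict is then decided by breadth alone.
    """
    if dna.starts != rna.starts or dna.ends != rna.ends:
        raise DataError(f"contig {contig_id}: DNA and RNA windows differ")
    d = np.asarray(dna.depths)
    r = np.asarray(rna.depths)
    if cds_intervals:
        mask = np.zeros(len(d), dtype=bool)
        for s, e in cds_intervals:
            for i, (ws, we) in enumerate(zip(dna.starts, dna.ends)):
                if ws < e and s < we:
                    mask[i] = True
    else:
        mask = np.ones(len(d), dtype=bool)
    breadth = float((r[mask] > 0).mean()) if mask.any() else 0.0
    if np.all(d == d[0]) or np.all(r == r[0]) or len(d) < 3:
        rho = float("nan")
        ok = breadth >= min_rna_breadth
    else:
        rho = float(spearmanr(d, r).statistic)
        ok = rho >= min_rho and breadth >= min_rna_breadth
    return rho, breadth, ok


def filter_intronless(gene: GeneModel) -> bool:
    """Pass iff the gene has a single exon (no introns)."""
    return gene.n_exons == 1


def filter_ciliate_homologs(
    gene_id: str,
    panel_hits: Sequence[HitRecord],
    max_evalue: float = 1e-5,
    max_species: int = 0,
) -> bool:
    """Pass iff at most ``max_species`` reference-panel species hit the gene.

    A species counts as hit when it has >= 1 hit at E <= ``max_evalue``
    (boundary E-values count as hits).  Excludes genes broadly conserved
    across ciliate lineages, which cannot be recent transfers into this one.
    """
    species = {h.taxon_label for h in panel_hits if h.query == gene_id and h.evalue <= max_evalue}
    return len(species) <= max_species


def filter_stress_de(
    gene_id: str,
    de_table: pd.DataFrame,
    min_abs_log2fc: float = 1.0,
    max_fdr: float = 0.05,
) -> tuple[bool, list[str]]:
    """Pass iff the gene responds in >= 1 stress condition.

    Returns the pass flag and the list of supporting conditions with
    |log2FC| >= ``min_abs_log2fc`` and FDR <= ``max_fdr``.
    """
    sub = de_table[de_table["gene_id"] == gene_id]
    hits = sub[(sub["log2FC"].abs() >= min_abs_log2fc) & (sub["FDR"] <= max_fdr)]
    conditions = sorted(hits["condition"].astype(str))
    return bool(conditions), conditions


def tree_nesting_check(
    newick: str,
    query: str,
    leaf_groups: Mapping[str, str],
    min_support: float = 70.0,
) -> str:
    """Is the query nested inside a well-supported prokaryotic clade?

    Examines the smallest clade containing the query leaf and at least one
    other leaf.  Returns ``nested`` if every non-query leaf in that clade is
    in the prokaryote group and the clade's support >= ``min_support``;
    ``unresolved`` if the clade has no parseable support, its support is below
    threshold, or the query hangs off the root of a star-like tree;
    ``not_nested`` otherwise.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == query:
            leaf = lf
            break
    if leaf is None:
        raise DataError(f"query leaf {query!r} absent from tree")
    node = leaf.parent_node
    while node is not None:
        others = [
            l.taxon.label
            for l in node.leaf_iter()
            if l.taxon is not None and l.taxon.label != query
        ]
        if others:
            break
        node = node.parent_node
    if node is None or not others:
        return "unresolved"
    if node is tree.seed_node:
        # the smallest enclosing clade is the whole tree: no outgroup context
        return "unresolved"
    support = None
    if node.label is not None:
        try:
            support = float(node.label)
        except ValueError:
            support = None
    if support is None or support < min_support:
        return "unresolved"
    groups = {leaf_groups.get(l) for l in others}
    return "nested" if groups == {"prokaryote"} else "not_nested"


# ---------------------------------------------------------------------------
# orchestration


FILTER_NAMES = (
    "telomere",
    "spanning",
    "coverage",
    "intronless",
    "ciliate_panel",
    "stress_de",
    "tree",
)


@dataclass(frozen=True)
class ScreenConfig:
    """Toggles and thresholds for the full screen.

    ``min_spanning_reads=3`` operationalizes "multiple" spanning reads;
    ``end_slack=50`` bp tolerates terminal soft-clipping of long reads.
    Disabling a filter records "disabled" in the ledger and removes it from
    the conjunction.
    """

    ai_threshold: float = 0.05
    enabled: tuple[str, ...] = FILTER_NAMES
    min_spanning_reads: int = 3
    min_cov_frac: float = 0.95
    end_slack: int = 50
    min_rho: float = 0.5
    min_rna_breadth: float = 0.8
    min_abs_log2fc: float = 1.0
    max_fdr: float = 0.05
    panel_max_evalue: float = 1e-5
    panel_max_species: int = 0
    tree_min_support: float = 70.0
    telomere_params: TelomereParams = field(default_factory=TelomereParams)

    def __post_init__(self):
        unknown = set(self.enabled) - set(FILTER_NAMES)
        if unknown:
            raise DataError(f"unknown filters enabled: {sorted(unknown)}")

    def is_enabled(self, name: str) -> bool:
        return name in self.enabled


@dataclass
class CandidateVerdict:
    """Per-candidate ledger of every filter outcome and the final call.

    The final call is the conjunction of the AI screen and every enabled
    filter (the tree filter contributes a pass only on a "nested" verdict).
    Disabled filters are recorded as ``None`` flags / "disabled" in TSV.
    """

    gene_id: str
    ai: float
    ai_pass: bool
    telomere_pass: bool | None = None
    spanning_reads: int | None = None
    spanning_pass: bool | None = None
    dna_rna_rho: float | None = None
    rna_breadth: float | None = None
    coverage_pass: bool | None = None
    intronless_pass: bool | None = None
    ciliate_absent_pass: bool | None = None
    de_pass: bool | None = None
    de_conditions: list[str] = field(default_factory=list)
    tree_verdict: str | None = None
    final_call: bool = False

    def compute_final_call(self, config: ScreenConfig) -> bool:
        flags = [self.ai_pass]
        if config.is_enabled("telomere"):
            flags.append(bool(self.telomere_pass))
        if config.is_enabled("spanning"):
            flags.append(bool(self.spanning_pass))
        if config.is_enabled("coverage"):
            flags.append(bool(self.coverage_pass))
        if config.is_enabled("intronless"):
            flags.append(bool(self.intronless_pass))
        if config.is_enabled("ciliate_panel"):
            flags.append(bool(self.ciliate_absent_pass))
        if config.is_enabled("stress_de"):
            flags.append(bool(self.de_pass))
        if config.is_enabled("tree"):
            flags.append(self.tree_verdict == "nested")
        self.final_call = all(flags)
        return self.final_call

    def to_row(self) -> dict:
        def fmt(v):
            if v is None:
                return "disabled"
            if isinstance(v, bool):
                return int(v)
            if isinstance(v, float):
                return "NA" if math.isnan(v) else round(v, 4)
            return v

        return {
            "gene_id": self.gene_id,
            "ai": round(self.ai, 4),
            "ai_pass": int(self.ai_pass),
            "telomere_pass": fmt(self.telomere_pass),
            "spanning_reads": fmt(self.spanning_reads),
            "spanning_pass": fmt(self.spanning_pass),
            "dna_rna_rho": fmt(self.dna_rna_rho),
            "rna_breadth": fmt(self.rna_breadth),
            "coverage_pass": fmt(self.coverage_pass),
            "intronless_pass": fmt(self.intronless_pass),
            "ciliate_absent_pass": fmt(self.ciliate_absent_pass),
            "de_pass": fmt(self.de_pass),
            "de_conditions": ",".join(self.de_conditions) or ".",
            "tree_verdict": self.tree_verdict if self.tree_verdict is not None else "disabled",
            "final_call": int(self.final_call),
        }


def run_hgt_screen(
    genome: Mapping[str, Contig],
    genes: Sequence[GeneModel],
    hits: Sequence[HitRecord],
    contig_status: Mapping[str, str],
    alignments: Sequence[PafRecord] | None = None,
    dna_cov: Mapping[str, CoverageTrack] | None = None,
    rna_cov: Mapping[str, CoverageTrack] | None = None,
    de_table: pd.DataFrame | None = None,
    trees: Mapping[str, tuple[str, Mapping[str, str]]] | None = None,
    panel_hits: Sequence[HitRecord] | None = None,
    config: ScreenConfig = ScreenConfig(),
) -> tuple[list[CandidateVerdict], dict]:
    """Run the full HGT screen: AI candidacy followed by the filter cascade.

    Candidates are the AI-positive genes; each receives a complete per-filter
    ledger (disabled filters recorded explicitly) and a conjunctive final
    call, in deterministic gene_id order.  Raises
    :class:`~nanohgt.errors.ScreenInputError` naming the first enabled filter
    whose input is missing.
    """
    if config.is_enabled("spanning") and alignments is None:
        raise ScreenInputError("spanning", "no read alignments provided")
    if config.is_enabled("coverage") and (dna_cov is None or rna_cov is None):
        raise ScreenInputError("coverage", "DNA and RNA coverage tracks required")
    if config.is_enabled("stress_de") and de_table is None:
        raise ScreenInputError("stress_de", "no DE table provided")
    if config.is_enabled("tree") and trees is None:
        raise ScreenInputError("tree", "no gene trees provided")
    if config.is_enabled("ciliate_panel") and panel_hits is None:
        raise ScreenInputError("ciliate_panel", "no reference-panel hits provided")

    genes_by_id = {g.id: g for g in genes}
    ai_results = alien_index_table(hits, threshold=config.ai_threshold)

    candidates = sorted(q for q, r in ai_results.items() if r.is_alien)
    verdicts: list[CandidateVerdict] = []
    attrition = {"candidates": len(candidates)}
    for name in FILTER_NAMES:
        attrition[name] = 0

    for gid in candidates:
        if gid not in genes_by_id:
            raise DataError(f"AI-positive query {gid!r} absent from the annotation")
        gene = genes_by_id[gid]
        contig = genome.get(gene.contig_id)
        if contig is None:
            raise DataError(f"gene {gid}: unknown contig {gene.contig_id!r}")
        v = CandidateVerdict(gene_id=gid, ai=ai_results[gid].ai, ai_pass=True)

        if config.is_enabled("telomere"):
            v.telomere_pass = filter_telomere_flanked(gene, contig_status)
            attrition["telomere"] += int(not v.telomere_pass)
        if config.is_enabled("spanning"):
            v.spanning_reads, v.spanning_pass = filter_spanning_reads(
                gene.contig_id,
                contig.length,
                alignments,
                config.min_spanning_reads,
                config.min_cov_frac,
                config.end_slack,
            )
            attrition["spanning"] += int(not v.spanning_pass)
        if config.is_enabled("coverage"):
            dtrack = dna_cov.get(gene.contig_id)
            rtrack = rna_cov.get(gene.contig_id)
            if dtrack is None or rtrack is None:
                raise ScreenInputError("coverage", f"no track for contig {gene.contig_id}")
            v.dna_rna_rho, v.rna_breadth, v.coverage_pass = filter_dna_rna_consistency(
                gene.contig_id,
                dtrack,
                rtrack,
                config.min_rho,
                config.min_rna_breadth,
                cds_intervals=gene.cds,
            )
            attrition["coverage"] += int(not v.coverage_pass)
        if config.is_enabled("intronless"):
            v.intronless_pass = filter_intronless(gene)
            attrition["intronless"] += int(not v.intronless_pass)
        if config.is_enabled("ciliate_panel"):
            v.ciliate_absent_pass = filter_ciliate_homologs(
                gid, panel_hits, config.panel_max_evalue, config.panel_max_species
            )
            attrition["ciliate_panel"] += int(not v.ciliate_absent_pass)
        if config.is_enabled("stress_de"):
            v.de_pass, v.de_conditions = filter_stress_de(
                gid, de_table, config.min_abs_log2fc, config.max_fdr
            )
            attrition["stress_de"] += int(not v.de_pass)
        if config.is_enabled("tree"):
            if gid not in trees:
                v.tree_verdict = "unresolved"
            else:
                nwk, groups = trees[gid]
                v.tree_verdict = tree_nesting_check(nwk, gid, groups, config.tree_min_support)
            attrition["tree"] += int(v.tree_verdict != "nested")

        v.compute_final_call(config)
        verdicts.append(v)

    attrition["final_calls"] = sum(1 for v in verdicts if v.final_call)
    report = {
        "n_queries": len(ai_results),
        "attrition": attrition,
        "final_calls": sorted(v.gene_id for v in verdicts if v.final_call),
        "enabled_filters": list(config.enabled),
    }
    return verdicts, report


def write_verdicts_tsv(path, verdicts: Sequence[CandidateVerdict]) -> None:
    rows = [v.to_row() for v in verdicts]
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=list(CandidateVerdict("x", 0.0, False).to_row()))
    df.to_csv(path, sep="\t", index=False)


def write_report_json(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
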