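"""Nanochromosome architecture: parsing, telomere scanning, assembly statistics.

Spirotrich ciliate macronuclear (MAC) genomes are extremely fragmented:
"gene-sized" nanochromosomes of roughly 1-3.5 kbp, each carrying 1-2 genes and
capped at both ends by short telomeric repeats (C-rich strand ``CCCCAAAA``,
G-rich strand ``TTTTGGGG``).  This module parses a MAC assembly (FASTA) and its
annotation (GFF3), detects telomeric repeat runs at contig termini, classifies
contigs by telomere completeness (both / one / none ends capped), and computes
the standard assembly- and gene-architecture statistics used to describe such
genomes (N50/L50, GC content, GC skew in sliding windows, genes per contig,
exon/intron structure, gene density).

Coordinates are 0-based half-open internally; conversion to/from the 1-based
closed GFF3 convention happens only at the file boundary.
"""

from __future__ import annotations

import json
import statistics
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import DataError

__all__ = [
    "Contig",
    "TelomereCall",
    "TelomereParams",
    "GeneModel",
    "AssemblyStats",
    "GeneArchStats",
    "read_fasta",
    "read_gff3",
    "scan_telomeres",
    "classify_contigs",
    "assembly_stats",
    "gc_skew_windows",
    "gene_architecture_stats",
]

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

#: Spirotrich telomeric repeat, C-rich strand.
DEFAULT_TELOMERE_UNIT = "CCCCAAAA"


@dataclass(frozen=True)
class Contig:
    """A nanochromosome-scale assembly contig."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self):
        if not self.seq:
            raise DataError(f"contig {self.id!r} has empty sequence")


@dataclass(frozen=True)
class TelomereCall:
    """Outcome of scanning one contig terminus for a telomeric repeat run."""

    contig_id: str
    end: str  # five_prime | three_prime
    present: bool
    unit: str
    copies: int
    offset_from_terminus: int


@dataclass(frozen=True)
class TelomereParams:
    """Detection settings for :func:`scan_telomeres`.

    ``min_copies=2`` and ``window=50`` reproduce canonical short spirotrich
    telomere tracts; matching is rotation-tolerant because assembly breakpoints
    do not respect repeat-unit phase.
    """

    unit: str = DEFAULT_TELOMERE_UNIT
    min_copies: int = 2
    window: int = 50
    max_mismatch_per_unit: int = 0


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon/CDS intervals in internal 0-based half-open coordinates."""

    id: str
    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise DataError(f"gene {self.id}: bad strand {self.strand!r}")
        if not self.exons:
            raise DataError(f"gene {self.id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise DataError(f"gene {self.id}: degenerate exon ({s},{e})")
            if s < prev_end:
                raise DataError(f"gene {self.id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def intron_lengths(self) -> list[int]:
        return [self.exons[i + 1][0] - self.exons[i][1] for i in range(self.n_introns)]


@dataclass(frozen=True)
class AssemblyStats:
    total_bp: int
    n_contigs: int
    gc_fraction: float
    n50: int
    l50: int
    median_contig_len: float
    telomere_counts: dict[str, int] | None = None

    def to_dict(self) -> dict:
        d = {
            "total_bp": self.total_bp,
            "n_contigs": self.n_contigs,
            "gc_fraction": self.gc_fraction,
            "n50": self.n50,
            "l50": self.l50,
            "median_contig_len": self.median_contig_len,
        }
        if self.telomere_counts is not None:
            d["telomere_counts"] = dict(self.telomere_counts)
        return d


@dataclass(frozen=True)
class GeneArchStats:
    n_genes: int
    genes_per_contig_hist: dict[int, int]
    frac_one_gene: float
    frac_two_genes: float
    mean_exons_per_gene: float
    median_exon_len: float
    median_intron_len: float | None
    frac_intronless: float
    gene_density_per_mbp: float

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["genes_per_contig_hist"] = {str(k): v for k, v in self.genes_per_contig_hist.items()}
        return d


# ---------------------------------------------------------------------------
# parsing


def read_fasta(path) -> dict[str, Contig]:
    """Read a FASTA assembly into an ordered ``id -> Contig`` map.

    Raises :class:`DataError` on duplicate contig IDs.
    """
    contigs: dict[str, Contig] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise DataError(f"duplicate contig ID {rec.id!r}")
        contigs[rec.id] = Contig(rec.id, str(rec.seq).upper())
    if not contigs:
        raise DataError(f"no FASTA records in {path}")
    return contigs


_KNOWN_FEATURES = {"gene", "mRNA", "exon", "CDS"}


def read_gff3(path, contig_lengths: Mapping[str, int] | None = None) -> list[GeneModel]:
    """Parse a GFF3 annotation into :class:`GeneModel` records.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    Feature types other than gene/mRNA/exon/CDS are ignored with a warning.
    When ``contig_lengths`` is given, exon/CDS intervals are bounds-checked and
    a :class:`DataError` naming the offending gene is raised on violation.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    unknown = {ft for ft in db.featuretypes() if ft not in _KNOWN_FEATURES}
    if unknown:
        warnings.warn(f"ignoring unknown GFF3 feature types: {sorted(unknown)}")

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(g, featuretype="exon")
        )
        cds = sorted((f.start - 1, f.end) for f in db.children(g, featuretype="CDS"))
        if not exons:  # single-feature gene rows
            exons = [(g.start - 1, g.end)]
        if not cds:
            cds = list(exons)
        gm = GeneModel(g.id, g.seqid, g.strand, tuple(exons), tuple(cds))
        if contig_lengths is not None:
            if g.seqid not in contig_lengths:
                raise DataError(f"gene {g.id}: unknown contig {g.seqid!r}")
            clen = contig_lengths[g.seqid]
            for s, e in list(gm.exons) + list(gm.cds):
                if e > clen:
                    raise DataError(
                        f"gene {g.id}: interval ({s},{e}) exceeds contig "
                        f"{g.seqid} length {clen}"
                    )
        genes.append(gm)
    return genes


# ---------------------------------------------------------------------------
# telomere scanning


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _rotations(unit: str) -> list[str]:
    return [unit[i:] + unit[:i] for i in range(len(unit))]


def _count_tandem_copies(seq: str, start: int, pattern: str, max_mm: int) -> int:
    """Number of consecutive copies of ``pattern`` starting at ``start``,
    allowing up to ``max_mm`` mismatches per copy."""
    k = len(pattern)
    n = 0
    pos = start
    while pos + k <= len(seq):
        mm = sum(a != b for a, b in zip(seq[pos : pos + k], pattern))
        if mm > max_mm:
            break
        n += 1
        pos += k
    return n


def _scan_one_side(seq: str, patterns: Sequence[str], params: TelomereParams) -> tuple[bool, int, int]:
    """Scan for a qualifying run whose start lies within ``window`` of seq[0].

    Returns (present, copies, offset).  The earliest qualifying start wins;
    among patterns at that start the longest run is reported.
    """
    window = min(params.window, len(seq))
    for j in range(window + 1):
        best = 0
        for pat in patterns:
            c = _count_tandem_copies(seq, j, pat, params.max_mismatch_per_unit)
            if c > best:
                best = c
        if best >= params.min_copies:
            return True, best, j
    return False, 0, 0


def scan_telomeres(
    contig: Contig, params: TelomereParams = TelomereParams()
) -> tuple[TelomereCall, TelomereCall]:
    """Detect telomeric repeat runs at both termini of a contig.

    An end is called present iff a tandem run of at least ``min_copies``
    unit-periodic copies — of the C-rich unit, its G-rich reverse complement,
    or any rotation of either — begins (5' end) or ends (3' end) within
    ``window`` bp of that terminus.  Both orientations are tested at both ends,
    so the call set is invariant under reverse-complementing the contig.
    """
    if len(params.unit) != 8:
        raise DataError(f"telomere unit must be 8 bp, got {params.unit!r}")
    if params.window > contig.length:
        warnings.warn(
            f"telomere window {params.window} exceeds contig {contig.id} "
            f"length {contig.length}; clamping"
        )
    seq = contig.seq.upper()
    fwd_patterns = _rotations(params.unit.upper()) + _rotations(_revcomp(params.unit.upper()))
    present5, copies5, off5 = _scan_one_side(seq, fwd_patterns, params)
    # 3' end: a run must END within `window` of the terminus; scan the reversed
    # sequence with reversed patterns (reversal, not complementation, because
    # both orientations are already in the pattern set).
    rev_patterns = [p[::-1] for p in fwd_patterns]
    present3, copies3, off3 = _scan_one_side(seq[::-1], rev_patterns, params)
    return (
        TelomereCall(contig.id, FIVE_PRIME, present5, params.unit, copies5, off5),
        TelomereCall(contig.id, THREE_PRIME, present3, params.unit, copies3, off3),
    )


def classify_contigs(
    genome: Mapping[str, Contig], params: TelomereParams = TelomereParams()
) -> tuple[dict[str, int], dict[str, str]]:
    """Assign each contig a telomere status in {both, one, none}.

    Returns (counts, per-contig status map); the three classes partition the
    contig set so counts always sum to ``len(genome)``.
    """
    if not genome:
        raise DataError("empty genome")
    status: dict[str, str] = {}
    for cid, contig in genome.items():
        c5, c3 = scan_telomeres(contig, params)
        n = int(c5.present) + int(c3.present)
        status[cid] = {2: "both", 1: "one", 0: "none"}[n]
    counts = Counter(status.values())
    return {"both": counts.get("both", 0), "one": counts.get("one", 0), "none": counts.get("none", 0)}, status


# ---------------------------------------------------------------------------
# assembly and gene statistics


def assembly_stats(
    genome: Mapping[str, Contig], telomere_counts: dict[str, int] | None = None
) -> AssemblyStats:
    """Whole-assembly statistics.

    N50 is the length L of the contig at which the cumulative length of
    contigs sorted in descending order first reaches half the total; L50 is
    the number of contigs in that prefix.  GC is (G+C)/(A+C+G+T): ambiguous
    bases (N) are excluded from the denominator.
    """
    if not genome:
        raise DataError("empty genome")
    lengths = np.array(sorted((c.length for c in genome.values()), reverse=True))
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    idx = int(np.searchsorted(cum, total / 2))
    n50 = int(lengths[idx])
    l50 = idx + 1

    base_counts: Counter[str] = Counter()
    for c in genome.values():
        base_counts.update(c.seq.upper())
    acgt = sum(base_counts[b] for b in "ACGT")
    gc = (base_counts["G"] + base_counts["C"]) / acgt if acgt else 0.0

    return AssemblyStats(
        total_bp=total,
        n_contigs=len(genome),
        gc_fraction=gc,
        n50=n50,
        l50=l50,
        median_contig_len=float(np.median(lengths)),
        telomere_counts=telomere_counts,
    )


@dataclass(frozen=True)
class SkewWindow:
    start: int
    end: int
    skew: float
    undefined: bool = False


def gc_skew_windows(contig: Contig, window: int = 20000, step: int = 5000) -> list[SkewWindow]:
    """GC skew (G-C)/(G+C) in sliding windows.

    Tail windows shorter than ``window`` are reported with their true span;
    windows with no G or C get skew 0 flagged as undefined.
    """
    if not (window >= step > 0):
        raise DataError("require window >= step > 0")
    seq = contig.seq.upper()
    out = []
    for start in range(0, len(seq), step):
        end = min(start + window, len(seq))
        chunk = seq[start:end]
        g = chunk.count("G")
        c = chunk.count("C")
        if g + c == 0:
            out.append(SkewWindow(start, end, 0.0, undefined=True))
        else:
            out.append(SkewWindow(start, end, (g - c) / (g + c)))
    return out


def gene_architecture_stats(
    genes: Sequence[GeneModel],
    genome: Mapping[str, Contig],
    ncrna_count: int = 0,
) -> GeneArchStats:
    """Gene-structure statistics over an annotated assembly.

    ``frac_one_gene`` / ``frac_two_genes`` are fractions among gene-bearing
    contigs.  Intronless means single-exon.  Gene density optionally includes a
    non-coding RNA count: density = (n_genes + ncrna_count) / (total bp / 1e6);
    the default ``ncrna_count=0`` counts protein-coding genes only.
    """
    if not genes:
        raise DataError("no genes")
    for g in genes:
        if g.contig_id not in genome:
            raise DataError(f"gene {g.id}: unknown contig {g.contig_id!r}")
    per_contig = Counter(g.contig_id for g in genes)
    hist = Counter(per_contig.values())
    n_bearing = len(per_contig)
    exon_lens = [e - s for g in genes for s, e in g.exons]
    intron_lens = [il for g in genes for il in g.intron_lengths()]
    total_bp = sum(c.length for c in genome.values())
    return GeneArchStats(
        n_genes=len(genes),
        genes_per_contig_hist=dict(sorted(hist.items())),
        frac_one_gene=hist.get(1, 0) / n_bearing,
        frac_two_genes=hist.get(2, 0) / n_bearing,
        mean_exons_per_gene=sum(g.n_exons for g in genes) / len(genes),
        median_exon_len=float(statistics.median(exon_lens)),
        median_intron_len=float(statistics.median(intron_lens)) if intron_lens else None,
        frac_intronless=sum(1 for g in genes if g.n_exons == 1) / len(genes),
        gene_density_per_mbp=(len(genes) + ncrna_count) / (total_bp / 1e6),
    )


def write_contig_table(
    path,
    genome: Mapping[str, Contig],
    status: Mapping[str, str],
    genes: Iterable[GeneModel] = (),
) -> None:
    """Per-contig TSV: id, length, gc, telo5, telo3, n_genes."""
    per_contig = Counter(g.contig_id for g in genes)
    with open(path, "w") as fh:
        fh.write("contig_id\tlength\tgc\ttelo5\ttelo3\tn_genes\n")
        for cid, c in genome.items():
            seq = c.seq.upper()
            acgt = sum(seq.count(b) for b in "ACGT")
            gc = (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0
            # the status map has no per-end detail; rescanning is cheap
            c5, c3 = scan_telomeres(c)
            fh.write(f"{cid}\t{c.length}\t{gc:.4f}\t{int(c5.present)}\t{int(c3.present)}\t{per_contig.get(cid, 0)}\n")


def write_stats_json(path, stats: AssemblyStats, arch: GeneArchStats | None = None) -> None:
    payload: dict = {"assembly": stats.to_dict()}
    if arch is not None:
        payload["genes"] = arch.to_dict()
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
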