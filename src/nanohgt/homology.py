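"""Taxon-annotated homology tables, Alien Index screening, identity profiling.

The Alien Index (AI) contrasts a query's best homology hit among ingroup taxa
(here: eukaryotes outside the recipient's own lineage) with its best hit among
outgroup taxa (prokaryotes):

    AI = ln(bbh_ingroup + eps) - ln(bbh_outgroup + eps)

where bbh_* is the smallest E-value among that group's hits (``missing_evalue``
when a group has no hit at all) and ``eps`` is a pseudocount guarding against
ln(0).  Large positive AI means the query resembles prokaryotic proteins far
more than eukaryotic ones — the primary screen for horizontally transferred
genes.  Queries passing the screen are then profiled by optimal global
(Needleman-Wunsch, affine gap) percent identity against homolog panels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import DataError

__all__ = [
    "HitRecord",
    "AlienIndexResult",
    "IdentityProfile",
    "read_hit_table",
    "read_taxon_map",
    "alien_index",
    "alien_index_table",
    "global_align",
    "identity_profile",
    "GROUPS",
]

GROUPS = ("ingroup", "outgroup", "self_lineage", "other")

#: BLAST/DIAMOND -outfmt 6 default columns.
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HitRecord:
    query: str
    subject: str
    pident: float
    aln_len: int
    evalue: float
    bitscore: float
    taxon_label: str
    group: str

    def __post_init__(self):
        if self.evalue < 0:
            raise DataError(f"hit {self.query}->{self.subject}: negative E-value")
        if self.group not in GROUPS:
            raise DataError(f"hit {self.query}->{self.subject}: bad group {self.group!r}")


@dataclass(frozen=True)
class AlienIndexResult:
    query: str
    best_ingroup_evalue: float
    best_outgroup_evalue: float
    ai: float
    is_alien: bool
    no_evidence: bool = False


@dataclass(frozen=True)
class IdentityProfile:
    candidate: str
    per_group: Mapping[str, tuple[float, float]]  # group -> (min, max) % identity


def read_taxon_map(path) -> dict[str, str]:
    """Read a two-column TSV mapping taxon label -> group."""
    df = pd.read_csv(path, sep="\t", header=None, names=["taxon", "group"], comment="#")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise DataError(f"taxon map contains unknown groups: {sorted(bad)}")
    return dict(zip(df["taxon"], df["group"]))


def read_hit_table(path, taxon_map: Mapping[str, str]) -> list[HitRecord]:
    """Parse a 12-column BLAST/DIAMOND tabular file with a 13th taxon column.

    Taxa absent from ``taxon_map`` are assigned group "other" with a warning;
    malformed rows raise :class:`DataError` naming the line number.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - I/O failure path
        raise DataError(f"cannot read hit table {path}: {exc}") from exc
    if df.shape[1] < 13:
        raise DataError(
            f"hit table {path} has {df.shape[1]} columns; need 12 BLAST columns + taxon"
        )
    records: list[HitRecord] = []
    unmapped: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            pident = float(row[2])
            aln_len = int(row[3])
            evalue = float(row[10])
            bitscore = float(row[11])
        except (TypeError, ValueError) as exc:
            raise DataError(f"hit table {path}: malformed row at line {i}: {exc}") from exc
        taxon = str(row[12])
        group = taxon_map.get(taxon)
        if group is None:
            unmapped.add(taxon)
            group = "other"
        records.append(
            HitRecord(str(row[0]), str(row[1]), pident, aln_len, evalue, bitscore, taxon, group)
        )
    if unmapped:
        warnings.warn(f"taxa not in taxon map assigned to 'other': {sorted(unmapped)[:10]}")
    return records


def alien_index(
    hits: Sequence[HitRecord],
    threshold: float = 0.05,
    missing_evalue: float = 1.0,
    pseudocount: float = 1e-200,
    exclude_self_lineage: bool = True,
) -> AlienIndexResult:
    """Alien Index for the hits of a single query.

    Hits flagged ``self_lineage`` are excluded by default so that the
    recipient's own close relatives cannot mask a transfer.  With no hits in
    either informative group the result carries AI=0 and ``no_evidence``.
    """
    if not hits:
        raise DataError("alien_index requires at least one hit")
    queries = {h.query for h in hits}
    if len(queries) != 1:
        raise DataError(f"alien_index got hits from multiple queries: {sorted(queries)}")
    usable = [h for h in hits if not (exclude_self_lineage and h.group == "self_lineage")]
    in_hits = [h.evalue for h in usable if h.group == "ingroup"]
    out_hits = [h.evalue for h in usable if h.group == "outgroup"]
    query = hits[0].query
    if not in_hits and not out_hits:
        return AlienIndexResult(query, missing_evalue, missing_evalue, 0.0, False, no_evidence=True)
    bbh_in = min(in_hits) if in_hits else missing_evalue
    bbh_out = min(out_hits) if out_hits else missing_evalue
    ai = math.log(bbh_in + pseudocount) - math.log(bbh_out + pseudocount)
    return AlienIndexResult(query, bbh_in, bbh_out, ai, ai > threshold)


def alien_index_table(
    records: Iterable[HitRecord], **kwargs
) -> dict[str, AlienIndexResult]:
    """Alien Index per query over a full hit table, keyed and ordered by query."""
    by_query: dict[str, list[HitRecord]] = {}
    for h in records:
        by_query.setdefault(h.query, []).append(h)
    return {q: alien_index(by_query[q], **kwargs) for q in sorted(by_query)}


# ---------------------------------------------------------------------------
# global alignment


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float


def _build_matrix(matrix_name: str):
    m = substitution_matrices.load(matrix_name)
    if "X" in m.alphabet:
        # unknown residues are uninformative: score them neutrally
        m = m.copy()
        for a in m.alphabet:
            m["X", a] = 0.0
            m[a, "X"] = 0.0
    return m


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal global alignment with affine gaps.

    A gap of length L costs ``gap_open + (L-1) * gap_extend``; end gaps are
    penalized (true Needleman-Wunsch).  Percent identity counts identical
    columns over the full alignment length, gap columns included in the
    denominator.  Among co-optimal alignments the first traceback reported by
    the aligner is used, which is deterministic for fixed inputs.
    """
    if not a or not b:
        raise DataError("global_align requires non-empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _build_matrix(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    try:
        alns = aligner.align(a.upper(), b.upper())
    except ValueError as exc:
        raise DataError(f"alignment failed: {exc}") from exc
    best = alns[0]
    ga, gb = str(best[0]), str(best[1])
    ident = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    pid = 100.0 * ident / len(ga)
    return AlignmentResult(ga, gb, float(best.score), pid)


def identity_profile(
    candidate: str,
    candidate_seq: str,
    homologs_by_group: Mapping[str, Mapping[str, str]],
    **align_kwargs,
) -> IdentityProfile:
    """Min/max global percent identity of a candidate against grouped homologs.

    Empty groups are omitted with a warning.  This is the profiling used to
    contrast a transfer candidate's similarity to prokaryotic versus eukaryotic
    homolog panels.
    """
    per_group: dict[str, tuple[float, float]] = {}
    for group, seqs in homologs_by_group.items():
        if not seqs:
            warnings.warn(f"identity_profile: empty homolog group {group!r} omitted")
            continue
        idents = [
            global_align(candidate_seq, s, **align_kwargs).percent_identity
            for _, s in sorted(seqs.items())
        ]
        per_group[group] = (min(idents), max(idents))
    return IdentityProfile(candidate, per_group)


def write_ai_table(path, results: Mapping[str, AlienIndexResult]) -> None:
    """Write AI results as TSV (query, bbh_in, bbh_out, ai, is_alien)."""
    with open(path, "w") as fh:
        fh.write("query\tbbh_ingroup\tbbh_outgroup\tai\tis_alien\n")
        for q in sorted(results):
            r = results[q]
            fh.write(
                f"{q}\t{r.best_ingroup_evalue:.3e}\t{r.best_outgroup_evalue:.3e}"
                f"\t{r.ai:.6f}\t{int(r.is_alien)}\n"
            )
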