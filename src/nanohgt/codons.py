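"""Codon usage under reassignable genetic codes.

Many ciliates deviate from the standard nuclear code: in the ciliate nuclear
code (NCBI translation table 6) the canonical stops TAA and TAG are reassigned
to glutamine and TGA is the only functional stop.  This module extracts CDS
sequences from an annotated assembly, tallies codons (terminal stop codons
kept separate from internal sense codons), computes relative synonymous codon
usage (RSCU) under an arbitrary code, and infers from the data which of the
three canonical stop codons actually behave as stops — high terminal usage
with near-zero in-frame occurrence marks a stop; frequent in-frame occurrence
marks a reassigned sense codon.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .architecture import Contig, GeneModel
from .errors import DataError

__all__ = [
    "GeneticCode",
    "StopUsageReport",
    "extract_cds",
    "codon_counts",
    "rscu",
    "infer_stop_usage",
    "CANONICAL_STOPS",
]

STOP = "*"
CANONICAL_STOPS = ("TAA", "TAG", "TGA")
_ALL_CODONS = ["".join(p) for p in product("TCAG", repeat=3)]


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon -> amino acid table; stops are ``'*'``."""

    id: str
    table: Mapping[str, str]

    def __post_init__(self):
        if set(self.table) != set(_ALL_CODONS):
            raise DataError(f"genetic code {self.id!r} must map exactly 64 codons")
        if STOP not in self.table.values():
            raise DataError(f"genetic code {self.id!r} has no stop codon")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in _ALL_CODONS if self.table[c] == STOP)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in _ALL_CODONS if self.table[c] != STOP)

    def families(self) -> dict[str, tuple[str, ...]]:
        """Synonymous families: amino acid -> codons (stops excluded)."""
        fam: dict[str, list[str]] = {}
        for c in _ALL_CODONS:
            aa = self.table[c]
            if aa != STOP:
                fam.setdefault(aa, []).append(c)
        return {aa: tuple(cs) for aa, cs in fam.items()}

    @classmethod
    def from_ncbi(cls, table_id: int, label: str | None = None) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(t.forward_table)
        for s in t.stop_codons:
            table[s] = STOP
        return cls(label or t.names[0].lower().replace(" ", "_"), table)

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls.from_ncbi(1, "standard")

    @classmethod
    def ciliate(cls) -> "GeneticCode":
        """Ciliate nuclear code: TAA/TAG -> Gln, TGA the only stop."""
        code = cls.from_ncbi(6, "ciliate")
        assert code.table["TAA"] == "Q" and code.table["TAG"] == "Q"
        assert code.stop_codons == ("TGA",)
        return code

    @classmethod
    def preset(cls, name: str) -> "GeneticCode":
        try:
            return {"standard": cls.standard, "ciliate": cls.ciliate}[name]()
        except KeyError:
            raise DataError(f"unknown genetic code preset {name!r}") from None


def extract_cds(
    genome: Mapping[str, Contig],
    genes: Sequence[GeneModel],
) -> tuple[dict[str, str], list[str]]:
    """Extract spliced CDS per gene.

    Minus-strand genes are exon-joined in ascending genomic order and then
    reverse-complemented, which yields the transcript-order CDS.  Genes whose
    CDS length is not a multiple of 3 are flagged (second return value) and
    excluded from the returned map, with a warning.
    """
    out: dict[str, str] = {}
    flagged: list[str] = []
    for g in genes:
        if g.contig_id not in genome:
            raise DataError(f"gene {g.id}: unknown contig {g.contig_id!r}")
        seq = genome[g.contig_id].seq
        parts = [seq[s:e] for s, e in g.cds]
        cds = "".join(parts)
        if g.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        if len(cds) % 3 != 0:
            flagged.append(g.id)
            continue
        out[g.id] = cds.upper()
    if flagged:
        warnings.warn(
            f"{len(flagged)} CDS with length not a multiple of 3 excluded: "
            f"{flagged[:5]}{'...' if len(flagged) > 5 else ''}"
        )
    return out, flagged


def codon_counts(cds_map: Mapping[str, str]) -> tuple[Counter, Counter]:
    """Tally codons over a CDS set.

    Returns ``(internal, terminal)``: the last codon of each CDS goes to the
    terminal tally (it reflects stop usage, not synonymous choice), all others
    to the internal tally.  Internal total is sum(len/3 - 1); terminal total
    equals the number of CDS.
    """
    internal: Counter[str] = Counter()
    terminal: Counter[str] = Counter()
    for gid, cds in cds_map.items():
        if len(cds) % 3 != 0:
            raise DataError(f"CDS {gid} length {len(cds)} not a multiple of 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        internal.update(codons[:-1])
        terminal[codons[-1]] += 1
    return internal, terminal


def rscu(counts: Mapping[str, int], code: GeneticCode) -> dict[str, float]:
    """Relative synonymous codon usage.

    RSCU_c = n_fam * x_c / sum(x over the synonymous family); families with a
    zero total get RSCU 0 for every member (flagged via warning).  Stop codons
    are not part of any family.
    """
    for c, n in counts.items():
        if n < 0:
            raise DataError(f"negative count for codon {c}")
        if len(c) != 3 or c not in code.table:
            raise DataError(f"codon {c!r} not in genetic code {code.id!r}")
    out: dict[str, float] = {}
    zero_families = []
    for aa, fam in code.families().items():
        total = sum(counts.get(c, 0) for c in fam)
        if total == 0:
            zero_families.append(aa)
            for c in fam:
                out[c] = 0.0
        else:
            n_fam = len(fam)
            for c in fam:
                out[c] = n_fam * counts.get(c, 0) / total
    if zero_families:
        warnings.warn(f"families with zero total count: {sorted(zero_families)}")
    return out


@dataclass(frozen=True)
class StopUsageReport:
    """Per canonical stop codon: terminal usage, in-frame density, class.

    ``f_terminal`` is the fraction of CDS ending in the codon; ``d_inframe``
    is non-terminal occurrences per 1000 internal codons; classification is
    one of stop / sense / ambiguous.
    """

    per_codon: Mapping[str, dict]
    n_cds: int
    n_internal_codons: int

    @property
    def stop_set(self) -> frozenset[str]:
        return frozenset(
            c for c, d in self.per_codon.items() if d["classification"] == "stop"
        )

    def to_dict(self) -> dict:
        return {
            "per_codon": {c: dict(d) for c, d in self.per_codon.items()},
            "n_cds": self.n_cds,
            "n_internal_codons": self.n_internal_codons,
            "stop_set": sorted(self.stop_set),
        }


def infer_stop_usage(
    genome: Mapping[str, Contig],
    genes: Sequence[GeneModel],
    tau_term: float = 0.05,
    delta_stop: float = 0.2,
    delta_sense: float = 1.0,
) -> StopUsageReport:
    """Infer which canonical stop codons function as stops.

    A codon is classified ``stop`` if f_terminal >= ``tau_term`` and its
    in-frame density is <= ``delta_stop`` per 1000 codons; ``sense`` if the
    density is >= ``delta_sense``; otherwise ``ambiguous``.  On a genome using
    the ciliate nuclear code this yields stop set {TGA} with TAA/TAG sense.
    """
    cds_map, _ = extract_cds(genome, genes)
    if not cds_map:
        raise DataError("no in-frame CDS to analyze")
    internal, terminal = codon_counts(cds_map)
    n_cds = sum(terminal.values())
    n_internal = sum(internal.values())
    per_codon = {}
    for c in CANONICAL_STOPS:
        f_term = terminal.get(c, 0) / n_cds
        d_inframe = 1000.0 * internal.get(c, 0) / n_internal if n_internal else 0.0
        if f_term >= tau_term and d_inframe <= delta_stop:
            cls = "stop"
        elif d_inframe >= delta_sense:
            cls = "sense"
        else:
            cls = "ambiguous"
        per_codon[c] = {
            "f_terminal": f_term,
            "d_inframe": d_inframe,
            "classification": cls,
        }
    return StopUsageReport(per_codon, n_cds, n_internal)
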