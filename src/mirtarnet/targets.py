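"""Candidate miRNA-mRNA pairs: seed-match scanning and multi-tool consensus.

The built-in predictor ("seedscan") implements canonical seed matching only.
The seed is nucleotides 2-8 of the mature miRNA (1-based, 5'->3').  A site on
the UTR sense strand (read 5'->3') is one of:

* ``6mer``     - reverse complement of miRNA nt 2-7,
* ``7mer-m8``  - reverse complement of nt 2-8,
* ``7mer-A1``  - reverse complement of nt 2-7 followed by an A,
* ``8mer``     - reverse complement of nt 2-8 followed by an A.

The A opposite miRNA position 1 is required to be a literal adenosine on the
mRNA regardless of the miRNA's first nucleotide, matching the canonical
site-type definitions.  Each occurrence of the 6-nt seed core is assigned the
single most specific type it supports (8mer > 7mer-m8 / 7mer-A1 > 6mer), so a
7mer contained in an 8mer at the same core is never double-counted.
Coordinates are 0-based half-open on the UTR.  ``N`` never matches.

External predictors are not reimplemented; their output tables are imported
as (mirna_id, gene_id) pair lists and combined with the built-in scan by
consensus voting: a pair is retained when at least ``min_tools`` tools
reported it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import ParseError

__all__ = [
    "SITE_TYPES",
    "MatureMiRNA",
    "UTRRecord",
    "SeedSite",
    "CandidatePair",
    "find_seed_sites",
    "predict_builtin",
    "read_mirna_fasta",
    "read_utr_fasta",
    "read_tool_table",
    "consensus",
    "reverse_complement_dna",
]

#: site types ordered weakest to strongest
SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
_SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
BUILTIN_TOOL_NAME = "seedscan"


def _as_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement_dna(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA: id and 5'->3' sequence (RNA; T is transcribed to U)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        rna = self.sequence.upper().replace("T", "U")
        if len(rna) < 8:
            raise ValueError(f"miRNA {self.id!r}: length {len(rna)} < 8")
        bad = set(rna) - set("ACGU")
        if bad:
            raise ValueError(f"miRNA {self.id!r}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", rna)

    @property
    def seed7(self) -> str:
        """Nucleotides 2-8 (the seed plus position 8), RNA."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class UTRRecord:
    """A 3'UTR in sense orientation: gene id and DNA sequence."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"UTR {self.gene_id!r}: empty sequence")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"UTR {self.gene_id!r}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class SeedSite:
    """One classified seed-match site; ``start``/``end`` are 0-based half-open."""

    mirna_id: str
    gene_id: str
    site_type: str
    start: int
    end: int


@dataclass(frozen=True)
class CandidatePair:
    """A (miRNA, gene) candidate with the set of tools supporting it."""

    mirna_id: str
    gene_id: str
    tools: frozenset[str]

    @property
    def consensus_count(self) -> int:
        return len(self.tools)

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_id)


def find_seed_sites(mirna: MatureMiRNA, utr: UTRRecord) -> list[SeedSite]:
    """All seed-match sites of ``mirna`` in ``utr``, most specific type per core.

    Scans for the 6-nt core (reverse complement of miRNA nt 2-7) and upgrades
    each occurrence by the flanking m8 match and/or the A1 adenosine.
    """
    match7 = reverse_complement_dna(_as_dna(mirna.seed7))  # rc of nt 2-8
    core6 = match7[1:]  # rc of nt 2-7
    m8_char = match7[0]
    seq = utr.sequence
    sites: list[SeedSite] = []
    pos = seq.find(core6)
    while pos != -1:
        has_m8 = pos > 0 and seq[pos - 1] == m8_char
        has_a1 = pos + 6 < len(seq) and seq[pos + 6] == "A"
        if has_m8 and has_a1:
            site = SeedSite(mirna.id, utr.gene_id, "8mer", pos - 1, pos + 7)
        elif has_m8:
            site = SeedSite(mirna.id, utr.gene_id, "7mer-m8", pos - 1, pos + 6)
        elif has_a1:
            site = SeedSite(mirna.id, utr.gene_id, "7mer-A1", pos, pos + 7)
        else:
            site = SeedSite(mirna.id, utr.gene_id, "6mer", pos, pos + 6)
        sites.append(site)
        pos = seq.find(core6, pos + 1)
    return sites


def predict_builtin(
    mirnas: Sequence[MatureMiRNA],
    utrs: Sequence[UTRRecord],
    min_site_type: str = "7mer-A1",
) -> list[CandidatePair]:
    """Seed-scan predictor: one pair per (miRNA, UTR) with a qualifying site.

    ``min_site_type`` sets the weakest site type that counts (default
    ``7mer-A1``, i.e. any 7mer or 8mer site qualifies but a lone 6mer does
    not).  Multiple sites in one UTR still yield a single pair.
    """
    if min_site_type not in _SITE_RANK:
        raise ValueError(f"unknown site type {min_site_type!r}; expected {SITE_TYPES}")
    min_rank = _SITE_RANK[min_site_type]
    tools = frozenset({BUILTIN_TOOL_NAME})
    pairs: list[CandidatePair] = []
    for mirna in mirnas:
        for utr in utrs:
            sites = find_seed_sites(mirna, utr)
            if any(_SITE_RANK[s.site_type] >= min_rank for s in sites):
                pairs.append(CandidatePair(mirna.id, utr.gene_id, tools))
    return pairs


def read_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    """Mature miRNA sequences from FASTA (RNA or DNA alphabet)."""
    return [MatureMiRNA(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_utr_fasta(path: str | Path) -> list[UTRRecord]:
    """3'UTR sequences from FASTA, record id = gene id."""
    return [UTRRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_tool_table(path: str | Path, tool_name: str) -> list[CandidatePair]:
    """Read one prediction tool's TSV (columns ``mirna_id``, ``gene_id``).

    Rows are deduplicated; malformed rows raise :class:`ParseError` with the
    1-based line number.
    """
    tools = frozenset({tool_name})
    pairs: list[CandidatePair] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise ParseError(f"{path}: empty file (expected a header line)")
        cols = header.rstrip("\n").split("\t")
        try:
            i_mir, i_gene = cols.index("mirna_id"), cols.index("gene_id")
        except ValueError:
            raise ParseError(
                f"{path}: header must contain 'mirna_id' and 'gene_id', got {cols}"
            ) from None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) <= max(i_mir, i_gene) or not fields[i_mir] or not fields[i_gene]:
                raise ParseError(f"{path}: malformed row at line {lineno}: {line!r}")
            key = (fields[i_mir], fields[i_gene])
            if key not in seen:
                seen.add(key)
                pairs.append(CandidatePair(key[0], key[1], tools))
    return pairs


def consensus(
    pair_lists: Iterable[Sequence[CandidatePair]],
    min_tools: int = 3,
) -> list[CandidatePair]:
    """Union candidate pairs across tools, keeping those with enough votes.

    Tool sets of identical (miRNA, gene) pairs are merged; a pair survives iff
    its merged tool count reaches ``min_tools``.  Output is sorted by
    (mirna_id, gene_id) and therefore order-invariant over the input lists.
    """
    if min_tools < 1:
        raise ValueError(f"min_tools must be >= 1, got {min_tools}")
    lists = list(pair_lists)
    merged: dict[tuple[str, str], set[str]] = {}
    for plist in lists:
        for pair in plist:
            merged.setdefault(pair.key, set()).update(pair.tools)
    if merged and min_tools > len(lists):
        warnings.warn(
            f"min_tools={min_tools} exceeds the {len(lists)} supplied tool lists;"
            " the consensus may be empty",
            stacklevel=2,
        )
    kept = [
        CandidatePair(m, g, frozenset(tools))
        for (m, g), tools in merged.items()
        if len(tools) >= min_tools
    ]
    kept.sort(key=lambda p: p.key)
    return kept
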