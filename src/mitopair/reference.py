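"""Human mitochondrial reference layer.

The human mitochondrial genome is a circular molecule of 16,569 bp (rCRS
numbering, 1-based inclusive).  It encodes 13 OXPHOS protein subunits, 22
tRNAs and 2 rRNAs, plus the non-coding control region (D-Loop) which spans
the origin of the coordinate system (16024..576).  This module bundles a
feature map of that genome, the vertebrate mitochondrial genetic code
(translation table 2) and the circular-coordinate arithmetic every other
module relies on.

Notable quirks carried by the map:

* ``ATP8`` and ``ATP6`` overlap (8527..8572) in different reading frames;
  a position in the overlap belongs to both genes.
* Several regulatory sub-elements of the control region and the L-strand
  replication origin (``OLR1``) are shipped as ``regulatory`` features and
  may overlap tRNA genes.
* Genes whose length is not a multiple of three end in an incomplete stop
  codon completed by polyadenylation of the transcript; the trailing one or
  two bases are flagged so annotation can report them as ``stop_region``
  instead of forcing a codon call.

The bundled reference sequence is a synthetic stand-in for the rCRS (see
``data/rcrs_synthetic.fasta``): base-per-base it is a simulated sequence,
constructed to be consistent with the gene map and with the reference
alleles and codons of every variant documented in this package's tests.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import ConfigurationError, InputError

GENOME_LENGTH = 16569

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_CATEGORIES = {"protein", "tRNA", "rRNA", "dloop", "regulatory", "intergenic"}


def complement(seq: str) -> str:
    """Complement (not reverse) of a nucleotide string."""
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated interval of the mitochondrial genome.

    ``start``/``end`` are 1-based inclusive rCRS coordinates.  A feature
    whose span crosses the origin (the D-Loop) has ``start > end`` and its
    coordinates wrap through position 16569 -> 1.
    """

    name: str
    start: int
    end: int
    strand: str  # 'H' or 'L'
    category: str
    complex: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= GENOME_LENGTH and 1 <= self.end <= GENOME_LENGTH):
            raise ConfigurationError(f"{self.name}: coordinates outside 1..{GENOME_LENGTH}")
        if self.strand not in ("H", "L"):
            raise ConfigurationError(f"{self.name}: strand must be 'H' or 'L'")
        if self.category not in _CATEGORIES:
            raise ConfigurationError(f"{self.name}: unknown category {self.category!r}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    @property
    def length(self) -> int:
        if self.wraps:
            return (GENOME_LENGTH - self.start + 1) + self.end
        return self.end - self.start + 1

    @property
    def incomplete_stop_bases(self) -> int:
        """Number of trailing bases forming an incomplete stop codon (0, 1 or 2)."""
        if self.category != "protein":
            return 0
        return self.length % 3

    def contains(self, position: int) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    def offset(self, position: int) -> int:
        """0-based offset of ``position`` along the feature in genome orientation."""
        if not self.contains(position):
            raise InputError(f"position {position} not in feature {self.name}")
        if self.wraps and position <= self.end:
            return (GENOME_LENGTH - self.start + 1) + position - 1
        return position - self.start

    def positions(self) -> Iterator[int]:
        """All genome positions of the feature, in genome orientation."""
        if self.wraps:
            yield from range(self.start, GENOME_LENGTH + 1)
            yield from range(1, self.end + 1)
        else:
            yield from range(self.start, self.end + 1)


@dataclass(frozen=True)
class GeneticCode:
    """Codon table with start and stop codon sets (DNA alphabet)."""

    table: dict
    start_codons: frozenset
    stop_codons: frozenset
    name: str = "vertebrate mitochondrial"

    @classmethod
    def vertebrate_mitochondrial(cls) -> "GeneticCode":
        """NCBI translation table 2: ATA=Met, TGA=Trp, AGA/AGG=stop."""
        tbl = CodonTable.unambiguous_dna_by_id[2]
        return cls(
            table=dict(tbl.forward_table),
            start_codons=frozenset(tbl.start_codons),
            stop_codons=frozenset(tbl.stop_codons),
        )

    @classmethod
    def standard(cls) -> "GeneticCode":
        tbl = CodonTable.unambiguous_dna_by_id[1]
        return cls(
            table=dict(tbl.forward_table),
            start_codons=frozenset(tbl.start_codons),
            stop_codons=frozenset(tbl.stop_codons),
            name="standard",
        )


def translate(codon: str, code: GeneticCode) -> Optional[str]:
    """Translate one codon; returns a one-letter amino acid, '*' for stop.

    A codon containing a base outside {A,C,G,T} returns ``None`` so callers
    can fall back to an "unknown effect" annotation.
    """
    codon = codon.upper()
    if len(codon) != 3:
        raise InputError(f"codon must have length 3, got {codon!r}")
    if any(b not in "ACGT" for b in codon):
        return None
    if codon in code.stop_codons:
        return "*"
    return code.table[codon]


@dataclass(frozen=True)
class MitoGeneMap:
    """The full annotation: every position 1..16569 maps to >=1 feature."""

    features: tuple
    genome_length: int = GENOME_LENGTH
    reference_sequence: Optional[str] = None
    _by_name: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_name", {f.name: f for f in self.features})

    def feature(self, name: str) -> GeneFeature:
        try:
            return self._by_name[name]
        except KeyError:
            raise InputError(f"no feature named {name!r}") from None

    def locate(self, position: int) -> list:
        if not (1 <= position <= self.genome_length):
            raise InputError(f"position {position} outside 1..{self.genome_length}")
        return [f for f in self.features if f.contains(position)]

    @property
    def protein_genes(self) -> list:
        return [f for f in self.features if f.category == "protein"]

    @property
    def trna_genes(self) -> list:
        return [f for f in self.features if f.category == "tRNA"]

    @property
    def rrna_genes(self) -> list:
        return [f for f in self.features if f.category == "rRNA"]

    def ref_base(self, position: int) -> str:
        if self.reference_sequence is None:
            raise ConfigurationError(
                "no reference sequence loaded; pass include_reference=True to load_gene_map()"
            )
        if not (1 <= position <= self.genome_length):
            raise InputError(f"position {position} outside 1..{self.genome_length}")
        return self.reference_sequence[position - 1]

    def ref_slice(self, start: int, length: int) -> str:
        """``length`` reference bases starting at 1-based ``start``, circular."""
        return "".join(
            self.ref_base((start - 1 + i) % self.genome_length + 1) for i in range(length)
        )


def locate(position: int, gene_map: MitoGeneMap) -> list:
    """Every feature covering ``position`` (always >=1 on a valid map)."""
    return gene_map.locate(position)


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("mitopair") / "data" / name)


def load_gene_map(
    path: Optional[str] = None,
    fasta: Optional[str] = None,
    include_reference: bool = True,
) -> MitoGeneMap:
    """Load the bundled (or a user-supplied) mitochondrial feature map.

    The map file is tab-delimited with columns
    ``name/start/end/strand/category/complex`` (1-based inclusive; '.' for
    no complex).  The reference FASTA holds one 16,569 nt record.
    """
    map_path = Path(path) if path else _data_path("mito_gene_map.tsv")
    if not map_path.exists():
        raise ConfigurationError(f"gene map file not found: {map_path}")
    try:
        df = pd.read_csv(map_path, sep="\t", dtype={"name": str})
    except Exception as exc:  # malformed bundled file
        raise ConfigurationError(f"cannot parse gene map {map_path}: {exc}") from exc
    required = {"name", "start", "end", "strand", "category", "complex"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"gene map missing columns {required - set(df.columns)}")

    features = tuple(
        GeneFeature(
            name=row["name"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            category=row["category"],
            complex=None if row["complex"] in (".", "", None) else str(row["complex"]),
        )
        for row in df.to_dict("records")
    )

    reference = None
    if include_reference:
        fasta_path = Path(fasta) if fasta else _data_path("rcrs_synthetic.fasta")
        if fasta and not fasta_path.exists():
            raise ConfigurationError(f"reference FASTA not found: {fasta_path}")
        if fasta_path.exists():
            record = next(SeqIO.parse(str(fasta_path), "fasta"))
            reference = str(record.seq).upper()
            if len(reference) != GENOME_LENGTH:
                raise ConfigurationError(
                    f"reference sequence length {len(reference)} != {GENOME_LENGTH}"
                )

    gmap = MitoGeneMap(features=features, reference_sequence=reference)
    _validate_map(gmap)
    return gmap


def _validate_map(gmap: MitoGeneMap) -> None:
    n_protein = len(gmap.protein_genes)
    n_trna = len(gmap.trna_genes)
    n_rrna = len(gmap.rrna_genes)
    if (n_protein, n_trna, n_rrna) != (13, 22, 2):
        raise ConfigurationError(
            f"expected 13 protein/22 tRNA/2 rRNA genes, got {n_protein}/{n_trna}/{n_rrna}"
        )
    if not any(f.category == "dloop" for f in gmap.features):
        raise ConfigurationError("gene map lacks a D-Loop feature")
    covered = [False] * (GENOME_LENGTH + 1)
    for f in gmap.features:
        for p in f.positions():
            covered[p] = True
    missing = [p for p in range(1, GENOME_LENGTH + 1) if not covered[p]]
    if missing:
        raise ConfigurationError(
            f"{len(missing)} positions uncovered by any feature (first: {missing[:5]})"
        )
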