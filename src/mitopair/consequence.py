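"""Strand-aware consequence annotation on the mitochondrial genome.

Protein-coding effects are computed under the vertebrate mitochondrial
genetic code.  H-strand genes are read directly in genome orientation;
L-strand genes (ND6 and eight tRNAs) are read on the complementary strand
in the 3'->5' direction of the genome axis, so both the codon lookup and
the mutated allele are complemented.  A position covered by several
features (the ATP8/ATP6 overlap, tRNAs inside the L-strand replication
origin) yields one consequence per feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from .errors import DataError, InputError
from .io import VariantKey
from .reference import GeneFeature, GeneticCode, MitoGeneMap, complement, translate

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"

TRANSITION = "transition"
TRANSVERSION = "transversion"
NOT_APPLICABLE = "not_applicable"

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

#: effect labels, most specific (protein) first; used for primary-consequence choice
EFFECT_PRIORITY = [
    "nonsense",
    "frameshift",
    "missense",
    "in_frame",
    "synonymous",
    "stop_region",
    "unknown",
    "tRNA",
    "rRNA",
    "regulatory",
    "dloop_noncoding",
    "intergenic",
]


@dataclass(frozen=True)
class Consequence:
    """Annotation of one variant with respect to one overlapping feature."""

    feature_name: str
    category: str
    variant_type: str
    substitution_class: str
    effect: str
    aa_change: Optional[str] = None  # "ref/alt" one-letter pair, protein effects only
    aa_position: Optional[int] = None  # 1-based from the gene's initiator Met


def variant_type(key: VariantKey) -> str:
    """SNV / insertion / deletion from normalized allele lengths."""
    if len(key.ref) == 1 and len(key.alt) == 1:
        return SNV
    if len(key.ref) > len(key.alt):
        return DELETION
    return INSERTION


def substitution_class(key: VariantKey) -> str:
    """Transition (purine<->purine, pyrimidine<->pyrimidine) or transversion."""
    if variant_type(key) != SNV:
        return NOT_APPLICABLE
    r, a = key.ref, key.alt
    same_family = ({r, a} <= _PURINES) or ({r, a} <= _PYRIMIDINES)
    return TRANSITION if same_family else TRANSVERSION


def _coding_offset(gene: GeneFeature, position: int) -> int:
    """0-based offset along the coding sequence (5'->3' of the mRNA)."""
    off = gene.offset(position)
    if gene.strand == "H":
        return off
    return gene.length - 1 - off


def codon_at(gene: GeneFeature, position: int, gmap: MitoGeneMap) -> tuple:
    """(codon, within_codon_index, codon_number) in coding orientation.

    ``codon_number`` is 1-based (codon 1 = initiator Met).  Raises
    :class:`InputError` if the position lies in the gene's incomplete
    trailing stop bases, which do not form a full codon.
    """
    c_off = _coding_offset(gene, position)
    n_full = gene.length // 3
    ci, within = divmod(c_off, 3)
    if ci >= n_full:
        raise InputError(f"{gene.name}: position {position} in incomplete stop region")
    bases = []
    for k in range(3):
        coding_pos = 3 * ci + k
        if gene.strand == "H":
            genome_off = coding_pos
        else:
            genome_off = gene.length - 1 - coding_pos
        # map feature offset back to a genome position (features here never wrap)
        gpos = gene.start + genome_off
        base = gmap.ref_base(gpos)
        bases.append(base if gene.strand == "H" else complement(base))
    return "".join(bases), within, ci + 1


def _protein_effect(
    key: VariantKey, gene: GeneFeature, gmap: MitoGeneMap, code: GeneticCode
) -> Consequence:
    vt = variant_type(key)
    sub = substitution_class(key)
    if vt != SNV:
        indel_len = abs(len(key.ref) - len(key.alt))
        effect = "frameshift" if indel_len % 3 else "in_frame"
        return Consequence(gene.name, gene.category, vt, sub, effect)

    c_off = _coding_offset(gene, key.position)
    if c_off >= 3 * (gene.length // 3):
        return Consequence(gene.name, gene.category, vt, sub, "stop_region")

    codon, within, aa_pos = codon_at(gene, key.position, gmap)
    ref_allele = key.ref if gene.strand == "H" else complement(key.ref)
    alt_allele = key.alt if gene.strand == "H" else complement(key.alt)
    if codon[within] != ref_allele:
        raise DataError(
            f"reference base mismatch at {key.position} in {gene.name}: "
            f"codon has {codon[within]}, variant ref implies {ref_allele}"
        )
    mutated = codon[:within] + alt_allele + codon[within + 1 :]
    aa_ref = translate(codon, code)
    aa_alt = translate(mutated, code)
    if aa_ref is None or aa_alt is None:
        return Consequence(gene.name, gene.category, vt, sub, "unknown")
    if aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "nonsense"
    else:
        # includes disruption of a planted stop codon; reported as missense
        effect = "missense"
    return Consequence(
        gene.name, gene.category, vt, sub, effect, f"{aa_ref}/{aa_alt}", aa_pos
    )


_NONCODING_EFFECT = {
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "regulatory": "regulatory",
    "dloop": "dloop_noncoding",
    "intergenic": "intergenic",
}


def annotate(key: VariantKey, gmap: MitoGeneMap, code: GeneticCode) -> List[Consequence]:
    """One consequence per feature covering the variant position.

    Requires a loaded reference sequence; the ref allele must match the
    reference base at the position (checked for SNVs and the anchor base of
    indels), otherwise :class:`DataError` is raised.
    """
    key = key.validate()
    ref_base = gmap.ref_base(key.position)
    if key.ref[0] != ref_base:
        raise DataError(
            f"reference mismatch at {key.position}: file says {key.ref[0]}, reference has {ref_base}"
        )
    out: List[Consequence] = []
    for feature in gmap.locate(key.position):
        if feature.category == "protein":
            out.append(_protein_effect(key, feature, gmap, code))
        else:
            out.append(
                Consequence(
                    feature.name,
                    feature.category,
                    variant_type(key),
                    substitution_class(key),
                    _NONCODING_EFFECT[feature.category],
                )
            )
    return out


def primary_consequence(consequences: List[Consequence]) -> Optional[Consequence]:
    """Single representative consequence for tabulation.

    Priority follows the field's convention: protein-coding effects first,
    then tRNA, rRNA, regulatory elements, D-Loop, intergenic — so a variant
    inside both a tRNA and the L-strand replication origin is tabulated as
    a tRNA change, and a control-region variant inside a regulatory element
    is tabulated as regulatory.
    """
    if not consequences:
        return None
    return min(consequences, key=lambda c: EFFECT_PRIORITY.index(c.effect))
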