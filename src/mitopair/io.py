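"""Paired blood-tumor variant observations: containers and file dialects.

A variant's identity is the full ``(position, ref, alt)`` triple on the
rCRS.  Each patient contributes one blood and one tumor observation per
variant; a variant undetected in a tissue is represented with
``alt_reads=0`` at that tissue's depth, never as a missing record — the
somatic test requires an explicit blood zero.

Two dialects are supported: a flat TSV (one row per patient/variant) and
VCF 4.2 with per-sample allelic depths (``AD``), read through pysam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, NamedTuple, Optional

import pandas as pd
import pysam

from .errors import FormatError, InputError, ValidationError
from .reference import GENOME_LENGTH

logger = logging.getLogger(__name__)

#: minimum per-site depth for an observation to enter analysis
MIN_DEPTH = 300

_ALPHABET = set("ACGT")


class VariantKey(NamedTuple):
    """Identity of a variant: 1-based position plus ref and alt alleles."""

    position: int
    ref: str
    alt: str

    def validate(self) -> "VariantKey":
        if not (1 <= self.position <= GENOME_LENGTH):
            raise InputError(f"position {self.position} outside 1..{GENOME_LENGTH}")
        if not self.ref or not self.alt:
            raise InputError("ref and alt must be non-empty")
        if set(self.ref) - _ALPHABET or set(self.alt) - _ALPHABET:
            raise InputError(f"alleles must be over A/C/G/T: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise InputError(f"ref == alt at {self.position}")
        return self

    def __str__(self) -> str:
        return f"{self.ref}{self.position}{self.alt}"


def normalize_key(position: int, ref: str, alt: str) -> VariantKey:
    """Trim shared allele context so VCF-style and HGVS-style inputs unify.

    Right-trims a shared suffix, then left-trims a shared prefix advancing
    the position, always keeping at least one base per allele (VCF anchor
    convention for indels).
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return VariantKey(position, ref, alt).validate()


@dataclass(frozen=True)
class VariantObservation:
    """Read support for one variant allele in one tissue of one patient."""

    patient_id: str
    tissue: str  # 'blood' or 'tumor'
    alt_reads: int
    depth: int

    def __post_init__(self) -> None:
        if self.tissue not in ("blood", "tumor"):
            raise InputError(f"tissue must be 'blood' or 'tumor', got {self.tissue!r}")
        if self.alt_reads < 0 or self.depth < 0:
            raise ValidationError("read counts must be non-negative")
        if self.alt_reads > self.depth:
            raise ValidationError(
                f"{self.patient_id}/{self.tissue}: alt_reads {self.alt_reads} > depth {self.depth}"
            )

    @property
    def maf(self) -> float:
        """Mutant allele fraction: alt-supporting reads over total depth."""
        if self.depth == 0:
            return 0.0
        return self.alt_reads / self.depth


@dataclass(frozen=True)
class PairedVariantRecord:
    """One variant with its matched blood and tumor observations."""

    key: VariantKey
    blood: VariantObservation
    tumor: VariantObservation

    def __post_init__(self) -> None:
        if self.blood.patient_id != self.tumor.patient_id:
            raise ValidationError("blood and tumor observations belong to different patients")
        if self.blood.tissue != "blood" or self.tumor.tissue != "tumor":
            raise ValidationError("tissue labels swapped or wrong")

    @property
    def patient_id(self) -> str:
        return self.blood.patient_id


TSV_COLUMNS = [
    "patient_id",
    "position",
    "ref",
    "alt",
    "blood_alt",
    "blood_depth",
    "tumor_alt",
    "tumor_depth",
]


def read_paired_tsv(path, min_depth: int = MIN_DEPTH) -> List[PairedVariantRecord]:
    """Read the flat paired-count dialect.

    Rows where either tissue's depth is zero or below ``min_depth`` are
    excluded with a logged warning (the study design requires >=300x per
    base).  ``alt > depth`` raises a :class:`ValidationError` naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str}, na_values=["."])
    if df.empty and df.columns.size == 0:
        return []
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records: List[PairedVariantRecord] = []
    n_depth_excluded = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        bd, td = int(row.blood_depth), int(row.tumor_depth)
        ba, ta = int(row.blood_alt), int(row.tumor_alt)
        if ba > bd or ta > td:
            raise ValidationError(f"{path} line {i}: alt_reads exceeds depth")
        if bd < min_depth or td < min_depth:
            n_depth_excluded += 1
            continue
        key = normalize_key(int(row.position), str(row.ref), str(row.alt))
        records.append(
            PairedVariantRecord(
                key=key,
                blood=VariantObservation(str(row.patient_id), "blood", ba, bd),
                tumor=VariantObservation(str(row.patient_id), "tumor", ta, td),
            )
        )
    if n_depth_excluded:
        logger.warning(
            "%s: excluded %d rows below %dx depth", path, n_depth_excluded, min_depth
        )
    return records


def read_paired_vcf(
    path,
    blood_sample_name: str,
    tumor_sample_name: str,
    patient_id: Optional[str] = None,
    min_depth: int = MIN_DEPTH,
) -> List[PairedVariantRecord]:
    """Read a two-sample VCF 4.2 with per-sample allelic depths.

    Emits one record per ALT allele per site (multiallelic sites are
    decomposed).  Site depth is the sum of the sample's AD values.  A sample
    record lacking AD raises :class:`FormatError` naming the sample and site.
    """
    path = str(path)
    patient_id = patient_id or blood_sample_name
    vcf = pysam.VariantFile(path)
    for s in (blood_sample_name, tumor_sample_name):
        if s not in vcf.header.samples:
            raise FormatError(f"{path}: sample {s!r} not in VCF header")
    records: List[PairedVariantRecord] = []
    n_depth_excluded = 0
    for rec in vcf:
        ads = {}
        for s in (blood_sample_name, tumor_sample_name):
            ad = rec.samples[s].get("AD")
            if ad is None or all(v is None for v in ad):
                raise FormatError(
                    f"{path}: sample {s!r} lacks AD at {rec.chrom}:{rec.pos}"
                )
            ads[s] = [int(v or 0) for v in ad]
        if rec.alts is None:
            continue
        for alt_idx, alt in enumerate(rec.alts, start=1):
            key = normalize_key(rec.pos, rec.ref, alt)
            b_ad, t_ad = ads[blood_sample_name], ads[tumor_sample_name]
            blood = VariantObservation(patient_id, "blood", b_ad[alt_idx], sum(b_ad))
            tumor = VariantObservation(patient_id, "tumor", t_ad[alt_idx], sum(t_ad))
            if blood.depth < min_depth or tumor.depth < min_depth:
                n_depth_excluded += 1
                continue
            records.append(PairedVariantRecord(key=key, blood=blood, tumor=tumor))
    if n_depth_excluded:
        logger.warning(
            "%s: excluded %d allele records below %dx depth", path, n_depth_excluded, min_depth
        )
    return records


#: column order of the classified TSV (bit-stable across runs)
CLASSIFIED_COLUMNS = [
    "patient_id",
    "position",
    "ref",
    "alt",
    "blood_alt",
    "blood_depth",
    "blood_maf",
    "tumor_alt",
    "tumor_depth",
    "tumor_maf",
    "origin",
    "blood_ploidy",
    "tumor_ploidy",
    "genes",
    "variant_type",
    "substitution_class",
    "effect",
    "aa_change",
]


def write_classified(path, records: Iterable) -> None:
    """Write classified (and optionally annotated) records as TSV.

    One row per (patient, variant); '.' marks absent annotation fields.
    """
    rows = []
    for cv in records:
        rec = cv.record
        primary = cv.primary_consequence
        rows.append(
            {
                "patient_id": rec.patient_id,
                "position": rec.key.position,
                "ref": rec.key.ref,
                "alt": rec.key.alt,
                "blood_alt": rec.blood.alt_reads,
                "blood_depth": rec.blood.depth,
                "blood_maf": f"{rec.blood.maf:.6g}",
                "tumor_alt": rec.tumor.alt_reads,
                "tumor_depth": rec.tumor.depth,
                "tumor_maf": f"{rec.tumor.maf:.6g}",
                "origin": cv.origin,
                "blood_ploidy": cv.blood_ploidy,
                "tumor_ploidy": cv.tumor_ploidy,
                "genes": ";".join(c.feature_name for c in cv.consequences) or ".",
                "variant_type": primary.variant_type if primary else ".",
                "substitution_class": primary.substitution_class if primary else ".",
                "effect": primary.effect if primary else ".",
                "aa_change": (primary.aa_change or ".") if primary else ".",
            }
        )
    df = pd.DataFrame(rows, columns=CLASSIFIED_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_classified(path) -> pd.DataFrame:
    """Read back a classified TSV as a DataFrame (columns as written)."""
    return pd.read_csv(path, sep="\t", dtype={"patient_id": str}, na_values=["."])
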