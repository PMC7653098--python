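"""MAF-threshold classification of variant origin and ploidy, plus
blood->tumor heteroplasmy-shift statistics.

Origin classes follow the matched-pair design: a variant with blood
MAF > 1% in at least one cohort patient is germline everywhere it occurs;
a variant absent from blood (MAF < 0.1%) but present in the tumor
(MAF > 1%) is a somatic mutation; the ambiguous band (blood MAF between
0.1% and 1%) is a "probable mutation" and is excluded from downstream
somatic analyses.  Ploidy is a pure step function of one tissue's MAF:
>=95% homoplasmic, 1%..<95% heteroplasmic, <1% undetected.

Boundary conventions (documented, not in the thresholds' sources):
MAF exactly 0.95 is homoplasmic; blood MAF exactly 0.001 is a probable
mutation (the somatic rule is strictly below 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consequence import Consequence, primary_consequence
from .errors import InputError, ValidationError
from .io import PairedVariantRecord, VariantKey

GERMLINE = "germline"
SOMATIC = "somatic"
PROBABLE_MUTATION = "probable_mutation"
ABSENT = "absent"

HOMOPLASMIC = "homoplasmic"
HETEROPLASMIC = "heteroplasmic"
UNDETECTED = "undetected"

ORIGIN_CLASSES = (GERMLINE, SOMATIC, PROBABLE_MUTATION, ABSENT)
PLOIDY_CLASSES = (HOMOPLASMIC, HETEROPLASMIC, UNDETECTED)


@dataclass(frozen=True)
class ClassificationConfig:
    """MAF thresholds of the matched blood-tumor design."""

    somatic_normal_max: float = 0.001
    somatic_tumor_min: float = 0.01
    germline_blood_min: float = 0.01
    het_low: float = 0.01
    hom_min: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.somatic_normal_max < self.somatic_tumor_min):
            raise InputError("need 0 < somatic_normal_max < somatic_tumor_min")
        if not (self.het_low < self.hom_min):
            raise InputError("need het_low < hom_min")


def _check_maf(maf: float, label: str) -> None:
    if not (0.0 <= maf <= 1.0):
        raise ValidationError(f"{label} MAF {maf} outside [0, 1]")


def classify_ploidy(maf: float, cfg: ClassificationConfig) -> str:
    """Step function of one tissue's MAF: homoplasmic / heteroplasmic / undetected."""
    _check_maf(maf, "ploidy")
    if maf >= cfg.hom_min:
        return HOMOPLASMIC
    if maf >= cfg.het_low:
        return HETEROPLASMIC
    return UNDETECTED


def germline_evidenced_keys(
    records: Iterable[PairedVariantRecord], cfg: ClassificationConfig
) -> FrozenSet[VariantKey]:
    """Variant keys with blood MAF above the germline threshold in >=1 patient."""
    return frozenset(
        r.key for r in records if r.blood.maf > cfg.germline_blood_min
    )


def classify_origin(
    record: PairedVariantRecord,
    cfg: ClassificationConfig,
    germline_keys: FrozenSet[VariantKey] = frozenset(),
) -> str:
    """Origin class of one (patient, variant) observation.

    ``germline_keys`` carries the cohort context: a variant germline-
    evidenced in any patient is germline in every patient and ineligible
    to be called somatic elsewhere.
    """
    b, t = record.blood.maf, record.tumor.maf
    _check_maf(b, "blood")
    _check_maf(t, "tumor")
    if b > cfg.germline_blood_min or record.key in germline_keys:
        return GERMLINE
    if t > cfg.somatic_tumor_min:
        if b < cfg.somatic_normal_max:
            return SOMATIC
        return PROBABLE_MUTATION
    return ABSENT


@dataclass(frozen=True)
class ClassifiedVariant:
    """A paired record plus origin class, per-tissue ploidy and annotation."""

    record: PairedVariantRecord
    origin: str
    blood_ploidy: str
    tumor_ploidy: str
    consequences: tuple = ()

    @property
    def key(self) -> VariantKey:
        return self.record.key

    @property
    def patient_id(self) -> str:
        return self.record.patient_id

    @property
    def primary_consequence(self) -> Optional[Consequence]:
        return primary_consequence(list(self.consequences))


def classify_cohort(
    records: Sequence[PairedVariantRecord],
    cfg: Optional[ClassificationConfig] = None,
    gene_map=None,
    genetic_code=None,
) -> List[ClassifiedVariant]:
    """Classify all records with cohort-level germline propagation.

    When ``gene_map`` and ``genetic_code`` are given, each variant is also
    annotated with its consequences.
    """
    from .consequence import annotate  # local import keeps module load light

    cfg = cfg or ClassificationConfig()
    germ = germline_evidenced_keys(records, cfg)
    annot_cache: Dict[VariantKey, tuple] = {}
    out: List[ClassifiedVariant] = []
    for rec in records:
        cons: tuple = ()
        if gene_map is not None and genetic_code is not None:
            if rec.key not in annot_cache:
                annot_cache[rec.key] = tuple(annotate(rec.key, gene_map, genetic_code))
            cons = annot_cache[rec.key]
        out.append(
            ClassifiedVariant(
                record=rec,
                origin=classify_origin(rec, cfg, germ),
                blood_ploidy=classify_ploidy(rec.blood.maf, cfg),
                tumor_ploidy=classify_ploidy(rec.tumor.maf, cfg),
                consequences=cons,
            )
        )
    return out


@dataclass
class ShiftResult:
    """Blood->tumor heteroplasmy shift of one germline variant across carriers."""

    variant: VariantKey
    deltas: pd.Series  # per carrier patient: tumor MAF - blood MAF
    u_statistic: float
    p_value: float
    n_pairs: int
    n_shift_to_homoplasmy: int  # carriers homoplasmic in tumor but not in blood
    method: str = ""


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], max_exact_n: int = 8
) -> tuple:
    """Two-sided Mann-Whitney U comparing two MAF samples.

    Exact enumeration when both samples have n <= ``max_exact_n`` and no
    ties span the groups; otherwise the normal approximation with tie
    correction.  Returns (U of the first sample, p, method).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= max_exact_n and len(y) <= max_exact_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def shift_analysis(
    cohort, variant: VariantKey, cfg: Optional[ClassificationConfig] = None
) -> Optional[ShiftResult]:
    """Compare blood vs tumor MAF distributions of one germline variant.

    ``cohort`` is any object with a ``records`` attribute of classified
    variants.  Returns ``None`` when the variant has no germline carrier.
    """
    cfg = cfg or ClassificationConfig()
    carriers = [
        cv for cv in cohort.records if cv.key == variant and cv.origin == GERMLINE
    ]
    if not carriers:
        return None
    blood = np.array([cv.record.blood.maf for cv in carriers])
    tumor = np.array([cv.record.tumor.maf for cv in carriers])
    deltas = pd.Series(
        tumor - blood, index=[cv.patient_id for cv in carriers], name=str(variant)
    )
    u, p, method = mann_whitney_u(blood, tumor)
    n_shift = int(np.sum((tumor >= cfg.hom_min) & (blood < cfg.hom_min)))
    return ShiftResult(
        variant=variant,
        deltas=deltas,
        u_statistic=u,
        p_value=p,
        n_pairs=len(carriers),
        n_shift_to_homoplasmy=n_shift,
        method=method,
    )


def recurrence(cohort) -> pd.DataFrame:
    """Carrier counts per (variant, origin class).

    One row per (position, ref, alt, origin) with the number of distinct
    carrier patients, a singleton flag (exactly one carrier) and the cohort
    frequency (carriers / all patients).  Detected means the observation is
    not ``absent``.
    """
    n_patients = cohort.n_patients
    rows: Dict[tuple, set] = {}
    for cv in cohort.records:
        if cv.origin == ABSENT:
            continue
        rows.setdefault((cv.key, cv.origin), set()).add(cv.patient_id)
    out = pd.DataFrame(
        [
            {
                "position": key.position,
                "ref": key.ref,
                "alt": key.alt,
                "origin": origin,
                "carriers": len(patients),
                "singleton": len(patients) == 1,
                "frequency": len(patients) / n_patients if n_patients else np.nan,
            }
            for (key, origin), patients in sorted(
                rows.items(), key=lambda kv: (kv[0][0].position, kv[0][0].alt, kv[0][1])
            )
        ],
        columns=["position", "ref", "alt", "origin", "carriers", "singleton", "frequency"],
    )
    return out
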