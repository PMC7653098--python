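"""Cohort-level summaries: per-gene mutation rates, class breakdowns,
subtype stratification and sharing, association tests, and unsupervised
clustering of mutation profiles.

Counting conventions
--------------------
A *variant* is identified by its ``(position, ref, alt)`` triple; cohort
tallies count distinct variants, not (patient, variant) observations,
matching the way matched-pair mtDNA studies report class totals.  Because
two alternate alleles can share a position, both tallies — distinct triples
and distinct positions — are reported where it matters.  Per-gene counts
assign a variant to every feature covering its position, so the ATP8/ATP6
overlap is double-counted, and mutation rates divide by each feature's own
length; per-subtype rates divide by the whole genome (16,569 bp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, FrozenSet, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .classify import ABSENT, GERMLINE, PROBABLE_MUTATION, SOMATIC, ClassifiedVariant
from .consequence import NOT_APPLICABLE, SNV, TRANSITION, TRANSVERSION
from .errors import InputError, ValidationError
from .io import VariantKey
from .reference import GENOME_LENGTH, MitoGeneMap

logger = logging.getLogger(__name__)

SUBTYPES = ("LA", "LB", "H2", "TN")

METADATA_COLUMNS = [
    "patient_id",
    "age",
    "subtype",
    "follow_up_months",
    "vital_status",
]


@dataclass
class CohortTable:
    """All classified variants across patients plus patient metadata.

    ``patients`` needs at least a ``patient_id`` column; ``subtype`` uses
    the IHC labels LA/LB/H2/TN (anything else counts as unassigned).
    """

    patients: pd.DataFrame
    records: List[ClassifiedVariant]
    _frame: Optional[pd.DataFrame] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if "patient_id" not in self.patients.columns:
            raise ValidationError("patient metadata needs a patient_id column")
        known = set(self.patients["patient_id"].astype(str))
        unknown = {cv.patient_id for cv in self.records} - known
        if unknown:
            raise ValidationError(
                f"records reference patients absent from metadata: {sorted(unknown)[:5]}"
            )

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-(patient, variant) view used by the summaries."""
        if self._frame is not None:
            return self._frame
        rows = []
        for cv in self.records:
            rec = cv.record
            prim = cv.primary_consequence
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "position": rec.key.position,
                    "ref": rec.key.ref,
                    "alt": rec.key.alt,
                    "blood_maf": rec.blood.maf,
                    "tumor_maf": rec.tumor.maf,
                    "origin": cv.origin,
                    "blood_ploidy": cv.blood_ploidy,
                    "tumor_ploidy": cv.tumor_ploidy,
                    "variant_type": prim.variant_type if prim else None,
                    "substitution_class": prim.substitution_class if prim else None,
                    "effect": prim.effect if prim else None,
                    "gene": prim.feature_name if prim else None,
                    "category": prim.category if prim else None,
                }
            )
        frame = pd.DataFrame(rows)
        if not frame.empty:
            frame = frame.merge(self.patients, on="patient_id", how="left")
        self._frame = frame
        return frame

    def somatic_burden(self) -> pd.Series:
        """Somatic mutation count per patient (0 for mutation-free patients)."""
        counts: Dict[str, int] = {
            str(pid): 0 for pid in self.patients["patient_id"].astype(str)
        }
        for cv in self.records:
            if cv.origin == SOMATIC:
                counts[cv.patient_id] += 1
        return pd.Series(counts, name="burden").sort_index()

    def keys_by_origin(self, origin: str) -> Set[VariantKey]:
        return {cv.key for cv in self.records if cv.origin == origin}

    def detected_tumor_keys(self) -> Set[VariantKey]:
        """Distinct variants detected in any tumor (origin not absent)."""
        return {cv.key for cv in self.records if cv.origin != ABSENT}


def rate_per_kb(count: int, length_bp: int) -> float:
    """Variants per kilobase: count x 1000 / length.

    Full precision is returned; display rounding is the caller's concern
    (see :func:`percent` for the half-up convention used in reports).
    """
    if length_bp <= 0:
        raise ValidationError(f"length_bp must be positive, got {length_bp}")
    if count < 0:
        raise ValidationError("count must be non-negative")
    return count * 1000.0 / length_bp


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding used for displayed percentages and rates."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Display percentage with half-up rounding (e.g. 68/92 -> 73.9)."""
    if denominator == 0:
        raise ValidationError("percentage denominator is zero")
    return round_half_up(100.0 * numerator / denominator, decimals)


def gene_rates(
    cohort: CohortTable, gene_map: MitoGeneMap, origin: Optional[str] = None
) -> pd.DataFrame:
    """Per-feature variant counts and rates per kb.

    ``origin=None`` counts every variant detected in tumors; ``origin=
    'somatic'`` (etc.) restricts to that class.  Both the distinct-variant
    and distinct-position tallies are emitted; ``count`` (used for the
    rate) is the distinct-variant one.
    """
    if origin is None:
        keys = cohort.detected_tumor_keys()
    else:
        keys = cohort.keys_by_origin(origin)
    rows = []
    for feat in gene_map.features:
        hit_keys = [k for k in keys if feat.contains(k.position)]
        n_keys = len(hit_keys)
        n_pos = len({k.position for k in hit_keys})
        rows.append(
            {
                "gene": feat.name,
                "category": feat.category,
                "length_bp": feat.length,
                "count": n_keys,
                "count_positions": n_pos,
                "rate_per_kb": rate_per_kb(n_keys, feat.length),
            }
        )
    return pd.DataFrame(rows)


def class_breakdown(cohort: CohortTable) -> dict:
    """Every ratio the cohort report prints, with explicit denominators.

    Returns a nested dict; each leaf is ``{"count", "denominator", "pct"}``.
    Variant-level tallies are over distinct (position, ref, alt) triples;
    the somatic ploidy tally calls a recurrent mutation homoplasmic when
    any carrier's tumor MAF reaches the homoplasmy threshold.
    """
    frame = cohort.to_frame()
    if frame.empty:
        return {"empty": True}
    detected = frame[frame["origin"] != ABSENT]

    def ratio(count: int, denom: int) -> dict:
        return {
            "count": int(count),
            "denominator": int(denom),
            "pct": percent(count, denom) if denom else float("nan"),
        }

    out: dict = {"empty": False}

    # origin classes over distinct variants detected in the cohort
    per_key_origin = detected.groupby(["position", "ref", "alt"])["origin"].agg(
        lambda s: GERMLINE if (s == GERMLINE).any() else s.iloc[0]
    )
    n_keys = len(per_key_origin)
    n_sites = detected.groupby("position").ngroups
    out["variants"] = {
        "distinct_variants": n_keys,
        "distinct_positions": int(n_sites),
        "rate_per_kb_genome": rate_per_kb(n_keys, GENOME_LENGTH),
    }
    out["origin"] = {
        origin: ratio((per_key_origin == origin).sum(), n_keys)
        for origin in (GERMLINE, SOMATIC, PROBABLE_MUTATION)
    }

    # variant type / substitution spectrum over distinct tumor variants
    per_key = detected.drop_duplicates(subset=["position", "ref", "alt"])
    n_snv = int((per_key["variant_type"] == SNV).sum())
    out["variant_type"] = {
        vt: ratio((per_key["variant_type"] == vt).sum(), n_keys)
        for vt in ("SNV", "insertion", "deletion")
    }
    out["substitution"] = {
        sc: ratio((per_key["substitution_class"] == sc).sum(), n_snv)
        for sc in (TRANSITION, TRANSVERSION)
    }

    # somatic-mutation-focused tallies
    som = detected[detected["origin"] == SOMATIC]
    som_keys = som.drop_duplicates(subset=["position", "ref", "alt"])
    n_som = len(som_keys)
    coding = som_keys[som_keys["category"] == "protein"]
    noncoding = som_keys[som_keys["category"] != "protein"]
    out["somatic"] = {"distinct_mutations": n_som}
    if n_som:
        n_coding = len(coding)
        nonsyn = coding[coding["effect"].isin(["missense", "nonsense", "frameshift", "in_frame"])]
        out["somatic"]["coding"] = ratio(n_coding, n_som)
        out["somatic"]["noncoding"] = ratio(len(noncoding), n_som)
        if n_coding:
            out["somatic"]["nonsynonymous"] = ratio(len(nonsyn), n_coding)
            out["somatic"]["synonymous"] = ratio(
                (coding["effect"] == "synonymous").sum(), n_coding
            )
        if len(nonsyn):
            for eff in ("missense", "nonsense", "frameshift"):
                out["somatic"][eff] = ratio((nonsyn["effect"] == eff).sum(), len(nonsyn))
        if len(noncoding):
            out["somatic"]["regulatory"] = ratio(
                (noncoding["effect"] == "regulatory").sum(), len(noncoding)
            )
            out["somatic"]["trna_rrna"] = ratio(
                noncoding["effect"].isin(["tRNA", "rRNA"]).sum(), len(noncoding)
            )
            out["somatic"]["dloop_intergenic"] = ratio(
                noncoding["effect"].isin(["dloop_noncoding", "intergenic"]).sum(),
                len(noncoding),
            )
        # ploidy at the mutation level: homoplasmic if any carrier reaches it
        hom_keys = som.groupby(["position", "ref", "alt"])["tumor_ploidy"].agg(
            lambda s: (s == "homoplasmic").any()
        )
        out["somatic"]["homoplasmic"] = ratio(hom_keys.sum(), n_som)
        out["somatic"]["heteroplasmic"] = ratio((~hom_keys).sum(), n_som)
        # recurrence
        carriers = som.groupby(["position", "ref", "alt"])["patient_id"].nunique()
        out["somatic"]["singletons"] = ratio((carriers == 1).sum(), n_som)
        out["somatic"]["recurrent"] = ratio((carriers >= 2).sum(), n_som)

    # patients with >=1 somatic mutation
    burden = cohort.somatic_burden()
    out["patients"] = {
        "total": cohort.n_patients,
        "somatic_positive": ratio((burden > 0).sum(), cohort.n_patients),
        "mean_burden": float(burden.mean()) if len(burden) else float("nan"),
    }
    return out


@dataclass
class SubtypeSharing:
    """Venn partition of the somatic mutation universe over IHC subtypes."""

    by_subtype: Dict[str, Set[VariantKey]]
    venn: Dict[FrozenSet[str], Set[VariantKey]]
    n_excluded_patients: int

    @property
    def exclusive_counts(self) -> Dict[str, int]:
        return {
            s: len(self.venn.get(frozenset([s]), set())) for s in self.by_subtype
        }

    @property
    def rates_per_kb(self) -> Dict[str, float]:
        """Per-subtype mutation rate over the whole genome length."""
        return {
            s: rate_per_kb(len(keys), GENOME_LENGTH)
            for s, keys in self.by_subtype.items()
        }

    @property
    def universe(self) -> Set[VariantKey]:
        out: Set[VariantKey] = set()
        for keys in self.by_subtype.values():
            out |= keys
        return out


def subtype_sharing(cohort: CohortTable) -> SubtypeSharing:
    """Partition somatic mutations into subtype-exclusive and shared sets."""
    frame = cohort.to_frame()
    som = frame[frame["origin"] == SOMATIC] if not frame.empty else frame
    if "subtype" not in frame.columns:
        raise ValidationError("cohort metadata lacks a subtype column")
    assigned = som[som["subtype"].isin(SUBTYPES)] if not som.empty else som
    n_excluded = 0
    if not som.empty:
        n_excluded = som[~som["subtype"].isin(SUBTYPES)]["patient_id"].nunique()
        if n_excluded:
            logger.warning("subtype_sharing: excluded %d patients without subtype", n_excluded)
    by_subtype: Dict[str, Set[VariantKey]] = {}
    if not som.empty:
        for subtype, grp in assigned.groupby("subtype"):
            by_subtype[str(subtype)] = {
                VariantKey(int(r.position), r.ref, r.alt)
                for r in grp.itertuples(index=False)
            }
    venn: Dict[FrozenSet[str], Set[VariantKey]] = {}
    universe: Set[VariantKey] = set().union(*by_subtype.values()) if by_subtype else set()
    for key in universe:
        members = frozenset(s for s, keys in by_subtype.items() if key in keys)
        venn.setdefault(members, set()).add(key)
    return SubtypeSharing(by_subtype=by_subtype, venn=venn, n_excluded_patients=n_excluded)


@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    p_value: float
    test_used: str  # 'fisher' or 'chi2'


def association_test(table) -> AssociationResult:
    """Independence test on an r x c count table.

    Fisher's exact test when any expected cell is below 5 and the table is
    2x2 (larger sparse tables fall back to chi-square with a warning),
    otherwise the chi-square test without continuity correction.  Both are
    two-sided.
    """
    arr = np.asarray(table)
    if arr.ndim != 2 or (arr < 0).any() or not np.issubdtype(arr.dtype, np.number):
        raise InputError("association_test needs a non-negative 2-D count table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("degenerate table: a row or column margin is zero")
    expected = stats.contingency.expected_freq(arr)
    if (expected < 5).any():
        if arr.shape == (2, 2):
            odds, p = stats.fisher_exact(arr, alternative="two-sided")
            return AssociationResult(float(odds), float(p), "fisher")
        logger.warning(
            "expected cell < 5 in a %sx%s table; using chi-square anyway", *arr.shape
        )
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return AssociationResult(float(chi2), float(p), "chi2")


@dataclass
class ClusterResult:
    """Average-linkage clustering of patient mutation profiles (Jaccard)."""

    linkage: np.ndarray
    patient_ids: List[str]
    leaf_order: List[str]

    def cut(self, n_clusters: int) -> Dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return dict(zip(self.patient_ids, (int(l) for l in labels)))


def cluster_profiles(cohort: CohortTable) -> Optional[ClusterResult]:
    """Hierarchically cluster patients on binary somatic-mutation profiles.

    Jaccard distance, average linkage; patients enter in sorted id order so
    the leaf ordering is deterministic.  Returns ``None`` with fewer than
    two patients carrying somatic mutations.
    """
    frame = cohort.to_frame()
    som = frame[frame["origin"] == SOMATIC] if not frame.empty else frame
    if som.empty:
        return None
    matrix = (
        som.assign(present=1)
        .pivot_table(
            index="patient_id",
            columns=["position", "ref", "alt"],
            values="present",
            fill_value=0,
            aggfunc="max",
        )
        .sort_index()
    )
    if matrix.shape[0] < 2:
        return None
    dist = pdist(matrix.values.astype(bool), metric="jaccard")
    link = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(link)
    ids = [str(i) for i in matrix.index]
    return ClusterResult(
        linkage=link, patient_ids=ids, leaf_order=[ids[i] for i in order]
    )
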