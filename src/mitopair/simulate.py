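"""Synthetic matched blood-tumor mtDNA cohort generator with known truth.

The generator emulates the observed structure of a 92-patient matched-pair
breast-cancer cohort: per-patient germline variant counts around 37 +/- 9,
somatic mutations in ~74% of tumors (1..17 each), per-base depths of
300-6000x, germline blood heteroplasmy below 20% or homoplasmic, a
fraction of germline variants shifting toward homoplasmy in the tumor,
somatic tumor MAFs spanning 1%..100% with ~21% homoplasmic, an 84%
transition fraction among somatic SNVs, and IHC-subtype and haplogroup
frequencies matching the study population.  Observed read counts are drawn
beta-binomially around the true MAF, so threshold classification can be
tested against the generator's truth labels.

Every draw comes from one seeded numpy Generator, so a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .classify import GERMLINE, SOMATIC
from .consequence import annotate, primary_consequence
from .errors import InputError, ValidationError
from .haplogroups import HaplogroupPanel, load_panel
from .io import PairedVariantRecord, VariantKey, VariantObservation
from .reference import GENOME_LENGTH, GeneticCode, MitoGeneMap, load_gene_map

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass(frozen=True)
class SimulationParams:
    """Study-condition parameters of the synthetic cohort.

    Defaults encode the emulated study's observed rates; probabilities are
    validated on construction.
    """

    n_patients: int = 92
    seed: Optional[int] = None

    # sequencing depth, uniform per site and tissue
    depth_min: int = 300
    depth_max: int = 6000
    rho: float = 0.002  # beta-binomial overdispersion of read counts

    # germline variant count per patient: truncated normal
    germline_mean: float = 37.0
    germline_sd: float = 9.0
    germline_min: int = 16
    germline_max: int = 75

    # cohort-level pool of shared germline polymorphic sites (beyond the
    # haplogroup backbone): population variants recur across patients, so
    # each patient samples from one pool rather than the whole genome
    germline_pool_size: int = 530
    germline_pool_weight_beta: Tuple[float, float] = (0.25, 1.0)

    # somatic mutation count: zero-inflated, 1..17 among positive tumors
    somatic_zero_prob: float = 0.261
    somatic_geom_p: float = 0.369  # geometric over 1..somatic_max, mean ~2.7
    somatic_max: int = 17

    # germline blood-MAF mixture (non-backbone variants)
    germline_hom_prob: float = 0.30
    germline_verylow_prob: float = 0.40  # very low heteroplasmy, 1.2-2%
    hom_maf_low: float = 0.97  # homoplasmic true MAF ~ U(hom_maf_low, 1)

    # blood->tumor shift model for heteroplasmic germline variants
    shift_prob: float = 0.35
    shift_beta: Tuple[float, float] = (8.0, 2.0)  # tumor MAF skewed toward 1

    # somatic tumor-MAF mixture: ~21.4% homoplasmic
    somatic_hom_prob: float = 0.214
    somatic_het_beta: Tuple[float, float] = (1.0, 2.0)  # scaled to (0.01, 0.95)

    # mutational spectrum
    ti_fraction_somatic: float = 0.84
    ti_fraction_germline: float = 0.67
    indel_fraction: float = 0.02

    # patient metadata
    subtype_probs: tuple = (("LA", 0.633), ("LB", 0.244), ("TN", 0.067), ("H2", 0.056))
    unassigned_prob: float = 2.0 / 92.0
    haplogroup_freqs: tuple = (
        ("A", 0.446),
        ("B", 0.228),
        ("C", 0.119),
        ("D", 0.120),
        ("L", 0.054),
        ("H", 0.022),
        ("J", 0.011),
    )
    marker_dropout: float = 0.05
    age_mean: float = 53.8
    age_sd: float = 11.5

    # overall survival: exponential baseline, administrative censoring
    survival_log_hr: float = 0.0
    baseline_hazard: float = 0.009  # per month
    censor_min: float = 30.0
    censor_max: float = 124.0

    def __post_init__(self) -> None:
        probs = {
            "somatic_zero_prob": self.somatic_zero_prob,
            "germline_hom_prob": self.germline_hom_prob,
            "germline_verylow_prob": self.germline_verylow_prob,
            "shift_prob": self.shift_prob,
            "somatic_hom_prob": self.somatic_hom_prob,
            "ti_fraction_somatic": self.ti_fraction_somatic,
            "ti_fraction_germline": self.ti_fraction_germline,
            "indel_fraction": self.indel_fraction,
            "marker_dropout": self.marker_dropout,
            "unassigned_prob": self.unassigned_prob,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if self.germline_hom_prob + self.germline_verylow_prob > 1.0:
            raise ValidationError("germline MAF mixture weights exceed 1")
        if self.rho < 0:
            raise ValidationError("rho must be >= 0")
        if not abs(sum(p for _, p in self.haplogroup_freqs) - 1.0) < 1e-9:
            raise ValidationError("haplogroup frequencies must sum to 1")
        if not abs(sum(p for _, p in self.subtype_probs) - 1.0) < 1e-9:
            raise ValidationError("subtype probabilities must sum to 1")
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    ``variants``: one row per (patient, variant) with the true origin
    class, true MAFs and planted effect label.  ``patients``: per-patient
    haplogroup backbone, subtype, burden and survival group.
    """

    variants: pd.DataFrame
    patients: pd.DataFrame


def generate_read_counts(
    true_maf: float, depth: int, rho: float, rng: np.random.Generator
) -> int:
    """Beta-binomial alt-read draw; ``rho=0`` degenerates to binomial."""
    if rho < 0:
        raise ValidationError("rho must be >= 0")
    if not (0.0 <= true_maf <= 1.0):
        raise ValidationError("true_maf outside [0, 1]")
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    if true_maf == 0.0:
        return 0
    if true_maf == 1.0:
        return int(depth)
    if rho == 0.0:
        return int(rng.binomial(depth, true_maf))
    a = true_maf * (1.0 - rho) / rho
    b = (1.0 - true_maf) * (1.0 - rho) / rho
    p = rng.beta(a, b)
    return int(rng.binomial(depth, p))


def _truncated_normal_int(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int
) -> int:
    for _ in range(1000):
        x = int(round(rng.normal(mean, sd)))
        if lo <= x <= hi:
            return x
    return int(np.clip(round(mean), lo, hi))


def _somatic_count(rng: np.random.Generator, params: SimulationParams) -> int:
    if rng.random() < params.somatic_zero_prob:
        return 0
    for _ in range(1000):
        k = int(rng.geometric(params.somatic_geom_p))
        if k <= params.somatic_max:
            return k
    return 1


def _draw_alt(rng: np.random.Generator, ref: str, ti_fraction: float) -> str:
    if rng.random() < ti_fraction:
        return _TRANSITION[ref]
    return _TRANSVERSIONS[ref][rng.integers(2)]


def _draw_key(
    rng: np.random.Generator,
    gmap: MitoGeneMap,
    excluded_positions: set,
    ti_fraction: float,
    indel_fraction: float,
) -> VariantKey:
    while True:
        pos = int(rng.integers(1, GENOME_LENGTH + 1))
        if pos in excluded_positions:
            continue
        ref = gmap.ref_base(pos)
        if rng.random() < indel_fraction and pos < GENOME_LENGTH:
            if rng.random() < 0.5:  # insertion
                ins = "ACGT"[rng.integers(4)]
                return VariantKey(pos, ref, ref + ins)
            nxt = gmap.ref_base(pos + 1)
            return VariantKey(pos, ref + nxt, ref)
        return VariantKey(pos, ref, _draw_alt(rng, ref, ti_fraction))


def _germline_blood_maf(rng: np.random.Generator, p: SimulationParams) -> float:
    u = rng.random()
    if u < p.germline_hom_prob:
        return float(rng.uniform(p.hom_maf_low, 1.0))
    if u < p.germline_hom_prob + p.germline_verylow_prob:
        return float(rng.uniform(0.012, 0.02))
    return float(0.02 + 0.18 * rng.beta(1.2, 2.5))


def _germline_tumor_maf(
    rng: np.random.Generator, blood_maf: float, p: SimulationParams
) -> float:
    if blood_maf >= p.hom_maf_low:  # homoplasmic stays homoplasmic
        return float(rng.uniform(p.hom_maf_low, 1.0))
    if rng.random() < p.shift_prob:
        return float(rng.beta(*p.shift_beta))
    return blood_maf


def _somatic_tumor_maf(rng: np.random.Generator, p: SimulationParams) -> float:
    if rng.random() < p.somatic_hom_prob:
        return float(rng.uniform(0.96, 1.0))
    return float(0.01 + 0.94 * rng.beta(*p.somatic_het_beta))


def _categorical(rng: np.random.Generator, pairs) -> str:
    labels = [l for l, _ in pairs]
    probs = np.array([p for _, p in pairs], float)
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def generate_cohort(
    params: Optional[SimulationParams] = None,
    seed: Optional[int] = None,
    gene_map: Optional[MitoGeneMap] = None,
    panel: Optional[HaplogroupPanel] = None,
) -> Tuple[List[PairedVariantRecord], pd.DataFrame, SyntheticTruth]:
    """Generate a matched-pair cohort: records, patient metadata, truth.

    ``seed`` overrides ``params.seed``; one of the two must be set.
    """
    params = params or SimulationParams()
    if seed is None:
        seed = params.seed
    if seed is None:
        raise InputError("an explicit seed is required")
    rng = np.random.default_rng(int(seed))
    gmap = gene_map or load_gene_map()
    panel = panel or load_panel()
    code = GeneticCode.vertebrate_mitochondrial()

    records: List[PairedVariantRecord] = []
    truth_rows: List[dict] = []
    patient_rows: List[dict] = []
    effect_cache: Dict[VariantKey, str] = {}

    def planted_effect(key: VariantKey) -> str:
        if key not in effect_cache:
            prim = primary_consequence(annotate(key, gmap, code))
            effect_cache[key] = prim.effect if prim else "unknown"
        return effect_cache[key]

    # cohort-level pool of shared germline polymorphic sites: population
    # variants recur across patients (the emulated study saw ~564 germline
    # positions across all blood samples), so per-patient germline draws
    # come from this pool with skewed popularity weights (a few common
    # variants, many near-singletons)
    marker_positions = {k.position for keys in panel.markers.values() for k in keys}
    pool: List[VariantKey] = []
    pool_positions: set = set(marker_positions)
    while len(pool) < params.germline_pool_size:
        key = _draw_key(
            rng, gmap, pool_positions,
            params.ti_fraction_germline, params.indel_fraction,
        )
        pool.append(key)
        pool_positions.add(key.position)
    raw_w = rng.beta(*params.germline_pool_weight_beta, size=len(pool))
    raw_w = np.maximum(raw_w, 1e-6)
    pool_weights = raw_w / raw_w.sum()
    # somatic mutations must avoid germline-evidenced sites: by the cohort-
    # level class definition a variant germline in any patient is germline
    germline_sites = pool_positions  # pool + backbone marker positions

    width = len(str(params.n_patients))
    for i in range(params.n_patients):
        pid = f"P{i + 1:0{width}d}"
        haplogroup = _categorical(rng, params.haplogroup_freqs)
        if rng.random() < params.unassigned_prob:
            subtype = "unassigned"
        else:
            subtype = _categorical(rng, params.subtype_probs)
        age = float(np.clip(rng.normal(params.age_mean, params.age_sd), 30, 92))

        used_positions: set = set()
        variants: List[tuple] = []  # (key, origin, blood_maf, tumor_maf, backbone)

        backbone = sorted(panel.markers[haplogroup])
        kept = [m for m in backbone if rng.random() >= params.marker_dropout]
        for key in kept:
            used_positions.add(key.position)
            b = float(rng.uniform(params.hom_maf_low, 1.0))
            t = float(rng.uniform(params.hom_maf_low, 1.0))
            variants.append((key, GERMLINE, b, t, True))

        n_germ = _truncated_normal_int(
            rng, params.germline_mean, params.germline_sd,
            params.germline_min, params.germline_max,
        )
        n_extra = min(max(0, n_germ - len(kept)), len(pool))
        chosen = rng.choice(len(pool), size=n_extra, replace=False, p=pool_weights)
        for idx in sorted(chosen):
            key = pool[idx]
            used_positions.add(key.position)
            b = _germline_blood_maf(rng, params)
            t = _germline_tumor_maf(rng, b, params)
            variants.append((key, GERMLINE, b, t, False))

        n_som = _somatic_count(rng, params)
        for _ in range(n_som):
            key = _draw_key(
                rng, gmap, used_positions | germline_sites,
                params.ti_fraction_somatic, params.indel_fraction,
            )
            used_positions.add(key.position)
            t = _somatic_tumor_maf(rng, params)
            variants.append((key, SOMATIC, 0.0, t, False))

        for key, origin, b_maf, t_maf, is_backbone in variants:
            b_depth = int(rng.integers(params.depth_min, params.depth_max + 1))
            t_depth = int(rng.integers(params.depth_min, params.depth_max + 1))
            b_alt = generate_read_counts(b_maf, b_depth, params.rho, rng)
            t_alt = generate_read_counts(t_maf, t_depth, params.rho, rng)
            records.append(
                PairedVariantRecord(
                    key=key,
                    blood=VariantObservation(pid, "blood", b_alt, b_depth),
                    tumor=VariantObservation(pid, "tumor", t_alt, t_depth),
                )
            )
            truth_rows.append(
                {
                    "patient_id": pid,
                    "position": key.position,
                    "ref": key.ref,
                    "alt": key.alt,
                    "true_origin": origin,
                    "true_blood_maf": b_maf,
                    "true_tumor_maf": t_maf,
                    "effect": planted_effect(key),
                    "backbone": is_backbone,
                }
            )
        patient_rows.append(
            {
                "patient_id": pid,
                "age": round(age, 1),
                "subtype": subtype,
                "haplogroup": haplogroup,
                "burden": n_som,
            }
        )

    patients = pd.DataFrame(patient_rows)
    surv = generate_survival(
        patients.assign(group=(patients["burden"] > 0).astype(int)),
        log_hr=params.survival_log_hr,
        rng=rng,
        baseline_hazard=params.baseline_hazard,
        censor_window=(params.censor_min, params.censor_max),
    )
    metadata = patients[["patient_id", "age", "subtype"]].merge(
        surv[["patient_id", "time", "event"]], on="patient_id"
    )
    metadata = metadata.rename(columns={"time": "follow_up_months"})
    metadata["vital_status"] = np.where(metadata.pop("event") == 1, "death", "censored")

    truth = SyntheticTruth(
        variants=pd.DataFrame(truth_rows),
        patients=patients.merge(surv[["patient_id", "group"]], on="patient_id"),
    )
    return records, metadata, truth


def generate_survival(
    patients: pd.DataFrame,
    log_hr: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    baseline_hazard: float = 0.009,
    censor_window: Tuple[float, float] = (30.0, 124.0),
) -> pd.DataFrame:
    """Exponential survival times with administrative censoring.

    ``patients`` needs ``patient_id`` and a binary ``group`` column; the
    hazard of group 1 is scaled by ``exp(log_hr)``.  Censoring times are
    uniform over ``censor_window`` (a degenerate window censors everyone
    still alive at that single time).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    group = patients["group"].to_numpy(int)
    n = len(patients)
    rate = baseline_hazard * np.exp(log_hr * group)
    event_time = rng.exponential(1.0 / rate)
    lo, hi = censor_window
    censor_time = np.full(n, float(lo)) if hi <= lo else rng.uniform(lo, hi, size=n)
    time = np.minimum(event_time, censor_time)
    return pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy(),
            "time": time,
            "event": (event_time <= censor_time).astype(int),
            "group": group,
        }
    )


def survival_experiment(
    n: int,
    log_hr: float,
    seed: int,
    baseline_hazard: float = 0.009,
    p_high: float = 0.5,
    censor_window: Tuple[float, float] = (30.0, 124.0),
) -> pd.DataFrame:
    """Standalone two-group survival dataset for recovery experiments.

    Returns columns suitable for :func:`mitopair.survival.hazard_ratio`:
    ``time``, ``event`` and a ``group`` label (low/high).
    """
    rng = np.random.default_rng(seed)
    patients = pd.DataFrame(
        {
            "patient_id": [f"S{i}" for i in range(n)],
            "group": (rng.random(n) < p_high).astype(int),
        }
    )
    df = generate_survival(
        patients, log_hr, rng=rng,
        baseline_hazard=baseline_hazard, censor_window=censor_window,
    )
    df["group"] = np.where(df["group"] == 1, "high", "low")
    return df


def records_to_tsv(records: List[PairedVariantRecord]) -> pd.DataFrame:
    """Flat paired-count table in the TSV dialect of :mod:`mitopair.io`."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "position": r.key.position,
                "ref": r.key.ref,
                "alt": r.key.alt,
                "blood_alt": r.blood.alt_reads,
                "blood_depth": r.blood.depth,
                "tumor_alt": r.tumor.alt_reads,
                "tumor_depth": r.tumor.depth,
            }
            for r in records
        ]
    )


def write_patient_vcf(records: List[PairedVariantRecord], path, patient_id: str) -> None:
    """Write one patient's records as a two-sample (blood, tumor) VCF 4.2."""
    recs = sorted(
        (r for r in records if r.patient_id == patient_id),
        key=lambda r: (r.key.position, r.key.alt),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=MT,length={GENOME_LENGTH}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tblood\ttumor\n")
        for r in recs:
            b, t = r.blood, r.tumor
            fh.write(
                f"MT\t{r.key.position}\t.\t{r.key.ref}\t{r.key.alt}\t.\tPASS\t.\t"
                f"AD:DP\t{b.depth - b.alt_reads},{b.alt_reads}:{b.depth}\t"
                f"{t.depth - t.alt_reads},{t.alt_reads}:{t.depth}\n"
            )
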