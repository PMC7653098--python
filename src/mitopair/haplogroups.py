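"""Haplogroup assignment by marker-panel scoring.

A maternal lineage (haplogroup) is called from a patient's blood variant
profile by comparing it against a panel of lineage-defining markers and
scoring each haplogroup with the Kulczynski measure

    score = 1/2 * ( n_found / n_expected  +  n_found / (n_found + n_extra) )

over the panel's marker universe: observed variants outside the universe
are ignored, since only lineage-defining positions are informative.  The
bundled panel is a small simplified fixture covering the seven top-level
haplogroups A, B, C, D, H, J and L with canonical diagnostic markers;
users may supply a fuller panel in the same TSV format (columns
``haplogroup/position/ref/alt``).  Only high-MAF blood variants (>0.5)
should enter scoring, because panel markers are effectively homoplasmic
in carriers — see :func:`blood_profile`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Optional, Set

import pandas as pd

from .classify import ClassifiedVariant
from .errors import ConfigurationError
from .io import VariantKey


@dataclass(frozen=True)
class HaplogroupPanel:
    """Expected marker sets per haplogroup label."""

    markers: Dict[str, FrozenSet[VariantKey]]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ConfigurationError("haplogroup panel is empty")
        for label, keys in self.markers.items():
            if not keys:
                raise ConfigurationError(f"haplogroup {label!r} has no markers")

    @property
    def universe(self) -> FrozenSet[VariantKey]:
        out: Set[VariantKey] = set()
        for keys in self.markers.values():
            out |= keys
        return frozenset(out)

    @property
    def labels(self) -> list:
        return sorted(self.markers)


def load_panel(path: Optional[str] = None) -> HaplogroupPanel:
    """Load the bundled (or a user-supplied) marker panel."""
    panel_path = (
        Path(path)
        if path
        else Path(importlib.resources.files("mitopair") / "data" / "haplogroup_panel.tsv")
    )
    if not panel_path.exists():
        raise ConfigurationError(f"haplogroup panel not found: {panel_path}")
    df = pd.read_csv(panel_path, sep="\t")
    required = {"haplogroup", "position", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"panel missing columns {required - set(df.columns)}")
    markers: Dict[str, Set[VariantKey]] = {}
    for row in df.itertuples(index=False):
        markers.setdefault(str(row.haplogroup), set()).add(
            VariantKey(int(row.position), str(row.ref), str(row.alt)).validate()
        )
    return HaplogroupPanel(markers={k: frozenset(v) for k, v in markers.items()})


@dataclass(frozen=True)
class HaplogroupCall:
    """Best-scoring haplogroup for one patient profile."""

    label: str
    score: float
    n_expected: int
    n_found: int
    n_extra: int
    tied: bool = False
    no_call: bool = False


def kulczynski_score(observed: Set[VariantKey], expected: FrozenSet[VariantKey]) -> tuple:
    """(score, n_found, n_extra) of one haplogroup for a panel-restricted profile."""
    n_found = len(observed & expected)
    n_extra = len(observed - expected)
    if n_found == 0:
        return 0.0, 0, n_extra
    precision = n_found / (n_found + n_extra)
    recall = n_found / len(expected)
    return 0.5 * (recall + precision), n_found, n_extra


def assign_haplogroup(
    blood_variants: Iterable[VariantKey], panel: HaplogroupPanel
) -> HaplogroupCall:
    """Score every panel haplogroup and return the best call.

    The observed profile is first restricted to the panel's marker
    universe.  Ties are broken lexicographically and flagged; an empty
    restricted profile yields a no-call with score 0.
    """
    observed = set(blood_variants) & set(panel.universe)
    scored = []
    for label in panel.labels:
        score, n_found, n_extra = kulczynski_score(observed, panel.markers[label])
        scored.append((score, label, n_found, n_extra))
    best_score = max(s[0] for s in scored)
    winners = [s for s in scored if s[0] == best_score]
    score, label, n_found, n_extra = min(winners, key=lambda s: s[1])
    return HaplogroupCall(
        label=label,
        score=score,
        n_expected=len(panel.markers[label]),
        n_found=n_found,
        n_extra=n_extra,
        tied=len(winners) > 1,
        no_call=not observed,
    )


def blood_profile(
    records: Iterable[ClassifiedVariant], min_maf: float = 0.5
) -> Dict[str, Set[VariantKey]]:
    """Per-patient sets of high-MAF blood variants for haplogroup scoring."""
    profiles: Dict[str, Set[VariantKey]] = {}
    for cv in records:
        profiles.setdefault(cv.patient_id, set())
        if cv.record.blood.maf > min_maf:
            profiles[cv.patient_id].add(cv.key)
    return profiles
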