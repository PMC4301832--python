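"""Chronic diagnosis groups: ICD-10 prefix mapping and gender restrictions.

A diagnosis group bundles ICD-10 codes with comparable pathophysiology into a
single chronic condition. The shipped default configuration defines the 46
groups used throughout the package; the ICD-10 prefix lists are representative
stand-ins (the full grouping is not redistributable) and are validated to be
mutually non-overlapping, which guarantees every code maps to at most one
group.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

RESTRICTIONS = ("both", "female_only", "male_only")


@dataclass(frozen=True)
class DiagnosisGroup:
    """One chronic condition category built from ICD-10 code prefixes."""

    group_id: str
    label: str
    icd10_patterns: tuple[str, ...]
    gender_restriction: str = "both"
    prevalence_female: float = 0.0
    prevalence_male: float = 0.0
    synthetic_prevalence: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.icd10_patterns:
            raise ValueError(f"group {self.group_id!r} has no ICD-10 patterns")
        if self.gender_restriction not in RESTRICTIONS:
            raise ValueError(
                f"group {self.group_id!r}: gender_restriction must be one of "
                f"{RESTRICTIONS}, got {self.gender_restriction!r}"
            )

    def matches(self, code: str) -> bool:
        code = code.strip().upper()
        return any(code.startswith(p) for p in self.icd10_patterns)

    def allowed_for(self, gender: str) -> bool:
        if self.gender_restriction == "female_only":
            return gender == "F"
        if self.gender_restriction == "male_only":
            return gender == "M"
        return True

    def prevalence(self, gender: str) -> float:
        return self.prevalence_female if gender == "F" else self.prevalence_male


class MappingError(ValueError):
    """Invalid diagnosis-group configuration (duplicate ids, overlapping codes)."""


def validate_groups(groups: list[DiagnosisGroup]) -> None:
    """Reject duplicate ids and prefix sets under which one code could map twice."""
    seen: dict[str, str] = {}
    ids = set()
    for g in groups:
        if g.group_id in ids:
            raise MappingError(f"duplicate group_id {g.group_id!r}")
        ids.add(g.group_id)
        for pat in g.icd10_patterns:
            pat = pat.upper()
            for other, owner in seen.items():
                if owner != g.group_id and (pat.startswith(other) or other.startswith(pat)):
                    raise MappingError(
                        f"overlapping ICD-10 patterns: {pat!r} ({g.group_id}) vs "
                        f"{other!r} ({owner}) — a code may match at most one group"
                    )
            seen[pat] = g.group_id
    restricted = {
        g.group_id
        for g in groups
        if g.gender_restriction == "female_only" and g.prevalence_male != 0.0
        or g.gender_restriction == "male_only" and g.prevalence_female != 0.0
    }
    if restricted:
        raise MappingError(
            f"gender-restricted groups must have prevalence 0 in the excluded "
            f"gender: {sorted(restricted)}"
        )


def load_groups(path) -> list[DiagnosisGroup]:
    """Read a diagnosis-group config (YAML, one record per group) and validate it."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    groups = [
        DiagnosisGroup(
            group_id=rec["id"],
            label=rec.get("label", rec["id"]),
            icd10_patterns=tuple(str(p).upper() for p in rec["icd10"]),
            gender_restriction=rec.get("restriction", "both"),
            prevalence_female=float(rec.get("prevalence_female", 0.0)),
            prevalence_male=float(rec.get("prevalence_male", 0.0)),
            synthetic_prevalence=bool(rec.get("synthetic_prevalence", False)),
        )
        for rec in raw["groups"]
    ]
    validate_groups(groups)
    return groups


def default_groups() -> list[DiagnosisGroup]:
    """The packaged 46-group configuration."""
    ref = importlib.resources.files("triadnet.data") / "diagnosis_groups.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_groups(path)
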