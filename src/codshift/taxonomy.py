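"""Cause-of-death taxonomy.

A registry's cause-of-death recode groups the underlying cause of each death
into a controlled vocabulary ("lung cancer", "COPD", "septicemia", ...).  For
the analyses here each cause label additionally belongs to one of four broad
groups: the index cancer (lung), other cancers, non-cancer diseases, and
unknown/unrecorded causes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence


class CauseGroup(str, Enum):
    """Broad grouping of a cause-of-death label."""

    LUNG_CANCER = "LUNG_CANCER"
    NON_LUNG_CANCER = "NON_LUNG_CANCER"
    NON_CANCER = "NON_CANCER"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class CauseTaxonomy:
    """An ordered cause vocabulary with a group assignment per label.

    Parameters
    ----------
    categories
        Ordered, unique cause labels.
    group_of
        Map from every label to its :class:`CauseGroup`.  Every group except
        ``UNKNOWN`` must have at least one label.
    """

    categories: tuple[str, ...]
    group_of: Mapping[str, CauseGroup] = field(repr=False)

    def __init__(self, categories: Sequence[str], group_of: Mapping[str, CauseGroup | str]):
        cats = tuple(categories)
        if len(set(cats)) != len(cats):
            raise ValueError("cause labels must be unique")
        mapped = {c: CauseGroup(group_of[c]) for c in cats}
        if set(group_of) != set(cats):
            raise ValueError("group_of keys must match categories exactly")
        present = set(mapped.values())
        required = {CauseGroup.LUNG_CANCER, CauseGroup.NON_LUNG_CANCER, CauseGroup.NON_CANCER}
        missing = required - present
        if missing:
            raise ValueError(f"taxonomy missing labels for groups: {sorted(g.value for g in missing)}")
        object.__setattr__(self, "categories", cats)
        object.__setattr__(self, "group_of", mapped)

    def __contains__(self, label: str) -> bool:
        return label in self.group_of

    def __len__(self) -> int:
        return len(self.categories)

    def group(self, label: str) -> CauseGroup:
        try:
            return self.group_of[label]
        except KeyError:
            raise KeyError(f"unknown cause label: {label!r}") from None

    def labels_in_group(self, group: CauseGroup | str) -> tuple[str, ...]:
        group = CauseGroup(group)
        return tuple(c for c in self.categories if self.group_of[c] is group)

    def resolve_cause_group(self, cause_group: CauseGroup | str) -> tuple[str, ...]:
        """Return the labels selected by a group name or a single label."""
        try:
            return self.labels_in_group(CauseGroup(cause_group))
        except ValueError:
            if cause_group in self.group_of:
                return (str(cause_group),)
            raise KeyError(f"{cause_group!r} is neither a cause group nor a taxonomy label")


#: Non-cancer cause labels used by default, in registry-recode style.
NON_CANCER_CAUSES: tuple[str, ...] = (
    "heart diseases",
    "COPD",
    "cerebrovascular disease",
    "pneumonia and influenza",
    "septicemia",
    "other infectious diseases",
    "accidents and adverse effects",
    "hypertension",
    "chronic liver disease and cirrhosis",
    "diabetes mellitus",
)

NON_LUNG_CANCER_CAUSES: tuple[str, ...] = (
    "colon cancer",
    "liver cancer",
    "nervous system cancer",
    "other cancers",
)


def default_taxonomy() -> CauseTaxonomy:
    """The default lung-cancer-cohort taxonomy (16 labels, 4 groups)."""
    categories = ("lung cancer", *NON_LUNG_CANCER_CAUSES, *NON_CANCER_CAUSES, "unknown")
    group_of: dict[str, CauseGroup] = {"lung cancer": CauseGroup.LUNG_CANCER}
    group_of.update({c: CauseGroup.NON_LUNG_CANCER for c in NON_LUNG_CANCER_CAUSES})
    group_of.update({c: CauseGroup.NON_CANCER for c in NON_CANCER_CAUSES})
    group_of["unknown"] = CauseGroup.UNKNOWN
    return CauseTaxonomy(categories, group_of)
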