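"""Survey schema: scale definitions, field declarations and the default codebook.

The survey instrument has three wellbeing scales — CASP-19 quality of life
(19 items, 1-4), Satisfaction with Life (5 items, 1-7) and the WHO-5
psychological wellbeing index (5 items, 1-6, where 1 = "All of the time" is
the *best* response) — plus demographic and lifelong-learning fields.  The
codebook declares, for every column of a survey table, its kind (ordinal,
nominal, count, flag, item), its allowed levels or bounds, and, for item
fields, which scale the item belongs to and its orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

QUALITY = "quality"
SATISFACTION = "satisfaction"
PSYCHOLOGICAL = "psychological"
SCALE_IDS = (QUALITY, SATISFACTION, PSYCHOLOGICAL)

HIGHER_IS_BETTER = "higher_is_better"
LOWER_IS_BETTER = "lower_is_better"


class SchemaError(ValueError):
    """A table does not match the codebook (missing/undeclared column)."""


class ValidationError(ValueError):
    """A cell value violates its codebook declaration."""


@dataclass(frozen=True)
class ScaleDefinition:
    """One wellbeing instrument: ordered items with per-item response bounds.

    Parameters
    ----------
    scale_id : str
        One of ``quality``, ``satisfaction``, ``psychological``.
    items : tuple of str
        Ordered item column names; the number of items is the ``k`` of the
        index formula.
    m, M : tuple of float
        Per-item lower / upper response bound.
    orientation : tuple of str
        Per-item flag; ``lower_is_better`` items are reflected during
        normalization so that 1 always means best wellbeing.
    """

    scale_id: str
    items: tuple[str, ...]
    m: tuple[float, ...]
    M: tuple[float, ...]
    orientation: tuple[str, ...]

    def __post_init__(self) -> None:
        k = len(self.items)
        if not (len(self.m) == len(self.M) == len(self.orientation) == k):
            raise ValueError("items, m, M and orientation must have equal length")
        for item, lo, hi in zip(self.items, self.m, self.M):
            if hi <= lo:
                raise ValueError(f"item {item!r}: upper bound {hi} <= lower bound {lo}")
        for o in self.orientation:
            if o not in (HIGHER_IS_BETTER, LOWER_IS_BETTER):
                raise ValueError(f"unknown orientation {o!r}")

    @property
    def k(self) -> int:
        return len(self.items)

    @classmethod
    def uniform(
        cls,
        scale_id: str,
        items: Sequence[str],
        m: float,
        M: float,
        orientation: str = HIGHER_IS_BETTER,
    ) -> "ScaleDefinition":
        """Scale whose items all share the same bounds and orientation."""
        k = len(items)
        return cls(scale_id, tuple(items), (m,) * k, (M,) * k, (orientation,) * k)


@dataclass(frozen=True)
class FieldSpec:
    """Declaration for one survey column.

    ``kind`` is one of ``item`` (scale item, numeric within bounds),
    ``ordinal``/``nominal`` (value drawn from ``levels``), ``count``
    (non-negative integer) or ``flag`` (0/1).  ``labels``, when given for an
    item field, maps verbal responses onto the integer grid ``m..M`` in
    listed order (worst first), so re-mapping the verbal anchors is a pure
    codebook change.
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()
    scale_id: str | None = None
    labels: tuple[str, ...] = ()
    allow_missing: bool = False


@dataclass
class Codebook:
    """Complete declaration of a survey table: fields plus scale membership."""

    fields: dict[str, FieldSpec]
    scales: dict[str, ScaleDefinition]
    id_field: str = "respondent_id"

    def __post_init__(self) -> None:
        declared_items = {f.name for f in self.fields.values() if f.kind == "item"}
        scale_items = {it for s in self.scales.values() for it in s.items}
        if declared_items != scale_items:
            diff = declared_items.symmetric_difference(scale_items)
            raise SchemaError(f"item declarations and scales disagree on: {sorted(diff)}")

    @property
    def columns(self) -> list[str]:
        return [self.id_field] + list(self.fields)

    def bounds(self, item: str) -> tuple[float, float, str]:
        """Return (m, M, orientation) for one item column."""
        spec = self.fields[item]
        scale = self.scales[spec.scale_id]
        j = scale.items.index(item)
        return scale.m[j], scale.M[j], scale.orientation[j]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "id_field": self.id_field,
            "fields": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    **({"levels": list(f.levels)} if f.levels else {}),
                    **({"scale_id": f.scale_id} if f.scale_id else {}),
                    **({"labels": list(f.labels)} if f.labels else {}),
                    **({"allow_missing": True} if f.allow_missing else {}),
                }
                for f in self.fields.values()
            ],
            "scales": [
                {
                    "scale_id": s.scale_id,
                    "items": list(s.items),
                    "m": list(s.m),
                    "M": list(s.M),
                    "orientation": list(s.orientation),
                }
                for s in self.scales.values()
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "Codebook":
        fields = {
            f["name"]: FieldSpec(
                name=f["name"],
                kind=f["kind"],
                levels=tuple(f.get("levels", ())),
                scale_id=f.get("scale_id"),
                labels=tuple(f.get("labels", ())),
                allow_missing=bool(f.get("allow_missing", False)),
            )
            for f in d["fields"]
        }
        scales = {
            s["scale_id"]: ScaleDefinition(
                scale_id=s["scale_id"],
                items=tuple(s["items"]),
                m=tuple(float(x) for x in s["m"]),
                M=tuple(float(x) for x in s["M"]),
                orientation=tuple(s["orientation"]),
            )
            for s in d["scales"]
        }
        return cls(fields=fields, scales=scales, id_field=d.get("id_field", "respondent_id"))

    @classmethod
    def from_yaml(cls, path) -> "Codebook":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# -- default instrument ------------------------------------------------------

CASP_ITEMS = tuple(f"casp_{i:02d}" for i in range(1, 20))
SWLS_ITEMS = tuple(f"swls_{i:02d}" for i in range(1, 6))
WHO_ITEMS = tuple(f"who_{i:02d}" for i in range(1, 6))

CLASS_FLAGS = (
    "class_singing",
    "class_dancing",
    "class_music",
    "class_exercise",
    "class_other",
)
PLACE_FLAGS = (
    "place_gym",
    "place_sports_club",
    "place_museum",
    "place_library",
    "place_educational_institute",
    "place_other",
)

MARITAL_LEVELS = ("single", "married", "widowed", "divorced")
EDUCATION_LEVELS = ("no formal", "primary", "secondary", "post-secondary", "tertiary")
WORK_LEVELS = ("working", "part-time", "ad-hoc", "freelance", "retired", "unemployed")
WORKING_LEVELS = ("working", "part-time", "ad-hoc", "freelance")  # collapse to work "yes"
HEALTH_LEVELS = ("poor", "fair", "good", "very good")
REL_LEVELS = ("poor", "fair", "good", "excellent")
YESNO = ("no", "yes")

# CASP-19 verbal anchors, worst-to-best under the default orientation.
CASP_LABELS = ("Never", "Not often", "Sometimes", "Often")


def default_codebook() -> Codebook:
    """The shipped codebook: CASP-19 / SWLS / WHO-5 plus learning fields.

    Orientation defaults: CASP and Satisfaction-with-Life items run low=worst,
    high=best; WHO-5 runs 1 ("All of the time") = best to 6 ("At no time") =
    worst and is therefore declared ``lower_is_better``.
    """
    scales = {
        QUALITY: ScaleDefinition.uniform(QUALITY, CASP_ITEMS, 1, 4),
        SATISFACTION: ScaleDefinition.uniform(SATISFACTION, SWLS_ITEMS, 1, 7),
        PSYCHOLOGICAL: ScaleDefinition.uniform(
            PSYCHOLOGICAL, WHO_ITEMS, 1, 6, orientation=LOWER_IS_BETTER
        ),
    }
    fields: dict[str, FieldSpec] = {}
    for it in CASP_ITEMS:
        fields[it] = FieldSpec(it, "item", scale_id=QUALITY, labels=CASP_LABELS)
    for it in SWLS_ITEMS:
        fields[it] = FieldSpec(it, "item", scale_id=SATISFACTION)
    for it in WHO_ITEMS:
        fields[it] = FieldSpec(it, "item", scale_id=PSYCHOLOGICAL)

    fields["marital"] = FieldSpec("marital", "nominal", levels=MARITAL_LEVELS)
    fields["no_children"] = FieldSpec("no_children", "count")
    fields["education"] = FieldSpec("education", "ordinal", levels=EDUCATION_LEVELS)
    fields["work"] = FieldSpec("work", "nominal", levels=WORK_LEVELS)
    fields["gender"] = FieldSpec("gender", "nominal", levels=("male", "female"))
    fields["health"] = FieldSpec("health", "ordinal", levels=HEALTH_LEVELS)
    fields["disability"] = FieldSpec("disability", "flag")
    fields["mobility"] = FieldSpec("mobility", "flag")
    fields["family_rel"] = FieldSpec("family_rel", "ordinal", levels=REL_LEVELS)
    fields["friends_rel"] = FieldSpec("friends_rel", "ordinal", levels=REL_LEVELS)
    fields["learn_elderly"] = FieldSpec(
        "learn_elderly", "nominal", levels=YESNO, allow_missing=True
    )
    for f in CLASS_FLAGS + PLACE_FLAGS:
        fields[f] = FieldSpec(f, "flag")
    return Codebook(fields=fields, scales=scales)
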