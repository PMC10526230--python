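"""Ordinal semantic attribute levels and their binary re-categorization.

Radiologists grade lung nodules on ordinal scales: malignancy suspicion,
margin sharpness, sphericity, subtlety (conspicuity against surroundings)
and internal texture each on 1-5, and calcification pattern on 1-6 where
level 6 means "absent".  For binary screening these collapse to two
classes: levels 4-5 are positive for the five 5-level attributes, and for
calcification only level 6 ("absent") is positive, i.e. the positive class
is *absence* of calcification.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict

import pandas as pd

#: Attribute names in canonical head order (the five semantic tasks, then
#: malignancy, the main disease-level task, last).
SEMANTIC_FEATURES = ("calcification", "margin", "sphericity", "subtlety", "texture")
ALL_FEATURES = SEMANTIC_FEATURES + ("malignancy",)

#: Number of ordinal levels per attribute.
N_LEVELS = {f: (6 if f == "calcification" else 5) for f in ALL_FEATURES}

# Text labels accepted by the level parser, per attribute (case-insensitive).
_TEXT_LEVELS = {
    "malignancy": {
        "highly unlikely": 1,
        "moderately unlikely": 2,
        "indeterminate": 3,
        "moderately suspicious": 4,
        "highly suspicious": 5,
    },
    "margin": {"poorly defined": 1, "sharp": 5},
    "sphericity": {"linear": 1, "ovoid": 3, "round": 5},
    "subtlety": {
        "extremely subtle": 1,
        "moderately subtle": 2,
        "fairly subtle": 3,
        "moderately obvious": 4,
        "obvious": 5,
    },
    "texture": {"non-solid": 1, "part solid": 3, "solid": 5},
    "calcification": {
        "popcorn": 1,
        "laminated": 2,
        "solid": 3,
        "non-central": 4,
        "central": 5,
        "absent": 6,
    },
}


class LevelError(ValueError):
    """An ordinal level is outside the documented range for its attribute."""


def parse_level(feature: str, value) -> int:
    """Parse an ordinal level given either numerically or as a text label.

    Text labels ("Absent", "Obvious", ...) are matched case-insensitively.
    """
    if feature not in ALL_FEATURES:
        raise LevelError(f"unknown semantic feature {feature!r}")
    if isinstance(value, str):
        stripped = value.strip().lower()
        try:
            level = int(stripped)
        except ValueError:
            try:
                level = _TEXT_LEVELS[feature][stripped]
            except KeyError:
                raise LevelError(
                    f"unrecognized level {value!r} for feature {feature!r}"
                ) from None
    else:
        level = int(value)
        if level != value:
            raise LevelError(f"non-integer level {value!r} for feature {feature!r}")
    if not 1 <= level <= N_LEVELS[feature]:
        raise LevelError(
            f"level {level} out of range 1-{N_LEVELS[feature]} for feature {feature!r}"
        )
    return level


@dataclass(frozen=True)
class OrdinalAttributes:
    """One nodule's ordinal levels: 1-5 everywhere except calcification (1-6)."""

    malignancy: int
    margin: int
    sphericity: int
    subtlety: int
    texture: int
    calcification: int

    def __post_init__(self):
        for f in fields(self):
            object.__setattr__(self, f.name, parse_level(f.name, getattr(self, f.name)))

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BinaryLabels:
    """Binary (0/1) label per attribute, derived from :func:`binarize`."""

    malignancy: int
    margin: int
    sphericity: int
    subtlety: int
    texture: int
    calcification: int

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v not in (0, 1):
                raise LevelError(f"binary label {f.name} must be 0/1, got {v!r}")

    def as_dict(self) -> dict:
        return asdict(self)

    def as_tuple(self, order=ALL_FEATURES) -> tuple:
        return tuple(getattr(self, f) for f in order)


def binarize(attrs: OrdinalAttributes) -> BinaryLabels:
    """Collapse ordinal levels to binary classes.

    Malignancy, margin, sphericity, subtlety and texture: levels 1-3 map to
    0 and 4-5 to 1.  Calcification: levels 1-5 (a calcification pattern is
    present) map to 0 and level 6 ("absent") to 1.
    """
    return BinaryLabels(
        malignancy=int(attrs.malignancy >= 4),
        margin=int(attrs.margin >= 4),
        sphericity=int(attrs.sphericity >= 4),
        subtlety=int(attrs.subtlety >= 4),
        texture=int(attrs.texture >= 4),
        calcification=int(attrs.calcification == 6),
    )


def binarize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append binary ``<feature>_bin`` columns to an ordinal label table.

    The table must carry one ordinal column per attribute; entries may be
    numeric levels or Table-style text labels.
    """
    out = table.copy()
    for feat in ALL_FEATURES:
        if feat not in out.columns:
            raise LevelError(f"label table is missing column {feat!r}")
        levels = [parse_level(feat, v) for v in out[feat]]
        out[feat] = levels
        if feat == "calcification":
            out[feat + "_bin"] = [int(v == 6) for v in levels]
        else:
            out[feat + "_bin"] = [int(v >= 4) for v in levels]
    return out


def read_label_table(path) -> pd.DataFrame:
    """Read a nodule label CSV (columns: id + the six ordinal attributes)."""
    table = pd.read_csv(path)
    if "id" not in table.columns:
        raise LevelError("label table is missing an 'id' column")
    return binarize_table(table)


def write_label_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
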