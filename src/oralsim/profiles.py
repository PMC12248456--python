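"""Risk-factor profiles: the covariate vector carried by every simulated individual.

A profile holds the exposures and molecular markers that enter the three
transition hazards of the four-state progression model
(normal -> leukoplakia -> erythroleukoplakia -> oral cancer):

* betel-quid chewing and cigarette smoking as four-level dose categories
  (0 = occasional/none is the reference level),
* HPV infection status,
* eight binary miRNA aberrant-expression indicators,
* nineteen binary risk-genotype indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

BETEL_LEVELS = (
    "Occasional use",
    "1-10 pieces per day",
    "11-20 pieces per day",
    "20+ pieces per day",
)
SMOKING_LEVELS = (
    "Occasional use",
    "1-10 sticks per day",
    "11-20 sticks per day",
    "20+ sticks per day",
)

# miRNA aberrant-expression flags. Four of them act on the occurrence of
# leukoplakia and all eight on the malignant transformation of
# erythroleukoplakia; each is a single per-individual flag shared by both
# transitions.
MIRNA_FLAGS = (
    "miR_3614",
    "miR_10b",
    "miR_215",
    "miR_182",
    "miR_431",
    "miR_486",
    "miR_7",
    "miR_4707",
)

# Risk-genotype / epigenetic flags acting on erythroleukoplakia -> cancer.
GENOTYPE_FLAGS = (
    "PAI1",
    "ACE",
    "TIMP2",
    "hOGG1",
    "ERCC5",
    "miR137_meth",
    "TIMP3",
    "BRCA1",
    "COL9A1",
    "NOTCH1",
    "HSPA13",
    "NFKB1_rs28362491",
    "NFKB1_rs72696119",
    "H19_rs217727",
    "H19_rs2839701",
    "FAT1",
    "MALAT1",
    "RYR2",
    "P53",
)

BINARY_COLUMNS = ("hpv",) + MIRNA_FLAGS + GENOTYPE_FLAGS
PROFILE_COLUMNS = ("betel_category", "smoking_category") + BINARY_COLUMNS


@dataclass
class RiskFactorProfile:
    """One individual's exposure / genotype / miRNA indicator vector."""

    betel_category: int = 0
    smoking_category: int = 0
    hpv: int = 0
    flags: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.betel_category not in range(4):
            raise ValueError(f"betel_category must be 0..3, got {self.betel_category}")
        if self.smoking_category not in range(4):
            raise ValueError(f"smoking_category must be 0..3, got {self.smoking_category}")
        if self.hpv not in (0, 1):
            raise ValueError(f"hpv must be 0/1, got {self.hpv}")
        known = set(MIRNA_FLAGS) | set(GENOTYPE_FLAGS)
        for name, value in self.flags.items():
            if name not in known:
                raise ValueError(f"unknown risk-factor flag {name!r}")
            if value not in (0, 1):
                raise ValueError(f"flag {name!r} must be 0/1, got {value}")

    def to_series(self) -> pd.Series:
        data = {col: 0 for col in PROFILE_COLUMNS}
        data["betel_category"] = self.betel_category
        data["smoking_category"] = self.smoking_category
        data["hpv"] = self.hpv
        data.update(self.flags)
        return pd.Series(data, index=list(PROFILE_COLUMNS))

    def to_frame(self) -> pd.DataFrame:
        return self.to_series().to_frame().T


REFERENCE_PROFILE = RiskFactorProfile()


def validate_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Check a profile table has the expected columns and value ranges."""
    missing = [c for c in PROFILE_COLUMNS if c not in profiles.columns]
    if missing:
        raise ValueError(f"profile table missing columns: {missing}")
    for col in ("betel_category", "smoking_category"):
        vals = profiles[col].to_numpy()
        if ((vals < 0) | (vals > 3)).any():
            raise ValueError(f"{col} outside 0..3")
    for col in BINARY_COLUMNS:
        vals = profiles[col].to_numpy()
        if ((vals != 0) & (vals != 1)).any():
            raise ValueError(f"{col} must be binary 0/1")
    return profiles
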