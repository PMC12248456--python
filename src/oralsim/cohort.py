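"""Synthetic screening cohorts.

Generates seeded cohorts of risk-factor profiles emulating a high-risk oral
cancer screening population: categorical betel-quid and smoking exposure,
HPV status, nineteen risk genotypes and eight miRNA aberration flags, each
drawn independently from configurable marginal prevalences. Default
marginals reproduce the published simulated-cohort distribution (betel,
smoking and HPV as decile-table row averages) and the published
control-group genotype frequencies; miRNA aberration prevalences are not
published and default to 0.25.

Risk factors are sampled independently: the enrichment of heavy exposure in
upper risk deciles is emergent from the composite score, not built into the
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .evidence import load_evidence
from .profiles import GENOTYPE_FLAGS, MIRNA_FLAGS, PROFILE_COLUMNS, validate_profiles

__all__ = [
    "PrevalenceTable",
    "Cohort",
    "default_prevalences",
    "generate_cohort",
    "decile_distribution_table",
]

#: Decile-table row averages for betel-quid use (occasional, 1-10, 11-20, 20+).
DEFAULT_BETEL = (0.240, 0.302, 0.330, 0.128)
#: Decile-table row averages for smoking; sum to 1.001 due to rounding and are
#: renormalised at construction.
DEFAULT_SMOKING = (0.769, 0.141, 0.062, 0.029)
DEFAULT_HPV = 0.17
DEFAULT_MIRNA_PREVALENCE = 0.25


@dataclass
class PrevalenceTable:
    """Marginal prevalences from which cohort profiles are sampled."""

    betel: tuple[float, float, float, float]
    smoking: tuple[float, float, float, float]
    hpv: float
    genotype: dict[str, float]
    mirna: dict[str, float]

    def __post_init__(self) -> None:
        for name, probs in (("betel", self.betel), ("smoking", self.smoking)):
            probs = tuple(float(p) for p in probs)
            if len(probs) != 4:
                raise ValueError(f"{name} prevalences must have 4 categories")
            if any(p < 0 or p > 1 for p in probs):
                raise ValueError(f"{name} prevalences must lie in [0, 1]")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} prevalences must sum to 1")
            setattr(self, name, probs)
        if not 0 <= self.hpv <= 1:
            raise ValueError("hpv prevalence must lie in [0, 1]")
        if set(self.genotype) != set(GENOTYPE_FLAGS):
            raise ValueError("genotype prevalences must cover all 19 genotype flags")
        if set(self.mirna) != set(MIRNA_FLAGS):
            raise ValueError("mirna prevalences must cover all 8 miRNA flags")
        for d in (self.genotype, self.mirna):
            for k, p in d.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"prevalence of {k!r} must lie in [0, 1]")

    def to_yaml(self, path) -> None:
        payload = {
            "betel": list(self.betel),
            "smoking": list(self.smoking),
            "hpv": self.hpv,
            "genotype": dict(self.genotype),
            "mirna": dict(self.mirna),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PrevalenceTable":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        try:
            return cls(
                betel=tuple(payload["betel"]),
                smoking=tuple(payload["smoking"]),
                hpv=float(payload["hpv"]),
                genotype={k: float(v) for k, v in payload["genotype"].items()},
                mirna={k: float(v) for k, v in payload["mirna"].items()},
            )
        except KeyError as exc:
            raise ValueError(f"prevalence file missing field {exc}") from exc


def default_prevalences() -> PrevalenceTable:
    """Default marginals of the simulated high-risk screening population."""
    smoking = np.asarray(DEFAULT_SMOKING)
    smoking = tuple(smoking / smoking.sum())
    evidence = load_evidence()
    genotype = {}
    for flag in GENOTYPE_FLAGS:
        entries = [e for e in evidence if e.factor_id == flag and e.transition == "E->C"]
        if len(entries) != 1 or entries[0].control_prevalence is None:
            raise RuntimeError(f"no control prevalence available for {flag}")
        genotype[flag] = entries[0].control_prevalence
    mirna = {flag: DEFAULT_MIRNA_PREVALENCE for flag in MIRNA_FLAGS}
    return PrevalenceTable(
        betel=DEFAULT_BETEL,
        smoking=smoking,
        hpv=DEFAULT_HPV,
        genotype=genotype,
        mirna=mirna,
    )


@dataclass
class Cohort:
    """A generated cohort: profile table plus its generation provenance."""

    profiles: pd.DataFrame
    seed: int
    prevalences: PrevalenceTable = field(repr=False)

    def __len__(self) -> int:
        return len(self.profiles)


def _sample_categorical(probs, n: int, rng: np.random.Generator) -> np.ndarray:
    cumulative = np.cumsum(probs)
    return np.searchsorted(cumulative, rng.random(n), side="right").astype(np.int8)


def generate_cohort(
    n: int,
    prevalences: PrevalenceTable | None = None,
    seed: int = 0,
) -> Cohort:
    """Sample ``n`` independent risk-factor profiles, reproducibly by seed."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if prevalences is None:
        prevalences = default_prevalences()
    rng = np.random.default_rng(seed)
    data = {
        "betel_category": _sample_categorical(prevalences.betel, n, rng),
        "smoking_category": _sample_categorical(prevalences.smoking, n, rng),
        "hpv": (rng.random(n) < prevalences.hpv).astype(np.int8),
    }
    for flag in MIRNA_FLAGS:
        data[flag] = (rng.random(n) < prevalences.mirna[flag]).astype(np.int8)
    for flag in GENOTYPE_FLAGS:
        data[flag] = (rng.random(n) < prevalences.genotype[flag]).astype(np.int8)
    profiles = pd.DataFrame(data, columns=list(PROFILE_COLUMNS))
    profiles.insert(0, "id", np.arange(n))
    profiles = profiles.set_index("id")
    return Cohort(profiles=profiles, seed=seed, prevalences=prevalences)


def decile_distribution_table(profiles: pd.DataFrame, deciles) -> pd.DataFrame:
    """Percentage distribution of betel, smoking and HPV by risk decile.

    Mirrors the published decile-distribution layout: one row per category,
    one column per decile; each categorical block sums to 100% per decile.
    """
    validate_profiles(profiles)
    deciles = np.asarray(deciles)
    if len(deciles) != len(profiles):
        raise ValueError("decile labels and profile table differ in length")
    from .profiles import BETEL_LEVELS, SMOKING_LEVELS

    blocks = []
    layout = [
        ("Betel nut chewing", "betel_category", BETEL_LEVELS),
        ("Smoking", "smoking_category", SMOKING_LEVELS),
        ("HPV infection", "hpv", ("No", "Yes")),
    ]
    values = {col: profiles[col].to_numpy() for _, col, _ in layout}
    for block_name, col, labels in layout:
        for level, label in enumerate(labels):
            row = {"block": block_name, "category": label}
            for d in range(1, 11):
                mask = deciles == d
                row[d] = 100.0 * (values[col][mask] == level).mean()
            blocks.append(row)
    return pd.DataFrame(blocks).set_index(["block", "category"])
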