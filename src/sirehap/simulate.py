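"""Half-sib gamete-transmission simulator with a known-truth log.

Each sire is a double heterozygote carrying two parental haplotypes H1, H2.
A paternal gamete is H1 or H2 (equiprobable) with probability 1 - r, or one
of the two single-crossover products (equiprobable) with probability r,
where r in [0, 0.5] is the recombination fraction between the two regions.
Each progeny genotype is the unordered union of the paternal gamete allele
and an independent maternal draw per region from stated allele frequencies;
dams are not output (half-sib design, maternal genotypes unknown).  Every
draw is logged so inference can be checked against the simulated truth.

Randomness comes from a ``numpy.random.Generator`` seeded from the config;
there is no global random state.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .genotypes import (
    Allele,
    AnimalRecord,
    FamilyDataset,
    LocusGenotype,
    PaternalHaplotype,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SireSpec:
    sire_id: str
    haplotype1: PaternalHaplotype
    haplotype2: PaternalHaplotype

    def __post_init__(self) -> None:
        h1, h2 = self.haplotype1, self.haplotype2
        if (
            h1.region1_allele == h2.region1_allele
            or h1.region2_allele == h2.region2_allele
        ):
            raise ConfigError(
                f"sire {self.sire_id!r} must be heterozygous at both regions "
                f"(got {h1} / {h2})"
            )

    def genotype(self, region: int) -> LocusGenotype:
        if region == 1:
            return LocusGenotype(1, (self.haplotype1.region1_allele,
                                     self.haplotype2.region1_allele))
        return LocusGenotype(2, (self.haplotype1.region2_allele,
                                 self.haplotype2.region2_allele))


@dataclass
class SimulationConfig:
    sires: list[SireSpec]
    recomb_fraction: float
    maternal_freqs: dict[int, dict[str, float]]  # region -> label -> frequency
    progeny_per_sire: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.recomb_fraction <= 0.5:
            raise ConfigError(
                f"recomb_fraction must be in [0, 0.5], got {self.recomb_fraction}"
            )
        if self.progeny_per_sire < 0:
            raise ConfigError("progeny_per_sire must be non-negative")
        ids = [s.sire_id for s in self.sires]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate sire ids in config")
        for region in (1, 2):
            freqs = self.maternal_freqs.get(region)
            if not freqs:
                raise ConfigError(f"maternal_freqs missing region {region}")
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigError(
                    f"maternal frequencies for region {region} sum to {total}, not 1"
                )
            if any(f < 0 for f in freqs.values()):
                raise ConfigError("maternal frequencies must be non-negative")


@dataclass(frozen=True)
class TruthEntry:
    animal_id: str
    sire_id: str
    transmitted: PaternalHaplotype
    recombinant: bool
    maternal1: str
    maternal2: str


@dataclass
class TruthLog:
    entries: list[TruthEntry] = field(default_factory=list)

    def by_animal(self) -> dict[str, TruthEntry]:
        return {e.animal_id: e for e in self.entries}

    @property
    def n_recombinant(self) -> int:
        return sum(e.recombinant for e in self.entries)

    def to_tsv(self) -> str:
        out = StringIO()
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["animal_id", "sire_id", "transmitted", "recombinant", "maternal1", "maternal2"]
        )
        for e in self.entries:
            writer.writerow(
                [e.animal_id, e.sire_id, str(e.transmitted),
                 "1" if e.recombinant else "0", e.maternal1, e.maternal2]
            )
        return out.getvalue()


def simulate_gamete(
    sire_haplotypes: tuple[PaternalHaplotype, PaternalHaplotype],
    r: float,
    rng: np.random.Generator,
) -> tuple[PaternalHaplotype, bool]:
    """Draw one paternal gamete: parental with prob. 1-r, crossover with prob. r."""
    if not 0.0 <= r <= 0.5:
        raise ConfigError(f"recombination fraction must be in [0, 0.5], got {r}")
    h1, h2 = sire_haplotypes
    pick = rng.random() < 0.5
    if rng.random() < r:
        gamete = PaternalHaplotype(
            h1.region1_allele if pick else h2.region1_allele,
            h2.region2_allele if pick else h1.region2_allele,
        )
        return gamete, True
    return (h1 if pick else h2), False


def _maternal_sampler(freqs: dict[str, float], region: int, rng: np.random.Generator):
    labels = sorted(freqs)  # sorted for seed-stable draws
    probs = np.array([freqs[l] for l in labels], dtype=float)
    cum = np.cumsum(probs / probs.sum())

    def draw() -> Allele:
        return Allele(region, labels[int(np.searchsorted(cum, rng.random()))])

    return draw


def simulate_family(
    config: SimulationConfig,
    sire_id: str,
    rng: Union[np.random.Generator, None] = None,
) -> tuple[list[AnimalRecord], TruthLog]:
    """Simulate one sire's half-sib family; returns progeny records and truth."""
    spec = next((s for s in config.sires if s.sire_id == sire_id), None)
    if spec is None:
        raise KeyError(f"unknown sire {sire_id!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for region in (1, 2):
        needed = {a.label for a in spec.genotype(region).alleles}
        known = set(config.maternal_freqs[region])
        # maternal pool may lack sire alleles (that is how one makes every
        # progeny informative) but labels used must at least be defined
        if not known:
            raise ConfigError(f"no maternal alleles defined for region {region}")
        del needed
    draw1 = _maternal_sampler(config.maternal_freqs[1], 1, rng)
    draw2 = _maternal_sampler(config.maternal_freqs[2], 2, rng)
    records: list[AnimalRecord] = []
    truth = TruthLog()
    for i in range(config.progeny_per_sire):
        gamete, is_rec = simulate_gamete(
            (spec.haplotype1, spec.haplotype2), config.recomb_fraction, rng
        )
        m1, m2 = draw1(), draw2()
        animal_id = f"{sire_id}_p{i + 1:03d}"
        records.append(
            AnimalRecord(
                animal_id=animal_id,
                role="progeny",
                sire_id=sire_id,
                genotype1=LocusGenotype(1, (gamete.region1_allele, m1)),
                genotype2=LocusGenotype(2, (gamete.region2_allele, m2)),
            )
        )
        truth.entries.append(
            TruthEntry(
                animal_id=animal_id,
                sire_id=sire_id,
                transmitted=gamete,
                recombinant=is_rec,
                maternal1=m1.label,
                maternal2=m2.label,
            )
        )
    return records, truth


def simulate_study(config: SimulationConfig) -> tuple[FamilyDataset, TruthLog]:
    """Simulate all families of the config into one dataset; deterministic per seed."""
    if not config.sires:
        raise ConfigError("config defines no sires")
    rng = np.random.default_rng(config.seed)
    records: list[AnimalRecord] = []
    truth = TruthLog()
    for spec in config.sires:
        records.append(
            AnimalRecord(
                animal_id=spec.sire_id,
                role="sire",
                genotype1=spec.genotype(1),
                genotype2=spec.genotype(2),
            )
        )
        fam_records, fam_truth = simulate_family(config, spec.sire_id, rng)
        records.extend(fam_records)
        truth.entries.extend(fam_truth.entries)
    return FamilyDataset.from_records(records), truth


# ---------------------------------------------------------------------------
# Config file I/O and the default study template
# ---------------------------------------------------------------------------


def _parse_haplotype(text: str) -> PaternalHaplotype:
    parts = text.split("-")
    if len(parts) != 2:
        raise ConfigError(f"haplotype must be written 'X1-Y2', got {text!r}")
    return PaternalHaplotype.from_labels(parts[0], parts[1])


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Load a YAML simulation config.

    Expected layout::

        seed: 1
        recomb_fraction: 0.05
        progeny_per_sire: 60
        maternal_freqs:
          region1: {A1: 0.2, B1: 0.2, C1: 0.2, D1: 0.2, E1: 0.2}
          region2: {A2: 0.25, B2: 0.25, C2: 0.25, D2: 0.25}
        sires:
          - id: S1
            haplotypes: [A1-B2, D1-A2]
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        sires = [
            SireSpec(
                sire_id=str(entry["id"]),
                haplotype1=_parse_haplotype(entry["haplotypes"][0]),
                haplotype2=_parse_haplotype(entry["haplotypes"][1]),
            )
            for entry in raw["sires"]
        ]
        maternal = {
            1: {str(k): float(v) for k, v in raw["maternal_freqs"]["region1"].items()},
            2: {str(k): float(v) for k, v in raw["maternal_freqs"]["region2"].items()},
        }
        return SimulationConfig(
            sires=sires,
            recomb_fraction=float(raw["recomb_fraction"]),
            maternal_freqs=maternal,
            progeny_per_sire=int(raw["progeny_per_sire"]),
            seed=int(raw["seed"]),
        )
    except (KeyError, IndexError, TypeError) as exc:
        raise ConfigError(f"{path}: missing or malformed config field ({exc})") from exc


def default_study_config(seed: int = 0, recomb_fraction: float = 0.05) -> SimulationConfig:
    """A study-scale template: 7 doubly heterozygous sires, 60 progeny each.

    Sire diplotypes mirror the seven NZ Romney sire-lines of the ovine FABP4
    half-sib study; maternal pools put roughly even mass on the 5 region-1
    and 4 region-2 variants.
    """
    diplotypes = [
        ("Totaranui_376_02", "A1-B2", "D1-A2"),
        ("Waidale_618_04", "C1-C2", "D1-A2"),
        ("Snowlea_192_02", "B1-B2", "C1-C2"),
        ("Mana_83_04", "B1-B2", "C1-C2"),
        ("Doughboy_45_04", "B1-B2", "C1-A2"),
        ("Glenleith_25_02", "A1-A2", "B1-B2"),
        ("Mana_90_01", "A1-B2", "C1-A2"),
    ]
    sires = [
        SireSpec(sid, _parse_haplotype(h1), _parse_haplotype(h2))
        for sid, h1, h2 in diplotypes
    ]
    return SimulationConfig(
        sires=sires,
        recomb_fraction=recomb_fraction,
        maternal_freqs={
            1: {label: 0.2 for label in ("A1", "B1", "C1", "D1", "E1")},
            2: {label: 0.25 for label in ("A2", "B2", "C2", "D2")},
        },
        progeny_per_sire=60,
        seed=seed,
    )
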