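"""Synthetic germplasm collections with controlled, replayable structure.

The generator emulates the features of a genotyped genebank that matter for
information-theoretic scoring: per-locus multiallelic frequency profiles
drawn around a collection-level base profile, a tunable amount of
accession-level drift, planted rare accessions carrying private alleles, an
inbred mode in which each accession is fixed (frequencies in {0, 1}, as for
largely homozygous landrace lines) and per accession-locus block missing
data.  Every draw flows from a single seeded generator, so the ground-truth
manifest of planted signal is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .freqtable import FrequencyTable

__all__ = ["SynthConfig", "SynthManifest", "generate", "table1_fixture"]

PRIVATE_ALLELE_FREQ = 0.5  # outbred-mode within-accession frequency of a planted allele


class ConfigError(ValueError):
    """Inconsistent generator configuration."""


@dataclass
class SynthConfig:
    """Parameters of a synthetic collection.

    Defaults describe a desk-scale diverse panel: 100 accessions typed at 50
    biallelic loci, flat Dirichlet base profiles, moderate accession drift,
    no planted signal, no missing data.
    """

    n_accessions: int = 100
    n_loci: int = 50
    alleles_per_locus: int | tuple[int, int] = 2
    base_profile_concentration: float = 1.0
    accession_divergence_scale: float = 0.3
    n_rare_accessions: int = 0
    n_private_alleles_each: int = 0
    inbred: bool = False
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 2 or self.n_loci < 1:
            raise ConfigError("need >=2 accessions and >=1 locus")
        if self.n_rare_accessions * self.n_private_alleles_each > self.n_loci:
            raise ConfigError(
                "more planted private alleles than loci "
                f"({self.n_rare_accessions} x {self.n_private_alleles_each} > {self.n_loci})"
            )
        if self.n_rare_accessions > self.n_accessions:
            raise ConfigError("more rare accessions than accessions")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")


@dataclass
class SynthManifest:
    """Ground truth of the planted signal, for assertions in tests."""

    rare_accessions: list[str] = field(default_factory=list)
    private_alleles: list[tuple[str, str]] = field(default_factory=list)  # (locus, allele)
    private_owner: dict[str, str] = field(default_factory=dict)  # locus -> accession

    def to_dict(self) -> dict:
        return {
            "rare_accessions": self.rare_accessions,
            "private_alleles": [list(p) for p in self.private_alleles],
            "private_owner": self.private_owner,
        }


def _allele_counts(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.alleles_per_locus, int):
        k = np.full(cfg.n_loci, cfg.alleles_per_locus)
    else:
        lo, hi = cfg.alleles_per_locus
        k = rng.integers(lo, hi + 1, size=cfg.n_loci)
    if (k < 2).any():
        raise ConfigError("every locus needs >=2 alleles")
    return k


def generate(cfg: SynthConfig) -> tuple[FrequencyTable, SynthManifest]:
    """Draw a frequency table and its ground-truth manifest from ``cfg``.

    Loci are independent.  For each locus a base profile is drawn from a
    symmetric Dirichlet with concentration ``base_profile_concentration``;
    each accession's latent profile is a Dirichlet resample around the base
    with spread proportional to ``accession_divergence_scale`` (0 means all
    accessions share the base profile exactly).  Planted private alleles are
    extra allele rows owned by one designated rare accession each; the
    owner's block at a planted locus is never masked, so the private allele
    stays observable at any missing rate.
    """
    rng = np.random.default_rng(cfg.seed)
    k = _allele_counts(cfg, rng)
    acc_ids = [f"ACC{j + 1:04d}" for j in range(cfg.n_accessions)]
    locus_ids = [f"L{i + 1:04d}" for i in range(cfg.n_loci)]

    manifest = SynthManifest()
    rare_idx = (
        rng.choice(cfg.n_accessions, size=cfg.n_rare_accessions, replace=False)
        if cfg.n_rare_accessions
        else np.array([], dtype=int)
    )
    manifest.rare_accessions = [acc_ids[j] for j in rare_idx]
    n_planted = cfg.n_rare_accessions * cfg.n_private_alleles_each
    planted_loci = (
        rng.choice(cfg.n_loci, size=n_planted, replace=False)
        if n_planted
        else np.array([], dtype=int)
    )
    owner_of = {}  # locus ordinal -> accession ordinal
    for slot, locus in enumerate(planted_loci):
        owner_of[int(locus)] = int(rare_idx[slot // cfg.n_private_alleles_each])

    allele_index: list[tuple[str, str]] = []
    blocks: list[np.ndarray] = []
    for i, locus in enumerate(locus_ids):
        ki = int(k[i])
        base = rng.dirichlet(np.full(ki, cfg.base_profile_concentration))
        if cfg.accession_divergence_scale <= 0:
            profiles = np.tile(base, (cfg.n_accessions, 1))
        else:
            # larger scale -> smaller concentration -> wider drift from base
            alpha = np.maximum(base / cfg.accession_divergence_scale, 1e-3)
            profiles = rng.dirichlet(alpha, size=cfg.n_accessions)
        names = [f"A{a + 1}" for a in range(ki)]

        if i in owner_of:
            owner = owner_of[i]
            private = np.zeros(cfg.n_accessions)
            f = 1.0 if cfg.inbred else PRIVATE_ALLELE_FREQ
            private[owner] = f
            profiles[owner] *= 1.0 - f
            profiles = np.column_stack([profiles, private])
            names.append("PRIV")
            manifest.private_alleles.append((locus, "PRIV"))
            manifest.private_owner[locus] = acc_ids[owner]

        if cfg.inbred:
            block = np.zeros_like(profiles)
            for j in range(cfg.n_accessions):
                if i in owner_of and j == owner_of[i]:
                    block[j, -1] = 1.0  # the planted allele is the fixed one
                else:
                    p = profiles[j] / profiles[j].sum()
                    block[j, rng.choice(len(p), p=p)] = 1.0
            profiles = block
        else:
            profiles = profiles / profiles.sum(axis=1, keepdims=True)

        if cfg.missing_rate > 0:
            mask = rng.random(cfg.n_accessions) < cfg.missing_rate
            if i in owner_of:
                mask[owner_of[i]] = False  # keep planted signal observable
            if mask.all():
                mask[int(rng.integers(cfg.n_accessions))] = False
            profiles = profiles.copy()
            profiles[mask] = np.nan

        allele_index.extend((locus, a) for a in names)
        blocks.append(profiles.T)

    table = FrequencyTable(acc_ids, allele_index, np.vstack(blocks))
    return table, manifest


def table1_fixture() -> FrequencyTable:
    """The four-accession, three-biallelic-locus toy collection.

    Accession A4 carries a private allele (Locus 2, Allele 1) and the only
    high frequency of Locus 3 Allele 1, making it the rarest and most
    divergent accession of the set.
    """
    values = np.array(
        [
            [1.0, 0.0, 1.0, 0.0],
            [0.0, 1.0, 0.0, 1.0],
            [0.0, 0.0, 0.0, 1.0],
            [1.0, 1.0, 1.0, 0.0],
            [0.5, 0.0, 0.0, 1.0],
            [0.5, 1.0, 1.0, 0.0],
        ]
    )
    allele_index = [
        ("Locus1", "Allele1"),
        ("Locus1", "Allele2"),
        ("Locus2", "Allele1"),
        ("Locus2", "Allele2"),
        ("Locus3", "Allele1"),
        ("Locus3", "Allele2"),
    ]
    return FrequencyTable(["A1", "A2", "A3", "A4"], allele_index, values)
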