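"""Information-theoretic diversity metrics on allele-frequency tables.

All quantities are plug-in Shannon estimates in bits (log base 2), under the
convention ``0 * log2(0) = 0`` and an equiprobable prior ``P[X_j] = 1/N``
over accessions.

* Allele specificity ``S_i``: the mutual information between the identity of
  a random accession and the event that a random allele copy drawn from the
  collection is allele ``i``.  ``S_i = sum_j p_ij / (N p_i) * log2(p_ij / p_i)``
  where ``p_i`` is the mean of ``p_ij`` across accessions.  It is 0 for a
  monomorphic allele and reaches ``log2(N)`` for a private allele.
* Accession rarity ``R_j``: the frequency-weighted mean specificity of the
  alleles accession ``j`` carries, ``R_j = sum_i p_ij S_i`` per locus,
  averaged over loci.
* Accession divergence ``D_j``: the Kullback-Leibler divergence between the
  accession's allele-frequency distribution and the collection average,
  ``D_j = sum_i p_ij log2(p_ij / p_i)`` per locus, averaged over loci.
* Mutual information ``I(X; M)``: on complete data the mean rarity, the mean
  divergence and the locus-averaged ``sum_i p_i S_i`` are one and the same
  number; with missing data the three estimates can drift apart and are
  reported separately.

With missing data, ``p_i`` for an allele is the mean over the accessions in
which its locus is observed, and each accession averages only its observed
loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .freqtable import FrequencyTable, ValidationError

__all__ = [
    "SpecificityVector",
    "AccessionScores",
    "MutualInfo",
    "allele_specificity",
    "relative_specificity",
    "accession_rarity",
    "accession_divergence",
    "accession_scores",
    "mutual_information",
]


@dataclass
class SpecificityVector:
    """Per-allele specificity scores, aligned with the table's allele rows.

    ``defined`` is False for alleles never observed among the available
    accessions (``mean_freq == 0``) or with fewer than 2 available
    accessions; such rows carry NaN scores and are excluded from locus sums.
    """

    allele_index: list[tuple[str, str]]
    specificity_abs: np.ndarray  # bits
    specificity_rel: np.ndarray  # in [0, 1]
    n_available: np.ndarray  # accessions with the allele's locus observed
    mean_freq: np.ndarray  # the p_i actually used
    defined: np.ndarray  # bool

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": [l for l, _ in self.allele_index],
                "allele": [a for _, a in self.allele_index],
                "specificity_abs": self.specificity_abs,
                "specificity_rel": self.specificity_rel,
                "n_available": self.n_available,
            }
        )

    def __getitem__(self, key: tuple[str, str]) -> float:
        return float(self.specificity_abs[self.allele_index.index(key)])


@dataclass
class AccessionScores:
    """Per-accession rarity and divergence, both in bits, averaged over loci.

    Accessions with every locus missing are unscored (NaN, ``n_loci_used`` 0).
    """

    accession_ids: list[str]
    rarity: np.ndarray
    divergence: np.ndarray
    n_loci_used: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.accession_ids,
                "rarity": self.rarity,
                "divergence": self.divergence,
                "n_loci_used": self.n_loci_used,
            }
        )

    def rarity_of(self, accession_id: str) -> float:
        return float(self.rarity[self.accession_ids.index(accession_id)])

    def divergence_of(self, accession_id: str) -> float:
        return float(self.divergence[self.accession_ids.index(accession_id)])


@dataclass
class MutualInfo:
    """I(X;M) computed three independent ways; identical on complete data."""

    value_from_specificity: float
    value_from_rarity: float
    value_from_divergence: float

    @property
    def consistent(self) -> bool:
        vals = (
            self.value_from_specificity,
            self.value_from_rarity,
            self.value_from_divergence,
        )
        return max(vals) - min(vals) < 1e-9


def _xlog2_ratio(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """``p * log2(p / q)`` with ``0 log 0 = 0``; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    q = np.broadcast_to(np.asarray(q, dtype=float), p.shape)
    out = np.zeros_like(p)
    nan = np.isnan(p) | np.isnan(q)
    pos = ~nan & (p > 0)
    out[pos] = p[pos] * np.log2(p[pos] / q[pos])
    out[nan] = np.nan
    return out


def _mean_freq(t: FrequencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Missing-aware row means p_i and per-row available-accession counts."""
    obs = ~t.missing_mask
    n_avail = obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        p = np.where(n_avail > 0, np.nansum(t.values, axis=1) / np.maximum(n_avail, 1), np.nan)
    return p, n_avail


def allele_specificity(t: FrequencyTable) -> SpecificityVector:
    """Specificity ``S_i`` in bits for every allele row of the table.

    For each allele the number of accessions and the average frequency are
    taken over the accessions where its locus is observed; missing cells
    contribute nothing.  Raises for a single-accession table, where
    ``log2(1) = 0`` makes the score vacuous.
    """
    if t.n_accessions < 2:
        raise ValidationError(
            "allele specificity is undefined on a single-accession table"
        )
    p_i, n_avail = _mean_freq(t)
    defined = (n_avail >= 2) & (p_i > 0)

    terms = _xlog2_ratio(t.values, p_i[:, None])
    s_abs = np.full(t.n_alleles, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        sums = np.nansum(np.where(np.isnan(terms), 0.0, terms), axis=1)
        s_abs[defined] = sums[defined] / (n_avail[defined] * p_i[defined])
    # guard tiny negative round-off on monomorphic rows
    s_abs[defined & (np.abs(s_abs) < 1e-15)] = 0.0

    s_rel = np.full(t.n_alleles, np.nan)
    ok = defined & (n_avail >= 2)
    s_rel[ok] = s_abs[ok] / np.log2(n_avail[ok])
    return SpecificityVector(
        allele_index=list(t.allele_index),
        specificity_abs=s_abs,
        specificity_rel=s_rel,
        n_available=n_avail,
        mean_freq=p_i,
        defined=defined,
    )


def relative_specificity(s: SpecificityVector) -> SpecificityVector:
    """Return ``s`` with the relative scores (re)populated.

    The relative specificity divides the absolute score by its ceiling
    ``log2(n_available)``, undoing the penalty missing data places on the
    absolute score; a private allele scores exactly 1.0 regardless of how
    many accessions were genotyped.  Rows with fewer than 2 available
    accessions stay flagged NaN rather than raising.
    """
    s_rel = np.full_like(s.specificity_abs, np.nan)
    ok = s.defined & (s.n_available >= 2)
    s_rel[ok] = s.specificity_abs[ok] / np.log2(s.n_available[ok])
    s.specificity_rel = s_rel
    return s


def _per_locus_scores(t: FrequencyTable, per_row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average per-row contributions into per-accession means over observed loci.

    ``per_row`` is (A, N) with NaN wherever the accession misses the locus.
    Returns (per-accession mean over observed loci, n_loci_used).
    """
    locus_rows = t.locus_rows()
    n_loci = len(locus_rows)
    locus_sums = np.empty((n_loci, t.n_accessions))
    locus_obs = np.empty((n_loci, t.n_accessions), dtype=bool)
    for k, rows in enumerate(locus_rows):
        block = per_row[rows]
        obs = ~np.isnan(block).all(axis=0)
        locus_obs[k] = obs
        locus_sums[k] = np.where(obs, np.nansum(block, axis=0), np.nan)
    n_used = locus_obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_used > 0, np.nansum(locus_sums, axis=0) / np.maximum(n_used, 1), np.nan)
    return mean, n_used


def accession_rarity(t: FrequencyTable, s: SpecificityVector | None = None) -> AccessionScores:
    """Rarity ``R_j`` per accession (divergence left NaN; see accession_scores)."""
    if s is None:
        s = allele_specificity(t)
    s_eff = np.where(s.defined, s.specificity_abs, 0.0)  # undefined rows carry p_ij = 0
    contrib = t.values * s_eff[:, None]
    rarity, n_used = _per_locus_scores(t, contrib)
    return AccessionScores(
        accession_ids=list(t.accession_ids),
        rarity=rarity,
        divergence=np.full(t.n_accessions, np.nan),
        n_loci_used=n_used,
    )


def accession_divergence(t: FrequencyTable) -> AccessionScores:
    """Kullback-Leibler divergence ``D_j`` per accession (rarity left NaN)."""
    p_i, _ = _mean_freq(t)
    # p_i = 0 with p_ij > 0 is impossible: p_i averages over j itself.
    bad = (p_i == 0) & (np.nansum(t.values, axis=1) > 0)
    assert not bad.any(), "zero mean frequency for an observed allele"
    contrib = _xlog2_ratio(t.values, p_i[:, None])
    div, n_used = _per_locus_scores(t, contrib)
    return AccessionScores(
        accession_ids=list(t.accession_ids),
        rarity=np.full(t.n_accessions, np.nan),
        divergence=div,
        n_loci_used=n_used,
    )


def accession_scores(t: FrequencyTable, s: SpecificityVector | None = None) -> AccessionScores:
    """Both rarity and divergence in one :class:`AccessionScores`."""
    r = accession_rarity(t, s)
    d = accession_divergence(t)
    r.divergence = d.divergence
    return r


def mutual_information(t: FrequencyTable) -> MutualInfo:
    """I(X;M) via specificity, rarity and divergence routes.

    On complete data the three agree to round-off (the identity
    ``I = sum_i p_i S_i = mean_j R_j = mean_j D_j`` holds per locus and is
    preserved by the unweighted average over loci).  With missing data each
    route uses only the observed cells and they are reported separately.
    """
    s = allele_specificity(t)
    p_eff = np.where(s.defined, s.mean_freq, 0.0)
    s_eff = np.where(s.defined, s.specificity_abs, 0.0)
    per_locus = [float((p_eff[rows] * s_eff[rows]).sum()) for rows in t.locus_rows()]
    from_spec = float(np.mean(per_locus))

    scores = accession_scores(t, s)
    from_rarity = float(np.nanmean(scores.rarity))
    from_div = float(np.nanmean(scores.divergence))
    return MutualInfo(from_spec, from_rarity, from_div)
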