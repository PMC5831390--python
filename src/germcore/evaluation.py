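"""Quality criteria for a core subset against its parent collection.

A candidate core is judged on five criteria: its mean within-subset
Kullback-Leibler divergence, the mean pairwise Modified Rogers distance, the
Shannon diversity of its pooled allele-frequency distribution, the fraction
of parent alleles it retains (allele richness) and the complementary count
of lost alleles.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict

import numpy as np

from .freqtable import FrequencyTable, ValidationError
from .coreselect import subset_mean_divergence

__all__ = ["EvalReport", "evaluate_subset", "modified_rogers", "shannon_diversity"]


@dataclass
class EvalReport:
    """Five-criterion quality report for a subset of a collection."""

    subset_size: int
    mean_divergence: float  # bits
    mean_mr: float  # in [0, 1]
    shannon: float  # nats, pooled-allele entropy
    allele_richness: float  # fraction of parent alleles retained
    lost_alleles: int
    parent_alleles: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def modified_rogers(
    a: np.ndarray, b: np.ndarray, locus_rows: list[np.ndarray]
) -> tuple[float, int]:
    """Modified Rogers distance between two accession frequency columns.

    ``sqrt( (1 / 2L) * sum_loci sum_alleles (p_ia - p_ib)^2 )`` over the L
    pairwise-complete loci; bounded in [0, 1], reaching 1 for two inbreds
    fixed for opposite alleles at every locus.  Returns ``(distance, L)``;
    with zero shared loci the distance is NaN.
    """
    total = 0.0
    shared = 0
    for rows in locus_rows:
        da, db = a[rows], b[rows]
        if np.isnan(da).any() or np.isnan(db).any():
            continue
        shared += 1
        total += float(((da - db) ** 2).sum())
    if shared == 0:
        return float("nan"), 0
    return float(np.sqrt(total / (2 * shared))), shared


def shannon_diversity(t: FrequencyTable, ids=None) -> float:
    """Shannon entropy (nats) of the pooled normalized allele frequencies.

    The mean allele frequencies of the collection (or of the subset ``ids``)
    across *all* alleles of all loci are normalized into one distribution
    ``q_i = p_i / sum p_i`` and its entropy ``-sum q_i ln q_i`` is returned,
    with ``0 ln 0 = 0``.  This global pooled convention (rather than a
    per-locus average) matches how core-selection software commonly reports
    the criterion; it is convention-sensitive, so compare like with like.
    """
    sub = t if ids is None else t.subset(list(ids))
    n_obs = (~sub.missing_mask).sum(axis=1)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, np.nansum(sub.values, axis=1) / np.maximum(n_obs, 1), 0.0)
    total = p.sum()
    if total <= 0:
        raise ValidationError("no allele with positive frequency")
    q = p / total
    pos = q > 0
    return float(-(q[pos] * np.log(q[pos])).sum())


def evaluate_subset(parent: FrequencyTable, ids) -> EvalReport:
    """Score the subset ``ids`` of ``parent`` on all five criteria."""
    ids = list(ids)
    unknown = [i for i in ids if i not in parent.accession_ids]
    if unknown:
        raise KeyError(f"unknown accession ids: {unknown}")
    if len(ids) < 2:
        raise ValidationError("a subset of at least 2 accessions is required")

    mean_div = subset_mean_divergence(parent, ids, reference="self")

    sub = parent.subset(ids)
    locus_rows = parent.locus_rows()
    cols = [parent.accession_ids.index(i) for i in ids]
    dists = []
    for ja, jb in itertools.combinations(cols, 2):
        d, shared = modified_rogers(parent.values[:, ja], parent.values[:, jb], locus_rows)
        if shared:
            dists.append(d)
    mean_mr = float(np.mean(dists)) if dists else float("nan")

    sh = shannon_diversity(sub)

    parent_present = np.nansum(parent.values, axis=1) > 0
    subset_present = np.nansum(sub.values, axis=1) > 0
    lost = int((parent_present & ~subset_present).sum())
    n_parent = int(parent_present.sum())
    return EvalReport(
        subset_size=len(ids),
        mean_divergence=mean_div,
        mean_mr=mean_mr,
        shannon=sh,
        allele_richness=1.0 - lost / n_parent,
        lost_alleles=lost,
        parent_alleles=n_parent,
    )
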