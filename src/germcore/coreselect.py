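"""Greedy core-subset selection maximizing within-subset mean divergence.

The selection (HCore) starts from the rarest accession of the full
collection and grows the core one accession at a time, keeping at each step
the candidate whose addition maximizes the mean Kullback-Leibler divergence
of the subset, with the reference frequencies recomputed *within the
subset*.  Rarity and divergence are context-relative: an accession rare in
the full collection need not be rare inside a small core, which is why a
simple top-k by rarity does not maximize subset diversity and a greedy
re-scoring loop is used instead.

Two scoring modes exist:

* ``exact`` — for every candidate, the subset-average frequencies ``p_i``
  include the candidate itself (the divergence of the would-be subset is
  computed exactly).
* ``fast`` — the reference frequencies ``p̂_i`` are the running means of the
  *current* core, frozen during candidate evaluation and updated only when
  an accession is committed.  This turns each step into one vectorized pass
  over the candidates and is the intended regime for collections with
  thousands of accessions.

``auto`` mode (the default) scores exactly while the core holds up to
``exact_threshold`` accessions (default 30) and switches to the running-mean
approximation afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .freqtable import FrequencyTable, ValidationError
from .metrics import _xlog2_ratio, accession_rarity

__all__ = ["CoreResult", "select_core", "subset_mean_divergence"]

logger = logging.getLogger(__name__)


@dataclass
class CoreResult:
    """Ordered greedy selection with its per-step objective trace.

    ``objective_trace[k]`` is the mean within-subset divergence (bits) of the
    first ``k + 1`` selected accessions, evaluated in the scoring mode
    recorded in ``step_mode[k]`` (the first step, a single accession, has
    divergence 0 by definition).
    """

    selected: list[str]
    objective_trace: list[float]
    step_mode: list[str]
    target_size: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.selected) + 1),
                "accession_id": self.selected,
                "objective_after_add": self.objective_trace,
                "mode": self.step_mode,
            }
        )


def _locus_row_map(t: FrequencyTable) -> np.ndarray:
    """Row -> locus ordinal, for per-locus bookkeeping."""
    row_locus = np.empty(t.n_alleles, dtype=int)
    for k, rows in enumerate(t.locus_rows()):
        row_locus[rows] = k
    return row_locus


def _member_divergences(
    values: np.ndarray, cols: np.ndarray, p_ref: np.ndarray, row_locus: np.ndarray, n_loci: int
) -> np.ndarray:
    """Mean-over-observed-loci KL divergence of each member column vs p_ref."""
    terms = _xlog2_ratio(values[:, cols], p_ref[:, None])
    locus_sum = np.zeros((n_loci, len(cols)))
    locus_obs = np.zeros((n_loci, len(cols)), dtype=bool)
    nan = np.isnan(terms)
    np.add.at(locus_sum, row_locus, np.where(nan, 0.0, terms))
    np.logical_or.at(locus_obs, row_locus, ~nan)
    n_used = locus_obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n_used > 0, locus_sum.sum(axis=0) / np.maximum(n_used, 1), np.nan)


def subset_mean_divergence(
    t: FrequencyTable, ids, *, reference="self", p_hat: np.ndarray | None = None
) -> float:
    """Mean divergence (bits) of the accessions ``ids`` within their own universe.

    With ``reference="self"`` the reference frequencies are the means over
    ``ids`` only — the subset is treated as a complete collection.  With
    ``reference="fixed"`` the supplied ``p_hat`` vector is used instead.
    """
    ids = list(ids)
    if len(ids) < 2:
        raise ValidationError("divergence needs a subset of at least 2 accessions")
    unknown = [i for i in ids if i not in t.accession_ids]
    if unknown:
        raise KeyError(f"unknown accession ids: {unknown}")
    cols = np.array([t.accession_ids.index(i) for i in ids])
    row_locus = _locus_row_map(t)
    if reference == "self":
        sub = t.values[:, cols]
        n_obs = (~np.isnan(sub)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            p_ref = np.where(n_obs > 0, np.nansum(sub, axis=1) / np.maximum(n_obs, 1), np.nan)
    elif reference == "fixed":
        if p_hat is None:
            raise ValueError("reference='fixed' requires p_hat")
        p_ref = np.asarray(p_hat, dtype=float)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    d = _member_divergences(t.values, cols, p_ref, row_locus, t.n_loci)
    return float(np.nanmean(d))


def select_core(
    t: FrequencyTable,
    size: int | None = None,
    *,
    fraction: float | None = None,
    exact_threshold: int = 30,
    mode: str = "auto",
    strict_size: bool = True,
) -> CoreResult:
    """Greedy core selection of ``size`` accessions maximizing mean divergence.

    The first member is the accession with maximum full-collection rarity;
    every later step adds the candidate maximizing the subset's mean
    divergence (exact or running-mean scoring per ``mode``).  Ties are broken
    by input column order, making the algorithm fully deterministic.

    Parameters
    ----------
    size:
        Number of accessions to select (>= 2).  Alternatively give
        ``fraction`` of the collection (rounded to nearest, minimum 2).
    exact_threshold:
        In ``auto`` mode, the core size up to which scoring is exact; beyond
        it the running-mean reference takes over.
    mode:
        ``"exact"``, ``"fast"`` or ``"auto"``.
    strict_size:
        If True, ``size > N`` raises; otherwise it is clamped to ``N`` with
        a warning.
    """
    if mode not in ("exact", "fast", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    n = t.n_accessions
    if (size is None) == (fraction is None):
        raise ValueError("give exactly one of size or fraction")
    if size is None:
        size = max(2, round(fraction * n))
        logger.info("fraction %.4g of %d accessions -> core size %d", fraction, n, size)
    if size < 2:
        raise ValidationError("core size must be >= 2 (divergence of a singleton is vacuous)")
    if size > n:
        if strict_size:
            raise ValidationError(f"core size {size} exceeds collection size {n}")
        logger.warning("core size %d clamped to collection size %d", size, n)
        size = n

    row_locus = _locus_row_map(t)
    n_loci = t.n_loci
    values = t.values
    obs = ~np.isnan(values)

    scores = accession_rarity(t)
    first = int(np.nanargmax(scores.rarity))  # ties: first in input order
    selected = [first]
    trace = [0.0]
    modes = ["exact" if mode != "fast" else "fast"]

    # running per-row sums / counts over the committed core
    core_sum = np.where(obs[:, first], values[:, first], 0.0)
    core_cnt = obs[:, first].astype(int)

    remaining = [j for j in range(n) if j != first]
    while len(selected) < size:
        use_exact = mode == "exact" or (mode == "auto" and len(selected) < exact_threshold)
        cols = np.array(selected)
        if use_exact:
            best_j, best_obj = None, -np.inf
            for j in remaining:
                cand_sum = core_sum + np.where(obs[:, j], values[:, j], 0.0)
                cand_cnt = core_cnt + obs[:, j]
                with np.errstate(invalid="ignore"):
                    p_ref = np.where(cand_cnt > 0, cand_sum / np.maximum(cand_cnt, 1), np.nan)
                d = _member_divergences(
                    values, np.append(cols, j), p_ref, row_locus, n_loci
                )
                objective = float(np.nanmean(d))
                if objective > best_obj:
                    best_j, best_obj = j, objective
            step_mode = "exact"
        else:
            with np.errstate(invalid="ignore"):
                p_hat = np.where(core_cnt > 0, core_sum / np.maximum(core_cnt, 1), np.nan)
            d_members = _member_divergences(values, cols, p_hat, row_locus, n_loci)
            member_total = float(np.nansum(d_members))
            best_j, best_obj = None, -np.inf
            for j in remaining:
                p_ref = p_hat
                # a core-absent allele the candidate carries would hit log(x/0);
                # fall back to the candidate-inclusive mean on those rows only
                novel = (core_cnt > 0) & (p_hat == 0) & obs[:, j] & (values[:, j] > 0)
                if novel.any():
                    p_ref = p_hat.copy()
                    p_ref[novel] = values[novel, j] / (core_cnt[novel] + 1)
                d_c = _member_divergences(values, np.array([j]), p_ref, row_locus, n_loci)[0]
                if np.isnan(d_c):
                    continue
                objective = (member_total + d_c) / (len(selected) + 1)
                if objective > best_obj:
                    best_j, best_obj = j, objective
            step_mode = "fast"
        if best_j is None:
            raise ValidationError("no scoreable candidate remains (all-missing columns?)")
        selected.append(best_j)
        remaining.remove(best_j)
        core_sum += np.where(obs[:, best_j], values[:, best_j], 0.0)
        core_cnt += obs[:, best_j]
        trace.append(best_obj)
        modes.append(step_mode)
        if len(selected) % 100 == 0:
            logger.info("core size %d, objective %.6f", len(selected), best_obj)

    return CoreResult(
        selected=[t.accession_ids[j] for j in selected],
        objective_trace=trace,
        step_mode=modes,
        target_size=size,
    )
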