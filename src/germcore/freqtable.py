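"""Within-accession allele-frequency tables: data model, validation and I/O.

The central container is :class:`FrequencyTable`, an alleles x accessions
matrix of allele frequencies ``p_ij`` — the frequency of allele ``i`` within
accession ``j``.  Rows are grouped by locus, and within each accession a
locus is either fully observed (its allele frequencies sum to one) or
missing as a block.  Missing cells are stored as NaN.

Tables can be read from delimited text (``locus,allele,<acc1>,...``) or
derived from diploid genotype calls.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyTable",
    "GenotypeMatrix",
    "FormatError",
    "ValidationError",
    "read_frequency_table",
    "read_genotype_matrix",
    "genotypes_from_vcf",
    "frequencies_from_genotypes",
    "compact_biallelic",
    "write_scores",
]

SUM_TOL = 1e-9


class FormatError(ValueError):
    """Malformed input file (bad cell, duplicate row, wrong header)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a table invariant."""


@dataclass
class FrequencyTable:
    """Alleles x accessions matrix of within-accession allele frequencies.

    Parameters
    ----------
    accession_ids:
        Unique accession (column) identifiers, input order preserved.
    allele_index:
        ``(locus_id, allele_id)`` per row, rows grouped by locus.
    values:
        ``(n_alleles, n_accessions)`` float array in ``[0, 1]``; NaN marks
        missing data.  A locus is missing per accession as a whole block.
    """

    accession_ids: list[str]
    allele_index: list[tuple[str, str]]
    values: np.ndarray
    loci: dict[str, list[int]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.loci is None:
            loci: dict[str, list[int]] = {}
            for row, (locus, _) in enumerate(self.allele_index):
                loci.setdefault(locus, []).append(row)
            self.loci = loci
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_alleles(self) -> int:
        return len(self.allele_index)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_alleles, n_accessions)``; True where data are missing."""
        return np.isnan(self.values)

    def locus_rows(self) -> list[np.ndarray]:
        """Row-index array per locus, in locus input order."""
        return [np.asarray(rows, dtype=int) for rows in self.loci.values()]

    def accession_column(self, accession_id: str) -> np.ndarray:
        return self.values[:, self.accession_ids.index(accession_id)]

    # -- validation ------------------------------------------------------
    def validate(self, tol: float = SUM_TOL) -> None:
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValidationError("duplicate accession ids")
        if len(set(self.allele_index)) != len(self.allele_index):
            raise ValidationError("duplicate (locus, allele) rows")
        if self.values.shape != (self.n_alleles, self.n_accessions):
            raise ValidationError(
                f"values shape {self.values.shape} does not match index "
                f"({self.n_alleles} alleles x {self.n_accessions} accessions)"
            )
        seen: set[str] = set()
        last = None
        for locus, _ in self.allele_index:
            if locus != last and locus in seen:
                raise ValidationError(f"rows of locus {locus!r} are not contiguous")
            seen.add(locus)
            last = locus
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0) | (self.values > 1)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"frequency out of [0,1] at locus {self.allele_index[r][0]!r}, "
                f"allele {self.allele_index[r][1]!r}, accession {self.accession_ids[c]!r}"
            )
        for locus, rows in self.loci.items():
            if len(rows) < 2:
                raise ValidationError(f"locus {locus!r} has fewer than 2 alleles")
            block = self.values[np.asarray(rows)]
            nan = np.isnan(block)
            partial = nan.any(axis=0) & ~nan.all(axis=0)
            if partial.any():
                j = int(np.flatnonzero(partial)[0])
                raise ValidationError(
                    f"locus {locus!r} is partially missing in accession "
                    f"{self.accession_ids[j]!r} (a locus must be observed or "
                    "missing as a unit)"
                )
            observed = ~nan.all(axis=0)
            sums = block[:, observed].sum(axis=0)
            off = np.abs(sums - 1.0) > tol
            if off.any():
                k = int(np.flatnonzero(off)[0])
                j = int(np.flatnonzero(observed)[k])
                raise ValidationError(
                    f"allele frequencies of locus {locus!r} sum to "
                    f"{sums[k]:.12g} (not 1) in accession {self.accession_ids[j]!r}"
                )

    def subset(self, ids: list[str]) -> "FrequencyTable":
        """Column-subset table restricted to ``ids`` (kept in input order)."""
        unknown = [i for i in ids if i not in self.accession_ids]
        if unknown:
            raise KeyError(f"unknown accession ids: {unknown}")
        keep = set(ids)
        cols = [j for j, a in enumerate(self.accession_ids) if a in keep]
        return FrequencyTable(
            accession_ids=[self.accession_ids[j] for j in cols],
            allele_index=list(self.allele_index),
            values=self.values[:, cols].copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.allele_index, names=["locus", "allele"])
        return pd.DataFrame(self.values, index=idx, columns=self.accession_ids)


MISSING_CALL = "./."


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls; columns are individuals labelled by accession.

    Several columns may carry the same accession id — those individuals are
    pooled when frequencies are derived.  A call is an ``(allele, allele)``
    pair (order irrelevant) or ``None`` for missing; never an empty string.
    """

    accession_ids: list[str]
    locus_ids: list[str]
    calls: list[list[tuple[str, str] | None]]  # [locus][individual]

    def __post_init__(self) -> None:
        if not self.accession_ids or not self.locus_ids:
            raise ValidationError("genotype matrix needs >=1 accession and >=1 locus")
        for row in self.calls:
            if len(row) != len(self.accession_ids):
                raise ValidationError("ragged genotype matrix")
            for call in row:
                if call is not None and ("" in call or len(call) != 2):
                    raise ValidationError(f"malformed call {call!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_frequency_table(
    path,
    *,
    sep: str = ",",
    missing_token: str = "NA",
    strict: bool = True,
    tol: float = SUM_TOL,
) -> FrequencyTable:
    """Read a ``locus,allele,<acc1>,...`` delimited file into a table.

    In strict mode (default) any locus whose non-missing frequencies do not
    sum to one within ``tol`` in some accession is a :class:`ValidationError`
    naming the locus; in lenient mode such blocks are renormalized to sum to
    one and the affected loci are recorded nowhere but in the values.
    """
    df = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, na_values=[], header=0
    )
    if df.shape[1] < 3:
        raise FormatError(
            "expected two key columns (locus, allele) plus >=1 accession column"
        )
    locus_col, allele_col = df.columns[:2]
    accession_ids = [str(c) for c in df.columns[2:]]
    allele_index = list(zip(df[locus_col].astype(str), df[allele_col].astype(str)))
    dupes = pd.Series(allele_index)
    if dupes.duplicated().any():
        first = dupes[dupes.duplicated()].iloc[0]
        raise FormatError(f"duplicate (locus, allele) row: {first}")

    raw = df.iloc[:, 2:].to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    for r in range(raw.shape[0]):
        for c in range(raw.shape[1]):
            cell = str(raw[r, c]).strip()
            if cell == missing_token:
                values[r, c] = np.nan
                continue
            try:
                values[r, c] = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric cell {cell!r} at row {allele_index[r]}, "
                    f"accession {accession_ids[c]!r}"
                ) from None

    if not strict:
        values = _renormalize(values, allele_index, tol)
    return FrequencyTable(accession_ids, allele_index, values)


def _renormalize(values, allele_index, tol):
    loci: dict[str, list[int]] = {}
    for row, (locus, _) in enumerate(allele_index):
        loci.setdefault(locus, []).append(row)
    out = values.copy()
    for rows in loci.values():
        block = out[np.asarray(rows)]
        sums = np.nansum(block, axis=0)
        observed = ~np.isnan(block).all(axis=0)
        fix = observed & (np.abs(sums - 1.0) > tol) & (sums > 0)
        if fix.any():
            block[:, fix] /= sums[fix]
            out[np.asarray(rows)] = block
    return out


_CALL_RE = re.compile(r"^([^/|]+)[/|]([^/|]+)$")


def read_genotype_matrix(path, *, sep: str = ",") -> GenotypeMatrix:
    """Read ``locus,<acc1>,...`` CSV of diploid calls like ``A/B`` (missing ``./.``)."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("expected a locus column plus >=1 accession column")
    locus_ids = [str(v) for v in df.iloc[:, 0]]
    accession_ids = [str(c) for c in df.columns[1:]]
    calls: list[list[tuple[str, str] | None]] = []
    for r, locus in enumerate(locus_ids):
        row: list[tuple[str, str] | None] = []
        for c, acc in enumerate(accession_ids):
            cell = str(df.iat[r, c + 1]).strip()
            if cell == MISSING_CALL or cell == "":
                row.append(None)
                continue
            m = _CALL_RE.match(cell)
            if not m or "." in m.groups():
                raise FormatError(
                    f"malformed genotype call {cell!r} at locus {locus!r}, "
                    f"individual {acc!r}"
                )
            row.append((m.group(1), m.group(2)))
        calls.append(row)
    return GenotypeMatrix(accession_ids, locus_ids, calls)


def genotypes_from_vcf(path, *, split_multiallelic: bool = False) -> GenotypeMatrix:
    """Build a :class:`GenotypeMatrix` from a VCF of single-sample-per-accession GTs.

    Only biallelic SNP records are used; multi-allelic records are split into
    biallelic REF-vs-ALT loci when ``split_multiallelic`` is set, otherwise
    they raise :class:`ValidationError`.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    accession_ids = list(vcf.samples)
    locus_ids: list[str] = []
    calls: list[list[tuple[str, str] | None]] = []
    for rec in vcf:
        alts = [a for a in rec.ALT if a not in (None, ".")]
        if not rec.is_snp:
            continue
        if len(alts) > 1 and not split_multiallelic:
            raise ValidationError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; "
                "pass split_multiallelic=True to split it"
            )
        for k, alt in enumerate(alts, start=1):
            alleles = {0: rec.REF, k: alt}
            row: list[tuple[str, str] | None] = []
            for gt in rec.genotypes:
                a, b = gt[0], gt[1]
                if a < 0 or b < 0:
                    row.append(None)
                elif a in alleles and b in alleles:
                    row.append((alleles[a], alleles[b]))
                else:  # carries some other ALT: unobserved for this split locus
                    row.append(None)
            suffix = f"_{alt}" if len(alts) > 1 else ""
            locus_ids.append(f"{rec.CHROM}:{rec.POS}{suffix}")
            calls.append(row)
    if not locus_ids:
        raise ValidationError("no biallelic SNP records found in VCF")
    return GenotypeMatrix(accession_ids, locus_ids, calls)


def frequencies_from_genotypes(g: GenotypeMatrix) -> FrequencyTable:
    """Derive per-accession allele frequencies from diploid calls.

    Individuals sharing an accession id are pooled: the frequency of an
    allele is its chromosome count over ``2 x`` the accession's non-missing
    individuals at that locus.  A locus is missing in an accession when all
    of its individuals are missing there.
    """
    accessions: list[str] = []
    for a in g.accession_ids:
        if a not in accessions:
            accessions.append(a)
    cols_of = {a: [c for c, x in enumerate(g.accession_ids) if x == a] for a in accessions}

    allele_index: list[tuple[str, str]] = []
    blocks: list[np.ndarray] = []
    for r, locus in enumerate(g.locus_ids):
        alleles: list[str] = []
        for call in g.calls[r]:
            if call is None:
                continue
            for a in call:
                if a not in alleles:
                    alleles.append(a)
        if len(alleles) < 2:
            raise ValidationError(
                f"locus {locus!r} has fewer than 2 observed alleles"
            )
        block = np.full((len(alleles), len(accessions)), np.nan)
        for j, acc in enumerate(accessions):
            counts = dict.fromkeys(alleles, 0)
            n = 0
            for c in cols_of[acc]:
                call = g.calls[r][c]
                if call is None:
                    continue
                n += 1
                counts[call[0]] += 1
                counts[call[1]] += 1
            if n:
                block[:, j] = [counts[a] / (2 * n) for a in alleles]
        allele_index.extend((locus, a) for a in alleles)
        blocks.append(block)
    return FrequencyTable(accessions, allele_index, np.vstack(blocks))


def compact_biallelic(t: FrequencyTable) -> FrequencyTable:
    """Reduce a fully biallelic table to one row per locus.

    The retained row is the first allele of each locus in input order; the
    other allele's frequency is the complement ``1 - value`` wherever data
    are observed.  Scoring on the compacted view with the complement expanded
    is identical to scoring the full table, so this is purely a compact
    storage form.  The single-row "loci" are exposed through a companion
    attribute-free convention: each kept row keeps its locus id and the
    complementary row can be re-expanded with :func:`expand_biallelic`.
    """
    for locus, rows in t.loci.items():
        if len(rows) != 2:
            raise ValidationError(
                f"locus {locus!r} has {len(rows)} alleles; compaction requires "
                "exactly 2 per locus"
            )
    keep = [rows[0] for rows in t.loci.values()]
    view = FrequencyTable.__new__(FrequencyTable)
    view.accession_ids = list(t.accession_ids)
    view.allele_index = [t.allele_index[r] for r in keep]
    view.values = t.values[np.asarray(keep)].copy()
    view.loci = {t.allele_index[r][0]: [i] for i, r in enumerate(keep)}
    return view


def expand_biallelic(view: FrequencyTable, *, second_allele: str = "complement") -> FrequencyTable:
    """Inverse of :func:`compact_biallelic`: re-add the complementary rows."""
    allele_index: list[tuple[str, str]] = []
    rows = []
    for r, (locus, allele) in enumerate(view.allele_index):
        allele_index.append((locus, allele))
        other = second_allele if second_allele != "complement" else f"~{allele}"
        allele_index.append((locus, other))
        rows.append(view.values[r])
        rows.append(1.0 - view.values[r])
    return FrequencyTable(view.accession_ids, allele_index, np.vstack(rows))


def write_scores(path, scores) -> None:
    """Write accession or allele scores as CSV with a deterministic row order.

    ``AccessionScores`` -> ``id,rarity,divergence,n_loci_used``;
    ``SpecificityVector`` -> ``locus,allele,specificity_abs,specificity_rel,
    n_available``.  Values are written at full precision so a round-trip read
    reproduces them bit for bit.
    """
    df = scores.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17g")
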