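import numpy as np
import pytest

from germcore import FrequencyTable, table1_fixture


@pytest.fixture
def table1():
    return table1_fixture()


@pytest.fixture
def table1_csv(tmp_path, table1):
    path = tmp_path / "table1.csv"
    df = table1.to_dataframe().reset_index()
    df.to_csv(path, index=False)
    return path


def random_table(
    rng: np.random.Generator,
    n_accessions: int,
    n_loci: int,
    max_alleles: int = 4,
    missing_rate: float = 0.0,
) -> FrequencyTable:
    """Random complete (or block-masked) table, independent of germcore.synth."""
    allele_index = []
    blocks = []
    for i in range(n_loci):
        k = int(rng.integers(2, max_alleles + 1))
        block = rng.dirichlet(np.ones(k), size=n_accessions).T
        if missing_rate > 0:
            mask = rng.random(n_accessions) < missing_rate
            if mask.all():
                mask[0] = False
            block[:, mask] = np.nan
        allele_index.extend((f"L{i}", f"A{a}") for a in range(k))
        blocks.append(block)
    ids = [f"ACC{j}" for j in range(n_accessions)]
    return FrequencyTable(ids, allele_index, np.vstack(blocks))


# ---------------------------------------------------------------------------
# naive direct-summation oracles: explicit loops, no vectorization, kept
# deliberately independent of the production code paths they check
# ---------------------------------------------------------------------------

def naive_specificity(t: FrequencyTable) -> dict:
    import math

    out = {}
    for r, key in enumerate(t.allele_index):
        vals = [v for v in t.values[r] if not math.isnan(v)]
        n = len(vals)
        p_i = sum(vals) / n
        if p_i == 0 or n < 2:
            out[key] = None
            continue
        s = 0.0
        for v in vals:
            if v > 0:
                s += v / (n * p_i) * math.log2(v / p_i)
        out[key] = s
    return out


def naive_scores(t: FrequencyTable) -> tuple[dict, dict]:
    """(rarity, divergence) per accession id via explicit loops."""
    import math

    spec = naive_specificity(t)
    p_bar = {}
    for r, key in enumerate(t.allele_index):
        vals = [v for v in t.values[r] if not math.isnan(v)]
        p_bar[key] = sum(vals) / len(vals) if vals else None
    rarity, divergence = {}, {}
    for j, acc in enumerate(t.accession_ids):
        r_loc, d_loc = [], []
        for locus, rows in t.loci.items():
            col = [t.values[r][j] for r in rows]
            if all(math.isnan(v) for v in col):
                continue
            r_sum = d_sum = 0.0
            for r, v in zip(rows, col):
                key = t.allele_index[r]
                if spec[key] is not None:
                    r_sum += v * spec[key]
                if v > 0:
                    d_sum += v * math.log2(v / p_bar[key])
            r_loc.append(r_sum)
            d_loc.append(d_sum)
        rarity[acc] = sum(r_loc) / len(r_loc)
        divergence[acc] = sum(d_loc) / len(d_loc)
    return rarity, divergence


def naive_subset_divergence(t: FrequencyTable, ids) -> float:
    """Mean KL divergence of a subset treated as its own universe."""
    _, div = naive_scores(t.subset(list(ids)))
    return float(np.mean(list(div.values())))


def naive_greedy(t: FrequencyTable, size: int) -> list[str]:
    """From-scratch greedy: rarest first, then per-step argmax of the
    subset mean divergence recomputed in full for every candidate."""
    rarity, _ = naive_scores(t)
    current = [max(t.accession_ids, key=lambda a: rarity[a])]
    while len(current) < size:
        best, best_obj = None, -np.inf
        for cand in t.accession_ids:
            if cand in current:
                continue
            _, div = naive_scores(t.subset(current + [cand]))
            obj = float(np.mean(list(div.values())))
            if obj > best_obj:
                best, best_obj = cand, obj
        current.append(best)
    return current
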