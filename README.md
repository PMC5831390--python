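# germcore

Information-theoretic diversity scoring and core-subset selection for
germplasm collections.

Genebanks conserve thousands of accessions — landraces, breeding lines, wild
relatives — typed at thousands of molecular markers. Curators and breeders
need two things from such data: a way to find the *rare* material (accessions
carrying alleles found almost nowhere else) and a way to distil the
collection into a small, maximally diverse *core subset*. `germcore`
implements both on a single footing: Shannon information on within-accession
allele frequencies.

## The model

The input is a table of within-accession allele frequencies
`p_ij` ∈ [0, 1] — allele *i* (rows, grouped by locus) within accession *j*
(columns, *N* accessions), with an equiprobable prior over accessions.
Everything below is a plug-in estimate in bits (log base 2), with
0·log 0 = 0.

- **Allele specificity** — the mutual information between accession identity
  and the event that a random copy of allele *i* was drawn:

  `S_i = Σ_j p_ij / (N p̄_i) · log2(p_ij / p̄_i)`,  `p̄_i = mean_j p_ij`.

  `S_i = 0` for a monomorphic allele; `S_i = log2(N)` for a private allele
  (one carried by a single accession). With missing data, *N* and `p̄_i` use
  only the accessions where the allele's locus was scored, so the ceiling
  drops to `log2(n_available)`; the *relative* specificity
  `S_i / log2(n_available)` undoes that penalty.

- **Accession rarity** — the frequency-weighted mean specificity of the
  alleles an accession carries, `R_j = Σ_i p_ij S_i` per locus, averaged
  over loci.

- **Accession divergence** — the Kullback–Leibler divergence of the
  accession's allele-frequency distribution from the collection average,
  `D_j = Σ_i p_ij log2(p_ij / p̄_i)` per locus, averaged over loci.

- **Identity** — on complete data, mean rarity, mean divergence and the
  locus-averaged `Σ_i p̄_i S_i` are all the same number: the mutual
  information `I(X; M)` between accessions and marker alleles.

- **Core selection (HCore)** — a greedy maximization of within-subset mean
  divergence. Rarity is context-relative (an accession rare in the full
  collection need not be rare inside a small core), so simply taking the
  top-*k* rarest accessions is not optimal; instead the core starts from the
  rarest accession and repeatedly adds whichever candidate maximizes the
  subset's mean divergence, with the reference frequencies recomputed within
  the subset (exactly up to a configurable core size, then via running-mean
  approximation for speed on large collections).

- **Evaluation** — a subset is scored against its parent on mean divergence,
  mean pairwise Modified Rogers distance, pooled Shannon diversity, allele
  richness and lost alleles.

## Worked example

The built-in toy collection has four accessions (A1–A4) typed at three
biallelic loci; A4 carries a private allele at Locus 2.

```python
>>> from germcore import table1_fixture, allele_specificity, accession_scores
>>> t = table1_fixture()
>>> s = allele_specificity(t)
>>> round(s[("Locus2", "Allele1")], 3)   # private allele: the log2(4) maximum
2.0
>>> round(s[("Locus2", "Allele2")], 3)   # the least specific allele
0.415
>>> sc = accession_scores(t, s)
>>> [round(sc.rarity_of(a), 3) for a in t.accession_ids]
[0.732, 0.631, 0.631, 1.361]
>>> [round(sc.divergence_of(a), 3) for a in t.accession_ids]
[0.487, 0.698, 0.698, 1.472]
```

A4's private allele gives it both the top rarity (1.361 bits) and the top
divergence (1.472 bits); A1 is the least divergent yet second rarest —
the two scores emphasize different things. Greedy selection accordingly
seeds the core with A4:

```python
>>> from germcore import select_core
>>> select_core(t, size=2, mode="exact").selected
['A4', 'A3']
```

The same workflows are available from the shell:

```sh
germcore simulate --seed 7 --config synth.yaml --out freq.csv --manifest truth.json
germcore score --in freq.csv --out-prefix scores
germcore core --in freq.csv --size 20 --mode auto --out core.csv
germcore evaluate --in freq.csv --subset core.csv --out report.json
```

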