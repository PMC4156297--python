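# phylodiscord

Tools for diagnosing **discordant genetic signal** among closely
related taxa — the situation where nuclear and plastid gene trees
disagree, alleles transcend species borders, and it is unclear whether
hybridization, incomplete lineage sorting (ILS), or a simple paucity of
informative sites is responsible.

The package targets the classic two-marker sampling design of plant
phylogeography: a multi-copy biparental nuclear marker
(ITS1–5.8S–ITS2) sequenced directly, so that intra-individual
polymorphism shows up as IUPAC ambiguity codes, plus a uniparental
plastid spacer (e.g. *rpl32*–*trnL*). It provides, as one pipeline or as
independent library calls:

- **IPS/APS analysis** — detect intra-individual polymorphic sites
  (IPS) and classify additive polymorphic sites (APS): an ambiguity
  code at a column is additive when each constituent base occurs
  unambiguously in another accession at the same column, the signature
  of two parental ribotypes in one genome. Datasets can be split into
  APS-free and APS-bearing subsets.
- **Fitch parsimony** — site classification, tree length `L = Σ sᵢ`,
  consistency index `CI = Σmᵢ/Σsᵢ` and retention index
  `RI = (Σgᵢ−Σsᵢ)/(Σgᵢ−Σmᵢ)`, heuristic MP search (random addition +
  SPR; exhaustive for ≤ 7 taxa), bootstrap support, and the
  incongruence length difference (ILD) permutation test with
  `D = L(A∪B) − L(A) − L(B)`.
- **Split spectra** — classify columns supporting a bipartition as
  symmetric, asymmetric, or noisy, and tabulate per-split spectra.
- **Statistical-parsimony haplotype networks** — collapse sequences to
  haplotypes and connect them by single-mutation steps up to a fixed
  connection limit, inserting inferred unsampled intermediates and
  keeping equal-length alternative connections (loops).
- **Likelihood topology tests** — per-site log-likelihoods by
  Felsenstein pruning under JC69/K80/HKY85/SYM/TVM/GTR (+Γ, +I),
  branch-length optimization, and RELL-based weighted
  Kishino–Hasegawa (WKH) and weighted Shimodaira–Hasegawa (WSH) tests
  of constrained versus best topologies.
- **Coalescent hybridization test** — multispecies-coalescent
  simulation over a posterior sample of species trees annotated with
  per-branch population sizes θ (pair coalescence rate 1/(θ·h), with
  heredity scalar h), and the posterior-predictive minimum-distance
  test: `p = #{simulated min inter-species distance ≤ observed}/n_sim`.
  Small p flags species pairs whose sequences are too similar for ILS
  without migration — the test that separates hybridization from ILS.
- **Synthetic studies** — a generator producing complete two-locus
  studies with known truth (species tree, ILS, optional hybridization
  pulses, ribotype mixing with tunable concerted-evolution
  homogenization), so every stage is testable without external data.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Generate a synthetic study (4 ingroup species, 3 individuals each, a
divergent outgroup, ITS-like and cpDNA-like loci) and analyse it:

```sh
phylodiscord simulate --outdir study --n-species 4 --samples 3 \
    --homogenization 0.3 --seed 42
phylodiscord polymorphism study/ITS.fasta --taxon-map study/taxon_map.tsv
```

```json
{
  "columns": 653,
  "polymorphic_columns": 65,
  "max_ips_per_sequence": 26,
  "aps_columns": 33,
  "max_aps_per_sequence": 23,
  "aps_bearing_sequences": 6
}
```

Of the 653 ITS columns, 65 carry an ambiguity code in at least one
ingroup individual (up to 26 in a single sequence); at 33 of those
columns the code is additive, and 6 individuals carry at least one APS
— these are the accessions whose genomes look like unhomogenized
mixtures of two parental ribotypes, and the ones an APS-free tree
analysis would set aside.

```sh
phylodiscord network study/cpDNA.fasta --taxon-map study/taxon_map.tsv --limit 30
```

```json
{
  "n_sampled": 7,
  "n_inferred": 17,
  "n_edges": 23,
  "n_components": 1,
  "total_frequency": 12,
  "path_length_counts": {"1": 2, "3": 2, "4": 2, "6": 2, "...": "..."}
}
```

The 12 ingroup plastid sequences collapse to 7 haplotypes, all
connected within the 30-step limit through 17 inferred unsampled
intermediates; the path-length spectrum shows how many mutational
steps separate each sampled pair.

The full pipeline (`phylodiscord report`) chains these with the
parsimony statistics, the ILD test between loci, split spectra, RELL
topology tests and — given a posterior file of annotated species trees
— the hybridization test, writing tab-separated tables plus one
`summary.json` per run. `phylodiscord validate DIR` recomputes dataset
statistics (sequence counts, variable/informative sites, polymorphism
counts, haplotype counts) from alignment files supplied in `DIR` and
tabulates them against published reference values.

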