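# repsubsets

Quantitative analysis of human T-cell differentiation across tissues:
marker-based subset phenotyping with cohort age-trend statistics, and TCRα
repertoire clonality/overlap analysis with subsample-to-smallest resampling
normalization.

The package is aimed at immunologists working with (a) per-cell boolean
marker calls exported from flow-cytometry gating and (b) clonotype tables
from AIRR-seq pipelines (AIRR Rearrangement TSV or immunoSEQ-style exports).
Because the kind of donor data this analysis was designed for is typically
not publicly depositable, the package ships a first-class synthetic-data
generator that emulates the cohort and repertoire structure, providing
ground truth for every stage.

## What it computes

**Subset phenotyping.** Each cell's boolean marker vector is classified into
the five differentiation subsets from the CD45RA × CCR7 quadrant, with CD95
splitting the double-positive quadrant:

| subset | CD45RA | CCR7 | CD95 |
|---|---|---|---|
| naive | + | + | − |
| SCM (stem cell memory) | + | + | + |
| CM (central memory) | − | + | |
| EM (effector memory) | − | − | |
| EMRA | + | − | |

CD27/CD28 are recorded but never discriminate. Recent thymic emigrants
(RTE) are CD21⁺ naive cells. Groups with fewer than 100 cells per
(donor, tissue, compartment) are excluded from frequency tables. An
alternative CD62L-concordant *sorting* scheme is provided; CCR7/CD62L
discordant cells are left unassigned.

**Repertoire statistics.** For clone sizes n₁…n_R with N = Σ nᵢ:

- Simpson's diversity D = Σ nᵢ(nᵢ−1) / (N(N−1)) — the probability that two
  cells drawn without replacement share a clonotype;
- Simpson's clonality √D — 0 for fully polyclonal, 1 for monoclonal;
- Jaccard index J(A,B) = |A∩B| / |A∪B| on unique clonotype key sets.

Both depend on sampling depth, so repertoires in a comparison are
normalized by repeatedly subsampling the larger ones — uniformly, without
replacement, at the level of unique clonotypes, template counts retained —
to the unique-clonotype count of the smallest repertoire (100 000
iterations by default) and averaging. Productive and nonproductive
rearrangements are partitioned and analyzed separately: nonproductive
sequences are not expressed and hence not selected, so their sharing
between sorted subsets marks common clonal origin.

**Cohort statistics.** Spearman rank correlations of subset frequencies
against donor age, Kruskal–Wallis comparisons across tissues, and
median/IQR summaries.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_subset_frequencies_trends.py --seed 1
python analysis/03_repertoire_clonality.py --seed 1
python analysis/04_clonal_overlap.py --seed 1
```

prints (seed 1):

```
wrote scratch/cohort_cells.tsv: 192000 cells, 12 donors aged 1.9-63.7 y, ...
blood CD4 naive frequency: median 45.6% (IQR 28.5-53.2%)
naive CD4 blood vs age: rho = -0.895, p = 0.0001 (n = 12)
spleen CD8 memory CD21+: median 22.8% (IQR 21.9-23.7%)
CD4 clonality ranking (k=500): EM > CM > naive > SCM
CD8 clonality ranking (k=300): EM > EMRA > SCM > naive
CD4 nonproductive: CM-EM overlap 0.0025 vs max naive-memory 0.0001 (ordering recovered)
CD8 nonproductive: EM-EMRA overlap 0.0099 vs max naive-memory 0.0001 (ordering recovered)
```

Reading the output: the simulated cohort shows the age-dependent
replacement of naive CD4⁺ cells by memory subsets (strongly negative
Spearman rho), a stable CD21⁺ fraction among splenic CD8⁺ memory cells,
the highest clonality in effector-memory repertoires with naive and SCM
near-polyclonal, and clonotype sharing concentrated between memory subsets
— in the nonproductive as well as the productive repertoire, the signature
of shared clonal origin. Tidy TSV tables land in `results/`.

The same operations are available as a CLI for real data:

```sh
repsubsets convert   --in export.tsv --dialect immunoseq --out rep.tsv
repsubsets phenotype --cells cells.tsv --scheme analysis --out cohort.tsv
repsubsets trends    --cohort cohort.tsv --stat spearman --out trends.tsv
repsubsets diversity --in a.tsv --in b.tsv --k auto --iters 100000 --seed 1 --out div.tsv
repsubsets overlap   --in a.tsv --in b.tsv --iters 100000 --seed 1 --out ovl.tsv
repsubsets demo      --seed 1        # scaled end-to-end smoke run
```

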