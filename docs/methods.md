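# Methods

## Model and assumptions

`smorfpred` treats a smORF's RNA abundance as observable only through the
microarray probe sets whose probes physically overlap it. The model makes
three assumptions:

1. **Shared signal.** A probe set's summarised signal is a mixture of the
   transcripts its probes cover. The fraction of the set's retained probes
   that overlap a smORF (the weight `w ∈ (0, 1]`) is used as the fraction of
   the linear-scale signal attributed to the smORF. Weights for different
   smORFs covered by the same probe set are deliberately *not* normalised to
   sum to one: overlapping transcripts genuinely share signal.
2. **Rank sufficiency.** All downstream inference is rank-based (Spearman),
   so only the ordering of a smORF's expression across samples matters. This
   makes predictions invariant to the weight scale (scaling every surviving
   weight by `c > 0` shifts `E` by `log2 c` uniformly) and to any strictly
   increasing per-feature transform of expression. Both invariances are
   enforced by tests.
3. **Guilt by association.** Genes strongly co-expressed with a smORF share
   its functional context, so enrichment of the correlated-gene list against
   curated gene sets yields candidate functions, pooled across datasets.

## Pipeline and parameters

| parameter | default | meaning |
|---|---|---|
| `max_hits` | 100 | probes with ≥ this many exact genomic matches are discarded as ambiguous (retention requires ≥1 and <100 matches) |
| `weight_min` | 0.1 | annotations with `w ≤ 0.1` are excluded from quantification (strict `w > 0.1`) |
| `estimator` | median | summary of the weighted linear-scale signals; even counts interpolate (mean of the two middle values); mean and max are alternatives |
| `leaf_size` | 5 | BallTree leaf size |
| `k` | 1000 | maximum correlated genes retained per dataset |
| `rho_min` | 0.5 | Spearman threshold for a correlated gene (positive correlations only) |
| `p_max`, `fdr_max` | 0.05, 0.2 | selection rule for predicted functions |
| `fdr_family` | per-collection | BH family: within each gene-set collection, or `all` jointly |

Coordinates are 0-based half-open (BED) everywhere; probe–smORF
intersection requires ≥1 shared base and ignores strand, matching the
default behaviour of standard interval tools. Probe matching covers both
strands (reverse-complement hits reported on `−`); a palindromic probe's
reverse-complement occurrence is the same genomic locus and is reported
once. smORFs are single contiguous intervals of ≤303 nt (100 codons +
stop); multi-exon smORFs are out of scope.

## Numerical choices

- **Exact tree search.** `1 − ρ` violates the triangle inequality, so the
  BallTree is built on centred, unit-norm rank vectors under the Euclidean
  metric (`d² = 2(1 − ρ)`, a strictly decreasing function of ρ). Candidates
  from a radius query (radius padded by 1e-7) are re-scored by the exact dot
  product of standardised rank vectors. Scoring uses per-row 1-D dot
  products rather than one matrix–vector product, because BLAS results can
  differ in the last ulp with operand shape; this makes tree and brute-force
  hit lists bit-identical.
- **Tie-breaks.** Hits are ordered by ρ descending, then gene id ascending;
  ties at the k-th place resolve lexicographically, so output is
  reproducible across platforms and search strategies.
- **Degenerate rows.** Zero-variance (constant) features carry no rank
  information: they are excluded from the index *and* from the enrichment
  background, and listed in the run metadata. Rows with <3 samples or
  non-finite values are rejected with a diagnostic; a zero-variance query is
  an error, never silently ρ = 0.
- **Hypergeometric tail.** Computed in-package via log-gamma and
  `logsumexp`; exhaustive enumeration (all `C(T, N)` draws for `T ≤ 12`)
  and `scipy.stats.hypergeom.sf` serve as independent cross-checks in the
  tests. Relative agreement with enumeration is at machine precision
  (~4e-15 over 3094 cases).
- **Pooling.** Multi-dataset evidence pools the *counts*, never the
  p-values (no Fisher combination): the pooled p is the tail at
  (ΣI, ΣM, ΣN, ΣT). Datasets where the smORF is unquantifiable contribute
  nothing (not zeros); terms absent from a dataset's background are skipped
  there rather than reported with p = 1, keeping the BH family meaningful.
- **BH FDR** delegates to `statsmodels.multipletests(method="fdr_bh")` and
  is checked against a hand-rolled step-up oracle. Note that BH is not
  idempotent in general (re-adjusting an adjusted list can raise values);
  the guaranteed properties — adjusted ≥ raw, order-monotone — are tested
  instead.

## Open design points and how they were resolved

- *Weight denominator.* "All remaining probes of the set" is read as the
  probes surviving the match filter (the default); dividing by the set's
  original probe count is available via `denominator="all"` for users whose
  platforms annotate that way.
- *FDR family.* With no authoritative convention, BH is applied within each
  collection by default — collections differ hugely in size and are usually
  browsed separately — with a joint `all` switch.
- *Even-count medians* interpolate, matching the convention of mainstream
  statistical environments.
- *Query resolution.* smORFs can be looked up by id, by exact sequence
  against the genome, or by coordinate overlap (first by start, then id,
  when several overlap). Fuzzy/alignment-based lookup is out of scope.

## The synthetic benchmark

The fixture generator emulates every input the pipeline consumes, with
planted ground truth at two layers.

**Platform layer.** A genome is assembled from the probe sequences
themselves: per smORF, a 10-probe set laid contiguously with the smORF
covering the first 8 probes (true weight 0.8); decoy sets contribute exactly
one straddling probe (true weight 0.1, dropped by the threshold); one probe
is planted in exactly 100 tandem copies of an aperiodic 25-mer (rejected by
the <100-matches rule); one probe never matches and one contains a non-ACGT
character. Reannotation must recover the truth table exactly.

**Expression layer.** Planted co-expression uses a Gaussian copula: a
module's member genes and its smORF load on a shared latent factor with
loading `√r`, where `r = 2·sin(π·ρ*/6)` is the Pearson correlation that
yields Spearman ρ* for bivariate Gaussians. smORF probe-set rows repeat the
smORF latent plus small probe noise (sd 0.1); values are placed on a
log2-like scale (baseline 7, sd 1); 10% of entries are rounded to one
decimal to exercise the mean-rank tie path; the first ten genes get
duplicate probe sets to exercise median aggregation of duplicate gene ids.
All randomness derives child streams from one seed; identical seeds give
byte-identical bundles.

**Default study conditions** (used by the benchmark tests and
`scripts/acceptance.py`): 2000 background genes, 40 gene sets of 50 genes,
3 datasets × 60 samples, one module at ρ* = 0.8. Under these conditions the
planted term is selected in ≥90% of 50 replicates (observed 100%) and in
≤10% under ρ* = 0 (observed 0%). These problem sizes keep a full benchmark
run under a minute; they are scaled-down study conditions, not estimates of
real-archive behaviour.

**What the generator does not model** — probe affinity differences, batch
effects, array saturation, correlated noise between decoy sets, multi-exon
smORFs, or platform-specific probe chemistry. Passing the benchmark
demonstrates correctness of the algorithms and their filters under the
stated generative model, not performance on real archives, where weaker and
confounded correlations will lower recovery.

## Known limitations

- Probe matching is exact; probes crossing splice junctions or carrying
  mismatches are not recovered.
- A smORF inside a highly expressed host transcript inherits the host's
  profile; the weight model cannot deconvolve co-located transcripts.
- Pooling counts across datasets assumes comparable backgrounds; datasets
  with very different platforms dilute each other.
- Negative correlations are ignored by default (`rho_min = 0.5 > 0`);
  repressive relationships are invisible to the predictor.
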